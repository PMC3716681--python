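# Methods

This note documents the models, defaults and design choices behind `rdcnv`:
what the estimator assumes, what the simulator does and does not emulate, and
which decisions were genuinely open.

## Copy-number estimation

The read-depth model assumes depth in a 1 kb bin is proportional to the
underlying copy number once two nuisance effects are removed: GC-dependent
amplification bias and reduced effective mappability in repeat-masked
sequence.

**Mappability normalization.** Raw depth of a bin with masked fraction `m` is
rescaled by `1/(1−m)` before any estimation, on the model that masked bases
contribute no uniquely alignable depth. Bins with `m > 0.8` (configurable
`mask_max`) are excluded outright: they carry an explicit excluded flag, never
a silent CN 0, and cannot seed baselines, correction factors or MCR chains.

**Two-stage diploid baseline.** No prior diploid map is assumed. Stage one
averages raw depth over bins intersecting 1:1 orthologous genic regions
(≥ 200 supporting non-excluded bins required, else a named
`BaselineUnstableError`). Because coding sequence is GC-atypical, stage two
re-derives a genome-wide diploid set: all non-excluded bins whose provisional
CN `2d/D` lies in `[1.5, 2.5]`. The window bounds are a package decision —
wide enough to capture diploid depth at ±25 % noise, narrow enough to exclude
single-copy gains/losses — and are exposed as `diploid_window`.

**GC correction.** Factors are estimated on the diploid set in GC intervals
of width 0.01 with a minimum support of 50 bins per interval; sparse
intervals are merged with their nearest populated neighbour (ties to lower
GC) before factors are computed, and a single-populated-interval degenerate
case produces an all-ones table with a warning. Interval width and support
are decisions, not reconstructions of any published table. On simulated data
with the linear bias g(GC) = 1 + 0.5 (GC − 0.4), correction reduces the
depth-on-GC regression slope by two orders of magnitude and leaves
|corr(depth, GC)| ≈ 0.001 on the diploid set.

*Known limitation:* because the diploid set is selected by thresholding
GC-biased raw depth, the per-interval truncated means carry a small
GC-dependent selection bias (~1–3 % residual trend at the GC extremes when
measured on held-out truth-diploid bins). It is negligible for calling at
the CN > 3 threshold but would matter for sub-0.1-copy precision work.

**Sex handling.** Male X bins outside the pseudo-autosomal region are doubled
(`CN = 2·(2d)/D`); PAR bins follow the autosomal rule. Male X non-PAR bins
fall out of the diploid window automatically, so mixed-sex cohorts need no
special-casing upstream.

## MCR chaining

Bins qualify when estimated CN ≥ 1 (a pre-filter: sub-haploid bins cannot be
gains and usually flag mapping artifacts) and their half-up-rounded CN is
≥ 4 — the CN > 3 rule applied to the rounded estimate, which avoids
noise-driven run breaking exactly at the threshold. A continuous mode
(strictly CN > 3 on the raw estimate) is exposed for sensitivity analysis.
Runs must span ≥ 6 kb; `max_gap_bins` (default 0, strict contiguity) allows
bridging interior below-threshold or excluded bins when set. Rounding is
half-up (`floor(cn + 0.5)`), not banker's rounding, so an estimate of
exactly 3.5 chains.

## CNVR calling

MCR intervals from all individuals merge by single-linkage union; book-ended
(shared-boundary) intervals merge, keeping bin-aligned fragments of one
event together, and merged coordinates are not re-trimmed. The CN matrix
uses continuous (unrounded) CN so the dispersion statistic is not
quantization-inflated, and every individual gets a value in every region
(individuals without an MCR there contribute their ≈ 2). The calling
statistic is the sample standard deviation (n−1 denominator; the n vs n−1
choice is a documented decision covered by an explicit boundary test) with
an inclusive ≥ 0.7 threshold. Fewer than two individuals is a hard error.

## Gene annotation

Gene-level reporting applies three filters in order: union-coverage of the
gene body by CNVRs ≥ 0.70 (inclusive); exonic CN > 2 (strict) in at least
one individual; exonic-CN sample s.d. ≥ 0.5 (inclusive) across individuals.
Exon depth is aggregated by bin-overlap weighting — each exonic base
contributes its bin's GC-corrected depth, reusing the genome-wide correction
table rather than refitting on exons — a resolution compromise, since depth
exists here per bin, not per base. The exon screen exists to reject CNVRs
riding on high-copy sequence outside a gene's coding parts. Term enrichment
is a generic upper-tail hypergeometric test against a caller-supplied
background with Benjamini–Hochberg correction; no ontology-graph propagation
is performed (term→gene mapping is a flat two-column table).

## Genomic context

Association statistics use fixed-width 10 kb intervals: one flank on each
side of every region (clipped at chromosome ends and flagged), and a
background "other" set defined as the 10 kb tiling of the genome excluding
the flank sets and the source regions — the natural complement, configurable
in principle to random sampling. Repeat-family density is bases per
interval, counted against the interval union so record fragmentation cannot
change the answer. Enrichment is a two-sided Fisher exact test on
family-vs-other base counts; the p-value is computed in-package from
log-gamma hypergeometric probabilities summed over the full support, with a
chi-square fallback when the support is too large to enumerate (base-level
2×2 tables can have margins in the millions). Whether base counts or
interval counts are the right unit is a judgement call; base counts were
chosen and flagged. SD association counts a segmental duplication when it
overlaps any CNVR expanded by 10 kb on both sides (distance ≤ 10 kb or
overlap), reported both at full precision and truncated to one decimal. GC
contrast compares mean bin GC (as a percent) inside CNVRs and their flanks
against all remaining bins.

## Group comparison

A balanced subset (default 3 per group, seed-controlled, error if a group is
smaller) feeds a complete re-run of merge → matrix → s.d.-call within each
group's members only, and within any requested union of groups. A union's
set is computed from the union's members, not by uniting per-group sets —
the two differ whenever a region is fixed within groups but different
between them, and a test documents exactly that case. A group CNVR is
"specific" when it overlaps (≥ 1 base) no CNVR of any other group; the
specificity ratio is specific/total rounded to two decimals, the only
definition simultaneously consistent with both worked ratio examples
(277/2289 → 0.12, 151/2084 → 0.07). Per-group gene statistics report, across
a group's members, the mean and s.d. of the per-individual count of
final-filtered genes whose own exonic CN exceeds 2 — the package's reading
of a "cumulative gene count" per group.

## The synthetic cohort

The simulator emulates the study design the pipeline targets: 16 individuals
in four groups (3 Asian wild, 5 Asian domestic, 3 European wild, 5 European
domestic) with per-individual coverages spanning 7.1–11×, on a ~20 Mb
genome of four autosomes plus an X with a 200 kb PAR, in 1 kb bins.

* **GC landscape:** a bounded AR(1) process per chromosome (mean 0.42,
  lag-1 correlation 0.98, stationary s.d. 0.05, clipped to [0.2, 0.7]) —
  realistic autocorrelation without modelling sequence. Regions destined for
  gain events run 1.5 GC percentage points low over the typical event
  footprint and its flank, reproducing the empirical tendency of CNVRs to
  sit in GC-poor sequence.
* **Events:** gains only by default (CN losses exist behind an off-by-default
  flag, mirroring their exclusion from analysis as false-positive-prone at
  these coverages). Integer CN in [4, 10] by default (real multi-copy genes
  reach CN ≈ 30; values ≥ 4 guarantee events clear the CN > 3 threshold,
  with CN exactly 4 as the boundary-stress case). Sizes are
  6 kb + Exp(7 kb) truncated at 122 kb and floored to whole bins — mean
  ≈ 13 kb. Scopes are shared (all individuals, one CN — hence truth s.d. 0,
  never a CNVR), group (all members of one group) and private (one
  individual). Events occupy pre-reserved, mutually disjoint autosomal
  "event sites" that never intersect ortholog genes, so the diploid anchor
  stays clean; reserving sites at build time also lets segmental
  duplications, boosted repeat families and a fraction of genes be placed in
  or near future event footprints, giving the context and gene analyses
  real signal.
* **Depth:** reads per bin are negative-binomial with mean
  (coverage/2) · CN · g(GC) · (1 − masked_frac) · bin_size/read_length and
  variance μ(1 + φμ); φ = 0.005 by default, giving ≈ 13 % depth CV at 8×
  — the mild over-dispersion of a well-behaved short-read library — with
  the Poisson limit at φ = 0. The default injected bias is the linear
  g(GC) = 1 + 0.5 (GC − 0.4). Masking attenuates depth multiplicatively;
  exclusion happens downstream in estimation, not in the generator.
* **What it does not emulate:** real read alignment (multi-mapping,
  edit-distance artifacts), base-level sequence, breakpoint microhomology,
  CN losses below 2, inter-individual coverage waviness, or batch effects.
  Passing recovery tests therefore demonstrates correctness of the
  estimation/calling chain under the stated noise model, not robustness to
  alignment pathology.

All randomness flows through seeded `numpy` generators; identical
(config, seed) pairs reproduce bit-identical genomes, truths and depth
tracks.

## Evaluation experiment sizes

The standard experiments (`rdcnv.evaluate`) run the full 16-individual
pipeline on the ~20 Mb default genome: the recovery study uses 50 truth
events (10 shared / 24 group / 16 private; sizes 6–60 kb, CN 4–10) and scores the
fraction of analytically polymorphic events (truth-CN s.d. ≥ 0.7 across the
cohort) recovered by an overlapping called CNVR, plus the median per-side
boundary error in bins; the null study repeats the event-free pipeline over
20 seeds and reports the fraction with zero CNVRs; the GC study quantifies
depth-GC decorrelation on one individual. Together they complete in well
under a minute on one CPU, which is what makes them usable as acceptance
checks.

## Degenerate inputs

Zero-depth individuals, all-masked chromosomes, empty diploid windows,
single-interval GC tables, sub-bin MCR length requests, single-individual
matrices, empty interval sets in enrichment, and test genes missing from an
enrichment background all fail loudly with named exceptions
(`rdcnv.errors`) rather than propagating zeros or NaNs.
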