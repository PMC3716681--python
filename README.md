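# rdcnv — read-depth copy-number analysis for multi-individual genomes

`rdcnv` implements a whole-genome, read-depth (RD) copy-number pipeline for
cohorts of re-sequenced diploid individuals, of the kind used to map copy
number variable regions (CNVRs) in livestock and wild populations. It is
aimed at researchers who have per-bin sequencing depth for a modest cohort
(tens of individuals at roughly 7–11× coverage) and want a tested,
reproducible path from depth to a population CNVR catalog — plus a synthetic
cohort simulator so every stage can be benchmarked against known truth.

## The method

Depth is averaged in 1 kb non-overlapping bins. For each individual:

1. **Diploid baseline, two stages.** The mean depth `D` over 1:1 orthologous
   genic regions (a putatively diploid anchor set) seeds a provisional copy
   number `2·d_b/D` per bin; all bins falling in a diploid window
   (default [1.5, 2.5]) then form a genome-wide diploid set, breaking the
   elevated-GC composition of coding regions.
2. **GC correction.** Per-GC-interval factors
   `f_i = mean(d | diploid) / mean(d | diploid, GC ∈ i)` (interval width
   0.01) rescale every bin's depth; the baseline is re-estimated on the
   corrected track.
3. **Copy number.** `CN_b = 2·d_b^corr / D`, with male X bins outside the
   pseudo-autosomal region doubled so male and female tracks are comparable.
4. **Multi-copy regions (MCRs).** Bins with rounded CN ≥ 4 (the CN > 3 rule)
   are chained; runs ≥ 6 kb become MCRs.
5. **CNVRs.** All individuals' MCRs are merged by single-linkage union;
   every individual's mean CN over every merged region forms a
   region × individual matrix, and regions with sample s.d. ≥ 0.7 across
   individuals are CNVRs.

Downstream reports annotate CNVRs with genes (≥ 70 % overlap, exonic CN > 2
in ≥ 1 individual, s.d. ≥ 0.5, hypergeometric term enrichment with
Benjamini–Hochberg correction), quantify association with segmental
duplications and repeat families in 10 kb flank intervals (Fisher exact
tests on base counts), contrast GC content, and re-run the CNVR caller
within balanced population groups to split catalogs into shared versus
group-specific regions.

## Worked example

```python
from rdcnv import build_genome, default_cohort, simulate_truth, catalog_stats
from rdcnv.simulate import CnvParams
from rdcnv.evaluate import run_cohort_pipeline

genome = build_genome(seed=1)                       # ~20 Mb, 1 kb bins, 4 autosomes + X
cohort = default_cohort()                           # 16 individuals, 4 groups, 7.1-11x
truth  = simulate_truth(genome, cohort, CnvParams(), seed=1)
cnvrs, cn_tracks, mcrs, extras = run_cohort_pipeline(genome, cohort, truth, seed=1)

stats = catalog_stats(cnvrs, genome.grid)
print(f"{stats['count']} CNVRs, mean size {stats['mean_size']/1e3:.1f} kb, "
      f"total {stats['total_mb']:.2f} Mb ({stats['genome_fraction_pct']:.2f}% of the genome)")
print(cnvrs[["chrom", "start", "end", "size", "sd"]].head(3).to_string(index=False))
```

prints

```
39 CNVRs, mean size 10.6 kb, total 0.41 Mb (2.06% of the genome)
chrom   start     end  size       sd
 chr1  218000  225000  7000 1.872122
 chr1  821000  833000 12000 0.957855
 chr1 1008000 1014000  6000 0.780699
```

Each CNVR row is a merged cross-individual region with its size and the
sample standard deviation of copy number across the 16 individuals — the
statistic that separates genuinely variable regions from fixed multi-copy
sequence (a region at the same elevated CN in everyone has s.d. 0 and is
never called). The full pipeline, with all per-stage reports and a manifest
recording every threshold and seed, runs as

```bash
rdcnv run-all --out runs/demo --seed 1
```

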