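"""Synthetic multi-individual genome, truth copy-number and depth simulator.

This module generates everything the downstream pipeline consumes, emulating a
re-sequencing study of 16 diploid individuals in four population groups
(Asian/European x wild/domestic) at 7-11x coverage:

* a binned reference genome with an autocorrelated GC landscape, repeat
  elements (driving a per-bin masked fraction), genes with exons (a subset
  flagged as cross-species 1:1 orthologs, the pipeline's diploid anchor),
  segmental duplications, and a pseudo-autosomal region on X;
* per-individual ground-truth copy-number profiles with gain events of 6-122 kb
  (mean ~13 kb) that are shared, group-specific or private;
* noisy, GC-biased raw depth tracks (negative-binomial read counts per bin).

Truth gain events are placed at pre-reserved autosomal "event sites" chosen at
genome build time, which lets segmental duplications and selected repeat
families be enriched near future copy-number variants so that the genomic
context analyses have signal to find. Event sites never intersect ortholog
genes, preserving the diploid anchor.
"""

from __future__ import annotations

import math
from collections.abc import Callable, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidConfigError, PlacementError
from .grid import BinGrid

__all__ = [
    "ChromSpec",
    "RepeatFamilyConfig",
    "GenomeConfig",
    "IndividualSpec",
    "CnvParams",
    "TruthEvent",
    "TruthCnProfile",
    "DepthTrack",
    "GenomeAnnotations",
    "SyntheticGenome",
    "GROUPS",
    "default_cohort",
    "build_genome",
    "simulate_truth",
    "simulate_depth",
    "expected_depth",
    "linear_gc_bias",
    "flat_gc_bias",
]

GROUPS = ("AsianWild", "AsianDomestic", "EuropeanWild", "EuropeanDomestic")

MASK_EXCLUDE_DEFAULT = 0.8  # bins masked above this fraction are excluded downstream


# --------------------------------------------------------------------- config
@dataclass(frozen=True)
class ChromSpec:
    name: str
    length: int
    is_x: bool = False


@dataclass(frozen=True)
class RepeatFamilyConfig:
    """One repeat family: how many elements, their size range, and how strongly
    they cluster in the 10 kb neighbourhood of future CNV event sites
    (``near_event_boost`` = fraction of elements placed in event-site flanks)."""

    count: int
    min_len: int
    max_len: int
    near_event_boost: float = 0.0


def _default_chromosomes() -> tuple[ChromSpec, ...]:
    # ~20 Mb genome: four autosomes plus X, all multiples of the 1 kb bin.
    return (
        ChromSpec("chr1", 6_000_000),
        ChromSpec("chr2", 5_000_000),
        ChromSpec("chr3", 4_000_000),
        ChromSpec("chr4", 3_000_000),
        ChromSpec("chrX", 2_000_000, is_x=True),
    )


def _default_repeats() -> dict[str, RepeatFamilyConfig]:
    return {
        "LINE-L1": RepeatFamilyConfig(400, 500, 6_000, near_event_boost=0.5),
        "SINE-tRNA-Glu": RepeatFamilyConfig(600, 100, 400),
        "LTR-ERV1": RepeatFamilyConfig(150, 300, 3_000, near_event_boost=0.5),
        "Satellite": RepeatFamilyConfig(40, 2_000, 5_000, near_event_boost=0.4),
    }


@dataclass(frozen=True)
class GenomeConfig:
    """Parameters of the synthetic reference genome."""

    chromosomes: tuple[ChromSpec, ...] = field(default_factory=_default_chromosomes)
    bin_size: int = 1000
    # GC landscape: bounded AR(1) on bins.
    gc_mean: float = 0.42
    gc_ar1: float = 0.98
    gc_sd: float = 0.05
    gc_clip: tuple[float, float] = (0.2, 0.7)
    gc_event_dip: float = 0.015  # CNV-site GC runs slightly low, as in real genomes
    # Genes.
    n_genes: int = 300
    ortholog_fraction: float = 0.5
    gene_len: tuple[int, int] = (2_000, 20_000)
    exons_per_gene: tuple[int, int] = (2, 8)
    genic_event_fraction: float = 0.3  # fraction of event sites seeded with a gene
    # Segmental duplications.
    n_sds: int = 60
    sd_len: tuple[int, int] = (5_000, 30_000)
    sd_near_event_frac: float = 0.3
    # Repeats.
    repeat_families: dict[str, RepeatFamilyConfig] = field(default_factory=_default_repeats)
    # Event sites reserved for truth CNV gains.
    n_event_sites: int = 60
    event_site_max_len: int = 122_000
    # PAR on X.
    par: tuple[int, int] = (0, 200_000)


@dataclass(frozen=True)
class IndividualSpec:
    id: str
    sex: str  # "male" | "female"
    group: str  # one of GROUPS
    coverage: float  # mean haploid-pair depth (x)

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise InvalidConfigError(f"{self.id}: sex must be male or female")
        if self.group not in GROUPS:
            raise InvalidConfigError(f"{self.id}: unknown group {self.group!r}")
        if not self.coverage > 0:
            raise InvalidConfigError(f"{self.id}: coverage must be positive")


def default_cohort() -> list[IndividualSpec]:
    """The 16-individual study design: 3 wild + 5 domestic per continent,
    per-individual coverages spanning the observed 7.1-11x range."""
    rows = [
        ("AsWB01", "AsianWild", 11.0), ("AsWB02", "AsianWild", 10.0),
        ("AsWB03", "AsianWild", 10.1),
        ("AsD01", "AsianDomestic", 9.0), ("AsD02", "AsianDomestic", 9.1),
        ("AsD03", "AsianDomestic", 8.1), ("AsD04", "AsianDomestic", 8.0),
        ("AsD05", "AsianDomestic", 10.5),
        ("EuWB01", "EuropeanWild", 9.0), ("EuWB02", "EuropeanWild", 8.0),
        ("EuWB03", "EuropeanWild", 10.0),
        ("EuD01", "EuropeanDomestic", 8.0), ("EuD02", "EuropeanDomestic", 8.0),
        ("EuD03", "EuropeanDomestic", 8.0), ("EuD04", "EuropeanDomestic", 7.1),
        ("EuD05", "EuropeanDomestic", 11.0),
    ]
    sexes = ["male", "female"] * 8
    return [
        IndividualSpec(i, s, g, c) for (i, g, c), s in zip(rows, sexes)
    ]


@dataclass(frozen=True)
class CnvParams:
    """Truth gain-event design: counts by sharing scope, integer CN range and a
    truncated-exponential size distribution on [size_min, size_max]."""

    n_shared: int = 10
    n_group: int = 24
    n_private: int = 16
    cn_range: tuple[int, int] = (4, 10)
    size_min: int = 6_000
    size_max: int = 122_000
    size_mean: int = 13_000
    allow_losses: bool = False  # CN-loss simulation, off by default
    n_losses: int = 0

    @property
    def n_events(self) -> int:
        return self.n_shared + self.n_group + self.n_private + (
            self.n_losses if self.allow_losses else 0
        )


# ---------------------------------------------------------------- annotations
@dataclass
class GenomeAnnotations:
    genes: pd.DataFrame      # gene_id, chrom, start, end, is_ortholog
    exons: pd.DataFrame      # gene_id, chrom, start, end
    sds: pd.DataFrame        # chrom, start, end
    repeats: pd.DataFrame    # chrom, start, end, family
    event_sites: pd.DataFrame  # chrom, start, end (reserved anchors)
    par: pd.DataFrame        # chrom, start, end

    @property
    def ortholog_regions(self) -> pd.DataFrame:
        return self.genes.loc[self.genes["is_ortholog"], ["chrom", "start", "end"]]


@dataclass
class SyntheticGenome:
    grid: BinGrid
    annotations: GenomeAnnotations
    config: GenomeConfig
    seed: int


# ------------------------------------------------------------------- profiles
@dataclass(frozen=True)
class TruthEvent:
    chrom: str
    start: int
    end: int
    cn: int
    scope: str  # "shared" | "group" | "private"
    carriers: tuple[str, ...]


@dataclass
class TruthCnProfile:
    individual_id: str
    cn: np.ndarray  # per-bin integer CN >= 0
    events: list[TruthEvent]


@dataclass
class DepthTrack:
    """Per-bin mean read depth for one individual.

    ``excluded`` marks bins whose masked fraction exceeds the exclusion
    threshold; those bins carry no usable depth for estimation.
    """

    individual_id: str
    depth: np.ndarray
    excluded: np.ndarray
    stage: str = "raw"  # "raw" | "gc_corrected"


# ------------------------------------------------------------------ GC curves
def linear_gc_bias(slope: float = 0.5, center: float = 0.4) -> Callable[[np.ndarray], np.ndarray]:
    """The bias family g(GC) = 1 + slope * (GC - center)."""

    def g(gc: np.ndarray) -> np.ndarray:
        return 1.0 + slope * (np.asarray(gc, dtype=float) - center)

    g.__name__ = f"linear_gc_bias(slope={slope}, center={center})"
    return g


def flat_gc_bias(gc: np.ndarray) -> np.ndarray:
    return np.ones_like(np.asarray(gc, dtype=float))


# -------------------------------------------------------------------- helpers
def _sample_interval(
    rng: np.random.Generator,
    chrom_lengths: list[tuple[str, int]],
    length: int,
    blocked,  # callable (chrom, start, end) -> bool
    retries: int = 200,
    what: str = "interval",
) -> tuple[str, int, int]:
    total = sum(l for _, l in chrom_lengths)
    weights = np.array([l / total for _, l in chrom_lengths])
    for _ in range(retries):
        ci = rng.choice(len(chrom_lengths), p=weights)
        name, clen = chrom_lengths[ci]
        if clen <= length:
            continue
        start = int(rng.integers(0, clen - length))
        if not blocked(name, start, start + length):
            return name, start, start + length
    raise PlacementError(f"could not place {what} of length {length} after {retries} tries")


class _Occupancy:
    """Per-chromosome interval occupancy with O(k) overlap checks."""

    def __init__(self) -> None:
        self._by_chrom: dict[str, list[tuple[int, int]]] = {}

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        return any(s < end and start < e for s, e in self._by_chrom.get(chrom, ()))

    def add(self, chrom: str, start: int, end: int) -> None:
        self._by_chrom.setdefault(chrom, []).append((start, end))


# --------------------------------------------------------------- build_genome
def build_genome(config: GenomeConfig | None = None, seed: int = 0) -> SyntheticGenome:
    """Generate the binned reference genome and its annotation set.

    Deterministic for a fixed ``(config, seed)``. Raises
    :class:`InvalidConfigError` for degenerate chromosome sizes and
    :class:`PlacementError` when annotations cannot be placed without overlap.
    """
    config = config or GenomeConfig()
    bs = config.bin_size
    for cs in config.chromosomes:
        if cs.length < 10 * bs:
            raise InvalidConfigError(
                f"{cs.name}: length {cs.length} < 10 x bin_size {bs}"
            )
        if cs.length % bs:
            raise InvalidConfigError(f"{cs.name}: length not a multiple of bin_size")
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(0xB1,))
    rng_gc, rng_sites, rng_genes, rng_sds, rng_reps = (
        np.random.default_rng(s) for s in ss.spawn(5)
    )

    chrom_pairs = [(c.name, c.length) for c in config.chromosomes]
    autosomes = [(c.name, c.length) for c in config.chromosomes if not c.is_x]
    n_bins = sum(c.length // bs for c in config.chromosomes)

    # GC landscape: stationary AR(1) per chromosome, clipped.
    lo, hi = config.gc_clip
    phi, mu = config.gc_ar1, config.gc_mean
    innov_sd = config.gc_sd * math.sqrt(max(1.0 - phi * phi, 1e-12))
    gc = np.empty(n_bins)
    pos = 0
    for c in config.chromosomes:
        nb = c.length // bs
        eps = rng_gc.normal(0.0, innov_sd, nb)
        x = np.empty(nb)
        x[0] = mu + rng_gc.normal(0.0, config.gc_sd)
        for i in range(1, nb):
            x[i] = mu + phi * (x[i - 1] - mu) + eps[i]
        gc[pos:pos + nb] = np.clip(x, lo, hi)
        pos += nb

    occupancy = _Occupancy()

    # 1. Reserve autosomal event sites (future truth CNV locations).
    site_rows = []
    if config.n_event_sites:
        if not autosomes:
            raise InvalidConfigError("event sites require at least one autosome")
        for k in range(config.n_event_sites):
            length = config.event_site_max_len
            # keep a flank-sized buffer between sites so flank analyses separate
            chrom, start, end = _sample_interval(
                rng_sites, autosomes, length + 20_000,
                lambda c, s, e: occupancy.overlaps(c, s - 20_000, e + 20_000),
                what=f"event site {k}",
            )
            start = (start // bs) * bs  # bin-aligned
            end = start + length
            occupancy.add(chrom, start, end)
            site_rows.append((chrom, start, end))
    event_sites = pd.DataFrame(site_rows, columns=["chrom", "start", "end"])

    # GC runs slightly low where gains will land: dip the typical event
    # footprint plus its 10 kb flank, not the whole reserved site, so the
    # contrast against the rest of the genome survives.
    if config.gc_event_dip:
        for chrom, start, end in site_rows:
            dip_end = min(end, start + 20_000)
            glo, ghi = _grid_range(chrom_pairs, bs, chrom, max(0, start - 10_000), dip_end)
            gc[glo:ghi] = np.clip(gc[glo:ghi] - config.gc_event_dip, 0.0, 1.0)

    # 2. Genes. Orthologs first (never inside event sites); then the rest, a
    # fraction seeded inside event sites so genic CNVRs exist.
    n_ortho = int(round(config.n_genes * config.ortholog_fraction))
    gene_rows, exon_rows = [], []
    gene_occ = _Occupancy()

    def _add_gene(gid: str, chrom: str, start: int, end: int, ortho: bool) -> None:
        gene_rows.append((gid, chrom, start, end, ortho))
        gene_occ.add(chrom, start, end)
        n_ex = int(rng_genes.integers(config.exons_per_gene[0], config.exons_per_gene[1] + 1))
        # exons: evenly spaced sub-intervals covering ~half of the gene body
        glen = end - start
        edges = np.sort(rng_genes.choice(np.arange(1, 2 * n_ex), size=2 * n_ex - 1, replace=False))
        cuts = np.concatenate(([0], edges, [2 * n_ex])) * (glen / (2 * n_ex))
        for j in range(n_ex):
            es = start + int(cuts[2 * j])
            ee = start + int(cuts[2 * j + 1])
            if ee > es:
                exon_rows.append((gid, chrom, es, ee))

    for k in range(n_ortho):
        length = int(rng_genes.integers(config.gene_len[0], config.gene_len[1] + 1))
        chrom, start, end = _sample_interval(
            rng_genes, chrom_pairs, length,
            lambda c, s, e: occupancy.overlaps(c, s, e) or gene_occ.overlaps(c, s, e),
            what=f"ortholog gene {k}",
        )
        _add_gene(f"ORTH{k:04d}", chrom, start, end, True)

    n_other = config.n_genes - n_ortho
    n_in_sites = min(len(site_rows), int(round(config.n_event_sites * config.genic_event_fraction)))
    for k in range(n_other):
        length = int(rng_genes.integers(config.gene_len[0], config.gene_len[1] + 1))
        if k < n_in_sites:
            # seed a gene at the start of an event site, where the future gain
            # actually lies, short enough that typical events cover >= 70% of it
            chrom, s0, e0 = site_rows[k]
            length = min(length, 12_000, e0 - s0)
            start = s0 + int(rng_genes.integers(0, 1000))
            _add_gene(f"GENE{k:04d}", chrom, start, start + length, False)
        else:
            try:
                chrom, start, end = _sample_interval(
                    rng_genes, chrom_pairs, length,
                    lambda c, s, e: gene_occ.overlaps(c, s, e) or occupancy.overlaps(c, s, e),
                    what=f"gene {k}",
                )
            except PlacementError:
                continue  # dense configs may not fit every filler gene
            _add_gene(f"GENE{k:04d}", chrom, start, end, False)

    genes = pd.DataFrame(gene_rows, columns=["gene_id", "chrom", "start", "end", "is_ortholog"])
    exons = pd.DataFrame(exon_rows, columns=["gene_id", "chrom", "start", "end"])

    # 3. Segmental duplications: a configurable fraction lands within 10 kb of
    # an event site, the rest anywhere outside ortholog genes.
    sd_rows = []
    n_near = int(round(config.n_sds * config.sd_near_event_frac))
    chrom_len = dict(chrom_pairs)
    for k in range(config.n_sds):
        length = int(rng_sds.integers(config.sd_len[0], config.sd_len[1] + 1))
        if k < n_near and site_rows:
            # anchor to the event footprint at the site start: SD midpoint
            # within 10 kb of (or inside) the site interval
            chrom, s0, e0 = site_rows[int(rng_sds.integers(0, len(site_rows)))]
            m = int(rng_sds.integers(0, 10_000))
            mid = (s0 - m) if rng_sds.integers(0, 2) == 0 else (s0 + m)
            start = max(0, min(mid - length // 2, chrom_len[chrom] - length))
            sd_rows.append((chrom, start, start + length))
        else:
            try:
                chrom, start, end = _sample_interval(
                    rng_sds, chrom_pairs, length,
                    lambda c, s, e: gene_occ.overlaps(c, s, e),
                    what=f"SD {k}",
                )
            except PlacementError:
                continue
            sd_rows.append((chrom, start, end))
    sds = pd.DataFrame(sd_rows, columns=["chrom", "start", "end"]).sort_values(
        ["chrom", "start"], ignore_index=True
    )

    # 4. Repeat elements; boosted families cluster in event-site flanks (never
    # inside the sites themselves, so chaining is not broken by masking).
    rep_rows = []
    for family, fam in config.repeat_families.items():
        n_boost = int(round(fam.count * fam.near_event_boost)) if site_rows else 0
        for k in range(fam.count):
            length = int(rng_reps.integers(fam.min_len, fam.max_len + 1))
            if k < n_boost:
                # left flank of an event site, fully within 10 kb upstream, so
                # the resulting masking never lands on event bins themselves
                chrom, s0, e0 = site_rows[int(rng_reps.integers(0, len(site_rows)))]
                offset = int(rng_reps.integers(0, max(1, 10_000 - length)))
                start = max(0, s0 - offset - length)
                rep_rows.append((chrom, start, start + length, family))
            else:
                for _ in range(50):
                    chrom, start, end = _sample_interval(
                        rng_reps, chrom_pairs, length, lambda c, s, e: False,
                        what=f"repeat {family} {k}",
                    )
                    # keep heavy masking away from reserved event sites
                    if not occupancy.overlaps(chrom, start, end):
                        rep_rows.append((chrom, start, end, family))
                        break
    repeats = pd.DataFrame(rep_rows, columns=["chrom", "start", "end", "family"]).sort_values(
        ["chrom", "start"], ignore_index=True
    )

    # 5. Masked fraction per bin = fraction of the bin covered by repeats.
    masked = np.zeros(n_bins)
    for chrom, start, end, _fam in repeats.itertuples(index=False):
        glo, ghi = _grid_range(chrom_pairs, bs, chrom, start, end)
        for gi in range(glo, ghi):
            b0 = _bin_start(chrom_pairs, bs, gi)
            ov = min(end, b0 + bs) - max(start, b0)
            masked[gi] = min(1.0, masked[gi] + ov / bs)

    x_name = next((c.name for c in config.chromosomes if c.is_x), None)
    par = pd.DataFrame(
        [(x_name, *config.par)] if x_name else [], columns=["chrom", "start", "end"]
    )
    grid = BinGrid(
        chromosomes=tuple(chrom_pairs),
        bin_size=bs,
        gc=gc,
        masked_frac=masked,
        is_x=tuple(c.is_x for c in config.chromosomes),
        par_regions=(config.par,) if x_name else (),
    )
    ann = GenomeAnnotations(
        genes=genes, exons=exons, sds=sds, repeats=repeats,
        event_sites=event_sites, par=par,
    )
    return SyntheticGenome(grid=grid, annotations=ann, config=config, seed=seed)


def _grid_range(chrom_pairs, bs, chrom, start, end):
    off = 0
    for name, length in chrom_pairs:
        nb = length // bs
        if name == chrom:
            lo = max(0, start // bs)
            hi = min(nb, -(-end // bs))
            return off + lo, off + max(lo, hi)
        off += nb
    raise KeyError(chrom)


def _bin_start(chrom_pairs, bs, gi):
    off = 0
    for name, length in chrom_pairs:
        nb = length // bs
        if gi < off + nb:
            return (gi - off) * bs
        off += nb
    raise IndexError(gi)


# -------------------------------------------------------------- simulate_truth
def simulate_truth(
    genome: SyntheticGenome,
    individuals: Sequence[IndividualSpec],
    cnv_params: CnvParams | None = None,
    seed: int = 0,
) -> dict[str, TruthCnProfile]:
    """Assign gain events to the reserved event sites and build per-individual
    truth CN profiles.

    Shared events carry one CN in every individual; group events raise CN in
    all members of exactly one group; private events in exactly one
    individual. Outside events the profile is the diploid baseline (CN 2 on
    autosomes; CN 1 on male X outside the PAR).
    """
    params = cnv_params or CnvParams()
    grid = genome.grid
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(0xC2,)))
    sites = genome.annotations.event_sites
    if params.n_events > len(sites):
        raise PlacementError(
            f"{params.n_events} events requested but only {len(sites)} event sites reserved"
        )
    cn_lo, cn_hi = params.cn_range
    if not (2 < cn_lo <= cn_hi):
        raise InvalidConfigError("event CN range must lie above 2")
    if not (grid.bin_size <= params.size_min <= params.size_max):
        raise InvalidConfigError("invalid event size range")

    ids = [s.id for s in individuals]
    by_group: dict[str, list[str]] = {}
    for s in individuals:
        by_group.setdefault(s.group, []).append(s.id)
    groups = sorted(by_group)

    site_order = rng.permutation(len(sites)) if len(sites) else np.array([], dtype=int)
    scale = max(params.size_mean - params.size_min, 1)
    events: list[TruthEvent] = []
    gi_iter = iter(site_order)
    scopes = (
        ["shared"] * params.n_shared + ["group"] * params.n_group + ["private"] * params.n_private
    )
    group_cycle = 0
    private_cycle = 0
    for scope in scopes:
        si = int(next(gi_iter))
        chrom, s0, e0 = sites.iloc[si][["chrom", "start", "end"]]
        size = params.size_min + rng.exponential(scale)
        size = min(size, params.size_max, e0 - s0)
        size = max(params.size_min, int(size // grid.bin_size) * grid.bin_size)
        start = int(s0)
        end = start + int(size)
        cn = int(rng.integers(cn_lo, cn_hi + 1))
        if scope == "shared":
            carriers = tuple(ids)
        elif scope == "group":
            carriers = tuple(by_group[groups[group_cycle % len(groups)]])
            group_cycle += 1
        else:
            carriers = (ids[private_cycle % len(ids)],)
            private_cycle += 1
        events.append(TruthEvent(str(chrom), start, end, cn, scope, carriers))

    # Sanity: the diploid anchor stays clean.
    ortho = genome.annotations.ortholog_regions
    for ev in events:
        sub = ortho[ortho["chrom"] == ev.chrom]
        if ((sub["start"] < ev.end) & (ev.start < sub["end"])).any():
            raise PlacementError(f"event at {ev.chrom}:{ev.start}-{ev.end} hits an ortholog gene")

    x_mask = grid.x_bin_mask()
    par_mask = grid.par_bin_mask()
    profiles: dict[str, TruthCnProfile] = {}
    for spec in individuals:
        cn_arr = np.full(grid.n_bins, 2, dtype=np.int64)
        if spec.sex == "male":
            cn_arr[x_mask & ~par_mask] = 1
        my_events = []
        for ev in events:
            if spec.id in ev.carriers:
                lo, hi = grid.bin_range(ev.chrom, ev.start, ev.end)
                cn_arr[lo:hi] = ev.cn
                my_events.append(ev)
        profiles[spec.id] = TruthCnProfile(spec.id, cn_arr, my_events)
    return profiles


# -------------------------------------------------------------- simulate_depth
def expected_depth(
    grid: BinGrid,
    truth: TruthCnProfile,
    spec: IndividualSpec,
    gc_bias: Callable[[np.ndarray], np.ndarray] = flat_gc_bias,
) -> np.ndarray:
    """Pre-noise expected depth per bin:
    (coverage / 2) x CN x g(GC) x (1 - masked_frac)."""
    g = np.asarray(gc_bias(grid.gc), dtype=float)
    if np.any(g <= 0):
        raise InvalidConfigError("GC bias curve must be positive on [0, 1]")
    return (spec.coverage / 2.0) * truth.cn * g * (1.0 - grid.masked_frac)


def simulate_depth(
    genome: SyntheticGenome | BinGrid,
    truth: TruthCnProfile,
    spec: IndividualSpec,
    gc_bias: Callable[[np.ndarray], np.ndarray] = flat_gc_bias,
    dispersion: float = 0.005,
    seed: int = 0,
    read_length: int = 100,
    mask_exclude: float = MASK_EXCLUDE_DEFAULT,
) -> DepthTrack:
    """Draw a noisy raw depth track for one individual.

    Reads per bin are negative-binomial with mean
    ``expected_depth x bin_size / read_length`` and variance
    ``mu x (1 + dispersion x mu)``; ``dispersion = 0`` gives the Poisson
    limit. Depth is reported back in coverage units.
    """
    grid = genome.grid if isinstance(genome, SyntheticGenome) else genome
    if dispersion < 0:
        raise InvalidConfigError("dispersion must be >= 0")
    mu_depth = expected_depth(grid, truth, spec, gc_bias)
    mu_reads = mu_depth * grid.bin_size / read_length
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(0xD3,)))
    if dispersion == 0:
        counts = rng.poisson(mu_reads)
    else:
        n = 1.0 / dispersion
        p = n / (n + np.maximum(mu_reads, 1e-300))
        counts = np.where(mu_reads > 0, rng.negative_binomial(n, p), 0)
    depth = counts.astype(float) * read_length / grid.bin_size
    excluded = grid.masked_frac > mask_exclude
    return DepthTrack(spec.id, depth, excluded, stage="raw")
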