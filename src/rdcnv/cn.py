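"""GC-corrected copy-number estimation from raw per-bin depth.

The estimator follows a two-stage diploid-baseline scheme:

1. **Seed stage** — the mean raw depth over bins inside 1:1 orthologous genic
   regions (a putatively diploid anchor set) gives a provisional diploid
   depth ``D``.
2. **Refinement** — every non-excluded bin whose provisional copy number
   ``2 * depth / D`` falls in a diploid window (default [1.5, 2.5]) joins a
   genome-wide diploid set. This breaks the elevated-GC composition of coding
   regions. Per-GC-interval correction factors are estimated on that set,
   applied genome-wide, and the baseline re-estimated on corrected depth.

Copy number per bin is ``2 * corrected_depth / D``; male X bins outside the
pseudo-autosomal region are doubled so male and female X tracks are
comparable. Partially repeat-masked bins are first rescaled by
``1 / (1 - masked_frac)`` (mappability normalization); bins masked above the
exclusion threshold carry no estimate at all.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import (
    BaselineUnstableError,
    EstimationError,
    InvalidConfigError,
    RefinementFailedError,
)
from .grid import BinGrid
from .simulate import DepthTrack

__all__ = [
    "DiploidBaseline",
    "GcCorrectionTable",
    "CnTrack",
    "normalize_mappability",
    "seed_baseline",
    "predict_diploid_bins",
    "estimate_gc_correction",
    "correct_depth",
    "refine_baseline",
    "estimate_cn",
    "estimate_cn_track",
]


@dataclass
class DiploidBaseline:
    depth: float                # mean diploid depth D
    bins: np.ndarray            # global indices the estimate came from
    stage: str                  # "ortholog_seed" | "refined"

    def __post_init__(self) -> None:
        if not self.depth > 0:
            raise EstimationError(f"diploid baseline must be positive, got {self.depth}")


@dataclass
class GcCorrectionTable:
    """Per-GC-interval multiplicative depth correction factors.

    Intervals of width ``width`` partition [0, 1]. Intervals whose diploid-bin
    support fell below the minimum were merged with the nearest populated
    neighbour before factor estimation (``merged`` flags them).
    """

    width: float
    factor: np.ndarray   # one factor per interval, > 0
    support: np.ndarray  # diploid bins per interval
    merged: np.ndarray   # bool, interval took its factor from a neighbour

    @property
    def n_intervals(self) -> int:
        return len(self.factor)

    def interval_of(self, gc: np.ndarray) -> np.ndarray:
        idx = np.floor(np.asarray(gc, dtype=float) / self.width).astype(int)
        return np.clip(idx, 0, self.n_intervals - 1)


@dataclass
class CnTrack:
    individual_id: str
    cn: np.ndarray        # continuous CN >= 0; NaN on excluded bins
    excluded: np.ndarray
    stage: str = "refined"


def normalize_mappability(
    depth: DepthTrack, grid: BinGrid, mask_max: float = 0.8
) -> DepthTrack:
    """Rescale depth of partially masked bins by 1/(1 - masked_frac).

    Bins masked above ``mask_max`` are marked excluded instead. Idempotent on
    fully unmasked grids.
    """
    excluded = grid.masked_frac > mask_max
    scale = np.where(excluded, 1.0, 1.0 / np.maximum(1.0 - grid.masked_frac, 1e-12))
    return DepthTrack(depth.individual_id, depth.depth * scale, excluded, depth.stage)


def seed_baseline(
    depth: DepthTrack,
    orthologs,
    grid: BinGrid,
    min_bins: int = 200,
) -> DiploidBaseline:
    """Stage-1 baseline: mean raw depth over non-excluded ortholog-region bins."""
    mask = grid.regions_bin_mask(orthologs) & ~depth.excluded
    bins = np.flatnonzero(mask)
    if len(bins) < min_bins:
        raise BaselineUnstableError(
            f"only {len(bins)} non-excluded ortholog bins (< {min_bins})"
        )
    return DiploidBaseline(float(np.mean(depth.depth[bins])), bins, "ortholog_seed")


def predict_diploid_bins(
    depth: DepthTrack,
    baseline: DiploidBaseline,
    grid: BinGrid,
    diploid_window: tuple[float, float] = (1.5, 2.5),
) -> np.ndarray:
    """Genome-wide diploid bin set: provisional CN = 2*depth/D in the window."""
    if baseline.stage != "ortholog_seed":
        raise EstimationError("diploid prediction requires the ortholog-seed baseline")
    lo, hi = diploid_window
    prov = 2.0 * depth.depth / baseline.depth
    mask = (~depth.excluded) & (prov >= lo) & (prov <= hi)
    bins = np.flatnonzero(mask)
    if len(bins) == 0:
        raise RefinementFailedError("no bins fall in the diploid window")
    return bins


def estimate_gc_correction(
    depth: DepthTrack,
    diploid_bins: np.ndarray,
    grid: BinGrid,
    interval_width: float = 0.01,
    min_support: int = 50,
) -> GcCorrectionTable:
    """Per-GC-interval correction factors from the diploid bin set.

    ``factor_i = mean(depth over all diploid bins) / mean(depth over diploid
    bins with GC in interval i)``. Sparse intervals (support below
    ``min_support``) are merged with the nearest populated interval before
    factors are computed; if only one populated interval exists the table
    degenerates to all-ones with a warning.
    """
    if len(diploid_bins) == 0:
        raise EstimationError("diploid bin set is empty")
    if not (0 < interval_width <= 1):
        raise InvalidConfigError("interval_width must be in (0, 1]")
    n_iv = max(1, int(round(1.0 / interval_width)))
    idx_all = np.clip(
        np.floor(grid.gc / interval_width).astype(int), 0, n_iv - 1
    )
    idx = idx_all[diploid_bins]
    d = depth.depth[diploid_bins]
    support = np.bincount(idx, minlength=n_iv)
    sums = np.bincount(idx, weights=d, minlength=n_iv)
    overall = float(np.mean(d))

    populated = np.flatnonzero(support >= min_support)
    factor = np.ones(n_iv)
    merged = np.zeros(n_iv, dtype=bool)
    if len(populated) <= 1:
        warnings.warn(
            "degenerate GC correction table: <= 1 populated interval; factors set to 1",
            stacklevel=2,
        )
        return GcCorrectionTable(1.0 / n_iv, factor, support, merged)

    # Map every interval to its nearest populated interval (ties -> lower GC),
    # then pool depth within each merge group.
    targets = populated[
        np.argmin(np.abs(np.arange(n_iv)[:, None] - populated[None, :]), axis=1)
    ]
    group_sum = np.zeros(n_iv)
    group_n = np.zeros(n_iv)
    np.add.at(group_sum, targets, sums)
    np.add.at(group_n, targets, support)
    for i in range(n_iv):
        t = targets[i]
        mean_t = group_sum[t] / group_n[t]
        if mean_t <= 0:
            raise EstimationError(f"non-positive mean depth in GC interval {t}")
        factor[i] = overall / mean_t
        merged[i] = t != i
    return GcCorrectionTable(1.0 / n_iv, factor, support, merged)


def correct_depth(
    depth: DepthTrack, table: GcCorrectionTable, grid: BinGrid
) -> DepthTrack:
    """Apply GC correction bin-wise: corrected = raw x factor(GC interval)."""
    f = table.factor[table.interval_of(grid.gc)]
    return DepthTrack(depth.individual_id, depth.depth * f, depth.excluded, "gc_corrected")


def refine_baseline(depth: DepthTrack, diploid_bins: np.ndarray) -> DiploidBaseline:
    """Stage-2 baseline: mean GC-corrected depth over the diploid bin set."""
    if len(diploid_bins) == 0:
        raise BaselineUnstableError("empty diploid bin set")
    return DiploidBaseline(float(np.mean(depth.depth[diploid_bins])), np.asarray(diploid_bins), "refined")


def estimate_cn(
    depth: DepthTrack,
    baseline: DiploidBaseline,
    grid: BinGrid,
    sex: str = "female",
    par_regions=None,
) -> CnTrack:
    """Per-bin continuous copy number from GC-corrected depth.

    ``CN = 2 * depth / D`` everywhere except male X outside the PAR, where
    depth is doubled first. Excluded bins carry NaN.
    """
    if baseline.stage != "refined":
        raise EstimationError("estimate_cn requires the refined baseline")
    if sex not in ("male", "female"):
        raise InvalidConfigError(f"unknown sex {sex!r}")
    D = baseline.depth
    if not D > 0:
        raise EstimationError("non-positive diploid baseline")
    d = depth.depth.astype(float).copy()
    if sex == "male":
        x_mask = grid.x_bin_mask()
        if par_regions is not None:
            par_mask = np.zeros(grid.n_bins, dtype=bool)
            x = grid.x_name
            for _, row in par_regions.iterrows():
                if x is not None and row["chrom"] == x:
                    lo, hi = grid.bin_range(x, int(row["start"]), int(row["end"]))
                    par_mask[lo:hi] = True
        else:
            par_mask = grid.par_bin_mask()
        d[x_mask & ~par_mask] *= 2.0
    cn = 2.0 * d / D
    cn[depth.excluded] = np.nan
    return CnTrack(depth.individual_id, cn, depth.excluded.copy())


def estimate_cn_track(
    raw: DepthTrack,
    grid: BinGrid,
    orthologs,
    sex: str = "female",
    par_regions=None,
    mask_max: float = 0.8,
    min_seed_bins: int = 200,
    diploid_window: tuple[float, float] = (1.5, 2.5),
    gc_interval_width: float = 0.01,
    gc_min_support: int = 50,
):
    """Run the full two-stage estimation for one individual.

    Returns ``(CnTrack, GcCorrectionTable, refined DiploidBaseline)``.
    """
    norm = normalize_mappability(raw, grid, mask_max)
    seed = seed_baseline(norm, orthologs, grid, min_bins=min_seed_bins)
    dip = predict_diploid_bins(norm, seed, grid, diploid_window)
    table = estimate_gc_correction(norm, dip, grid, gc_interval_width, gc_min_support)
    corrected = correct_depth(norm, table, grid)
    refined = refine_baseline(corrected, dip)
    track = estimate_cn(corrected, refined, grid, sex=sex, par_regions=par_regions)
    return track, table, refined
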