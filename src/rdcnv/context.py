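"""Genomic context of CNVRs: segmental duplications, repeat families, GC.

Association is measured on fixed-width intervals (default 10 kb): one flank
interval on each side of every region of interest, against a background
("other") tiling of the remaining genome. Repeat-family densities are base
counts per interval, compared between interval sets with a two-sided Fisher
exact test on base-level 2x2 tables. SD association is the fraction of SDs
lying within the flank distance of any CNVR, and GC contrast compares mean
bin GC inside CNVRs and their flanks to the rest of the genome.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency, hypergeom

from .errors import UndefinedStatisticError
from .grid import BinGrid

__all__ = [
    "FlankIntervalSet",
    "make_flank_intervals",
    "make_other_intervals",
    "repeat_density",
    "fisher_exact_2x2",
    "enrichment_test",
    "sd_cnvr_overlap",
    "truncate_percent",
    "gc_contrast",
]


@dataclass
class FlankIntervalSet:
    label: str
    intervals: pd.DataFrame  # chrom, start, end, clipped
    width: int

    @property
    def n_intervals(self) -> int:
        return len(self.intervals)

    @property
    def total_bases(self) -> int:
        iv = self.intervals
        return int((iv["end"] - iv["start"]).sum()) if len(iv) else 0


def _merge_intervals(df: pd.DataFrame) -> list[tuple[str, int, int]]:
    rows: list[list] = []
    for chrom, start, end in (
        df[["chrom", "start", "end"]]
        .sort_values(["chrom", "start", "end"])
        .itertuples(index=False)
    ):
        if rows and rows[-1][0] == chrom and start <= rows[-1][2]:
            rows[-1][2] = max(rows[-1][2], end)
        else:
            rows.append([chrom, int(start), int(end)])
    return [tuple(r) for r in rows]


def make_flank_intervals(
    regions: pd.DataFrame,
    grid: BinGrid,
    width: int = 10_000,
    label: str = "flank",
) -> FlankIntervalSet:
    """One ``width``-sized interval on each side of each region, clipped at
    chromosome ends (clipped intervals kept with reduced width and flagged)."""
    rows = []
    for chrom, start, end in regions[["chrom", "start", "end"]].itertuples(index=False):
        try:
            clen = grid.chrom_length(chrom)
        except KeyError:
            continue
        left = (chrom, max(0, start - width), start)
        right = (chrom, end, min(clen, end + width))
        for c, s, e in (left, right):
            if e > s:
                rows.append((c, int(s), int(e), (e - s) < width))
    iv = pd.DataFrame(rows, columns=["chrom", "start", "end", "clipped"])
    return FlankIntervalSet(label, iv, width)


def make_other_intervals(
    grid: BinGrid,
    exclude: list[pd.DataFrame],
    width: int = 10_000,
) -> FlankIntervalSet:
    """Background tiling: full-width intervals of the genome not touching any
    excluded region (the flank sets and the regions themselves)."""
    blocked = _merge_intervals(
        pd.concat(
            [df[["chrom", "start", "end"]] for df in exclude if len(df)],
            ignore_index=True,
        )
        if any(len(df) for df in exclude)
        else pd.DataFrame(columns=["chrom", "start", "end"])
    )
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, s, e in blocked:
        by_chrom.setdefault(chrom, []).append((s, e))
    rows = []
    for chrom, clen in grid.chromosomes:
        blocks = by_chrom.get(chrom, [])
        for start in range(0, clen - width + 1, width):
            end = start + width
            if not any(s < end and start < e for s, e in blocks):
                rows.append((chrom, start, end, False))
    iv = pd.DataFrame(rows, columns=["chrom", "start", "end", "clipped"])
    return FlankIntervalSet("other", iv, width)


def _overlap_bases(intervals: pd.DataFrame, features: pd.DataFrame) -> int:
    """Total bases of ``features`` intersecting ``intervals`` (union-aware on
    the interval side; features counted per record against the union)."""
    merged = _merge_intervals(intervals)
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, s, e in merged:
        by_chrom.setdefault(chrom, []).append((s, e))
    total = 0
    for chrom, start, end in features[["chrom", "start", "end"]].itertuples(index=False):
        for s, e in by_chrom.get(chrom, ()):
            ov = min(end, e) - max(start, s)
            if ov > 0:
                total += ov
    return total


def repeat_density(fset: FlankIntervalSet, repeats: pd.DataFrame) -> dict[str, float]:
    """Mean repeat bases per interval, by family.

    Invariant to splitting one repeat record into adjacent pieces, since
    overlap is counted base-wise against the interval union.
    """
    if fset.n_intervals == 0:
        raise UndefinedStatisticError(f"interval set {fset.label!r} is empty")
    out = {}
    for family, sub in repeats.groupby("family"):
        out[str(family)] = _overlap_bases(fset.intervals, sub) / fset.n_intervals
    return out


def fisher_exact_2x2(table, max_support: int = 2_000_000) -> float:
    """Two-sided Fisher exact p-value for a 2x2 count table.

    Computed from log-gamma hypergeometric probabilities summed over the full
    support (all tables with the observed margins whose probability does not
    exceed the observed one). For margins whose support exceeds
    ``max_support`` a chi-square approximation is used instead.
    """
    (a, b), (c, d) = table
    if min(a + b, c + d, a + c, b + d) < 0 or (a + b + c + d) == 0:
        raise UndefinedStatisticError("Fisher test needs non-empty margins")
    n = a + b + c + d
    r1, c1 = a + b, a + c
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    if hi - lo + 1 > max_support:
        _, p, _, _ = chi2_contingency(np.array(table) + 0.0, correction=False)
        return float(p)
    ks = np.arange(lo, hi + 1)
    logp = hypergeom.logpmf(ks, n, c1, r1)
    log_obs = hypergeom.logpmf(a, n, c1, r1)
    p = float(np.exp(logp[logp <= log_obs + 1e-7]).sum())
    return min(p, 1.0)


def enrichment_test(
    family: str,
    fset: FlankIntervalSet,
    other: FlankIntervalSet,
    repeats: pd.DataFrame,
    method: str = "auto",
) -> float:
    """Fisher enrichment of one repeat family in ``fset`` against ``other``.

    The 2x2 table counts family vs non-family bases in the two interval sets.
    ``method`` is ``auto`` (exact when the support is enumerable, else
    chi-square), ``exact`` or ``chisq``.
    """
    fam = repeats[repeats["family"] == family]
    a = _overlap_bases(fset.intervals, fam)
    c = _overlap_bases(other.intervals, fam)
    b = fset.total_bases - a
    d = other.total_bases - c
    if min(a + b, c + d) == 0:
        raise UndefinedStatisticError("empty interval set in enrichment test")
    table = ((a, b), (c, d))
    if method == "chisq":
        _, p, _, _ = chi2_contingency(np.array(table) + 0.0, correction=False)
        return float(p)
    max_support = 2_000_000 if method == "auto" else 10**12
    return fisher_exact_2x2(table, max_support=max_support)


def truncate_percent(count: int, total: int, digits: int = 1) -> float:
    """Percentage truncated (not rounded) to ``digits`` decimals — the
    convention for quoting an 'approximately' figure."""
    if total <= 0:
        raise UndefinedStatisticError("total must be positive")
    scale = 10 ** digits
    return math.floor(100.0 * count / total * scale) / scale


def sd_cnvr_overlap(
    sds: pd.DataFrame, cnvrs: pd.DataFrame, flank: int = 10_000
) -> dict:
    """How many SDs lie within ``flank`` bases of (or overlap) any CNVR.

    Returns the count, the SD total, the percentage truncated to one decimal
    and at full precision.
    """
    expanded = cnvrs.copy()
    expanded["start"] = (expanded["start"] - flank).clip(lower=0)
    expanded["end"] = expanded["end"] + flank
    merged = _merge_intervals(expanded) if len(expanded) else []
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, s, e in merged:
        by_chrom.setdefault(chrom, []).append((s, e))
    count = 0
    for chrom, start, end in sds[["chrom", "start", "end"]].itertuples(index=False):
        if any(s < end and start < e for s, e in by_chrom.get(chrom, ())):
            count += 1
    total = len(sds)
    return {
        "count": count,
        "total": total,
        "percent": truncate_percent(count, total) if total else 0.0,
        "percent_full": 100.0 * count / total if total else 0.0,
    }


def gc_contrast(cnvrs: pd.DataFrame, grid: BinGrid, flank: int = 10_000) -> dict:
    """Mean GC (percent) of CNVR bins, flank bins and all remaining bins,
    with differences in percentage points (positive = CNVRs lower)."""
    cnvr_mask = grid.regions_bin_mask(cnvrs)
    flanks = make_flank_intervals(cnvrs, grid, width=flank, label="cnvr_flank")
    flank_mask = grid.regions_bin_mask(flanks.intervals) & ~cnvr_mask
    other_mask = ~cnvr_mask & ~flank_mask
    def _mean(mask):
        return float(np.mean(grid.gc[mask]) * 100.0) if mask.any() else float("nan")
    cn_gc, fl_gc, ot_gc = _mean(cnvr_mask), _mean(flank_mask), _mean(other_mask)
    return {
        "cnvr_gc_pct": cn_gc,
        "flank_gc_pct": fl_gc,
        "other_gc_pct": ot_gc,
        "cnvr_below_other_pp": ot_gc - cn_gc,
        "flank_below_other_pp": ot_gc - fl_gc,
    }
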