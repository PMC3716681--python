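"""Cross-individual merging of MCRs and copy-number-variable region calling.

The same gain may be chained with slightly different boundaries in different
individuals, so all individuals' MCRs are merged by single-linkage union
(overlapping or book-ended intervals coalesce transitively) into common
regions. Every individual — with or without an MCR there — then contributes
its mean copy number over each region, and regions whose sample standard
deviation (n-1 denominator) across individuals reaches the calling threshold
(default 0.7) are reported as CNVRs. Regions that are multi-copy but
invariant across the cohort stay MCR-only.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cn import CnTrack
from .errors import UndefinedStatisticError
from .grid import BinGrid
from .mcr import Mcr

__all__ = ["CnMatrix", "merge_mcrs", "build_cn_matrix", "call_cnvrs", "catalog_stats"]


@dataclass
class CnMatrix:
    """Region x individual continuous copy-number matrix."""

    regions: pd.DataFrame          # chrom, start, end (sorted, non-overlapping)
    individuals: list[str]
    values: np.ndarray             # shape (n_regions, n_individuals), no missing cells

    @property
    def n_regions(self) -> int:
        return len(self.regions)


def merge_mcrs(mcrs: Iterable[Mcr] | Mapping[str, Iterable[Mcr]]) -> pd.DataFrame:
    """Single-linkage union of all individuals' MCR intervals.

    Overlapping or book-ended (shared-boundary) intervals merge transitively;
    the result is independent of individual and input order.
    """
    if isinstance(mcrs, Mapping):
        items = [m for sub in mcrs.values() for m in sub]
    else:
        items = list(mcrs)
    if not items:
        return pd.DataFrame(columns=["chrom", "start", "end"])
    df = pd.DataFrame(
        [(m.chrom, m.start, m.end) for m in items], columns=["chrom", "start", "end"]
    ).sort_values(["chrom", "start", "end"], ignore_index=True)
    rows = []
    cur = None
    for chrom, start, end in df.itertuples(index=False):
        if cur is not None and chrom == cur[0] and start <= cur[2]:
            cur[2] = max(cur[2], end)
        else:
            if cur is not None:
                rows.append(tuple(cur))
            cur = [chrom, start, end]
    rows.append(tuple(cur))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def build_cn_matrix(
    regions: pd.DataFrame,
    cn_tracks: Mapping[str, CnTrack],
    grid: BinGrid,
) -> CnMatrix:
    """Mean CN of every individual over every merged region.

    Cell (r, i) is the mean continuous CN of individual i over region r's
    non-excluded bins; an individual with no MCR in r still gets its (~2)
    value. If every bin of a region is excluded for some individual, the mean
    falls back to all bins so the matrix never has missing cells.
    """
    individuals = list(cn_tracks)
    values = np.empty((len(regions), len(individuals)))
    for r, (chrom, start, end) in enumerate(
        regions[["chrom", "start", "end"]].itertuples(index=False)
    ):
        lo, hi = grid.bin_range(chrom, int(start), int(end))
        for i, ind in enumerate(individuals):
            seg = cn_tracks[ind].cn[lo:hi]
            m = np.nanmean(seg) if np.any(~np.isnan(seg)) else np.nan
            if np.isnan(m):
                m = float(np.mean(np.nan_to_num(seg, nan=2.0)))
            values[r, i] = m
    return CnMatrix(regions.reset_index(drop=True), individuals, values)


def call_cnvrs(
    matrix: CnMatrix, sd_threshold: float = 0.7, return_all: bool = False
) -> pd.DataFrame:
    """Call CNVRs: regions with sample s.d. of CN across individuals >= threshold.

    Returns a frame with region coordinates, size, s.d. and one CN column per
    individual; with ``return_all`` every merged region is returned with an
    ``is_cnvr`` flag, otherwise only the CNVR rows.
    """
    if len(matrix.individuals) < 2:
        raise UndefinedStatisticError(
            "CN standard deviation is undefined with fewer than 2 individuals"
        )
    sd = matrix.values.std(axis=1, ddof=1)
    out = matrix.regions.copy()
    out["size"] = out["end"] - out["start"]
    out["sd"] = sd
    out["is_cnvr"] = sd >= sd_threshold
    for i, ind in enumerate(matrix.individuals):
        out[f"cn_{ind}"] = matrix.values[:, i]
    if return_all:
        return out
    return out[out["is_cnvr"]].drop(columns="is_cnvr").reset_index(drop=True)


def catalog_stats(cnvrs: pd.DataFrame, grid: BinGrid) -> dict:
    """Catalog-level summary: count, mean size, total Mb, genome fraction and
    per-chromosome CNVR density (percent of chromosome bases in CNVRs)."""
    sizes = (cnvrs["end"] - cnvrs["start"]).to_numpy(dtype=float) if len(cnvrs) else np.array([])
    total_bases = float(sizes.sum())
    per_chrom = []
    for chrom, length in grid.chromosomes:
        sub = cnvrs[cnvrs["chrom"] == chrom] if len(cnvrs) else cnvrs
        bases = float((sub["end"] - sub["start"]).sum()) if len(sub) else 0.0
        per_chrom.append(
            {"chrom": chrom, "cnvr_bases": bases, "density_pct": 100.0 * bases / length}
        )
    return {
        "count": int(len(cnvrs)),
        "mean_size": float(sizes.mean()) if len(sizes) else 0.0,
        "total_mb": total_bases / 1e6,
        "genome_fraction_pct": 100.0 * total_bases / grid.genome_size,
        "per_chromosome": pd.DataFrame(per_chrom),
    }
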