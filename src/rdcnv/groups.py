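"""Population-group CNVR comparison.

To compare wild/domestic and Asian/European groups without sample-size bias,
a balanced subset (default three individuals per group) is drawn, the CNVR
pipeline is re-run within each group (and within any requested union of
groups) on its members only, and each group's set is partitioned into CNVRs
shared with at least one other group versus group-specific ones. The
specificity ratio is specific/total, the definition consistent with both
reported example ratios.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence

import numpy as np
import pandas as pd

from .cn import CnTrack
from .cnvr import build_cn_matrix, call_cnvrs, merge_mcrs
from .errors import InvalidConfigError
from .genes import filter_cn_genes, gene_cn_report
from .grid import BinGrid
from .mcr import Mcr

__all__ = [
    "subset_individuals",
    "group_cnvr_sets",
    "partition_shared_specific",
    "specific_ratio",
    "group_gene_stats",
]


def subset_individuals(
    metadata: pd.DataFrame, per_group: int = 3, seed: int = 0
) -> list[str]:
    """Deterministically draw ``per_group`` individuals from every group.

    ``metadata`` needs ``id`` and ``group`` columns. Errors if any group is
    smaller than ``per_group``.
    """
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(0xE4,)))
    chosen: list[str] = []
    for group in sorted(metadata["group"].unique()):
        members = sorted(metadata.loc[metadata["group"] == group, "id"])
        if len(members) < per_group:
            raise InvalidConfigError(
                f"group {group!r} has {len(members)} members, fewer than {per_group}"
            )
        pick = rng.choice(len(members), size=per_group, replace=False)
        chosen.extend(members[i] for i in sorted(pick))
    return chosen


def _cnvrs_for_members(
    members: Sequence[str],
    mcrs_by_individual: Mapping[str, Sequence[Mcr]],
    cn_tracks: Mapping[str, CnTrack],
    grid: BinGrid,
    sd_threshold: float,
) -> pd.DataFrame:
    mcrs = {m: mcrs_by_individual.get(m, []) for m in members}
    regions = merge_mcrs(mcrs)
    if not len(regions):
        return pd.DataFrame(columns=["chrom", "start", "end", "size", "sd"])
    matrix = build_cn_matrix(regions, {m: cn_tracks[m] for m in members}, grid)
    return call_cnvrs(matrix, sd_threshold)


def group_cnvr_sets(
    members_by_group: Mapping[str, Sequence[str]],
    mcrs_by_individual: Mapping[str, Sequence[Mcr]],
    cn_tracks: Mapping[str, CnTrack],
    grid: BinGrid,
    sd_threshold: float = 0.7,
    combos: Sequence[Sequence[str]] = (),
) -> dict[str, pd.DataFrame]:
    """Re-run the full merge -> matrix -> s.d. pipeline per group.

    ``combos`` adds unions of groups (e.g. ("AsianWild", "AsianDomestic")),
    each computed from the union's members — not from the union of per-group
    CNVR sets, which can legitimately differ.
    """
    out: dict[str, pd.DataFrame] = {}
    for group, members in members_by_group.items():
        out[group] = _cnvrs_for_members(members, mcrs_by_individual, cn_tracks, grid, sd_threshold)
    for combo in combos:
        label = "+".join(combo)
        members = [m for g in combo for m in members_by_group[g]]
        out[label] = _cnvrs_for_members(members, mcrs_by_individual, cn_tracks, grid, sd_threshold)
    return out


def _any_overlap(region, others: list[pd.DataFrame]) -> bool:
    chrom, start, end = region
    for df in others:
        if not len(df):
            continue
        sub = df[df["chrom"] == chrom]
        if ((sub["start"] < end) & (start < sub["end"])).any():
            return True
    return False


def specific_ratio(n_specific: int, n_total: int) -> float:
    """Group-specificity ratio, specific/total, rounded to 2 decimals."""
    if n_total <= 0:
        raise InvalidConfigError("total CNVR count must be positive")
    return round(n_specific / n_total, 2)


def partition_shared_specific(
    target: pd.DataFrame, others: Mapping[str, pd.DataFrame]
) -> dict:
    """Split a group's CNVRs into shared vs group-specific.

    A CNVR is specific iff it overlaps (by >= 1 base) no CNVR of any other
    group. ``shared + specific = total`` always.
    """
    other_sets = list(others.values())
    specific_rows = []
    for row in target[["chrom", "start", "end"]].itertuples(index=False):
        if not _any_overlap(tuple(row), other_sets):
            specific_rows.append(tuple(row))
    total = len(target)
    specific = len(specific_rows)
    return {
        "total": total,
        "specific": specific,
        "shared": total - specific,
        "ratio": specific_ratio(specific, total) if total else 0.0,
        "specific_regions": pd.DataFrame(specific_rows, columns=["chrom", "start", "end"]),
    }


def group_gene_stats(
    group_cnvrs: Mapping[str, pd.DataFrame],
    members_by_group: Mapping[str, Sequence[str]],
    genes: pd.DataFrame,
    exons: pd.DataFrame,
    raw_depths,
    gc_tables,
    baselines,
    grid: BinGrid,
    sexes=None,
    min_frac: float = 0.7,
    cn_gt: float = 2.0,
    sd_min: float = 0.5,
) -> pd.DataFrame:
    """Gene content of each group's CNVRs.

    Applies the gene overlap + exonic-CN filters within each group's members
    only, then reports per group the number of final genes and — across the
    group's members — the mean and s.d. of the per-individual count of final
    genes at CN > ``cn_gt`` in that individual (the "cumulative gene count").
    """
    rows = []
    for group, members in members_by_group.items():
        cnvrs = group_cnvrs[group]
        if not len(cnvrs):
            rows.append({"group": group, "gene_count": 0, "mean_count": 0.0, "sd_count": 0.0})
            continue
        report = gene_cn_report(
            cnvrs, genes, exons,
            {m: raw_depths[m] for m in members},
            {m: gc_tables[m] for m in members},
            {m: baselines[m] for m in members},
            grid, sexes=sexes, min_frac=min_frac, cn_gt=cn_gt, sd_min=sd_min,
        )
        final = filter_cn_genes(report, cn_gt, sd_min)
        per_ind = []
        for m in members:
            col = f"cn_{m}"
            per_ind.append(int((final[col] > cn_gt).sum()) if col in final else 0)
        per_ind = np.array(per_ind, dtype=float)
        rows.append(
            {
                "group": group,
                "gene_count": int(len(final)),
                "mean_count": float(per_ind.mean()) if len(per_ind) else 0.0,
                "sd_count": float(per_ind.std(ddof=1)) if len(per_ind) > 1 else 0.0,
            }
        )
    return pd.DataFrame(rows)
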