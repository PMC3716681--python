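"""Gene-level copy-number annotation of CNVRs and set enrichment.

Genes at least 70% covered by the CNVR union are candidates. Because a CNVR
can ride on high-copy sequence outside the coding parts of a gene, each
candidate's copy number is re-measured on its exons: GC-corrected depth
(reusing the genome-wide correction table, not a refit) is averaged over
exonic bases by bin-overlap weighting and scaled by the refined diploid
baseline. A gene makes the final list only if its exonic CN exceeds 2 in at
least one individual and the sample s.d. across individuals is at least 0.5.

Enrichment of annotation terms among final genes uses an upper-tail
hypergeometric test with Benjamini-Hochberg correction across terms.
"""

from __future__ import annotations

from collections.abc import Mapping

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .cn import DiploidBaseline, GcCorrectionTable, correct_depth
from .errors import InvalidConfigError
from .grid import BinGrid
from .simulate import DepthTrack

__all__ = [
    "overlap_genes",
    "gene_exon_cn",
    "gene_cn_report",
    "filter_cn_genes",
    "genic_cnvr_percent",
    "enrich",
]


def _interval_trees(regions: pd.DataFrame) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for chrom, start, end in regions[["chrom", "start", "end"]].itertuples(index=False):
        if end > start:
            trees.setdefault(chrom, IntervalTree()).addi(int(start), int(end))
    return trees


def overlap_genes(
    cnvrs: pd.DataFrame, genes: pd.DataFrame, min_frac: float = 0.7
) -> pd.DataFrame:
    """Fraction of each gene covered by the union of CNVRs.

    Returns one row per gene with ``frac`` and ``overlap_pass`` (frac >=
    ``min_frac``, inclusive). Coverage is computed on the union, so splitting
    a CNVR into book-ended pieces changes nothing.
    """
    trees = _interval_trees(cnvrs)
    rows = []
    for gid, chrom, start, end in genes[["gene_id", "chrom", "start", "end"]].itertuples(index=False):
        glen = end - start
        covered = 0
        tree = trees.get(chrom)
        if tree is not None and glen > 0:
            hits = sorted(
                (max(iv.begin, start), min(iv.end, end)) for iv in tree.overlap(start, end)
            )
            last = start
            for s, e in hits:
                s = max(s, last)
                if e > s:
                    covered += e - s
                    last = e
        frac = covered / glen if glen > 0 else 0.0
        rows.append((gid, frac, frac >= min_frac))
    return pd.DataFrame(rows, columns=["gene_id", "frac", "overlap_pass"])


def gene_exon_cn(
    genes: pd.DataFrame,
    exons: pd.DataFrame,
    raw_depth: DepthTrack,
    gc_table: GcCorrectionTable,
    baseline: DiploidBaseline,
    grid: BinGrid,
    sex: str = "female",
) -> pd.Series:
    """Exonic copy number of each gene for one individual.

    Depth exists at bin resolution, so exon depth is aggregated by
    bin-overlap weighting: each exonic base contributes its bin's
    GC-corrected depth. CN = 2 x weighted mean / D; male X genes outside the
    PAR are doubled like the genome-wide track. Excluded bins contribute
    nothing. Genes with no measurable exonic base get NaN.
    """
    if baseline.stage != "refined":
        raise InvalidConfigError("gene_exon_cn requires the refined baseline")
    corrected = correct_depth(raw_depth, gc_table, grid)
    par_mask = grid.par_bin_mask()
    x_mask = grid.x_bin_mask()
    out = {}
    exons_by_gene = dict(tuple(exons.groupby("gene_id")))
    for gid, chrom in genes[["gene_id", "chrom"]].itertuples(index=False):
        ex = exons_by_gene.get(gid)
        if ex is None or chrom not in grid.chrom_names:
            out[gid] = np.nan
            continue
        wsum = 0.0
        w = 0.0
        for start, end in ex[["start", "end"]].itertuples(index=False):
            lo, hi = grid.bin_range(chrom, int(start), int(end))
            for gi in range(lo, hi):
                if corrected.excluded[gi]:
                    continue
                _, b0, b1 = _bin_span(grid, chrom, gi)
                ov = min(end, b1) - max(start, b0)
                if ov <= 0:
                    continue
                d = corrected.depth[gi]
                if sex == "male" and x_mask[gi] and not par_mask[gi]:
                    d *= 2.0
                wsum += ov * d
                w += ov
        out[gid] = 2.0 * (wsum / w) / baseline.depth if w > 0 else np.nan
    return pd.Series(out, name=raw_depth.individual_id)


def _bin_span(grid: BinGrid, chrom: str, gi: int) -> tuple[str, int, int]:
    sl = grid.chrom_slice(chrom)
    local = gi - sl.start
    return chrom, local * grid.bin_size, (local + 1) * grid.bin_size


def gene_cn_report(
    cnvrs: pd.DataFrame,
    genes: pd.DataFrame,
    exons: pd.DataFrame,
    raw_depths: Mapping[str, DepthTrack],
    gc_tables: Mapping[str, GcCorrectionTable],
    baselines: Mapping[str, DiploidBaseline],
    grid: BinGrid,
    sexes: Mapping[str, str] | None = None,
    min_frac: float = 0.7,
    cn_gt: float = 2.0,
    sd_min: float = 0.5,
) -> pd.DataFrame:
    """Full per-gene report: overlap fraction, per-individual exonic CN, s.d.
    and the pass/fail flags of the three gene filters."""
    ov = overlap_genes(cnvrs, genes, min_frac)
    candidates = genes.merge(ov[ov["overlap_pass"]], on="gene_id")
    report = ov.copy()
    cn_cols = {}
    for ind, raw in raw_depths.items():
        sex = (sexes or {}).get(ind, "female")
        cn = gene_exon_cn(candidates, exons, raw, gc_tables[ind], baselines[ind], grid, sex)
        cn_cols[f"cn_{ind}"] = cn
    cn_df = pd.DataFrame(cn_cols)
    report = report.set_index("gene_id").join(cn_df)
    vals = report[[c for c in report.columns if c.startswith("cn_")]]
    report["max_cn"] = vals.max(axis=1)
    report["cn_sd"] = vals.std(axis=1, ddof=1)
    report["cn_pass"] = report["max_cn"] > cn_gt
    report["sd_pass"] = report["cn_sd"] >= sd_min
    report["final"] = report["overlap_pass"] & report["cn_pass"] & report["sd_pass"]
    # genes that never passed the overlap filter carry no CN measurements
    report.loc[~report["overlap_pass"], ["cn_pass", "sd_pass", "final"]] = False
    return report.reset_index()


def filter_cn_genes(
    report: pd.DataFrame, cn_gt: float = 2.0, sd_min: float = 0.5
) -> pd.DataFrame:
    """Final gene list: overlap candidates with max CN > ``cn_gt`` (strict)
    and sample s.d. >= ``sd_min`` (inclusive)."""
    keep = (
        report["overlap_pass"]
        & (report["max_cn"] > cn_gt)
        & (report["cn_sd"] >= sd_min)
    )
    return report[keep.fillna(False)].reset_index(drop=True)


def genic_cnvr_percent(n_genic_cnvrs: int, n_total_cnvrs: int, decimals: int = 2) -> float:
    """Percentage of CNVRs that overlap genes, rounded to ``decimals``."""
    if n_total_cnvrs <= 0:
        raise InvalidConfigError("total CNVR count must be positive")
    return round(100.0 * n_genic_cnvrs / n_total_cnvrs, decimals)


def enrich(
    gene_set,
    annotation: pd.DataFrame,
    background,
) -> pd.DataFrame:
    """Term enrichment of ``gene_set`` against ``background``.

    ``annotation`` maps ``term_id -> gene_id`` (two columns). For each term
    with at least one annotated gene in the background, the p-value is the
    upper-tail hypergeometric probability of drawing >= k annotated genes in
    ``len(gene_set)`` draws from ``len(background)`` genes of which K are
    annotated; q-values are Benjamini-Hochberg over all tested terms.
    """
    gene_set = set(gene_set)
    background = set(background)
    missing = gene_set - background
    if missing:
        raise InvalidConfigError(
            f"{len(missing)} test genes absent from background, e.g. {sorted(missing)[:3]}"
        )
    N, n = len(background), len(gene_set)
    rows = []
    for term, sub in annotation.groupby("term_id"):
        term_genes = set(sub["gene_id"]) & background
        K = len(term_genes)
        if K == 0:
            continue
        k = len(term_genes & gene_set)
        p = float(hypergeom.sf(k - 1, N, K, n))
        rows.append((term, k, K, p))
    out = pd.DataFrame(rows, columns=["term_id", "k", "K", "p"])
    if len(out):
        out["q"] = multipletests(out["p"], method="fdr_bh")[1]
        out = out.sort_values("p", ignore_index=True)
    else:
        out["q"] = []
    return out
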