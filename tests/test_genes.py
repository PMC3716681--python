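"""Gene-level CNVR annotation, exonic CN filters and enrichment."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_uniform_grid, regions_frame
from rdcnv.cn import DiploidBaseline, GcCorrectionTable
from rdcnv.errors import InvalidConfigError
from rdcnv.genes import (
    enrich,
    filter_cn_genes,
    gene_cn_report,
    gene_exon_cn,
    genic_cnvr_percent,
    overlap_genes,
)
from rdcnv.simulate import DepthTrack


def genes_frame(rows):
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end"])


class TestOverlap:
    def test_gene_fully_inside_cnvr(self):
        cnvrs = regions_frame([("chr1", 0, 50_000)])
        genes = genes_frame([("g1", "chr1", 10_000, 20_000)])
        out = overlap_genes(cnvrs, genes)
        assert out.loc[0, "frac"] == 1.0
        assert bool(out.loc[0, "overlap_pass"])

    def test_seventy_percent_boundary_is_inclusive(self):
        genes = genes_frame([("g1", "chr1", 0, 10_000)])
        out_69 = overlap_genes(regions_frame([("chr1", 0, 6_900)]), genes)
        assert out_69.loc[0, "frac"] == pytest.approx(0.69)
        assert not bool(out_69.loc[0, "overlap_pass"])
        out_70 = overlap_genes(regions_frame([("chr1", 0, 7_000)]), genes)
        assert out_70.loc[0, "frac"] == pytest.approx(0.70)
        assert bool(out_70.loc[0, "overlap_pass"])

    @pytest.mark.parametrize("seed", range(5))
    def test_fraction_matches_per_base_oracle(self, seed):
        rng = np.random.default_rng(seed)
        cnvrs = regions_frame(
            [("chr1", int(s), int(s) + int(l))
             for s, l in zip(rng.integers(0, 90_000, 8), rng.integers(1000, 20_000, 8))]
        )
        genes = genes_frame([("g1", "chr1", 30_000, 70_000)])
        out = overlap_genes(cnvrs, genes)
        covered = np.zeros(100_000, dtype=bool)
        for _, s, e in cnvrs.itertuples(index=False):
            covered[s:e] = True
        want = covered[30_000:70_000].sum() / 40_000
        assert out.loc[0, "frac"] == pytest.approx(want, rel=1e-12)

    def test_invariant_to_book_ended_splitting(self):
        genes = genes_frame([("g1", "chr1", 0, 10_000)])
        whole = overlap_genes(regions_frame([("chr1", 2_000, 9_000)]), genes)
        split = overlap_genes(
            regions_frame([("chr1", 2_000, 5_000), ("chr1", 5_000, 9_000)]), genes
        )
        assert whole.loc[0, "frac"] == split.loc[0, "frac"]


def flat_table():
    return GcCorrectionTable(0.01, np.ones(100), np.zeros(100), np.zeros(100, bool))


class TestExonCn:
    def test_diploid_depth_gives_cn_two(self):
        grid = make_uniform_grid(50)
        genes = genes_frame([("g1", "chr1", 10_000, 20_000)])
        exons = genes_frame([("g1", "chr1", 10_500, 12_500), ("g1", "chr1", 15_000, 18_000)])
        raw = DepthTrack("i1", np.full(50, 8.0), np.zeros(50, bool))
        base = DiploidBaseline(8.0, np.arange(50), "refined")
        cn = gene_exon_cn(genes, exons, raw, flat_table(), base, grid)
        assert cn["g1"] == pytest.approx(2.0)

    def test_exon_cn_matches_bin_mean_when_tiling_whole_bins(self):
        grid = make_uniform_grid(50)
        rng = np.random.default_rng(1)
        depth = rng.gamma(8, 1, 50)
        genes = genes_frame([("g1", "chr1", 10_000, 14_000)])
        exons = genes_frame([("g1", "chr1", 10_000, 14_000)])  # exactly 4 bins
        raw = DepthTrack("i1", depth, np.zeros(50, bool))
        base = DiploidBaseline(8.0, np.arange(50), "refined")
        cn = gene_exon_cn(genes, exons, raw, flat_table(), base, grid)
        assert cn["g1"] == pytest.approx(2 * depth[10:14].mean() / 8.0, rel=1e-12)

    def test_partial_bin_overlap_weighting(self):
        grid = make_uniform_grid(10)
        depth = np.full(10, 8.0)
        depth[3] = 16.0
        genes = genes_frame([("g1", "chr1", 3_500, 4_500)])
        exons = genes_frame([("g1", "chr1", 3_500, 4_500)])  # half in bin3, half bin4
        raw = DepthTrack("i1", depth, np.zeros(10, bool))
        base = DiploidBaseline(8.0, np.arange(10), "refined")
        cn = gene_exon_cn(genes, exons, raw, flat_table(), base, grid)
        assert cn["g1"] == pytest.approx(2 * (0.5 * 16 + 0.5 * 8) / 8.0)

    def test_gene_in_high_cn_event_recovered(self, sim_run, cohort):
        """A gene inside a truth gain should show the event's exonic CN."""
        genome = sim_run["genome"]
        ann = genome.annotations
        found = 0
        for ind, truth in sim_run["truth"].items():
            spec = next(s for s in cohort if s.id == ind)
            for ev in truth.events:
                inside = ann.genes[
                    (ann.genes["chrom"] == ev.chrom)
                    & (ann.genes["start"] >= ev.start)
                    & (ann.genes["end"] <= ev.end)
                ]
                if not len(inside):
                    continue
                cn = gene_exon_cn(
                    inside, ann.exons, sim_run["raw_depths"][ind],
                    sim_run["gc_tables"][ind], sim_run["baselines"][ind],
                    genome.grid, sex=spec.sex,
                )
                for v in cn.dropna():
                    assert abs(v - ev.cn) < 0.5 * max(1.0, ev.cn / 4)
                    found += 1
            if found > 10:
                break
        assert found > 0

    def test_cnvr_without_exonic_gain_fails_cn_filter(self):
        """High-copy sequence around a gene whose exons stay diploid must not
        pass the exonic-CN screen."""
        grid = make_uniform_grid(50)
        depth = np.full(50, 8.0)
        depth[10:20] = 24.0  # CN 6 region
        depth[14:16] = 8.0   # ...but the exons inside are diploid
        genes = genes_frame([("g1", "chr1", 11_000, 19_000)])
        exons = genes_frame([("g1", "chr1", 14_000, 16_000)])
        cnvrs = regions_frame([("chr1", 10_000, 20_000)])
        raws = {
            f"i{k}": DepthTrack(f"i{k}", depth, np.zeros(50, bool)) for k in range(4)
        }
        tables = {k: flat_table() for k in raws}
        bases = {k: DiploidBaseline(8.0, np.arange(50), "refined") for k in raws}
        report = gene_cn_report(cnvrs, genes, exons, raws, tables, bases, grid)
        row = report.set_index("gene_id").loc["g1"]
        assert bool(row["overlap_pass"])
        assert not bool(row["cn_pass"])
        assert not bool(row["final"])


class TestFilter:
    def _report(self, vectors):
        rows = []
        for gid, vec in vectors.items():
            vec = np.asarray(vec, dtype=float)
            rows.append(
                {
                    "gene_id": gid, "frac": 1.0, "overlap_pass": True,
                    "max_cn": vec.max(), "cn_sd": vec.std(ddof=1),
                }
            )
        return pd.DataFrame(rows)

    def test_all_diploid_gene_excluded(self):
        rep = self._report({"g1": [2.0] * 16})
        assert len(filter_cn_genes(rep)) == 0

    def test_cn_exactly_two_fails_strict_filter(self):
        rep = self._report({"g1": [2.0] * 15 + [2.0]})
        rep.loc[0, "max_cn"] = 2.0
        rep.loc[0, "cn_sd"] = 0.6
        assert len(filter_cn_genes(rep)) == 0

    def test_sd_boundary_inclusive(self):
        rep = self._report({"g1": [2.0] * 16})
        rep.loc[0, "max_cn"] = 4.0
        rep.loc[0, "cn_sd"] = 0.5
        assert len(filter_cn_genes(rep)) == 1
        rep.loc[0, "cn_sd"] = 0.499
        assert len(filter_cn_genes(rep)) == 0

    def test_matches_exhaustive_filter_oracle(self):
        rng = np.random.default_rng(7)
        vectors = {
            f"g{k}": rng.choice([2.0, 2.0, 3.0, 6.0], size=16) for k in range(10)
        }
        rep = self._report(vectors)
        got = set(filter_cn_genes(rep)["gene_id"])
        want = {
            gid for gid, vec in vectors.items()
            if max(vec) > 2.0 and np.std(vec, ddof=1) >= 0.5
        }
        assert got == want

    def test_single_individual_cn_sd_example(self):
        vec = [2.0] * 15 + [4.0]
        sd = float(np.std(vec, ddof=1))
        rep = self._report({"g1": vec})
        expected = sd >= 0.5
        assert (len(filter_cn_genes(rep)) == 1) == expected


def test_genic_percent():
    assert genic_cnvr_percent(7, 50) == 14.0
    assert genic_cnvr_percent(1, 3) == pytest.approx(33.33)


ANNOT = pd.DataFrame(
    [("T1", f"g{k}") for k in range(5)] + [("T2", f"g{k}") for k in range(20)],
    columns=["term_id", "gene_id"],
)
BACKGROUND = [f"g{k}" for k in range(20)]


class TestEnrichment:
    def test_term_annotating_everything_has_p_one(self):
        out = enrich([f"g{k}" for k in range(5)], ANNOT, BACKGROUND)
        assert out.set_index("term_id").loc["T2", "p"] == pytest.approx(1.0)

    def test_exact_combinatorial_example(self):
        out = enrich([f"g{k}" for k in range(5)], ANNOT, BACKGROUND)
        # all 5 drawn genes annotated by T1 (K=5, N=20, n=5, k=5)
        want = 1 / math.comb(20, 5)
        assert out.set_index("term_id").loc["T1", "p"] == pytest.approx(want, rel=1e-12)
        # exhaustive enumeration oracle over all C(20,5) draws
        hits = sum(
            1 for draw in itertools.combinations(range(20), 5) if max(draw) <= 4
        )
        assert want == hits / math.comb(20, 5)

    def test_bh_step_up_by_hand(self):
        from statsmodels.stats.multitest import multipletests

        q = multipletests([0.01, 0.02, 0.03, 0.04], method="fdr_bh")[1]
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_gene_missing_from_background_is_an_error(self):
        with pytest.raises(InvalidConfigError):
            enrich(["gX"], ANNOT, BACKGROUND)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        ps=st.lists(st.floats(1e-6, 1.0), min_size=1, max_size=20),
    )
    def test_bh_properties_on_random_p_vectors(self, ps):
        from statsmodels.stats.multitest import multipletests

        q = multipletests(ps, method="fdr_bh")[1]
        assert np.all(q <= 1.0)
        assert np.all(q >= np.asarray(ps) - 1e-12)
        order = np.argsort(ps)
        assert np.all(np.diff(q[order]) >= -1e-12)
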