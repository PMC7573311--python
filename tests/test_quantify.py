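"""Fractional counting, allocation arithmetic, FPKM formulas, ratio
distribution and correlations."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from homeoquant import classify as cls
from homeoquant import quantify as qt
from homeoquant.genome import GeneModel, ReferenceGenome
from homeoquant.readmap import AlignmentRecord


def _placed(fid, label, blocks, chrom="chr1"):
    span = sum(e - s for s, e in blocks)
    rec = AlignmentRecord(fid, 1, label, mapped=True, chrom=chrom,
                          start=blocks[0][0], span=span, strand="+",
                          blocks=tuple(blocks), mismatches=0)
    return (rec, None)


@pytest.fixture()
def overlap_genomes():
    chrom = {"chr1": "A" * 3000}
    genes = [GeneModel("gX", "chr1", "+", ((100, 600),)),
             GeneModel("gY", "chr1", "+", ((400, 900),)),
             GeneModel("gZ", "chr1", "+", ((1500, 2000),))]
    g = ReferenceGenome(chrom, genes)
    return g, g


class TestCountFragments:
    def test_single_gene_fragment_counts_one(self, overlap_genomes):
        gA, gR = overlap_genomes
        frag = cls.ClassifiedFragment("f1", 0, 2, cls.ORIGIN_A,
                                      aln_A=_placed("f1", "A", [(120, 220)]))
        table = qt.count_fragments([frag], gA, gR)
        assert table.counts.loc["gX", "a"] == 1.0
        assert table.counts.drop("gX")["a"].sum() == 0.0

    def test_fragment_over_two_genes_split_half(self, overlap_genomes):
        gA, gR = overlap_genomes
        frag = cls.ClassifiedFragment("f1", 0, 2, cls.ORIGIN_A,
                                      aln_A=_placed("f1", "A", [(450, 550)]))
        table = qt.count_fragments([frag], gA, gR)
        assert table.counts.loc["gX", "a"] == 0.5
        assert table.counts.loc["gY", "a"] == 0.5

    def test_intergenic_fragment_contributes_nothing(self, overlap_genomes):
        gA, gR = overlap_genomes
        frag = cls.ClassifiedFragment("f1", 0, 2, cls.ORIGIN_A,
                                      aln_A=_placed("f1", "A", [(2500, 2600)]))
        table = qt.count_fragments([frag], gA, gR)
        assert table.counts.values.sum() == 0.0

    def test_unclassified_counted_on_majority_genome(self, overlap_genomes):
        gA, gR = overlap_genomes
        frag = cls.ClassifiedFragment(
            "f1", 1, 1, cls.UNCLASSIFIED,
            aln_A=_placed("f1", "A", [(1600, 1700)]),
            aln_R=_placed("f1", "R", [(1600, 1700)]))
        table = qt.count_fragments([frag], gA, gR, unclassified_on="R")
        assert table.counts.loc["gZ", "u"] == 1.0

    def test_unknown_chromosome_rejected(self, overlap_genomes):
        gA, gR = overlap_genomes
        frag = cls.ClassifiedFragment("f1", 0, 2, cls.ORIGIN_A,
                                      aln_A=_placed("f1", "A", [(0, 100)],
                                                    chrom="chrNope"))
        with pytest.raises(ValueError, match="unknown chromosome"):
            qt.count_fragments([frag], gA, gR)

    def test_fixture_total_weight_conserved(self, triploid):
        counted = triploid.table.counts.values.sum()
        placed = sum(
            1 for f in triploid.classified if f.origin != cls.DISCARDED)
        # every non-discarded fragment lands in exactly one gene here
        # (the synthetic gene models do not overlap)
        assert counted == pytest.approx(placed)


class TestRatioAndAllocation:
    def test_printed_formula_examples(self):
        assert qt.a_origin_ratio(10, 20) == pytest.approx(1 / 3)
        assert qt.a_origin_ratio(0, 7) == 0.0
        assert np.isnan(qt.a_origin_ratio(0, 0))
        with pytest.raises(ValueError):
            qt.a_origin_ratio(-1, 2)

    def test_allocation_example(self):
        a2, r2, fb = qt.allocate_unclassified(10, 20, 6)
        assert float(a2) == pytest.approx(12.0)
        assert float(r2) == pytest.approx(24.0)
        assert not bool(fb)

    def test_no_unclassified_is_identity(self):
        a2, r2, _ = qt.allocate_unclassified(3.5, 8.25, 0.0)
        assert float(a2) == 3.5 and float(r2) == 8.25

    def test_fallback_splits_evenly_and_flags(self):
        a2, r2, fb = qt.allocate_unclassified(0, 0, 9)
        assert float(a2) == float(r2) == 4.5
        assert bool(fb)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.floats(0, 1e6), st.floats(0, 1e6), st.floats(0, 1e6))
    def test_conservation_property(self, a, r, u):
        a2, r2, _ = qt.allocate_unclassified(a, r, u)
        assert float(a2 + r2) == pytest.approx(a + r + u, abs=1e-9 * (1 + a + r + u))
        assert float(a2) >= 0 and float(r2) >= 0


class TestFpkm:
    def test_printed_formula_value(self):
        out = qt.fpkm(pd.Series({"h": 100.0}), pd.Series({"h": 1000.0}),
                      sample_total=1e6)
        assert out["h"] == pytest.approx(100.0)

    def test_zero_count_zero_fpkm(self):
        out = qt.fpkm(pd.Series({"h": 0.0, "i": 5.0}),
                      pd.Series({"h": 500.0, "i": 500.0}))
        assert out["h"] == 0.0

    def test_scale_invariance(self):
        counts = pd.Series({"h": 10.0, "i": 30.0})
        lengths = pd.Series({"h": 700.0, "i": 1400.0})
        one = qt.fpkm(counts, lengths, 1e5)
        two = qt.fpkm(2 * counts, lengths, 2e5)
        pd.testing.assert_series_equal(one, two)

    def test_zero_length_skipped_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            out = qt.fpkm(pd.Series({"h": 5.0, "i": 5.0}),
                          pd.Series({"h": 0.0, "i": 100.0}))
        assert np.isnan(out["h"]) and not np.isnan(out["i"])
        assert "zero length" in caplog.text

    def test_post_allocation_totals_make_fpkm_length_sum_exact(self,
                                                               triploid):
        for sub, lcol in (("A", "L_A"), ("R", "L_R")):
            f = qt.fpkm_polyploid(triploid.table, sub)
            total = float((f * triploid.table.lengths[lcol]).sum())
            assert total == pytest.approx(1e9, rel=1e-12)

    def test_progenitor_equals_polyploid_when_fully_classified(self):
        # a diploid sample where every fragment classifies to its own genome
        counts = pd.DataFrame({
            "a": [40.0, 10.0, 0.0], "r": [0.0, 0.0, 0.0],
            "u": [0.0, 0.0, 0.0]}, index=["g1", "g2", "g3"])
        lengths = pd.DataFrame({"L_A": [500.0, 1000.0, 800.0],
                                "L_R": [500.0, 1000.0, 800.0]},
                               index=counts.index)
        table = qt.HomeologCountTable(counts, lengths)
        pd.testing.assert_series_equal(qt.fpkm_progenitor(table, "A"),
                                       qt.fpkm_polyploid(table, "A"))


class TestRatioDistribution:
    def test_symmetric_pairs_mode_bin_contains_half(self):
        # all pairs with a == r: the mode bin must contain p = 0.5
        dist = qt.ratio_distribution(np.full(200, 0.5))
        assert abs(dist.mode - 0.5) <= 0.01 + 1e-12

    def test_single_subgenome_mass_on_edges(self):
        p = np.array([0.0] * 30 + [1.0] * 10 + [0.4] * 5)
        dist = qt.ratio_distribution(p)
        assert dist.n_zero == 30 and dist.n_one == 10
        assert dist.counts.sum() == 5

    def test_undefined_only_rejected(self):
        with pytest.raises(ValueError):
            qt.ratio_distribution([np.nan, np.nan])

    def test_triploid_sample_mode_bin_contains_one_third(self, triploid):
        ratios = qt.a_origin_ratio(triploid.table.counts["a"].values,
                                   triploid.table.counts["r"].values)
        dist = qt.ratio_distribution(ratios, bin_width=0.05)
        assert dist.mode - 0.025 <= 1 / 3 < dist.mode + 0.025

    def test_pooled_ratio_tracks_dosage(self, triploid):
        p = qt.pooled_origin_ratio(triploid.table)
        n = triploid.table.counts[["a", "r"]].values.sum()
        sigma = np.sqrt((1 / 3) * (2 / 3) / n)
        assert abs(p - 1 / 3) < 3 * sigma


class TestRatioCorrelation:
    def _ratio_frame(self, rng, n=400, noise_counts=500):
        true_p = rng.uniform(0.1, 0.9, size=n)
        cols = {}
        for t in (0.0, 2.0):
            a = rng.binomial(noise_counts, true_p)
            cols[t] = a / noise_counts
        return pd.DataFrame(cols)

    def test_identical_time_points_correlate_perfectly(self):
        rng = np.random.default_rng(0)
        df = self._ratio_frame(rng)
        df[2.0] = df[0.0]
        assert qt.ratio_timepoint_correlation(df, 0.0, 2.0) == \
            pytest.approx(1.0)

    def test_stable_dosage_high_correlation(self):
        rng = np.random.default_rng(1)
        df = self._ratio_frame(rng)
        assert qt.ratio_timepoint_correlation(df, 0.0, 2.0) > 0.9

    def test_shuffled_ratios_uncorrelated(self):
        rng = np.random.default_rng(2)
        df = self._ratio_frame(rng)
        df[2.0] = rng.permutation(df[2.0].values)
        r = qt.ratio_timepoint_correlation(df, 0.0, 2.0)
        assert abs(r) < 4 / np.sqrt(len(df))

    def test_constant_vector_undefined(self):
        df = pd.DataFrame({0.0: [0.5, 0.5, 0.5, 0.5],
                           2.0: [0.1, 0.2, 0.3, 0.4]})
        assert np.isnan(qt.ratio_timepoint_correlation(df, 0.0, 2.0))

    def test_too_few_pairs_rejected(self):
        df = pd.DataFrame({0.0: [0.5, np.nan], 2.0: [0.4, 0.6]})
        with pytest.raises(ValueError):
            qt.ratio_timepoint_correlation(df, 0.0, 2.0)
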