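import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ernascan import diffexpr as dx

from conftest import make_reads


class TestTwoProportionZ:
    def test_equal_proportions_give_null(self):
        res = dx.two_proportion_z(dx.RegionCounts(10, 10, 10**6, 10**6))
        assert res.z == 0.0 and res.p == 1.0

    def test_worked_example(self):
        res = dx.two_proportion_z(dx.RegionCounts(30, 10, 10**6, 10**6))
        assert res.z == pytest.approx(3.1623, abs=1e-4)
        assert res.p == pytest.approx(1.57e-3, rel=5e-3)

    def test_degenerate_pooled_proportion(self):
        res = dx.two_proportion_z(dx.RegionCounts(0, 0, 10**6, 10**6))
        assert res.z == 0.0 and res.p == 1.0

    def test_count_exceeding_library_rejected(self):
        with pytest.raises(ValueError):
            dx.RegionCounts(11, 0, 10, 10)

    def test_z_squared_equals_pearson_chi2(self):
        """On random 2x2 tables the squared statistic must equal the Pearson
        chi-square (no continuity correction) to 1e-9."""
        rng = np.random.default_rng(123)
        for _ in range(200):
            big_n_a = int(rng.integers(1_000, 10**6))
            big_n_b = int(rng.integers(1_000, 10**6))
            n_a = int(rng.integers(1, 500))
            n_b = int(rng.integers(1, 500))
            res = dx.two_proportion_z(
                dx.RegionCounts(n_a, n_b, big_n_a, big_n_b))
            table = [[n_a, big_n_a - n_a], [n_b, big_n_b - n_b]]
            chi2 = stats.chi2_contingency(table, correction=False)[0]
            assert res.z ** 2 == pytest.approx(chi2, abs=1e-9, rel=1e-9)

    def test_swapping_tissues_negates_z_preserves_p(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            n_a, n_b = int(rng.integers(0, 100)), int(rng.integers(0, 100))
            a = dx.two_proportion_z(dx.RegionCounts(n_a, n_b, 10**5, 2 * 10**5))
            b = dx.two_proportion_z(dx.RegionCounts(n_b, n_a, 2 * 10**5, 10**5))
            assert a.z == pytest.approx(-b.z, abs=1e-12)
            assert a.p == pytest.approx(b.p, abs=1e-12)


class TestIndices:
    @pytest.mark.parametrize("s,u,expected", [
        (5.0, 5.0, 0.0), (7.0, 0.0, 1.0), (3.0, 1.0, 0.5), (0.0, 4.0, -1.0),
    ])
    def test_specificity_index(self, s, u, expected):
        assert dx.specificity_index(s, u) == pytest.approx(expected)

    def test_specificity_undefined_at_zero(self):
        assert dx.specificity_index(0.0, 0.0) == 0.0

    def test_specificity_antisymmetric(self):
        assert dx.specificity_index(3, 1) == -dx.specificity_index(1, 3)

    @pytest.mark.parametrize("f,r,expected", [
        (5.0, 5.0, 0.0), (7.0, 0.0, 1.0), (30.0, 10.0, 0.5),
    ])
    def test_directionality_index(self, f, r, expected):
        assert dx.directionality_index(f, r) == pytest.approx(expected)

    def test_directionality_symmetric(self):
        assert dx.directionality_index(30, 10) == dx.directionality_index(10, 30)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            dx.specificity_index(-1, 1)
        with pytest.raises(ValueError):
            dx.directionality_index(-1, 1)


class TestRpkm:
    def test_arithmetic(self):
        assert dx.rpkm(20, 2_000, 10**7) == pytest.approx(1.0)

    def test_visualization_floor(self):
        assert dx.rpkm(0, 2_000, 10**7, visualization_floor=True) == 2.0**-9

    def test_no_floor_without_flag(self):
        assert dx.rpkm(0, 2_000, 10**7) == 0.0


class TestFoldChange:
    def test_zero_count_substituted_with_one(self):
        fold, lfc, _ = dx.enhancer_fold_change(40, 0, 10**6, 10**6)
        assert fold == 40.0 and lfc == pytest.approx(math.log2(40))

    def test_equal_counts(self):
        fold, lfc, _ = dx.enhancer_fold_change(25, 25, 10**6, 10**6)
        assert fold == 1.0 and lfc == 0.0

    def test_double_substitution(self):
        fold, lfc, p = dx.enhancer_fold_change(0, 0, 10**6, 10**6)
        assert fold == 1.0 and lfc == 0.0 and p == 1.0


class TestConcordance:
    def _catalog(self, rows):
        df = pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])
        df["score"], df["strand"] = 0.0, "."
        return df

    def test_all_concordant(self):
        cat = self._catalog([("chr1", 9_000, 11_000, "heart")])
        readsets = {
            "heart": make_reads([("chr1", 9_900, 10_100, "+")] * 5),
            "limb": make_reads([("chr1", 9_900, 10_100, "+")] * 2)}
        assert dx.concordance_fraction(cat, readsets, "heart") == 1.0

    def test_ties_are_discordant(self):
        cat = self._catalog([("chr1", 9_000, 11_000, "heart")])
        readsets = {
            "heart": make_reads([("chr1", 9_900, 10_100, "+")] * 3),
            "limb": make_reads([("chr1", 9_900, 10_100, "+")] * 3)}
        assert dx.concordance_fraction(cat, readsets, "heart") == 0.0

    def test_empty_catalog_rejected(self):
        with pytest.raises(ValueError):
            dx.concordance_fraction(self._catalog([]), {}, "heart")


class TestExactConcordanceTest:
    def test_in_vivo_worked_example(self):
        """12 of 15 enhancers most expressed in the predicted tissue under a
        1-in-3 null prints p = 0.0006."""
        p = dx.exact_concordance_test(12, 15, 1 / 3)
        assert f"{p:.1g}" == "0.0006"

    def test_all_successes_small_n(self):
        assert dx.exact_concordance_test(3, 3, 1 / 3) == \
            pytest.approx(2 / 27)

    def test_capped_at_one(self):
        assert dx.exact_concordance_test(5, 15, 1 / 3) == 1.0

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            dx.exact_concordance_test(16, 15, 0.5)
        with pytest.raises(ValueError):
            dx.exact_concordance_test(1, 2, 0.0)


class TestCallTstrs:
    def _region(self):
        return pd.DataFrame([{"chrom": "chr1", "start": 9_000, "end": 11_000,
                              "name": "r0", "score": 0.0, "strand": ".",
                              "peak_center": 10_000}])

    @staticmethod
    def _readset(n_window, strand, n_background=1_000):
        rows = ([("chr1", 9_900, 10_100, strand)] * n_window
                + [("chr1", 500_000, 500_200, "+")] * n_background)
        return make_reads(rows)

    def test_significant_region_assigned_to_higher_tissue(self):
        readsets = {"heart": self._readset(60, "+"),
                    "limb": self._readset(5, "-")}
        out = dx.call_tstrs(self._region(), readsets)
        assert out.iloc[0]["tissue"] == "heart"
        assert out.iloc[0]["p"] < 0.01
        assert out.iloc[0]["si"] > 0.8
        assert out.iloc[0]["di_heart"] == 1.0

    def test_subthreshold_region_unassigned(self):
        readsets = {"heart": self._readset(6, "+"),
                    "limb": self._readset(5, "-")}
        out = dx.call_tstrs(self._region(), readsets)
        assert out.iloc[0]["tissue"] == "none"

    def test_alpha_boundary_is_strict(self):
        z_crit = 2.5758293035489004  # p exactly alpha at this z
        p = 2 * stats.norm.sf(z_crit)
        assert not (p < 0.01)  # strict inequality excludes the boundary


class TestQpcrCandidates:
    def _tstrs(self, n=10):
        return pd.DataFrame({"name": [f"t{i}" for i in range(n)],
                             "z": np.linspace(-5, 5, n)})

    def test_requesting_whole_pool_returns_top_30_percent(self):
        got = dx.select_qpcr_candidates(self._tstrs(10), m=3, seed=0)
        pool = self._tstrs(10)
        top = pool.reindex(pool["z"].abs().sort_values(
            ascending=False).index).head(3)
        assert len(got) == 3
        assert set(got["name"]) == set(top["name"])

    def test_seeded_reproducibility(self):
        a = dx.select_qpcr_candidates(self._tstrs(30), m=5, seed=42)
        b = dx.select_qpcr_candidates(self._tstrs(30), m=5, seed=42)
        pd.testing.assert_frame_equal(a, b)

    def test_oversized_request_rejected(self):
        with pytest.raises(ValueError):
            dx.select_qpcr_candidates(self._tstrs(10), m=4, seed=0)
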