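import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ernascan import feature_overlap as fo
from ernascan.genomic_io import CoverageTrack

from conftest import make_intervals


def tstr_frame(rows):
    """(chrom, peak_center) tuples -> minimal TSTR table."""
    df = pd.DataFrame(rows, columns=["chrom", "peak_center"])
    df["name"] = [f"t{i}" for i in range(len(df))]
    df["start"] = df["peak_center"] - 500
    df["end"] = df["peak_center"] + 500
    return df


class TestConservationScore:
    def _phastcons(self, rows):
        df = make_intervals([(c, s, e) for c, s, e, _ in rows])
        df["score"] = [v for *_, v in rows]
        return df

    def test_most_constrained_element_wins(self):
        tstrs = tstr_frame([("chr1", 10_000)])
        pc = self._phastcons([("chr1", 9_800, 9_900, 350.0),
                              ("chr1", 10_100, 10_200, 500.0)])
        out = fo.conservation_score(tstrs, pc)
        assert out.iloc[0]["cons_score"] == 500.0

    def test_no_overlap_flags_not_conserved(self):
        tstrs = tstr_frame([("chr1", 10_000)])
        pc = self._phastcons([("chr1", 50_000, 50_300, 400.0)])
        out = fo.conservation_score(tstrs, pc)
        assert np.isnan(out.iloc[0]["cons_score"])
        assert not out.iloc[0]["conserved"]

    def test_single_base_window_touch_counts(self):
        tstrs = tstr_frame([("chr1", 10_000)])  # window [9500, 10500)
        pc = self._phastcons([("chr1", 10_499, 10_600, 420.0)])
        out = fo.conservation_score(tstrs, pc)
        assert out.iloc[0]["conserved"]


class TestCageOverlap:
    def test_midpoint_within_reach(self):
        # 1 kb TSTR window + 1 kb CAGE extension reaches 1.5 kb center gap
        tstrs = tstr_frame([("chr1", 10_000)])
        cage = make_intervals([("chr1", 11_390, 11_410)])  # midpoint 11,400
        assert fo.cage_overlap(tstrs, cage).iloc[0]["has_cage"]

    def test_midpoint_out_of_reach(self):
        tstrs = tstr_frame([("chr1", 10_000)])
        cage = make_intervals([("chr1", 11_590, 11_610)])  # midpoint 11,600
        assert not fo.cage_overlap(tstrs, cage).iloc[0]["has_cage"]

    def test_no_track_means_no_overlap(self):
        tstrs = tstr_frame([("chr1", 10_000)])
        assert not fo.cage_overlap(tstrs, make_intervals([])).iloc[0]["has_cage"]


def enumerate_fisher(a, b, c, d):
    """Full hypergeometric enumeration of the two-sided Fisher p-value."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    p_obs = stats.hypergeom.pmf(a, n, r1, c1)
    total = 0.0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        px = stats.hypergeom.pmf(x, n, r1, c1)
        if px <= p_obs * (1 + 1e-9):
            total += px
    return min(total, 1.0)


class TestFisherExact:
    def test_diagonal_table(self):
        p = fo.fisher_exact_2x2(fo.ContingencyTable2x2(5, 0, 0, 5))
        assert p == pytest.approx(2 / 252, rel=1e-9)

    def test_symmetric_table(self):
        assert fo.fisher_exact_2x2(fo.ContingencyTable2x2(1, 1, 1, 1)) == 1.0

    def test_degenerate_margin(self):
        assert fo.fisher_exact_2x2(fo.ContingencyTable2x2(0, 0, 3, 4)) == 1.0

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(100):
            a, b, c, d = (int(x) for x in rng.integers(0, 11, 4))
            if min(a + b, c + d, a + c, b + d) == 0:
                continue
            got = fo.fisher_exact_2x2(fo.ContingencyTable2x2(a, b, c, d))
            assert got == pytest.approx(enumerate_fisher(a, b, c, d),
                                        abs=1e-9)


class TestChipClassification:
    def _track(self, values, bin_size=1_000):
        t = CoverageTrack(bin_size=bin_size)
        t.data["chr1"] = np.asarray(values, dtype=float)
        return t

    def _uniform_background(self, value=5.0, nbins=1_100):
        return self._track(np.full(nbins, value))

    def test_coverage_at_percentile_is_enriched(self):
        """'Equal to or greater than' the 95th percentile counts as
        enriched."""
        chip = self._uniform_background(5.0)
        tstrs = tstr_frame([("chr1", 1_050_500)])
        out = fo.chip_enrichment_classify(
            tstrs, {"p300": chip}, None, "chr1", (0, 1_000_000),
            strategy="raw")
        assert out.iloc[0]["enriched_p300"]  # exactly at the cutoff

    def test_background_mean_coverage_is_not_enriched(self):
        rng = np.random.default_rng(2)
        values = rng.poisson(5, 1_100).astype(float)
        values[1_050] = 5.0  # TSTR window sits exactly at the background mean
        chip = self._track(values)
        tstrs = tstr_frame([("chr1", 1_050_500)])
        out = fo.chip_enrichment_classify(
            tstrs, {"p300": chip}, None, "chr1", (0, 1_000_000),
            strategy="raw")
        assert not out.iloc[0]["enriched_p300"]

    def test_enrichment_monotone_in_coverage(self):
        rng = np.random.default_rng(5)
        values = rng.poisson(5, 1_100).astype(float)
        tstrs = tstr_frame([("chr1", 1_050_500)])
        boosted = values.copy()
        boosted[1_050] += 100.0
        base = fo.chip_enrichment_classify(
            tstrs, {"p300": self._track(values)}, None, "chr1",
            (0, 1_000_000), strategy="raw")
        more = fo.chip_enrichment_classify(
            tstrs, {"p300": self._track(boosted)}, None, "chr1",
            (0, 1_000_000), strategy="raw")
        assert more.iloc[0]["enriched_p300"] >= base.iloc[0]["enriched_p300"]

    def test_short_background_span_rejected(self):
        tstrs = tstr_frame([("chr1", 10_000)])
        with pytest.raises(ValueError):
            fo.chip_enrichment_classify(tstrs, {}, None, "chr1", (0, 10_000))

    def test_class_derivation(self):
        tstrs = tstr_frame([("chr1", 1_050_500)])
        rng = np.random.default_rng(3)
        hot = self._track(np.r_[rng.poisson(5, 1_050).astype(float),
                                [500.0] * 50])
        cold = self._track(rng.poisson(5, 1_100).astype(float))
        cold.data["chr1"][1_050] = 5.0
        out = fo.chip_enrichment_classify(
            tstrs, {"p300": hot, "k27ac": cold}, None, "chr1",
            (0, 1_000_000), strategy="raw")
        assert out.iloc[0]["chip_class"] == "p300_only"

    def test_simulated_marks_recovered(self, poisson_bundle):
        """Loci planted with a mark classify as enriched for it in >=95% of
        cases on the study-condition fixture."""
        loci = [l for l in poisson_bundle.loci if l.has_p300]
        tstrs = tstr_frame([(l.chrom, l.center) for l in loci])
        bg_chrom, bg_len = poisson_bundle.genome.chromosomes[0]
        out = fo.chip_enrichment_classify(
            tstrs, poisson_bundle.tracks.chip_coverage,
            poisson_bundle.tracks.chip_input, bg_chrom, (0, bg_len))
        assert out["enriched_p300"].mean() >= 0.95


class TestTssDistance:
    def _genes(self, rows):
        return pd.DataFrame(rows, columns=["gene_name", "chrom", "strand",
                                           "tx_start", "tx_end"])

    def test_tss_at_center_gives_zero(self):
        genes = self._genes([("g1", "chr1", "+", 10_000, 20_000)])
        out = fo.distance_to_nearest_tss(tstr_frame([("chr1", 10_000)]),
                                         genes)
        assert out.iloc[0]["tss_distance"] == 0

    def test_single_distant_gene(self):
        genes = self._genes([("g1", "chr1", "+", 20_000, 30_000)])
        out = fo.distance_to_nearest_tss(tstr_frame([("chr1", 10_000)]),
                                         genes)
        assert out.iloc[0]["tss_distance"] == 10_000

    def test_minus_strand_tss_is_tx_end(self):
        genes = self._genes([("g1", "chr1", "-", 20_000, 30_000)])
        out = fo.distance_to_nearest_tss(tstr_frame([("chr1", 10_000)]),
                                         genes)
        assert out.iloc[0]["tss_distance"] == 20_000

    def test_matches_brute_force(self):
        rng = np.random.default_rng(9)
        genes = self._genes([
            (f"g{i}", rng.choice(["chr1", "chr2"]), rng.choice(["+", "-"]),
             int(s), int(s) + 5_000)
            for i, s in enumerate(rng.integers(0, 900_000, 50))])
        tstrs = tstr_frame([(c, int(p)) for c, p in
                            zip(rng.choice(["chr1", "chr2"], 20),
                                rng.integers(0, 900_000, 20))])
        out = fo.distance_to_nearest_tss(tstrs, genes)
        for row in out.itertuples(index=False):
            sub = genes[genes["chrom"] == row.chrom]
            tss = np.where(sub["strand"] == "+", sub["tx_start"],
                           sub["tx_end"])
            assert row.tss_distance == np.abs(tss - row.peak_center).min()

    def test_no_genes_rejected(self):
        with pytest.raises(ValueError):
            fo.distance_to_nearest_tss(tstr_frame([("chr1", 10)]),
                                       self._genes([]))


class TestClassSummaries:
    def _tstrs(self):
        df = tstr_frame([("chr1", i * 10_000) for i in range(1, 7)])
        df["chip_class"] = ["both"] * 6
        df["rpkm_heart"] = np.arange(6, dtype=float)
        df["di_heart"] = np.linspace(0, 1, 6)
        df["conserved"] = True
        df["tss_distance"] = 1_000
        return df

    def test_single_class_leaves_others_na(self):
        out = fo.class_summaries(self._tstrs(), ["heart"])
        row_none = out[out["chip_class"] == "none"].iloc[0]
        assert row_none["n"] == 0 and np.isnan(row_none["median_rpkm_heart"])
        row_both = out[out["chip_class"] == "both"].iloc[0]
        assert row_both["n"] == 6

    def test_class_counts_partition_total(self, poisson_bundle):
        loci = poisson_bundle.loci
        tstrs = tstr_frame([(l.chrom, l.center) for l in loci])
        bg_chrom, bg_len = poisson_bundle.genome.chromosomes[0]
        classified = fo.chip_enrichment_classify(
            tstrs, poisson_bundle.tracks.chip_coverage,
            poisson_bundle.tracks.chip_input, bg_chrom, (0, bg_len))
        out = fo.class_summaries(classified, [])
        assert out["n"].sum() == len(loci)

    def test_di_cumulative_curve_ends_at_one(self):
        out = fo.di_cumulative(self._tstrs(), "heart")
        assert out.groupby("chip_class")["cumulative"].max().eq(1.0).all()

    def test_planted_conservation_enrichment_detected(self, poisson_bundle):
        """Fisher test rejects at p<0.01 when conservation is planted at
        >=2-fold enrichment in specific loci over non-specific ones."""
        truth = poisson_bundle.truth
        spec = truth[truth["specific"] == 1]["conserved"].to_numpy(bool)
        non = truth[truth["specific"] == 0]["conserved"].to_numpy(bool)
        _, _, p = fo.conservation_enrichment(spec, non)
        assert p < 0.01
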