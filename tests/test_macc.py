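"""MACC slope fitting, trend tests, GC correction and quadrant classification."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats

from macckit import (
    Genome,
    TitrationSeries,
    classify_occupancy_accessibility,
    fit_macc,
    gc_content,
    gc_correct,
    h3_enrichment,
    mann_kendall_p,
    median_shift,
    significance_weight,
)
from macckit.macc import GCTrack, flag_cpg_islands
from macckit.tracks import BinnedTrack

from conftest import make_macc

CONCS = np.array([1.5, 6.25, 25.0, 100.0])


def series_from_matrix(y, concs=CONCS, bin_size=300):
    """Build a titration series from a (k, n_bins) frequency matrix."""
    y = np.asarray(y, dtype=float)
    tracks = [BinnedTrack(bin_size, {"chr1": row.copy()}, normalized=True) for row in y]
    return TitrationSeries(tracks, np.asarray(concs, float))


def ols_slope(x, y):
    """Closed-form least-squares slope: the independent oracle."""
    xc = x - x.mean()
    return float(xc @ (y - y.mean()) / (xc @ xc))


# ---------------------------------------------------------------------------
# fit_macc


class TestFitMACC:
    def test_rising_frequency_means_inaccessible(self):
        # y grows with MNase amount -> scenario 2 -> negative slope
        m = fit_macc(series_from_matrix([[1.0], [2.0], [3.0], [4.0]]))
        assert m.data["chr1"][0] == pytest.approx(-0.715, abs=5e-4)

    def test_sign_symmetry(self):
        m = fit_macc(series_from_matrix([[4.0], [3.0], [2.0], [1.0]]))
        assert m.data["chr1"][0] == pytest.approx(+0.715, abs=5e-4)

    def test_flat_response_gets_zero_slope_unit_p(self):
        m = fit_macc(series_from_matrix([[5.0], [5.0], [5.0], [5.0]]))
        assert m.data["chr1"][0] == 0.0
        assert m.pvalues["chr1"][0] == 1.0

    def test_all_zero_bin_is_missing(self):
        m = fit_macc(series_from_matrix([[0.0, 1.0], [0.0, 2.0], [0.0, 2.5], [0.0, 4.0]]))
        assert np.isnan(m.data["chr1"][0])
        assert np.isfinite(m.data["chr1"][1])

    def test_any_zero_exclusion_rule(self):
        m = fit_macc(
            series_from_matrix([[0.0, 1.0], [1.0, 2.0], [2.0, 2.5], [3.0, 4.0]]),
            exclude="any_zero",
        )
        assert np.isnan(m.data["chr1"][0])
        assert np.isfinite(m.data["chr1"][1])

    def test_identical_concentrations_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            fit_macc(series_from_matrix([[1.0], [2.0], [3.0], [4.0]], concs=[1, 2, 2, 3]))

    def test_slope_matches_closed_form_oracle(self):
        rng = np.random.default_rng(42)
        y = rng.gamma(2.0, 2.0, size=(4, 10_000))
        m = fit_macc(series_from_matrix(y))
        x = -np.log(CONCS)
        expected = np.array([ols_slope(x, y[:, j]) for j in range(y.shape[1])])
        np.testing.assert_allclose(m.data["chr1"], expected, atol=1e-10)

    def test_pvalue_matches_pearson_t_test(self):
        rng = np.random.default_rng(1)
        y = rng.gamma(2.0, 2.0, size=(4, 200))
        m = fit_macc(series_from_matrix(y))
        x = -np.log(CONCS)
        expected = np.array([stats.pearsonr(x, y[:, j]).pvalue for j in range(200)])
        np.testing.assert_allclose(m.pvalues["chr1"], expected, atol=1e-9)

    def test_log_base_change_rescales_by_ln2(self):
        rng = np.random.default_rng(2)
        y = rng.gamma(2.0, 2.0, size=(4, 500))
        m_e = fit_macc(series_from_matrix(y), log_base=math.e)
        m_2 = fit_macc(series_from_matrix(y), log_base=2)
        # base-2 log stretches the abscissa by 1/ln 2, so slopes shrink by ln 2
        np.testing.assert_allclose(
            m_2.data["chr1"], m_e.data["chr1"] * math.log(2), atol=1e-12
        )
        np.testing.assert_allclose(m_2.pvalues["chr1"], m_e.pvalues["chr1"], atol=1e-12)


# ---------------------------------------------------------------------------
# Mann-Kendall


class TestMannKendall:
    def test_exact_p_matches_exhaustive_enumeration_k4(self):
        # oracle: enumerate all 24 orderings of 4 distinct values
        base = np.array([1.0, 2.0, 3.0, 4.0])

        def s_stat(v):
            return sum(
                np.sign(v[j] - v[i]) for i in range(len(v)) for j in range(i + 1, len(v))
            )

        all_s = [s_stat(np.array(p)) for p in itertools.permutations(base)]
        for perm in itertools.permutations(base):
            s_obs = s_stat(np.array(perm))
            exact = np.mean([abs(s) >= abs(s_obs) for s in all_s])
            assert mann_kendall_p(perm) == pytest.approx(exact, abs=0)

    def test_monotone_k4(self):
        assert mann_kendall_p([1, 2, 3, 4]) == pytest.approx(2 / 24)

    def test_reversal_symmetry(self):
        assert mann_kendall_p([4, 3, 2, 1]) == mann_kendall_p([1, 2, 3, 4])

    def test_constant_series_p_one(self):
        assert mann_kendall_p([1, 1, 1, 1]) == 1.0

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            mann_kendall_p([1, 2])

    def test_large_k_approximation_close_to_scipy_kendall(self):
        rng = np.random.default_rng(3)
        v = rng.normal(size=15)
        ours = mann_kendall_p(v)
        ref = stats.kendalltau(np.arange(15), v).pvalue
        assert ours == pytest.approx(ref, rel=0.15)


# ---------------------------------------------------------------------------
# significance weighting


class TestSignificanceWeight:
    def test_weighting_formula_extremes(self):
        m = make_macc([2.0, 2.0])
        m.pvalues = {"chr1": np.array([1.0, 0.0])}
        w = significance_weight(m)
        np.testing.assert_array_equal(w.data["chr1"], [0.0, 2.0])

    def test_weighting_preserves_sign(self):
        rng = np.random.default_rng(4)
        m = make_macc(rng.normal(size=100))
        m.pvalues = {"chr1": rng.uniform(0, 0.99, 100)}
        w = significance_weight(m)
        assert np.all(np.sign(w.data["chr1"]) == np.sign(m.data["chr1"]))

    def test_double_weighting_rejected(self):
        m = make_macc([1.0])
        m.pvalues = {"chr1": np.array([0.5])}
        w = significance_weight(m)
        with pytest.raises(ValueError):
            significance_weight(w)

    def test_weighted_unweighted_strongly_correlated_on_simulation(self, c_macc10k):
        w = significance_weight(c_macc10k.copy())
        a = c_macc10k.defined_values()
        b = w.defined_values()
        assert np.corrcoef(a, b)[0, 1] >= 0.9

    def test_mann_kendall_weighting(self):
        y = np.array([[1.0, 5.0], [2.0, 5.0], [3.0, 5.0], [4.0, 5.0]])
        series = series_from_matrix(y)
        m = fit_macc(series)
        w = significance_weight(m.copy(), method="mann_kendall", series=series)
        # monotone bin: P = 2/24; flat bin: slope already 0
        assert w.data["chr1"][0] == pytest.approx(m.data["chr1"][0] * (1 - 2 / 24))
        assert w.data["chr1"][1] == 0.0


# ---------------------------------------------------------------------------
# GC content and correction


class TestGCContent:
    def test_base_counting(self, tmp_path):
        fa = tmp_path / "ref.fa"
        fa.write_text(">chr1\n" + "ATGC" + "GGGCCC"[:2] + "NN" + "\n")  # ATGCGG NN
        genome = Genome({"chr1": 8})
        gc = gc_content(str(fa), genome, 4)
        assert gc.data["chr1"][0] == pytest.approx(0.5)  # ATGC
        assert gc.data["chr1"][1] == pytest.approx(1.0)  # GGNN -> GG of 2 bases

    def test_all_n_bin_missing(self, tmp_path):
        fa = tmp_path / "ref.fa"
        fa.write_text(">chr1\nNNNNATAT\n")
        gc = gc_content(str(fa), Genome({"chr1": 8}), 4)
        assert np.isnan(gc.data["chr1"][0])
        assert gc.data["chr1"][1] == 0.0

    def test_missing_chromosome_rejected(self, tmp_path):
        fa = tmp_path / "ref.fa"
        fa.write_text(">chrX\nACGT\n")
        with pytest.raises(ValueError, match="chr1"):
            gc_content(str(fa), Genome({"chr1": 4}), 4)


def _biased_track(n=4000, seed=9, bias=1.0):
    """MACC-like values with an injected monotone GC trend."""
    rng = np.random.default_rng(seed)
    gc_vals = rng.uniform(0.25, 0.75, n)
    signal = rng.normal(0, 0.5, n)
    values = signal + bias * (gc_vals - 0.5) * 2.5
    m = make_macc(values)
    gc = GCTrack(300, {"chr1": gc_vals})
    return m, gc, signal


class TestGCCorrect:
    def test_no_bias_leaves_track_nearly_unchanged(self):
        m, gc, _ = _biased_track(bias=0.0)
        out = gc_correct(m, gc, seed=0)
        resid = out.data["chr1"] - m.data["chr1"]
        assert np.max(np.abs(resid - resid.mean())) < 0.2  # below the noise floor

    def test_injected_bias_removed(self):
        m, gc, signal = _biased_track(bias=1.0)
        r_pre = np.corrcoef(m.data["chr1"], gc.data["chr1"])[0, 1]
        out = gc_correct(m, gc, seed=0)
        r_post = np.corrcoef(out.data["chr1"], gc.data["chr1"])[0, 1]
        assert abs(r_pre) > 0.5
        assert abs(r_post) < 0.05
        # the underlying signal is recovered, not destroyed
        assert np.corrcoef(out.data["chr1"], signal)[0, 1] > 0.95

    def test_global_level_preserved(self):
        m, gc, _ = _biased_track(bias=1.0)
        out = gc_correct(m, gc, seed=0)
        assert out.data["chr1"].mean() == pytest.approx(m.data["chr1"].mean(), abs=1e-9)

    def test_cpg_stratification_leaves_unbiased_stratum_alone(self):
        # bias only inside the "island" stratum; outside bins must not move
        rng = np.random.default_rng(10)
        n = 3000
        gc_vals = rng.uniform(0.25, 0.75, n)
        island = np.zeros(n, dtype=bool)
        island[: n // 2] = True
        values = rng.normal(0, 0.5, n)
        values[island] += 2.0 * (gc_vals[island] - 0.5)
        m = make_macc(values)
        gc = GCTrack(300, {"chr1": gc_vals})
        gc.cpg = {"chr1": island}
        out = gc_correct(m, gc, stratify_cpg=True, seed=0)
        outside = ~island
        r_out = np.corrcoef(out.data["chr1"][island], gc_vals[island])[0, 1]
        assert abs(r_out) < 0.08
        # non-island bins: correction is (at most) a tiny level adjustment
        delta = out.data["chr1"][outside] - values[outside]
        assert np.std(delta) < 0.1

    def test_small_stratum_left_uncorrected(self):
        m, gc, _ = _biased_track(n=50, bias=1.0)
        out = gc_correct(m, gc, min_stratum_bins=100, seed=0)
        np.testing.assert_array_equal(out.data["chr1"], m.data["chr1"])
        assert out.gc_corrected

    def test_island_flagging_from_intervals(self):
        gc = GCTrack(300, {"chr1": np.full(10, 0.5)})
        flag_cpg_islands(gc, [("chr1", 450, 900)])
        assert gc.cpg["chr1"].tolist() == [False, True, True] + [False] * 7


# ---------------------------------------------------------------------------
# median shift, enrichment, quadrants


class TestMedianShift:
    def test_centres_distribution(self):
        m = median_shift(make_macc([1.0, 2.0, 3.0]))
        np.testing.assert_array_equal(m.data["chr1"], [-1.0, 0.0, 1.0])
        assert m.median_shifted

    def test_idempotent_on_centred_track(self):
        m = median_shift(make_macc([-1.0, 0.0, 1.0]))
        np.testing.assert_array_equal(m.data["chr1"], [-1.0, 0.0, 1.0])

    def test_pairwise_differences_preserved(self):
        rng = np.random.default_rng(6)
        vals = rng.normal(size=50)
        m = median_shift(make_macc(vals))
        np.testing.assert_allclose(np.diff(m.data["chr1"]), np.diff(vals), atol=0)

    def test_median_zero_invariant(self, shifted_tracks10k):
        c, h = shifted_tracks10k
        assert abs(np.median(c.defined_values())) < 1e-9
        assert abs(np.median(h.defined_values())) < 1e-9


class TestH3Enrichment:
    def test_equal_tracks_ratio_one(self):
        t = BinnedTrack(300, {"chr1": np.array([3.0, 7.0])}, normalized=True)
        out = h3_enrichment(t, t, 0.5)
        np.testing.assert_allclose(out.data["chr1"], 1.0)

    def test_doubled_chip(self):
        i = BinnedTrack(300, {"chr1": np.array([10.0])}, normalized=True)
        c = BinnedTrack(300, {"chr1": np.array([20.0])}, normalized=True)
        assert h3_enrichment(c, i, 0.0).data["chr1"][0] == 2.0

    def test_pseudocount_rescues_zero_input(self):
        z = BinnedTrack(300, {"chr1": np.array([0.0])}, normalized=True)
        assert h3_enrichment(z, z, 0.5).data["chr1"][0] == 1.0


class TestQuadrants:
    def test_concordant_tracks_have_no_high_occ_low_macc(self):
        vals = np.arange(1.0, 101.0)
        occ = BinnedTrack(300, {"chr1": vals}, normalized=True)
        m = make_macc(vals)
        quad = classify_occupancy_accessibility(occ, m)
        assert quad.counts["high_occ_low_macc"] == 0
        assert quad.counts["high_occ_high_macc"] > 0

    def test_anticoncordant_tracks_have_no_high_occ_high_macc(self):
        vals = np.arange(1.0, 101.0)
        occ = BinnedTrack(300, {"chr1": vals}, normalized=True)
        m = make_macc(vals[::-1].copy())
        quad = classify_occupancy_accessibility(occ, m)
        assert quad.counts["high_occ_high_macc"] == 0
        assert quad.counts["high_occ_low_macc"] > 0

    def test_matches_two_pass_thresholding_oracle(self):
        rng = np.random.default_rng(12)
        occ_vals = rng.gamma(2.0, 1.0, 10_000)
        macc_vals = rng.normal(size=10_000)
        occ = BinnedTrack(300, {"chr1": occ_vals}, normalized=True)
        m = make_macc(macc_vals)
        quad = classify_occupancy_accessibility(occ, m)
        occ_q = np.quantile(occ_vals, 0.80)
        lo = np.quantile(macc_vals, 0.05)
        hi = np.quantile(macc_vals, 0.95)
        oracle = np.zeros(10_000, dtype=int)
        for j in range(10_000):  # brute-force per-bin pass
            if occ_vals[j] > occ_q and macc_vals[j] > hi:
                oracle[j] = 1
            elif occ_vals[j] > occ_q and macc_vals[j] < lo:
                oracle[j] = 2
        np.testing.assert_array_equal(quad.labels["chr1"], oracle)

    def test_invalid_quantiles_rejected(self):
        occ = BinnedTrack(300, {"chr1": np.arange(10.0)}, normalized=True)
        with pytest.raises(ValueError):
            classify_occupancy_accessibility(occ, make_macc(np.arange(10.0)), occ_top=1.5)
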