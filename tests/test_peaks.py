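"""Peak calling, group assignment, NHP sites, overlap and region enrichment."""

import numpy as np
import pandas as pd
import pytest

from macckit import (
    Genome,
    assign_groups,
    build_annotation,
    call_local_peaks,
    chip_zscore_sites,
    overlap_with_sites,
    region_enrichment,
    select_representative_profile,
)
from macckit.annotation import CLASS_NAMES, ENHANCER, GENE_BODY, PROMOTER, UNANNOTATED
from macckit.tracks import BinnedTrack

from conftest import concat, make_macc


class TestLocalPeaks:
    def test_strict_maxima_and_plateau_exclusion(self):
        ps = call_local_peaks(make_macc([0.0, 2.0, 1.0, 3.0, 3.0, 1.0]))
        assert [(c, i) for c, i, _ in ps.peaks] == [("chr1", 1)]

    def test_monotone_track_has_no_peaks(self):
        assert len(call_local_peaks(make_macc(np.arange(50.0)))) == 0

    def test_neighbours_of_missing_bins_ineligible(self):
        vals = np.array([0.0, 5.0, np.nan, 1.0, 9.0, 1.0])
        ps = call_local_peaks(make_macc(vals))
        assert [(c, i) for c, i, _ in ps.peaks] == [("chr1", 4)]

    def test_matches_brute_force_triple_scan(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            vals = rng.normal(size=rng.integers(3, 120))
            vals[rng.random(vals.size) < 0.05] = np.nan
            ps = call_local_peaks(make_macc(vals))
            brute = [
                i
                for i in range(1, vals.size - 1)
                if np.isfinite(vals[i - 1 : i + 2]).all()
                and vals[i - 1] < vals[i] > vals[i + 1]
            ]
            assert [i for _, i, _ in ps.peaks] == brute


class TestAssignGroups:
    def _shifted(self, vals, **kw):
        m = make_macc(vals, **kw)
        m.median_shifted = True
        return m

    def test_positive_score_quantile_convention(self):
        # positive c-MACC values 1..10: inclusive-linear 80th percentile = 8.2;
        # h threshold (90th pct of positive h = 9.1) passed only by h = 10
        c_vals = np.concatenate([np.arange(1.0, 11.0), -np.ones(10)])
        h_vals = np.concatenate([np.arange(1.0, 11.0), -np.ones(10)])
        ga = assign_groups(self._shifted(c_vals), self._shifted(h_vals))
        assert ga.c_threshold == pytest.approx(8.2)
        assert ga.h_high_threshold == pytest.approx(9.1)
        labelled = np.flatnonzero(ga.labels["chr1"] == 2)
        # strict comparisons: c in {9, 10} exceed 8.2 but only h = 10 > 9.1
        assert set(c_vals[labelled]) == {10.0}

    def test_high_h_everywhere_empties_group1(self):
        # constant positive h: nothing can be *strictly* below its quantile
        rng = np.random.default_rng(1)
        c = self._shifted(rng.normal(0, 1, 1000))
        h = self._shifted(np.full(1000, 5.0))
        ga = assign_groups(c, h)
        assert ga.counts()["group1"] == 0

    def test_requires_median_shift(self):
        m = make_macc(np.arange(10.0))
        with pytest.raises(ValueError, match="median-shifted"):
            assign_groups(m, m)

    def test_no_positive_scores_rejected(self):
        c = self._shifted(-np.arange(1.0, 11.0))
        h = self._shifted(np.arange(1.0, 11.0))
        with pytest.raises(ValueError, match="positive"):
            assign_groups(c, h)

    def test_matches_brute_force_quantile_oracle(self):
        rng = np.random.default_rng(2)
        c_vals = rng.normal(0, 1, 5_000)
        h_vals = 0.5 * c_vals + rng.normal(0, 1, 5_000)
        ga = assign_groups(self._shifted(c_vals), self._shifted(h_vals))
        c_thr = np.quantile(c_vals[c_vals > 0], 0.80)
        h_lo = np.quantile(h_vals[h_vals > 0], 0.10)
        h_hi = np.quantile(h_vals[h_vals > 0], 0.90)
        oracle = np.zeros(5_000, dtype=int)
        for j in range(5_000):
            if c_vals[j] > c_thr and h_vals[j] < h_lo:
                oracle[j] = 1
            elif c_vals[j] > c_thr and h_vals[j] > h_hi:
                oracle[j] = 2
        np.testing.assert_array_equal(ga.labels["chr1"], oracle)

    def test_simulator_truth_recovery(self, truth10k, shifted_tracks10k):
        """Planted NHP loci land in group 1, fragile nucleosomes in group 2."""
        c, h = shifted_tracks10k
        ga = assign_groups(c, h)
        lab = concat(ga.labels, truth10k.chroms)
        nhp = concat(truth10k.nhp, truth10k.chroms)
        fragile = concat(truth10k.fragile, truth10k.chroms)
        assert (lab[nhp] == 1).mean() >= 0.80
        assert (lab[fragile] == 2).mean() >= 0.80


class TestChipZscoreSites:
    def test_constant_enrichment_yields_nothing(self):
        t = BinnedTrack(300, {"chr1": np.full(100, 2.0)}, normalized=True)
        sites = chip_zscore_sites(t, 3)
        assert not any(m.any() for m in sites.values())

    def test_single_outlier_bin(self):
        vals = np.zeros(1_000)
        vals[0] = 1.0  # hand oracle: z_outlier = (1 - mu)/sd with mu=1e-3
        mu, sd = vals.mean(), vals.std()
        assert (1.0 - mu) / sd > 3 > (0.0 - mu) / sd
        t = BinnedTrack(300, {"chr1": vals}, normalized=True)
        sites = chip_zscore_sites(t, 3)
        assert np.flatnonzero(sites["chr1"]).tolist() == [0]

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(3)
        t = BinnedTrack(300, {"chr1": rng.gamma(2, 1, 2_000)}, normalized=True)
        loose = np.concatenate(list(chip_zscore_sites(t, 2).values()))
        strict = np.concatenate(list(chip_zscore_sites(t, 5).values()))
        assert np.all(loose >= strict)


class TestRepresentativeProfile:
    def _track(self, vals):
        return BinnedTrack(300, {"chr1": np.asarray(vals, float)}, normalized=True)

    def test_single_profile_returned(self):
        t = self._track(np.random.default_rng(0).gamma(2, 1, 100))
        assert select_representative_profile([t]) is t

    def test_stable_profile_beats_volatile(self):
        rng = np.random.default_rng(4)
        # stable: 100 extreme outlier bins -> identical site counts at Z=2..5
        vals = rng.normal(0, 1, 5_000)
        vals[:100] = 1_000.0
        stable = self._track(vals)
        volatile = self._track(rng.normal(0, 1, 5_000))  # counts decay across Z
        chosen = select_representative_profile([volatile, stable])
        counts = lambda t: np.array(
            [sum(m.sum() for m in chip_zscore_sites(t, z).values()) for z in (2, 3, 4, 5)]
        )
        cv = lambda c: c.std() / c.mean()
        assert cv(counts(stable)) < cv(counts(volatile))  # oracle sanity
        assert chosen is stable

    def test_matches_brute_force_cv(self):
        rng = np.random.default_rng(5)
        profiles = [self._track(rng.gamma(2, 1, 3_000)) for _ in range(5)]
        cvs = []
        for t in profiles:
            counts = np.array(
                [
                    sum(int(m.sum()) for m in chip_zscore_sites(t, z).values())
                    for z in (2, 3, 4, 5)
                ],
                dtype=float,
            )
            cvs.append(counts.std() / counts.mean() if counts.mean() else np.inf)
        assert select_representative_profile(profiles) is profiles[int(np.argmin(cvs))]


class TestOverlap:
    def test_sites_everywhere(self):
        m = make_macc(np.sin(np.arange(200.0)))
        peaks = call_local_peaks(m)
        sites = {"chr1": np.ones(200, dtype=bool)}
        res = overlap_with_sites(peaks, sites, m, n_rand=5, seed=0)
        assert res.observed == 1.0
        assert res.expected == 1.0

    def test_peaks_subset_of_sites(self):
        m = make_macc(np.sin(np.arange(200.0)))
        peaks = call_local_peaks(m)
        sites = {"chr1": np.zeros(200, dtype=bool)}
        for c, i, _ in peaks.peaks:
            sites[c][i] = True
        res = overlap_with_sites(peaks, sites, m, n_rand=5, seed=0)
        assert res.observed == 1.0
        assert res.expected < 1.0

    def test_empty_sites(self):
        m = make_macc(np.sin(np.arange(50.0)))
        res = overlap_with_sites(call_local_peaks(m), {"chr1": np.zeros(50, bool)}, m)
        assert res.observed == res.expected == 0.0

    def test_expected_converges_to_site_fraction(self):
        rng = np.random.default_rng(6)
        m = make_macc(rng.normal(size=2_000))
        peaks = call_local_peaks(m)
        sites = {"chr1": rng.random(2_000) < 0.3}
        p = sites["chr1"].mean()  # all bins defined -> analytic expectation
        res = overlap_with_sites(peaks, sites, m, n_rand=400, seed=1)
        assert res.expected == pytest.approx(p, abs=0.02)

    def test_estimator_unbiased_over_seeds(self):
        rng = np.random.default_rng(7)
        m = make_macc(rng.normal(size=1_000))
        peaks = call_local_peaks(m)
        sites = {"chr1": rng.random(1_000) < 0.25}
        p = sites["chr1"].mean()
        draws = np.array(
            [overlap_with_sites(peaks, sites, m, n_rand=10, seed=s).expected for s in range(200)]
        )
        se = draws.std(ddof=1) / np.sqrt(200)
        assert abs(draws.mean() - p) <= 2 * se


class TestAnnotation:
    GENOME = Genome({"chr1": 60_000})
    GENES = pd.DataFrame(
        {
            "chrom": ["chr1", "chr1"],
            "start": [10_000, 40_000],
            "end": [20_000, 50_000],
            "strand": ["+", "-"],
            "name": ["geneA", "geneB"],
        }
    )

    def test_promoter_windows_are_strand_aware(self):
        ann = build_annotation(self.GENES, [], self.GENOME, 1_000, window=1_000)
        cls = ann.classes["chr1"]
        assert cls[9] == PROMOTER  # [9000, 10000) upstream of + gene
        assert cls[50] == PROMOTER  # [50000, 51000) upstream of - gene
        assert CLASS_NAMES[cls[10]] == "five_prime_gene"
        assert CLASS_NAMES[cls[49]] == "five_prime_gene"

    def test_enhancer_priority_wins(self):
        ann = build_annotation(
            self.GENES, [("chr1", 9_000, 10_000)], self.GENOME, 1_000, window=1_000
        )
        assert ann.classes["chr1"][9] == ENHANCER

    def test_gene_body_and_unannotated(self):
        ann = build_annotation(self.GENES, [], self.GENOME, 1_000, window=1_000)
        assert ann.classes["chr1"][15] == GENE_BODY
        assert ann.classes["chr1"][30] == UNANNOTATED

    def test_tss_region_overlapping_other_gene_excluded(self):
        genes = pd.DataFrame(
            {
                "chrom": ["chr1", "chr1"],
                "start": [10_000, 8_000],
                "end": [20_000, 9_500],
                "strand": ["+", "+"],
                "name": ["a", "b"],
            }
        )
        ann = build_annotation(genes, [], self.GENOME, 1_000, window=1_000)
        # bin 9 = [9000,10000) is gene A's promoter but overlaps gene b -> excluded
        assert ann.classes["chr1"][9] != PROMOTER

    def test_strandless_records_rejected(self):
        bad = self.GENES.assign(strand=["+", "."])
        with pytest.raises(ValueError, match="strand"):
            build_annotation(bad, [], self.GENOME, 1_000)


class TestRegionEnrichment:
    def _ann(self):
        return build_annotation(
            TestAnnotation.GENES, [("chr1", 0, 5_000)], TestAnnotation.GENOME, 1_000, 1_000
        )

    def test_all_bins_query_gives_unit_ratios(self):
        ann = self._ann()
        bins = {"chr1": np.ones(60, dtype=bool)}
        ratios = region_enrichment(bins, ann)
        for name, r in ratios.items():
            frac = ann.class_fractions()[name]
            if frac > 0:
                assert r == pytest.approx(1.0)
            else:
                assert np.isnan(r)

    def test_enrichment_arithmetic(self):
        ann = self._ann()
        # enhancer covers bins 0..4 (5/60 of genome); query 10 bins, 5 inside
        bins = {"chr1": np.zeros(60, dtype=bool)}
        bins["chr1"][[0, 1, 2, 3, 4, 30, 31, 32, 33, 34]] = True
        r = region_enrichment(bins, ann)["enhancer"]
        assert r == pytest.approx((5 / 10) / (5 / 60))

    def test_uniform_random_query_near_unity(self):
        ann = self._ann()
        rng = np.random.default_rng(8)
        bins = {"chr1": rng.random(60_000 // 1_000) < 0.5}
        ratios = region_enrichment(bins, ann)
        for name, frac in ann.class_fractions().items():
            if frac >= 0.1:  # classes large enough for a tight binomial CI
                assert ratios[name] == pytest.approx(1.0, abs=0.35)
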