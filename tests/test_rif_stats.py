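"""PMF convolution/deconvolution, KS test, calibration, thinning."""

import math

import numpy as np
import pytest
from scipy import stats as sps

from alphadosim.rif_stats import (CountPMF, compare_distributions,
                                  convolve_pmf, correct_missed_foci,
                                  deconvolve_background, fit_hits_to_rif,
                                  ks_two_sample, thin_hits)


class TestCountPMF:
    def test_rejects_unnormalized(self):
        with pytest.raises(ValueError):
            CountPMF([0.5, 0.4])

    def test_rejects_negative(self):
        with pytest.raises(ValueError):
            CountPMF([1.2, -0.2])

    def test_from_counts_moments(self):
        pmf = CountPMF.from_counts([0, 1, 1, 2])
        assert pmf.mean() == pytest.approx(1.0)
        assert pmf.var() == pytest.approx(0.5)


class TestConvolution:
    def test_point_mass_is_identity(self):
        px = CountPMF([0.2, 0.5, 0.3])
        delta = CountPMF([1.0])
        assert np.allclose(convolve_pmf(px, delta).p, px.p)

    def test_two_coin_flips(self):
        p = CountPMF([0.5, 0.5])
        assert np.allclose(convolve_pmf(p, p).p, [0.25, 0.5, 0.25])

    def test_mean_additivity_on_random_pmfs(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            px = CountPMF(rng.dirichlet(np.ones(rng.integers(2, 9))))
            py = CountPMF(rng.dirichlet(np.ones(rng.integers(2, 9))))
            pz = convolve_pmf(px, py)
            assert pz.mean() == pytest.approx(px.mean() + py.mean(), abs=1e-12)


class TestDeconvolution:
    @pytest.mark.parametrize("method", ["nnls", "sequential"])
    def test_exact_roundtrip(self, method):
        rng = np.random.default_rng(2)
        px = CountPMF(rng.dirichlet(np.ones(7)))
        py = CountPMF(rng.dirichlet(np.ones(5)))
        pz = convolve_pmf(px, py)
        rec, residual = deconvolve_background(pz, py, 15, method=method)
        assert np.abs(rec.p[:7] - px.p).max() < 1e-9
        assert residual < 1e-9

    def test_point_mass_background_returns_detected(self):
        pz = CountPMF([0.3, 0.4, 0.2, 0.1])
        rec, _ = deconvolve_background(pz, CountPMF([1.0]), 15)
        assert np.allclose(rec.p[:4], pz.p)

    def test_zero_mass_background_at_zero_rejected(self):
        with pytest.raises(ValueError):
            deconvolve_background(CountPMF([1.0]), CountPMF([0.0, 1.0]), 15)

    def test_recovers_rif_mean_from_synthetic_counts(self):
        # detected = RIF + background with known generator, n = 5000
        rng = np.random.default_rng(3)
        n = 5000
        rif = rng.binomial(rng.poisson(10.5, n), 0.2)
        bg = rng.poisson(1.5, n)
        det_pmf = CountPMF.from_counts(rif + bg)
        bg_pmf = CountPMF.from_counts(rng.poisson(1.5, n))
        rec, _ = deconvolve_background(det_pmf, bg_pmf, 15)
        se = rif.std() / math.sqrt(n)
        assert abs(rec.mean() - rif.mean()) < 2 * se + 2 / math.sqrt(n)


class TestKSTest:
    def test_identical_samples(self):
        d, p = ks_two_sample([1, 2, 3], [1, 2, 3], method="asymptotic")
        assert d == 0.0 and p == 1.0

    def test_disjoint_supports(self):
        d, _ = ks_two_sample([0, 0, 0], [1, 1, 1], method="asymptotic")
        assert d == 1.0

    def test_statistic_matches_scipy(self):
        rng = np.random.default_rng(4)
        a, b = rng.normal(size=40), rng.normal(0.5, size=55)
        d, _ = ks_two_sample(a, b)
        assert d == pytest.approx(sps.ks_2samp(a, b).statistic)

    def test_small_sample_permutation_p_matches_exact(self):
        rng = np.random.default_rng(5)
        a = rng.normal(size=8)
        b = rng.normal(0.8, size=8)
        d, p = ks_two_sample(a, b, method="permutation",
                             n_permutations=20_000, seed=5)
        exact = sps.ks_2samp(a, b, method="exact")
        assert d == pytest.approx(exact.statistic)
        assert abs(p - exact.pvalue) < 0.02

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            ks_two_sample([], [1.0])


class TestCalibration:
    def test_exactly_proportional_data(self):
        hits = [3.5, 7.0, 10.5]
        rif = [0.2 * h for h in hits]
        fit = fit_hits_to_rif(hits, rif)
        assert fit.slope == pytest.approx(0.2)
        assert fit.ci_high - fit.ci_low < 1e-12
        assert fit.ci_low == pytest.approx(0.2)
        assert fit.hits_per_rif == pytest.approx(5.0)

    def test_intercept_mode(self):
        hits = [2.0, 4.0, 6.0, 8.0]
        rif = [0.5 + 0.2 * h for h in hits]
        fit = fit_hits_to_rif(hits, rif, through_origin=False)
        assert fit.slope == pytest.approx(0.2)
        assert fit.intercept == pytest.approx(0.5)

    def test_single_condition_rejected(self):
        with pytest.raises(ValueError):
            fit_hits_to_rif([1.0], [0.2])


class TestThinning:
    def test_identity_and_annihilation(self):
        counts = np.array([0, 3, 7, 12])
        assert np.array_equal(thin_hits(counts, 1.0, seed=6), counts)
        assert thin_hits(counts, 0.0, seed=6).sum() == 0

    def test_binomial_expectation(self):
        thinned = thin_hits(np.full(100_000, 10), 0.2, seed=7)
        assert thinned.mean() == pytest.approx(2.0, abs=0.01)

    def test_out_of_range_probability_rejected(self):
        with pytest.raises(ValueError):
            thin_hits([1], 1.5, seed=8)

    def test_thinning_moment_algebra(self):
        # mean p*mu and var p^2 var + p(1-p) mu, within 3 SE
        rng = np.random.default_rng(9)
        hits = rng.poisson(8.0, 200_000)
        p = 0.2
        thinned = thin_hits(hits, p, seed=10)
        mu, var = hits.mean(), hits.var()
        exp_mean = p * mu
        exp_var = p * p * var + p * (1 - p) * mu
        se_mean = thinned.std() / math.sqrt(len(hits))
        assert abs(thinned.mean() - exp_mean) < 3 * se_mean
        se_var = thinned.var() * math.sqrt(2.0 / len(hits))
        assert abs(thinned.var() - exp_var) < 3 * se_var


class TestMissedFociCorrection:
    def test_full_detection_is_identity(self):
        c = np.array([0, 1, 5])
        assert np.array_equal(correct_missed_foci(c, 1.0, seed=11), c)

    def test_exact_added_count(self):
        rng = np.random.default_rng(12)
        counts = rng.poisson(0.9, 1000)
        while counts.sum() != 900:
            counts = rng.poisson(0.9, 1000)
        fixed = correct_missed_foci(counts, 0.75, seed=13)
        assert fixed.sum() - counts.sum() == 300

    def test_corrected_mean_in_expectation(self):
        rng = np.random.default_rng(14)
        counts = rng.poisson(2.0, 2000)
        means = [correct_missed_foci(counts, 0.75, seed=s).mean()
                 for s in range(100)]
        target = counts.mean() / 0.75
        se = np.std(means) / 10
        assert abs(np.mean(means) - target) < 2 * se + 1e-3

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            correct_missed_foci([1], 0.0, seed=15)


class TestComparison:
    def test_identical_pmfs_have_zero_differences(self):
        pmf = CountPMF([0.5, 0.3, 0.2])
        out = compare_distributions(pmf, {"sim": pmf})
        assert np.allclose(out["probability_difference"]["sim"], 0.0)
        assert out["zero_excess"] == {"sim": False}

    def test_zero_inflated_detected_raises_flag(self):
        detected = CountPMF([0.6, 0.2, 0.2])
        simulated = CountPMF([0.4, 0.35, 0.25])
        out = compare_distributions(detected, {"sim": simulated})
        assert out["zero_excess"]["sim"] is True

    def test_point_mass_summary_has_zero_variance(self):
        pmf = CountPMF([0.0, 0.0, 1.0])
        out = compare_distributions(pmf, {"sim": pmf})
        row = out["summary"].loc["sim"]
        assert row["Variance"] == 0.0 and row["Mean"] == 2.0
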