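"""Ex-Gaussian density, moments, simulation, and ML / distributional fitting."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate, stats

from disfluency.contrasts import BLUR_HIGH_VS_OTHERS, BLUR_LOW_VS_CLEAR
from disfluency.exgauss import (
    ExGaussianParams,
    exgauss_cdf,
    exgauss_logpdf,
    exgauss_moments,
    exgauss_pdf,
    exgauss_rng,
    fit_exgauss_distributional,
    fit_exgauss_mle,
)

P_REF = ExGaussianParams(0.5, 0.05, 0.3)


class TestDensity:
    def test_integrates_to_one(self):
        total, err = integrate.quad(
            lambda x: float(exgauss_pdf(x, P_REF)), -2.0, 30.0, limit=300
        )
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_matches_exponnorm_reference(self):
        # independent oracle: scipy's exponentially-modified normal
        ref = stats.exponnorm(K=P_REF.tau / P_REF.sigma, loc=P_REF.mu, scale=P_REF.sigma)
        x = np.linspace(0.0, 3.0, 61)
        np.testing.assert_allclose(exgauss_pdf(x, P_REF), ref.pdf(x), rtol=1e-10)
        np.testing.assert_allclose(exgauss_cdf(x, P_REF), ref.cdf(x), atol=1e-12)

    def test_small_sigma_approaches_exponential(self):
        p = ExGaussianParams(0.5, 1e-5, 0.3)
        x = np.array([0.6, 0.9, 1.5])
        expected = (1.0 / p.tau) * np.exp(-(x - p.mu) / p.tau)
        np.testing.assert_allclose(exgauss_pdf(x, p), expected, rtol=1e-4)

    def test_small_tau_approaches_gaussian(self):
        p = ExGaussianParams(0.5, 0.05, 1e-6)
        for x in (0.4, 0.5, 0.6):  # mu and +-2 sigma
            assert exgauss_pdf(x, p) == pytest.approx(
                stats.norm.pdf(x, 0.5 + 1e-6, 0.05), rel=1e-3
            )

    def test_stable_in_far_tail(self):
        lp = exgauss_logpdf(np.array([10.0, 50.0]), P_REF)
        assert np.all(np.isfinite(lp))
        assert np.all(np.diff(lp) < 0)

    def test_invalid_params_raise(self):
        with pytest.raises(ValueError):
            ExGaussianParams(0.5, -0.1, 0.3)
        with pytest.raises(ValueError):
            ExGaussianParams(0.5, 0.05, 0.0)


class TestMoments:
    def test_closed_forms(self):
        mean, sd = exgauss_moments(P_REF)
        assert mean == pytest.approx(0.8)
        assert sd == pytest.approx(math.sqrt(0.0025 + 0.09))

    def test_monte_carlo_agreement(self):
        n = 10**6
        draws = exgauss_rng(P_REF, n, seed=42)
        mean, sd = exgauss_moments(P_REF)
        se_mean = sd / math.sqrt(n)
        assert abs(draws.mean() - mean) < 3 * se_mean
        # SE of the sample SD via the asymptotic formula with kurtosis
        m4 = np.mean((draws - draws.mean()) ** 4)
        se_sd = math.sqrt(max(m4 - sd**4, 0.0) / n) / (2 * sd)
        assert abs(draws.std() - sd) < 3 * se_sd

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        mu=st.floats(0.2, 1.0),
        sigma=st.floats(0.02, 0.3),
        tau=st.floats(0.05, 0.6),
    )
    def test_moments_match_simulation_property(self, mu, sigma, tau):
        p = ExGaussianParams(mu, sigma, tau)
        draws = exgauss_rng(p, 40_000, seed=7)
        mean, sd = exgauss_moments(p)
        assert abs(draws.mean() - mean) < 5 * sd / math.sqrt(len(draws))


class TestRng:
    def test_empty(self):
        assert exgauss_rng(P_REF, 0, seed=0).size == 0

    def test_positive_skew_when_tau_dominates(self):
        draws = exgauss_rng(ExGaussianParams(0.5, 0.02, 0.4), 100_000, seed=1)
        assert stats.skew(draws) > 1.0

    def test_ecdf_close_to_cdf(self):
        draws = exgauss_rng(P_REF, 100_000, seed=2)
        stat = stats.kstest(draws, lambda x: exgauss_cdf(x, P_REF)).statistic
        assert stat < 0.006  # ~1.36/sqrt(n) at the 5% level is 0.0043

    def test_deterministic(self):
        a = exgauss_rng(P_REF, 100, seed=5)
        b = exgauss_rng(P_REF, 100, seed=5)
        np.testing.assert_array_equal(a, b)


class TestMLE:
    def test_recovery_n5000(self):
        truth = ExGaussianParams(0.55, 0.08, 0.25)
        est, ll, ok = fit_exgauss_mle(exgauss_rng(truth, 5000, seed=3))
        assert ok
        assert est.mu == pytest.approx(truth.mu, abs=0.02)
        assert est.sigma == pytest.approx(truth.sigma, abs=0.02)
        assert est.tau == pytest.approx(truth.tau, abs=0.02)

    def test_loglik_of_truth_never_beats_mle(self):
        truth = ExGaussianParams(0.55, 0.08, 0.25)
        for seed in range(5):
            x = exgauss_rng(truth, 500, seed=seed)
            est, ll, _ = fit_exgauss_mle(x)
            ll_truth = float(np.sum(exgauss_logpdf(x, truth)))
            assert ll >= ll_truth - 1e-6

    def test_pure_gaussian_degenerates_to_small_tau(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0.6, 0.05, size=2000)
        est, _, _ = fit_exgauss_mle(x)
        assert est.tau < 0.02
        assert est.mu == pytest.approx(x.mean(), abs=0.03)

    def test_bias_shrinks_with_n(self):
        truth = ExGaussianParams(0.55, 0.08, 0.25)
        err = {}
        for n in (500, 5000):
            errs = []
            for seed in range(8):
                est, _, _ = fit_exgauss_mle(exgauss_rng(truth, n, seed=100 + seed))
                errs.append(abs(est.tau - truth.tau))
            err[n] = np.mean(errs)
        assert err[5000] < err[500]

    def test_too_few_points_raise(self):
        with pytest.raises(ValueError):
            fit_exgauss_mle(np.ones(5))


class TestDistributionalFit:
    @pytest.fixture(scope="class")
    @staticmethod
    def stage_specific_fit():
        from disfluency.io_preprocess import filter_rts, select_rt_analysis_trials
        from disfluency.synthetic import simulate_full_experiment

        trials, truth = simulate_full_experiment("1A", n_subjects=72, seed=21)
        enc, _ = filter_rts(trials[trials["phase"] == "encoding"])
        rt = select_rt_analysis_trials(enc, "ldt")
        fit = fit_exgauss_distributional(rt, [BLUR_HIGH_VS_OTHERS, BLUR_LOW_VS_CLEAR])
        return fit

    def test_mu_shift_recovered(self, stage_specific_fit):
        c1 = stage_specific_fit.coefficients["mu"]["high_vs_others"]
        assert 0.07 < c1 < 0.16  # injected 0.107 s

    def test_tau_inflation_recovered_and_null_contrast2(self, stage_specific_fit):
        c1 = stage_specific_fit.coefficients["log_beta"]["high_vs_others"]
        c2 = stage_specific_fit.coefficients["log_beta"]["low_vs_clear"]
        assert c1 > 0.2  # injected 0.43 on the log scale (trim-attenuated)
        # null effect: well within the subject-level noise band
        eff = stage_specific_fit.subject_effects["log_beta:low_vs_clear"]
        assert abs(c2) < 3 * eff.std() / np.sqrt(len(eff))

    def test_intercept_near_grand_mu(self, stage_specific_fit):
        # grand mu of the generating parameters: clear .54, low .556, high .655
        grand = np.mean([0.54, 0.556, 0.655])
        assert stage_specific_fit.coefficients["mu"]["intercept"] == pytest.approx(
            grand, abs=0.04
        )

    def test_two_stage_and_pooled_agree_in_sign(self):
        from disfluency.io_preprocess import filter_rts, select_rt_analysis_trials
        from disfluency.synthetic import simulate_full_experiment

        trials, _ = simulate_full_experiment("1A", n_subjects=36, seed=4)
        enc, _ = filter_rts(trials[trials["phase"] == "encoding"])
        rt = select_rt_analysis_trials(enc, "ldt")
        two = fit_exgauss_distributional(rt, [BLUR_HIGH_VS_OTHERS, BLUR_LOW_VS_CLEAR])
        pooled = fit_exgauss_distributional(
            rt, [BLUR_HIGH_VS_OTHERS, BLUR_LOW_VS_CLEAR], mode="pooled"
        )
        for param in ("mu", "log_beta"):
            t = two.coefficients[param]["high_vs_others"]
            p = pooled.coefficients[param]["high_vs_others"]
            assert np.sign(t) == np.sign(p)
            assert p == pytest.approx(t, abs=max(0.6 * abs(t), 0.05))
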