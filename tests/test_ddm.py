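"""Wiener first-passage density, simulator, EZ estimator, and ML fitting."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate, stats

from disfluency.ddm import (
    DDMParams,
    boundary_probability,
    ez_diffusion_estimate,
    ez_forward_moments,
    fit_ddm,
    fit_ddm_single,
    simulate_ddm_trials,
    wiener_fpt_density,
)

P_REF = DDMParams(v=1.0, a=1.5, z=0.5, ter=0.3)


def _integral(p, boundary, upper_limit=60.0):
    return integrate.quad(
        lambda t: wiener_fpt_density(t, p, boundary)[0], p.ter, upper_limit,
        limit=400,
    )[0]


class TestDensity:
    def test_symmetric_zero_drift(self):
        p = DDMParams(v=0.0, a=1.0, z=0.5, ter=0.0)
        assert _integral(p, "upper") == pytest.approx(0.5, abs=1e-5)

    def test_defective_densities_sum_to_one(self):
        iu = _integral(P_REF, "upper")
        il = _integral(P_REF, "lower")
        assert iu + il == pytest.approx(1.0, abs=1e-5)

    def test_integral_matches_absorption_probability(self):
        assert _integral(P_REF, "upper") == pytest.approx(
            boundary_probability(P_REF, "upper"), abs=1e-5
        )

    def test_zero_before_nondecision_time(self):
        d = wiener_fpt_density(np.array([0.1, 0.29, 0.3]), P_REF, "upper")
        assert np.all(d == 0.0)

    def test_nonnegative_everywhere(self):
        t = np.linspace(0.0, 10.0, 500)
        for boundary in ("upper", "lower"):
            assert np.all(wiener_fpt_density(t, P_REF, boundary) >= 0.0)

    def test_series_agree_at_switch_region(self):
        # forcing each expansion via extreme tolerance ratios must agree
        from disfluency.ddm import _f_lower_norm

        t = np.linspace(0.05, 2.0, 100)
        small = np.array([_f_lower_norm(np.array([ti]), 0.5, 1e-30)[0] for ti in t])
        tight = _f_lower_norm(t, 0.5, 1e-12)
        np.testing.assert_allclose(small, tight, atol=1e-6)

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(
        v=st.floats(-3.0, 3.0),
        a=st.floats(0.6, 2.5),
        z=st.floats(0.2, 0.8),
    )
    def test_defective_integral_property(self, v, a, z):
        p = DDMParams(v=v, a=a, z=z, ter=0.0)
        assert _integral(p, "upper") == pytest.approx(
            boundary_probability(p, "upper"), abs=1e-4
        )


class TestSimulator:
    def test_simulation_matches_density(self):
        rt, up = simulate_ddm_trials(P_REF, 100_000, dt=2e-4, seed=1)
        assert up.mean() == pytest.approx(
            boundary_probability(P_REF, "upper"), abs=0.01
        )
        # conditional upper-boundary RT distribution vs analytic (KS distance)
        grid = np.linspace(P_REF.ter, 8.0, 2000)
        dens = wiener_fpt_density(grid, P_REF, "upper")
        cdf = np.cumsum(dens) * (grid[1] - grid[0])
        cdf /= cdf[-1]
        stat = stats.kstest(
            rt[up == 1], lambda q: np.interp(q, grid, cdf)
        ).statistic
        assert stat < 0.02

    def test_dominant_drift(self):
        rt, up = simulate_ddm_trials(DDMParams(v=8.0, a=1.0), 2000, seed=0)
        assert up.mean() > 0.99

    def test_ter_shifts_rts_additively(self):
        p0 = DDMParams(v=1.5, a=1.2, ter=0.0)
        p1 = DDMParams(v=1.5, a=1.2, ter=0.2)
        rt0, _ = simulate_ddm_trials(p0, 5000, seed=7)
        rt1, _ = simulate_ddm_trials(p1, 5000, seed=7)
        assert np.min(rt1) - np.min(rt0) == pytest.approx(0.2, abs=1e-9)
        assert np.median(rt1) - np.median(rt0) == pytest.approx(0.2, abs=1e-9)

    def test_deterministic(self):
        a = simulate_ddm_trials(P_REF, 200, seed=3)
        b = simulate_ddm_trials(P_REF, 200, seed=3)
        np.testing.assert_array_equal(a[0], b[0])


class TestEZ:
    def test_algebraic_round_trip(self):
        truth = DDMParams(v=1.2, a=1.4, z=0.5, ter=0.3)
        pc, m, var = ez_forward_moments(truth)
        est = ez_diffusion_estimate(pc, var, m)
        assert est.v == pytest.approx(truth.v, abs=1e-9)
        assert est.a == pytest.approx(truth.a, abs=1e-9)
        assert est.ter == pytest.approx(truth.ter, abs=1e-9)

    def test_chance_accuracy_gives_small_drift(self):
        est = ez_diffusion_estimate(0.5 + 1e-4, 0.08, 0.6)
        assert abs(est.v) < 0.1

    def test_ter_grows_with_mean_rt(self):
        e1 = ez_diffusion_estimate(0.8, 0.08, 0.6)
        e2 = ez_diffusion_estimate(0.8, 0.08, 0.9)
        assert e2.ter - e1.ter == pytest.approx(0.3, abs=1e-9)

    def test_edge_correction(self):
        est = ez_diffusion_estimate(1.0, 0.05, 0.5, n=100)
        assert np.isfinite(est.v) and est.v > 0


class TestFit:
    def test_recovers_v_ter_ordering(self):
        # clear: fast drift, short ter; high blur: slow drift, long ter
        truth = {
            "clear": DDMParams(v=2.5, a=1.2, ter=0.35),
            "high": DDMParams(v=1.5, a=1.2, ter=0.45),
        }
        rng_seed = 11
        import pandas as pd

        frames = []
        for blur, p in truth.items():
            rt, up = simulate_ddm_trials(p, 3000, dt=5e-4, seed=rng_seed)
            frames.append(pd.DataFrame({"blur": blur, "rt": rt, "accuracy": up}))
            rng_seed += 1
        trials = pd.concat(frames, ignore_index=True)
        fits = fit_ddm(trials)
        assert fits["clear"]["params"].v > fits["high"]["params"].v
        assert fits["high"]["params"].ter > fits["clear"]["params"].ter
        for blur, p in truth.items():
            est = fits[blur]["params"]
            assert est.v == pytest.approx(p.v, rel=0.15)
            assert est.ter == pytest.approx(p.ter, abs=0.03)

    def test_self_consistency_on_accuracy(self):
        p = DDMParams(v=2.0, a=1.3, ter=0.3)
        rt, up = simulate_ddm_trials(p, 4000, dt=5e-4, seed=2)
        params, ll, status = fit_ddm_single(rt, up)
        implied = boundary_probability(params, "upper")
        assert implied == pytest.approx(up.mean(), abs=0.02)

    def test_ez_initializer_close_to_ml(self):
        # in the unbiased no-contaminant limit the EZ moments solution should
        # sit near the full-ML optimum
        p = DDMParams(v=1.8, a=1.4, ter=0.3)
        rt, up = simulate_ddm_trials(p, 6000, dt=5e-4, seed=5)
        correct = up.astype(bool)
        ez = ez_diffusion_estimate(
            correct.mean(), float(np.var(rt[correct])), float(np.mean(rt[correct])),
            n=len(rt),
        )
        ml, _, _ = fit_ddm_single(rt, up)
        assert ez.v == pytest.approx(ml.v, rel=0.15)
        assert ez.a == pytest.approx(ml.a, rel=0.15)
        assert ez.ter == pytest.approx(ml.ter, abs=0.05)

    def test_few_trials_warn_status(self):
        p = DDMParams(v=2.0, a=1.2, ter=0.3)
        rt, up = simulate_ddm_trials(p, 30, seed=9)
        _, _, status = fit_ddm_single(rt, up)
        assert status in ("warning", "degenerate")
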