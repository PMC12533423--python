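"""Four-parameter Wiener diffusion model: first-passage density, simulation,
EZ-style closed-form moments estimator, and per-condition ML fitting.

Evidence accumulates from relative start point z (in units of the boundary
separation a) with drift v and unit diffusion; the first boundary reached
(upper = correct under accuracy coding) gives the response, and the observed
RT adds a non-decision time ter.  No inter-trial variability parameters are
modelled; z defaults to 0.5.

The first-passage density uses the classical small-time and large-time series
with the number of terms chosen per evaluation point by the standard accuracy
criterion; the cheaper expansion is selected pointwise (tolerance 1e-8).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "DDMParams",
    "wiener_fpt_density",
    "boundary_probability",
    "simulate_ddm_trials",
    "ez_diffusion_estimate",
    "ez_forward_moments",
    "fit_ddm",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class DDMParams:
    """Drift v, boundary separation a, relative start point z, non-decision time ter."""

    v: float
    a: float
    z: float = 0.5
    ter: float = 0.0

    def __post_init__(self):
        if not self.a > 0:
            raise ValueError("boundary separation a must be positive")
        if not 0 < self.z < 1:
            raise ValueError("relative start point z must lie in (0, 1)")
        if self.ter < 0:
            raise ValueError("non-decision time must be >= 0")


def _f_lower_norm(t_norm: np.ndarray, w: float, eps: float) -> np.ndarray:
    """Density of first passage through the LOWER boundary for a zero-drift
    process on [0, 1] started at w, in normalized time t' = t / a^2.

    Pointwise choice between the small-time and large-time expansions using
    the standard term-count bounds.
    """
    t = np.asarray(t_norm, dtype=float)
    out = np.zeros_like(t)
    pos = t > 0
    tp = t[pos]

    # required number of terms for each expansion (Navarro & Fuss 2009 bounds)
    with np.errstate(divide="ignore", invalid="ignore"):
        ks = 2.0 + np.sqrt(-2.0 * tp * np.log(2.0 * np.sqrt(2.0 * np.pi * tp) * eps))
        ks = np.where(2.0 * np.sqrt(2.0 * np.pi * tp) * eps < 1.0, ks, 2.0)
        ks = np.maximum(ks, np.sqrt(tp) + 1.0)
        kl = np.sqrt(np.maximum(-2.0 * np.log(np.pi * tp * eps), 0.0)
                     / (np.pi**2 * tp))
        kl = np.where(np.pi * tp * eps < 1.0, np.maximum(kl, 1.0 / (np.pi * np.sqrt(tp))),
                      1.0 / (np.pi * np.sqrt(tp)))

    use_small = ks < kl
    val = np.empty_like(tp)

    if np.any(use_small):
        tt = tp[use_small]
        K = int(np.ceil(ks[use_small].max()))
        k_range = np.arange(-K, K + 1)
        terms = (w + 2.0 * k_range[:, None]) * np.exp(
            -((w + 2.0 * k_range[:, None]) ** 2) / (2.0 * tt[None, :])
        )
        val[use_small] = terms.sum(axis=0) / np.sqrt(2.0 * np.pi * tt**3)

    if np.any(~use_small):
        tt = tp[~use_small]
        K = int(np.ceil(kl[~use_small].max()))
        k_range = np.arange(1, K + 1)
        terms = (
            k_range[:, None]
            * np.exp(-(k_range[:, None] ** 2) * np.pi**2 * tt[None, :] / 2.0)
            * np.sin(k_range[:, None] * np.pi * w)
        )
        val[~use_small] = np.pi * terms.sum(axis=0)

    out[pos] = np.maximum(val, 0.0)
    return out


def wiener_fpt_density(
    t, p: DDMParams, boundary: str = "upper", eps: float = 1e-8
) -> np.ndarray:
    """Defective first-passage density at observed time t (seconds).

    Density is zero for t <= ter.  The two boundary densities integrate to the
    closed-form absorption probabilities and jointly to 1.
    """
    t = np.atleast_1d(np.asarray(t, dtype=float))
    if boundary == "lower":
        v, w = p.v, p.z
    elif boundary == "upper":
        v, w = -p.v, 1.0 - p.z
    else:
        raise ValueError("boundary must be 'upper' or 'lower'")
    td = t - p.ter
    dens = np.zeros_like(td)
    pos = td > 0
    if np.any(pos):
        tnorm = td[pos] / p.a**2
        f0 = _f_lower_norm(tnorm, w, eps)
        dens[pos] = (
            f0 / p.a**2 * np.exp(-v * p.a * w - v**2 * td[pos] / 2.0)
        )
    return dens


def boundary_probability(p: DDMParams, boundary: str = "upper") -> float:
    """Closed-form absorption probability at a boundary."""
    v, a, z = p.v, p.a, p.z
    if abs(v) < 1e-12:
        p_upper = z
    else:
        p_upper = (1.0 - math.exp(-2.0 * v * a * z)) / (
            1.0 - math.exp(-2.0 * v * a)
        )
    # note: with start x0 = z*a, drift v, unit diffusion on [0, a]:
    # P(hit upper) = (1 - exp(-2 v z a)) / (1 - exp(-2 v a))
    if boundary == "upper":
        return p_upper
    if boundary == "lower":
        return 1.0 - p_upper
    raise ValueError("boundary must be 'upper' or 'lower'")


def simulate_ddm_trials(
    p: DDMParams,
    n: int,
    dt: float = 1e-3,
    seed: int | np.random.Generator = 0,
    max_time: float = 20.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Euler–Maruyama simulation with unit diffusion.

    Returns (rt, boundary) with boundary 1 for upper and 0 for lower; RTs
    include the non-decision time.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    x = np.full(n, p.z * p.a)
    rt = np.full(n, np.nan)
    hit_upper = np.zeros(n, dtype=bool)
    active = np.ones(n, dtype=bool)
    sqrt_dt = math.sqrt(dt)
    t = 0.0
    n_steps = int(max_time / dt)
    for _ in range(n_steps):
        if not active.any():
            break
        t += dt
        idx = np.flatnonzero(active)
        x[idx] += p.v * dt + sqrt_dt * rng.standard_normal(idx.size)
        up = x[idx] >= p.a
        lo = x[idx] <= 0.0
        done = up | lo
        if done.any():
            fin = idx[done]
            rt[fin] = t
            hit_upper[fin] = up[done]
            active[fin] = False
    # censor stragglers at the closed-form probability split (rare for sane params)
    if active.any():
        stuck = np.flatnonzero(active)
        rt[stuck] = max_time
        hit_upper[stuck] = x[stuck] > p.a * p.z
    return rt + p.ter, hit_upper.astype(int)


# ---------------------------------------------------------------------------
# EZ-style closed-form estimator (unit diffusion)
# ---------------------------------------------------------------------------


def ez_forward_moments(p: DDMParams) -> tuple[float, float, float]:
    """(p_correct, rt_mean, rt_var) implied by an unbiased (z = 0.5) model."""
    v, a, ter = p.v, p.a, p.ter
    if abs(v) < 1e-10:
        pc = 0.5
        mdt = a**2 / 4.0
        vrt = a**4 / 24.0
    else:
        y = math.exp(-a * v)
        pc = 1.0 / (1.0 + y)
        mdt = (a / (2.0 * v)) * (1.0 - y) / (1.0 + y)
        vrt = (a / (2.0 * v**3)) * (1.0 - 2.0 * a * v * y - y**2) / (y + 1.0) ** 2
    return pc, mdt + ter, vrt


def ez_diffusion_estimate(
    p_correct: float, rt_var: float, rt_mean: float, n: Optional[int] = None
) -> DDMParams:
    """Closed-form method-of-moments (v, a, ter) with z = 0.5.

    p_correct at exactly 0, 0.5 or 1 is edge-corrected (half-a-trial rule when
    n is given, a fixed nudge of 1e-4 otherwise).
    """
    if not 0.0 <= p_correct <= 1.0:
        raise ValueError("p_correct must lie in [0, 1]")
    if rt_var <= 0:
        raise ValueError("rt_var must be positive")
    eps = 0.5 / n if n else 1e-4
    pc = min(max(p_correct, eps), 1.0 - eps)
    if abs(pc - 0.5) < 1e-9:
        pc += eps
    L = math.log(pc / (1.0 - pc))
    x = L * (L * pc**2 - L * pc + pc - 0.5) / rt_var
    v = math.copysign(abs(x) ** 0.25, pc - 0.5)
    a = L / v
    y = math.exp(-v * a)
    mdt = (a / (2.0 * v)) * (1.0 - y) / (1.0 + y)
    ter = rt_mean - mdt
    return DDMParams(v=v, a=a, z=0.5, ter=max(ter, 0.0))


# ---------------------------------------------------------------------------
# per-condition maximum-likelihood fitting
# ---------------------------------------------------------------------------


def _neg_loglik(theta: np.ndarray, rt: np.ndarray, correct: np.ndarray,
                t_min: float) -> float:
    v, log_a, u = theta
    a = math.exp(log_a)
    ter = t_min / (1.0 + math.exp(-u))  # ter in (0, min rt)
    try:
        p = DDMParams(v=v, a=a, z=0.5, ter=ter)
    except ValueError:
        return np.inf
    dens = np.empty_like(rt)
    up = correct.astype(bool)
    dens[up] = wiener_fpt_density(rt[up], p, "upper")
    dens[~up] = wiener_fpt_density(rt[~up], p, "lower")
    if np.any(dens <= 0) or np.any(~np.isfinite(dens)):
        return np.inf
    return -float(np.sum(np.log(dens)))


def fit_ddm_single(
    rt: np.ndarray, correct: np.ndarray, min_trials_warn: int = 40
) -> tuple[DDMParams, float, str]:
    """ML fit of (v, a, ter) with z = 0.5 for one condition.

    Accuracy coding: correct responses absorb at the upper boundary.
    Returns (params, loglik, status) with status 'ok', 'warning' (few trials
    or no convergence) or 'degenerate' (single response category).
    """
    rt = np.asarray(rt, dtype=float)
    correct = np.asarray(correct)
    status = "ok"
    if len(rt) < min_trials_warn:
        status = "warning"
        log.warning("DDM fit on only %d trials", len(rt))
    pc = float(np.mean(correct))
    if pc in (0.0, 1.0):
        status = "degenerate"
    t_min = float(np.min(rt))
    start = ez_diffusion_estimate(pc, float(np.var(rt[correct.astype(bool)]))
                                  if 0 < pc else float(np.var(rt)),
                                  float(np.mean(rt[correct.astype(bool)]))
                                  if 0 < pc else float(np.mean(rt)),
                                  n=len(rt))
    ter0 = min(max(start.ter, 1e-3), 0.95 * t_min)
    u0 = math.log(ter0 / (t_min - ter0)) if 0 < ter0 < t_min else 0.0
    theta0 = np.array([start.v, math.log(max(start.a, 0.2)), u0])
    res = optimize.minimize(
        _neg_loglik, theta0, args=(rt, correct, t_min), method="Nelder-Mead",
        options={"xatol": 1e-5, "fatol": 1e-7, "maxiter": 2000},
    )
    if not res.success and status == "ok":
        status = "warning"
    v, log_a, u = res.x
    params = DDMParams(v=float(v), a=float(math.exp(log_a)), z=0.5,
                       ter=float(t_min / (1.0 + math.exp(-u))))
    return params, -float(res.fun), status


def fit_ddm(
    trials: pd.DataFrame,
    condition_cols: Sequence[str] = ("blur",),
    min_trials_warn: int = 40,
) -> dict:
    """Per-condition ML Wiener fits on a trial table with 'rt' and 'accuracy'.

    Returns {condition: {"params": DDMParams, "loglik": float, "status": str,
    "n": int}} keyed by the condition tuple (scalar when one column).
    """
    out = {}
    for cond, grp in trials.groupby(list(condition_cols), sort=True):
        key = cond if len(condition_cols) > 1 else (
            cond[0] if isinstance(cond, tuple) else cond
        )
        params, ll, status = fit_ddm_single(
            grp["rt"].to_numpy(), grp["accuracy"].to_numpy(), min_trials_warn
        )
        out[key] = {"params": params, "loglik": ll, "status": status, "n": len(grp)}
    return out
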