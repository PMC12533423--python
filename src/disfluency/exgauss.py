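"""Ex-Gaussian RT distribution: density, moments, simulation, and fitting.

The ex-Gaussian is the convolution of a Gaussian (mu, sigma) and an
exponential with mean tau (rate lambda = 1/tau).  Its overall mean is
mu + tau and its SD is sqrt(sigma^2 + tau^2).  mu/sigma index the central
(shift) portion of the RT distribution, tau the slow tail (skew).

The log-density is evaluated in log space,

    logpdf(x) = -log(tau) + (mu - x)/tau + sigma^2 / (2 tau^2)
                + log Phi((x - mu)/sigma - sigma/tau),

which is stable for small sigma and small tau (``scipy.special.log_ndtr``
handles the far-tail normal log-CDF).

Condition effects are estimated either *two-stage* (per-subject, per-condition
ML fits, then contrasts on the subject-level parameters — tau and sigma on the
log scale, matching the analysis convention of an identity link on mu and log
links on sigma and beta/tau) or *pooled* (one joint ML fit with contrast-coded
condition terms on each link scale).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special

from .contrasts import ContrastSpec

__all__ = [
    "ExGaussianParams",
    "ExGaussCoefficients",
    "exgauss_logpdf",
    "exgauss_pdf",
    "exgauss_cdf",
    "exgauss_moments",
    "exgauss_rng",
    "fit_exgauss_mle",
    "fit_exgauss_distributional",
]

log = logging.getLogger(__name__)

_SQRT2 = math.sqrt(2.0)


@dataclass(frozen=True)
class ExGaussianParams:
    """Natural-scale ex-Gaussian parameters (seconds)."""

    mu: float
    sigma: float
    tau: float

    def __post_init__(self):
        if not (self.sigma > 0 and self.tau > 0):
            raise ValueError(f"sigma and tau must be positive, got {self}")
        if not (np.isfinite(self.mu) and np.isfinite(self.sigma) and np.isfinite(self.tau)):
            raise ValueError(f"parameters must be finite, got {self}")

    @property
    def rate(self) -> float:
        """Exponential rate lambda = 1/tau."""
        return 1.0 / self.tau

    def mean(self) -> float:
        return self.mu + self.tau

    def sd(self) -> float:
        return math.hypot(self.sigma, self.tau)


def _validate(p: ExGaussianParams) -> ExGaussianParams:
    if not isinstance(p, ExGaussianParams):
        p = ExGaussianParams(*p)
    return p


def exgauss_logpdf(x, p: ExGaussianParams) -> np.ndarray:
    p = _validate(p)
    x = np.asarray(x, dtype=float)
    z = (x - p.mu) / p.sigma
    return (
        -np.log(p.tau)
        + (p.mu - x) / p.tau
        + 0.5 * (p.sigma / p.tau) ** 2
        + special.log_ndtr(z - p.sigma / p.tau)
    )


def exgauss_pdf(x, p: ExGaussianParams) -> np.ndarray:
    return np.exp(exgauss_logpdf(x, p))


def exgauss_cdf(x, p: ExGaussianParams) -> np.ndarray:
    """CDF: Phi(z) - exp(logpdf-ish tail term); evaluated stably in log space."""
    p = _validate(p)
    x = np.asarray(x, dtype=float)
    z = (x - p.mu) / p.sigma
    # F(x) = Phi(z) - exp( (mu - x)/tau + sigma^2/(2 tau^2) + log Phi(z - sigma/tau) )
    log_term = (p.mu - x) / p.tau + 0.5 * (p.sigma / p.tau) ** 2 + special.log_ndtr(
        z - p.sigma / p.tau
    )
    return np.clip(special.ndtr(z) - np.exp(log_term), 0.0, 1.0)


def exgauss_moments(p: ExGaussianParams) -> tuple[float, float]:
    """Closed-form (mean, sd): mean = mu + tau, sd = sqrt(sigma^2 + tau^2)."""
    p = _validate(p)
    return p.mean(), p.sd()


def exgauss_rng(
    p: ExGaussianParams, n: int, seed: int | np.random.Generator = 0
) -> np.ndarray:
    """n draws as Normal(mu, sigma) + Exponential(mean tau); seed-deterministic."""
    p = _validate(p)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if n == 0:
        return np.empty(0)
    return rng.normal(p.mu, p.sigma, size=n) + rng.exponential(p.tau, size=n)


# ---------------------------------------------------------------------------
# maximum-likelihood fitting
# ---------------------------------------------------------------------------


def _moment_start(x: np.ndarray) -> np.ndarray:
    """Method-of-moments starting point on the (mu, log sigma, log tau) scale."""
    m, s = float(np.mean(x)), float(np.std(x))
    skew = float(np.clip(pd.Series(x).skew() if len(x) > 2 else 0.0, 0.0, None))
    # tau0 from the third central moment: tau ~ (m3/2)^(1/3)
    tau0 = s * (skew / 2.0) ** (1.0 / 3.0) if skew > 0 else 0.5 * s
    tau0 = float(np.clip(tau0, 0.05 * s, 0.95 * s))
    mu0 = m - tau0
    sigma0 = math.sqrt(max(s**2 - tau0**2, (0.05 * s) ** 2))
    return np.array([mu0, math.log(sigma0), math.log(tau0)])


# soft box on the log-scale parameters: sigma in [5 ms, 2 s], tau in [5 ms, 5 s].
# The EMG likelihood is degenerate as sigma -> 0 (exponential limit) and small
# cells otherwise drift there; sub-5-ms Gaussian spread is not a credible RT
# process, so runaway fits are pulled back with a quadratic penalty.
_LSIG_BOUNDS = (math.log(0.005), math.log(2.0))
_LTAU_BOUNDS = (math.log(0.005), math.log(5.0))


def _soft_bound(value: float, lo: float, hi: float) -> float:
    if value < lo:
        return 1e3 * (lo - value) ** 2
    if value > hi:
        return 1e3 * (value - hi) ** 2
    return 0.0


def _nll(theta: np.ndarray, x: np.ndarray) -> float:
    mu, lsig, ltau = theta
    if not (np.isfinite(lsig) and np.isfinite(ltau)):
        return np.inf
    penalty = _soft_bound(lsig, *_LSIG_BOUNDS) + _soft_bound(ltau, *_LTAU_BOUNDS)
    p = ExGaussianParams(mu, math.exp(np.clip(lsig, -20, 5)),
                         math.exp(np.clip(ltau, -20, 5)))
    ll = exgauss_logpdf(x, p)
    if not np.all(np.isfinite(ll)):
        return np.inf
    return -float(np.sum(ll)) + penalty


def fit_exgauss_mle(
    rts: np.ndarray, min_n: int = 10
) -> tuple[ExGaussianParams, float, bool]:
    """ML fit on the (mu, log sigma, log tau) scale.

    Returns (params, loglik, converged).  Non-convergence returns the best
    point found, flagged False.
    """
    x = np.asarray(rts, dtype=float)
    if len(x) < min_n:
        raise ValueError(f"need at least {min_n} RTs, got {len(x)}")
    theta0 = _moment_start(x)
    res = optimize.minimize(_nll, theta0, args=(x,), method="Nelder-Mead",
                            options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 2000})
    best = res
    if not res.success:
        res2 = optimize.minimize(_nll, res.x, args=(x,), method="BFGS")
        if res2.fun < best.fun:
            best = res2
        if not (res.success or res2.success):
            log.warning("ex-Gaussian fit did not converge (n=%d)", len(x))
    mu, lsig, ltau = best.x
    params = ExGaussianParams(mu, math.exp(lsig), math.exp(ltau))
    return params, -float(best.fun), bool(res.success or best.success)


@dataclass
class ExGaussCoefficients:
    """Contrast effects on mu (identity scale) and log sigma / log tau.

    ``coefficients[param][contrast_name]`` holds the point estimate; the
    per-subject effects backing the two-stage estimates are kept in
    ``subject_effects`` for bootstrap resampling.
    """

    mode: str
    coefficients: dict = field(default_factory=dict)
    subject_effects: Optional[pd.DataFrame] = None
    subject_params: Optional[pd.DataFrame] = None
    n_dropped_subjects: int = 0
    converged: bool = True

    PARAMS = ("mu", "log_sigma", "log_beta")


def _subject_condition_fits(
    trials: pd.DataFrame, condition_cols: Sequence[str], min_cell: int
) -> tuple[pd.DataFrame, int]:
    rows = []
    dropped = set()
    for (sid, *cond), grp in trials.groupby(["subject_id", *condition_cols], sort=True):
        if len(grp) < min_cell:
            dropped.add(sid)
            continue
        params, ll, ok = fit_exgauss_mle(grp["rt"].to_numpy(), min_n=min_cell)
        row = {"subject_id": sid, "n": len(grp), "converged": ok,
               "mu": params.mu, "log_sigma": math.log(params.sigma),
               "log_beta": math.log(params.tau)}
        row.update(dict(zip(condition_cols, cond)))
        rows.append(row)
    frame = pd.DataFrame(rows)
    if frame.empty:
        raise ValueError(
            f"no subject x condition cell reaches the {min_cell}-trial floor"
        )
    # a cell whose tau collapses onto the lower bound is a degenerate
    # near-Gaussian solution whose extreme log value would dominate the
    # subject-level average; such subjects are excluded with a log entry
    degenerate = frame["log_beta"] < _LTAU_BOUNDS[0] + 0.1
    dropped |= set(frame.loc[degenerate, "subject_id"])
    if dropped:
        log.info(
            "dropped %d subjects (cells below the %d-trial floor or "
            "degenerate tau fits)", len(dropped), min_cell,
        )
        frame = frame[~frame["subject_id"].isin(dropped)]
    return frame, len(dropped)


def fit_exgauss_distributional(
    trials: pd.DataFrame,
    contrasts: Sequence[ContrastSpec],
    mode: str = "two_stage",
    min_cell: int = 10,
) -> ExGaussCoefficients:
    """Condition effects on the three ex-Gaussian parameters.

    two_stage: fit each subject x condition cell by ML, then evaluate each
    contrast on the subject-level parameters (log scale for sigma and
    beta/tau); the per-subject contrast scores are retained for bootstrapping.

    pooled: one joint ML fit with contrast-coded linear predictors on mu
    (identity link) and on log sigma, log tau.
    """
    condition_cols = sorted({c.factor for c in contrasts})
    if mode == "two_stage":
        subj, n_dropped = _subject_condition_fits(trials, condition_cols, min_cell)
        if subj.empty:
            raise ValueError("no subject-level fits available")
        out = ExGaussCoefficients(mode=mode, n_dropped_subjects=n_dropped,
                                  subject_params=subj)
        effects = []
        for sid, grp in subj.groupby("subject_id"):
            row = {"subject_id": sid}
            for param in ExGaussCoefficients.PARAMS:
                for spec in contrasts:
                    cell_means = grp.groupby(spec.factor)[param].mean().to_dict()
                    try:
                        row[f"{param}:{spec.name}"] = spec.effect(cell_means)
                    except KeyError:
                        row[f"{param}:{spec.name}"] = np.nan
                row[f"{param}:intercept"] = grp[param].mean()
            effects.append(row)
        eff = pd.DataFrame(effects).set_index("subject_id")
        out.subject_effects = eff
        for param in ExGaussCoefficients.PARAMS:
            out.coefficients[param] = {
                spec.name: float(eff[f"{param}:{spec.name}"].mean())
                for spec in contrasts
            }
            out.coefficients[param]["intercept"] = float(
                eff[f"{param}:intercept"].mean()
            )
        return out

    if mode == "pooled":
        return _fit_pooled(trials, contrasts)
    raise ValueError(f"unknown mode {mode!r}")


def _fit_pooled(
    trials: pd.DataFrame, contrasts: Sequence[ContrastSpec]
) -> ExGaussCoefficients:
    x = trials["rt"].to_numpy(dtype=float)
    X = np.column_stack(
        [np.ones(len(trials))] + [c.codes(trials[c.factor]) for c in contrasts]
    )
    k = X.shape[1]

    def nll(theta):
        b_mu, b_ls, b_lt = theta[:k], theta[k : 2 * k], theta[2 * k :]
        mu = X @ b_mu
        sigma = np.exp(X @ b_ls)
        tau = np.exp(X @ b_lt)
        if np.any(~np.isfinite(sigma)) or np.any(~np.isfinite(tau)):
            return np.inf
        z = (x - mu) / sigma
        ll = (
            -np.log(tau)
            + (mu - x) / tau
            + 0.5 * (sigma / tau) ** 2
            + special.log_ndtr(z - sigma / tau)
        )
        return -float(np.sum(ll)) if np.all(np.isfinite(ll)) else np.inf

    start = _moment_start(x)
    theta0 = np.zeros(3 * k)
    theta0[0], theta0[k], theta0[2 * k] = start
    res = optimize.minimize(nll, theta0, method="Nelder-Mead",
                            options={"maxiter": 8000, "xatol": 1e-6, "fatol": 1e-8})
    out = ExGaussCoefficients(mode="pooled", converged=bool(res.success))
    names = ["intercept"] + [c.name for c in contrasts]
    for j, param in enumerate(ExGaussCoefficients.PARAMS):
        out.coefficients[param] = {
            nm: float(v) for nm, v in zip(names, res.x[j * k : (j + 1) * k])
        }
    return out
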