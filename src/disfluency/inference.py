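"""Uncertainty summaries, evidence ratios, hypothesis decisions, and power.

Contrast coefficients are summarized from a vector of draws (bootstrap
resamples here; posterior draws would work identically): mean, SE (draw SD),
an equal-tailed credible interval — 90% for directional hypotheses, 95% for
two-sided ones — the posterior probability that the effect lies in the
hypothesized direction, and the evidence ratio ER = p / (1 - p).  ER > 3 is
read as moderate-to-strong support, ER < 0.3 as support for the alternative,
and the band between as inconclusive.  A directional hypothesis is *supported*
when the interval excludes zero, the directional probability is high, and
ER > 3 — all three at once.

Draws default to 16,000.  An ER of infinity (every draw on one side) is
serialized as the string "Inf" in tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "EffectSummary",
    "HypothesisDecision",
    "PowerSpec",
    "summarize_effect",
    "decide_hypothesis",
    "bootstrap_contrast_draws",
    "power_one_sample",
    "DEFAULT_N_DRAWS",
]

DEFAULT_N_DRAWS = 16_000


@dataclass(frozen=True)
class EffectSummary:
    parameter: str
    contrast: str
    mean: float
    se: float
    cri_level: int            # 90 (directional) or 95 (two-sided)
    cri: tuple[float, float]
    posterior_prob: float
    evidence_ratio: float     # may be inf
    direction: str            # greater | less | two_sided

    def er_label(self) -> str:
        return "Inf" if math.isinf(self.evidence_ratio) else f"{self.evidence_ratio:.2f}"

    def as_row(self) -> dict:
        return {
            "parameter": self.parameter,
            "contrast": self.contrast,
            "mean": self.mean,
            "se": self.se,
            "cri_level": self.cri_level,
            "cri_lower": self.cri[0],
            "cri_upper": self.cri[1],
            "er": self.er_label(),
            "posterior_prob": self.posterior_prob,
        }


@dataclass(frozen=True)
class HypothesisDecision:
    supported: bool
    evidence: str             # supported | alternative | inconclusive
    zero_excluded: bool
    posterior_prob_high: bool
    er_above_3: bool


def summarize_effect(
    draws: np.ndarray,
    direction: str = "greater",
    parameter: str = "",
    contrast: str = "",
    min_draws: int = 1000,
) -> EffectSummary:
    """Mean / SE / CrI / directional probability / ER for one coefficient.

    The CrI level follows the reporting convention: 90% equal-tailed for
    directional hypotheses, 95% for two-sided.  posterior_prob is the fraction
    of draws in the hypothesized direction (for two-sided, the larger of the
    two sides); ER = p / (1 - p), infinite when every draw agrees.
    """
    draws = np.asarray(draws, dtype=float)
    if len(draws) < min_draws:
        raise ValueError(f"need >= {min_draws} draws, got {len(draws)}")
    if direction not in ("greater", "less", "two_sided"):
        raise ValueError(f"unknown direction {direction!r}")
    cri_level = 95 if direction == "two_sided" else 90
    alpha = 1.0 - cri_level / 100.0
    lo, hi = np.quantile(draws, [alpha / 2.0, 1.0 - alpha / 2.0])
    if direction == "greater":
        p = float(np.mean(draws > 0.0))
    elif direction == "less":
        p = float(np.mean(draws < 0.0))
    else:
        p = float(max(np.mean(draws > 0.0), np.mean(draws < 0.0)))
    er = math.inf if p >= 1.0 else p / (1.0 - p)
    return EffectSummary(
        parameter=parameter,
        contrast=contrast,
        mean=float(np.mean(draws)),
        se=float(np.std(draws, ddof=1)),
        cri_level=cri_level,
        cri=(float(lo), float(hi)),
        posterior_prob=p,
        evidence_ratio=er,
        direction=direction,
    )


def decide_hypothesis(
    summary: EffectSummary, er_threshold: float = 3.0, prob_floor: float = 0.95
) -> HypothesisDecision:
    """Conjunction decision rule plus the tri-state evidence label."""
    zero_excluded = not (summary.cri[0] <= 0.0 <= summary.cri[1])
    prob_high = summary.posterior_prob >= prob_floor
    er_high = summary.evidence_ratio > er_threshold
    if er_high:
        evidence = "supported"
    elif summary.evidence_ratio < 1.0 / er_threshold:
        evidence = "alternative"
    else:
        evidence = "inconclusive"
    return HypothesisDecision(
        supported=zero_excluded and prob_high and er_high,
        evidence=evidence,
        zero_excluded=zero_excluded,
        posterior_prob_high=prob_high,
        er_above_3=er_high,
    )


def bootstrap_contrast_draws(
    subject_effects: pd.DataFrame | np.ndarray,
    column: Optional[str] = None,
    n_boot: int = DEFAULT_N_DRAWS,
    seed: int = 0,
) -> np.ndarray:
    """Case-resampling bootstrap over subjects of a contrast's mean.

    ``subject_effects`` is the per-subject effect table (one row per subject);
    ``column`` selects the contrast; a bare vector is accepted directly.

    The raw percentile interval of a bootstrapped mean is narrow at small n
    (it behaves like a z- rather than a t-interval); draws are therefore
    rescaled around their mean by the t-calibration factor
    ``t_{n-1, .975} / z_{.975} * sqrt(n / (n - 1))`` so downstream
    equal-tailed intervals attain near-nominal coverage.
    """
    if n_boot < 1000:
        import warnings

        warnings.warn(f"n_boot={n_boot} is small; summaries need >= 1000 draws")
    if isinstance(subject_effects, pd.DataFrame):
        if column is None:
            raise ValueError("column required with a DataFrame input")
        values = subject_effects[column].dropna().to_numpy(dtype=float)
    else:
        values = np.asarray(subject_effects, dtype=float)
        values = values[np.isfinite(values)]
    n = len(values)
    if n < 2:
        raise ValueError("need at least two subjects to bootstrap")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    draws = values[idx].mean(axis=1)
    expand = (
        stats.t.ppf(0.975, n - 1) / stats.norm.ppf(0.975) * math.sqrt(n / (n - 1))
    )
    center = draws.mean()
    return center + (draws - center) * expand


@dataclass(frozen=True)
class PowerSpec:
    n: int
    delta: float              # standardized effect size
    alpha: float = 0.05
    sided: str = "one"

    def __post_init__(self):
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.n < 2:
            raise ValueError("n must be >= 2")
        if self.sided not in ("one", "two"):
            raise ValueError("sided must be 'one' or 'two'")


def power_one_sample(spec: PowerSpec) -> float:
    """Exact noncentral-t power of a one-sample t test.

    Noncentrality delta * sqrt(n); df = n - 1.  Two-sided power ignores the
    (negligible) probability mass in the wrong-direction rejection region.
    """
    df = spec.n - 1
    nc = spec.delta * math.sqrt(spec.n)
    alpha = spec.alpha if spec.sided == "one" else spec.alpha / 2.0
    t_crit = stats.t.ppf(1.0 - alpha, df)
    return float(stats.nct.sf(t_crit, df, nc))
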