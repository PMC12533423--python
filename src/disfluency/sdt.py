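"""Signal-detection analysis of old/new recognition.

Under the equal-variance Gaussian model, d' = z(hit rate) - z(false-alarm
rate) measures discrimination and the criterion c = -(z(H) + z(F))/2 measures
bias (positive = conservative).  The same quantities fall out of a probit
regression of P("old") on item status coded +-1/2: with the status code
s in {-1/2 (new), +1/2 (old)}, P("old") = Phi(d' s + c_model) where
c_model = -c; interactions of status with condition contrasts are d'
differences, condition main effects are differences in -c.

Rates of exactly 0 or 1 are corrected log-linearly (add 0.5 to each count,
1 to each denominator) before the inverse-normal transform.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .contrasts import ContrastSpec

__all__ = [
    "RecognitionCounts",
    "SDTEstimates",
    "tabulate_recognition",
    "dprime_criterion",
    "fit_probit_sdt",
]

OLD_RESPONSE = "old"


@dataclass(frozen=True)
class RecognitionCounts:
    n_old: int
    n_new: int
    hits: int
    misses: int
    false_alarms: int
    correct_rejections: int

    def __post_init__(self):
        if self.hits + self.misses != self.n_old:
            raise ValueError("hits + misses must equal n_old")
        if self.false_alarms + self.correct_rejections != self.n_new:
            raise ValueError("false alarms + correct rejections must equal n_new")


@dataclass(frozen=True)
class SDTEstimates:
    hit_rate: float
    fa_rate: float
    dprime: float
    criterion: float          # conventional sign: positive = conservative
    correction: str = "none"

    @property
    def c_model(self) -> float:
        """Regression parameterization (-c)."""
        return -self.criterion


def tabulate_recognition(
    trials: pd.DataFrame,
    condition_cols: Sequence[str] = ("blur",),
) -> dict:
    """Hit/miss/FA/CR counts per condition from test-phase trials.

    New items carry the blur condition under which they (or, for yoked
    designs, their studied counterparts) are scored, so each condition has its
    own false-alarm rate.
    """
    test = trials[trials["phase"] == "test"]
    if (test["status"] == "na").any():
        raise ValueError("test trials with status 'na' present")
    out = {}
    for cond, grp in test.groupby(list(condition_cols), sort=True):
        key = cond if len(condition_cols) > 1 else (
            cond[0] if isinstance(cond, tuple) else cond
        )
        old = grp[grp["status"] == "old"]
        new = grp[grp["status"] == "new"]
        say_old_old = int((old["response"] == OLD_RESPONSE).sum())
        say_old_new = int((new["response"] == OLD_RESPONSE).sum())
        out[key] = RecognitionCounts(
            n_old=len(old),
            n_new=len(new),
            hits=say_old_old,
            misses=len(old) - say_old_old,
            false_alarms=say_old_new,
            correct_rejections=len(new) - say_old_new,
        )
    return out


def dprime_criterion(
    counts: RecognitionCounts, correction: str = "loglinear"
) -> SDTEstimates:
    """d' and criterion from counts, with 0/1-rate protection.

    ``loglinear`` always adds 0.5 / 1; ``none`` leaves rates untouched and
    will produce infinite estimates at the extremes.
    """
    if counts.n_old == 0 or counts.n_new == 0:
        raise ValueError("need both old and new items")
    if correction == "loglinear":
        h = (counts.hits + 0.5) / (counts.n_old + 1.0)
        f = (counts.false_alarms + 0.5) / (counts.n_new + 1.0)
    elif correction == "none":
        h = counts.hits / counts.n_old
        f = counts.false_alarms / counts.n_new
    else:
        raise ValueError(f"unknown correction {correction!r}")
    zh, zf = stats.norm.ppf(h), stats.norm.ppf(f)
    return SDTEstimates(
        hit_rate=float(h),
        fa_rate=float(f),
        dprime=float(zh - zf),
        criterion=float(-0.5 * (zh + zf)),
        correction=correction,
    )


@dataclass
class ProbitSDTFit:
    """Probit-regression SDT fit.

    ``dprime_effects`` maps contrast name -> d' difference (status x contrast
    interaction); ``bias_effects`` maps contrast name -> difference in -c
    (condition main effect).  ``dprime_intercept`` is the grand d',
    ``c_model_intercept`` the grand -c.
    """

    params: pd.Series
    bse: pd.Series
    dprime_intercept: float
    c_model_intercept: float
    dprime_effects: dict = field(default_factory=dict)
    bias_effects: dict = field(default_factory=dict)
    family: str = "bernoulli"
    separation_corrected: bool = False


def _aggregate(trials: pd.DataFrame, condition_cols: Sequence[str]) -> pd.DataFrame:
    test = trials[trials["phase"] == "test"]
    grp = test.groupby([*condition_cols, "status"], sort=True)
    agg = grp.agg(
        say_old=("response", lambda s: int((s == OLD_RESPONSE).sum())),
        total=("response", "size"),
    ).reset_index()
    return agg


def fit_probit_sdt(
    trials: pd.DataFrame,
    contrasts: Sequence[ContrastSpec] = (),
    family: str = "bernoulli",
    condition_cols: Optional[Sequence[str]] = None,
) -> ProbitSDTFit:
    """Probit regression of P("old") on status, contrasts, and interactions.

    Status is coded +1/2 (old) / -1/2 (new).  ``bernoulli`` fits trial rows;
    ``binomial`` aggregates to (successes, totals) per condition x status cell
    first — the two give identical point estimates without random effects.
    Cells showing complete separation are flagged and handled by log-linear
    count smoothing in binomial mode.
    """
    if condition_cols is None:
        condition_cols = sorted({c.factor for c in contrasts}) or ["blur"]
    if family == "bernoulli":
        data = trials[trials["phase"] == "test"].copy()
        y = (data["response"] == OLD_RESPONSE).astype(float).to_numpy()
        totals = None
    elif family == "binomial":
        data = _aggregate(trials, condition_cols)
        y = data["say_old"].to_numpy(dtype=float)
        totals = data["total"].to_numpy(dtype=float)
    else:
        raise ValueError(f"unknown family {family!r}")

    status = np.where(data["status"] == "old", 0.5, -0.5)
    cols = {"intercept": np.ones(len(data)), "status": status}
    for spec in contrasts:
        code = spec.codes(data[spec.factor])
        cols[spec.name] = code
        cols[f"status:{spec.name}"] = status * code
    X = pd.DataFrame(cols)

    separation = False
    if family == "binomial":
        at_edge = (y == 0) | (y == totals)
        if at_edge.any():
            separation = True
            y = y + 0.5
            totals = totals + 1.0
        endog = np.column_stack([y, totals - y])
        model = sm.GLM(endog, X, family=sm.families.Binomial(sm.families.links.Probit()))
    else:
        model = sm.GLM(y, X, family=sm.families.Binomial(sm.families.links.Probit()))
    res = model.fit()

    fit = ProbitSDTFit(
        params=res.params,
        bse=res.bse,
        dprime_intercept=float(res.params["status"]),
        c_model_intercept=float(res.params["intercept"]),
        family=family,
        separation_corrected=separation,
    )
    for spec in contrasts:
        fit.dprime_effects[spec.name] = float(res.params[f"status:{spec.name}"])
        fit.bias_effects[spec.name] = float(res.params[spec.name])
    return fit
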