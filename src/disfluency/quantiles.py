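"""Vincentile quantile profiles, delta plots, and pattern classification.

The group RT quantile profile is built in the classical four steps: (1) sort
each participant's correct RTs within condition, (2) take each participant's
quantiles and average them across participants (Vincentization), (3) average
between conditions where a composite reference is needed, and (4) take the
quantile-wise difference between conditions, keeping the sign of the contrast
(slower condition minus its reference).

Delta profiles are classified into the four canonical qualitative patterns:

* ``no_difference``   — all quantile differences negligibly small;
* ``complete_shift``  — a consistent difference at every quantile (flat delta);
* ``late_differences``— differences grow towards the slow quantiles;
* ``early_differences`` — differences shrink towards the slow quantiles.

Quantiles use linear interpolation of order statistics (numpy's default,
the "type 7" convention), recorded in the profile metadata.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .contrasts import ContrastSpec

__all__ = [
    "DEFAULT_PROBS",
    "QuantileProfile",
    "DeltaProfile",
    "vincentize",
    "delta_profile",
    "classify_delta_pattern",
    "plot_quantile_profile",
    "plot_delta_profile",
]

#: figure convention: the .1, .3, .5, .7 and .9 quantiles
DEFAULT_PROBS = (0.1, 0.3, 0.5, 0.7, 0.9)

PATTERNS = ("no_difference", "late_differences", "complete_shift", "early_differences")


@dataclass
class QuantileProfile:
    probs: tuple
    quantiles: pd.DataFrame          # condition x prob, seconds
    subject_quantiles: pd.DataFrame  # (subject, condition) x prob
    n_subjects: int
    n_dropped: int = 0
    estimator: str = "linear interpolation of order statistics (type 7)"

    def condition_quantiles(self, condition: str) -> np.ndarray:
        return self.quantiles.loc[condition].to_numpy()


@dataclass
class DeltaProfile:
    contrast: str
    probs: tuple
    delta: np.ndarray                 # seconds, condition A - reference
    subject_deltas: Optional[pd.DataFrame] = None  # subject x prob


def vincentize(
    trials: pd.DataFrame,
    probs: Sequence[float] = DEFAULT_PROBS,
    condition_col: str = "blur",
    min_trials: Optional[int] = None,
) -> QuantileProfile:
    """Per-subject per-condition quantiles averaged across subjects.

    Subjects lacking ``min_trials`` (default: the number of probs) correct
    trials in any condition they contribute to are dropped entirely so every
    condition averages the same subjects.
    """
    probs = tuple(probs)
    floor = min_trials if min_trials is not None else len(probs)
    counts = trials.groupby(["subject_id", condition_col])["rt"].count()
    bad = counts[counts < floor].index.get_level_values(0).unique()
    kept = trials[~trials["subject_id"].isin(bad)]
    if kept.empty:
        raise ValueError("no subjects clear the per-cell trial floor")

    rows = []
    for (sid, cond), grp in kept.groupby(["subject_id", condition_col], sort=True):
        q = np.quantile(np.sort(grp["rt"].to_numpy()), probs)
        rows.append({"subject_id": sid, condition_col: cond,
                     **{p: qi for p, qi in zip(probs, q)}})
    subj = pd.DataFrame(rows).set_index(["subject_id", condition_col])
    group = subj.groupby(level=condition_col).mean()
    group = group[list(probs)]
    return QuantileProfile(
        probs=probs,
        quantiles=group,
        subject_quantiles=subj,
        n_subjects=kept["subject_id"].nunique(),
        n_dropped=len(bad),
    )


def delta_profile(profile: QuantileProfile, contrast: ContrastSpec) -> DeltaProfile:
    """Quantile-wise contrast of Vincentized quantiles.

    The positive-weight condition(s) minus the mean of the negative-weight
    reference condition(s); composite references are averaged with equal
    weights, mirroring the contrast coding.
    """
    pos = [l for l, w in contrast.weights.items() if w > 0]
    neg = [l for l, w in contrast.weights.items() if w < 0]
    missing = [l for l in pos + neg if l not in profile.quantiles.index]
    if missing:
        raise KeyError(f"profile lacks condition(s) {missing}")
    delta = (
        profile.quantiles.loc[pos].mean(axis=0)
        - profile.quantiles.loc[neg].mean(axis=0)
    ).to_numpy()

    subj = profile.subject_quantiles
    per_subject = None
    if subj is not None:
        cond_level = subj.index.names[1]
        wide = subj.reset_index()
        present = wide.groupby("subject_id")[cond_level].agg(
            lambda s: set(pos + neg) <= set(s)
        )
        ok_subjects = present[present].index
        wide = wide[wide["subject_id"].isin(ok_subjects)]
        a = wide[wide[cond_level].isin(pos)].groupby("subject_id")[list(profile.probs)].mean()
        b = wide[wide[cond_level].isin(neg)].groupby("subject_id")[list(profile.probs)].mean()
        per_subject = a - b
    return DeltaProfile(
        contrast=contrast.name, probs=profile.probs, delta=delta,
        subject_deltas=per_subject,
    )


def classify_delta_pattern(
    delta: DeltaProfile | np.ndarray,
    floor: float = 0.010,
    slope_tol: float = 0.005,
) -> str:
    """Label a delta profile with one of the four canonical patterns.

    ``floor`` (seconds) is the magnitude below which a quantile difference is
    treated as zero; ``slope_tol`` (seconds per quantile step) bounds the
    trend considered flat.  Rules, in order:

    1. every |delta| below the floor            -> no_difference
    2. slope above +slope_tol                   -> late_differences
    3. slope below -slope_tol                   -> early_differences
    4. every |delta| at or above the floor      -> complete_shift
    5. otherwise: largest differences decide (late if they sit in the upper
       half of the quantile range, early if in the lower half).
    """
    d = delta.delta if isinstance(delta, DeltaProfile) else np.asarray(delta, float)
    if len(d) < 3:
        raise ValueError("need at least 3 quantile points to classify")
    if np.all(np.abs(d) < floor):
        return "no_difference"
    steps = np.arange(len(d), dtype=float)
    slope = np.polyfit(steps, d, 1)[0]
    if slope > slope_tol:
        return "late_differences"
    if slope < -slope_tol:
        return "early_differences"
    if np.all(np.abs(d) >= floor):
        return "complete_shift"
    return (
        "late_differences"
        if np.argmax(np.abs(d)) >= len(d) / 2
        else "early_differences"
    )


# ---------------------------------------------------------------------------
# plotting
# ---------------------------------------------------------------------------


def plot_quantile_profile(profile: QuantileProfile, ax=None, title: str = ""):
    """Quantile plot: one line per condition over the quantile probabilities."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4.5, 3.5))
    for cond in profile.quantiles.index:
        ax.plot(profile.probs, profile.condition_quantiles(cond), "o-", label=str(cond))
    ax.set_xlabel("quantile")
    ax.set_ylabel("RT (s)")
    ax.legend(frameon=False, fontsize=8)
    if title:
        ax.set_title(title, fontsize=10)
    return ax


def plot_delta_profile(delta: DeltaProfile, ax=None, title: str = ""):
    """Delta plot: quantile-wise condition difference, with the zero line."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4.5, 3.5))
    ax.axhline(0.0, color="0.6", lw=0.8)
    ax.plot(delta.probs, delta.delta * 1000.0, "o-", color="C3")
    ax.set_xlabel("quantile")
    ax.set_ylabel("delta (ms)")
    ax.set_title(title or delta.contrast, fontsize=10)
    return ax
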