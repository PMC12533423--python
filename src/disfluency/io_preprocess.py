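"""Trial-level I/O and preprocessing.

Trials live in a pandas DataFrame with one row per behavioural trial and the
columns in :data:`TRIAL_COLUMNS`.  RTs are stored in seconds; files recorded in
milliseconds can be converted on read with ``rt_unit="ms"``.

Preprocessing follows the standard order for this paradigm: participant
exclusions first (repeats, underage, encoding accuracy below threshold on all
encoding trials), RT trimming second.  Trim bounds are inclusive — removal is
defined by strict inequalities (faster than 0.2 s, slower than 2.5 s), so
boundary values are retained.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable

import pandas as pd

__all__ = [
    "TRIAL_COLUMNS",
    "ExclusionReport",
    "read_trials",
    "write_trials",
    "filter_rts",
    "exclude_participants",
    "select_rt_analysis_trials",
]

#: canonical column order for trial tables
TRIAL_COLUMNS = [
    "subject_id",
    "item_id",
    "list_id",
    "phase",       # encoding | test
    "task",        # ldt | semcat
    "blur",        # clear | low | high
    "frequency",   # high | low | none
    "stim_class",  # word | nonword | animal | nonanimal
    "status",      # old | new | na  (na iff encoding phase)
    "rt",          # seconds
    "response",
    "accuracy",    # 0 | 1
]

DEFAULT_MIN_RT = 0.2
DEFAULT_MAX_RT = 2.5
DEFAULT_ACCURACY_THRESHOLD = 0.80


@dataclass
class ExclusionReport:
    """Auditable record of what preprocessing removed and why."""

    n_input_trials: int = 0
    n_rt_trimmed: int = 0
    pct_rt_trimmed: float = 0.0
    n_nonpositive_rt: int = 0
    excluded_subjects: list[tuple[str, str]] = field(default_factory=list)
    n_subject_trials_removed: int = 0
    n_retained: int = 0

    def to_json(self, path: str | Path | None = None) -> str:
        payload = asdict(self)
        payload["excluded_subjects"] = [list(t) for t in self.excluded_subjects]
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    def log_lines(self) -> list[str]:
        lines = [
            f"input trials: {self.n_input_trials}",
            f"RT-trimmed trials: {self.n_rt_trimmed} ({self.pct_rt_trimmed:.2f}%)",
        ]
        for sid, reason in self.excluded_subjects:
            lines.append(f"excluded subject {sid}: {reason}")
        lines.append(f"retained trials: {self.n_retained}")
        return lines


def _empty_like(trials: pd.DataFrame) -> pd.DataFrame:
    return trials.iloc[0:0].copy()


def read_trials(path: str | Path, rt_unit: str = "s") -> pd.DataFrame:
    """Read a trial table from delimited text (CSV, UTF-8, header row)."""
    df = pd.read_csv(path)
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trial file {path} lacks columns {missing}")
    if rt_unit == "ms":
        df["rt"] = df["rt"] / 1000.0
    elif rt_unit != "s":
        raise ValueError(f"unknown rt_unit {rt_unit!r} (use 's' or 'ms')")
    return df[TRIAL_COLUMNS + [c for c in df.columns if c not in TRIAL_COLUMNS]]


def write_trials(trials: pd.DataFrame, path: str | Path) -> None:
    trials.to_csv(path, index=False)


def filter_rts(
    trials: pd.DataFrame,
    min_rt: float = DEFAULT_MIN_RT,
    max_rt: float = DEFAULT_MAX_RT,
) -> tuple[pd.DataFrame, ExclusionReport]:
    """Trim fast and slow RTs, keeping [min_rt, max_rt] inclusive.

    Nonpositive RTs are invalid recordings; they are removed and counted
    separately in the report.  Input row order is preserved.
    """
    if not min_rt < max_rt:
        raise ValueError("min_rt must be strictly below max_rt")
    report = ExclusionReport(n_input_trials=len(trials))
    if trials.empty:
        report.n_retained = 0
        return _empty_like(trials), report

    rt = trials["rt"]
    nonpositive = rt <= 0
    keep = (rt >= min_rt) & (rt <= max_rt) & ~nonpositive
    report.n_nonpositive_rt = int(nonpositive.sum())
    report.n_rt_trimmed = int((~keep).sum())
    report.pct_rt_trimmed = 100.0 * report.n_rt_trimmed / report.n_input_trials
    out = trials.loc[keep].copy()
    report.n_retained = len(out)
    return out, report


def exclude_participants(
    trials: pd.DataFrame,
    accuracy_threshold: float = DEFAULT_ACCURACY_THRESHOLD,
    repeat_ids: Iterable = (),
    underage_ids: Iterable = (),
) -> tuple[pd.DataFrame, ExclusionReport]:
    """Remove repeat / underage subjects and those with encoding accuracy below threshold.

    Accuracy is computed over all encoding trials (words and foils alike),
    before any RT trimming.  A subject at exactly the threshold is retained
    (the removal rule is strictly below).
    """
    if not 0 < accuracy_threshold < 1:
        raise ValueError("accuracy_threshold must lie in (0, 1)")
    report = ExclusionReport(n_input_trials=len(trials))
    repeat_ids = set(repeat_ids)
    underage_ids = set(underage_ids)

    excluded: dict = {}
    for sid in repeat_ids:
        excluded[sid] = "repeat"
    for sid in underage_ids:
        excluded.setdefault(sid, "underage")

    if not trials.empty:
        enc = trials[trials["phase"] == "encoding"]
        acc = enc.groupby("subject_id")["accuracy"].mean()
        for sid in trials["subject_id"].unique():
            if sid in excluded:
                continue
            if sid not in acc.index:
                # no encoding trials at all: accuracy is undefined -> excluded
                excluded[sid] = "accuracy_below_threshold"
            elif acc.loc[sid] < accuracy_threshold:
                excluded[sid] = "accuracy_below_threshold"

    report.excluded_subjects = sorted((str(s), r) for s, r in excluded.items())
    if trials.empty:
        return _empty_like(trials), report

    keep = ~trials["subject_id"].isin(excluded)
    out = trials.loc[keep].copy()
    report.n_subject_trials_removed = int((~keep).sum())
    report.n_retained = len(out)
    return out, report


def select_rt_analysis_trials(trials: pd.DataFrame, task: str) -> pd.DataFrame:
    """Correct, target-class, encoding-phase trials for the RT analyses.

    For the lexical decision task the targets are words (nonwords are foils);
    for semantic categorization they are the non-animal words (animals are
    foils and are excluded from analysis).
    """
    target_class = {"ldt": "word", "semcat": "nonanimal"}.get(task)
    if target_class is None:
        raise ValueError(f"unsupported task {task!r} (use 'ldt' or 'semcat')")
    mask = (
        (trials["phase"] == "encoding")
        & (trials["accuracy"] == 1)
        & (trials["stim_class"] == target_class)
    )
    return trials.loc[mask].copy()
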