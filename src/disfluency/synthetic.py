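"""Synthetic blur x frequency experiments with known ground truth.

Encoding RTs are generated per (subject, item) from either an ex-Gaussian or
a Wiener-diffusion process whose parameters vary by condition; subject and
item random intercepts act on each parameter's link scale (identity for mu /
v / ter, log for sigma and tau).  Recognition responses come from an
equal-variance Gaussian SDT model: with status coded s = +1/2 (old) / -1/2
(new), P("old") = Phi(d' s - c), i.e. P(hit) = Phi(d'/2 - c) and
P(false alarm) = Phi(-d'/2 - c).

Three generative presets encode the qualitative predictions of the candidate
accounts of the disfluency effect:

* ``metacognitive``   — blur lengthens only the slow tail (tau up for both
  blur levels; mu untouched);
* ``compensatory``    — high blur shifts the whole distribution (mu up) with
  no tail effect; low blur behaves like clear;
* ``stage_specific``  — high blur both shifts and skews (mu and tau up, sigma
  mildly up); low blur produces a small mu shift only.

The stage_specific magnitudes follow the Experiment-1A posterior means
(mu: +0.107 s for high vs. clear/low average, +0.016 s for low vs. clear;
log sigma: +0.16; log tau: +0.43 for the high contrast, 0 for low vs. clear),
on base clear-condition parameters mu = 0.54 s, sigma = 0.08 s, tau = 0.22 s.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import design as design_mod
from .design import BLUR_LEVELS, CounterbalanceList, DesignSpec
from .ddm import DDMParams, simulate_ddm_trials
from .exgauss import ExGaussianParams
from .io_preprocess import TRIAL_COLUMNS

__all__ = [
    "EncodingGenConfig",
    "RecognitionGenConfig",
    "simulate_encoding",
    "simulate_recognition",
    "simulate_full_experiment",
    "encoding_preset",
    "recognition_preset",
]


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class EncodingGenConfig:
    """Generator settings for encoding-phase RTs and accuracy."""

    generator: str = "exgauss"  # exgauss | ddm
    #: condition key (blur or (blur, frequency)) -> ExGaussianParams | DDMParams
    params: dict = field(default_factory=dict)
    #: per-condition lapse/error probability (exgauss generator only)
    error_rate: dict = field(default_factory=dict)
    #: random-effect SDs on link scales: mu (s), log_sigma, log_tau / v, ter
    subject_sd: dict = field(default_factory=lambda: {"mu": 0.05, "log_sigma": 0.15,
                                                      "log_tau": 0.15})
    item_sd: dict = field(default_factory=lambda: {"mu": 0.02})
    foil_params: Optional[object] = None   # nonword/animal trials; None = grand params
    foil_error_rate: float = 0.05

    def validate(self):
        for cond, p in self.params.items():
            if self.generator == "exgauss" and not isinstance(p, ExGaussianParams):
                raise TypeError(f"condition {cond}: expected ExGaussianParams")
            if self.generator == "ddm" and not isinstance(p, DDMParams):
                raise TypeError(f"condition {cond}: expected DDMParams")
        for cond, e in self.error_rate.items():
            if not 0.0 <= e <= 1.0:
                raise ValueError(f"error rate for {cond} outside [0, 1]")


@dataclass
class RecognitionGenConfig:
    """Equal-variance SDT generator: per-condition d' and criterion."""

    dprime: dict = field(default_factory=dict)     # condition -> d'
    criterion: dict = field(default_factory=dict)  # condition -> c (conventional)
    subject_sd_dprime: float = 0.25
    subject_sd_criterion: float = 0.25

    def validate(self):
        for d in (self.dprime, self.criterion):
            for cond, v in d.items():
                if not np.isfinite(v):
                    raise ValueError(f"non-finite SDT parameter for {cond}")


def _cond_key(blur: str, frequency: str) -> object:
    return blur if frequency == "none" else (blur, frequency)


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

_BASE = dict(mu=0.54, sigma=0.08, tau=0.22)

#: injected effects per preset on the analysis link scales, exp-1 blur factor:
#: (mu shift vs clear, log-sigma shift, log-tau shift) for low and high blur
_PRESET_EFFECTS = {
    # tau up for both blur levels, mu flat
    "metacognitive": {"low": (0.0, 0.0, 0.30), "high": (0.0, 0.0, 0.30)},
    # pure shift for high blur only
    "compensatory": {"low": (0.0, 0.0, 0.0), "high": (0.107, 0.0, 0.0)},
    # shift + skew for high, small shift for low (Experiment-1A magnitudes)
    "stage_specific": {"low": (0.016, 0.0, 0.0), "high": (0.115, 0.16, 0.43)},
}
# note: with low's mu at clear + 0.016, a high-blur mu of clear + 0.115 puts
# the high-vs-mean(clear, low) contrast at 0.115 - 0.008 = 0.107 s, matching
# the targeted contrast-1 effect.


def encoding_preset(
    name: str = "stage_specific", frequency: bool = False
) -> EncodingGenConfig:
    """Named generative scenario for the encoding phase.

    With ``frequency=True`` (Experiment-2 style) low-frequency words get an
    extra mu shift (+0.018 s) and log-tau inflation (+0.065), applied on top
    of the blur effects within each frequency level.
    """
    if name not in _PRESET_EFFECTS:
        raise KeyError(f"unknown preset {name!r}; choose from {sorted(_PRESET_EFFECTS)}")
    eff = _PRESET_EFFECTS[name]
    params: dict = {}
    error = {}
    err_by_blur = {"clear": 0.03, "low": 0.04, "high": 0.12}
    for blur in BLUR_LEVELS:
        dmu, dls, dlt = (0.0, 0.0, 0.0) if blur == "clear" else eff[blur]
        base = ExGaussianParams(
            mu=_BASE["mu"] + dmu,
            sigma=_BASE["sigma"] * math.exp(dls),
            tau=_BASE["tau"] * math.exp(dlt),
        )
        if not frequency:
            params[blur] = base
            error[blur] = err_by_blur[blur]
        else:
            for freq, (fmu, flt) in {"high": (0.0, 0.0), "low": (0.018, 0.065)}.items():
                params[(blur, freq)] = ExGaussianParams(
                    mu=base.mu + fmu, sigma=base.sigma, tau=base.tau * math.exp(flt)
                )
                error[(blur, freq)] = err_by_blur[blur]
    cfg = EncodingGenConfig(generator="exgauss", params=params, error_rate=error)
    cfg.validate()
    return cfg


def recognition_preset(exp: str = "1A") -> RecognitionGenConfig:
    """Recognition-memory ground truth per experiment preset.

    Experiments 1A/1B: d' elevated for high blur (clear = low < high), the
    high-vs-others contrast matching the reported ~0.13 (1A) / ~0.10 (1B)
    d' differences; criterion mildly conservative.  Experiment 2 adds the
    frequency effect (low-frequency words better discriminated) and the
    selective high-frequency x blur benefit.
    """
    if exp in ("1A", "1B"):
        gap = 0.131 if exp == "1A" else 0.100
        d0 = 1.0
        cfg = RecognitionGenConfig(
            dprime={"clear": d0, "low": d0, "high": d0 + gap},
            criterion={"clear": 0.10, "low": 0.02 if exp == "1A" else 0.10,
                       "high": 0.08 if exp == "1A" else 0.10},
        )
    elif exp == "2":
        d_hf, d_lf = 0.85, 1.12  # low-frequency advantage ~ 0.27
        cfg = RecognitionGenConfig(
            dprime={
                ("clear", "high"): d_hf, ("low", "high"): d_hf + 0.095,
                ("high", "high"): d_hf + 0.12,
                ("clear", "low"): d_lf, ("low", "low"): d_lf,
                ("high", "low"): d_lf + 0.03,
            },
            criterion={(b, f): 0.10 for b in BLUR_LEVELS for f in ("high", "low")},
        )
    else:
        raise KeyError(f"unknown experiment preset {exp!r}")
    cfg.validate()
    return cfg


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------


def _random_effects(ids: Sequence, sds: Mapping[str, float],
                    rng: np.random.Generator) -> pd.DataFrame:
    eff = {k: rng.normal(0.0, sd, size=len(ids)) for k, sd in sds.items()}
    return pd.DataFrame(eff, index=list(ids))


def simulate_encoding(
    config: EncodingGenConfig,
    lists: Sequence[CounterbalanceList],
    subject_map: Mapping[str, int],
    task: str = "ldt",
    foil_items: Optional[Sequence[str]] = None,
    seed: int = 0,
) -> pd.DataFrame:
    """One encoding trial per (subject, study item [+ foil item]).

    Study items come from each subject's list ('old' rows of the assignment);
    foils (nonwords for the LDT, animal words for semantic categorization) are
    shared across lists and rendered clear.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    lists_by_id = {l.list_id: l for l in lists}
    subjects = sorted(subject_map)
    subj_re = _random_effects(subjects, config.subject_sd, rng)

    all_items = sorted({i for l in lists for i in l.assignment})
    if foil_items:
        all_items = sorted(set(all_items) | set(foil_items))
    item_re = _random_effects(all_items, config.item_sd, rng)

    foil_class = {"ldt": "nonword", "semcat": "animal"}[task]
    target_class = {"ldt": "word", "semcat": "nonanimal"}[task]

    # trial grid: one row per (subject, study item) plus shared foils
    meta_rows = []
    for sid in subjects:
        lst = lists_by_id[subject_map[sid]]
        for item, (status, blur, freq) in lst.assignment.items():
            if status != "old":
                continue
            cls = "animal" if item.startswith("a") else target_class
            meta_rows.append((sid, item, lst.list_id, blur, freq, cls))
        for item in foil_items or []:
            meta_rows.append((sid, item, lst.list_id, "clear", "none", foil_class))
    meta = pd.DataFrame(
        meta_rows,
        columns=["subject_id", "item_id", "list_id", "blur", "frequency", "stim_class"],
    )
    is_target = (meta["stim_class"] == target_class).to_numpy()
    keys = [
        _cond_key(b, f) if tgt else None
        for b, f, tgt in zip(meta["blur"], meta["frequency"], is_target)
    ]
    unknown = {k for k in keys if k is not None} - set(config.params)
    if unknown:
        raise KeyError(f"no generative parameters for condition(s) {sorted(map(str, unknown))}")

    n = len(meta)
    if config.generator == "exgauss":
        grand = config.foil_params or _grand_params(config)
        base_mu = np.array([(config.params[k] if k else grand).mu for k in keys])
        base_sig = np.array([(config.params[k] if k else grand).sigma for k in keys])
        base_tau = np.array([(config.params[k] if k else grand).tau for k in keys])
        err = np.array([
            config.error_rate.get(k, 0.0) if k else config.foil_error_rate
            for k in keys
        ])
        s_mu = subj_re["mu"].reindex(meta["subject_id"]).fillna(0.0).to_numpy() \
            if "mu" in subj_re else 0.0
        s_ls = subj_re["log_sigma"].reindex(meta["subject_id"]).fillna(0.0).to_numpy() \
            if "log_sigma" in subj_re else 0.0
        s_lt = subj_re["log_tau"].reindex(meta["subject_id"]).fillna(0.0).to_numpy() \
            if "log_tau" in subj_re else 0.0
        i_mu = item_re["mu"].reindex(meta["item_id"]).fillna(0.0).to_numpy() \
            if "mu" in item_re else 0.0
        mu = base_mu + s_mu + i_mu
        sigma = base_sig * np.exp(s_ls)
        tau = base_tau * np.exp(s_lt)
        rt = np.maximum(rng.normal(mu, sigma) + tau * rng.standard_exponential(n), 1e-3)
        accuracy = (rng.random(n) >= err).astype(int)
    else:  # ddm: simulate per (condition, subject) block for speed
        rt = np.empty(n)
        accuracy = np.empty(n, dtype=int)
        key_series = pd.Series(keys, dtype=object)
        for (key, sid), idx in meta.groupby(
            [key_series.fillna("__foil__"), "subject_id"], sort=True
        ).indices.items():
            base = config.params[key] if key != "__foil__" else (
                config.foil_params or next(iter(config.params.values()))
            )
            v = base.v + (subj_re.loc[sid, "v"] if "v" in subj_re else 0.0)
            ter = max(base.ter + (subj_re.loc[sid, "ter"] if "ter" in subj_re else 0.0), 0.0)
            p = DDMParams(v=v, a=base.a, z=base.z, ter=ter)
            rts_block, upper = simulate_ddm_trials(p, len(idx), seed=rng)
            rt[idx] = rts_block
            accuracy[idx] = upper

    wrong = {"word": "nonword", "nonword": "word",
             "nonanimal": "animal", "animal": "nonanimal"}
    out = meta.copy()
    out["phase"] = "encoding"
    out["task"] = task
    out["status"] = "na"
    out["rt"] = rt
    out["accuracy"] = accuracy
    out["response"] = np.where(
        accuracy == 1,
        out["stim_class"],
        out["stim_class"].map(wrong),
    )
    return out[TRIAL_COLUMNS]


def _grand_params(config: EncodingGenConfig):
    ps = list(config.params.values())
    if config.generator == "exgauss":
        return ExGaussianParams(
            mu=float(np.mean([p.mu for p in ps])),
            sigma=float(np.mean([p.sigma for p in ps])),
            tau=float(np.mean([p.tau for p in ps])),
        )
    return ps[0]


def simulate_recognition(
    config: RecognitionGenConfig,
    lists: Sequence[CounterbalanceList],
    subject_map: Mapping[str, int],
    task: str = "ldt",
    seed: int = 0,
) -> pd.DataFrame:
    """Old/new test-phase responses from the equal-variance SDT model.

    Each subject responds to every word of their list (old and new); animal
    fillers and nonwords never appear at test.  P("old") = Phi(d' s - c) with
    s = +1/2 for old and -1/2 for new items; subject random effects perturb
    d' and c.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    lists_by_id = {l.list_id: l for l in lists}
    subjects = sorted(subject_map)
    re_d = dict(zip(subjects, rng.normal(0.0, config.subject_sd_dprime, len(subjects))))
    re_c = dict(zip(subjects, rng.normal(0.0, config.subject_sd_criterion, len(subjects))))

    target_class = {"ldt": "word", "semcat": "nonanimal"}[task]
    meta_rows = []
    for sid in subjects:
        lst = lists_by_id[subject_map[sid]]
        for item, (status, blur, freq) in lst.assignment.items():
            if item.startswith("a"):
                continue  # animal fillers excluded at design level
            meta_rows.append((sid, item, lst.list_id, status, blur, freq))
    meta = pd.DataFrame(
        meta_rows,
        columns=["subject_id", "item_id", "list_id", "status", "blur", "frequency"],
    )
    keys = [_cond_key(b, f) for b, f in zip(meta["blur"], meta["frequency"])]
    unknown = set(keys) - set(config.dprime)
    if unknown:
        raise KeyError(f"no d' for condition(s) {sorted(map(str, unknown))}")

    n = len(meta)
    d = np.maximum(
        np.array([config.dprime[k] for k in keys])
        + meta["subject_id"].map(re_d).to_numpy(),
        0.0,
    )
    c = np.array([config.criterion.get(k, 0.0) for k in keys]) \
        + meta["subject_id"].map(re_c).to_numpy()
    s = np.where(meta["status"] == "old", 0.5, -0.5)
    p_old = stats.norm.cdf(d * s - c)
    say_old = rng.random(n) < p_old

    out = meta.copy()
    out["phase"] = "test"
    out["task"] = task
    out["stim_class"] = target_class
    out["rt"] = np.maximum(
        rng.normal(0.9, 0.15, n) + 0.3 * rng.standard_exponential(n), 1e-3
    )
    out["response"] = np.where(say_old, "old", "new")
    out["accuracy"] = ((meta["status"] == "old").to_numpy() == say_old).astype(int)
    return out[TRIAL_COLUMNS]


# ---------------------------------------------------------------------------
# whole-experiment presets
# ---------------------------------------------------------------------------


def simulate_full_experiment(
    exp: str = "1A",
    preset: str = "stage_specific",
    n_subjects: Optional[int] = None,
    n_words: Optional[int] = None,
    seed: int = 0,
    encoding_config: Optional[EncodingGenConfig] = None,
    recognition_config: Optional[RecognitionGenConfig] = None,
) -> tuple[pd.DataFrame, dict]:
    """Complete synthetic experiment (encoding + test) plus its ground truth.

    Experiment presets:

    * ``1A`` — LDT, 6 lists, 84 study words + 84 nonword foils, blur
      reinstated at test (new items rendered at their assigned blur);
    * ``1B`` — as 1A but all test items clear; new items keep their yoked
      blur tag for scoring the three false-alarm rates;
    * ``2``  — semantic categorization, blur x frequency on 90 study
      non-animal words + 45 animal fillers, 432 subjects.
    """
    if exp in ("1A", "1B"):
        spec = DesignSpec(n_words=n_words or 84,
                          n_nonwords_or_fillers=n_words or 84)
        lists = design_mod.build_counterbalanced_lists(spec, seed=seed)
        n_per_list = (n_subjects if n_subjects is not None else 216) // spec.n_lists
        task = "ldt"
        foils = [f"x{i:03d}" for i in range(spec.n_nonwords_or_fillers)]
        enc_cfg = encoding_config or encoding_preset(preset, frequency=False)
        rec_cfg = recognition_config or recognition_preset(exp)
    elif exp == "2":
        n_study = n_words or 90
        lists = design_mod.build_exp2_study_list(
            n_nonanimal_study=n_study, n_animal=max(n_study // 2, 1), seed=seed
        )
        n_per_list = (n_subjects if n_subjects is not None else 432) // len(lists)
        task = "semcat"
        foils = []  # animal fillers live inside the lists
        enc_cfg = encoding_config or encoding_preset(preset, frequency=True)
        rec_cfg = recognition_config or recognition_preset("2")
    else:
        raise KeyError(f"unknown experiment preset {exp!r}")

    subject_map = (
        design_mod.assign_participants(lists, n_per_list) if n_per_list >= 1 else {}
    )
    truth = {
        "exp": exp, "preset": preset, "seed": seed,
        "n_subjects": len(subject_map), "n_lists": len(lists),
        "encoding_params": {
            str(k): vars(v) for k, v in enc_cfg.params.items()
        },
        "error_rate": {str(k): v for k, v in enc_cfg.error_rate.items()},
        "dprime": {str(k): v for k, v in rec_cfg.dprime.items()},
        "criterion": {str(k): v for k, v in rec_cfg.criterion.items()},
        "test_rendering": "clear" if exp == "1B" else "as_assigned",
    }
    if not subject_map:
        return pd.DataFrame(columns=TRIAL_COLUMNS), truth

    enc = simulate_encoding(enc_cfg, lists, subject_map, task=task,
                            foil_items=foils, seed=seed)
    rec = simulate_recognition(rec_cfg, lists, subject_map, task=task,
                               seed=seed + 1)
    trials = pd.concat([enc, rec], ignore_index=True)
    return trials, truth
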