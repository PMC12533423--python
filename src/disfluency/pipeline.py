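"""End-to-end analysis pipeline over one experiment's trial table.

Stages: preprocess (participant exclusions, RT trimming, target-trial
selection) -> encoding analyses (two-stage ex-Gaussian contrasts with
subject-bootstrap summaries; Vincentile quantile / delta profiles with
pattern labels; optionally per-condition DDM fits) -> recognition analyses
(d'/criterion per condition, probit contrast fits) -> tables and figures on
disk.  Reruns with the same config and seed are byte-identical.

Config keys (dict or YAML file): ``experiment`` (1A | 1B | 2), ``preset``,
``n_subjects``, ``seed``, ``trial_file`` (use a file instead of simulating),
``out_dir``, ``fit_ddm`` (bool, default False), ``n_boot``.
"""

from __future__ import annotations

import json
import platform
import zlib
from dataclasses import asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__ as pkg_version
from . import io_preprocess as iop
from .contrasts import (
    BLUR_HIGH_VS_OTHERS,
    BLUR_LOW_VS_CLEAR,
    FREQ_HIGH_VS_LOW,
    ContrastSpec,
)
from .ddm import fit_ddm
from .exgauss import fit_exgauss_distributional
from .inference import bootstrap_contrast_draws, decide_hypothesis, summarize_effect
from .quantiles import (
    classify_delta_pattern,
    delta_profile,
    plot_delta_profile,
    plot_quantile_profile,
    vincentize,
)
from .sdt import dprime_criterion, fit_probit_sdt, tabulate_recognition
from .synthetic import simulate_full_experiment

__all__ = ["run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


#: one-sided direction per (parameter, contrast), following the study's
#: preregistered directional hypotheses; everything else is two-sided
_DIRECTIONS = {
    ("mu", "high_vs_others"): "greater",
    ("mu", "low_vs_clear"): "greater",
    ("log_sigma", "high_vs_others"): "greater",
    ("log_beta", "high_vs_others"): "greater",
    ("mu", "high_vs_low_freq"): "less",
    ("log_beta", "high_vs_low_freq"): "less",
}


def _load_config(config) -> dict:
    if isinstance(config, (str, Path)):
        config = yaml.safe_load(Path(config).read_text())
    if not isinstance(config, Mapping):
        raise PipelineError("config", "config must be a mapping or YAML file path")
    return dict(config)


def run_pipeline(config) -> dict:
    """Run the full analysis; returns the report bundle (also written to disk)."""
    cfg = _load_config(config)
    exp = str(cfg.get("experiment", "1A"))
    seed = int(cfg.get("seed", 0))
    out_dir = Path(cfg.get("out_dir", "results/pipeline"))
    out_dir.mkdir(parents=True, exist_ok=True)
    n_boot = int(cfg.get("n_boot", 16_000))
    task = "semcat" if exp == "2" else "ldt"
    contrasts: list[ContrastSpec] = [BLUR_HIGH_VS_OTHERS, BLUR_LOW_VS_CLEAR]
    if exp == "2":
        contrasts.append(FREQ_HIGH_VS_LOW)

    # ---- stage: data -----------------------------------------------------
    try:
        if cfg.get("trial_file"):
            trials = iop.read_trials(cfg["trial_file"], rt_unit=cfg.get("rt_unit", "s"))
            truth = None
        else:
            trials, truth = simulate_full_experiment(
                exp=exp,
                preset=cfg.get("preset", "stage_specific"),
                n_subjects=cfg.get("n_subjects"),
                n_words=cfg.get("n_words"),
                seed=seed,
            )
        if trials.empty:
            raise ValueError("no trials to analyze")
    except Exception as e:  # noqa: BLE001
        raise PipelineError("data", str(e)) from e

    # ---- stage: preprocess ----------------------------------------------
    try:
        trials, excl_report = iop.exclude_participants(trials)
        encoding = trials[trials["phase"] == "encoding"]
        encoding, trim_report = iop.filter_rts(encoding)
        rt_trials = iop.select_rt_analysis_trials(encoding, task=task)
        test_trials = trials[trials["phase"] == "test"]
    except Exception as e:  # noqa: BLE001
        raise PipelineError("preprocess", str(e)) from e

    excl_report.to_json(out_dir / "exclusion_report.json")
    trim_report.to_json(out_dir / "rt_trim_report.json")

    bundle: dict = {"config": cfg, "ground_truth": truth,
                    "exclusions": excl_report, "rt_trim": trim_report}

    # ---- stage: ex-Gaussian ---------------------------------------------
    try:
        fit = fit_exgauss_distributional(rt_trials, contrasts, mode="two_stage")
        rows = []
        for param in fit.coefficients:
            for spec in contrasts:
                direction = _DIRECTIONS.get((param, spec.name), "two_sided")
                tag = zlib.crc32(f"{param}:{spec.name}".encode()) % 10_000
                draws = bootstrap_contrast_draws(
                    fit.subject_effects, f"{param}:{spec.name}",
                    n_boot=n_boot, seed=seed + tag,
                )
                summ = summarize_effect(draws, direction, parameter=param,
                                        contrast=spec.name)
                row = summ.as_row()
                row.update(asdict(decide_hypothesis(summ)))
                rows.append(row)
        exgauss_table = pd.DataFrame(rows)
    except Exception as e:  # noqa: BLE001
        raise PipelineError("exgauss", str(e)) from e
    exgauss_table.to_csv(out_dir / "exgauss_contrasts.csv", index=False)
    bundle["exgauss"] = {"fit": fit, "table": exgauss_table}

    # ---- stage: quantiles ------------------------------------------------
    try:
        profile = vincentize(rt_trials, condition_col="blur")
        deltas = {}
        patterns = {}
        for spec in (BLUR_HIGH_VS_OTHERS, BLUR_LOW_VS_CLEAR):
            d = delta_profile(profile, spec)
            deltas[spec.name] = d
            patterns[spec.name] = classify_delta_pattern(d)
        profile.quantiles.to_csv(out_dir / "vincentile_quantiles.csv")
        pd.DataFrame(
            {name: d.delta for name, d in deltas.items()}, index=profile.probs
        ).to_csv(out_dir / "delta_profiles.csv")
        (out_dir / "delta_patterns.json").write_text(json.dumps(patterns, indent=2))
    except Exception as e:  # noqa: BLE001
        raise PipelineError("quantiles", str(e)) from e
    bundle["quantiles"] = {"profile": profile, "deltas": deltas, "patterns": patterns}

    # ---- stage: DDM (optional) ------------------------------------------
    if cfg.get("fit_ddm", False):
        try:
            enc_words = encoding[
                encoding["stim_class"].isin(["word", "nonanimal"])
            ]
            ddm_fits = fit_ddm(enc_words, condition_cols=("blur",))
            ddm_table = pd.DataFrame(
                [
                    {"blur": k, **asdict(v["params"]), "loglik": v["loglik"],
                     "status": v["status"], "n": v["n"]}
                    for k, v in ddm_fits.items()
                ]
            )
            ddm_table.to_csv(out_dir / "ddm_fits.csv", index=False)
            bundle["ddm"] = ddm_fits
        except Exception as e:  # noqa: BLE001
            raise PipelineError("ddm", str(e)) from e

    # ---- stage: SDT ------------------------------------------------------
    try:
        cond_cols = ["blur", "frequency"] if exp == "2" else ["blur"]
        counts = tabulate_recognition(test_trials, condition_cols=cond_cols)
        sdt_rows = []
        for cond, cnt in counts.items():
            est = dprime_criterion(cnt)
            sdt_rows.append({
                "condition": str(cond), "hit_rate": est.hit_rate,
                "fa_rate": est.fa_rate, "dprime": est.dprime,
                "criterion": est.criterion, "c_model": est.c_model,
            })
        sdt_table = pd.DataFrame(sdt_rows)
        probit = fit_probit_sdt(
            test_trials, contrasts,
            family="binomial" if exp == "2" else "bernoulli",
        )
        sdt_table.to_csv(out_dir / "sdt_estimates.csv", index=False)
        pd.DataFrame(
            [
                {"contrast": name, "dprime_diff": probit.dprime_effects[name],
                 "neg_c_diff": probit.bias_effects[name]}
                for name in probit.dprime_effects
            ]
        ).to_csv(out_dir / "sdt_contrasts.csv", index=False)
    except Exception as e:  # noqa: BLE001
        raise PipelineError("sdt", str(e)) from e
    bundle["sdt"] = {"counts": counts, "table": sdt_table, "probit": probit}

    # ---- stage: figures --------------------------------------------------
    if cfg.get("figures", True):
        try:
            import matplotlib

            matplotlib.use("Agg")
            import matplotlib.pyplot as plt

            fig, axes = plt.subplots(1, 3, figsize=(12, 3.5))
            plot_quantile_profile(profile, ax=axes[0], title="Vincentile quantiles")
            plot_delta_profile(deltas["high_vs_others"], ax=axes[1],
                               title="high vs. clear/low")
            plot_delta_profile(deltas["low_vs_clear"], ax=axes[2],
                               title="low vs. clear")
            fig.tight_layout()
            fig.savefig(out_dir / "quantile_delta.png", dpi=120)
            plt.close(fig)

            fig, ax = plt.subplots(figsize=(5, 3.5))
            ax.bar(sdt_table["condition"], sdt_table["dprime"], color="C0")
            ax.set_ylabel("d'")
            ax.set_title("recognition sensitivity")
            ax.tick_params(axis="x", rotation=45)
            fig.tight_layout()
            fig.savefig(out_dir / "sdt_dprime.png", dpi=120)
            plt.close(fig)
        except Exception as e:  # noqa: BLE001
            raise PipelineError("figures", str(e)) from e

    meta = {
        "seed": seed,
        "experiment": exp,
        "package_version": pkg_version,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "python": platform.python_version(),
    }
    (out_dir / "run_meta.json").write_text(json.dumps(meta, indent=2))
    bundle["meta"] = meta
    return bundle
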