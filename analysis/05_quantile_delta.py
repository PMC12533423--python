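"""Vincentile quantile profiles, delta plots, and pattern classification.

Builds the group RT quantile profile per blur condition (.1/.3/.5/.7/.9),
takes quantile-wise contrasts (high vs. clear+low average; low vs. clear),
classifies each delta profile into the four canonical patterns, and writes
the figure panels.
"""

import json
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from disfluency.contrasts import BLUR_HIGH_VS_OTHERS, BLUR_LOW_VS_CLEAR
from disfluency.io_preprocess import read_trials
from disfluency.quantiles import (
    classify_delta_pattern,
    delta_profile,
    plot_delta_profile,
    plot_quantile_profile,
    vincentize,
)

DATA = Path("results/preprocessed")
OUT = Path("results/quantiles")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    for exp in ("1A", "1B", "2"):
        rt_trials = read_trials(DATA / f"exp{exp}_rt_trials.csv")
        profile = vincentize(rt_trials, condition_col="blur")
        profile.quantiles.to_csv(OUT / f"exp{exp}_quantiles.csv")

        deltas, patterns = {}, {}
        for spec in (BLUR_HIGH_VS_OTHERS, BLUR_LOW_VS_CLEAR):
            d = delta_profile(profile, spec)
            deltas[spec.name] = d
            patterns[spec.name] = classify_delta_pattern(d)
        pd.DataFrame(
            {name: d.delta for name, d in deltas.items()}, index=profile.probs
        ).to_csv(OUT / f"exp{exp}_delta.csv")
        (OUT / f"exp{exp}_patterns.json").write_text(json.dumps(patterns, indent=2))

        fig, axes = plt.subplots(1, 3, figsize=(12, 3.5))
        plot_quantile_profile(profile, ax=axes[0], title=f"Exp {exp} quantiles")
        plot_delta_profile(deltas["high_vs_others"], ax=axes[1],
                           title="high vs. clear/low")
        plot_delta_profile(deltas["low_vs_clear"], ax=axes[2], title="low vs. clear")
        fig.tight_layout()
        fig.savefig(OUT / f"exp{exp}_quantile_delta.png", dpi=120)
        plt.close(fig)

        print(f"Experiment {exp} delta patterns: {patterns}")
        ms = {k: (1000 * v.delta).round(1).tolist() for k, v in deltas.items()}
        print(f"  quantile effects (ms): {ms}")
    print(f"\nProfiles, deltas and figures under {OUT}/")


if __name__ == "__main__":
    main()
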