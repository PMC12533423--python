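"""Signal-detection analysis of the old/new recognition tests.

Per-condition hit / false-alarm rates, d' and criterion, and the probit
regression whose status x contrast interactions estimate d' differences
(Bernoulli family for Experiments 1A/1B, aggregated binomial for
Experiment 2, mirroring its factorial size).
"""

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from disfluency.contrasts import (
    BLUR_HIGH_VS_OTHERS,
    BLUR_LOW_VS_CLEAR,
    FREQ_HIGH_VS_LOW,
)
from disfluency.io_preprocess import read_trials
from disfluency.sdt import dprime_criterion, fit_probit_sdt, tabulate_recognition

DATA = Path("results/preprocessed")
OUT = Path("results/sdt")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    for exp in ("1A", "1B", "2"):
        test = read_trials(DATA / f"exp{exp}_test_trials.csv")
        cond_cols = ["blur", "frequency"] if exp == "2" else ["blur"]
        contrasts = [BLUR_HIGH_VS_OTHERS, BLUR_LOW_VS_CLEAR]
        family = "bernoulli"
        if exp == "2":
            contrasts.append(FREQ_HIGH_VS_LOW)
            family = "binomial"

        counts = tabulate_recognition(test, condition_cols=cond_cols)
        rows = []
        for cond, cnt in counts.items():
            est = dprime_criterion(cnt)
            rows.append({"condition": str(cond), "hit_rate": round(est.hit_rate, 3),
                         "fa_rate": round(est.fa_rate, 3),
                         "dprime": round(est.dprime, 3),
                         "criterion": round(est.criterion, 3)})
        table = pd.DataFrame(rows)
        table.to_csv(OUT / f"exp{exp}_sdt.csv", index=False)

        probit = fit_probit_sdt(test, contrasts, family=family)
        eff = pd.DataFrame([
            {"contrast": name,
             "dprime_diff": round(probit.dprime_effects[name], 3),
             "neg_c_diff": round(probit.bias_effects[name], 3)}
            for name in probit.dprime_effects
        ])
        eff.to_csv(OUT / f"exp{exp}_sdt_contrasts.csv", index=False)

        print(f"\nExperiment {exp} recognition:")
        print(table.to_string(index=False))
        print(eff.to_string(index=False))

        fig, ax = plt.subplots(figsize=(5.5, 3.5))
        ax.bar(table["condition"], table["dprime"], color="C0")
        ax.set_ylabel("d'")
        ax.set_title(f"Experiment {exp} sensitivity")
        ax.tick_params(axis="x", rotation=45)
        fig.tight_layout()
        fig.savefig(OUT / f"exp{exp}_dprime.png", dpi=120)
        plt.close(fig)
    print(f"\nSDT tables and figures under {OUT}/")


if __name__ == "__main__":
    main()
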