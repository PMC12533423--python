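"""Simulate the three blur x frequency experiments and write their trial tables.

Generates Experiment 1A (LDT, blur reinstated at test), 1B (LDT, clear test
items with yoked false-alarm sets), and 2 (semantic categorization with the
word-frequency factor) from the stage_specific generative scenario, and
stores trials plus ground truth under results/data/.
"""

import json
import sys
from pathlib import Path

from disfluency.io_preprocess import write_trials
from disfluency.synthetic import simulate_full_experiment

OUT = Path("results/data")
SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 0


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    for offset, exp in enumerate(("1A", "1B", "2")):
        trials, truth = simulate_full_experiment(exp, preset="stage_specific",
                                                 seed=SEED + offset)
        write_trials(trials, OUT / f"exp{exp}_trials.csv")
        (OUT / f"exp{exp}_truth.json").write_text(json.dumps(truth, indent=2))
        enc = trials[trials["phase"] == "encoding"]
        print(
            f"Experiment {exp}: {truth['n_subjects']} subjects, "
            f"{len(trials):,} trials ({len(enc):,} encoding), "
            f"{truth['n_lists']} lists"
        )
    print(f"\nTrial tables and ground truth written to {OUT}/")


if __name__ == "__main__":
    main()
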