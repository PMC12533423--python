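"""Apply the standard exclusion and trimming rules to the simulated experiments.

Participant exclusions (encoding accuracy < 80%) come first, then RT trimming
to [0.2 s, 2.5 s]; the correct-target-trial subsets used by the RT analyses
are written alongside auditable exclusion reports.
"""

from pathlib import Path

from disfluency.io_preprocess import (
    exclude_participants,
    filter_rts,
    read_trials,
    select_rt_analysis_trials,
    write_trials,
)

DATA = Path("results/data")
OUT = Path("results/preprocessed")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    for exp, task in (("1A", "ldt"), ("1B", "ldt"), ("2", "semcat")):
        trials = read_trials(DATA / f"exp{exp}_trials.csv")
        trials, excl = exclude_participants(trials)
        enc = trials[trials["phase"] == "encoding"]
        enc, trim = filter_rts(enc)
        rt_trials = select_rt_analysis_trials(enc, task=task)
        test = trials[trials["phase"] == "test"]

        write_trials(rt_trials, OUT / f"exp{exp}_rt_trials.csv")
        write_trials(test, OUT / f"exp{exp}_test_trials.csv")
        excl.to_json(OUT / f"exp{exp}_exclusions.json")
        trim.to_json(OUT / f"exp{exp}_rt_trim.json")
        print(f"Experiment {exp}:")
        for line in trim.log_lines():
            print(f"  {line}")
        print(f"  RT-analysis trials (correct targets): {len(rt_trials):,}")
    print(f"\nPreprocessed tables under {OUT}/")


if __name__ == "__main__":
    main()
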