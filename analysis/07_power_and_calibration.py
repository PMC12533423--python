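"""Design power and interval calibration.

Computes the exact noncentral-t power behind the preregistered sample sizes
and the empirical null coverage of the bootstrap credible intervals.
"""

import json
from pathlib import Path

from disfluency.inference import PowerSpec, power_one_sample
from disfluency.studies import bootstrap_coverage_study

OUT = Path("results/inference")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    power_216 = power_one_sample(PowerSpec(n=216, delta=0.20, alpha=0.05, sided="one"))
    power_432 = power_one_sample(PowerSpec(n=432, delta=0.20, alpha=0.05, sided="one"))
    coverage = bootstrap_coverage_study(n_sims=400, base_seed=0)
    out = {
        "power_n216_delta020_onesided": round(power_216, 4),
        "power_n432_delta020_onesided": round(power_432, 4),
        "null_coverage_95pct_interval": coverage,
    }
    (OUT / "power_calibration.json").write_text(json.dumps(out, indent=2))
    print(f"Power at n=216, delta=0.20, one-sided alpha=.05: {power_216:.3f}")
    print(f"Power at n=432 (doubled design):                 {power_432:.3f}")
    print(f"Null 95% interval coverage (400 sims):           {coverage:.3f}")
    print(f"\nWritten to {OUT}/power_calibration.json")


if __name__ == "__main__":
    main()
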