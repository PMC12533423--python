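# disfluency

Distributional response-time and recognition-memory analysis of **perceptual
disfluency** experiments — paradigms in which words are studied under graded
visual degradation (clear / low-blur / high-blur, optionally crossed with word
frequency) and memory is probed with a surprise old/new recognition test.

Mean RTs hide *where* in the RT distribution a manipulation acts. This package
implements the distributional toolkit used to localize blur effects during
encoding, together with a synthetic-experiment generator that reproduces the
counterbalanced structure of such studies with known ground truth:

- **Ex-Gaussian decomposition.** RTs are modelled as Gaussian(μ, σ) +
  Exponential(mean τ): the overall mean is μ + τ and the SD is √(σ² + τ²).
  μ indexes a shift of the whole distribution (early processes), τ the slow
  tail (late processes). Condition effects are estimated with an identity link
  on μ and log links on σ and τ, via per-subject ML fits aggregated across
  subjects (two-stage) or a pooled contrast-coded ML fit.
- **Wiener diffusion decomposition.** A four-parameter first-passage model
  (drift *v*, boundary *a*, start point *z* = 0.5, non-decision time *Ter*)
  with the classical small-time/large-time series density, an Euler simulator,
  EZ-style closed-form initialization, and per-condition ML fitting.
- **Vincentile quantile and delta plots.** Per-subject quantiles
  (.1/.3/.5/.7/.9) averaged across subjects; quantile-wise condition
  differences classified into the four canonical patterns (no difference /
  complete shift / late differences / early differences).
- **Signal detection for recognition.** d′ = z(H) − z(F),
  c = −(z(H) + z(F))/2, and the equivalent probit regression in which the
  status × condition interaction is a d′ difference and condition main
  effects are −c differences.
- **Inference.** Subject-resampling bootstrap (16,000 t-calibrated draws) with
  90% credible intervals for directional hypotheses and 95% for two-sided
  ones, directional posterior probabilities, evidence ratios ER = p/(1 − p)
  (ER > 3 moderate-to-strong support, ER < 0.3 support for the alternative),
  and exact noncentral-t power.

## Worked example

Simulate a full 216-subject lexical-decision experiment under the
*stage-specific* scenario (high blur shifts **and** skews the RT
distribution; low blur only shifts it), preprocess it with the standard
rules (accuracy < 80% exclusions, RTs trimmed to [0.2 s, 2.5 s], correct
word trials only), and test the tail-inflation hypothesis:

```python
from disfluency import (simulate_full_experiment, filter_rts,
                        select_rt_analysis_trials, fit_exgauss_distributional,
                        bootstrap_contrast_draws, summarize_effect,
                        decide_hypothesis)
from disfluency.contrasts import BLUR_HIGH_VS_OTHERS, BLUR_LOW_VS_CLEAR

trials, truth = simulate_full_experiment("1A", preset="stage_specific", seed=5)
encoding, trim = filter_rts(trials[trials["phase"] == "encoding"])
rt_trials = select_rt_analysis_trials(encoding, task="ldt")

fit = fit_exgauss_distributional(rt_trials, [BLUR_HIGH_VS_OTHERS, BLUR_LOW_VS_CLEAR])
draws = bootstrap_contrast_draws(fit.subject_effects,
                                 "log_beta:high_vs_others", seed=5)
summary = summarize_effect(draws, direction="greater",
                           parameter="log_beta", contrast="high_vs_others")
decision = decide_hypothesis(summary)
```

Output:

```
trials analysed: 16,928 (0.2% RT-trimmed)
mu shift, high vs clear/low:   +0.121 s
log-tau shift, high vs others: +0.353 [0.272, 0.431] 90% CrI
posterior prob = 1.000, ER = Inf, supported = True
```

The μ contrast recovers the injected 0.107 s shift of high-blur words against
the clear/low average, and the log-τ contrast recovers the injected tail
inflation (0.43 on the log scale, attenuated by the 2.5-s trim) with an
interval excluding zero, a directional posterior probability of 1, and an
infinite evidence ratio — the conjunction required to call the hypothesis
supported.

## Analysis pipeline

The numbered scripts under `analysis/` run the whole study on synthetic data
and write tables and figures under `results/`:

```bash
python analysis/01_simulate_experiments.py   # Exp 1A / 1B / 2 trial tables
python analysis/02_preprocess.py             # exclusions + RT trimming
python analysis/03_fit_exgauss.py            # distributional contrast tables
python analysis/04_fit_ddm.py                # Wiener fits + ordering recovery
python analysis/05_quantile_delta.py         # Vincentile / delta profiles
python analysis/06_recognition_sdt.py        # d', criterion, probit contrasts
python analysis/07_power_and_calibration.py  # power + interval calibration
```

`disfluency.pipeline.run_pipeline(config)` runs the same stages end-to-end
from a single YAML/dict config.

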