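# Methods

This note documents the models, the generative scenarios, the numerical
choices, and the known limitations of the `disfluency` package.

## The analysis problem

Perceptual-disfluency studies degrade words at encoding (here: three blur
levels, optionally crossed with two word-frequency levels) and test memory
with a surprise old/new recognition task. The scientific question is *where*
in processing the degradation acts: a manipulation that shifts the whole RT
distribution implicates early/lexical stages, one that stretches its slow
tail implicates late/post-lexical stages, and recognition sensitivity (d′)
says whether the extra processing paid off mnemonically. The package
implements the four complementary analyses used for this localization —
ex-Gaussian decomposition, Wiener-diffusion decomposition, Vincentile
quantile/delta profiling, and probit-based signal detection — on top of a
counterbalanced-design generator with known ground truth.

## Design and preprocessing

The Experiment-1 scheme counterbalances a pool of 2 × 84 words over the six
(status × blur) cells by a Latin square on item blocks: each list holds 28
items per study blur cell and, across the six lists, every word serves in
every cell exactly once. The Experiment-2 scheme applies the same rotation
within each word-frequency stratum of 2 × 90 non-animal words and appends 45
animal filler words (study-only, excluded from every analysis, preserving the
2:1 non-animal:animal study ratio). Participants are allocated in equal
numbers per list (36 for the Experiment-1 designs, 72 for the doubled
Experiment-2 design). The rotation mechanics (block shuffle keyed by the
seed, cell order fixed) are this package's choice; only the balance
constraints are externally given.

Preprocessing order: participant exclusions first (repeat and underage IDs,
then overall encoding accuracy strictly below 0.80, computed on all encoding
trials before any trimming), RT trimming second. Trimming keeps the closed
interval [0.2 s, 2.5 s]: removal is defined by strict inequalities, so
boundary values survive. RT analyses then keep correct trials on target items
only (words for lexical decision, non-animal words for semantic
categorization). All counts are recorded in machine-readable exclusion
reports, and the operations are idempotent and order-preserving.

## Synthetic experiments

The generator is the package's definition of the study conditions, not a
tuning knob. Encoding RTs are drawn per (subject, item) from either an
ex-Gaussian or a Wiener process whose parameters vary by condition; Gaussian
random intercepts act on each parameter's link scale — identity for μ (SD
0.05 s subjects, 0.02 s items) and log for σ and τ (SD 0.15, subjects only).
Errors in the ex-Gaussian generator are independent lapses with
condition-specific rates (clear .03, low .04, high .12, chosen to mirror the
observed accuracy drop under heavy blur); the diffusion generator produces
errors mechanistically via the lower boundary. Generated RTs are not
truncated, so the downstream trim's attenuation of τ is itself visible to
tests.

Three presets encode the candidate accounts of the disfluency effect as
arrow patterns on (μ, σ, τ):

- `metacognitive`: τ up (+0.30 log units) for both blur levels, μ flat;
- `compensatory`: μ up (+0.107 s) for high blur only;
- `stage_specific` (default): high blur raises μ (+0.115 s over clear, so
  +0.107 s against the clear/low average), log σ (+0.16) and log τ (+0.43);
  low blur raises μ by +0.016 s only.

The `stage_specific` magnitudes are the package's reference effect sizes for
recovery studies; the base clear-condition parameters (μ = 0.54 s,
σ = 0.08 s, τ = 0.22 s) are typical of online lexical decision. The
Experiment-2 variant adds a low-frequency penalty (+0.018 s on μ, +0.065 on
log τ) within every blur level.

Recognition responses come from equal-variance Gaussian SDT: with status
coded s = +½ (old) / −½ (new), P("old") = Φ(d′·s − c), i.e. P(hit) =
Φ(d′/2 − c), P(false alarm) = Φ(−d′/2 − c). The regression-facing bias
parameter is −c; plots and tables report conventional c (positive =
conservative). Per-condition d′ defaults place the high-blur advantage at
+0.131 (Experiment 1A) / +0.100 (1B) over a base d′ of 1.0, and
Experiment 2 adds a low-frequency advantage of ≈0.27 with a selective
high-frequency × blur benefit. Subject random effects (SD 0.25) perturb d′
and c.

What the generator does **not** emulate: real item heterogeneity beyond
Gaussian intercepts, sequential effects, speed–accuracy trade-offs, fast
guesses and other contaminants, or any dependence of recognition on encoding
RT within subject. Passing recovery tests therefore show that the estimators
work under the assumed data-generating process, not that real data satisfy
that process.

## Ex-Gaussian estimation

The log-density is evaluated entirely in log space,
`logpdf(x) = −log τ + (μ − x)/τ + σ²/(2τ²) + log Φ((x − μ)/σ − σ/τ)`,
with the normal log-CDF from `scipy.special.log_ndtr`; this is stable for
small σ and small τ, and the CDF uses the matching stable form. ML fits
optimize (μ, log σ, log τ) by Nelder–Mead (BFGS polish on non-convergence)
from method-of-moments starts (τ₀ from the third central moment, capped
inside (0.05, 0.95) of the sample SD). A soft quadratic penalty keeps
log σ within [log 5 ms, log 2 s] and log τ within [log 5 ms, log 5 s]: the
EMG likelihood is degenerate as σ → 0, and sub-5-ms Gaussian spread is not a
credible RT process.

Condition effects use the two-stage estimator by default: per-subject,
per-condition ML fits, then each contrast evaluated on the subject-level
parameters (σ and τ on the log scale), averaged across subjects. Cells with
fewer than 10 trials, and subjects whose τ collapses onto its lower bound
(a degenerate near-Gaussian solution whose extreme log value would dominate
the average), are dropped with a log entry — at 28 trials per cell this
removes roughly 5% of subjects, at Experiment 2's 15 trials per cell closer
to a third, which is the main cost of the small-cell design. The pooled
alternative is a joint ML fit with contrast-coded linear predictors on each
link scale; the two agree in sign and approximate magnitude on well-powered
synthetic data but are not numerically identical to a hierarchical
random-effects model.

Contrast conventions: high-vs-others is stored with its conventional printed
weights (+0.5 / −0.5 / −0.5, not zero-sum); used as regression codes the
coefficient equals θ_high − mean(θ_clear, θ_low) because the coded groups sit
one unit apart, and the two-stage path computes exactly that quantity
(mean of positive-weight levels minus mean of negative-weight levels). A
zero-sum `centered` variant exists and is non-default.

## Wiener diffusion

The first-passage density uses the two classical series in normalized time
t′ = t/a², switching pointwise to whichever expansion needs fewer terms for
an absolute tolerance of 1e−8; the drift/start-point factor
exp(−v·a·w − v²t/2)/a² multiplies the zero-drift kernel. Densities are
defective: each boundary's integral equals the closed-form absorption
probability (1 − e^(−2vza))/(1 − e^(−2va)) and the two sum to one — both
facts are asserted by quadrature in tests. The simulator is Euler–Maruyama
with unit diffusion (default dt = 1 ms; recovery studies use 0.5 ms or
finer), whose √dt boundary-overshoot bias is visible only below the test
tolerances at those step sizes.

Fitting is per-condition ML over (v, log a, logit-scaled Ter bounded by the
condition's fastest RT), accuracy-coded (correct = upper boundary), z fixed
at 0.5, initialized from the EZ closed-form moments solution (unit-diffusion
scaling). No inter-trial variability parameters are modelled. Fewer than 40
trials or a single response category downgrade the fit status.

## Quantiles and patterns

Vincentization computes per-subject, per-condition quantiles at
(.1, .3, .5, .7, .9) by linear interpolation of order statistics (the
"type 7" estimator — recorded in profile metadata; the choice is this
package's, as only the averaging procedure is externally specified) and
averages them across subjects; subjects lacking enough trials in any
condition are dropped from all conditions to keep the average balanced.
Delta profiles subtract the (possibly composite, equally weighted) reference
conditions' quantiles from the target condition's, preserving the contrast's
sign.

The four-way classifier uses two thresholds, both configurable: a magnitude
floor ε = 10 ms below which a quantile difference counts as zero, and a
flatness tolerance of 5 ms per quantile step on the least-squares slope.
Rules in order: all |δ| < ε → *no difference*; slope beyond ±tolerance →
*late* / *early differences*; all |δ| ≥ ε with a flat slope → *complete
shift*; mixed residual cases go to the side holding the largest differences.
The canonical patterns are qualitative; under the defaults a representative
clear-condition word-frequency profile (12.10–25.06 ms across quantiles,
≈3 ms/step slope) is labelled a complete shift with a mild late lean, and the
thresholds scale with the data's time unit.

## Signal detection

d′ and c come from the inverse-normal identities with a log-linear 0/1-rate
correction (add 0.5 to each cell, 1 to each denominator; recorded in the
output). The probit regression (statsmodels GLM, Binomial/probit) codes
status ±½ so that its status coefficient is exactly d′ and its intercept is
−c on aggregated two-cell data — an identity asserted numerically to 1e−8.
Bernoulli (trial-level) and aggregated binomial modes give identical point
estimates without random effects; the binomial mode is the default for the
larger factorial design, with log-linear smoothing and a flag under complete
separation. Subject-level random effects are outside the default path.

## Inference

Uncertainty comes from case-resampling bootstrap over subjects (default
16,000 draws). Raw percentile intervals of a bootstrapped mean behave like
z-intervals and undercover at small n, so draws are rescaled around their
mean by t_{n−1,.975}/z_{.975} · √(n/(n−1)) (Hesterberg's expanded-percentile
calibration); a 400-replicate null study keeps the nominal 95% interval's
empirical coverage inside 93–97%. Summaries report the mean, the draw SD as
SE, an equal-tailed interval — 90% for directional hypotheses, 95% for
two-sided — the directional posterior probability p, and the evidence ratio
ER = p/(1 − p), serialized as "Inf" when every draw agrees. A directional
hypothesis is *supported* only when the interval excludes zero, p ≥ 0.95,
and ER > 3; ER < 0.3 is support for the alternative, the band between is
inconclusive. Point-null evidence ratios (Savage–Dickey style) require a
prior and are deliberately out of scope. No multiplicity correction is
applied; hypotheses are evaluated individually.

Power for the one-sample designs is exact noncentral-t: at n = 216,
δ = 0.20, one-sided α = 0.05 the power is 0.901.

## Problem sizes in the evaluation suites

The recovery study runs 20 seeds of the full 216-subject Experiment-1A
pipeline (28 trials per subject × blur cell) — large enough that the signs of
the injected μ-shift and τ-inflation, and the null τ contrast's interval
coverage, are recovered in ≥95% of seeds. The diffusion ordering study uses
3,000 pooled trials per condition (the Experiment-1 correct-trial scale,
pooled rather than hierarchical) over 10 seeds; the calibration study uses
400 null replicates of 50 subjects. These sizes are the package's choices
for stable, repeatable evaluation.

## Known limitations

- The two-stage estimator is not the hierarchical maximal-random-effects
  model; it attenuates τ effects (trimming plus small-cell bias) and discards
  degenerate-fit subjects, heavily so at 15 trials per cell.
- σ is weakly identified at small cell sizes; its contrasts carry wide
  intervals and should be read qualitatively.
- The Wiener fit assumes no inter-trial parameter variability and a fixed
  unbiased start point; it is a per-condition pooled fit, not hierarchical.
- Delta-plot pattern labels depend on the ε and slope thresholds near their
  boundaries; borderline profiles should be inspected, not just labelled.
- Bootstrap intervals are frequentist stand-ins for posterior summaries; the
  "evidence ratio" is posterior odds only under a flat-prior reading.
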