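# Methods

`cycleattention` analyses cyclist attention from wearable eye-tracking
data. It covers the full measurement-and-modelling chain: reduction of
labelled gaze-sample streams to per-trial indicators, a PCA composite
attention score cut into three ordered levels, a flat cumulative-logit
model, a hierarchical ordered logistic model with cyclist-specific
random thresholds, and the evaluation of both. A synthetic-data module
generates study-shaped data under known parameters so every stage is
testable end to end.

## The ordinal models

Attention level `F ∈ {1 Distracted, 2 Scattered, 3 Focused}` is modelled
through a continuous latent variable with cut points. The flat
(proportional-odds) model is

    logit P(F_ij ≤ k) = γ_k − θ_ij,     θ_ij = Σ_p β_p x_pij,

with `γ_1 < γ_2` and dummy-coded predictors: riding style (aggressive is
the reference, so the conservative dummy is estimated) and traffic
density (dense is the reference; sparse and moderate estimated). Under
this sign convention a positive `β` moves mass toward higher levels and
`exp(β)` is the odds ratio of *more focused* attention, which is how the
odds-ratio report reads (conservative riders and sparse traffic both
raise the odds of staying attentive).

The hierarchical model keeps `θ_ij` but lets the thresholds differ per
cyclist `j` and trial:

    γ_kj = γ_k + Σ_q α_q z_qij + B_j,    B_j ~ Normal(0, 1/τ),

with `z = (lane-fixation share, pupil-diameter CV)`. Both cut points
shift by the same amount, so the spacing `γ_2j − γ_1j` is a common-shift
invariant (asserted in tests on every draw). A common shift `Σ α_q z_q`
is observationally equivalent to subtracting it from `θ`; we keep the
thresholds-side parameterization and verify the likelihood equality of
both formulations on random inputs rather than pretending the two are
separately identified.

### Flat-model estimation

Maximum likelihood via BFGS with an analytic score, on the
order-preserving parameterization `γ_2 = γ_1 + exp(δ)`. Convergence:
gradient ∞-norm below 1e-8 (with a 1e-5 fallback check), at most 100
iterations; non-convergence is surfaced with the gradient norm, which is
the usual symptom of separation. The covariance is the inverse observed
information, obtained by numerical differentiation in the natural
`(γ, β)` space at the optimum. The fit is cross-checked in the test
suite against an independent ordinal-model implementation
(statsmodels), against the closed-form 2×2 odds ratio in the binary
reduction, and against a 0.01-step brute-force likelihood grid at n=12.
Wald statistics are `(est/se)²` against χ²(1) and 95% intervals use
±1.96·se.

### Hierarchical estimation

The precision prior `τ ~ Gamma(0.01, 0.01)` and vague `Normal(0, 10³)`
priors on `γ, β, α` make the model a standard BUGS-style hierarchical
ordinal regression, estimated by Metropolis-within-Gibbs:

* scalar random-walk Metropolis for `γ_1, γ_2` (proposals violating the
  order are rejected as outside the support), each `β_p` and each `α_q`;
* a vector proposal for `B` with per-cyclist acceptance (the likelihood
  factorizes over cyclists given the rest);
* **translation moves** along the weakly identified ridges: propose
  `B → B + δ, γ → γ − δ` (exactly likelihood-invariant, judged on the
  priors alone) and `α_q → α_q + δ, γ → γ − δ·z̄_q` (and the analogue
  for each `β_p`), so the sampler can slide along the
  `γ + α·z̄ + B̄` ridge instead of diffusing across it. Without these
  moves the chains mix poorly in `γ` and `α` and interval coverage
  degrades;
* conjugate Gibbs for the precision:
  `τ | B ~ Gamma(0.01 + J/2, 0.01 + ΣB_j²/2)` (checked against the
  analytic posterior by KS test).

Step sizes adapt toward a 0.35 acceptance rate (the middle of the
0.25–0.45 band) in 50-iteration windows during warmup only, so the
retained chain is a fixed Markov kernel. Defaults are 4 chains of 5,000
warmup + 5,000 retained iterations; tests and the acceptance script use
1–2 chains of 1,000 warmup + 1,500 draws, which suffices at the sizes
they simulate (a few hundred trials) — judged by split-chain R-hat
< 1.1 and the calibration study below. Category log-probabilities are
computed on the cumulative scale with `log_expit` and a log-diff-exp
for the middle category, so tail trials contribute −∞ (rejection)
rather than NaN.

Reports use posterior means with posterior SDs, plus `(mean/SD)²`
Wald-style statistics for layout parity with the flat model's table;
these are descriptive, not frequentist tests. Out-of-sample cyclists
get `B_j = 0` (the prior mean) with a warning; all shipped evaluations
are in-sample plug-in predictions at the posterior means, matching how
the accuracy cross-tables are defined.

**Calibration.** The acceptance suite re-simulates 20 datasets (30
cyclists × 12 trials) from known parameters and requires ≥ 90% of the
160 parameter/replicate 95%-interval checks to cover the truth; it also
checks that with `α = 0` and near-degenerate `τ` the posterior means of
`β` collapse onto the flat MLE within 3 Monte-Carlo SEs.

## Gaze metrics

Streams are tables of 50 Hz device samples already labelled
fixation/saccade/blink/other with an AOI tag (lane/left/right/none) on
fixations; no event detection from raw coordinates is attempted.
Numerical rules that needed pinning down:

* each sample owns the interval to the next sample; the last sample
  owns the median inter-sample gap (on an even-rate stream this is
  exact sample counting). Time percentages are event-labelled duration
  over total duration, blink frequency counts contiguous blink runs per
  minute, and mean event durations average run lengths;
* the lane-fixation share divides lane-AOI fixation time by *total*
  fixation time, including fixations outside any named AOI;
* pupil statistics use present (non-blink) samples only; the pupil CV is
  SD/mean with the population (n) denominator by default, configurable
  to n−1. An all-blink stream yields NaN pupil statistics rather than
  an error; an empty stream is an error.

## Attention scoring

PCA runs on the correlation matrix (the indicators mix proportions,
counts/min, milliseconds and millimetres, so covariance PCA would be
unit-dependent). Components with eigenvalue > 1 are retained — if none
passes, the leading component is kept — and combined with
eigenvalue-proportional weights. Each component's sign is oriented to
correlate positively with the fixation-time percentage so that a higher
composite always reads "more focused". The composite is cut into three
equal-frequency tertiles (sizes as equal as integer division allows,
remainder to the lowest level; boundary ties are split by stable input
order with a warning). Equal-frequency cuts, the eigenvalue rule and the
seven-indicator default set are configuration, not facts about any
particular dataset; fixed-value cuts can be re-applied via the stored
cut points. The region-resolved "fixation time distribution" indicator
is operationalized as the lane-fixation share. Factor screening is
classical one-way ANOVA on the composite.

## Synthetic data generator

The generator emulates the study design it is meant to exercise: 9
cyclists × 3 sections (104 m/7.9%, 90 m/4.4%, 120 m/0% grade) × 2
directions × 2 periods = 108 cells, with uniform random attrition at
rate 11/108 (≈ 97 survivors on average). Traffic density is tied to the
period (peak→dense, offpeak→sparse) with a configurable fraction of
cells relabelled moderate — 0.25 by default so all three printed levels
occur; the per-level trial counts of the original study are unknown, so
this fraction is exposed as a parameter. Riding style follows the speed
rule: a trial speed strictly above the grand mean speed is aggressive.

Defaults for the generating parameters: `γ = (0.1, 1.5)`,
`β = (conservative 1.2, sparse 2.0, moderate 0.9)`,
`α = (lane share 3.0, pupil CV −9.5)`, `τ = 4` (cyclist SD 0.5); lane
share ~ Beta(mean 0.60, concentration 20), pupil CV ~ Normal(0.10,
0.03) truncated at 0, speeds ~ Normal(4.2, 0.8) between cyclists with
0.3 within. The β values sit near the published report's coefficient
magnitudes and the α signs match its direction of effect; the absolute
threshold/covariate scales are chosen to be self-consistent with
realistic covariate ranges and to yield a near-balanced three-level
outcome, since published table scales cannot be reconciled with
plausible covariate units without the raw data. Indicator columns
(fixation %, blink rate, pupil stats, ...) are drawn with means shifted
by the drawn attention level so the PCA stage sees realistic, noisy
inputs whose scored levels agree with the generating levels ~75–80% of
the time.

Gaze streams are synthesized from per-trial targets as interleaved
event runs whose sample counts match the targeted shares to within one
sample; pupil draws are affinely rescaled to hit the target mean/SD
exactly. The round trip through the metric extraction therefore
recovers targets essentially exactly (the 2% test tolerance absorbs
rounding at short durations).

What the generator does *not* emulate: road-geometry effects on
attention (slope is generated as a null factor), serial correlation
within a ride, drift or measurement error in the eye tracker, and any
dependence of attrition on conditions (loss is uniform). Passing tests
therefore demonstrate correctness of the estimators under the assumed
model, not robustness to those real-data features.

## Known limitations

* The hierarchical sampler is a random-walk scheme; for much larger
  designs (thousands of trials) a gradient-based sampler would mix
  faster.
* In-sample accuracy comparisons at the study's size (9 cyclists, ~97
  trials) are noisy; the hierarchical model's advantage is reliable in
  expectation but not in every single replicate.
* Published coefficient tables cannot be reproduced without the
  deposited raw data; the package validates its estimators by
  simulation and closed forms instead, and reproduces exactly the
  quantities that are pure arithmetic on printed values (accuracies,
  odds ratios, confidence intervals).
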