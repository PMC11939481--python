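# cycleattention

Analysis pipeline for cyclist attention on campus roads, measured by
wearable eye tracking. The package takes labelled gaze-sample streams
(or pre-aggregated trial tables), derives per-trial attention
indicators, reduces them to a composite attention score with three
ordered levels, and asks which riding conditions move attention — using
two competing ordinal models:

* a standard **cumulative-logit** (proportional-odds) model,
  `logit P(F ≤ k) = γ_k − θ`, `θ = Σ β_p x_p`, with riding style and
  traffic density as dummy-coded predictors; and
* a **hierarchical ordered logistic** model in which each cyclist `j`
  has their own thresholds,

      γ_kj = γ_k + Σ_q α_q z_qj + B_j,   B_j ~ Normal(0, 1/τ),

  shifted by two eye-movement covariates (lane-fixation share and the
  pupil-diameter coefficient of variation `P = σ/d̄`) and a zero-mean
  cyclist random effect with `τ ~ Gamma(0.01, 0.01)`.

The flat model is fit by maximum likelihood (Wald tests, 95% CIs, odds
ratios); the hierarchical model by Metropolis-within-Gibbs MCMC with a
conjugate update for `τ`. Both are compared on observed-vs-predicted
cross tables, and odds ratios can be re-expressed against any reference
level by the exact contrast identity. A synthetic-data module
reproduces the study design (9 cyclists × 3 sections × 2 directions ×
2 periods = 108 trials, ~10% attrition) under known parameters, so the
whole chain is testable without any external data. It is aimed at
traffic-behaviour and human-factors researchers working in Python.

## Worked example

```python
from cycleattention import (DesignSpec, TrueParams, accuracy, cross_table,
                            fit_hier_mcmc, fit_ordered_logit, generate_design,
                            predict_category_hier, simulate_trials)
from cycleattention.ologit import predict_trials

spec = DesignSpec()                       # the 108-cell study layout
trials = simulate_trials(generate_design(spec, seed=1), TrueParams(),
                         seed=2, attrition_rate=spec.attrition_rate)
flat = fit_ordered_logit(trials)
hier = fit_hier_mcmc(trials, n_iter=1500, n_warmup=1000, seed=3, n_chains=2)

obs = trials.attention_level.to_numpy()
print(accuracy(cross_table(obs, predict_trials(flat, trials)[0])))
print(accuracy(cross_table(obs, predict_category_hier(hier, trials)[0])))
print(flat.summary().round(3)[["estimate", "se", "wald", "p", "odds_ratio"]])
```

prints (93 valid trials survive attrition on this seed)

```
58.06451612903226
56.98924731182796
                            estimate     se    wald      p  odds_ratio
threshold[1]                   1.373  0.459   8.955  0.003       3.947
threshold[2]                   2.629  0.515  26.021  0.000      13.860
riding_style[conservative]     0.826  0.429   3.707  0.054       2.284
traffic_density[moderate]      1.154  0.570   4.094  0.043       3.172
traffic_density[sparse]        2.271  0.507  20.110  0.000       9.694
```

The accuracies are the percentage of trials whose modal predicted level
matches the observed level (in-sample; at this sample size the gap
between the two models swings a few points between replicates). In the
coefficient table, `odds_ratio = exp(estimate)` is the multiplicative
change in the odds of a *more focused* attention level: here
conservative riders have ~2.3× the odds of aggressive riders, and
sparse traffic ~9.7× the odds of dense traffic, of higher attention.

The `examples/` directory holds one short script per capability
(simulation, gaze metrics, scoring, model comparison, per-cyclist
thresholds), and a thin CLI drives the same pipeline from the shell:

```bash
cycleattention simulate --seed 1 --out trials.csv
cycleattention run-all --seed 1 --out runs/demo
```

See `docs/methods.md` for the model details, sampler design, generator
defaults and known limitations.

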