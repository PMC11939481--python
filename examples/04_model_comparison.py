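"""Fit both attention models and compare their in-sample accuracy.

The flat cumulative-logit model shares one pair of thresholds across
cyclists; the hierarchical model lets each cyclist's thresholds move
with the lane-fixation share, the pupil CV, and a cyclist random
effect.  Both are scored by the observed-vs-predicted cross table.
"""

from cycleattention import (DesignSpec, TrueParams, accuracy, compare_models,
                            cross_table, fit_hier_mcmc, fit_ordered_logit,
                            generate_design, odds_ratios,
                            predict_category_hier, simulate_trials)
from cycleattention.ologit import predict_trials

spec = DesignSpec()
trials = simulate_trials(generate_design(spec, seed=1), TrueParams(), seed=2,
                         attrition_rate=spec.attrition_rate)
obs = trials.attention_level.to_numpy()

flat = fit_ordered_logit(trials)
print("ordered logit\n", flat.summary().round(3)[["estimate", "se", "wald",
                                                  "p", "odds_ratio"]])

hier = fit_hier_mcmc(trials, n_iter=1500, n_warmup=1000, seed=3, n_chains=2)
print("\nhierarchical (posterior summaries)\n",
      hier.summary().round(3)[["estimate", "se", "q2.5", "q97.5", "rhat"]])

t_flat = cross_table(obs, predict_trials(flat, trials)[0])
t_hier = cross_table(obs, predict_category_hier(hier, trials)[0])
print(f"\naccuracy: ordered {accuracy(t_flat):.2f}% | "
      f"hierarchical {accuracy(t_hier):.2f}% | "
      f"gain {compare_models(t_hier, t_flat):.2f} pp")

ors = odds_ratios(dict(zip(flat.names, flat.beta)), recode_reference="sparse",
                  factor_prefix="traffic_density")
print("\nodds ratios with 'sparse' as the density reference\n", ors.round(3))
# An odds ratio > 1 means higher odds of a more focused attention level.
# With only 9 cyclists the in-sample accuracy gap between the two models
# moves a few points between replicates; across many seeds the
# hierarchical model wins most of the time (see the test suite's
# replicated comparison).
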