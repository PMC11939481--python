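"""Per-cyclist attention thresholds from the hierarchical fit.

Each cyclist's two cut points are the base thresholds shifted by the
trial covariates and the cyclist's random effect; the spacing between
the cut points is common to everyone (a common-shift model).
"""

import numpy as np

from cycleattention import (DesignSpec, TrueParams, fit_hier_mcmc,
                            generate_design, simulate_trials,
                            threshold_for_cyclist)

spec = DesignSpec()
trials = simulate_trials(generate_design(spec, seed=1), TrueParams(), seed=2,
                         attrition_rate=spec.attrition_rate)
fit = fit_hier_mcmc(trials, n_iter=1500, n_warmup=1000, seed=4, n_chains=1)

z_typical = trials[["lane_fixation_share", "pupil_cv"]].mean().to_numpy()
print(f"covariates evaluated at the sample mean: {z_typical.round(3)}")
for cyclist in fit.data.cyclists[:4]:
    t = threshold_for_cyclist(fit, cyclist, z_typical)
    g1, g2 = t["mean"].to_numpy()
    print(f"cyclist {cyclist}: thresholds ({g1:6.2f}, {g2:6.2f})  "
          f"spacing {g2 - g1:.2f}")

b = fit._flat("b").mean(axis=0)
print("random-effect posterior means:", np.round(b, 2))
print("posterior mean tau:", round(float(fit._flat('tau').mean()), 2),
      "(precision of the cyclist effect; higher = less heterogeneity)")
# Cyclists with higher thresholds need a larger latent attention value to
# be classified as focused — i.e. they are harder to impress.
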