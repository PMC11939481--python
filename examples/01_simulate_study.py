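"""Simulate the campus cycling study design.

Nine cyclists ride three road sections in both directions during a peak
and an off-peak period (108 design cells); a ~10% attrition rate mimics
recording losses.  Ordinal attention levels are drawn from the
hierarchical ordered logistic model with known parameters.
"""

from cycleattention import DesignSpec, TrueParams, generate_design, simulate_trials

spec = DesignSpec()
skeletons = generate_design(spec, seed=1)
trials = simulate_trials(skeletons, TrueParams(), seed=2,
                         attrition_rate=spec.attrition_rate)

print(f"design cells: {len(skeletons)}  valid trials: {len(trials)}")
print("traffic density:", skeletons.traffic_density.value_counts().to_dict())
print("riding style:   ", trials.riding_style.value_counts().to_dict())
print("attention level:", trials.attention_level.value_counts().sort_index().to_dict())
print(trials.head(3)[["cyclist", "section", "period", "traffic_density",
                      "riding_style", "lane_fixation_share", "pupil_cv",
                      "attention_level"]].to_string(index=False))
# Level 1 = Distracted, 2 = Scattered, 3 = Focused; lane_fixation_share and
# pupil_cv are the covariates that will shift each cyclist's thresholds.
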