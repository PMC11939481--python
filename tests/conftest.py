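import numpy as np
import pytest

from cycleattention import DesignSpec, TrueParams, generate_design, simulate_trials


@pytest.fixture(scope="session")
def true_params() -> TrueParams:
    return TrueParams()


@pytest.fixture(scope="session")
def study_trials(true_params):
    """A mid-sized synthetic trial table (25 cyclists, no attrition)."""
    spec = DesignSpec(n_cyclists=25, attrition_rate=0.0)
    skeletons = generate_design(spec, seed=7)
    return simulate_trials(skeletons, true_params, seed=8)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def gaze_targets() -> dict:
    return dict(
        fixation_time_pct=0.6,
        saccade_time_pct=0.25,
        blink_freq_per_min=12.0,
        lane_fixation_share=0.7,
        pupil_mean_mm=4.0,
        pupil_sd_mm=0.5,
        avg_fixation_ms=300.0,
    )
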