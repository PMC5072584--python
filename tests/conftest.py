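import numpy as np
import pytest

from wristspeed.synthetic import (
    NoiseSpec,
    SubjectProfile,
    TrialPlan,
    simulate_trial,
)


@pytest.fixture(scope="session")
def default_profile():
    return SubjectProfile()


@pytest.fixture(scope="session")
def quiet_walk():
    """Zero-noise 20-s walk at 120 cm/s with gentle heading wander."""

    def heading(t):
        return 0.3 + 0.1 * np.sin(2 * np.pi * t / 18.0)

    plan = TrialPlan(
        segments=[(20.0, 120.0)], heading=heading, noise=NoiseSpec.zero()
    )
    return simulate_trial(SubjectProfile(), plan, trial_id="quiet")


@pytest.fixture(scope="session")
def noisy_walk():
    """Default-noise 20-s walk at 120 cm/s."""
    plan = TrialPlan(segments=[(20.0, 120.0)], heading=0.5,
                     noise=NoiseSpec(seed=7))
    return simulate_trial(SubjectProfile(), plan, trial_id="noisy")
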