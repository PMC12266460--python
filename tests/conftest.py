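import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from leapcea import GeneratorConfig, build_base_case_from_fixtures, generate_cohort
from leapcea.states import Arm
from leapcea.transitions import TransitionMatrix

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


def random_stochastic_matrix(rng, interval_months: float = 6.0) -> TransitionMatrix:
    """Random row-stochastic 4x4 with an exactly absorbing DEAD row."""
    probs = rng.random((4, 4)) + 0.01
    probs /= probs.sum(axis=1, keepdims=True)
    probs[3] = [0.0, 0.0, 0.0, 1.0]
    return TransitionMatrix(probs, interval_months)


@pytest.fixture(scope="session")
def fixture_base_case():
    """Base case assembled from the packaged summary fixtures."""
    base, matrices = build_base_case_from_fixtures()
    return base


@pytest.fixture(scope="session")
def small_cohort():
    """Trial-sized synthetic cohort (153 + 149 participants)."""
    return generate_cohort(GeneratorConfig(seed=11))


@pytest.fixture(scope="session")
def large_cohort():
    """10,000 participants per arm for parameter-recovery checks."""
    return generate_cohort(
        GeneratorConfig(
            seed=13,
            n_per_arm={Arm.EDUCATION_CONTROL: 10_000, Arm.INDIVIDUAL_COACHING: 10_000},
            missing_rate=0.0,
        )
    )
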