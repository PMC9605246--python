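import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from fedstress.cohort import (
    ParticipantProfile,
    SessionPlan,
    generate_cohort,
    generate_participant,
)
from fedstress.experiment import extract_cohort_features
from fedstress.features import build_feature_matrix

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def short_plan() -> SessionPlan:
    """A 4-minute session: 2 min neutral, 1 min stress, 1 min amusement."""
    return SessionPlan((("neutral", 120.0), ("stress", 60.0), ("amusement", 60.0)))


@pytest.fixture(scope="session")
def recording(short_plan):
    return generate_participant(ParticipantProfile(participant_id=1, rng_seed=11), short_plan)


@pytest.fixture(scope="session")
def feature_matrix(recording):
    return build_feature_matrix(recording)


@pytest.fixture(scope="session")
def cohort_matrices(short_plan):
    """Feature matrices of a 3-participant heterogeneous cohort."""
    cohort = generate_cohort(3, atypical_fraction=0.0, seed=42, plan=short_plan)
    return extract_cohort_features(cohort)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
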