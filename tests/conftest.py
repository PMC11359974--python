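import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from dynoreli import (
    OnsetSpec,
    StudyParams,
    TraceParams,
    extract_study_outcomes,
    generate_study,
)

RATE = 1961.0


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def times_6s():
    return np.arange(int(RATE * 6)) / RATE


@pytest.fixture(scope="session")
def small_study():
    """A seeded 8-subject study with traces, shared across tests."""
    sp = StudyParams(n_subjects=8, seed=2024)
    return generate_study(sp)


@pytest.fixture(scope="session")
def small_study_outcomes(small_study):
    return extract_study_outcomes(small_study, OnsetSpec())


@pytest.fixture
def default_trace_params():
    return TraceParams()
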