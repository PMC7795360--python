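import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import shoulderseg as ss

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def healthy_profile():
    return ss.SubjectProfile.default("healthy", "H01")


@pytest.fixture
def fs_profile():
    return ss.SubjectProfile.default("fs", "P01")


@pytest.fixture(scope="session")
def small_dataset():
    """2 healthy + 2 fs subjects x 2 tasks = 8 sequences."""
    return ss.generate_dataset(2, 2, ["T1", "T2"], seed=11)


@pytest.fixture(scope="session")
def one_sequence():
    return ss.generate_sequence(
        ss.SubjectProfile.default("healthy", "H01"), "T1", seed=3
    )
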