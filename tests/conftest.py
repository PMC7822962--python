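import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import crowdmix as cm

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def two_flanker_dataset():
    """600 synthetic trials from one observer, exp1 geometry, default regime."""
    return cm.generate_dataset(cm.DesignConfig(seed=101))


@pytest.fixture(scope="session")
def two_flanker_trials(two_flanker_dataset):
    err = cm.compute_errors(two_flanker_dataset)
    return cm.trial_errors(err, "two_flanker")


@pytest.fixture(scope="session")
def four_flanker_trials(two_flanker_dataset):
    err = cm.compute_errors(two_flanker_dataset)
    return cm.trial_errors(err, "four_flanker")


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
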