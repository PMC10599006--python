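import numpy as np
import pytest

from neuroadc import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def tiny_config():
    """A small, fast cohort configuration shared across tests."""
    return CohortConfig(n_patients=12, volume_shape=(16, 16, 12), seed=42)


@pytest.fixture(scope="session")
def tiny_cohort(tiny_config):
    return generate_cohort(tiny_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
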