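import numpy as np
import pytest

from glioprep import CohortConfig, make_brain_phantom


@pytest.fixture(scope="session")
def tiny_config():
    """Small cohort configuration for fast unit tests."""
    return CohortConfig(
        shape=(48, 48, 48),
        n_paired=3,
        n_low_grade=8,
        n_high_grade=10,
        master_seed=7,
    )


@pytest.fixture(scope="session")
def phantom(tiny_config):
    """One deterministic low-grade phantom shared by read-only tests."""
    return make_brain_phantom(tiny_config, grade="low", seed=123)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240)
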