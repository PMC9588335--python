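import numpy as np
import pytest

from nodalscore import BetaBinParams, SyntheticConfig, generate_cohort


@pytest.fixture(scope="session")
def shapes() -> BetaBinParams:
    """Published shape estimates of the positive-node model."""
    return BetaBinParams(1.51, 1.15)


@pytest.fixture(scope="session")
def small_cohort():
    """A small deterministic synthetic cohort shared across tests."""
    return generate_cohort(SyntheticConfig(n_patients=800, seed=11))


@pytest.fixture(scope="session")
def default_cohort():
    """Full-size synthetic cohort at the default configuration."""
    return generate_cohort(SyntheticConfig(n_patients=12_431, seed=11))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
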