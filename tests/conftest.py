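import numpy as np
import pytest

from offspring_iv import (
    SimulationConfig,
    prepare_analysis_frame,
    simulate_trios,
    synthetic_lms_reference,
)


@pytest.fixture(scope="session")
def default_config():
    return SimulationConfig()


@pytest.fixture(scope="session")
def small_trios(default_config):
    """A modest default-condition cohort shared across tests."""
    return simulate_trios(default_config.replace(n_families=4000, seed=11))


@pytest.fixture(scope="session")
def prepared_small(small_trios):
    """The same cohort with z-scores and BMI categories attached."""
    return prepare_analysis_frame(
        small_trios, lms_reference=synthetic_lms_reference()
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
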