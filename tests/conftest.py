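import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture(scope="session")
def small_cohort():
    """A small but fully valid synthetic cohort shared across tests."""
    from phototraits import SyntheticCohortConfig, simulate_cohort

    config = SyntheticCohortConfig(n_users=8, photos_per_user=(30, 34),
                                   image_size=(32, 32))
    return simulate_cohort(config, seed=11)
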