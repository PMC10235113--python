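import numpy as np
import pytest
from hypothesis import settings

from divkit.simulate import SimConfig, simulate_dataset

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_study():
    """A small but complete synthetic study (8 sites, 40-species pool)."""
    return simulate_dataset(SimConfig(seed=202, n_sites=8, pool_size=40,
                                      richness_range=(5, 20)))


@pytest.fixture(scope="session")
def small_dataset(small_study):
    return small_study.reconciled()


@pytest.fixture(scope="session")
def full_study():
    """Study at the default conditions (20 sites, 97-species pool)."""
    return simulate_dataset(SimConfig(seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
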