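import numpy as np
import pytest

from stochtune.config import KineticsPriors, PhysioConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def priors():
    return KineticsPriors()


@pytest.fixture
def small_physio():
    """A short-run physiological config for unit tests."""
    return PhysioConfig(n_genes=1, n_steps=2000, seed=7)
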