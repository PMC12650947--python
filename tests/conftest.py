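import numpy as np
import pytest

from irrev import generators


@pytest.fixture(scope="session")
def logistic_10k():
    """A fully chaotic logistic orbit, the canonical irreversible series."""
    return generators.logistic(10_000, r=4.0, seed=1)


@pytest.fixture(scope="session")
def gaussian_1k():
    """iid Gaussian noise: the reversible null."""
    return np.random.default_rng(123).normal(size=1000)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
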