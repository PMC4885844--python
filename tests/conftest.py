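import numpy as np
import pytest

import dualhebb as dh


@pytest.fixture(scope="session")
def small_gaussian_model():
    """p=4, M=40 Gaussian world model used across unit tests."""
    return dh.make_gaussian_model(p=4, M=40, seed=101)


@pytest.fixture(scope="session")
def default_gaussian_model():
    """Full-size model at the standard operating point (p=10, M=200)."""
    return dh.make_gaussian_model(seed=202)


@pytest.fixture(scope="session")
def small_poisson_model():
    return dh.make_poisson_model(p=4, M=40, seed=303)


@pytest.fixture()
def rng():
    return np.random.default_rng(4242)
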