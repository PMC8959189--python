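import numpy as np
import pytest

import pymt_tme as pt


@pytest.fixture(scope="session")
def table3():
    return pt.table3_parameters()


@pytest.fixture(scope="session")
def dataset():
    return pt.builtin_dataset()


@pytest.fixture(scope="session")
def model():
    return pt.TumorImmuneModel.builtin()


@pytest.fixture(scope="session")
def fit(model):
    return model.fit()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_state(rng, scale=1.0):
    """A random nonnegative nondimensional-like state."""
    return rng.uniform(0.0, scale, 15)


def random_params(rng, scale=0.05):
    return rng.uniform(0.0, scale, 57)
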