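import numpy as np
import pytest

from mitonet import make_fixture, run, validate_params


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def tiny_params():
    return make_fixture("tiny-default")


@pytest.fixture(scope="session")
def tiny_trajectory(tiny_params):
    """One short full-model run shared by read-only tests."""
    return run(tiny_params.replace(t_sim=400.0), seed=99)


@pytest.fixture(scope="session")
def default_params():
    return validate_params()
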