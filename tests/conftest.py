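import numpy as np
import pytest

from mapkosc import build_network, default_params


@pytest.fixture(scope="session")
def params():
    return default_params()


@pytest.fixture(scope="session")
def network(params):
    return build_network(params)


@pytest.fixture(scope="session")
def nf_free_params(params):
    return params.without_negative_feedback()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
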