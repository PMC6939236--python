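import numpy as np
import pytest

from spinsim import build_network, canonical_microcircuit, generate_toy_net
from spinsim.partition import map_network


@pytest.fixture(scope="session")
def canonical_spec():
    return canonical_microcircuit()


@pytest.fixture(scope="session")
def balanced_spec():
    return generate_toy_net("two_pop_balanced", {"duration": 200.0}, seed=7)


@pytest.fixture(scope="session")
def balanced_net(balanced_spec):
    return build_network(balanced_spec)


@pytest.fixture(scope="session")
def balanced_map(balanced_spec):
    return map_network(balanced_spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
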