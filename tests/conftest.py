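import numpy as np
import pytest

from coageing import SpeciesParams, grow_network
from coageing.fixtures import chain_network, two_dependee_motif


@pytest.fixture(scope="session")
def net100():
    return grow_network(100, 12345)


@pytest.fixture(scope="session")
def net100_b():
    return grow_network(100, 54321)


@pytest.fixture
def chain():
    return chain_network()


@pytest.fixture
def motif():
    return two_dependee_motif()


@pytest.fixture
def frail_pair():
    """A long-lived species A co-ageing against a frail antagonist B."""
    params_a = SpeciesParams(n_nodes=100, d=0.002, r=0.02, C=0.015)
    params_b = SpeciesParams(n_nodes=100, d=0.008, r=0.05, C=0.015)
    return params_a, params_b
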