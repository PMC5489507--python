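import networkx as nx
import numpy as np
import pytest

from coopnet.harness import make_fixtures
from coopnet.pdgame import PayoffParams


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def gadgets():
    """Deterministic hand-built graphs shared across the suite."""
    return make_fixtures(seed=7, sizes=())


@pytest.fixture(scope="session")
def ba200():
    return make_fixtures(seed=7, sizes=(200,))["ba-200"]


@pytest.fixture(scope="session")
def ba300():
    return make_fixtures(seed=7, sizes=(300,))["ba-300"]


@pytest.fixture(scope="session")
def pp():
    return PayoffParams.from_ratio(0.95)


def random_simple_graph(rng, n_max=30, p=0.3):
    """A random Erdos-Renyi simple graph with 0..N-1 nodes (test helper)."""
    n = int(rng.integers(3, n_max + 1))
    g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
    return g
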