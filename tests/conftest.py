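import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True,
                          max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def lattice35():
    """Ring lattice WS(n=35, k=10, p=0)."""
    from swnf.synthgen import make_ws_graph
    return make_ws_graph(35, 10, 0.0, seed=0)


def random_graph(n, p_edge, rng):
    """Erdos-Renyi-style adjacency for oracle tests."""
    a = rng.random((n, n)) < p_edge
    a = np.triu(a, 1)
    a = a | a.T
    return a
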