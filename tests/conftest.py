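import numpy as np
import pytest

from modconn.fc import ConnectivityMatrix


def random_connectivity(n: int, rng: np.random.Generator,
                        density: float = 0.5) -> ConnectivityMatrix:
    """Random symmetric nonnegative network with ~density edge fraction."""
    w = rng.random((n, n))
    mask = rng.random((n, n)) < density
    w = np.triu(w * mask, 1)
    w = w + w.T
    return ConnectivityMatrix(w, [f"n{i}" for i in range(n)])


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def two_cliques():
    """Two disjoint binary 5-cliques."""
    w = np.zeros((10, 10))
    w[:5, :5] = 1.0
    w[5:, 5:] = 1.0
    np.fill_diagonal(w, 0.0)
    return ConnectivityMatrix(w, [f"n{i}" for i in range(10)])
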