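import numpy as np
import pytest

from netsig import WeightedGraph


@pytest.fixture
def unit_triangle() -> WeightedGraph:
    return WeightedGraph(
        np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]], dtype=float), is_binary=True
    )


@pytest.fixture
def unit_path3() -> WeightedGraph:
    """Path 0-1-2 with unit weights."""
    return WeightedGraph(
        np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], dtype=float), is_binary=True
    )


@pytest.fixture
def two_node() -> WeightedGraph:
    return WeightedGraph(np.array([[0.0, 0.5], [0.5, 0.0]]))


def random_connected_weighted(n: int, seed: int, p: float = 0.4) -> WeightedGraph:
    from netsig import make_erdos_renyi

    return make_erdos_renyi(n, p, weighted=True, seed=seed, require_connected=True)
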