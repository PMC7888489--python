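import numpy as np
import pytest

from connsyn import ConnectivityMatrix


@pytest.fixture
def single_edge_3():
    """3 nodes, one edge of weight 2 between nodes 0 and 1."""
    w = np.zeros((3, 3))
    w[0, 1] = w[1, 0] = 2.0
    return ConnectivityMatrix(weights=w)


@pytest.fixture
def complete_unit_4():
    """Complete 4-node graph, unit weights."""
    w = np.ones((4, 4)) - np.eye(4)
    return ConnectivityMatrix(weights=w)


@pytest.fixture
def path_abc():
    """Path graph a-b-c with unit weights."""
    w = np.zeros((3, 3))
    w[0, 1] = w[1, 0] = 1.0
    w[1, 2] = w[2, 1] = 1.0
    return ConnectivityMatrix(weights=w, labels=("a", "b", "c"))
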