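import numpy as np
import pytest

from symptomnet import ItemDataset, WeightedNetwork, uniform_schema


def make_network(labels, edges):
    """Network from an iterable of (a, b, weight) index triples."""
    p = len(labels)
    W = np.zeros((p, p))
    for a, b, w in edges:
        W[a, b] = W[b, a] = w
    return WeightedNetwork(tuple(labels), W)


@pytest.fixture
def path_abc():
    """Path graph A - B - C with unit weights."""
    return make_network("ABC", [(0, 1, 1.0), (1, 2, 1.0)])


@pytest.fixture
def two_triangles():
    """Two disconnected unit-weight triangles on six nodes."""
    return make_network(
        "abcdef",
        [(0, 1, 1.0), (1, 2, 1.0), (0, 2, 1.0), (3, 4, 1.0), (4, 5, 1.0), (3, 5, 1.0)],
    )


@pytest.fixture
def small_counts_dataset():
    """30 subjects x 4 three-level items, deterministic content."""
    rng = np.random.default_rng(1234)
    vals = rng.integers(0, 3, size=(30, 4)).astype(float)
    return ItemDataset(schema=uniform_schema(4), values=vals)


def random_small_network(rng, n_nodes=None, weighted=True, p_edge=0.45):
    """Random graph on <= 8 nodes for brute-force oracle comparisons."""
    if n_nodes is None:
        n_nodes = int(rng.integers(4, 9))
    W = np.zeros((n_nodes, n_nodes))
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            if rng.random() < p_edge:
                W[i, j] = W[j, i] = rng.uniform(0.1, 1.0) if weighted else 1.0
    labels = tuple(f"n{k}" for k in range(n_nodes))
    return WeightedNetwork(labels, W)
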