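"""Node centrality indices: strength, closeness, betweenness.

Strength sums absolute incident edge weights.  Closeness and betweenness
are shortest-path indices; by default path lengths use the field
convention distance = 1/|weight| (``inverse_weight``), with an unweighted
``hop`` mode also available.  Unreachable pairs are excluded from the
closeness sum; a node reaching nothing has closeness 0 by convention.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import shortest_path

from .network import WeightedNetwork

DISTANCE_MODES = ("inverse_weight", "hop")


def strength(net: WeightedNetwork) -> pd.Series:
    """s_i = sum_j |w_ij|."""
    return pd.Series(
        net.abs_weights().sum(axis=1), index=list(net.node_labels), name="strength"
    )


def _distance_matrix(net: WeightedNetwork, distance: str) -> np.ndarray:
    if distance not in DISTANCE_MODES:
        raise ValueError(f"distance must be one of {DISTANCE_MODES}")
    a = net.abs_weights()
    if distance == "hop":
        d = (a > 0).astype(float)
    else:
        with np.errstate(divide="ignore"):
            d = np.where(a > 0, 1.0 / a, 0.0)
    return shortest_path(d, method="D", directed=False, unweighted=(distance == "hop"))


def closeness(net: WeightedNetwork, distance: str = "inverse_weight") -> pd.Series:
    """c_i = 1 / sum_j d(i, j) over reachable j (0 if none reachable)."""
    D = _distance_matrix(net, distance)
    p = net.p
    vals = np.zeros(p)
    for i in range(p):
        row = np.delete(D[i], i)
        finite = row[np.isfinite(row)]
        if finite.size and finite.sum() > 0:
            vals[i] = 1.0 / finite.sum()
    return pd.Series(vals, index=list(net.node_labels), name="closeness")


def reachable_counts(net: WeightedNetwork, distance: str = "inverse_weight") -> pd.Series:
    """Number of other nodes each node can reach (reported with closeness)."""
    D = _distance_matrix(net, distance)
    counts = np.isfinite(D).sum(axis=1) - 1
    return pd.Series(counts, index=list(net.node_labels), name="n_reachable")


def betweenness(net: WeightedNetwork, distance: str = "inverse_weight") -> pd.Series:
    """b_k = sum over pairs i<j (k not in {i,j}) of sigma_ij(k)/sigma_ij."""
    import networkx as nx

    if distance not in DISTANCE_MODES:
        raise ValueError(f"distance must be one of {DISTANCE_MODES}")
    G = net.to_graph(distance=distance)
    weight = None if distance == "hop" else "length"
    vals = nx.betweenness_centrality(G, weight=weight, normalized=False)
    return pd.Series(
        [vals[lab] for lab in net.node_labels],
        index=list(net.node_labels),
        name="betweenness",
    )


CENTRALITY_FUNCS = {
    "strength": strength,
    "closeness": closeness,
    "betweenness": betweenness,
}


def centrality_table(
    net: WeightedNetwork, distance: str = "inverse_weight"
) -> pd.DataFrame:
    """All three centrality indices as one table (raw scores)."""
    return pd.DataFrame(
        {
            "strength": strength(net),
            "closeness": closeness(net, distance),
            "betweenness": betweenness(net, distance),
        }
    )
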