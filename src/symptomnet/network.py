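"""Weighted undirected network container and serialization."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

SYMMETRY_TOL = 1e-12


@dataclass(frozen=True)
class WeightedNetwork:
    """Symmetric weighted adjacency over labeled nodes, zero diagonal.

    Edge weights are signed regression weights from the mixed-graph fit
    (in practice all positive for residual-symptom networks).  ``provenance``
    records the configuration and data fingerprint that produced the fit.
    """

    node_labels: tuple[str, ...]
    weights: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        W = np.asarray(self.weights, dtype=float)
        p = len(self.node_labels)
        if W.shape != (p, p):
            raise ValueError(f"weights shape {W.shape} does not match {p} labels")
        if np.max(np.abs(W - W.T), initial=0.0) > SYMMETRY_TOL:
            raise ValueError("weights matrix is not symmetric")
        W = (W + W.T) / 2.0
        np.fill_diagonal(W, 0.0)
        W.flags.writeable = False
        object.__setattr__(self, "weights", W)
        object.__setattr__(self, "node_labels", tuple(self.node_labels))

    @property
    def p(self) -> int:
        return len(self.node_labels)

    @property
    def n_possible_edges(self) -> int:
        return self.p * (self.p - 1) // 2

    def edge_mask(self) -> np.ndarray:
        """Boolean upper-triangle mask of present edges."""
        iu = np.triu_indices(self.p, k=1)
        return self.weights[iu] != 0.0

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(np.triu(self.weights, k=1)))

    def density(self) -> float:
        """Detected edges over possible edges p(p-1)/2."""
        if self.p < 2:
            return 0.0
        return self.n_edges / self.n_possible_edges

    def abs_weights(self) -> np.ndarray:
        return np.abs(self.weights)

    def edge_list(self) -> pd.DataFrame:
        """Long-format edge list (node_a, node_b, weight), present edges only."""
        i, j = np.nonzero(np.triu(self.weights, k=1))
        return pd.DataFrame(
            {
                "node_a": [self.node_labels[a] for a in i],
                "node_b": [self.node_labels[b] for b in j],
                "weight": self.weights[i, j],
            }
        )

    # ------------------------------------------------------------------ I/O
    def to_adjacency_csv(self, path) -> None:
        df = pd.DataFrame(
            self.weights, index=list(self.node_labels), columns=list(self.node_labels)
        )
        df.index.name = "node"
        df.to_csv(path)

    @classmethod
    def from_adjacency_csv(cls, path) -> "WeightedNetwork":
        df = pd.read_csv(path, index_col=0)
        return cls(tuple(str(c) for c in df.columns), df.to_numpy(dtype=float))

    def to_edge_tsv(self, path) -> None:
        self.edge_list().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_edge_tsv(cls, path, node_labels=None) -> "WeightedNetwork":
        df = pd.read_csv(path, sep="\t")
        if node_labels is None:
            seen: list[str] = []
            for col in ("node_a", "node_b"):
                for v in df[col].astype(str):
                    if v not in seen:
                        seen.append(v)
            node_labels = seen
        node_labels = tuple(str(x) for x in node_labels)
        idx = {lab: k for k, lab in enumerate(node_labels)}
        W = np.zeros((len(node_labels), len(node_labels)))
        for _, row in df.iterrows():
            a, b = idx[str(row["node_a"])], idx[str(row["node_b"])]
            W[a, b] = W[b, a] = float(row["weight"])
        return cls(node_labels, W)

    def to_graphml(self, path) -> None:
        """GraphML export for network-interchange tooling."""
        import networkx as nx

        nx.write_graphml(self.to_graph(), path)

    def to_graph(self, distance: str = "inverse_weight"):
        """networkx Graph with 'weight' and 'length' edge attributes."""
        import networkx as nx

        G = nx.Graph()
        G.add_nodes_from(self.node_labels)
        i, j = np.nonzero(np.triu(self.weights, k=1))
        for a, b in zip(i, j):
            w = self.weights[a, b]
            length = 1.0 if distance == "hop" else 1.0 / abs(w)
            G.add_edge(
                self.node_labels[a], self.node_labels[b], weight=w, length=length
            )
        return G
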