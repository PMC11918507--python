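"""Smart local moving community detection and cluster-based node roles.

:func:`slm_partition` maximizes weighted modularity by the smart local
moving heuristic: local moving of single nodes, followed by splitting each
community via local moving on its own subnetwork, aggregation of the
subcommunities into a reduced network, and repetition until modularity no
longer improves.  Multiple random restarts are taken and the best-Q
partition returned (ties broken by the lexicographically smallest
canonical assignment, for reproducibility).

Cluster quality is summarized by modularity, conductance and coverage.
Within a partition, a node's strength splits exactly into bridge strength
(absolute weight to other clusters) and stabilizing index (absolute weight
within its own cluster); the top bridge-strength nodes are flagged as
bridge nodes and each cluster's highest stabilizing index marks its
stabilizing node.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .network import WeightedNetwork


@dataclass(frozen=True)
class Partition:
    """Node -> cluster assignment, clusters labeled by size-descending rank."""

    node_labels: tuple[str, ...]
    labels: np.ndarray
    modularity: float
    seed: Optional[int] = None
    restarts: int = 1

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels, dtype=int)
        if lab.shape != (len(self.node_labels),):
            raise ValueError("labels length must match node_labels")
        lab = lab.copy()
        lab.flags.writeable = False
        object.__setattr__(self, "labels", lab)

    @property
    def n_clusters(self) -> int:
        return len(np.unique(self.labels)) if len(self.labels) else 0

    def members(self, c: int) -> np.ndarray:
        return np.flatnonzero(self.labels == c)

    def sizes(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.n_clusters)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"node": list(self.node_labels), "cluster": self.labels}
        ).set_index("node")


def canonical_labels(labels: np.ndarray) -> np.ndarray:
    """Relabel clusters 0..K-1 by decreasing size, ties by first member."""
    labels = np.asarray(labels, dtype=int)
    uniq = np.unique(labels)
    order = sorted(
        uniq,
        key=lambda c: (-int((labels == c).sum()), int(np.flatnonzero(labels == c)[0])),
    )
    remap = {c: k for k, c in enumerate(order)}
    return np.array([remap[c] for c in labels], dtype=int)


def modularity(
    net: WeightedNetwork | np.ndarray,
    labels: np.ndarray,
    resolution: float = 1.0,
) -> float:
    """Weighted modularity Q = sum_c (e_c/m - resolution (d_c/2m)^2).

    e_c is the intra-cluster edge weight, d_c the cluster degree sum and
    m the total edge weight; absolute weights are used.  Q = 0 when the
    network has no edges.
    """
    W = net.abs_weights() if isinstance(net, WeightedNetwork) else np.abs(
        np.asarray(net, dtype=float)
    )
    labels = np.asarray(labels, dtype=int)
    two_m = W.sum()
    if two_m == 0:
        return 0.0
    k = W.sum(axis=1)
    q = 0.0
    for c in np.unique(labels):
        idx = labels == c
        intra = W[np.ix_(idx, idx)].sum()  # counts each internal edge twice
        dc = k[idx].sum()
        q += intra / two_m - resolution * (dc / two_m) ** 2
    return float(q)


# ----------------------------------------------------------- SLM internals
def _local_moving(
    W: np.ndarray, labels: np.ndarray, rng: np.random.Generator, resolution: float
) -> bool:
    """In-place local moving; returns whether any node changed community.

    Candidate destinations for a node are its neighbors' communities plus
    a fresh empty community; moves are accepted on the best positive
    modularity gain.  Self-loops (from aggregation) stay with the node and
    do not enter the gain comparison.
    """
    n = W.shape[0]
    two_m = W.sum()
    if two_m == 0:
        return False
    k = W.sum(axis=1)
    comm_deg = np.zeros(n)
    for c in range(n):
        comm_deg[c] = 0.0
    uniq = np.unique(labels)
    comm_deg = np.bincount(labels, weights=k, minlength=n + len(uniq) + 1)
    free = [c for c in range(len(comm_deg)) if c not in set(labels)]
    moved_any = True
    changed = False
    while moved_any:
        moved_any = False
        for i in rng.permutation(n):
            ci = labels[i]
            nbrs = np.flatnonzero(W[i])
            nbrs = nbrs[nbrs != i]
            w_to = {}
            for j in nbrs:
                w_to[labels[j]] = w_to.get(labels[j], 0.0) + W[i, j]
            comm_deg[ci] -= k[i]
            best_c, best_gain = ci, w_to.get(ci, 0.0) - resolution * k[i] * comm_deg[
                ci
            ] / two_m
            candidates = set(w_to)
            if free:
                candidates.add(free[-1])
            for c in candidates:
                if c == ci:
                    continue
                gain = w_to.get(c, 0.0) - resolution * k[i] * comm_deg[c] / two_m
                if gain > best_gain + 1e-12:
                    best_gain, best_c = gain, c
            labels[i] = best_c
            comm_deg[best_c] += k[i]
            if best_c != ci:
                moved_any = True
                changed = True
                if free and best_c == free[-1]:
                    free.pop()
                if not np.any(labels == ci) and ci < len(comm_deg):
                    free.append(ci)
    return changed


def _compress(labels: np.ndarray) -> np.ndarray:
    _, out = np.unique(labels, return_inverse=True)
    return out.astype(int)


def _aggregate(W: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Reduced network: one node per community, self-loops keep intra weight."""
    k = labels.max() + 1
    M = np.zeros((k, len(labels)))
    M[labels, np.arange(len(labels))] = 1.0
    return M @ W @ M.T


def _split_communities(
    W: np.ndarray, labels: np.ndarray, rng: np.random.Generator, resolution: float
) -> tuple[np.ndarray, np.ndarray]:
    """Re-run local moving inside each community's own subnetwork.

    Returns (sub_labels, red_init): the refined subcommunity assignment and,
    per subcommunity, the community it came from.
    """
    n = W.shape[0]
    sub_labels = np.full(n, -1)
    parents: list[int] = []
    next_sub = 0
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        if len(idx) > 1:
            Wc = W[np.ix_(idx, idx)]
            local = np.arange(len(idx))
            _local_moving(Wc, local, rng, resolution)
            local = _compress(local)
        else:
            local = np.zeros(1, dtype=int)
        sub_labels[idx] = local + next_sub
        next_sub += int(local.max()) + 1
        parents.extend([int(c)] * (int(local.max()) + 1))
    return sub_labels, _compress(np.asarray(parents))


def _slm_level(
    W: np.ndarray, init: np.ndarray, rng: np.random.Generator, resolution: float
) -> np.ndarray:
    """One SLM pass: local moving, community splitting, then recursion on
    the aggregated network of subcommunities (initialized by community)."""
    labels = _compress(init.copy())
    _local_moving(W, labels, rng, resolution)
    labels = _compress(labels)
    n = W.shape[0]
    if labels.max() + 1 == n:
        return labels
    sub_labels, red_init = _split_communities(W, labels, rng, resolution)
    if sub_labels.max() + 1 == n:  # no reduction possible; avoid recursing
        return labels
    W_red = _aggregate(W, sub_labels)
    red = _slm_level(W_red, red_init, rng, resolution)
    out = _compress(red[sub_labels])
    if modularity(W, out, resolution) >= modularity(W, labels, resolution) - 1e-12:
        return out
    return labels


def _slm_single(
    W: np.ndarray, rng: np.random.Generator, resolution: float, iterations: int
) -> np.ndarray:
    labels = np.arange(W.shape[0])
    for _ in range(max(iterations, 1)):
        labels = _slm_level(W, labels, rng, resolution)
    return labels


def slm_partition(
    net: WeightedNetwork,
    resolution: float = 1.0,
    iterations: int = 1,
    restarts: int = 20,
    seed: Optional[int] = None,
) -> Partition:
    """Best-of-``restarts`` smart local moving partition of the network.

    Works on absolute weights.  An empty network yields all-singleton
    clusters.  Equal-modularity restarts are resolved toward the
    lexicographically smallest canonical label vector.
    """
    W = net.abs_weights()
    n = net.p
    rng = np.random.default_rng(seed)
    best_labels = np.arange(n)
    best_q = modularity(W, best_labels, resolution)
    if W.sum() > 0:
        for _ in range(max(restarts, 1)):
            labels = _slm_single(W.copy(), rng, resolution, iterations)
            q = modularity(W, labels, resolution)
            cand = canonical_labels(labels)
            if q > best_q + 1e-12 or (
                abs(q - best_q) <= 1e-12
                and tuple(cand) < tuple(canonical_labels(best_labels))
            ):
                best_q, best_labels = q, labels
    return Partition(
        node_labels=net.node_labels,
        labels=canonical_labels(best_labels),
        modularity=best_q,
        seed=seed,
        restarts=restarts,
    )


# ------------------------------------------------------------- quality
@dataclass(frozen=True)
class ClusterQuality:
    """Conductance (per-cluster and volume-weighted), modularity, coverage."""

    per_cluster: pd.DataFrame  # cluster, size, volume, cut, conductance
    conductance: float
    modularity: float
    coverage: float


def cluster_quality(net: WeightedNetwork, partition: Partition) -> ClusterQuality:
    """Cut-based quality metrics of a partition on absolute weights.

    Per-cluster conductance = cut(c) / min(vol(c), vol(rest)); the
    network-level figure is the volume-weighted mean over clusters of
    size >= 2 (singleton clusters would degenerate the metric).  Coverage
    is the fraction of total edge weight that falls within clusters.
    """
    W = net.abs_weights()
    labels = partition.labels
    total_vol = W.sum()  # = 2m
    rows = []
    intra_total = 0.0
    for c in np.unique(labels):
        idx = labels == c
        vol = W[idx].sum()
        intra = W[np.ix_(idx, idx)].sum()
        cut = vol - intra
        intra_total += intra
        denom = min(vol, total_vol - vol)
        cond = cut / denom if denom > 0 else 0.0
        rows.append(
            {
                "cluster": int(c),
                "size": int(idx.sum()),
                "volume": vol,
                "cut": cut,
                "conductance": cond,
            }
        )
    per_cluster = pd.DataFrame(rows).set_index("cluster")
    big = per_cluster[per_cluster["size"] >= 2]
    if len(big) and big["volume"].sum() > 0:
        network_cond = float(
            (big["conductance"] * big["volume"]).sum() / big["volume"].sum()
        )
    else:
        network_cond = 0.0
    coverage = float(intra_total / total_vol) if total_vol > 0 else 1.0
    return ClusterQuality(
        per_cluster=per_cluster,
        conductance=network_cond,
        modularity=modularity(net, labels),
        coverage=coverage,
    )


def scale_partition(net: WeightedNetwork, schema) -> Partition:
    """The a-priori partition given by questionnaire membership."""
    scale_of = {it.item_id: it.scale for it in schema.items}
    scales = []
    for lab in net.node_labels:
        sc = scale_of.get(lab, "custom")
        if sc not in scales:
            scales.append(sc)
    labels = np.array([scales.index(scale_of.get(lab, "custom")) for lab in net.node_labels])
    return Partition(
        node_labels=net.node_labels,
        labels=canonical_labels(labels),
        modularity=modularity(net, labels),
    )


# ------------------------------------------------- bridge / stabilizing
@dataclass(frozen=True)
class BridgeTable:
    """Per-node bridge/stabilizing decomposition and per-cluster anchors."""

    table: pd.DataFrame  # node, cluster, strength, bridge_strength, ...
    stabilizing: pd.DataFrame  # cluster -> stabilizing node(s) and index
    top_k: int


def bridge_strengths(net: WeightedNetwork, partition: Partition) -> pd.Series:
    """Sum of absolute weights on inter-cluster edges, per node."""
    W = net.abs_weights()
    lab = partition.labels
    inter = lab[:, None] != lab[None, :]
    return pd.Series(
        (W * inter).sum(axis=1), index=list(net.node_labels), name="bridge_strength"
    )


def stabilizing_indices(net: WeightedNetwork, partition: Partition) -> pd.Series:
    """Sum of absolute weights on intra-cluster edges, per node."""
    W = net.abs_weights()
    lab = partition.labels
    intra = lab[:, None] == lab[None, :]
    np.fill_diagonal(intra, False)
    return pd.Series(
        (W * intra).sum(axis=1), index=list(net.node_labels), name="stabilizing_index"
    )


def bridge_nodes(
    net: WeightedNetwork, partition: Partition, top_k: int = 5
) -> BridgeTable:
    """Flag the ``top_k`` highest bridge-strength nodes, extending ties.

    If the node at the cut shares its bridge strength with others, all tied
    nodes are flagged (the flagged set can exceed ``top_k``).  Nodes with
    zero bridge strength are never flagged — isolated clusters have no
    bridge nodes by definition.
    """
    bs = bridge_strengths(net, partition)
    si = stabilizing_indices(net, partition)
    W = net.abs_weights()
    s = W.sum(axis=1)
    nz = bs[bs > 0].sort_values(ascending=False)
    if len(nz) <= top_k:
        flagged = set(nz.index)
    else:
        cut = nz.iloc[top_k - 1]
        flagged = set(nz[nz >= cut - 1e-12].index)
    table = pd.DataFrame(
        {
            "node": list(net.node_labels),
            "cluster": partition.labels,
            "strength": s,
            "bridge_strength": bs.to_numpy(),
            "stabilizing_index": si.to_numpy(),
            "bridge_node": [lab in flagged for lab in net.node_labels],
        }
    ).set_index("node")
    stab_rows = []
    for c in np.unique(partition.labels):
        members = [net.node_labels[i] for i in partition.members(c)]
        if len(members) == 1:
            stab_rows.append(
                {"cluster": int(c), "stabilizing_nodes": [], "stabilizing_index": 0.0}
            )
            continue
        vals = si[members]
        top = vals.max()
        winners = sorted(vals[np.isclose(vals, top)].index.tolist())
        stab_rows.append(
            {
                "cluster": int(c),
                "stabilizing_nodes": winners,
                "stabilizing_index": float(top),
            }
        )
    stabilizing = pd.DataFrame(stab_rows).set_index("cluster")
    return BridgeTable(table=table, stabilizing=stabilizing, top_k=top_k)


def stabilizing_nodes(net: WeightedNetwork, partition: Partition) -> pd.DataFrame:
    """Per-cluster stabilizing node(s): argmax of the stabilizing index.

    Singleton clusters have no stabilizing node (index 0, empty list);
    exact ties are reported jointly.
    """
    return bridge_nodes(net, partition).stabilizing
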