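"""Community detection vs exhaustive search; bridge/stabilizing identities."""

import itertools

import numpy as np
import pytest

import symptomnet as sn
from symptomnet.community import (
    bridge_strengths,
    canonical_labels,
    cluster_quality,
    modularity,
    scale_partition,
    stabilizing_indices,
)
from symptomnet.network import WeightedNetwork

from conftest import make_network, random_small_network


def set_partitions(n):
    """All partitions of range(n) as label arrays (restricted growth strings)."""
    def rec(k, labels, mx):
        if k == n:
            yield np.array(labels)
            return
        for c in range(mx + 1):
            yield from rec(k + 1, labels + [c], max(mx, c + 1))

    yield from rec(0, [], 0)


def brute_force_max_modularity(net):
    best_q, best = -np.inf, None
    for labels in set_partitions(net.p):
        q = modularity(net, labels)
        if q > best_q + 1e-12:
            best_q, best = q, labels
    return best_q, best


class TestModularity:
    def test_one_cluster_zero(self, two_triangles):
        assert modularity(two_triangles, np.zeros(6, dtype=int)) == pytest.approx(0.0)

    def test_two_triangles_bipartition(self, two_triangles):
        assert modularity(two_triangles, np.array([0, 0, 0, 1, 1, 1])) == pytest.approx(0.5)

    def test_matches_edge_list_recomputation(self):
        rng = np.random.default_rng(60)
        for _ in range(20):
            net = random_small_network(rng)
            labels = rng.integers(0, 3, size=net.p)
            # independent recomputation from the explicit edge list
            edges = net.edge_list()
            m = edges["weight"].abs().sum()
            if m == 0:
                assert modularity(net, labels) == 0.0
                continue
            idx = {lab: k for k, lab in enumerate(net.node_labels)}
            e_c, d_c = {}, {}
            for _, row in edges.iterrows():
                a, b = idx[row["node_a"]], idx[row["node_b"]]
                w = abs(row["weight"])
                d_c[labels[a]] = d_c.get(labels[a], 0.0) + w
                d_c[labels[b]] = d_c.get(labels[b], 0.0) + w
                if labels[a] == labels[b]:
                    e_c[labels[a]] = e_c.get(labels[a], 0.0) + w
            q_ref = sum(
                e_c.get(c, 0.0) / m - (d_c.get(c, 0.0) / (2 * m)) ** 2
                for c in set(labels)
            )
            assert modularity(net, labels) == pytest.approx(q_ref, abs=1e-12)

    def test_empty_network_defined_zero(self):
        net = make_network("abc", [])
        assert modularity(net, np.array([0, 1, 2])) == 0.0


class TestSlmPartition:
    def test_two_triangles_found(self, two_triangles):
        part = sn.slm_partition(two_triangles, restarts=5, seed=0)
        assert part.n_clusters == 2
        assert part.modularity == pytest.approx(0.5)
        assert len(set(part.labels[:3])) == 1 and len(set(part.labels[3:])) == 1

    def test_complete_graph_single_cluster(self):
        W = np.ones((5, 5)) - np.eye(5)
        net = WeightedNetwork(tuple("abcde"), W)
        part = sn.slm_partition(net, restarts=5, seed=0)
        assert part.n_clusters == 1
        assert part.modularity == pytest.approx(0.0)

    def test_empty_network_all_singletons(self):
        net = make_network("abcd", [])
        part = sn.slm_partition(net, seed=0)
        assert part.n_clusters == 4

    def test_attains_exhaustive_maximum_on_small_graphs(self):
        rng = np.random.default_rng(61)
        for _ in range(20):
            n_nodes = int(rng.integers(4, 8))
            net = random_small_network(rng, n_nodes=n_nodes)
            q_star, _ = brute_force_max_modularity(net)
            part = sn.slm_partition(net, restarts=20, seed=int(rng.integers(1e6)))
            assert part.modularity == pytest.approx(q_star, abs=1e-9)

    def test_beats_greedy_agglomerative_baseline(self):
        import networkx as nx

        rng = np.random.default_rng(62)
        wins = 0
        for _ in range(25):
            net = random_small_network(rng, n_nodes=20, p_edge=0.15)
            seed = int(rng.integers(1e6))
            if net.n_edges == 0:
                continue
            # extra iterations re-randomize the community splits, letting
            # block moves escape the single-pass local optimum
            part = sn.slm_partition(net, restarts=20, iterations=3, seed=seed)
            G = net.to_graph()
            comms = nx.algorithms.community.greedy_modularity_communities(
                G, weight="weight"
            )
            labels = np.zeros(net.p, dtype=int)
            for c, nodes in enumerate(comms):
                for lab in nodes:
                    labels[net.node_labels.index(lab)] = c
            assert part.modularity >= modularity(net, labels) - 1e-9
            wins += 1
        assert wins > 0

    def test_seed_determinism(self, two_triangles):
        a = sn.slm_partition(two_triangles, restarts=8, seed=5)
        b = sn.slm_partition(two_triangles, restarts=8, seed=5)
        assert np.array_equal(a.labels, b.labels)


class TestClusterQuality:
    def test_connected_components_partition(self, two_triangles):
        part = sn.slm_partition(two_triangles, restarts=5, seed=0)
        q = cluster_quality(two_triangles, part)
        assert q.conductance == pytest.approx(0.0)
        assert q.coverage == pytest.approx(1.0)

    def test_whole_network_one_cluster_coverage_one(self):
        rng = np.random.default_rng(63)
        net = random_small_network(rng, n_nodes=6)
        part = sn.Partition(net.node_labels, np.zeros(6, dtype=int), 0.0)
        assert cluster_quality(net, part).coverage == pytest.approx(1.0)

    def test_coverage_plus_cut_fraction_is_one(self):
        rng = np.random.default_rng(64)
        for _ in range(10):
            net = random_small_network(rng, n_nodes=7)
            if net.n_edges == 0:
                continue
            labels = rng.integers(0, 3, size=7)
            part = sn.Partition(net.node_labels, canonical_labels(labels), 0.0)
            q = cluster_quality(net, part)
            total = net.abs_weights().sum() / 2
            cut = q.per_cluster["cut"].sum() / 2
            assert q.coverage + cut / total == pytest.approx(1.0)

    def test_data_driven_partition_beats_questionnaire_partition(self):
        """With cross-scale coupling, SLM clusters have lower conductance
        than the partition given by questionnaire membership."""
        schema = sn.ItemSchema(
            tuple(sn.Item(f"m{k}", "MADRS", 0, 6) for k in range(4))
            + tuple(sn.Item(f"y{k}", "YMRS", 0, 4) for k in range(4))
        )
        # true structure couples m0,m1,y0,y1 and m2,m3,y2,y3 across scales
        W = np.zeros((8, 8))
        for a, b in [(0, 1), (0, 4), (1, 5), (4, 5), (2, 3), (2, 6), (3, 7), (6, 7)]:
            W[a, b] = W[b, a] = 0.3
        net = WeightedNetwork(tuple(schema.item_ids), W)
        slm = sn.slm_partition(net, restarts=10, seed=1)
        data_q = cluster_quality(net, slm)
        scale_q = cluster_quality(net, scale_partition(net, schema))
        assert data_q.conductance < scale_q.conductance

    def test_label_invariance(self):
        rng = np.random.default_rng(65)
        net = random_small_network(rng, n_nodes=7)
        labels = rng.integers(0, 3, size=7)
        perm = np.array([2, 0, 1])
        q1 = cluster_quality(net, sn.Partition(net.node_labels, canonical_labels(labels), 0.0))
        q2 = cluster_quality(
            net, sn.Partition(net.node_labels, canonical_labels(perm[labels]), 0.0)
        )
        assert q1.conductance == pytest.approx(q2.conductance)
        assert q1.coverage == pytest.approx(q2.coverage)
        assert q1.modularity == pytest.approx(q2.modularity)


class TestBridgeAndStabilizing:
    def test_isolated_cluster_never_bridges(self, two_triangles):
        part = sn.slm_partition(two_triangles, restarts=5, seed=0)
        table = sn.bridge_nodes(two_triangles, part).table
        assert np.all(table["bridge_strength"] == 0.0)
        assert not table["bridge_node"].any()

    def test_singleton_cluster_bridge_equals_strength(self):
        net = make_network("abc", [(0, 1, 0.4), (0, 2, 0.2)])
        labels = np.array([0, 1, 1])
        part = sn.Partition(net.node_labels, labels, 0.0)
        bs = bridge_strengths(net, part)
        assert bs["a"] == pytest.approx(0.6)  # all incident edges leave cluster

    def test_tie_at_cut_extends_selection(self):
        # hub z collects all cross-cluster edges; spoke bridge strengths are
        # 0.9, 0.8 and four tied 0.5s straddling the rank-5 cut, so the
        # flagged set extends to 7 nodes instead of 5
        weights = [0.9, 0.8, 0.5, 0.5, 0.5, 0.5, 0.3, 0.2, 0.0]
        labels = np.array([0] * 9 + [1])
        edges = [(i, 9, w) for i, w in enumerate(weights) if w > 0]
        net = make_network("abcdefghiz", edges)
        part = sn.Partition(net.node_labels, labels, 0.0)
        res = sn.bridge_nodes(net, part, top_k=5)
        flagged = res.table[res.table["bridge_node"]]
        assert len(flagged) == 7  # z, a, b and the four tied 0.5s
        assert set(flagged.index) == {"z", "a", "b", "c", "d", "e", "f"}
        unflagged_nonzero = res.table[
            (~res.table["bridge_node"]) & (res.table["bridge_strength"] > 0)
        ]
        assert set(unflagged_nonzero.index) == {"g", "h"}

    def test_star_hub_is_stabilizing_node(self):
        net = make_network("hxyz", [(0, 1, 0.2), (0, 2, 0.2), (0, 3, 0.2)])
        part = sn.Partition(net.node_labels, np.zeros(4, dtype=int), 0.0)
        stab = sn.stabilizing_nodes(net, part)
        assert stab.loc[0, "stabilizing_nodes"] == ["h"]

    def test_singleton_cluster_has_no_stabilizing_node(self):
        net = make_network("ab", [(0, 1, 0.5)])
        part = sn.Partition(net.node_labels, np.array([0, 1]), 0.0)
        stab = sn.stabilizing_nodes(net, part)
        assert stab.loc[0, "stabilizing_nodes"] == []
        assert stab.loc[0, "stabilizing_index"] == 0.0

    def test_strength_decomposition_identity(self):
        rng = np.random.default_rng(66)
        for _ in range(100):
            net = random_small_network(rng)
            labels = rng.integers(0, 4, size=net.p)
            part = sn.Partition(net.node_labels, canonical_labels(labels), 0.0)
            bs = bridge_strengths(net, part).to_numpy()
            si = stabilizing_indices(net, part).to_numpy()
            s = sn.strength(net).to_numpy()
            assert np.allclose(bs + si, s, atol=1e-12)

    def test_bridge_table_label_invariance(self):
        rng = np.random.default_rng(67)
        net = random_small_network(rng, n_nodes=8)
        labels = rng.integers(0, 3, size=8)
        perm = np.array([1, 2, 0])
        p1 = sn.Partition(net.node_labels, canonical_labels(labels), 0.0)
        p2 = sn.Partition(net.node_labels, canonical_labels(perm[labels]), 0.0)
        assert np.allclose(
            bridge_strengths(net, p1).to_numpy(), bridge_strengths(net, p2).to_numpy()
        )
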