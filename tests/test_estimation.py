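"""Nodewise Poisson lasso: EBIC, path behavior, network combination rules."""

import math
import subprocess
import textwrap
import warnings

import numpy as np
import pytest

import symptomnet as sn
from symptomnet.estimation import (
    EstimationConfig,
    EstimationError,
    _fit_node_matrix,
    classify_predictability,
    ebic,
    flag_overlapping_pairs,
)
from symptomnet.network import WeightedNetwork

QUIET = EstimationConfig()


def _estimate(ds, cfg=QUIET):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return sn.estimate_network(ds, cfg)


class TestEbic:
    def test_gamma_zero_reduces_to_bic(self):
        assert ebic(-100, 3, 100, 51, 0) == pytest.approx(200 + 3 * math.log(100))

    def test_zero_df_is_minus_two_loglik(self):
        assert ebic(-123.4, 0, 50, 10, 0.7) == pytest.approx(246.8)

    def test_documented_value(self):
        expected = 200 + 3 * math.log(100) + 1.5 * math.log(51)
        assert ebic(-100, 3, 100, 51, 0.25) == pytest.approx(expected)
        assert expected == pytest.approx(219.713, abs=5e-4)

    def test_matches_independent_recomputation_on_random_tuples(self):
        rng = np.random.default_rng(99)
        for _ in range(100):
            ll = float(rng.uniform(-500, 0))
            df = int(rng.integers(0, 30))
            n = int(rng.integers(1, 10_000))
            pc = int(rng.integers(1, 200))
            g = float(rng.uniform(0, 1))
            spreadsheet = (-2.0) * ll + df * math.log(n) + 2 * g * df * math.log(pc)
            assert abs(ebic(ll, df, n, pc, g) - spreadsheet) < 1e-9


class TestFitNode:
    def test_lambda_max_gives_empty_model(self, small_counts_dataset):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sn.fit_node(small_counts_dataset, 0)
        assert np.all(fit.coefs[0] == 0.0)
        assert fit.df[0] == 0

    def test_null_target_selects_empty_model(self):
        rng = np.random.default_rng(21)
        vals = rng.integers(0, 3, size=(2000, 6)).astype(float)
        ds = sn.ItemDataset(schema=sn.uniform_schema(6), values=vals)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sn.fit_node(ds, 0)
        assert fit.df[fit.selected] == 0

    def test_single_true_predictor_recovered_with_positive_sign(self):
        p = 8
        W = np.zeros((p, p))
        W[0, 3] = W[3, 0] = 0.3
        net = sn.TrueNetwork(W, 0.0, (0, 0.3))
        ds = sn.sample_copula(net, sn.uniform_schema(p), 2000, seed=22)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sn.fit_node(ds, 0)
        sel = fit.selected_coefs
        active = dict(zip(fit.predictor_idx, sel))
        assert active[3] > 0
        assert sum(v != 0 for v in sel) == 1

    def test_matches_r_glmnet_path(self, tmp_path):
        """Independent oracle: glmnet's Poisson lasso on the same path."""
        rng = np.random.default_rng(5)
        n, p = 300, 6
        Z = rng.standard_normal((n, p))
        y = rng.poisson(np.exp(0.2 + 0.4 * Z[:, 0] - 0.3 * Z[:, 2]))
        X = np.column_stack([y, Z]).astype(float)
        cfg = EstimationConfig(refit=False, tol=1e-9, max_iter=5000)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = _fit_node_matrix(X, 0, cfg)
        Zs = (X[:, 1:] - X[:, 1:].mean(0)) / X[:, 1:].std(0)
        np.savetxt(tmp_path / "Z.csv", Zs, delimiter=",")
        np.savetxt(tmp_path / "y.csv", y, delimiter=",")
        np.savetxt(tmp_path / "lam.csv", fit.lambdas, delimiter=",")
        script = tmp_path / "fit.R"
        script.write_text(
            textwrap.dedent(
                """
                suppressMessages(library(glmnet))
                Z <- as.matrix(read.csv("Z.csv", header=FALSE))
                y <- scan("y.csv", quiet=TRUE)
                lams <- scan("lam.csv", quiet=TRUE)
                fit <- glmnet(Z, y, family="poisson", lambda=lams,
                              standardize=FALSE, thresh=1e-12)
                write.csv(t(as.matrix(coef(fit))), "out.csv", row.names=FALSE)
                """
            )
        )
        subprocess.run(
            ["Rscript", "fit.R"], cwd=tmp_path, check=True, capture_output=True
        )
        ref = np.loadtxt(tmp_path / "out.csv", delimiter=",", skiprows=1)
        assert np.max(np.abs(ref[:, 0] - fit.intercepts)) < 1e-5
        assert np.max(np.abs(ref[:, 1:] - fit.coefs)) < 1e-5

    def test_constant_target_rejected(self):
        vals = np.zeros((50, 3))
        vals[:, 1] = np.arange(50) % 3
        ds = sn.ItemDataset(schema=sn.uniform_schema(3), values=vals)
        with pytest.raises(EstimationError):
            sn.fit_node(ds, 0)


class TestEstimateNetwork:
    def test_independence_data_low_density(self):
        rng = np.random.default_rng(31)
        vals = rng.integers(0, 3, size=(2000, 10)).astype(float)
        ds = sn.ItemDataset(schema=sn.uniform_schema(10), values=vals)
        net = _estimate(ds)
        assert net.density() <= 0.05

    def test_and_rule_is_subgraph_of_or_rule(self):
        truth = sn.generate_network(10, 0.2, 0.15, 0.3, seed=32)
        ds = sn.sample_copula(truth, sn.uniform_schema(10), 1500, seed=33)
        and_net = _estimate(ds, EstimationConfig(rule="and"))
        or_net = _estimate(ds, EstimationConfig(rule="or"))
        and_edges = and_net.weights != 0
        or_edges = or_net.weights != 0
        assert np.all(or_edges[and_edges])

    def test_gamma_monotone_in_edge_count(self):
        truth = sn.generate_network(10, 0.2, 0.1, 0.3, seed=34)
        ds = sn.sample_copula(truth, sn.uniform_schema(10), 800, seed=35)
        counts = [
            _estimate(ds, EstimationConfig(gamma=g)).n_edges for g in (0.0, 0.25, 0.5)
        ]
        assert counts[0] >= counts[1] >= counts[2]

    def test_sign_recovery_on_positive_networks(self):
        agree = []
        for rep in range(5):
            truth = sn.generate_network(20, 0.1, 0.15, 0.3, seed=100 + rep)
            ds = sn.sample_copula(truth, sn.uniform_schema(20), 5000, seed=200 + rep)
            est = _estimate(ds)
            both = (truth.weights > 0) & (est.weights != 0)
            if both.any():
                agree.append(float((est.weights[both] > 0).mean()))
        assert agree and np.mean(agree) == 1.0

    def test_constant_item_error_names_item(self):
        vals = np.zeros((100, 3))
        vals[:, 0] = np.arange(100) % 3
        vals[:, 2] = np.arange(100) % 2
        ds = sn.ItemDataset(schema=sn.uniform_schema(3), values=vals)
        with pytest.raises(EstimationError, match="item_01"):
            sn.estimate_network(ds)


class TestDensity:
    def test_paper_scale_arithmetic(self):
        p = 52
        W = np.zeros((p, p))
        iu = np.triu_indices(p, k=1)
        sel = (iu[0][:71], iu[1][:71])
        W[sel] = 0.1
        W = W + W.T
        net = WeightedNetwork(tuple(f"n{k}" for k in range(p)), W)
        assert net.n_possible_edges == 1326
        assert sn.density(net) == pytest.approx(71 / 1326)

    def test_empty_and_complete(self):
        p = 6
        empty = WeightedNetwork(tuple("abcdef"), np.zeros((p, p)))
        full = np.ones((p, p)) - np.eye(p)
        complete = WeightedNetwork(tuple("abcdef"), full)
        assert sn.density(empty) == 0.0
        assert sn.density(complete) == 1.0


class TestPredictability:
    def test_isolated_node_zero(self, small_counts_dataset):
        net = WeightedNetwork(
            tuple(small_counts_dataset.item_ids), np.zeros((4, 4))
        )
        r2 = sn.predictability(small_counts_dataset, net)["r2"]
        assert np.all(r2 == 0.0)

    def test_deterministic_copy_highly_predictable(self):
        # y equals its neighbor exactly; two-level items keep the identity
        # representable under the log link, so the refit is exact
        rng = np.random.default_rng(41)
        a = rng.integers(1, 3, size=500)
        schema = sn.ItemSchema(
            (
                sn.Item("u", "custom", 1, 2),
                sn.Item("v", "custom", 1, 2),
                sn.Item("w", "custom", 0, 2),
            )
        )
        vals = np.column_stack([a, a, rng.integers(0, 3, size=500)]).astype(float)
        ds = sn.ItemDataset(schema=schema, values=vals)
        W = np.zeros((3, 3))
        W[0, 1] = W[1, 0] = 0.5
        net = WeightedNetwork(tuple(ds.item_ids), W)
        r2 = sn.predictability(ds, net)["r2"]
        assert r2.iloc[0] >= 0.99 and r2.iloc[1] >= 0.99

    @pytest.mark.parametrize(
        "r2,band", [(0.4, "moderate"), (0.6, "high"), (0.15, "low"), (0.51, "high")]
    )
    def test_bands(self, r2, band):
        assert classify_predictability(r2) == band


class TestTopologicalOverlap:
    def test_single_pair_hand_value(self):
        W = np.zeros((2, 2))
        W[0, 1] = W[1, 0] = 0.4
        net = WeightedNetwork(("a", "b"), W)
        to = sn.topological_overlap(net)
        assert to[0, 1] == pytest.approx(0.4 / (0.4 + 1 - 0.4))
        assert to[0, 0] == to[1, 1] == 1.0

    def test_empty_network_zero_offdiag(self):
        net = WeightedNetwork(tuple("abc"), np.zeros((3, 3)))
        to = sn.topological_overlap(net)
        assert np.all(to[~np.eye(3, dtype=bool)] == 0.0)

    def test_redundant_pair_flagged_near_one(self):
        # two items with identical neighborhoods and a strong mutual edge
        p = 6
        W = np.zeros((p, p))
        for j in range(2, p):
            W[0, j] = W[j, 0] = 1.0
            W[1, j] = W[j, 1] = 1.0
        W[0, 1] = W[1, 0] = 0.95
        net = WeightedNetwork(tuple(f"n{k}" for k in range(p)), W)
        to = sn.topological_overlap(net)
        # (4*1 + 0.95) / (4.95 + 1 - 0.95) = 0.99
        assert to[0, 1] == pytest.approx(0.99)
        flagged = flag_overlapping_pairs(net, warn_level=0.9)
        assert {"n0", "n1"} == set(flagged.iloc[0][["node_a", "node_b"]])
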