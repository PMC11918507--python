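"""Ground-truth networks and synthetic discrete questionnaire data.

Two generative routes produce subjects x items count data whose pairwise
dependence structure follows a known sparse positive-weight network:

* :func:`sample_copula` — a Gaussian copula whose latent partial
  correlations are proportional to the true edge weights, discretized into
  each item's level range with right-skewed marginal probabilities
  (residual symptoms are rare, so the lowest level dominates).
* :func:`sample_pairwise_count` — a Gibbs sampler for the pairwise count
  model whose node conditionals are truncated Poisson with log-rate
  ``alpha_j + sum_k w_jk x_k``, the exponential-family form matched by the
  nodewise Poisson estimator.

The default study condition is a 52-node network with density 0.08 and
edge weights uniform on (0, 0.3].
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats
from scipy.special import gammaln

from .data import ItemDataset, euthymia_filter
from .schema import ItemSchema

#: geometric decay ratio of successive level probabilities (right skew)
LEVEL_DECAY = 0.45


class GenerationError(RuntimeError):
    """Raised when a sampler cannot produce valid data."""


@dataclass(frozen=True)
class TrueNetwork:
    """A known sparse nonnegative-weight network used as simulation truth."""

    weights: np.ndarray
    density: float
    weight_range: tuple[float, float]
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        W = np.asarray(self.weights, dtype=float)
        if not np.allclose(W, W.T):
            raise ValueError("true network must be symmetric")
        if np.any(np.diag(W) != 0):
            raise ValueError("true network must have zero diagonal")
        if np.any(W < 0):
            raise ValueError("true network weights must be nonnegative")
        W = W.copy()
        W.flags.writeable = False
        object.__setattr__(self, "weights", W)

    @property
    def p(self) -> int:
        return self.weights.shape[0]

    def edge_mask(self) -> np.ndarray:
        iu = np.triu_indices(self.p, k=1)
        return self.weights[iu] > 0

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(np.triu(self.weights, k=1)))


def generate_network(
    p: int,
    density: float,
    weight_low: float = 0.0,
    weight_high: float = 0.3,
    seed: Optional[int] = None,
) -> TrueNetwork:
    """Random sparse network: uniform edge placement, uniform weights.

    Exactly ``round(density * p(p-1)/2)`` upper-triangle entries are
    nonzero; weights are i.i.d. uniform on ``(weight_low, weight_high]``.
    """
    if not 0 <= density <= 1:
        raise ValueError("density must be in [0, 1]")
    if not 0 <= weight_low < weight_high:
        raise ValueError("need 0 <= weight_low < weight_high")
    rng = np.random.default_rng(seed)
    n_pairs = p * (p - 1) // 2
    m = int(round(density * n_pairs))
    W = np.zeros((p, p))
    if m > 0:
        chosen = rng.choice(n_pairs, size=m, replace=False)
        iu = np.triu_indices(p, k=1)
        # uniform on (low, high]: 1 - U with U ~ [0, 1)
        w = weight_low + (weight_high - weight_low) * (1.0 - rng.random(m))
        rows, cols = iu[0][chosen], iu[1][chosen]
        W[rows, cols] = w
        W[cols, rows] = w
    return TrueNetwork(
        weights=W, density=density, weight_range=(weight_low, weight_high), seed=seed
    )


# ------------------------------------------------------------------ copula
def copula_correlation(net: TrueNetwork) -> np.ndarray:
    """Latent Gaussian correlation whose partial correlations track the net.

    Builds precision Omega = I - c W with c the largest constant <= 1
    keeping Omega positive definite, so that the latent partial correlation
    of a pair equals c * w_ij — and equals the true weight itself whenever
    the spectral radius of W is below 1, which holds throughout the default
    study condition (52 nodes, density 0.08, weights in (0, 0.3]).  Only
    denser/heavier networks are rescaled; then inverts and standardizes to
    a correlation matrix.
    """
    W = net.weights
    p = net.p
    if p == 0 or W.max() <= 0:
        return np.eye(p)
    lam_top = np.linalg.eigvalsh(W)[-1]
    c = 1.0 if lam_top < 1.0 - 1e-6 else (1.0 - 1e-6) / lam_top
    for _ in range(60):
        Omega = np.eye(p) - c * W
        if np.linalg.eigvalsh(Omega)[0] > 1e-10:
            break
        c *= 0.9
    else:
        raise GenerationError("could not build a positive-definite latent precision")
    Sigma = np.linalg.inv(Omega)
    d = np.sqrt(np.diag(Sigma))
    return Sigma / np.outer(d, d)


def level_probabilities(n_levels: int, decay: float = LEVEL_DECAY) -> np.ndarray:
    """Right-skewed level probabilities proportional to decay**level."""
    probs = decay ** np.arange(n_levels)
    return probs / probs.sum()


def _item_thresholds(schema: ItemSchema, decay: float) -> list[np.ndarray]:
    cuts = []
    for it in schema.items:
        probs = level_probabilities(it.n_levels, decay)
        cum = np.cumsum(probs)[:-1]
        cuts.append(stats.norm.ppf(cum))
    return cuts


@dataclass(frozen=True)
class TruncationConfig:
    """Euthymia-style caps applied to sampled data (resampling to size)."""

    madrs_max: float = 10
    ymrs_max: float = 12


def sample_copula(
    net: TrueNetwork,
    schema: ItemSchema,
    n: int,
    seed: Optional[int] = None,
    decay: float = LEVEL_DECAY,
    truncation: Optional[TruncationConfig] = None,
    max_tries: int = 200,
) -> ItemDataset:
    """Draw n subjects from the Gaussian-copula item model.

    With ``truncation`` set, sampled batches are passed through the
    euthymia filter and sampling repeats until n subjects qualify,
    emulating the restriction-of-range effect of the inclusion rule.
    """
    if net.p != len(schema):
        raise ValueError("network dimension must equal schema item count")
    rng = np.random.default_rng(seed)
    corr = copula_correlation(net)
    try:
        L = np.linalg.cholesky(corr)
    except np.linalg.LinAlgError as exc:
        raise GenerationError("latent correlation not positive definite") from exc
    cuts = _item_thresholds(schema, decay)
    mins = schema.min_levels

    def draw(size: int) -> np.ndarray:
        Z = rng.standard_normal((size, net.p)) @ L.T
        X = np.empty_like(Z, dtype=np.int64)
        for j in range(net.p):
            X[:, j] = mins[j] + np.searchsorted(cuts[j], Z[:, j])
        return X

    if n == 0:
        return ItemDataset(schema=schema, values=np.zeros((0, net.p)))
    if truncation is None:
        return ItemDataset(schema=schema, values=draw(n).astype(float))
    kept: list[np.ndarray] = []
    total = 0
    for _ in range(max_tries):
        batch = ItemDataset(schema=schema, values=draw(max(n, 64)).astype(float))
        ok = euthymia_filter(batch, truncation.madrs_max, truncation.ymrs_max)
        if ok.n_subjects:
            kept.append(ok.values)
            total += ok.n_subjects
        if total >= n:
            vals = np.vstack(kept)[:n]
            return ItemDataset(schema=schema, values=vals)
    raise GenerationError("truncation rejection sampling failed to reach n subjects")


# --------------------------------------------------------- pairwise counts
def truncated_poisson_mean(rate: float, lo: int, hi: int) -> float:
    """Mean of a Poisson(rate) truncated to the integer range [lo, hi]."""
    ks = np.arange(lo, hi + 1)
    logp = ks * math.log(max(rate, 1e-300)) - gammaln(ks + 1)
    pr = np.exp(logp - logp.max())
    pr /= pr.sum()
    return float((ks * pr).sum())


def solve_alpha(target_mean: float, lo: int, hi: int) -> float:
    """Intercept alpha with truncated-Poisson(e^alpha) mean == target_mean."""
    if not lo < target_mean < hi:
        raise ValueError("target_mean must lie strictly inside the level range")
    f = lambda a: truncated_poisson_mean(math.exp(a), lo, hi) - target_mean
    a_lo, a_hi = -20.0, 5.0
    from scipy.optimize import brentq

    return float(brentq(f, a_lo, a_hi, xtol=1e-10))


def sample_pairwise_count(
    net: TrueNetwork,
    schema: ItemSchema,
    n: int,
    seed: Optional[int] = None,
    burn_in: int = 500,
    thin: int = 2,
    alpha: Optional[np.ndarray] = None,
    target_mean: float = 0.3,
    rate_cap: float = 1e6,
) -> ItemDataset:
    """Gibbs-sample the pairwise count model matched to the estimator.

    Node conditionals are Poisson(exp(alpha_j + sum_k w_jk x_k)) truncated
    to the item's level range.  One chain is run; ``n`` states are kept
    after ``burn_in`` sweeps, one every ``thin`` sweeps.
    """
    if net.p != len(schema):
        raise ValueError("network dimension must equal schema item count")
    if np.any(net.weights < 0):
        raise GenerationError("pairwise count model requires nonnegative weights")
    rng = np.random.default_rng(seed)
    p = net.p
    mins, maxs = schema.min_levels, schema.max_levels
    if alpha is None:
        alpha = np.array(
            [solve_alpha(target_mean, mins[j], maxs[j]) for j in range(p)]
        )
    alpha = np.asarray(alpha, dtype=float)
    # per-item support and log-factorial tables
    supports = [np.arange(mins[j], maxs[j] + 1) for j in range(p)]
    logfacts = [gammaln(s + 1) for s in supports]
    x = mins.astype(float).copy()
    W = net.weights
    out = np.empty((n, p), dtype=np.int64)
    kept = 0
    sweep = 0
    u = rng.random(burn_in * p + n * thin * p + p)  # pre-drawn uniforms
    ui = 0
    while kept < n:
        for j in range(p):
            eta = alpha[j] + W[j] @ x
            if eta > math.log(rate_cap):
                raise GenerationError(
                    "divergent conditional rate; rescale the network weights"
                )
            ks = supports[j]
            logp = ks * eta - logfacts[j]
            pr = np.exp(logp - logp.max())
            cum = np.cumsum(pr)
            x[j] = ks[np.searchsorted(cum, u[ui] * cum[-1])]
            ui += 1
        sweep += 1
        if sweep > burn_in and (sweep - burn_in) % max(thin, 1) == 0:
            out[kept] = x.astype(np.int64)
            kept += 1
            if ui + p > len(u):
                u = rng.random(len(u))
                ui = 0
    if n == 0:
        out = np.zeros((0, p), dtype=np.int64)
    return ItemDataset(schema=schema, values=out.astype(float))


def sample_dataset(
    net: TrueNetwork,
    schema: ItemSchema,
    n: int,
    model: str = "copula",
    seed: Optional[int] = None,
    **kwargs,
) -> ItemDataset:
    """Dispatch to one of the two samplers by name."""
    if model == "copula":
        return sample_copula(net, schema, n, seed=seed, **kwargs)
    if model == "pairwise_count":
        return sample_pairwise_count(net, schema, n, seed=seed, **kwargs)
    raise ValueError(f"unknown generator model {model!r}")


def write_truth_tsv(net: TrueNetwork, node_labels, path) -> None:
    """Write the true edge list as TSV (node_a, node_b, weight)."""
    import pandas as pd

    i, j = np.nonzero(np.triu(net.weights, k=1))
    pd.DataFrame(
        {
            "node_a": [node_labels[a] for a in i],
            "node_b": [node_labels[b] for b in j],
            "weight": net.weights[i, j],
        }
    ).to_csv(path, sep="\t", index=False)
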