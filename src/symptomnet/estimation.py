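"""Mixed-graph estimation by regularized nodewise Poisson regressions.

Each item (a count-valued node) is regressed on all remaining items with
an l1 penalty along a decreasing lambda path; the model at each node is
selected by the extended BIC (EBIC, gamma = 0.25 by default), and nodewise
coefficients are combined into a symmetric weighted network with the AND
rule (an edge requires both directed coefficients nonzero; its weight is
their mean).  Predictors are standardized, so edge weights are signed
Poisson regression weights on standardized data.

The module also provides network density, node predictability (R^2 from an
unpenalized refit on the selected neighbors) and the topological overlap
matrix used to flag near-redundant item pairs.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .data import ItemDataset
from .network import WeightedNetwork

_ETA_CLIP = 30.0


class EstimationError(RuntimeError):
    pass


@dataclass(frozen=True)
class EstimationConfig:
    """Settings for the nodewise Poisson lasso.

    gamma            EBIC hyperparameter (0 reduces to BIC).
    rule             'and' (conservative, default) or 'or' edge combination.
    n_lambda         number of path points, log-spaced down from lambda_max.
    lambda_min_ratio smallest lambda as a fraction of lambda_max.
    standardize      center/scale predictors to unit variance.
    refit            relaxed selection: score each support on the path by
                     the EBIC of its unpenalized ML refit (and report the
                     refit coefficients), so shrinkage does not bias model
                     choice; set False to score the penalized fit itself.
    """

    gamma: float = 0.25
    rule: str = "and"
    n_lambda: int = 50
    lambda_min_ratio: float = 0.01
    standardize: bool = True
    refit: bool = True
    tol: float = 1e-6
    max_iter: int = 1000

    def __post_init__(self) -> None:
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        if self.rule not in ("and", "or"):
            raise ValueError("rule must be 'and' or 'or'")
        if self.n_lambda < 2:
            raise ValueError("n_lambda must be >= 2")
        if not 0 < self.lambda_min_ratio < 1:
            raise ValueError("lambda_min_ratio must be in (0, 1)")


def ebic(
    loglik: float, df: float, n: int, p_candidates: int, gamma: float
) -> float:
    """Extended BIC: -2 loglik + df log n + 2 gamma df log(candidates)."""
    return -2.0 * loglik + df * math.log(n) + 2.0 * gamma * df * math.log(p_candidates)


def _soft(v: np.ndarray, t: float) -> np.ndarray:
    return np.sign(v) * np.maximum(np.abs(v) - t, 0.0)


def _poisson_loss(eta: np.ndarray, y: np.ndarray) -> float:
    """Mean negative log-likelihood kernel: mean(exp(eta) - y*eta)."""
    return float(np.mean(np.exp(eta) - y * eta))


def _fista(
    X: np.ndarray,
    y: np.ndarray,
    lam: float,
    b0: float,
    b: np.ndarray,
    step: float,
    tol: float,
    max_iter: int,
) -> tuple[float, np.ndarray, float, bool]:
    """Proximal-gradient (FISTA) solve of one l1-penalized Poisson fit.

    Minimizes mean(exp(eta) - y eta) + lam * ||b||_1 with eta = b0 + X b;
    the intercept is unpenalized.  Backtracking line search handles the
    non-global Lipschitz gradient of the exponential; momentum restarts on
    objective increase keep the iteration monotone.
    """
    n = len(y)
    z0, z = b0, b.copy()
    bp0, bp = b0, b.copy()
    t_mom = 1.0
    prev_obj = np.inf
    converged = False
    for _ in range(max_iter):
        eta = np.clip(z0 + X @ z, -_ETA_CLIP, _ETA_CLIP)
        mu = np.exp(eta)
        r = mu - y
        g = X.T @ r / n
        g0 = float(r.mean())
        loss_z = float(np.mean(mu - y * eta))
        while True:
            nb = _soft(z - step * g, step * lam)
            nb0 = z0 - step * g0
            d, d0 = nb - z, nb0 - z0
            eta_n = np.clip(nb0 + X @ nb, -_ETA_CLIP, _ETA_CLIP)
            loss_n = float(np.mean(np.exp(eta_n) - y * eta_n))
            quad = loss_z + g @ d + g0 * d0 + (d @ d + d0 * d0) / (2.0 * step)
            if loss_n <= quad + 1e-12 or step < 1e-12:
                break
            step *= 0.5
        obj = loss_n + lam * float(np.abs(nb).sum())
        if obj > prev_obj + 1e-12:  # adaptive restart
            t_mom = 1.0
            z0, z = nb0, nb.copy()
        prev_obj = min(prev_obj, obj)
        db = np.max(np.abs(nb - bp)) if len(nb) else 0.0
        scale = max(1.0, np.max(np.abs(nb), initial=0.0))
        if db < tol * scale and abs(nb0 - bp0) < tol * max(1.0, abs(nb0)):
            bp0, bp = nb0, nb
            converged = True
            break
        t_new = 0.5 * (1.0 + math.sqrt(1.0 + 4.0 * t_mom * t_mom))
        mom = (t_mom - 1.0) / t_new
        z = nb + mom * (nb - bp)
        z0 = nb0 + mom * (nb0 - bp0)
        t_mom = t_new
        bp0, bp = nb0, nb
        step *= 1.25
    return bp0, bp, step, converged


def _poisson_ml_refit(
    Z: np.ndarray,
    y: np.ndarray,
    b0: float,
    b: np.ndarray,
    tol: float = 1e-9,
    max_iter: int = 60,
) -> tuple[float, np.ndarray, bool]:
    """Unpenalized Poisson ML on the given columns (Newton, warm-started)."""
    n = len(y)
    beta = np.concatenate([[b0], b])
    D = np.column_stack([np.ones(n), Z])
    for _ in range(max_iter):
        eta = np.clip(D @ beta, -_ETA_CLIP, _ETA_CLIP)
        mu = np.exp(eta)
        grad = D.T @ (y - mu)
        H = (D * mu[:, None]).T @ D
        H[np.diag_indices_from(H)] += 1e-9
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            return b0, b, False
        # damped Newton: halve until the log-likelihood does not decrease
        ll_old = float(y @ eta - mu.sum())
        t = 1.0
        for _ in range(30):
            cand = beta + t * step
            eta_c = np.clip(D @ cand, -_ETA_CLIP, _ETA_CLIP)
            ll_new = float(y @ eta_c - np.exp(eta_c).sum())
            if ll_new >= ll_old - 1e-12:
                break
            t *= 0.5
        beta = beta + t * step
        if np.max(np.abs(t * step)) < tol * max(1.0, np.max(np.abs(beta))):
            return float(beta[0]), beta[1:], True
    return float(beta[0]), beta[1:], False


@dataclass(frozen=True)
class NodeFit:
    """Lambda path of one nodewise regression with EBIC bookkeeping.

    ``coefs`` holds the penalized path solutions; when the config asks for
    relaxed selection, ``refit_coefs``/``refit_intercepts`` hold the ML
    refits on each path support and EBIC is computed from those.
    """

    node: int
    predictor_idx: np.ndarray
    lambdas: np.ndarray
    intercepts: np.ndarray
    coefs: np.ndarray  # n_lambda x n_predictors, on the standardized scale
    loglik: np.ndarray
    df: np.ndarray
    ebic: np.ndarray
    converged: np.ndarray
    selected: int
    refit_intercepts: Optional[np.ndarray] = None
    refit_coefs: Optional[np.ndarray] = None

    @property
    def selected_coefs(self) -> np.ndarray:
        if self.refit_coefs is not None:
            return self.refit_coefs[self.selected]
        return self.coefs[self.selected]


def _standardized_predictors(
    X: np.ndarray, cols: Sequence[int]
) -> tuple[np.ndarray, np.ndarray]:
    """Center/scale columns; zero-variance predictors are dropped."""
    Z = X[:, cols].astype(float)
    sd = Z.std(axis=0)
    keep = sd > 0
    if not keep.all():
        dropped = [cols[k] for k in np.flatnonzero(~keep)]
        warnings.warn(f"dropping zero-variance predictors {dropped}", stacklevel=3)
    Z = Z[:, keep]
    Z = (Z - Z.mean(axis=0)) / Z.std(axis=0)
    return Z, np.asarray(cols)[keep]


def fit_node(
    ds: ItemDataset, j: int, cfg: EstimationConfig = EstimationConfig()
) -> NodeFit:
    """l1-penalized Poisson path of item j on all other items."""
    X = ds.counts_matrix().astype(float)
    return _fit_node_matrix(X, j, cfg)


def _fit_node_matrix(X: np.ndarray, j: int, cfg: EstimationConfig) -> NodeFit:
    n, p = X.shape
    if n < 2:
        raise EstimationError("need at least 2 subjects")
    y = X[:, j]
    if y.std() == 0:
        raise EstimationError(f"target item {j} has zero variance")
    others = [k for k in range(p) if k != j]
    if cfg.standardize:
        Z, pred_idx = _standardized_predictors(X, others)
    else:
        Z, pred_idx = X[:, others].astype(float), np.asarray(others)
    d = Z.shape[1]
    ybar = y.mean()
    b0 = math.log(ybar) if ybar > 0 else -_ETA_CLIP
    lam_max = float(np.max(np.abs(Z.T @ (y - ybar)) / n)) if d else 1.0
    lam_max = max(lam_max, 1e-10)
    lambdas = np.geomspace(lam_max, lam_max * cfg.lambda_min_ratio, cfg.n_lambda)
    coefs = np.zeros((cfg.n_lambda, d))
    intercepts = np.zeros(cfg.n_lambda)
    loglik = np.zeros(cfg.n_lambda)
    dfs = np.zeros(cfg.n_lambda, dtype=int)
    conv = np.zeros(cfg.n_lambda, dtype=bool)
    b = np.zeros(d)
    step = 1.0
    log_yfact = float(gammaln(y + 1).sum())
    refit_b0 = np.zeros(cfg.n_lambda) if cfg.refit else None
    refit_b = np.zeros((cfg.n_lambda, d)) if cfg.refit else None
    refit_cache: dict[tuple, tuple] = {}
    for k, lam in enumerate(lambdas):
        b0, b, step, ok = _fista(Z, y, lam, b0, b, step, cfg.tol, cfg.max_iter)
        if not ok:
            warnings.warn(
                f"node {j}: path point {k} (lambda={lam:.4g}) did not fully "
                "converge",
                stacklevel=3,
            )
        coefs[k] = b
        intercepts[k] = b0
        conv[k] = ok
        dfs[k] = int(np.count_nonzero(b))
        if cfg.refit:
            support = tuple(np.flatnonzero(b))
            if support not in refit_cache:
                r0, rb, r_ok = _poisson_ml_refit(
                    Z[:, list(support)], y, b0, b[list(support)]
                )
                if not r_ok:  # separation etc.: keep the penalized fit
                    r0, rb = b0, b[list(support)]
                eta_r = np.clip(r0 + Z[:, list(support)] @ rb, -_ETA_CLIP, _ETA_CLIP)
                ll = float(y @ eta_r - np.exp(eta_r).sum()) - log_yfact
                refit_cache[support] = (r0, rb, ll)
            r0, rb, ll = refit_cache[support]
            refit_b0[k] = r0
            refit_b[k][list(support)] = rb
            loglik[k] = ll
        else:
            eta = np.clip(b0 + Z @ b, -_ETA_CLIP, _ETA_CLIP)
            loglik[k] = float(y @ eta - np.exp(eta).sum()) - log_yfact
    p_cand = max(p - 1, 1)
    ebics = np.array(
        [ebic(loglik[k], dfs[k], n, p_cand, cfg.gamma) for k in range(cfg.n_lambda)]
    )
    # ties broken toward the largest lambda (most parsimonious path point)
    selected = int(np.argmin(ebics))
    return NodeFit(
        node=j,
        predictor_idx=pred_idx,
        lambdas=lambdas,
        intercepts=intercepts,
        coefs=coefs,
        loglik=loglik,
        df=dfs,
        ebic=ebics,
        converged=conv,
        selected=selected,
        refit_intercepts=refit_b0,
        refit_coefs=refit_b,
    )


def estimate_network(
    ds: ItemDataset, cfg: EstimationConfig = EstimationConfig()
) -> WeightedNetwork:
    """Fit every node and combine nodewise coefficients into a network.

    AND rule: edge (i, j) present iff both coefficient(i->j) and
    coefficient(j->i) are nonzero; weight = mean of the two.  OR rule:
    present if either is nonzero; weight = mean over the nonzero ones.
    """
    X = ds.counts_matrix().astype(float)
    n, p = X.shape
    constant = [ds.item_ids[k] for k in range(p) if X[:, k].std() == 0]
    if constant:
        raise EstimationError(f"constant items cannot be estimated: {constant}")
    B = np.zeros((p, p))  # B[j, k] = coefficient of predictor k in node j's fit
    for j in range(p):
        fit = _fit_node_matrix(X, j, cfg)
        B[j, fit.predictor_idx] = fit.selected_coefs
    W = np.zeros((p, p))
    for i in range(p):
        for j in range(i + 1, p):
            a, b = B[i, j], B[j, i]
            if cfg.rule == "and":
                w = 0.5 * (a + b) if (a != 0 and b != 0) else 0.0
            else:
                nz = [v for v in (a, b) if v != 0]
                w = float(np.mean(nz)) if nz else 0.0
            W[i, j] = W[j, i] = w
    return WeightedNetwork(
        node_labels=tuple(ds.item_ids),
        weights=W,
        provenance={
            "n_subjects": n,
            "gamma": cfg.gamma,
            "rule": cfg.rule,
            "n_lambda": cfg.n_lambda,
            "lambda_min_ratio": cfg.lambda_min_ratio,
        },
    )


def density(net: WeightedNetwork) -> float:
    """Fraction of possible edges present (p(p-1)/2 possible pairs)."""
    return net.density()


# -------------------------------------------------------- predictability
def classify_predictability(r2: float) -> str:
    """Bands: high if R^2 > 0.5, moderate if 0.15 < R^2 <= 0.5, else low."""
    if r2 > 0.5:
        return "high"
    if r2 > 0.15:
        return "moderate"
    return "low"


def predictability(ds: ItemDataset, net: WeightedNetwork) -> pd.DataFrame:
    """Per-node explained variance from the selected neighbors.

    Each node is refit by an unpenalized Poisson regression on its network
    neighbors; R^2 = 1 - SS_res/SS_tot on the count scale, floored at 0.
    Nodes without neighbors get R^2 = 0 by convention.
    """
    import statsmodels.api as sm

    X = ds.counts_matrix().astype(float)
    rows = []
    for j, label in enumerate(net.node_labels):
        y = X[:, j]
        neigh = np.flatnonzero(net.weights[j])
        if len(neigh) == 0 or y.std() == 0:
            r2 = 0.0
        else:
            Z = X[:, neigh]
            Z = (Z - Z.mean(axis=0)) / np.where(Z.std(axis=0) > 0, Z.std(axis=0), 1.0)
            design = sm.add_constant(Z, has_constant="add")
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                try:
                    res = sm.GLM(y, design, family=sm.families.Poisson()).fit()
                    yhat = np.asarray(res.mu)
                except Exception:  # perfect separation etc.
                    yhat = np.full_like(y, y.mean())
            ss_res = float(((y - yhat) ** 2).sum())
            ss_tot = float(((y - y.mean()) ** 2).sum())
            r2 = max(0.0, 1.0 - ss_res / ss_tot) if ss_tot > 0 else 0.0
        rows.append(
            {
                "node": label,
                "r2": r2,
                "band": classify_predictability(r2),
                "n_neighbors": int(np.count_nonzero(net.weights[j])),
            }
        )
    return pd.DataFrame(rows).set_index("node")


# ---------------------------------------------------- topological overlap
def topological_overlap(net: WeightedNetwork) -> np.ndarray:
    """Topological overlap matrix on absolute weights, diagonal 1.

    TO(i,j) = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij) with
    a = |W| and k the row sums; values near 1 flag item pairs that share
    essentially the same neighborhood (candidate same-construct items).
    """
    a = net.abs_weights()
    k = a.sum(axis=1)
    num = a @ a + a
    denom = np.minimum.outer(k, k) + 1.0 - a
    with np.errstate(divide="ignore", invalid="ignore"):
        to = np.where(denom > 0, num / denom, 0.0)
    np.fill_diagonal(to, 1.0)
    return to


def flag_overlapping_pairs(
    net: WeightedNetwork, warn_level: float = 0.9
) -> pd.DataFrame:
    """Item pairs whose topological overlap exceeds the warning level."""
    to = topological_overlap(net)
    i, j = np.triu_indices(net.p, k=1)
    mask = to[i, j] > warn_level
    return pd.DataFrame(
        {
            "node_a": [net.node_labels[a] for a in i[mask]],
            "node_b": [net.node_labels[b] for b in j[mask]],
            "topological_overlap": to[i[mask], j[mask]],
        }
    ).sort_values("topological_overlap", ascending=False, ignore_index=True)
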