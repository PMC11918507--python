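"""Simulation-based power analysis for network estimation.

"Power" here is edge-detection sensitivity: for each replicate, a random
true network is drawn, a dataset of the candidate sample size is simulated
from it, the network is re-estimated, and sensitivity (true edges
recovered / true edges) and specificity (true non-edges kept empty / true
non-edges) are scored.  The headline figure is the across-replicate
probability that sensitivity exceeds a stated threshold — the design point
of interest being a 52-node network with density 0.08 and edge weights in
(0, 0.3], where n = 634 should give sensitivity > 0.5 with probability at
least 0.8.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .estimation import EstimationConfig, EstimationError, estimate_network
from .schema import ItemSchema, analysis_schema, uniform_schema
from .synthetic import GenerationError, generate_network, sample_dataset

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PowerConfig:
    """Design of a power run (one row of conditions per n in ``n_grid``)."""

    p: int = 52
    density: float = 0.08
    weight_low: float = 0.0
    weight_high: float = 0.3
    n_grid: tuple[int, ...] = (634,)
    networks_per_condition: int = 10
    datasets_per_network: int = 1
    model: str = "copula"
    sensitivity_threshold: float = 0.5
    schema: Optional[ItemSchema] = None
    estimation: EstimationConfig = field(default_factory=EstimationConfig)
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if min(self.networks_per_condition, self.datasets_per_network) < 1:
            raise ValueError("replicate counts must be >= 1")
        if list(self.n_grid) != sorted(self.n_grid):
            raise ValueError("n_grid must be ascending")

    def resolve_schema(self) -> ItemSchema:
        if self.schema is not None:
            return self.schema
        if self.p == 52:
            return analysis_schema("male")
        return uniform_schema(self.p)


@dataclass(frozen=True)
class PowerResult:
    """Replicate-level scores and per-condition summaries."""

    replicates: pd.DataFrame  # n, network_seed, sensitivity, specificity
    summary: pd.DataFrame  # per n: mean/quantiles of sensitivity, Pr(exceed)
    config: PowerConfig


def score_recovery(true_mask: np.ndarray, est_mask: np.ndarray) -> tuple[float, float]:
    """(sensitivity, specificity) of estimated vs true edge sets.

    Sensitivity is NaN (undefined) when the true network has no edges.
    """
    n_true = int(true_mask.sum())
    n_null = int((~true_mask).sum())
    sens = float((true_mask & est_mask).sum() / n_true) if n_true else float("nan")
    spec = float((~true_mask & ~est_mask).sum() / n_null) if n_null else float("nan")
    return sens, spec


def run_power(cfg: PowerConfig) -> PowerResult:
    """Run the full power simulation described by ``cfg``."""
    schema = cfg.resolve_schema()
    if len(schema) != cfg.p:
        raise ValueError("schema item count must equal p")
    root = np.random.default_rng(cfg.seed)
    rows = []
    for n in cfg.n_grid:
        for rep in range(cfg.networks_per_condition):
            net_seed = int(root.integers(0, 2**31 - 1))
            truth = generate_network(
                cfg.p, cfg.density, cfg.weight_low, cfg.weight_high, seed=net_seed
            )
            true_mask = truth.edge_mask()
            for ds_rep in range(cfg.datasets_per_network):
                data_seed = int(root.integers(0, 2**31 - 1))
                try:
                    ds = sample_dataset(
                        truth, schema, n, model=cfg.model, seed=data_seed
                    )
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        est = estimate_network(ds, cfg.estimation)
                except (EstimationError, GenerationError) as exc:
                    logger.warning(
                        "replicate failed (n=%d, net_seed=%d, data_seed=%d): %s",
                        n,
                        net_seed,
                        data_seed,
                        exc,
                    )
                    continue
                sens, spec = score_recovery(true_mask, est.edge_mask())
                rows.append(
                    {
                        "n": n,
                        "network_rep": rep,
                        "dataset_rep": ds_rep,
                        "network_seed": net_seed,
                        "data_seed": data_seed,
                        "n_true_edges": int(true_mask.sum()),
                        "sensitivity": sens,
                        "specificity": spec,
                    }
                )
    replicates = pd.DataFrame(rows)
    summaries = []
    for n in cfg.n_grid:
        sub = replicates[replicates["n"] == n]
        sens = sub["sensitivity"].dropna()
        spec = sub["specificity"].dropna()
        summaries.append(
            {
                "n": n,
                "n_replicates": len(sub),
                "mean_sensitivity": sens.mean() if len(sens) else float("nan"),
                "sensitivity_q20": sens.quantile(0.2) if len(sens) else float("nan"),
                "sensitivity_q50": sens.quantile(0.5) if len(sens) else float("nan"),
                "mean_specificity": spec.mean() if len(spec) else float("nan"),
                "pr_sensitivity_exceeds": (
                    float((sens > cfg.sensitivity_threshold).mean())
                    if len(sens)
                    else float("nan")
                ),
            }
        )
    summary = pd.DataFrame(summaries).set_index("n")
    return PowerResult(replicates=replicates, summary=summary, config=cfg)
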