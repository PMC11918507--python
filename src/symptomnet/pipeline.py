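"""End-to-end pipeline: filter -> estimate -> describe -> resample -> cluster.

:func:`run_pipeline` chains the analysis stages on one dataset and writes
a report bundle to an output directory: adjacency matrix (CSV, full
precision), edge list with bootstrap CIs (TSV), node statistics (TSV),
cluster quality (TSV), a plain-text summary, and the exact configuration
that produced them (JSON).  Outputs are deterministic under the seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .centrality import centrality_table
from .community import bridge_nodes, cluster_quality, slm_partition
from .data import (
    ItemDataset,
    drop_sex_specific,
    euthymia_filter,
    read_dataset,
    scale_descriptives,
)
from .estimation import (
    EstimationConfig,
    estimate_network,
    flag_overlapping_pairs,
    predictability,
)
from .stability import bootstrap_edges, casedrop_stability, interpret_cs

logger = logging.getLogger(__name__)

FLOAT_FMT = "%.6g"


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to reproduce one pipeline run."""

    sex: Optional[str] = None
    madrs_max: float = 10
    ymrs_max: float = 12
    estimation: EstimationConfig = field(default_factory=EstimationConfig)
    bootstrap_B: int = 1000
    stability_subsamples: int = 2500
    slm_restarts: int = 20
    bridge_top_k: int = 5
    distance: str = "inverse_weight"
    overlap_warn_level: float = 0.9
    seed: int = 0
    run_bootstrap: bool = True
    run_stability: bool = True

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["package_version"] = __version__
        return d


class PipelineError(RuntimeError):
    def __init__(self, stage: str, seed: int, cause: Exception):
        super().__init__(f"stage {stage!r} failed (seed={seed}): {cause}")
        self.stage = stage


def run_pipeline(ds: ItemDataset, cfg: RunConfig, out_dir) -> dict:
    """Run all stages on ``ds`` and write the report bundle to ``out_dir``.

    Returns a dict of in-memory results keyed by stage.  On stage failure
    a FAILED marker naming the stage is left next to any partial outputs.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "FAILED").unlink(missing_ok=True)  # clear stale marker from reruns
    (out / "config.json").write_text(json.dumps(cfg.to_dict(), indent=1))
    results: dict = {}
    stage = "prepare"
    try:
        work = ds.drop_missing()
        if cfg.sex is not None:
            work = drop_sex_specific(work, cfg.sex)
            if work.sex is not None:
                mask = np.array([s == cfg.sex for s in work.sex])
                work = work.select_subjects(mask)
        work = euthymia_filter(work, cfg.madrs_max, cfg.ymrs_max)
        results["dataset"] = work

        stage = "descriptives"
        desc = scale_descriptives(work)
        desc.totals.to_csv(out / "scale_totals.tsv", sep="\t", float_format=FLOAT_FMT)
        desc.spearman.to_csv(
            out / "scale_spearman.tsv", sep="\t", float_format=FLOAT_FMT
        )
        results["descriptives"] = desc

        stage = "estimate"
        net = estimate_network(work, cfg.estimation)
        net.to_adjacency_csv(out / "adjacency.csv")
        results["network"] = net

        stage = "node_statistics"
        stats = centrality_table(net, cfg.distance)
        stats["r2"] = predictability(work, net)["r2"]
        results["overlap_warnings"] = flag_overlapping_pairs(
            net, cfg.overlap_warn_level
        )

        stage = "bootstrap"
        edge_table = net.edge_list()
        if cfg.run_bootstrap:
            boot = bootstrap_edges(
                work, cfg.estimation, B=cfg.bootstrap_B, seed=cfg.seed
            )
            results["bootstrap"] = boot
            edge_table = boot.table
        edge_table.to_csv(
            out / "edges.tsv", sep="\t", index=False, float_format=FLOAT_FMT
        )

        stage = "stability"
        if cfg.run_stability:
            stab = casedrop_stability(
                work,
                cfg.estimation,
                n_subsamples=cfg.stability_subsamples,
                seed=cfg.seed + 1,
            )
            results["stability"] = stab
            stab.retention.to_csv(
                out / "stability_retention.tsv", sep="\t", float_format=FLOAT_FMT
            )

        stage = "cluster"
        part = slm_partition(net, restarts=cfg.slm_restarts, seed=cfg.seed + 2)
        quality = cluster_quality(net, part)
        bridges = bridge_nodes(net, part, top_k=cfg.bridge_top_k)
        results["partition"] = part
        results["quality"] = quality
        results["bridges"] = bridges
        stats["cluster"] = part.labels
        stats["bridge_strength"] = bridges.table["bridge_strength"]
        stats["stabilizing_index"] = bridges.table["stabilizing_index"]
        stats["bridge_node"] = bridges.table["bridge_node"]
        stats.to_csv(out / "node_statistics.tsv", sep="\t", float_format=FLOAT_FMT)
        quality.per_cluster.to_csv(
            out / "cluster_quality.tsv", sep="\t", float_format=FLOAT_FMT
        )
        results["node_statistics"] = stats

        stage = "summary"
        lines = [
            f"symptomnet {__version__} pipeline summary",
            f"seed: {cfg.seed}",
            f"subjects analyzed: {work.n_subjects}",
            f"nodes: {net.p}",
            f"edges: {net.n_edges}/{net.n_possible_edges} possible pairs",
            f"density: {net.density():.4f}",
        ]
        if "bootstrap" in results:
            boot = results["bootstrap"]
            lines.append(
                "significant edges (95% CI excludes 0): "
                f"{int(boot.table['significant'].sum())} "
                f"({100 * boot.fraction_significant:.1f}% of detected edges; "
                f"effective B = {boot.effective_B})"
            )
        if "stability" in results:
            stab = results["stability"]
            for name, cs in stab.cs.items():
                lines.append(f"CS({name}) = {cs:.2f} ({interpret_cs(cs)})")
        lines.append(f"clusters: {part.n_clusters} (modularity Q = {part.modularity:.4f})")
        lines.append(
            f"conductance = {quality.conductance:.4f}, coverage = {quality.coverage:.4f}"
        )
        (out / "summary.txt").write_text("\n".join(lines) + "\n")
        results["summary"] = lines
    except Exception as exc:
        (out / "FAILED").write_text(f"stage={stage} seed={cfg.seed} error={exc}\n")
        raise PipelineError(stage, cfg.seed, exc) from exc
    return results


def run_pipeline_from_files(
    csv_path, schema_path, cfg: RunConfig, out_dir
) -> dict:
    ds = read_dataset(csv_path, schema_path)
    return run_pipeline(ds, cfg, out_dir)
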