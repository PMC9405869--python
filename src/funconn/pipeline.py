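"""End-to-end orchestration: simulate/ingest → networks → metrics → inference.

The pipeline runs, per parcellation spec, the full chain: node time series →
Pearson connectivity → proportional-threshold sweep → the six graph
parameters per threshold → AUC aggregation and hub classification → paired
pre/post inference (Bonferroni, m = 6) → threshold-subset stability. All
randomness (synthetic cohorts, null ensembles, modularity restarts) derives
from one global seed, so a run is idempotent: the same config produces
byte-identical result files.

Atlas geometry is out of scope: a parcellation is abstracted to a node
count plus the index of the target node (the analogue of picking the
region of interest in each atlas). Users with real data supply node x
timepoint matrices via a manifest CSV.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .aggregate import auc_table, classify_hubs
from .connectivity import (
    ThresholdGrid,
    default_threshold_grid,
    pearson_connectivity,
    proportional_threshold,
)
from .inference import analyze_metrics, run_stability_analysis
from .metrics import (
    NullEnsembleConfig,
    degree_centrality,
    local_efficiency,
    modularity,
    nodal_efficiency,
    shortest_path_distances,
    small_worldness_robust,
)
from .synthetic import SyntheticConfig, TimeSeriesPanel, read_panel, simulate_panel

logger = logging.getLogger(__name__)

__all__ = [
    "ParcellationSpec",
    "RunConfig",
    "compute_metric_table",
    "small_world_screen",
    "run_pipeline",
]


@dataclass(frozen=True)
class ParcellationSpec:
    """A parcellation abstracted to its size and target-node index."""

    name: str
    n_nodes: int
    target_node: int

    def __post_init__(self) -> None:
        if self.n_nodes < 3:
            raise ValueError("a parcellation needs at least 3 nodes")
        if not (0 <= self.target_node < self.n_nodes):
            raise ValueError("target_node out of range for parcellation")


@dataclass
class RunConfig:
    """Everything one pipeline run needs; exactly one input source."""

    synthetic: SyntheticConfig | None = None
    manifest: str | None = None
    parcellations: list[ParcellationSpec] = field(
        default_factory=lambda: [ParcellationSpec("aal116", 116, 0)]
    )
    grid: ThresholdGrid = field(default_factory=default_threshold_grid)
    null_ensemble: NullEnsembleConfig = field(
        default_factory=lambda: NullEnsembleConfig(n_random=10, n_swaps_per_edge=5)
    )
    modularity_restarts: int = 3
    output_dir: str = "results"
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.synthetic is None) == (self.manifest is None):
            raise ValueError("supply exactly one of synthetic config or manifest path")
        if self.manifest is not None and len(self.parcellations) != 1:
            raise ValueError("manifest input supports a single parcellation spec")

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        kwargs: dict = {}
        if "synthetic" in raw and raw["synthetic"] is not None:
            kwargs["synthetic"] = SyntheticConfig(**raw["synthetic"])
        if raw.get("manifest"):
            kwargs["manifest"] = raw["manifest"]
        if "parcellations" in raw:
            kwargs["parcellations"] = [ParcellationSpec(**p) for p in raw["parcellations"]]
        if "grid" in raw:
            g = raw["grid"]
            if isinstance(g, dict):
                props = tuple(
                    round(g["start"] + g["step"] * k, 10)
                    for k in range(int(round((g["stop"] - g["start"]) / g["step"])) + 1)
                )
                kwargs["grid"] = ThresholdGrid(props)
            else:
                kwargs["grid"] = ThresholdGrid(tuple(g))
        if "null_ensemble" in raw:
            ne = raw["null_ensemble"]
            kwargs["null_ensemble"] = NullEnsembleConfig(
                n_random=ne.get("n_random", 10),
                n_swaps_per_edge=ne.get("swaps", 5),
                seed=ne.get("seed", 0),
            )
        if "modularity" in raw:
            kwargs["modularity_restarts"] = raw["modularity"].get("restarts", 3)
        for key in ("output_dir", "seed"):
            if key in raw:
                kwargs[key] = raw[key]
        return cls(**kwargs)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Load a YAML (or JSON, a YAML subset) config file."""
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def compute_metric_table(
    panel: TimeSeriesPanel,
    grid: ThresholdGrid,
    target_node: int,
    null_cfg: NullEnsembleConfig | None = None,
    modularity_restarts: int = 3,
    seed: int = 0,
    keep_networks_dir: str | Path | None = None,
) -> pd.DataFrame:
    """Tidy per-threshold metric table for one panel.

    Columns: subject, session, threshold, parameter, node (NaN for global
    parameters), value. Contains the three global parameters, the target
    node's nodal and local efficiency, and degree centrality for every node
    (input to hub classification). Small-Worldness is skipped when
    ``null_cfg`` is None.
    """
    rows: list[dict] = []
    for si, sub in enumerate(panel.subjects):
        for zi, ses in enumerate(panel.sessions):
            conn = pearson_connectivity(panel.series[(sub, ses)])
            for ti, prop in enumerate(grid):
                net = proportional_threshold(conn, prop)
                if keep_networks_dir is not None:
                    out = Path(keep_networks_dir)
                    out.mkdir(parents=True, exist_ok=True)
                    np.savetxt(
                        out / f"{sub}_ses-{ses}_p{int(round(prop * 100)):02d}.tsv",
                        net.weights,
                        delimiter="\t",
                    )
                cell_seed = (seed * 2_654_435 + si * 8_191 + zi * 131 + ti) % (2**31 - 1)
                dist = shortest_path_distances(net)
                n = net.n_nodes
                with np.errstate(divide="ignore"):
                    inv = 1.0 / dist
                inv[~np.isfinite(inv)] = 0.0
                np.fill_diagonal(inv, 0.0)
                e_glob = float(inv.sum() / (n * (n - 1)))
                e_nodal = float(inv[target_node].sum() / (n - 1))
                q, _ = modularity(net, seed=cell_seed, restarts=modularity_restarts)
                record = [
                    ("global_efficiency", np.nan, e_glob),
                    ("modularity", np.nan, q),
                    ("nodal_efficiency", float(target_node), e_nodal),
                    (
                        "local_efficiency",
                        float(target_node),
                        local_efficiency(net, target_node),
                    ),
                ]
                if null_cfg is not None:
                    sigma_cfg = NullEnsembleConfig(
                        n_random=null_cfg.n_random,
                        n_swaps_per_edge=null_cfg.n_swaps_per_edge,
                        seed=cell_seed,
                    )
                    record.append(
                        ("small_worldness", np.nan, small_worldness_robust(net, sigma_cfg))
                    )
                strengths = degree_centrality(net)
                base = {"subject": sub, "session": ses, "threshold": prop}
                for param, node, value in record:
                    rows.append({**base, "parameter": param, "node": node, "value": value})
                for node_idx, s in enumerate(strengths):
                    rows.append(
                        {
                            **base,
                            "parameter": "degree_centrality",
                            "node": float(node_idx),
                            "value": float(s),
                        }
                    )
    return pd.DataFrame(rows)


def small_world_screen(metrics: pd.DataFrame) -> dict:
    """Realism screen: how many constructed networks have sigma < 1."""
    sw = metrics[metrics["parameter"] == "small_worldness"]["value"]
    n_total = int(sw.size)
    n_below = int((sw < 1).sum())
    return {
        "n_networks": n_total,
        "n_below_one": n_below,
        "fraction_below_one": (n_below / n_total) if n_total else float("nan"),
    }


def _results_to_frame(results) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(r) for r in results])


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; write result CSVs, a run summary and a log.

    Returns the run-summary dict (also written to ``run_summary.json``).
    """
    t0 = time.time()
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    summary: dict = {
        "funconn_version": __version__,
        "seed": config.seed,
        "grid": list(config.grid),
        "n_thresholds": len(config.grid),
        "null_ensemble": dataclasses.asdict(config.null_ensemble),
        "modularity_restarts": config.modularity_restarts,
        "parcellations": {},
    }
    stability_inputs: dict = {}
    primary_results = None
    for pi, spec in enumerate(config.parcellations):
        stage = f"parcellation {spec.name}"
        logger.info("simulate/ingest: %s", stage)
        if config.synthetic is not None:
            syn = replace(
                config.synthetic,
                n_nodes=spec.n_nodes,
                target_node=spec.target_node,
                seed=(config.seed * 10_007 + pi) % (2**31 - 1),
            )
            panel = simulate_panel(syn)
        else:
            panel = read_panel(config.manifest)
            if panel.n_nodes != spec.n_nodes:
                raise ValueError(
                    f"{stage}: manifest matrices have {panel.n_nodes} nodes, "
                    f"spec says {spec.n_nodes}"
                )
        t_stage = time.time()
        metrics = compute_metric_table(
            panel,
            config.grid,
            spec.target_node,
            null_cfg=config.null_ensemble,
            modularity_restarts=config.modularity_restarts,
            seed=config.seed + pi,
        )
        logger.info("%s: metrics in %.1fs", stage, time.time() - t_stage)
        metrics.to_csv(out_dir / f"metrics_{spec.name}.csv", index=False)
        n_networks = len(panel.subjects) * len(panel.sessions) * len(config.grid)
        screen = small_world_screen(metrics)
        summary["parcellations"][spec.name] = {
            "n_subjects": len(panel.subjects),
            "n_sessions": len(panel.sessions),
            "n_networks": n_networks,
            "small_world_screen": screen,
        }
        stability_inputs[spec.name] = (metrics, config.grid, spec.target_node)
        if pi == 0:
            dc = metrics[metrics["parameter"] == "degree_centrality"]
            hubs = classify_hubs(dc[["subject", "session", "threshold", "node", "value"]])
            curves = metrics[metrics["parameter"] != "degree_centrality"]
            aucs = auc_table(curves, config.grid)
            aucs.to_csv(out_dir / f"auc_{spec.name}.csv", index=False)
            hubs.counts.to_csv(out_dir / f"hub_counts_{spec.name}.csv", index=False)
            primary_results = analyze_metrics(metrics, config.grid, spec.target_node, m=6)
            _results_to_frame(primary_results).to_csv(
                out_dir / "primary_results.csv", index=False
            )
    stability = run_stability_analysis(stability_inputs)
    stability.to_csv(out_dir / "stability.csv", index=False)
    summary["primary"] = [dataclasses.asdict(r) for r in primary_results]
    summary["runtime_s"] = round(time.time() - t0, 2)
    with open(out_dir / "run_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    logger.info("pipeline done in %.1fs", summary["runtime_s"])
    return summary
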