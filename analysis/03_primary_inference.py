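#!/usr/bin/env python
"""Paired pre/post inference on the six parameters, Bonferroni-corrected.

Collapses the per-threshold metric curves to AUCs, classifies hubs from the
pooled degree-centrality distribution, and runs the six dependent tests
(m = 6). Also draws the threshold-curve figure (group mean ± SD per session
per parameter) that makes the AUC comparison visible.

Run from the repository root after 02:  python analysis/03_primary_inference.py
"""

import dataclasses
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from funconn.aggregate import classify_hubs
from funconn.connectivity import default_threshold_grid
from funconn.inference import analyze_metrics
from funconn.synthetic import SyntheticConfig

TARGET = SyntheticConfig().target_node


def curve_figure(metrics: pd.DataFrame, out: Path) -> None:
    params = ["global_efficiency", "modularity", "small_worldness",
              "nodal_efficiency", "local_efficiency"]
    fig, axes = plt.subplots(1, 5, figsize=(18, 3.2), sharex=True)
    for ax, param in zip(axes, params):
        sub = metrics[metrics["parameter"] == param]
        for ses, color in (("pre", "tab:blue"), ("post", "tab:red")):
            g = sub[sub["session"] == ses].groupby("threshold")["value"]
            mean, sd = g.mean(), g.std()
            ax.plot(mean.index, mean, color=color, label=ses)
            ax.fill_between(mean.index, mean - sd, mean + sd, color=color, alpha=0.2)
        ax.set_title(param.replace("_", " "))
        ax.set_xlabel("edge retention")
    axes[0].legend()
    fig.tight_layout()
    fig.savefig(out, dpi=120)


def main() -> None:
    metrics = pd.read_csv("scratch/metrics_per_threshold.csv")
    grid = default_threshold_grid()
    results = analyze_metrics(metrics, grid, target_node=TARGET, m=6)
    table = pd.DataFrame([dataclasses.asdict(r) for r in results])
    Path("results").mkdir(exist_ok=True)
    table.to_csv("results/primary_results.csv", index=False)
    print(table.to_string(index=False, float_format=lambda v: f"{v:.4f}"))

    dc = metrics[metrics["parameter"] == "degree_centrality"]
    hubs = classify_hubs(dc[["subject", "session", "threshold", "node", "value"]])
    hubs.counts.to_csv("results/hub_counts.csv", index=False)
    print(f"\nhub cutoff = pooled mean + SD = {hubs.cutoff:.3f} "
          f"(mean {hubs.pooled_mean:.3f}, sd {hubs.pooled_sd:.3f})")
    print("mean hub count per session:")
    print(hubs.counts.groupby("session")["n_hubs"].mean().to_string())

    curve_figure(metrics, Path("scratch/threshold_curves.png"))
    print("\nwrote results/primary_results.csv, results/hub_counts.csv, "
          "scratch/threshold_curves.png")


if __name__ == "__main__":
    main()
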