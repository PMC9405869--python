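"""Threshold-curve aggregation (AUC) and hub classification.

Every graph parameter is computed once per threshold, giving a curve per
subject and session; group inference uses the area under that curve (AUC)
over the sparsity grid so no single arbitrary threshold drives the result.
Hubness bypasses AUCs: degree-centrality values from all nodes, thresholds,
subjects and both sessions are pooled into one distribution, and a node is
a hub wherever its value is at least one SD above the pooled mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .connectivity import ThresholdGrid

__all__ = ["MetricCurve", "AUCRecord", "HubTable", "curve_auc", "auc_table", "classify_hubs"]


@dataclass(frozen=True)
class MetricCurve:
    """One parameter's per-threshold values for one subject/session."""

    subject: str
    session: str
    parameter: str
    values: tuple[float, ...]
    node: int | None = None


@dataclass(frozen=True)
class AUCRecord:
    subject: str
    session: str
    parameter: str
    auc: float
    node: int | None = None


@dataclass
class HubTable:
    """Pooled degree-centrality distribution with cutoff-based hub flags.

    ``table`` holds one row per (subject, session, threshold, node) with the
    degree-centrality ``value`` and boolean ``hub`` flag; ``counts`` one row
    per (subject, session) with the summed hub count over nodes and
    thresholds. ``cutoff = mean + sd`` of the pooled distribution (sample
    SD, both sessions combined).
    """

    table: pd.DataFrame
    counts: pd.DataFrame
    pooled_mean: float
    pooled_sd: float
    cutoff: float


def curve_auc(curve: MetricCurve | np.ndarray, grid: ThresholdGrid) -> float | AUCRecord:
    """Trapezoidal area under a metric curve against the threshold grid.

    Accepts either a bare value array (returns a float) or a
    :class:`MetricCurve` (returns an :class:`AUCRecord`).
    """
    if isinstance(curve, MetricCurve):
        values = np.asarray(curve.values, dtype=float)
    else:
        values = np.asarray(curve, dtype=float)
    x = np.asarray(list(grid), dtype=float)
    if values.shape != x.shape:
        raise ValueError(f"curve length {values.size} does not match grid length {x.size}")
    if x.size < 2:
        raise ValueError("need at least 2 thresholds for an AUC")
    if not np.all(np.isfinite(values)):
        raise ValueError("curve contains non-finite values")
    auc = float(np.trapezoid(values, x))
    if isinstance(curve, MetricCurve):
        return AUCRecord(curve.subject, curve.session, curve.parameter, auc, curve.node)
    return auc


def auc_table(metrics: pd.DataFrame, grid: ThresholdGrid) -> pd.DataFrame:
    """Collapse a tidy per-threshold metric table to per-subject/session AUCs.

    ``metrics`` columns: subject, session, threshold, parameter, node
    (nullable), value. Rows are aligned to the grid by the threshold column;
    every (subject, session, parameter, node) group must cover the full grid.
    """
    props = np.asarray(list(grid), dtype=float)
    if props.size < 2:
        raise ValueError("need at least 2 thresholds for an AUC")
    out = []
    for (sub, ses, param, node), grp in metrics.groupby(
        ["subject", "session", "parameter", "node"], dropna=False, sort=True
    ):
        grp = grp.sort_values("threshold")
        th = grp["threshold"].to_numpy(dtype=float)
        if th.size != props.size or not np.allclose(th, props):
            raise ValueError(
                f"curve for {sub}/{ses}/{param} does not align with the threshold grid"
            )
        out.append(
            {
                "subject": sub,
                "session": ses,
                "parameter": param,
                "node": node,
                "auc": float(np.trapezoid(grp["value"].to_numpy(dtype=float), th)),
            }
        )
    return pd.DataFrame(out)


def classify_hubs(degree_values: pd.DataFrame) -> HubTable:
    """Flag hubs against the pooled pre+post degree-centrality distribution.

    ``degree_values`` columns: subject, session, threshold, node, value.
    The cutoff is ``mean + 1*SD`` (sample SD) of all values pooled across
    subjects, sessions, thresholds and nodes; a value is a hub when it is at
    least the cutoff (inclusive). Counts sum flags over nodes and thresholds
    within each subject/session.
    """
    vals = degree_values["value"].to_numpy(dtype=float)
    if vals.size < 2:
        raise ValueError("need at least 2 pooled degree-centrality values")
    mean = float(vals.mean())
    sd = float(vals.std(ddof=1))
    if sd == 0:
        raise ValueError("degenerate pooled degree-centrality distribution (SD = 0)")
    cutoff = mean + sd
    table = degree_values.copy()
    table["hub"] = table["value"] >= cutoff
    counts = (
        table.groupby(["subject", "session"], sort=True)["hub"]
        .sum()
        .rename("n_hubs")
        .reset_index()
    )
    return HubTable(table=table, counts=counts, pooled_mean=mean, pooled_sd=sd, cutoff=cutoff)
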