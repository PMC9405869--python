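"""Paired pre/post inference and the stability analysis.

Each of the six parameters (Global Efficiency, Modularity, Small-Worldness,
Hubness, and the target node's Nodal and Local Efficiency) is compared
between sessions with a dependent test on per-subject summary values (AUCs
over the threshold grid, hub counts for Hubness). Normality of the paired
differences is gated by a Shapiro–Wilk test at alpha = 0.05: normal
differences get a paired t-test, otherwise the Wilcoxon signed-rank test is
used as fallback (such cells are flagged, since W and t statistics are not
directly comparable). Multiplicity is handled by Bonferroni over the
six-parameter family. The stability analysis repeats the comparisons,
uncorrected, on the total / lower-half / upper-half threshold grids for
each parcellation.

Effect sizes are d_z = mean(diff) / SD(diff); an "average-variance"
alternative (mean diff over the pooled SD of pre and post) is available via
``effect_size="av"``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .aggregate import auc_table, classify_hubs
from .connectivity import ThresholdGrid

__all__ = [
    "PARAMETERS",
    "ComparisonResult",
    "paired_compare",
    "run_primary_analysis",
    "analyze_metrics",
    "threshold_subsets",
    "run_stability_analysis",
]

#: the fixed six-parameter family used for Bonferroni correction
PARAMETERS = (
    "global_efficiency",
    "modularity",
    "small_worldness",
    "hubness",
    "nodal_efficiency",
    "local_efficiency",
)

GLOBAL_PARAMETERS = ("global_efficiency", "modularity", "small_worldness")
NODAL_PARAMETERS = ("nodal_efficiency", "local_efficiency")


@dataclass(frozen=True)
class ComparisonResult:
    parameter: str
    test: str  # "paired-t" | "wilcoxon"
    statistic: float
    df: int | None
    p_raw: float
    p_corrected: float
    effect_size_d: float
    n_pairs: int


def paired_compare(
    pre: np.ndarray,
    post: np.ndarray,
    m: int = 1,
    parameter: str = "",
    normality_alpha: float = 0.05,
    effect_size: str = "dz",
) -> ComparisonResult:
    """Dependent two-sided comparison of post vs pre with Bonferroni over m.

    Differences are ``post - pre`` (positive statistic = increase after the
    intervention). Shapiro–Wilk on the differences decides between the
    paired t-test and the Wilcoxon signed-rank fallback.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape or pre.ndim != 1:
        raise ValueError("pre and post must be 1-d arrays of equal length")
    n = pre.size
    if n < 3:
        raise ValueError("need at least 3 pairs")
    diff = post - pre
    sd = diff.std(ddof=1)
    if sd == 0:
        raise ValueError(
            f"zero-variance paired differences for {parameter or 'parameter'}: "
            "t and d are undefined"
        )
    if effect_size == "dz":
        d = float(diff.mean() / sd)
    elif effect_size == "av":
        pooled = np.sqrt((pre.std(ddof=1) ** 2 + post.std(ddof=1) ** 2) / 2)
        d = float(diff.mean() / pooled)
    else:
        raise ValueError("effect_size must be 'dz' or 'av'")

    normal = stats.shapiro(diff).pvalue >= normality_alpha
    if normal:
        res = stats.ttest_rel(post, pre)
        test, statistic, df, p_raw = "paired-t", float(res.statistic), n - 1, float(res.pvalue)
    else:
        res = stats.wilcoxon(diff, zero_method="wilcox", alternative="two-sided", method="auto")
        test, statistic, df, p_raw = "wilcoxon", float(res.statistic), None, float(res.pvalue)
    return ComparisonResult(
        parameter=parameter,
        test=test,
        statistic=statistic,
        df=df,
        p_raw=p_raw,
        p_corrected=min(1.0, m * p_raw),
        effect_size_d=d,
        n_pairs=n,
    )


def _paired_vectors(
    table: pd.DataFrame, value_col: str, sessions: tuple[str, str] = ("pre", "post")
) -> tuple[np.ndarray, np.ndarray]:
    wide = table.pivot_table(index="subject", columns="session", values=value_col, sort=True)
    missing = wide.index[wide[list(sessions)].isna().any(axis=1)].tolist()
    if missing:
        raise ValueError(f"subjects missing a session: {missing}")
    return wide[sessions[0]].to_numpy(), wide[sessions[1]].to_numpy()


def run_primary_analysis(
    aucs: pd.DataFrame,
    hub_counts: pd.DataFrame,
    m: int = len(PARAMETERS),
    effect_size: str = "dz",
) -> list[ComparisonResult]:
    """The six Bonferroni-corrected paired comparisons.

    ``aucs``: tidy AUC table (subject, session, parameter, node, auc) holding
    the three global parameters plus the target node's nodal and local
    efficiency; ``hub_counts``: per-(subject, session) hub counts.
    """
    results = []
    for param in PARAMETERS:
        if param == "hubness":
            pre, post = _paired_vectors(hub_counts, "n_hubs")
        else:
            sub = aucs[aucs["parameter"] == param]
            if sub.empty:
                raise ValueError(f"no AUC rows for parameter {param}")
            pre, post = _paired_vectors(sub, "auc")
        results.append(
            paired_compare(pre, post, m=m, parameter=param, effect_size=effect_size)
        )
    return results


def analyze_metrics(
    metrics: pd.DataFrame,
    grid: ThresholdGrid,
    target_node: int,
    m: int = len(PARAMETERS),
    effect_size: str = "dz",
) -> list[ComparisonResult]:
    """AUC-collapse a tidy per-threshold metric table and run the six tests.

    ``metrics`` columns: subject, session, threshold, parameter, node, value;
    degree_centrality rows (one per node) feed hub classification, the other
    parameters are AUC-collapsed. Nodal and local efficiency rows must be for
    ``target_node``.
    """
    props = list(grid)
    metrics = metrics[metrics["threshold"].isin(props)]
    dc = metrics[metrics["parameter"] == "degree_centrality"]
    hubs = classify_hubs(dc[["subject", "session", "threshold", "node", "value"]])
    curves = metrics[metrics["parameter"] != "degree_centrality"]
    aucs = auc_table(curves, grid)
    return run_primary_analysis(aucs, hubs.counts, m=m, effect_size=effect_size)


def threshold_subsets(grid: ThresholdGrid) -> dict[str, ThresholdGrid]:
    """Total / lower-half / upper-half partitions of a threshold grid.

    For the default 18-point grid: total = 6–40%, low = 6–22%, high = 24–40%.
    """
    props = list(grid)
    if len(props) < 4:
        raise ValueError("threshold subsets need a grid of at least 4 thresholds")
    half = (len(props) + 1) // 2
    return {
        "total": grid,
        "low": ThresholdGrid(tuple(props[:half])),
        "high": ThresholdGrid(tuple(props[half:])),
    }


def run_stability_analysis(
    parcellations: dict[str, tuple[pd.DataFrame, ThresholdGrid, int]],
    effect_size: str = "dz",
) -> pd.DataFrame:
    """Uncorrected comparisons per parcellation x threshold subset x parameter.

    ``parcellations`` maps a parcellation name to (tidy metric table, full
    threshold grid, target node index). Returns one row per cell with the
    chosen test, its statistic and raw p; cells decided by the Wilcoxon
    fallback are flagged ``non_comparable`` because their statistics do not
    share the t-scale.
    """
    rows = []
    for name, (metrics, grid, target_node) in parcellations.items():
        for subset_name, subset_grid in threshold_subsets(grid).items():
            results = analyze_metrics(
                metrics, subset_grid, target_node, m=1, effect_size=effect_size
            )
            for res in results:
                rows.append(
                    {
                        "parcellation": name,
                        "subset": subset_name,
                        "parameter": res.parameter,
                        "test": res.test,
                        "statistic": res.statistic,
                        "df": res.df,
                        "p_raw": res.p_raw,
                        "effect_size_d": res.effect_size_d,
                        "non_comparable": res.test == "wilcoxon",
                    }
                )
    return pd.DataFrame(rows)
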