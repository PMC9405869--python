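"""Weighted network construction from node time series.

Edges are Pearson correlations between node time courses; only positive
weights are kept, and networks are sparsified by proportional thresholding:
the strongest fraction ``p`` of all possible node pairs is retained with its
original weights (never binarized), everything else is set to zero.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "ConnectivityMatrix",
    "ThresholdGrid",
    "WeightedNetwork",
    "pearson_connectivity",
    "default_threshold_grid",
    "proportional_threshold",
    "SubQuotaWarning",
]


class SubQuotaWarning(UserWarning):
    """Fewer positive edges than the proportional-threshold quota."""


@dataclass
class ConnectivityMatrix:
    """Full (unthresholded) Pearson connectivity: symmetric, zero diagonal."""

    weights: np.ndarray
    labels: list[str] | None = None

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("connectivity matrix must be square")
        if not np.allclose(w, w.T, atol=1e-12):
            raise ValueError("connectivity matrix must be symmetric")
        if np.any(np.abs(w) > 1 + 1e-9):
            raise ValueError("Pearson correlations must lie in [-1, 1]")
        np.fill_diagonal(w, 0.0)
        self.weights = w

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]


@dataclass
class ThresholdGrid:
    """Ordered edge-retention fractions used for the sparsity sweep."""

    proportions: tuple[float, ...]

    def __post_init__(self) -> None:
        p = tuple(float(x) for x in self.proportions)
        if len(p) < 1:
            raise ValueError("threshold grid must be non-empty")
        if any(not (0 < x <= 1) for x in p):
            raise ValueError("proportions must lie in (0, 1]")
        if any(b <= a for a, b in zip(p, p[1:])):
            raise ValueError("proportions must be strictly increasing")
        self.proportions = p

    def __len__(self) -> int:
        return len(self.proportions)

    def __iter__(self):
        return iter(self.proportions)

    def subset(self, lo: float, hi: float) -> "ThresholdGrid":
        """Grid restricted to proportions in [lo, hi] (inclusive, with tolerance)."""
        kept = tuple(p for p in self.proportions if lo - 1e-9 <= p <= hi + 1e-9)
        return ThresholdGrid(kept)


@dataclass
class WeightedNetwork:
    """Thresholded nonnegative weighted undirected network (zero diagonal)."""

    weights: np.ndarray
    proportion: float = 1.0

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("adjacency matrix must be square")
        if not np.allclose(w, w.T, atol=1e-12):
            raise ValueError("adjacency matrix must be symmetric")
        if np.any(w < 0):
            raise ValueError("weights must be nonnegative")
        np.fill_diagonal(w, 0.0)
        self.weights = w

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(np.triu(self.weights, 1)))

    def edge_list(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(i, j, w) arrays of the upper-triangular edges, i < j."""
        iu, ju = np.nonzero(np.triu(self.weights, 1))
        return iu, ju, self.weights[iu, ju]


def pearson_connectivity(series: np.ndarray, labels: list[str] | None = None) -> ConnectivityMatrix:
    """Pearson correlation of every node's time course with every other node.

    Parameters
    ----------
    series : array, shape (n_nodes, n_timepoints)
        One row per node. At least 3 timepoints, no constant row.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 2:
        raise ValueError("series must be a node x timepoint matrix")
    if x.shape[1] < 3:
        raise ValueError("need at least 3 timepoints for Pearson correlation")
    sd = x.std(axis=1)
    dead = np.nonzero(sd == 0)[0]
    if dead.size:
        raise ValueError(f"zero-variance signal at node index {dead[0]}")
    r = np.corrcoef(x)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 0.0)
    return ConnectivityMatrix(r, labels=labels)


def default_threshold_grid() -> ThresholdGrid:
    """The 18-point sparsity grid: 6% to 40% of edges in 2% steps."""
    # round() keeps the float grid exact (0.06, 0.08, ..., 0.40)
    props = tuple(round(0.06 + 0.02 * k, 2) for k in range(18))
    return ThresholdGrid(props)


def proportional_threshold(conn: ConnectivityMatrix, proportion: float) -> WeightedNetwork:
    """Keep the strongest ``proportion`` of all possible edges, weights intact.

    Negative and zero correlations are discarded before ranking. The retention
    quota is ``floor(proportion * n(n-1)/2)`` over all possible undirected
    pairs; ties at the cutoff are broken by ascending (i, j) node order so the
    result is deterministic and edge sets are nested across proportions. If
    fewer positive edges exist than the quota, all of them are kept and a
    :class:`SubQuotaWarning` records the achieved density.
    """
    if not (0 < proportion <= 1):
        raise ValueError("proportion must lie in (0, 1]")
    w = conn.weights
    n = conn.n_nodes
    quota = int(np.floor(proportion * n * (n - 1) / 2))
    iu, ju = np.triu_indices(n, k=1)
    vals = w[iu, ju]
    pos = vals > 0
    iu, ju, vals = iu[pos], ju[pos], vals[pos]
    if vals.size < quota:
        achieved = vals.size / (n * (n - 1) / 2)
        warnings.warn(
            f"only {vals.size} positive edges available for quota {quota}; "
            f"achieved density {achieved:.4f}",
            SubQuotaWarning,
            stacklevel=2,
        )
        keep = slice(None)
    else:
        # primary key: weight descending; then i, j ascending (lexsort: last key primary)
        order = np.lexsort((ju, iu, -vals))
        keep = order[:quota]
    out = np.zeros((n, n))
    out[iu[keep], ju[keep]] = vals[keep]
    out += out.T
    return WeightedNetwork(out, proportion=proportion)
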