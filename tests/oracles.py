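"""Independent brute-force reference implementations for small graphs.

Everything here is deliberately naive — exhaustive simple-path enumeration
for shortest paths, direct triple loops for clustering, restricted-growth
enumeration of all set partitions for modularity — so the tests compare the
package's algorithms against implementations that share no code with them.
Only practical for graphs with at most ~8 nodes.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def brute_distances(w: np.ndarray) -> np.ndarray:
    """All-pairs shortest paths under length 1/w by simple-path enumeration."""
    n = w.shape[0]
    dist = np.full((n, n), np.inf)
    np.fill_diagonal(dist, 0.0)

    def dfs(node, target, visited, acc):
        nonlocal best
        if acc >= best:
            return
        if node == target:
            best = acc
            return
        for nxt in range(n):
            if w[node, nxt] > 0 and nxt not in visited:
                dfs(nxt, target, visited | {nxt}, acc + 1.0 / w[node, nxt])

    for i in range(n):
        for j in range(i + 1, n):
            best = np.inf
            dfs(i, j, {i}, 0.0)
            dist[i, j] = dist[j, i] = best
    return dist


def brute_global_efficiency(w: np.ndarray) -> float:
    n = w.shape[0]
    if n < 2:
        return 0.0
    d = brute_distances(w)
    total = 0.0
    for i in range(n):
        for j in range(n):
            if i != j and math.isfinite(d[i, j]):
                total += 1.0 / d[i, j]
    return total / (n * (n - 1))


def brute_nodal_efficiency(w: np.ndarray, node: int) -> float:
    n = w.shape[0]
    d = brute_distances(w)
    return sum(
        1.0 / d[node, j] for j in range(n) if j != node and math.isfinite(d[node, j])
    ) / (n - 1)


def brute_local_efficiency(w: np.ndarray, node: int) -> float:
    nbrs = [j for j in range(w.shape[0]) if w[node, j] > 0]
    if len(nbrs) < 2:
        return 0.0
    sub = w[np.ix_(nbrs, nbrs)]
    return brute_global_efficiency(sub)


def brute_clustering(w: np.ndarray) -> np.ndarray:
    """Onnela coefficient with max-normalized weights, direct loops."""
    n = w.shape[0]
    wmax = w.max()
    out = np.zeros(n)
    if wmax == 0:
        return out
    wn = w / wmax
    for i in range(n):
        nbrs = [j for j in range(n) if w[i, j] > 0]
        k = len(nbrs)
        if k < 2:
            continue
        acc = 0.0
        for j, h in itertools.combinations(nbrs, 2):
            acc += (wn[i, j] * wn[i, h] * wn[j, h]) ** (1.0 / 3.0)
        out[i] = 2.0 * acc / (k * (k - 1))
    return out


def brute_modularity_value(w: np.ndarray, labels) -> float:
    """Q by the ordered-pair double loop."""
    labels = list(labels)
    n = w.shape[0]
    s = w.sum(axis=1)
    two_m = s.sum()
    q = 0.0
    for i in range(n):
        for j in range(n):
            if labels[i] == labels[j]:
                q += w[i, j] - s[i] * s[j] / two_m
    return q / two_m


def all_partitions(n: int):
    """Every set partition of range(n) as a label list (restricted growth)."""

    def rec(prefix, n_blocks):
        idx = len(prefix)
        if idx == n:
            yield list(prefix)
            return
        for b in range(n_blocks + 1):
            prefix.append(b)
            yield from rec(prefix, max(n_blocks, b + 1))
            prefix.pop()

    yield from rec([], 0)


def brute_max_modularity(w: np.ndarray) -> float:
    """Global maximum of Q over every partition (exhaustive, n <= 8)."""
    return max(brute_modularity_value(w, labels) for labels in all_partitions(w.shape[0]))


def random_weighted_graph(rng: np.random.Generator, n: int, p_edge: float = 0.6) -> np.ndarray:
    """Random symmetric nonnegative weighted graph, possibly disconnected."""
    w = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p_edge:
                w[i, j] = w[j, i] = rng.uniform(0.05, 1.0)
    return w
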