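"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written without reference to the package
implementation: plain enumeration and dense all-pairs algorithms.
"""

from __future__ import annotations

import itertools

import numpy as np


def midranks(values) -> np.ndarray:
    """Average ranks, computed directly from sorted positions."""
    values = np.asarray(values, float)
    order = np.argsort(values, kind="mergesort")
    ranks = np.empty(len(values))
    i = 0
    while i < len(values):
        j = i
        while j + 1 < len(values) and values[order[j + 1]] == values[order[i]]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def spearman_rho(x, y) -> float:
    rx = midranks(x) - (len(x) + 1) / 2.0
    ry = midranks(y) - (len(y) + 1) / 2.0
    denom = np.sqrt((rx**2).sum() * (ry**2).sum())
    if denom == 0:
        raise ZeroDivisionError("constant input")
    return float((rx * ry).sum() / denom)


def spearman_exact_p(x, y) -> tuple[float, float]:
    """Two-sided permutation p over all orderings of y."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    rx = midranks(x) - (n + 1) / 2.0
    ry = midranks(y) - (n + 1) / 2.0
    denom = np.sqrt((rx**2).sum() * (ry**2).sum())
    rho_obs = float((rx * ry).sum() / denom)
    perms = np.array(list(itertools.permutations(range(n))))
    rho_all = (ry[perms] * rx).sum(axis=1) / denom
    p = float((np.abs(rho_all) >= abs(rho_obs) - 1e-12).mean())
    return rho_obs, p


def signed_rank_exact_p(diffs, alternative="greater") -> float:
    """Enumerate all 2^n sign assignments on mid-ranks of |d| (zeros dropped)."""
    d = np.asarray(diffs, float)
    d = d[d != 0]
    n = len(d)
    ranks = midranks(np.abs(d))
    w_obs = ranks[d > 0].sum()
    stats = []
    for signs in itertools.product([0, 1], repeat=n):
        stats.append(ranks[np.array(signs, bool)].sum())
    stats = np.array(stats)
    p_ge = (stats >= w_obs - 1e-12).mean()
    p_le = (stats <= w_obs + 1e-12).mean()
    if alternative == "greater":
        return float(p_ge)
    if alternative == "less":
        return float(p_le)
    return float(min(1.0, 2.0 * min(p_ge, p_le)))


def rank_sum_exact_p(x, y, alternative="two-sided") -> float:
    """Enumerate all label assignments of size len(x) on pooled mid-ranks."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    pooled = np.concatenate([x, y])
    ranks = midranks(pooled)
    n, n1 = len(pooled), len(x)
    w_obs = ranks[:n1].sum()
    stats = []
    for combo in itertools.combinations(range(n), n1):
        stats.append(ranks[list(combo)].sum())
    stats = np.array(stats)
    p_ge = (stats >= w_obs - 1e-12).mean()
    p_le = (stats <= w_obs + 1e-12).mean()
    if alternative == "greater":
        return float(p_ge)
    if alternative == "less":
        return float(p_le)
    return float(min(1.0, 2.0 * min(p_ge, p_le)))


def who_decision_bruteforce(nutrients: dict, limits: dict, always_prohibited=False) -> bool:
    """Independent per-threshold evaluation: permitted iff value <= limit
    for every limit present (inclusive boundary)."""
    if always_prohibited:
        return False
    for key, limit in limits.items():
        if nutrients[key] > limit:
            return False
    return True


def all_pairs_shortest(n_nodes: int, edges: list[tuple[int, int, float]]) -> np.ndarray:
    """Dense Floyd-Warshall over an undirected weighted edge list."""
    dist = np.full((n_nodes, n_nodes), np.inf)
    np.fill_diagonal(dist, 0.0)
    for u, v, w in edges:
        if w < dist[u, v]:
            dist[u, v] = dist[v, u] = w
    for k in range(n_nodes):
        dist = np.minimum(dist, dist[:, k : k + 1] + dist[k : k + 1, :])
    return dist
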