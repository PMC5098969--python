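"""Independent brute-force oracles used to check the fast implementations.

Each oracle deliberately avoids the code path it validates: betweenness by
exhaustive simple-path enumeration, Cliff's delta by all-pairs counting, and
the polychoric likelihood by a 1-D grid search with rectangle probabilities
from scipy's generic multivariate-normal CDF.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import multivariate_normal, norm

REL_TOL = 1e-9


def enum_betweenness(W: np.ndarray) -> np.ndarray:
    """Exhaustive-path weighted betweenness for small graphs (p <= 7).

    Edge length is 1/|w|; tied shortest paths share credit fractionally.
    """
    W = np.asarray(W, float)
    p = W.shape[0]
    adj = [
        [j for j in range(p) if j != i and abs(W[i, j]) > 1e-10]
        for i in range(p)
    ]

    def all_paths(s, t):
        paths = []

        def dfs(node, visited, length):
            if node == t:
                paths.append((length, list(visited)))
                return
            for nxt in adj[node]:
                if nxt not in visited:
                    visited.append(nxt)
                    dfs(nxt, visited, length + 1.0 / abs(W[node, nxt]))
                    visited.pop()

        dfs(s, [s], 0.0)
        return paths

    b = np.zeros(p)
    for s in range(p):
        for t in range(s + 1, p):
            paths = all_paths(s, t)
            if not paths:
                continue
            dmin = min(lng for lng, _ in paths)
            shortest = [
                pth for lng, pth in paths
                if lng <= dmin * (1 + REL_TOL) + REL_TOL
            ]
            sigma = len(shortest)
            for v in range(p):
                if v in (s, t):
                    continue
                through = sum(1 for pth in shortest if v in pth)
                b[v] += through / sigma
    return b


def cliff_naive(x, y) -> float:
    """All-pairs dominance count."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    gt = sum(1 for a in x for c in y if a > c)
    lt = sum(1 for a in x for c in y if a < c)
    return (gt - lt) / (x.size * y.size)


def polychoric_grid_mle(table, step: float = 0.01) -> float:
    """Grid-search two-step polychoric MLE with scipy rectangle probabilities."""
    table = np.asarray(table, float)
    r = table.sum(axis=1)
    c = table.sum(axis=0)
    n = table.sum()
    tau_r = norm.ppf(np.cumsum(r)[:-1] / n)
    tau_c = norm.ppf(np.cumsum(c)[:-1] / n)
    a = np.concatenate([[-30.0], tau_r, [30.0]])  # effectively +/- inf
    b = np.concatenate([[-30.0], tau_c, [30.0]])
    pts = np.array([[ai, bj] for ai in a for bj in b])
    grid = np.arange(-0.99, 0.991, step)
    best, best_nll = 0.0, np.inf
    for rho in grid:
        C = multivariate_normal(cov=[[1.0, rho], [rho, 1.0]]).cdf(pts)
        C = C.reshape(a.size, b.size)
        P = C[1:, 1:] - C[:-1, 1:] - C[1:, :-1] + C[:-1, :-1]
        P = np.clip(P, 1e-12, None)
        nll = -(table * np.log(P)).sum()
        if nll < best_nll:
            best_nll, best = nll, rho
    return float(best)


def random_contingency_table(rng, max_k: int = 5, n: int = 300):
    """Random bivariate ordinal table with all categories occupied."""
    while True:
        k1 = rng.integers(2, max_k + 1)
        k2 = rng.integers(2, max_k + 1)
        rho = rng.uniform(-0.85, 0.85)
        L = np.linalg.cholesky([[1.0, rho], [rho, 1.0]])
        z = rng.standard_normal((n, 2)) @ L.T
        t1 = np.sort(rng.uniform(-1.2, 1.2, size=k1 - 1))
        t2 = np.sort(rng.uniform(-1.2, 1.2, size=k2 - 1))
        x = np.searchsorted(t1, z[:, 0])
        y = np.searchsorted(t2, z[:, 1])
        table = np.zeros((k1, k2))
        np.add.at(table, (x, y), 1.0)
        if (table.sum(axis=1) > 0).all() and (table.sum(axis=0) > 0).all():
            return table, rho


def random_weighted_graph(rng, p: int, edge_prob: float = 0.5) -> np.ndarray:
    """Random symmetric weight matrix with continuous weights in +/-[0.2, 1]."""
    W = np.zeros((p, p))
    for i in range(p):
        for j in range(i + 1, p):
            if rng.random() < edge_prob:
                w = rng.uniform(0.2, 1.0) * rng.choice([-1.0, 1.0])
                W[i, j] = W[j, i] = w
    return W
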