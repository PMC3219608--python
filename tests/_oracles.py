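"""Brute-force reference implementations, independent of the library paths.

These are deliberately naive: direct probability-mass summation for the
hypergeometric/Fisher tests, literal step-up for Benjamini-Hochberg, an
explicit ECDF gap scan for the two-sample KS statistic, and BFS-based
shortest-path counting for betweenness.  The test suite compares the
package's (scipy/statsmodels/networkx-backed) results against these.
"""

from __future__ import annotations

import math
from collections import deque

import numpy as np


def log_binom(n: int, k: int) -> float:
    return math.lgamma(n + 1) - math.lgamma(k + 1) - math.lgamma(n - k + 1)


def hypergeom_pmf(k: int, big_n: int, big_k: int, n: int) -> float:
    """P(X = k) for k successes drawing n from big_n with big_k successes."""
    if k < max(0, n + big_k - big_n) or k > min(n, big_k):
        return 0.0
    return math.exp(log_binom(big_k, k) + log_binom(big_n - big_k, n - k)
                    - log_binom(big_n, n))


def fisher_one_sided(table) -> float:
    """P(X >= a) by direct pmf summation (enrichment tail)."""
    (a, b), (c, d) = table
    big_n, big_k, n = a + b + c + d, a + b, a + c
    return sum(hypergeom_pmf(k, big_n, big_k, n)
               for k in range(a, min(n, big_k) + 1))


def fisher_two_sided(table) -> float:
    """Two-sided Fisher p: sum of all tables (fixed margins) with pmf <= observed."""
    (a, b), (c, d) = table
    big_n, big_k, n = a + b + c + d, a + b, a + c
    p_obs = hypergeom_pmf(a, big_n, big_k, n)
    total = 0.0
    for k in range(max(0, n + big_k - big_n), min(n, big_k) + 1):
        p = hypergeom_pmf(k, big_n, big_k, n)
        if p <= p_obs * (1 + 1e-9):
            total += p
    return min(total, 1.0)


def bh_step_up(pvalues) -> np.ndarray:
    """Literal Benjamini-Hochberg step-up, returning adjusted p in input order."""
    p = np.asarray(pvalues, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running = min(running, p[i] * m / rank_from_top)
        adj[i] = running
    return adj


def ks_statistic(x, y) -> float:
    """Max gap between the two empirical CDFs, evaluated at every data point."""
    x = np.sort(np.asarray(x, dtype=float))
    y = np.sort(np.asarray(y, dtype=float))
    best = 0.0
    for t in np.concatenate([x, y]):
        fx = np.sum(x <= t) / len(x)
        fy = np.sum(y <= t) / len(y)
        best = max(best, abs(fx - fy))
    return best


def betweenness_bfs(nodes, edges) -> dict:
    """Exact normalized betweenness by per-pair shortest-path counting.

    For every ordered pair (s, t), shortest-path counts through v are
    sigma_sv * sigma_vt when d(s,v) + d(v,t) = d(s,t); this enumerates pairs
    directly instead of using dependency accumulation.
    """
    adj: dict = {v: set() for v in nodes}
    for a, b in edges:
        adj[a].add(b)
        adj[b].add(a)

    def bfs(src):
        dist = {src: 0}
        sigma = {src: 1.0}
        queue = deque([src])
        while queue:
            u = queue.popleft()
            for w in adj[u]:
                if w not in dist:
                    dist[w] = dist[u] + 1
                    sigma[w] = 0.0
                    queue.append(w)
                if dist[w] == dist[u] + 1:
                    sigma[w] += sigma[u]
        return dist, sigma

    info = {v: bfs(v) for v in nodes}
    n = len(nodes)
    scale = 2.0 / ((n - 1) * (n - 2)) if n > 2 else 0.0
    result = {}
    for v in nodes:
        total = 0.0
        for s in nodes:
            if s == v:
                continue
            dist_s, sig_s = info[s]
            for t in nodes:
                if t == v or t == s or t not in dist_s:
                    continue
                dist_t, sig_t = info[t]
                if v in dist_s and v in dist_t and \
                        dist_s[v] + dist_t[v] == dist_s[t]:
                    total += sig_s[v] * sig_t[v] / sig_s[t]
        result[v] = total * scale / 2.0  # each unordered pair counted twice
    return result
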