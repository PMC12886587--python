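"""Brute-force reference implementations used as independent oracles.

These deliberately avoid the library's own vectorised code paths: plain
Python loops, explicit product-moment sums, breadth-first search, and direct
t-distribution tail integration via scipy's CDF.
"""

import itertools
import math

import numpy as np
from scipy import stats


def brute_pairwise(X):
    """Loop-and-sum Pearson matrix with t-transform p-values."""
    n, m = X.shape
    R = np.eye(n)
    P = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        xi, xj = X[i], X[j]
        dx = xi - sum(xi) / m
        dy = xj - sum(xj) / m
        r = float(sum(dx * dy) / math.sqrt(sum(dx * dx) * sum(dy * dy)))
        r = max(-1.0, min(1.0, r))
        R[i, j] = R[j, i] = r
        if abs(r) == 1.0:
            p = 0.0
        else:
            t = abs(r) * math.sqrt((m - 2) / (1 - r * r))
            p = 2 * (1 - stats.t.cdf(t, df=m - 2))
        P[i, j] = P[j, i] = p
    return R, P


def brute_knn(g, k):
    """Edge kept iff within the k strongest (ties included) of an endpoint."""
    kept = set()
    for u, v, d in g.edges(data=True):
        w = d["weight"]
        for end in (u, v):
            stronger = sum(
                1 for x in g[end] if g[end][x]["weight"] > w
            )
            if stronger < k:
                kept.add(frozenset((u, v)))
                break
    return kept


def bfs_components(g):
    """Breadth-first reachability partition."""
    remaining = set(g.nodes)
    comps = set()
    while remaining:
        start = next(iter(remaining))
        comp = {start}
        queue = [start]
        while queue:
            u = queue.pop()
            for v in g[u]:
                if v not in comp:
                    comp.add(v)
                    queue.append(v)
        comps.add(frozenset(comp))
        remaining -= comp
    return comps


def brute_delta(X, Y):
    """Element-wise difference of two loop-computed correlation matrices."""
    RX, _ = brute_pairwise(X)
    RY, _ = brute_pairwise(Y)
    return RY - RX
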