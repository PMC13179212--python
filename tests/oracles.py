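"""Independent brute-force reference implementations used only by tests.

These deliberately avoid the code paths (and, where possible, the
libraries) used by the package: pure-Python loops, Andrew's monotone
chain for hulls, Prim's algorithm for spanning trees, Lance-Williams
recursion for Ward heights.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def gower_brute(X: np.ndarray, w: np.ndarray) -> np.ndarray:
    n = len(X)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            acc = 0.0
            for k in range(X.shape[1]):
                acc += w[k] * abs(X[i, k] - X[j, k])
            d[i, j] = acc / w.sum()
    return d


def bray_curtis_brute(u, v) -> float:
    num = sum(abs(a - b) for a, b in zip(u, v))
    den = sum(a + b for a, b in zip(u, v))
    return num / den if den else 0.0


def hull_area_brute(points: np.ndarray) -> float:
    """Convex hull area via monotone chain + shoelace (no scipy)."""
    pts = sorted(set(map(tuple, points)))
    if len(pts) < 3:
        return 0.0

    def cross(o, a, b):
        return (a[0] - o[0]) * (b[1] - o[1]) - (a[1] - o[1]) * (b[0] - o[0])

    lower: list = []
    for p in pts:
        while len(lower) >= 2 and cross(lower[-2], lower[-1], p) <= 0:
            lower.pop()
        lower.append(p)
    upper: list = []
    for p in reversed(pts):
        while len(upper) >= 2 and cross(upper[-2], upper[-1], p) <= 0:
            upper.pop()
        upper.append(p)
    hull = lower[:-1] + upper[:-1]
    if len(hull) < 3:
        return 0.0
    area = 0.0
    for (x1, y1), (x2, y2) in zip(hull, hull[1:] + hull[:1]):
        area += x1 * y2 - x2 * y1
    return abs(area) / 2.0


def mst_edges_prim(D: np.ndarray) -> list[tuple[int, int]]:
    n = len(D)
    in_tree = {0}
    edges = []
    while len(in_tree) < n:
        best = None
        for i in in_tree:
            for j in range(n):
                if j not in in_tree and (best is None or D[i, j] < best[0]):
                    best = (D[i, j], i, j)
        _, i, j = best
        edges.append((i, j))
        in_tree.add(j)
    return edges


def feve_brute(coords: np.ndarray, weights: np.ndarray) -> float:
    n = len(coords)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            D[i, j] = math.dist(coords[i], coords[j])
    edges = mst_edges_prim(D)
    ew = [D[i, j] / (weights[i] + weights[j]) for i, j in edges]
    total = sum(ew)
    if total == 0:
        return 1.0
    pew = [e / total for e in ew]
    thr = 1.0 / (n - 1)
    return (sum(min(p, thr) for p in pew) - thr) / (1.0 - thr)


def fdis_brute(coords: np.ndarray, weights: np.ndarray) -> float:
    c = sum(w * x for w, x in zip(weights, coords)) / weights.sum()
    return sum(w * math.dist(x, c) for w, x in zip(weights, coords)) / weights.sum()


def rao_brute(D: np.ndarray, p: np.ndarray) -> tuple[float, float, float]:
    q = 0.0
    for i in range(len(p)):
        for j in range(len(p)):
            q += D[i, j] * p[i] * p[j]
    simpson = 1.0 - sum(x * x for x in p)
    return q, simpson, simpson - q


def rarefaction_exact(sets: list[set], size: int) -> float:
    vals = [
        len(set().union(*combo))
        for combo in itertools.combinations(sets, size)
    ]
    return sum(vals) / len(vals)


def ward_heights_lw(D: np.ndarray) -> list[float]:
    """Merge heights from the Lance-Williams Ward recursion on distances."""
    clusters = {i: 1 for i in range(len(D))}
    D = D.astype(float).copy()
    active = list(range(len(D)))
    heights = []
    while len(active) > 1:
        best = None
        for a, b in itertools.combinations(active, 2):
            if best is None or D[a, b] < best[0]:
                best = (D[a, b], a, b)
        h, a, b = best
        heights.append(h)
        na, nb = clusters[a], clusters[b]  # index a hosts the merged cluster
        for k in active:
            if k in (a, b):
                continue
            nk = clusters[k]
            D_ak = math.sqrt(
                ((na + nk) * D[a, k] ** 2 + (nb + nk) * D[b, k] ** 2 - nk * h**2)
                / (na + nb + nk)
            )
            D[a, k] = D[k, a] = D_ak
        clusters[a] = na + nb
        active.remove(b)
    return heights
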