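"""Independent brute-force reimplementations used as test oracles.

Everything here is written as plain Python loops with no code shared with
the package, so agreement between the two is meaningful.
"""

from __future__ import annotations

import math

import numpy as np


def bfs_distances(n_vertices: int, edges: list[tuple[int, int]]) -> np.ndarray:
    """All-pairs shortest paths by repeated breadth-first search."""
    adjacency = {i: [] for i in range(n_vertices)}
    for i, j in edges:
        adjacency[i].append(j)
        adjacency[j].append(i)
    dist = np.full((n_vertices, n_vertices), -1, dtype=int)
    for source in range(n_vertices):
        dist[source, source] = 0
        frontier = [source]
        d = 0
        while frontier:
            d += 1
            nxt = []
            for u in frontier:
                for v in adjacency[u]:
                    if dist[source, v] == -1:
                        dist[source, v] = d
                        nxt.append(v)
            frontier = nxt
    return dist


def brute_hnar(degrees: list[int]) -> float:
    total = 0.0
    for d in degrees:
        total += 1.0 / d
    return len(degrees) / total


def brute_idm(dist: np.ndarray) -> float:
    a = dist.shape[0]
    distances = []
    for i in range(a):
        for j in range(i + 1, a):
            distances.append(float(dist[i, j]))
    w = sum(distances)
    entropy = 0.0
    for d in distances:
        p = d / w
        entropy -= p * math.log2(p)
    return entropy


def brute_mp(elements: list[str], alpha: dict[str, float]) -> float:
    total = 0.0
    for el in elements:
        total += alpha[el] / alpha["C"]
    return total / len(elements)


def brute_geary(dist: np.ndarray, weights: list[float], lag: int) -> float | None:
    a = len(weights)
    mean = sum(weights) / a
    var = sum((w - mean) ** 2 for w in weights) / (a - 1)
    num = 0.0
    count = 0
    for i in range(a):
        for j in range(a):
            if i != j and dist[i, j] == lag:
                num += (weights[i] - weights[j]) ** 2
                count += 1
    if count == 0 or var == 0.0:
        return None
    delta = count // 2  # unordered pairs
    return (num / (2.0 * delta)) / var


def brute_disp(coords: np.ndarray, weights: list[float]) -> float:
    n = len(weights)
    wsum = sum(weights)
    weighted = [0.0, 0.0, 0.0]
    centroid = [0.0, 0.0, 0.0]
    for i in range(n):
        for k in range(3):
            weighted[k] += weights[i] * coords[i, k]
            centroid[k] += coords[i, k] / n
    for k in range(3):
        weighted[k] /= wsum
    return math.sqrt(sum((weighted[k] - centroid[k]) ** 2 for k in range(3)))


def brute_morse(coords: np.ndarray, weights: list[float], signal: int) -> float:
    s = signal - 1
    n = len(weights)
    total = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            r = math.dist(coords[i], coords[j])
            term = 1.0 if s == 0 else math.sin(s * r) / (s * r)
            total += weights[i] * weights[j] * term
    return total


def ols_normal_equations(X: np.ndarray, y: np.ndarray):
    """Closed-form OLS with intercept: coefficients, SEs, T statistics."""
    n, p = X.shape
    design = np.hstack([np.ones((n, 1)), X])
    xtx_inv = np.linalg.inv(design.T @ design)
    beta = xtx_inv @ design.T @ y
    resid = y - design @ beta
    sigma2 = resid @ resid / (n - p - 1)
    se = np.sqrt(np.diag(xtx_inv) * sigma2)
    return beta, se, beta / se


def loo_press_hat_matrix(X: np.ndarray, y: np.ndarray) -> float:
    """PRESS for OLS via the hat-matrix identity sum (e_i / (1-h_ii))^2."""
    n = X.shape[0]
    design = np.hstack([np.ones((n, 1)), X])
    hat = design @ np.linalg.inv(design.T @ design) @ design.T
    resid = y - hat @ y
    return float(np.sum((resid / (1.0 - np.diag(hat))) ** 2))


def best_subset_sse(X: np.ndarray, y: np.ndarray, max_size: int = 2):
    """Exhaustive best subset (by SSE) over all subsets up to ``max_size``."""
    from itertools import combinations

    n, p = X.shape
    best = (float("inf"), ())
    for size in range(1, max_size + 1):
        for subset in combinations(range(p), size):
            design = np.hstack([np.ones((n, 1)), X[:, subset]])
            beta, *_ = np.linalg.lstsq(design, y, rcond=None)
            resid = y - design @ beta
            sse = float(resid @ resid)
            if sse < best[0]:
                best = (sse, subset)
    return best
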