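"""Independent brute-force oracles the tests compare the package against.

Everything here is deliberately naive — exhaustive enumeration, iterative
relaxation, hand-written Floyd-Warshall — and shares no code path with
the implementation under test.
"""

from __future__ import annotations

from itertools import permutations

import numpy as np


def floyd_warshall_hops(adjacency: np.ndarray) -> np.ndarray:
    """Hop counts of shortest topological paths; inf when disconnected."""
    n = len(adjacency)
    d = np.where(adjacency, 1.0, np.inf)
    np.fill_diagonal(d, 0.0)
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def iic_enumeration(areas: np.ndarray, adjacency: np.ndarray, total_area: float) -> float:
    nl = floyd_warshall_hops(adjacency)
    total = 0.0
    n = len(areas)
    for i in range(n):
        for j in range(n):
            if np.isfinite(nl[i, j]):
                total += areas[i] * areas[j] / (1.0 + nl[i, j])
    return total / total_area**2


def max_product_enumeration(prob: np.ndarray) -> np.ndarray:
    """P*_ij by exhaustive enumeration of all simple paths (n <= ~7)."""
    n = len(prob)
    pstar = np.zeros((n, n))
    np.fill_diagonal(pstar, 1.0)
    nodes = list(range(n))
    for i in range(n):
        for j in range(i + 1, n):
            best = 0.0
            others = [v for v in nodes if v not in (i, j)]
            for k in range(len(others) + 1):
                for mid in permutations(others, k):
                    path = (i, *mid, j)
                    p = 1.0
                    for u, v in zip(path, path[1:]):
                        p *= prob[u, v]
                    best = max(best, p)
            pstar[i, j] = pstar[j, i] = best
    return pstar


def pc_enumeration(areas: np.ndarray, prob: np.ndarray, total_area: float) -> float:
    pstar = max_product_enumeration(prob)
    return float((np.outer(areas, areas) * pstar).sum() / total_area**2)


def pairwise_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC by exhaustive positive/negative pair comparison, ties half."""
    pos = scores[labels.astype(bool)]
    neg = scores[~labels.astype(bool)]
    wins = ties = 0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1
            elif p == q:
                ties += 1
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


def vif_by_regression(X: np.ndarray) -> np.ndarray:
    """VIF per column via statsmodels OLS (independent of the package)."""
    import statsmodels.api as sm

    out = []
    for k in range(X.shape[1]):
        y = X[:, k]
        others = np.delete(X, k, axis=1)
        r2 = sm.OLS(y, sm.add_constant(others)).fit().rsquared
        out.append(np.inf if r2 >= 1 - 1e-12 else 1.0 / (1.0 - r2))
    return np.array(out)


def grid_cwd_relaxation(resistance: np.ndarray, cell_size: float, source_mask: np.ndarray) -> np.ndarray:
    """Cost-weighted distance by Bellman-Ford-style relaxation to a fixed
    point over the 8-neighbor grid; no priority queue, no shared code."""
    sqrt2 = np.sqrt(2.0)
    h, w = resistance.shape
    cwd = np.full((h, w), np.inf)
    cwd[source_mask] = 0.0
    moves = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)]
    changed = True
    while changed:
        changed = False
        for r in range(h):
            for c in range(w):
                for dr, dc in moves:
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < h and 0 <= cc < w:
                        step = (resistance[r, c] + resistance[rr, cc]) / 2.0 * cell_size
                        if dr and dc:
                            step *= sqrt2
                        cand = cwd[rr, cc] + step
                        if cand < cwd[r, c] - 1e-12:
                            cwd[r, c] = cand
                            changed = True
    return cwd


def flood_fill_components(binary: np.ndarray) -> int:
    """8-connected component count by explicit stack-based flood fill."""
    seen = np.zeros_like(binary, dtype=bool)
    h, w = binary.shape
    count = 0
    for r0 in range(h):
        for c0 in range(w):
            if binary[r0, c0] and not seen[r0, c0]:
                count += 1
                stack = [(r0, c0)]
                seen[r0, c0] = True
                while stack:
                    r, c = stack.pop()
                    for dr in (-1, 0, 1):
                        for dc in (-1, 0, 1):
                            rr, cc = r + dr, c + dc
                            if 0 <= rr < h and 0 <= cc < w and binary[rr, cc] and not seen[rr, cc]:
                                seen[rr, cc] = True
                                stack.append((rr, cc))
    return count
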