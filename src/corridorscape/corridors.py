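"""Resistance surfaces, cost-weighted distance, and least-cost corridors.

Movement cost is modeled on the 8-neighbor grid graph: stepping between
adjacent cells u, v costs ``(R_u + R_v) / 2 * cell_size`` (times sqrt(2)
for diagonal moves), the convention of standard least-cost GIS tools. The
cost-weighted distance CWD_S(x) is the minimum accumulated cost from any
cell of a source S to x (0 inside S). A corridor between sources A and B
consists of

* the least-cost path, whose cost ``lcp_cost = min_x CWD_A(x) + CWD_B(x)``,
* a swath of cells with ``CWD_A + CWD_B - lcp_cost <= cutoff`` (default
  20,000 cost units, the Linkage-Mapper default used at 300 m resolution).

Networks link pairs of sources whose cost-allocation regions (each cell
assigned to its cheapest source) are adjacent, and drop corridors whose
least-cost cost exceeds the cutoff.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra

from .mspa import SourceSet
from .raster import Raster

_SQRT2 = float(np.sqrt(2.0))


def resistance_from_suitability(suitability: Raster, r_min: float = 1.0, r_max: float = 100.0) -> Raster:
    """Linear suitability-to-resistance transform R = r_min + (r_max - r_min)(1 - H).

    Continuous by construction: perfect habitat (H=1) costs r_min per meter
    traversed, non-habitat (H=0) costs r_max, never a binary surface.
    """
    if r_min <= 0:
        raise ValueError("r_min must be positive")
    if r_max <= r_min:
        raise ValueError("r_max must exceed r_min")
    h = np.asarray(suitability.data, dtype=float)
    if h.min() < -1e-12 or h.max() > 1 + 1e-12:
        raise ValueError("suitability must lie in [0, 1]")
    r = r_min + (r_max - r_min) * (1.0 - np.clip(h, 0.0, 1.0))
    return Raster(r, suitability.grid)


def _grid_graph(resistance: Raster):
    """Sparse 8-neighbor cost graph over the resistance raster."""
    r = np.asarray(resistance.data, dtype=float)
    if np.any(r <= 0):
        raise ValueError("resistance must be strictly positive everywhere")
    h, w = r.shape
    cell = resistance.grid.cell_size
    idx = np.arange(h * w).reshape(h, w)
    rows_l, cols_l, costs = [], [], []
    # right, down, down-right, down-left steps cover all 8-neighbor edges once
    for dr, dc, mult in ((0, 1, 1.0), (1, 0, 1.0), (1, 1, _SQRT2), (1, -1, _SQRT2)):
        src = idx[max(0, -dr) : h - max(0, dr), max(0, -dc) : w - max(0, dc)]
        dst = idx[max(0, dr) : h + min(0, dr), max(0, dc) : w + min(0, dc)]
        ru = r[max(0, -dr) : h - max(0, dr), max(0, -dc) : w - max(0, dc)]
        rv = r[max(0, dr) : h + min(0, dr), max(0, dc) : w + min(0, dc)]
        rows_l.append(src.ravel())
        cols_l.append(dst.ravel())
        costs.append(((ru + rv) / 2.0 * cell * mult).ravel())
    rows = np.concatenate(rows_l)
    cols = np.concatenate(cols_l)
    vals = np.concatenate(costs)
    n = h * w
    return coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()


def _as_flat_source(resistance: Raster, source: np.ndarray) -> np.ndarray:
    source = np.asarray(source)
    if source.size == 0:
        raise ValueError("source cell set is empty")
    h, w = resistance.data.shape
    rr, cc = source[:, 0], source[:, 1]
    if rr.min() < 0 or rr.max() >= h or cc.min() < 0 or cc.max() >= w:
        raise ValueError("source cells fall outside the raster")
    return rr * w + cc


def cost_weighted_distance(
    resistance: Raster, source: np.ndarray, return_predecessors: bool = False
):
    """Minimum accumulated cost from a source cell set to every cell.

    ``source`` is an (n, 2) array of row/col cells. Implemented as a
    single multi-source Dijkstra via a zero-cost virtual node attached to
    every source cell.
    """
    flat = _as_flat_source(resistance, source)
    graph = _grid_graph(resistance)
    n = graph.shape[0]
    # virtual super-source node n with zero-cost edges to the source cells
    from scipy.sparse import vstack, hstack, csr_matrix

    extra_col = csr_matrix((n, 1))
    top = hstack([graph, extra_col], format="csr")
    bottom = csr_matrix(
        (np.full(len(flat), 1e-12), (np.zeros(len(flat), dtype=int), flat)), shape=(1, n + 1)
    )
    g2 = vstack([top, bottom], format="csr")
    if return_predecessors:
        dist, pred = dijkstra(g2, directed=False, indices=n, return_predecessors=True)
        cwd = dist[:n].reshape(resistance.data.shape)
        cwd[source[:, 0], source[:, 1]] = 0.0
        return Raster(cwd, resistance.grid), pred[:n]
    dist = dijkstra(g2, directed=False, indices=n)
    cwd = dist[:n].reshape(resistance.data.shape)
    cwd[source[:, 0], source[:, 1]] = 0.0
    return Raster(cwd, resistance.grid)


@dataclass
class Corridor:
    """Least-cost corridor between one pair of sources."""

    source_pair: tuple[int, int]
    path: np.ndarray  # (n, 2) row/col along the least-cost path
    lcp_cost: float
    length_m: float
    swath: np.ndarray  # boolean mask, CWD_a + CWD_b - lcp_cost <= cutoff
    cutoff: float


@dataclass
class CorridorNetwork:
    corridors: list[Corridor]

    @property
    def count(self) -> int:
        return len(self.corridors)

    def stats(self) -> dict:
        lengths = np.array([c.length_m for c in self.corridors], dtype=float)
        if lengths.size == 0:
            return {"count": 0, "mean_length_m": None, "min_length_m": None, "max_length_m": None}
        return {
            "count": int(lengths.size),
            "mean_length_m": float(lengths.mean()),
            "min_length_m": float(lengths.min()),
            "max_length_m": float(lengths.max()),
        }


def _walk_path(pred: np.ndarray, start_flat: int, width: int) -> list[tuple[int, int]]:
    """Walk a Dijkstra predecessor array from a cell back into the source."""
    path = []
    node = start_flat
    n = len(pred)
    while node >= 0 and node < n:
        path.append((node // width, node % width))
        node = pred[node]
        if node >= n:  # reached the virtual super-source
            break
    return path


def _path_length(path: np.ndarray, cell: float) -> float:
    if len(path) < 2:
        return 0.0
    steps = np.abs(np.diff(path, axis=0))
    diag = (steps == 1).all(axis=1)
    return float((np.where(diag, _SQRT2, 1.0) * cell).sum())


def least_cost_corridor(
    resistance: Raster,
    source_a: np.ndarray,
    source_b: np.ndarray,
    cutoff: float = 20000.0,
) -> Corridor:
    """The least-cost path and corridor swath between two source cell sets."""
    source_a = np.asarray(source_a)
    source_b = np.asarray(source_b)
    set_a = {tuple(c) for c in source_a}
    set_b = {tuple(c) for c in source_b}
    touching = any(
        (r + dr, c + dc) in set_b for r, c in set_a for dr in (-1, 0, 1) for dc in (-1, 0, 1)
    )
    if touching:
        warnings.warn("sources overlap or touch; degenerate zero-cost corridor", stacklevel=2)
        h, w = resistance.data.shape
        return Corridor((0, 0), np.empty((0, 2), dtype=int), 0.0, 0.0, np.zeros((h, w), bool), cutoff)
    cwd_a, pred_a = cost_weighted_distance(resistance, source_a, return_predecessors=True)
    cwd_b, pred_b = cost_weighted_distance(resistance, source_b, return_predecessors=True)
    joint = cwd_a.data + cwd_b.data
    lcp_cost = float(joint.min())
    meet_flat = int(np.argmin(joint.ravel()))  # lowest row-major index among minima
    w = resistance.data.shape[1]
    leg_a = _walk_path(pred_a, meet_flat, w)  # meet -> source a
    leg_b = _walk_path(pred_b, meet_flat, w)  # meet -> source b
    path = np.array(leg_a[::-1] + leg_b[1:], dtype=int)
    swath = joint - lcp_cost <= cutoff
    return Corridor(
        source_pair=(0, 0),
        path=path,
        lcp_cost=lcp_cost,
        length_m=_path_length(path, resistance.grid.cell_size),
        swath=swath,
        cutoff=cutoff,
    )


def cost_allocation(resistance: Raster, sources: SourceSet) -> tuple[np.ndarray, list[Raster]]:
    """Assign every cell to its cheapest source; returns the allocation
    label raster (1-based source ids) and the per-source CWD rasters."""
    cwds = [cost_weighted_distance(resistance, s.cells) for s in sources.sources]
    stack = np.stack([c.data for c in cwds])
    alloc = np.argmin(stack, axis=0)
    ids = np.array([s.source_id for s in sources.sources])
    return ids[alloc], cwds


def _adjacent_pairs(alloc: np.ndarray) -> set[tuple[int, int]]:
    """Pairs of allocation labels sharing an 8-neighbor boundary."""
    pairs: set[tuple[int, int]] = set()
    for dr, dc in ((0, 1), (1, 0), (1, 1), (1, -1)):
        a = alloc[max(0, -dr) : alloc.shape[0] - max(0, dr), max(0, -dc) : alloc.shape[1] - max(0, dc)]
        b = alloc[max(0, dr) :, max(0, dc) :] if dc >= 0 else alloc[max(0, dr) :, : dc]
        b = b[: a.shape[0], : a.shape[1]]
        diff = a != b
        for u, v in zip(a[diff].ravel(), b[diff].ravel()):
            pairs.add((min(u, v), max(u, v)))
    return pairs


def build_network(
    sources: SourceSet,
    resistance: Raster,
    cutoff: float = 20000.0,
    drop_above_cutoff: bool = True,
    all_pairs: bool = False,
) -> CorridorNetwork:
    """One corridor per adjacent source pair, dropping pairs whose
    least-cost cost exceeds the cutoff (configurable)."""
    if sources.count < 2:
        return CorridorNetwork([])
    by_id = {s.source_id: s for s in sources.sources}
    if all_pairs:
        ids = sorted(by_id)
        pairs = {(a, b) for i, a in enumerate(ids) for b in ids[i + 1 :]}
    else:
        alloc, _ = cost_allocation(resistance, sources)
        pairs = _adjacent_pairs(alloc)
    corridors = []
    for a, b in sorted(pairs):
        cor = least_cost_corridor(resistance, by_id[a].cells, by_id[b].cells, cutoff=cutoff)
        cor.source_pair = (int(a), int(b))
        if drop_above_cutoff and cor.lcp_cost > cutoff:
            continue
        corridors.append(cor)
    return CorridorNetwork(corridors)
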