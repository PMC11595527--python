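"""Graph-theoretic habitat connectivity: IIC, PC, and per-patch dPC.

Habitat patches are nodes of a landscape graph. For a dispersal distance
d* the binary graph links patches whose edge-to-edge distance d_ij is at
most d*; the probabilistic graph assigns every pair a dispersal
probability p_ij = exp(-alpha * d_ij) with alpha = ln(2) / d*, i.e. a 50%
chance of traversing exactly d* (the Conefor convention).

Indices over patch areas a_i and total landscape area A_L:

    IIC = sum_ij [ a_i * a_j / (1 + nl_ij) ] / A_L**2

with nl_ij the number of links on the shortest topological path (pairs in
different components contribute nothing), and

    PC  = sum_ij [ a_i * a_j * P*_ij ] / A_L**2

with P*_ij the maximum product of stepwise probabilities over any path
(computed as a shortest path on weights -ln p). The importance of patch k,

    dPC_k = (PC - PC'_k) / PC * 100,

is the percentage the index drops when patch k and its links are removed
(A_L held fixed: removing habitat does not shrink the landscape).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.sparse.csgraph import csgraph_from_dense, shortest_path
from scipy.spatial import cKDTree

from .raster import Raster

#: 8-neighbor structuring element for connected components
_STRUCT8 = np.ones((3, 3), dtype=bool)


@dataclass
class Patch:
    patch_id: int
    area: float  # km²
    cells: np.ndarray  # (n, 2) row/col
    boundary: np.ndarray  # (m, 2) row/col of boundary cells


@dataclass
class PatchSet:
    """Habitat patches plus the total landscape area A_L (km²)."""

    patches: list[Patch]
    total_area: float
    cell_size: float

    def __post_init__(self) -> None:
        areas = self.areas
        if np.any(areas <= 0):
            raise ValueError("patch areas must be positive")
        if areas.sum() > self.total_area * (1 + 1e-9):
            raise ValueError("summed patch area exceeds the landscape area")

    @property
    def n(self) -> int:
        return len(self.patches)

    @property
    def areas(self) -> np.ndarray:
        return np.array([p.area for p in self.patches], dtype=float)


@dataclass
class ProbLinkSet:
    """Pairwise structure of the landscape graph for one dispersal distance.

    ``dist`` is the symmetric matrix of minimum edge-to-edge distances (m),
    ``adjacency`` the binary links (dist <= d*, off-diagonal), and ``prob``
    the dispersal kernel exp(-alpha * dist) with p_ii = 1.
    """

    dist: np.ndarray
    adjacency: np.ndarray
    prob: np.ndarray
    dispersal_distance: float
    alpha: float

    @classmethod
    def from_distances(cls, dist: np.ndarray, dispersal_distance: float) -> "ProbLinkSet":
        if dispersal_distance <= 0:
            raise ValueError("dispersal distance must be positive")
        dist = np.asarray(dist, dtype=float)
        alpha = np.log(2.0) / dispersal_distance
        adjacency = (dist <= dispersal_distance) & ~np.eye(len(dist), dtype=bool)
        prob = np.exp(-alpha * dist)
        np.fill_diagonal(prob, 1.0)
        return cls(dist, adjacency, prob, dispersal_distance, alpha)


def extract_patches(habitat: Raster, connectivity_rule: int = 8) -> PatchSet:
    """Connected components of a binary habitat raster.

    Areas are cell count x cell area (km²); A_L is the full raster extent.
    Boundary cells (used for edge-to-edge distances) are habitat cells with
    at least one non-habitat neighbor or lying on the raster border.
    """
    fg = habitat.data.astype(bool)
    struct = _STRUCT8 if connectivity_rule == 8 else ndimage.generate_binary_structure(2, 1)
    labels, n = ndimage.label(fg, structure=struct)
    cell_area = habitat.grid.cell_area_km2
    interior = ndimage.binary_erosion(fg, structure=_STRUCT8, border_value=0)
    boundary_mask = fg & ~interior
    patches = []
    for pid in range(1, n + 1):
        cells = np.argwhere(labels == pid)
        bnd = np.argwhere((labels == pid) & boundary_mask)
        patches.append(
            Patch(patch_id=pid, area=len(cells) * cell_area, cells=cells, boundary=bnd)
        )
    return PatchSet(patches, total_area=habitat.grid.extent_area_km2, cell_size=habitat.grid.cell_size)


def interpatch_distances(patches: PatchSet) -> np.ndarray:
    """Minimum Euclidean distance (m) between boundary-cell centers, per pair."""
    n = patches.n
    dist = np.zeros((n, n), dtype=float)
    pts = [p.boundary[:, ::-1] * patches.cell_size for p in patches.patches]  # (x=col, y=row) scale
    trees = [cKDTree(p) for p in pts]
    for i in range(n):
        for j in range(i + 1, n):
            d, _ = trees[j].query(pts[i])
            dist[i, j] = dist[j, i] = float(d.min())
    return dist


def _hop_counts(adjacency: np.ndarray) -> np.ndarray:
    """nl_ij: shortest-path link counts on the binary graph (inf if disconnected)."""
    if len(adjacency) == 0:
        return np.zeros((0, 0))
    nl = shortest_path(adjacency.astype(float), method="D", unweighted=True, directed=False)
    np.fill_diagonal(nl, 0.0)
    return nl


def iic(patches: PatchSet, links: ProbLinkSet) -> float:
    """Integral index of connectivity, in (0, 1]."""
    if patches.total_area <= 0:
        raise ValueError("landscape area must be positive")
    if patches.n == 0:
        return 0.0
    a = patches.areas
    nl = _hop_counts(links.adjacency)
    with np.errstate(divide="ignore"):
        terms = np.outer(a, a) / (1.0 + nl)
    terms[~np.isfinite(nl)] = 0.0
    return float(terms.sum() / patches.total_area**2)


def max_product_probabilities(links: ProbLinkSet) -> np.ndarray:
    """P*_ij: maximum product of stepwise probabilities over any path.

    Computed as an all-pairs shortest path on edge weights -ln p over the
    complete graph of direct dispersal probabilities.
    """
    p = links.prob
    n = len(p)
    if n == 0:
        return np.zeros((0, 0))
    with np.errstate(divide="ignore"):
        w = -np.log(p)
    np.fill_diagonal(w, np.inf)  # self-loops are irrelevant
    w[~np.isfinite(w)] = np.inf  # p = 0 means no direct link
    # zero-weight edges (p_ij = 1) must survive, so mark absences with inf
    graph = csgraph_from_dense(w, null_value=np.inf)
    d = shortest_path(graph, method="D", directed=False)
    pstar = np.exp(-d)
    np.fill_diagonal(pstar, 1.0)
    return pstar


def pc(patches: PatchSet, links: ProbLinkSet) -> float:
    """Probability of connectivity, in (0, 1]."""
    if patches.total_area <= 0:
        raise ValueError("landscape area must be positive")
    if patches.n == 0:
        return 0.0
    a = patches.areas
    pstar = max_product_probabilities(links)
    return float((np.outer(a, a) * pstar).sum() / patches.total_area**2)


def dpc(patches: PatchSet, links: ProbLinkSet) -> np.ndarray:
    """Per-patch importance: percent drop in PC when the patch is removed."""
    base = pc(patches, links)
    if base <= 0:
        raise ValueError("PC must be positive to compute dPC")
    a = patches.areas
    out = np.empty(patches.n)
    for k in range(patches.n):
        keep = np.ones(patches.n, dtype=bool)
        keep[k] = False
        sub_links = ProbLinkSet(
            dist=links.dist[np.ix_(keep, keep)],
            adjacency=links.adjacency[np.ix_(keep, keep)],
            prob=links.prob[np.ix_(keep, keep)],
            dispersal_distance=links.dispersal_distance,
            alpha=links.alpha,
        )
        ak = a[keep]
        if ak.size == 0:
            pc_removed = 0.0
        else:
            pstar = max_product_probabilities(sub_links)
            pc_removed = float((np.outer(ak, ak) * pstar).sum() / patches.total_area**2)
        out[k] = (base - pc_removed) / base * 100.0
    return out


def connectivity_report(
    habitat: Raster,
    dispersal_distances: tuple[float, ...] = (500.0, 1000.0),
    with_dpc: bool = True,
) -> dict:
    """IIC and PC per dispersal distance, plus per-patch areas and dPC.

    Returns a dict with an ``indices`` DataFrame (one row per distance,
    raw index and x100) and a ``patches`` DataFrame (id, area, dPC per
    distance). Empty habitat yields zero indices with a warning.
    """
    import warnings

    patches = extract_patches(habitat)
    if patches.n == 0:
        warnings.warn("habitat raster contains no patches; indices are 0", stacklevel=2)
        idx = pd.DataFrame(
            {
                "dispersal_distance_m": list(dispersal_distances),
                "IIC": 0.0,
                "PC": 0.0,
                "IIC_x100": 0.0,
                "PC_x100": 0.0,
            }
        )
        return {"indices": idx, "patches": pd.DataFrame(columns=["patch_id", "area_km2"])}
    dist = interpatch_distances(patches)
    rows = []
    patch_tbl = pd.DataFrame(
        {"patch_id": [p.patch_id for p in patches.patches], "area_km2": patches.areas}
    )
    for d in dispersal_distances:
        links = ProbLinkSet.from_distances(dist, d)
        iic_v = iic(patches, links)
        pc_v = pc(patches, links)
        rows.append(
            {
                "dispersal_distance_m": d,
                "IIC": iic_v,
                "PC": pc_v,
                "IIC_x100": iic_v * 100.0,
                "PC_x100": pc_v * 100.0,
            }
        )
        if with_dpc:
            patch_tbl[f"dPC_{int(d)}m"] = dpc(patches, links)
    return {"indices": pd.DataFrame(rows), "patches": patch_tbl}
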