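"""Gridded raster container, grid contract, and text raster I/O.

All spatial data live on a planar metric grid: row 0 is the northmost row,
x increases eastward, y increases northward, and the origin is the top-left
*corner* of cell (0, 0). Cell (r, c) has its center at
``(origin_x + (c + 0.5) * cell_size, origin_y - (r + 0.5) * cell_size)``.

Rasters are written as ESRI ASCII grids (``.asc``), a plain-text format
every GIS reads; no compiled geospatial stack is required.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np


class GridMismatchError(ValueError):
    """Two rasters that must share a grid do not."""


@dataclass(frozen=True)
class GridContract:
    """Shared grid definition every joint raster operation must agree on.

    Parameters
    ----------
    width, height:
        Grid size in cells (columns, rows).
    cell_size:
        Cell edge length in meters; cells are square and cover
        ``cell_size ** 2`` m² each.
    origin:
        ``(x, y)`` of the top-left corner of cell (0, 0), meters.
    nodata:
        Sentinel value marking missing cells.
    """

    width: int
    height: int
    cell_size: float
    origin: tuple[float, float] = (0.0, 0.0)
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        if self.width < 1 or self.height < 1:
            raise ValueError(f"grid must be at least 1x1, got {self.width}x{self.height}")
        if self.cell_size <= 0:
            raise ValueError(f"cell_size must be positive, got {self.cell_size}")

    @property
    def cell_area_km2(self) -> float:
        return self.cell_size**2 / 1e6

    @property
    def extent_area_km2(self) -> float:
        return self.width * self.height * self.cell_area_km2

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        x0, y0 = self.origin
        return (x0 + (col + 0.5) * self.cell_size, y0 - (row + 0.5) * self.cell_size)

    def cell_of(self, x: float, y: float) -> tuple[int, int]:
        """Nearest-cell lookup: the cell whose square contains (x, y)."""
        x0, y0 = self.origin
        col = int(np.floor((x - x0) / self.cell_size))
        row = int(np.floor((y0 - y) / self.cell_size))
        if not (0 <= row < self.height and 0 <= col < self.width):
            raise ValueError(f"point ({x}, {y}) falls outside the grid")
        return row, col


@dataclass
class Raster:
    """A 2-D array bound to a :class:`GridContract`.

    ``data`` has shape ``(grid.height, grid.width)``; masked (nodata)
    cells hold ``grid.nodata`` exactly.
    """

    data: np.ndarray
    grid: GridContract

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ValueError("raster data must be 2-D")
        h, w = self.data.shape
        if (w, h) != (self.grid.width, self.grid.height):
            raise GridMismatchError(
                f"data shape {self.data.shape} does not match grid "
                f"{self.grid.height}x{self.grid.width}"
            )

    @property
    def mask(self) -> np.ndarray:
        """Boolean array, True where the cell carries data."""
        return self.data != self.grid.nodata

    def values_at(self, xs: np.ndarray, ys: np.ndarray) -> np.ndarray:
        """Sample cell values at point coordinates (nearest cell)."""
        rows, cols = points_to_cells(self.grid, xs, ys)
        return self.data[rows, cols]

    def same_grid_as(self, other: "Raster") -> bool:
        return self.grid == other.grid

    def require_same_grid(self, other: "Raster") -> None:
        if not self.same_grid_as(other):
            raise GridMismatchError(f"grids differ: {self.grid} vs {other.grid}")


def points_to_cells(
    grid: GridContract, xs: np.ndarray, ys: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized nearest-cell lookup for planar point coordinates."""
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    x0, y0 = grid.origin
    cols = np.floor((xs - x0) / grid.cell_size).astype(int)
    rows = np.floor((y0 - ys) / grid.cell_size).astype(int)
    bad = (rows < 0) | (rows >= grid.height) | (cols < 0) | (cols >= grid.width)
    if np.any(bad):
        i = int(np.flatnonzero(bad)[0])
        raise ValueError(f"point ({xs.flat[i]}, {ys.flat[i]}) falls outside the grid")
    return rows, cols


def write_raster(raster: Raster, path: str | Path) -> None:
    """Write an ESRI ASCII grid (.asc).

    Float data are written with full repr precision so a read-back is
    value-identical; integer arrays round-trip as integers.
    """
    g = raster.grid
    path = Path(path)
    yll = g.origin[1] - g.height * g.cell_size
    is_int = np.issubdtype(raster.data.dtype, np.integer)
    header = (
        f"ncols {g.width}\n"
        f"nrows {g.height}\n"
        f"xllcorner {g.origin[0]!r}\n"
        f"yllcorner {yll!r}\n"
        f"cellsize {g.cell_size!r}\n"
        f"NODATA_value {int(g.nodata) if is_int else g.nodata!r}\n"
    )
    with path.open("w") as fh:
        fh.write(header)
        fmt = "%d" if is_int else "%.17g"
        np.savetxt(fh, raster.data, fmt=fmt)


def read_raster(path: str | Path, expect: GridContract | None = None) -> Raster:
    """Read an ESRI ASCII grid; optionally enforce a session grid contract."""
    path = Path(path)
    header: dict[str, float] = {}
    with path.open() as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        data = np.loadtxt(fh)
    data = np.atleast_2d(data)
    w, h = int(header["ncols"]), int(header["nrows"])
    cell = header["cellsize"]
    origin = (header["xllcorner"], header["yllcorner"] + h * cell)
    grid = GridContract(w, h, cell, origin, header.get("nodata_value", -9999.0))
    if np.all(np.abs(data) < 2**31) and np.all(data == np.round(data)):
        # integer-valued grid (binary habitat, class maps) reads back as int
        data = data.astype(np.int64)
    raster = Raster(data, grid)
    if expect is not None and grid != expect:
        raise GridMismatchError(
            f"raster {path} grid {grid} does not match expected contract {expect}"
        )
    return raster


def resample_to_grid(raster: Raster, target: GridContract, method: str = "bilinear") -> Raster:
    """Resample a raster onto a target grid.

    ``nearest`` is for categorical layers, ``bilinear`` for continuous ones.
    Resampling a raster onto its own grid is the identity.
    """
    if method not in ("nearest", "bilinear"):
        raise ValueError(f"unknown resampling method {method!r}")
    if raster.grid == target:
        return Raster(raster.data.copy(), target)
    src = raster.grid
    # extents must overlap
    src_x1 = src.origin[0] + src.width * src.cell_size
    src_y1 = src.origin[1] - src.height * src.cell_size
    tgt_x1 = target.origin[0] + target.width * target.cell_size
    tgt_y1 = target.origin[1] - target.height * target.cell_size
    if target.origin[0] >= src_x1 or tgt_x1 <= src.origin[0] or (
        target.origin[1] <= src_y1 or tgt_y1 >= src.origin[1]
    ):
        raise ValueError("target grid extent does not overlap the source raster")

    rows = np.arange(target.height)
    cols = np.arange(target.width)
    xs = target.origin[0] + (cols + 0.5) * target.cell_size
    ys = target.origin[1] - (rows + 0.5) * target.cell_size
    # fractional source indices of the target cell centers
    fc = (xs - src.origin[0]) / src.cell_size - 0.5
    fr = (src.origin[1] - ys) / src.cell_size - 0.5
    if method == "nearest":
        rr = np.clip(np.round(fr).astype(int), 0, src.height - 1)
        cc = np.clip(np.round(fc).astype(int), 0, src.width - 1)
        out = raster.data[np.ix_(rr, cc)]
    else:
        if np.issubdtype(raster.data.dtype, np.integer) and len(np.unique(raster.data)) <= 32:
            raise ValueError(
                "bilinear resampling of a categorical (integer-coded) layer; use method='nearest'"
            )
        r0 = np.clip(np.floor(fr).astype(int), 0, src.height - 1)
        c0 = np.clip(np.floor(fc).astype(int), 0, src.width - 1)
        r1 = np.clip(r0 + 1, 0, src.height - 1)
        c1 = np.clip(c0 + 1, 0, src.width - 1)
        wr = np.clip(fr - r0, 0.0, 1.0)[:, None]
        wc = np.clip(fc - c0, 0.0, 1.0)[None, :]
        d = raster.data.astype(float)
        out = (
            d[np.ix_(r0, c0)] * (1 - wr) * (1 - wc)
            + d[np.ix_(r0, c1)] * (1 - wr) * wc
            + d[np.ix_(r1, c0)] * wr * (1 - wc)
            + d[np.ix_(r1, c1)] * wr * wc
        )
    return Raster(out, target)


def constant_like(grid: GridContract, value: float, dtype=float) -> Raster:
    return Raster(np.full((grid.height, grid.width), value, dtype=dtype), grid)
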