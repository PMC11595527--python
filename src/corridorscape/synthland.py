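"""Synthetic landscapes with known ground truth.

Real studies of fragmented forest-pheasant habitat start from occurrence
records and environmental raster stacks that are rarely redistributable.
This module builds the equivalent inputs from scratch — a latent habitat
suitability field, partially collinear environmental covariates, presence
and background points, and binary patch mosaics with declared geometry —
so that every downstream stage (covariate screening, ensemble suitability
modeling, graph connectivity, morphological analysis, corridor mapping)
can be exercised against a known truth.

Everything is deterministic given the spec's integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .raster import GridContract, Raster


@dataclass(frozen=True)
class Hotspot:
    """A Gaussian bump of habitat quality.

    ``x, y`` are planar coordinates in meters, ``amplitude`` the peak
    suitability contribution in [0, 1], ``radius`` the Gaussian standard
    deviation in meters.
    """

    x: float
    y: float
    amplitude: float
    radius: float


@dataclass(frozen=True)
class LandscapeSpec:
    """Recipe for a synthetic suitability field: Gaussian bumps plus white
    noise, clipped to [0, 1]."""

    width: int
    height: int
    cell_size: float
    hotspots: tuple[Hotspot, ...] = ()
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width < 1 or self.height < 1:
            raise ValueError(f"landscape must be at least 1x1, got {self.width}x{self.height}")
        if self.cell_size <= 0:
            raise ValueError(f"cell_size must be positive, got {self.cell_size}")

    @property
    def grid(self) -> GridContract:
        return GridContract(self.width, self.height, self.cell_size)


@dataclass(frozen=True)
class Blob:
    """Axis-aligned habitat rectangle: origin (row, col), extent (h, w)
    in cells, with an optional absolute hole rectangle carved out."""

    origin: tuple[int, int]
    extent: tuple[int, int]
    hole: tuple[int, int, int, int] | None = None  # row, col, h, w


@dataclass(frozen=True)
class PatchMosaicSpec:
    """Recipe for a binary habitat raster made of rectangular blobs."""

    width: int
    height: int
    cell_size: float
    blobs: tuple[Blob, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        for b in self.blobs:
            r, c = b.origin
            h, w = b.extent
            if h < 1 or w < 1:
                raise ValueError(f"blob extent must be positive, got {b.extent}")
            if r < 0 or c < 0 or r + h > self.height or c + w > self.width:
                raise ValueError(f"blob {b} exceeds the {self.height}x{self.width} grid")

    @property
    def grid(self) -> GridContract:
        return GridContract(self.width, self.height, self.cell_size)


def make_suitability(spec: LandscapeSpec) -> Raster:
    """Latent habitat suitability: sum of Gaussian hotspots + white noise,
    clipped to [0, 1]. Deterministic given ``spec.seed``."""
    grid = spec.grid
    rows = np.arange(spec.height)
    cols = np.arange(spec.width)
    xs = grid.origin[0] + (cols + 0.5) * spec.cell_size
    ys = grid.origin[1] - (rows + 0.5) * spec.cell_size
    X, Y = np.meshgrid(xs, ys)
    field = np.zeros((spec.height, spec.width), dtype=float)
    for h in spec.hotspots:
        d2 = (X - h.x) ** 2 + (Y - h.y) ** 2
        field += h.amplitude * np.exp(-d2 / (2.0 * h.radius**2))
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        field += rng.normal(0.0, spec.noise_sd, size=field.shape)
    return Raster(np.clip(field, 0.0, 1.0), grid)


# monotone transforms applied to suitability to make "environmental" layers;
# cycled through so each informative covariate carries the signal differently
_MONOTONE = (
    lambda h: h,
    lambda h: h**2,
    lambda h: np.sqrt(h),
    lambda h: 1.0 / (1.0 + np.exp(-6.0 * (h - 0.5))),
    lambda h: np.log1p(4.0 * h),
)


def make_covariates(
    suitability: Raster,
    n_informative: int,
    n_collinear: int = 0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> dict[str, Raster]:
    """Environmental covariate stack with known structure.

    Informative layers are monotone transforms of the latent suitability
    plus Gaussian noise; collinear layers are linear combinations of the
    informative ones plus small noise, present specifically to trigger
    removal by a variance-inflation-factor screen.
    """
    if n_informative < 1:
        raise ValueError("need at least one informative covariate")
    rng = np.random.default_rng(seed)
    h = suitability.data.astype(float)
    layers: dict[str, Raster] = {}
    informative: list[np.ndarray] = []
    for i in range(n_informative):
        base = _MONOTONE[i % len(_MONOTONE)](h)
        if noise_sd > 0:
            base = base + rng.normal(0.0, noise_sd, size=base.shape)
        informative.append(base)
        layers[f"env{i + 1}"] = Raster(base, suitability.grid)
    for j in range(n_collinear):
        k = min(2 + j % 2, len(informative))
        picks = rng.choice(len(informative), size=k, replace=False)
        coefs = rng.uniform(0.5, 1.5, size=k)
        combo = sum(c * informative[p] for c, p in zip(coefs, picks))
        if noise_sd > 0:
            combo = combo + rng.normal(0.0, noise_sd * 0.5, size=combo.shape)
        layers[f"collin{j + 1}"] = Raster(combo, suitability.grid)
    return layers


def sample_occurrences(
    suitability: Raster,
    n_presence: int,
    n_background: int | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw presence and background points on the suitability grid.

    Presences are drawn with probability proportional to cell suitability
    (with replacement — several records may share a cell, as field surveys
    do); background (pseudo-absence) points are uniform over the grid.
    Coordinates are cell centers. Columns: id, x, y, label, source.
    """
    if n_presence < 1:
        raise ValueError("n_presence must be at least 1")
    if n_background is None:
        n_background = n_presence
    grid = suitability.grid
    w = suitability.data.astype(float).ravel()
    w = np.where(w > 0, w, 0.0)
    total = w.sum()
    if total <= 0:
        raise ValueError("cannot sample presences from an all-zero suitability field")
    rng = np.random.default_rng(seed)
    pres_idx = rng.choice(w.size, size=n_presence, replace=True, p=w / total)
    back_idx = rng.integers(0, w.size, size=n_background)

    def centers(flat_idx: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        rows, cols = np.unravel_index(flat_idx, suitability.data.shape)
        xs = grid.origin[0] + (cols + 0.5) * grid.cell_size
        ys = grid.origin[1] - (rows + 0.5) * grid.cell_size
        return xs, ys

    px, py = centers(pres_idx)
    bx, by = centers(back_idx)
    return pd.DataFrame(
        {
            "id": np.arange(n_presence + n_background),
            "x": np.concatenate([px, bx]),
            "y": np.concatenate([py, by]),
            "label": ["presence"] * n_presence + ["background"] * n_background,
            "source": ["field"] * n_presence + ["background"] * n_background,
        }
    )


def make_patch_mosaic(spec: PatchMosaicSpec) -> Raster:
    """Paint the spec's blobs (minus holes) onto a binary habitat raster.

    Overlapping blobs merge into a single connected component; the ground
    truth is whatever geometry ends up painted.
    """
    art = np.zeros((spec.height, spec.width), dtype=np.int64)
    for b in spec.blobs:
        r, c = b.origin
        h, w = b.extent
        art[r : r + h, c : c + w] = 1
    for b in spec.blobs:
        if b.hole is not None:
            hr, hc, hh, hw = b.hole
            art[hr : hr + hh, hc : hc + hw] = 0
    return Raster(art, spec.grid)


def _block(cx: float, cy: float, nx: int, ny: int, spacing: float = 2000.0,
           radius: float = 1200.0, amplitude: float = 1.0) -> list[Hotspot]:
    """A saturating cluster of bumps: overlapping Gaussians whose clipped sum
    forms a plateau-topped habitat block with steep margins."""
    out = []
    for i in range(nx):
        for j in range(ny):
            out.append(
                Hotspot(
                    x=cx + (i - (nx - 1) / 2) * spacing,
                    y=cy + (j - (ny - 1) / 2) * spacing,
                    amplitude=amplitude,
                    radius=radius,
                )
            )
    return out


def default_landscape(seed: int = 0) -> LandscapeSpec:
    """The package's reference study landscape.

    A 200x200 grid of 300 m cells (60x60 km, 3600 km²) at the
    movement-scale resolution used for this species. Habitat is three
    plateau-topped blocks (clusters of saturating Gaussian bumps) large
    enough to pass a 35 km² core filter, two small stepping-stone islets
    that fall below it, and low-amplitude ridges of intermediate
    suitability between blocks so that least-cost corridors have
    structure to follow. Habitat occupies roughly a tenth of the extent,
    giving presence/background data the discrimination reported for
    real forest-pheasant surveys.
    """
    hotspots = (
        *_block(15000.0, -18000.0, 6, 4, spacing=1500.0, radius=900.0),
        *_block(43000.0, -15000.0, 5, 5, spacing=1500.0, radius=900.0),
        *_block(31000.0, -45000.0, 6, 3, spacing=1500.0, radius=900.0),
        # stepping-stone islets (too small to be sources)
        Hotspot(x=28000.0, y=-17000.0, amplitude=1.0, radius=700.0),
        Hotspot(x=22000.0, y=-32000.0, amplitude=1.0, radius=700.0),
        # faint ridges of intermediate suitability between blocks
        Hotspot(x=28500.0, y=-16500.0, amplitude=0.22, radius=2200.0),
        Hotspot(x=34000.0, y=-16000.0, amplitude=0.22, radius=2000.0),
        Hotspot(x=22500.0, y=-31000.0, amplitude=0.22, radius=2200.0),
        Hotspot(x=26500.0, y=-38000.0, amplitude=0.22, radius=2000.0),
        Hotspot(x=38000.0, y=-30000.0, amplitude=0.22, radius=2200.0),
    )
    return LandscapeSpec(
        width=200,
        height=200,
        cell_size=300.0,
        hotspots=hotspots,
        noise_sd=0.005,
        seed=seed,
    )
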