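"""Planar raster grids and a text raster format.

All spatial data in this package live on a shared planar metric grid
(row-major, north-up, row 0 = northernmost). Rasters are stored as ESRI
ASCII grids (``.asc``), a self-describing plain-text format carrying the
same georeferencing fields as a single-band GeoTIFF (dimensions, lower-left
corner origin, cell size, nodata value).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
from scipy import ndimage

NODATA = -9999.0

CLIMATE_LAYERS = ("GDD", "BIO12", "BIO4", "BIO15")
SOIL_LAYERS = ("NITROGEN", "CALCAREOUS")
BIAS_LAYERS = ("OBSDENS", "DROAD", "DCITY")


@dataclass(frozen=True)
class GridSpec:
    """Geometry shared by every raster in a study.

    ``origin_x``/``origin_y`` are the coordinates of the lower-left corner
    of the grid, in metres. ``fine_to_coarse_factor`` relates the fine
    (model-fitting) grid to the coarse (diversity/prioritization) grid.
    """

    n_rows: int
    n_cols: int
    cell_size: float
    origin_x: float = 0.0
    origin_y: float = 0.0
    fine_to_coarse_factor: int = 1

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid dimensions must be >= 1")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be > 0")
        f = self.fine_to_coarse_factor
        if f < 1 or self.n_rows % f or self.n_cols % f:
            raise ValueError(
                f"fine grid {self.n_rows}x{self.n_cols} not divisible by "
                f"fine_to_coarse_factor={f}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax)."""
        return (
            self.origin_x,
            self.origin_y,
            self.origin_x + self.n_cols * self.cell_size,
            self.origin_y + self.n_rows * self.cell_size,
        )

    @property
    def cell_area(self) -> float:
        return self.cell_size**2

    @property
    def total_area(self) -> float:
        return self.n_cells * self.cell_area

    def coarse(self) -> "GridSpec":
        f = self.fine_to_coarse_factor
        return GridSpec(
            self.n_rows // f,
            self.n_cols // f,
            self.cell_size * f,
            self.origin_x,
            self.origin_y,
            1,
        )

    def cell_centres(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-cell centre coordinates as (X, Y) arrays of shape (n_rows, n_cols)."""
        xs = self.origin_x + (np.arange(self.n_cols) + 0.5) * self.cell_size
        ys_top_down = (
            self.origin_y + (self.n_rows - np.arange(self.n_rows) - 0.5) * self.cell_size
        )
        return np.meshgrid(xs, ys_top_down)

    def xy_to_rowcol(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Map point coordinates to (row, col); raises if any point is off-grid."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        col = np.floor((x - self.origin_x) / self.cell_size).astype(int)
        row_from_bottom = np.floor((y - self.origin_y) / self.cell_size).astype(int)
        # points exactly on the top/right edge belong to the last cell
        col = np.where((x == self.origin_x + self.n_cols * self.cell_size), self.n_cols - 1, col)
        row_from_bottom = np.where(
            y == self.origin_y + self.n_rows * self.cell_size, self.n_rows - 1, row_from_bottom
        )
        row = self.n_rows - 1 - row_from_bottom
        bad = (col < 0) | (col >= self.n_cols) | (row < 0) | (row >= self.n_rows)
        if np.any(bad):
            raise ValueError(f"{int(bad.sum())} point(s) fall outside the grid extent")
        return row, col


@dataclass
class LayerStack:
    """Named continuous and categorical rasters on one grid."""

    grid: GridSpec
    layers: dict[str, np.ndarray] = field(default_factory=dict)
    categorical_layers: dict[str, np.ndarray] = field(default_factory=dict)
    categories: dict[str, list[str]] = field(default_factory=dict)
    nodata_mask: np.ndarray | None = None  # True where nodata

    def __post_init__(self) -> None:
        for name, arr in {**self.layers, **self.categorical_layers}.items():
            if arr.shape != self.grid.shape:
                raise ValueError(f"layer {name!r} shape {arr.shape} != grid {self.grid.shape}")
        if self.nodata_mask is None:
            self.nodata_mask = np.zeros(self.grid.shape, dtype=bool)

    def copy(self) -> "LayerStack":
        return LayerStack(
            self.grid,
            {k: v.copy() for k, v in self.layers.items()},
            {k: v.copy() for k, v in self.categorical_layers.items()},
            {k: list(v) for k, v in self.categories.items()},
            self.nodata_mask.copy(),
        )

    def valid(self) -> np.ndarray:
        return ~self.nodata_mask


def write_ascii_grid(path: str | Path, grid: GridSpec, values: np.ndarray) -> None:
    values = np.asarray(values, dtype=float)
    if values.shape != grid.shape:
        raise ValueError("raster shape does not match grid")
    out = np.where(np.isnan(values), NODATA, values)
    header = (
        f"ncols {grid.n_cols}\n"
        f"nrows {grid.n_rows}\n"
        f"xllcorner {grid.origin_x}\n"
        f"yllcorner {grid.origin_y}\n"
        f"cellsize {grid.cell_size}\n"
        f"NODATA_value {NODATA}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, out, fmt="%.10g")


def read_ascii_grid(path: str | Path) -> tuple[GridSpec, np.ndarray]:
    with open(path) as fh:
        hdr = {}
        for _ in range(6):
            key, val = fh.readline().split()
            hdr[key.lower()] = float(val)
        values = np.loadtxt(fh, ndmin=2)
    grid = GridSpec(
        int(hdr["nrows"]),
        int(hdr["ncols"]),
        hdr["cellsize"],
        hdr.get("xllcorner", 0.0),
        hdr.get("yllcorner", 0.0),
    )
    values = np.where(values == hdr.get("nodata_value", NODATA), np.nan, values)
    return grid, values


class GridCompatError(ValueError):
    """Raised when two rasters disagree on geometry or nodata footprint."""


def validate_grid_compat(rasters: Mapping[str, tuple[GridSpec, np.ndarray]]) -> None:
    """Assert that all named rasters share dimensions, cell size, origin and nodata mask.

    Raises :class:`GridCompatError` naming both layers and the differing
    field on the first mismatch.
    """
    items = list(rasters.items())
    if len(items) < 2:
        raise ValueError("need at least two rasters to compare")
    ref_name, (ref_grid, ref_vals) = items[0]
    ref_mask = np.isnan(ref_vals)
    for name, (grid, vals) in items[1:]:
        for fld in ("n_rows", "n_cols", "cell_size", "origin_x", "origin_y"):
            a, b = getattr(ref_grid, fld), getattr(grid, fld)
            if a != b:
                raise GridCompatError(
                    f"{ref_name!r} vs {name!r}: {fld} differs ({a} != {b})"
                )
        mask = np.isnan(vals)
        if mask.shape != ref_mask.shape or np.any(mask != ref_mask):
            n_diff = int(np.sum(mask != ref_mask)) if mask.shape == ref_mask.shape else -1
            raise GridCompatError(
                f"{ref_name!r} vs {name!r}: nodata mask differs in {n_diff} cell(s)"
            )


def block_aggregate(values: np.ndarray, factor: int, how: str = "mean") -> np.ndarray:
    """Aggregate a fine raster to a coarse one by non-overlapping blocks."""
    r, c = values.shape
    if r % factor or c % factor:
        raise ValueError(f"shape {values.shape} not divisible by factor {factor}")
    blocks = values.reshape(r // factor, factor, c // factor, factor)
    if how == "mean":
        return blocks.mean(axis=(1, 3))
    if how == "sum":
        return blocks.sum(axis=(1, 3))
    if how == "max":
        return blocks.max(axis=(1, 3))
    raise ValueError(f"unknown aggregation {how!r}")


def distance_to(binary: np.ndarray, cell_size: float) -> np.ndarray:
    """Centre-to-centre Euclidean distance to the nearest True cell (0 inside)."""
    binary = np.asarray(binary, dtype=bool)
    if not binary.any():
        return np.full(binary.shape, np.inf)
    return ndimage.distance_transform_edt(~binary) * cell_size


def smooth_field(shape: tuple[int, int], rng: np.random.Generator, sigma: float) -> np.ndarray:
    """Standardized smooth Gaussian random field (mean 0, sd 1)."""
    raw = rng.standard_normal(shape)
    sm = ndimage.gaussian_filter(raw, sigma=sigma, mode="reflect")
    sd = sm.std()
    if sd == 0:
        return np.zeros(shape)
    return (sm - sm.mean()) / sd
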