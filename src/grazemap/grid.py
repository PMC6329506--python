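"""Raster grid geometry and the in-memory raster containers.

All rasters in the package live on a :class:`Grid`: a square-celled, axis-aligned
raster in a projected coordinate system with units of metres.  Raster indices are
0-based and row-major with the origin at the top-left corner (row 0 is the
northernmost row), matching the on-disk ESRI ASCII grid convention used by
:mod:`grazemap.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np

from .errors import GeometryError, ValidationError


@dataclass(frozen=True)
class Grid:
    """Geometry of a raster: shape, cell size and top-left corner coordinates.

    Parameters
    ----------
    n_rows, n_cols
        Raster shape.
    cell_size
        Edge length of the (square) cells in metres.
    x_origin, y_origin
        Projected coordinates (m) of the *top-left corner* of the top-left cell.
    crs_label
        Free-text label of the projected CRS; purely descriptive.
    """

    n_rows: int
    n_cols: int
    cell_size: float = 500.0
    x_origin: float = 0.0
    y_origin: float = 0.0
    crs_label: str = "local-metric"

    def __post_init__(self) -> None:
        if self.n_rows <= 0 or self.n_cols <= 0:
            raise ValidationError("grid shape must be positive")
        if not self.cell_size > 0:
            raise ValidationError("cell_size must be > 0")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def n_pixels(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def cell_area(self) -> float:
        """Area of one pixel in m²."""
        return self.cell_size * self.cell_size

    def same_geometry(self, other: "Grid") -> bool:
        return (
            self.shape == other.shape
            and self.cell_size == other.cell_size
            and self.x_origin == other.x_origin
            and self.y_origin == other.y_origin
        )

    def require_same_geometry(self, other: "Grid", what: str = "raster") -> None:
        if not self.same_geometry(other):
            raise GeometryError(f"{what} grids differ: {self} vs {other}")

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) coordinates of every cell center as 1-D arrays of length n_pixels."""
        cols = np.arange(self.n_cols)
        rows = np.arange(self.n_rows)
        x = self.x_origin + (cols + 0.5) * self.cell_size
        y = self.y_origin - (rows + 0.5) * self.cell_size
        xx, yy = np.meshgrid(x, y)
        return xx.ravel(), yy.ravel()

    def center_of(self, row: np.ndarray | int, col: np.ndarray | int):
        x = self.x_origin + (np.asarray(col) + 0.5) * self.cell_size
        y = self.y_origin - (np.asarray(row) + 0.5) * self.cell_size
        return x, y


class CoverClass(IntEnum):
    """Categorical land-cover legend.

    Bare soil is deliberately its own class: it is grazeable (treated like
    grassland on the energy side) but kept distinguishable in the input map.
    """

    GRASSLAND = 1
    BARE = 2
    CROPLAND = 3
    FOREST = 4
    WATER = 5
    ICE = 6
    ARTIFICIAL = 7
    PRESERVE = 8


#: classes on which grazing can occur
GRAZEABLE_CLASSES = frozenset({CoverClass.GRASSLAND, CoverClass.BARE, CoverClass.CROPLAND})
#: classes masked out of the supply map entirely
EXCLUDED_CLASSES = frozenset(
    {CoverClass.FOREST, CoverClass.WATER, CoverClass.ICE, CoverClass.ARTIFICIAL, CoverClass.PRESERVE}
)


@dataclass
class NPPRaster:
    """Annual total net primary productivity in gC/m²/yr; NaN marks missing."""

    grid: Grid
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise GeometryError("NPP array shape does not match grid")
        finite = np.isfinite(self.values)
        if np.any(self.values[finite] < 0):
            raise ValidationError("NPP must be non-negative")


@dataclass
class CoverRaster:
    """Per-pixel land-cover class codes (see :class:`CoverClass`)."""

    grid: Grid
    classes: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.classes = np.asarray(self.classes, dtype=np.int16)
        if self.classes.shape != self.grid.shape:
            raise GeometryError("cover array shape does not match grid")
        valid = np.isin(self.classes, [int(c) for c in CoverClass])
        if not valid.all():
            bad = np.unique(self.classes[~valid])
            raise ValidationError(f"unknown cover class codes: {bad.tolist()}")


@dataclass
class DistrictRaster:
    """Per-pixel district id (integer codes, negative = outside any district)."""

    grid: Grid
    district_id: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.district_id = np.asarray(self.district_id, dtype=np.int32)
        if self.district_id.shape != self.grid.shape:
            raise GeometryError("district array shape does not match grid")


def resample_continuous(grid: Grid, values: np.ndarray, factor: int) -> tuple[Grid, np.ndarray]:
    """Aggregate a continuous raster by an integer factor with an area-weighted mean.

    Cells are square and equal-area, so the area-weighted mean of a block is the
    arithmetic mean of its member cells; NaNs are ignored unless a whole block is
    missing.  Shape must be divisible by ``factor``.
    """
    if factor < 1:
        raise ValidationError("resampling factor must be >= 1")
    if grid.n_rows % factor or grid.n_cols % factor:
        raise GeometryError("grid shape not divisible by resampling factor")
    v = np.asarray(values, dtype=float).reshape(
        grid.n_rows // factor, factor, grid.n_cols // factor, factor
    )
    with np.errstate(invalid="ignore"):
        out = np.nanmean(v, axis=(1, 3))
    new = Grid(
        grid.n_rows // factor,
        grid.n_cols // factor,
        grid.cell_size * factor,
        grid.x_origin,
        grid.y_origin,
        grid.crs_label,
    )
    return new, out


def resample_categorical(grid: Grid, values: np.ndarray, factor: int) -> tuple[Grid, np.ndarray]:
    """Aggregate a categorical raster by an integer factor with nearest-neighbour
    (the class of the block's central cell)."""
    if factor < 1:
        raise ValidationError("resampling factor must be >= 1")
    if grid.n_rows % factor or grid.n_cols % factor:
        raise GeometryError("grid shape not divisible by resampling factor")
    v = np.asarray(values)
    mid = factor // 2
    out = v[mid::factor, mid::factor]
    new = Grid(
        grid.n_rows // factor,
        grid.n_cols // factor,
        grid.cell_size * factor,
        grid.x_origin,
        grid.y_origin,
        grid.crs_label,
    )
    return new, out.copy()
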