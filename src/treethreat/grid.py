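"""Regular WGS84 lat-lon grids and in-memory raster containers.

All analysis layers (climate-zone mosaic, water mask, binary change maps,
annual stacks) live on a shared :class:`GridSpec`: a regular grid in
geographic coordinates with half-open cells ``[west, east) x [south, north)``.
Row 0 is the southernmost row; arrays are indexed ``values[row, col]``.

Cell areas are geodesic approximations on a spherical Earth: a cell of
``res`` degrees centred at latitude phi has area ``(pi*R/180 * res)^2 *
cos(phi)`` km^2 with R = 6371.0088 km (the IUGG mean Earth radius).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import shapely

EARTH_RADIUS_KM = 6371.0088
#: km per degree of latitude on the sphere above (also used for 1-km buffers)
KM_PER_DEG = np.pi * EARTH_RADIUS_KM / 180.0


class GridMismatchError(ValueError):
    """Two layers that must share a grid do not."""


@dataclass(frozen=True)
class GridSpec:
    """Regular WGS84 grid with per-cell geodesic area.

    Parameters
    ----------
    lon_min, lat_min : float
        Coordinates of the grid's south-west corner (degrees).
    resolution : float
        Cell edge in degrees; cells are square in degree space.
    n_cols, n_rows : int
        Grid dimensions.
    """

    lon_min: float
    lat_min: float
    resolution: float
    n_cols: int
    n_rows: int

    def __post_init__(self) -> None:
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")
        if self.n_cols < 1 or self.n_rows < 1:
            raise ValueError("grid must have at least one cell")
        if not (-90 <= self.lat_min and self.lat_max <= 90):
            raise ValueError("grid exceeds valid latitudes")

    @classmethod
    def from_bbox(cls, bbox: Sequence[float], resolution: float) -> "GridSpec":
        """Grid covering ``(lon_min, lat_min, lon_max, lat_max)``."""
        lon_min, lat_min, lon_max, lat_max = bbox
        if lon_max <= lon_min or lat_max <= lat_min:
            raise ValueError("bbox is degenerate")
        n_cols = int(round((lon_max - lon_min) / resolution))
        n_rows = int(round((lat_max - lat_min) / resolution))
        return cls(lon_min, lat_min, resolution, max(n_cols, 1), max(n_rows, 1))

    @property
    def lon_max(self) -> float:
        return self.lon_min + self.n_cols * self.resolution

    @property
    def lat_max(self) -> float:
        return self.lat_min + self.n_rows * self.resolution

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    def lat_centers(self) -> np.ndarray:
        return self.lat_min + (np.arange(self.n_rows) + 0.5) * self.resolution

    def lon_centers(self) -> np.ndarray:
        return self.lon_min + (np.arange(self.n_cols) + 0.5) * self.resolution

    def cell_area_km2(self, rows: np.ndarray | int) -> np.ndarray | float:
        """Geodesic area (km^2) of cells in the given row(s)."""
        lat = self.lat_min + (np.asarray(rows) + 0.5) * self.resolution
        return (KM_PER_DEG * self.resolution) ** 2 * np.cos(np.radians(lat))

    def area_grid_km2(self) -> np.ndarray:
        """Full (n_rows, n_cols) array of cell areas."""
        col_areas = self.cell_area_km2(np.arange(self.n_rows))
        return np.repeat(col_areas[:, None], self.n_cols, axis=1)

    def index_of(self, lon: np.ndarray, lat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(row, col) of the half-open cell containing each point.

        Points on the north/east outer edge are assigned to the last cell so
        that the grid covers its closed bounding box.
        """
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        col = np.floor((lon - self.lon_min) / self.resolution).astype(int)
        row = np.floor((lat - self.lat_min) / self.resolution).astype(int)
        col = np.clip(col, 0, self.n_cols - 1)
        row = np.clip(row, 0, self.n_rows - 1)
        return row, col

    def cell_bounds(self, row: int, col: int) -> tuple[float, float, float, float]:
        west = self.lon_min + col * self.resolution
        south = self.lat_min + row * self.resolution
        return (west, south, west + self.resolution, south + self.resolution)

    def cell_boxes(self, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        """Vectorized shapely boxes for (rows, cols) pairs."""
        west = self.lon_min + np.asarray(cols) * self.resolution
        south = self.lat_min + np.asarray(rows) * self.resolution
        return shapely.box(west, south, west + self.resolution, south + self.resolution)

    def contains(self, lon: np.ndarray, lat: np.ndarray) -> np.ndarray:
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        return (
            (lon >= self.lon_min)
            & (lon <= self.lon_max)
            & (lat >= self.lat_min)
            & (lat <= self.lat_max)
        )


@dataclass
class Raster:
    """A single layer on a :class:`GridSpec`."""

    grid: GridSpec
    values: np.ndarray
    nodata: float | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.shape != self.grid.shape:
            raise GridMismatchError(
                f"values shape {self.values.shape} != grid shape {self.grid.shape}"
            )


@dataclass
class AnnualStack:
    """One raster per calendar year for a single variable.

    ``values`` has shape (n_years, n_rows, n_cols). Years are strictly
    increasing; temperatures are stored in degrees C, VPD in Pa,
    precipitation in mm, burned area as a 0/1 indicator.
    """

    variable: str
    years: list[int]
    grid: GridSpec
    values: np.ndarray
    units: str = ""

    def __post_init__(self) -> None:
        self.years = [int(y) for y in self.years]
        self.values = np.asarray(self.values)
        if np.any(np.diff(self.years) <= 0):
            raise ValueError("years must be strictly increasing")
        if self.values.shape != (len(self.years), *self.grid.shape):
            raise GridMismatchError("stack shape does not match years x grid")

    @property
    def n_years(self) -> int:
        return len(self.years)

    def layer(self, year: int) -> Raster:
        return Raster(self.grid, self.values[self.years.index(year)])


def check_same_grid(*layers) -> GridSpec:
    """Assert all layers share one GridSpec and return it."""
    grids = {layer.grid for layer in layers}
    if len(grids) != 1:
        raise GridMismatchError("layers do not share a grid")
    return next(iter(grids))
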