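"""Refined species extents: 95% minimum convex polygons masked by climate and water.

A raw extent of occurrence (the convex hull of all records) can sweep in
vast areas a species never occupies. The refinement used here follows the
range-building convention of home-range MCP estimation: drop the 5% of
records farthest from the coordinate centroid (guarding against country
centroids and other apparent outliers), take the convex hull of the rest,
then mask out climate zones the species does not occupy and water.

Climatic suitability is decided from the occurrence records themselves: a
1-km-radius disc is drawn around every record; grid cells overlapping a
disc by at least 25% of the disc's area are collected, and every climate
zone covering at least 5% of the collected cells counts as suitable.

The refined extent is stored as per-cell coverage weights: w = the exact
fraction of the cell covered by the polygon, restricted to suitable,
non-water cells. Extent area (EOO_area) is the coverage-weighted sum of
geodesic cell areas — the same quantity an exact zonal-statistics extraction
would produce.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import shapely
from shapely.geometry import MultiPoint, Point, Polygon

from .grid import GridSpec, KM_PER_DEG, Raster

DEFAULT_INCLUSION = 0.95
DEFAULT_BUFFER_KM = 1.0
DEFAULT_ZONE_FRAC = 0.05
DEFAULT_CELL_COVER = 0.25

#: Red List criterion-B extent classes (km^2).
WIDE_EXTENT_KM2 = 20_000.0
REGIONAL_EXTENT_KM2 = 5_000.0


class MinimalAreaError(ValueError):
    """Too few records to build a convex-polygon extent."""


class DegenerateHullError(ValueError):
    """The minimum convex polygon is a line or point and covers no area."""


class UnusableZoneError(ValueError):
    """No grid cell met the buffer-coverage rule for any record."""


class EmptyExtentError(ValueError):
    """Masking left no suitable land cell inside the polygon."""


class AntimeridianError(ValueError):
    """Extents spanning the +/-180 degree meridian are not supported."""


@dataclass
class ExtentMask:
    """A species' refined extent on an analysis grid.

    ``rows``/``cols``/``weights`` list the surviving cells; weights are the
    exact polygon-coverage fraction of each cell, in (0, 1]. ``eoo_area_km2``
    is the coverage-weighted geodesic area.
    """

    species_id: str
    polygon: Polygon
    suitable_zones: frozenset[int]
    grid: GridSpec
    rows: np.ndarray
    cols: np.ndarray
    weights: np.ndarray
    eoo_area_km2: float = field(init=False)

    def __post_init__(self) -> None:
        self.rows = np.asarray(self.rows, dtype=np.int64)
        self.cols = np.asarray(self.cols, dtype=np.int64)
        self.weights = np.asarray(self.weights, dtype=float)
        if np.any((self.weights <= 0) | (self.weights > 1 + 1e-12)):
            raise ValueError("coverage weights must lie in (0, 1]")
        self.weights = np.minimum(self.weights, 1.0)
        self.eoo_area_km2 = float(np.sum(self.weights * self.grid.cell_area_km2(self.rows)))

    @property
    def n_cells(self) -> int:
        return int(self.rows.size)

    def cell_areas_km2(self) -> np.ndarray:
        return np.asarray(self.grid.cell_area_km2(self.rows))


def _haversine_km(lon0: float, lat0: float, lon: np.ndarray, lat: np.ndarray) -> np.ndarray:
    """Great-circle distances from one point to many (km)."""
    p0, p1 = np.radians(lat0), np.radians(lat)
    dphi = p1 - p0
    dlmb = np.radians(lon) - np.radians(lon0)
    a = np.sin(dphi / 2) ** 2 + np.cos(p0) * np.cos(p1) * np.sin(dlmb / 2) ** 2
    from .grid import EARTH_RADIUS_KM
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0, 1)))


def mcp(lon, lat, inclusion: float = DEFAULT_INCLUSION) -> Polygon:
    """Minimum convex polygon of the ``inclusion`` fraction of records
    nearest the coordinate centroid.

    The ``round((1 - inclusion) * n)`` records with the largest great-circle
    distance to the arithmetic centroid of the coordinates are removed
    before hull construction; ties are broken by record order (earlier
    records kept). ``inclusion=1.0`` is the full convex hull.

    Raises ``MinimalAreaError`` for fewer than five records and
    ``DegenerateHullError`` when the hull is a line or point.
    """
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    n = lon.size
    if n < 5:
        raise MinimalAreaError(f"need >=5 records for a convex polygon, got {n}")
    if not 0 < inclusion <= 1:
        raise ValueError("inclusion must be in (0, 1]")
    n_drop = int(np.floor((1.0 - inclusion) * n + 0.5))
    if n_drop:
        d = _haversine_km(float(lon.mean()), float(lat.mean()), lon, lat)
        # stable sort: among equal distances the later record is dropped first
        order = np.argsort(d, kind="stable")
        keep = np.sort(order[: n - n_drop])
        lon, lat = lon[keep], lat[keep]
    hull = MultiPoint(np.column_stack([lon, lat])).convex_hull
    if not isinstance(hull, Polygon) or hull.area == 0:
        raise DegenerateHullError("minimum convex polygon covers no area")
    if hull.bounds[0] < -180 or hull.bounds[2] > 180:
        raise AntimeridianError("polygon crosses the antimeridian")
    return hull


def _buffer_cells(
    lon0: float, lat0: float, zone_raster: Raster, buffer_km: float, cell_cover: float
) -> list[tuple[int, int]]:
    """Cells overlapping the 1-km disc around a record by >= cell_cover of
    the disc's area. Computed in a local tangent plane in km."""
    grid = zone_raster.grid
    coslat = np.cos(np.radians(lat0))
    # disc in the local km plane centred at the record
    disc = Point(0.0, 0.0).buffer(buffer_km, quad_segs=64)
    disc_area = disc.area
    dlat = buffer_km / KM_PER_DEG
    dlon = buffer_km / (KM_PER_DEG * coslat)
    r0, c0 = grid.index_of(lon0 - dlon, lat0 - dlat)
    r1, c1 = grid.index_of(lon0 + dlon, lat0 + dlat)
    out = []
    for r in range(int(r0), int(r1) + 1):
        for c in range(int(c0), int(c1) + 1):
            w, s, e, nth = grid.cell_bounds(r, c)
            cell = shapely.box(
                (w - lon0) * KM_PER_DEG * coslat,
                (s - lat0) * KM_PER_DEG,
                (e - lon0) * KM_PER_DEG * coslat,
                (nth - lat0) * KM_PER_DEG,
            )
            if cell.intersection(disc).area >= cell_cover * disc_area - 1e-12:
                out.append((r, c))
    return out


def suitable_zones(
    lon,
    lat,
    zone_raster: Raster,
    buffer_km: float = DEFAULT_BUFFER_KM,
    zone_frac: float = DEFAULT_ZONE_FRAC,
    cell_cover: float = DEFAULT_CELL_COVER,
) -> frozenset[int]:
    """Climate zones suitable for a species, decided from its records.

    Collects, over all records, the grid cells whose overlap with the 1-km
    disc around the record is at least ``cell_cover`` of the disc area
    (inclusive), then returns every zone covering at least ``zone_frac`` of
    the distinct collected cells (inclusive).
    """
    lon = np.atleast_1d(np.asarray(lon, dtype=float))
    lat = np.atleast_1d(np.asarray(lat, dtype=float))
    cells: set[tuple[int, int]] = set()
    for x, y in zip(lon, lat):
        cells.update(_buffer_cells(float(x), float(y), zone_raster, buffer_km, cell_cover))
    if not cells:
        raise UnusableZoneError("no grid cell met the buffer-coverage rule")
    rr = np.array([c[0] for c in cells])
    cc = np.array([c[1] for c in cells])
    zones, counts = np.unique(zone_raster.values[rr, cc], return_counts=True)
    share = counts / counts.sum()
    return frozenset(int(z) for z, s in zip(zones, share) if s >= zone_frac - 1e-12)


def refine_extent(
    species_id: str,
    polygon: Polygon,
    zones: frozenset[int] | set[int],
    zone_raster: Raster,
    water_mask: Raster,
    grid: GridSpec | None = None,
) -> ExtentMask:
    """Mask a species' polygon to suitable, non-water cells with exact
    coverage weights.

    Every grid cell intersecting the polygon gets weight w = exact fraction
    of the cell covered by the polygon; cells whose zone is unsuitable or
    which are water (mask value 1) are dropped. Raises ``EmptyExtentError``
    when nothing survives (the species is then routed to the minimal-area
    path).
    """
    if grid is None:
        grid = zone_raster.grid
    if not zones:
        raise UnusableZoneError("empty suitable-zone set")
    if polygon.is_empty or polygon.area == 0:
        raise DegenerateHullError("polygon covers no area")
    if polygon.bounds[0] < -180 or polygon.bounds[2] > 180:
        raise AntimeridianError("polygon crosses the antimeridian")

    minx, miny, maxx, maxy = polygon.bounds
    r0, c0 = grid.index_of(minx, miny)
    r1, c1 = grid.index_of(maxx, maxy)
    rows, cols = np.meshgrid(
        np.arange(int(r0), int(r1) + 1), np.arange(int(c0), int(c1) + 1), indexing="ij"
    )
    rows, cols = rows.ravel(), cols.ravel()
    boxes = grid.cell_boxes(rows, cols)
    inter = shapely.area(shapely.intersection(boxes, polygon))
    w = inter / (grid.resolution**2)
    keep = w > 1e-12
    rows, cols, w = rows[keep], cols[keep], np.minimum(w[keep], 1.0)

    zone_ok = np.isin(zone_raster.values[rows, cols], list(zones))
    land_ok = water_mask.values[rows, cols] == 0
    keep = zone_ok & land_ok
    rows, cols, w = rows[keep], cols[keep], w[keep]
    if rows.size == 0:
        raise EmptyExtentError(f"no suitable land cell left for {species_id}")
    return ExtentMask(species_id, polygon, frozenset(int(z) for z in zones), grid, rows, cols, w)


def extent_class(area_km2: float) -> str:
    """Red List criterion-B size class: wide / regional / local."""
    if area_km2 < 0:
        raise ValueError("extent area cannot be negative")
    if area_km2 > WIDE_EXTENT_KM2:
        return "wide"
    if area_km2 > REGIONAL_EXTENT_KM2:
        return "regional"
    return "local"


def polygon_area_km2(polygon: Polygon, n_lat_bands: int = 512) -> float:
    """Geodesic area of a lon-lat polygon (km^2) via latitude banding.

    Slices the polygon into latitude bands and weights each band's planar
    (degree-space) area by cos(latitude of band centre); consistent with the
    per-cell geodesic areas used for the coverage-weighted sum.
    """
    minx, miny, maxx, maxy = polygon.bounds
    edges = np.linspace(miny, maxy, n_lat_bands + 1)
    total = 0.0
    for s, n in zip(edges[:-1], edges[1:]):
        band = shapely.box(minx - 1, s, maxx + 1, n)
        a = polygon.intersection(band).area  # degree^2
        total += a * KM_PER_DEG**2 * np.cos(np.radians((s + n) / 2))
    return float(total)
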