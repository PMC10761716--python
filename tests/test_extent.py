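"""MCP construction, zone suitability, coverage-weighted extent areas."""

import numpy as np
import pytest
import shapely
from shapely.geometry import MultiPoint, Polygon, box

from treethreat.extent import (
    DegenerateHullError,
    MinimalAreaError,
    UnusableZoneError,
    EmptyExtentError,
    extent_class,
    mcp,
    polygon_area_km2,
    refine_extent,
    suitable_zones,
)
from treethreat.grid import EARTH_RADIUS_KM, GridSpec, Raster


def _haversine(lon0, lat0, lon, lat):
    p0, p1 = np.radians(lat0), np.radians(lat)
    a = (np.sin((p1 - p0) / 2) ** 2
         + np.cos(p0) * np.cos(p1) * np.sin((np.radians(lon) - np.radians(lon0)) / 2) ** 2)
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a))


def test_full_inclusion_hull_is_unit_square():
    lon = [0, 0, 1, 1, 0.5]
    lat = [0, 1, 0, 1, 0.5]
    hull = mcp(lon, lat, inclusion=1.0)
    assert hull.equals(box(0, 0, 1, 1))


def test_mcp95_equals_hull_of_centroid_nearest_points(rng):
    lon = rng.uniform(0, 5, 100)
    lat = rng.uniform(0, 5, 100)
    got = mcp(lon, lat, inclusion=0.95)
    # oracle: drop the 5 farthest (great-circle) from the coordinate centroid
    d = _haversine(lon.mean(), lat.mean(), lon, lat)
    keep = np.argsort(d, kind="stable")[:95]
    expected = MultiPoint(np.column_stack([lon[keep], lat[keep]])).convex_hull
    assert got.equals(expected)


def test_collinear_points_raise_degenerate_hull():
    lon = np.linspace(0, 1, 7)
    with pytest.raises(DegenerateHullError):
        mcp(lon, lon * 2.0, inclusion=1.0)


def test_fewer_than_five_points_is_minimal_area():
    with pytest.raises(MinimalAreaError):
        mcp([0, 1, 2, 3], [0, 1, 0, 1])


def _zone_raster(values):
    values = np.asarray(values)
    grid = GridSpec(0.0, 0.0, 0.1, values.shape[1], values.shape[0])
    return Raster(grid, values)


def test_single_zone_raster_gives_that_zone():
    zones = _zone_raster(np.full((5, 5), 7))
    got = suitable_zones([0.25], [0.25], zones)
    assert got == {7}


def test_zone_shares_96_4_keep_only_majority_zone():
    # 25 records in 25 distinct cells: 24 in zone 1, one in zone 2
    values = np.ones((5, 5), dtype=int)
    values[4, 4] = 2
    zones = _zone_raster(values)
    lon = [0.05 + 0.1 * c for r in range(5) for c in range(5)]
    lat = [0.05 + 0.1 * r for r in range(5) for c in range(5)]
    got = suitable_zones(lon, lat, zones)
    assert got == {1}


def test_zone_share_exactly_five_percent_retained():
    # 20 distinct cells, one of zone 2 -> share exactly 5%, inclusive rule
    values = np.ones((4, 5), dtype=int)
    values[3, 4] = 2
    zones = _zone_raster(values)
    lon = [0.05 + 0.1 * c for r in range(4) for c in range(5)]
    lat = [0.05 + 0.1 * r for r in range(4) for c in range(5)]
    got = suitable_zones(lon, lat, zones)
    assert got == {1, 2}


def _land(grid):
    return Raster(grid, np.zeros(grid.shape, dtype=np.int8))


def test_polygon_over_four_full_cells_sums_their_areas(unit_grid):
    poly = box(0.2, 0.2, 0.4, 0.4)  # cells (2,2),(2,3),(3,2),(3,3)
    zones = Raster(unit_grid, np.ones(unit_grid.shape, dtype=int))
    ext = refine_extent("sp", poly, {1}, zones, _land(unit_grid))
    assert ext.n_cells == 4
    np.testing.assert_allclose(ext.weights, 1.0)
    expected = sum(unit_grid.cell_area_km2(r) for r in (2, 2, 3, 3))
    assert ext.eoo_area_km2 == pytest.approx(expected, rel=1e-12)


def test_water_masking_halves_equal_latitude_extent(unit_grid):
    poly = box(0.2, 0.3, 0.6, 0.4)  # four cells in one latitude row
    zones = Raster(unit_grid, np.ones(unit_grid.shape, dtype=int))
    water = np.zeros(unit_grid.shape, dtype=np.int8)
    water[3, 2] = water[3, 3] = 1  # flood two of the four
    full = refine_extent("sp", poly, {1}, zones, _land(unit_grid))
    half = refine_extent("sp", poly, {1}, zones, Raster(unit_grid, water))
    assert half.eoo_area_km2 == pytest.approx(full.eoo_area_km2 / 2, rel=1e-12)


def test_zero_surviving_cells_raises_empty_extent(unit_grid):
    poly = box(0.2, 0.2, 0.4, 0.4)
    zones = Raster(unit_grid, np.ones(unit_grid.shape, dtype=int))
    with pytest.raises(EmptyExtentError):
        refine_extent("sp", poly, {99}, zones, _land(unit_grid))
    with pytest.raises(UnusableZoneError):
        refine_extent("sp", poly, set(), zones, _land(unit_grid))


def test_coverage_weights_match_monte_carlo_oracle(rng):
    grid = GridSpec(0.0, 40.0, 0.2, 10, 10)  # mid-latitude: areas vary by row
    zones = Raster(grid, np.ones(grid.shape, dtype=int))
    for _ in range(3):
        pts = rng.uniform(0.2, 1.8, size=(8, 2))
        poly = MultiPoint(np.column_stack([pts[:, 0], 40 + pts[:, 1]])).convex_hull
        ext = refine_extent("sp", poly, {1}, zones, _land(grid))
        # oracle: 10^4 uniform sample points per cell
        area_mc = 0.0
        for r in range(grid.n_rows):
            for c in range(grid.n_cols):
                w, s, e, n = grid.cell_bounds(r, c)
                xs = rng.uniform(w, e, 10_000)
                ys = rng.uniform(s, n, 10_000)
                frac = shapely.contains_xy(poly, xs, ys).mean()
                area_mc += frac * grid.cell_area_km2(r)
        assert ext.eoo_area_km2 == pytest.approx(area_mc, rel=5e-3)


def test_masking_monotonicity(rng, unit_grid):
    pts = rng.uniform(0.1, 0.9, size=(12, 2))
    poly = MultiPoint(pts).convex_hull
    zone_vals = rng.integers(1, 4, unit_grid.shape)
    zones = Raster(unit_grid, zone_vals)
    land = _land(unit_grid)
    one = refine_extent("sp", poly, {1}, zones, land)
    two = refine_extent("sp", poly, {1, 2}, zones, land)
    all_z = refine_extent("sp", poly, {1, 2, 3}, zones, land)
    assert one.eoo_area_km2 <= two.eoo_area_km2 <= all_z.eoo_area_km2
    assert all_z.eoo_area_km2 <= polygon_area_km2(poly) * 1.001


@pytest.mark.parametrize("area,expected", [
    (25_000, "wide"), (10_000, "regional"), (20_000, "regional"),
    (5_000, "local"), (0, "local"),
])
def test_extent_class_thresholds(area, expected):
    assert extent_class(area) == expected


def test_negative_area_rejected():
    with pytest.raises(ValueError):
        extent_class(-1.0)
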