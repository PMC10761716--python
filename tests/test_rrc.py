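"""Threat-layer preprocessing and rate-of-recent-change calculations."""

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import box

from treethreat.extent import ExtentMask
from treethreat.grid import AnnualStack, GridSpec, Raster
from treethreat.rrc import (
    RRCRecord,
    annual_mean_seasonality,
    annual_min_max_temperature,
    bidirectional_rrc,
    build_builtup_change,
    build_cropland_change,
    build_deforestation,
    build_treecover_decline,
    impute_minimal_species,
    records_to_table,
    remove_outliers,
    unidirectional_rrc,
)


def _grid(n_cols=10, n_rows=1, res=0.1, lat_min=0.0):
    return GridSpec(0.0, lat_min, res, n_cols, n_rows)


def _full_extent(grid, species="sp"):
    """Extent covering every cell of the grid with weight 1."""
    rows, cols = np.meshgrid(np.arange(grid.n_rows), np.arange(grid.n_cols), indexing="ij")
    poly = box(grid.lon_min, grid.lat_min, grid.lon_max, grid.lat_max)
    return ExtentMask(species, poly, frozenset({1}), grid,
                      rows.ravel(), cols.ravel(), np.ones(rows.size))


# ------------------------------------------------------------- layer prep

def test_cropland_baseline_rule():
    grid = _grid(3)
    # cell 0: cropland only in baseline; cell 1: first in a later epoch; cell 2: never
    epochs = [np.array([[1, 0, 0]]), np.array([[0, 0, 0]]), np.array([[0, 1, 0]]),
              np.array([[0, 0, 0]]), np.array([[0, 1, 0]])]
    out = build_cropland_change([Raster(grid, e) for e in epochs])
    np.testing.assert_array_equal(out.values, [[0, 1, 0]])


def test_cropland_matches_cellwise_truth_table(rng):
    grid = _grid(40, 5)
    epochs = [Raster(grid, rng.integers(0, 2, grid.shape)) for _ in range(5)]
    out = build_cropland_change(epochs)
    for r in range(grid.n_rows):
        for c in range(grid.n_cols):
            post = any(epochs[k].values[r, c] for k in range(1, 5))
            expected = int(post and not epochs[0].values[r, c])
            assert out.values[r, c] == expected


def test_cropland_wrong_layer_count():
    grid = _grid(2)
    with pytest.raises(ValueError):
        build_cropland_change([Raster(grid, np.zeros(grid.shape))] * 4)


@pytest.mark.parametrize("series,expected", [
    ((80, 80, 80, 80), 0),   # stable
    ((80, 74, 74, 74), 1),   # one 6-point drop
    ((80, 77, 74, 71), 0),   # gradual 3-point drops never reach 5
    ((80, 85, 78, 90), 1),   # 7-point drop between increases
])
def test_treecover_decline_consecutive_rule(series, expected):
    grid = _grid(1)
    maps = [Raster(grid, np.array([[v]], dtype=float)) for v in series]
    assert build_treecover_decline(maps).values[0, 0] == expected


def test_treecover_range_validated():
    grid = _grid(1)
    maps = [Raster(grid, np.array([[v]], dtype=float)) for v in (80, 80, 80, 120)]
    with pytest.raises(ValueError):
        build_treecover_decline(maps)


def test_builtup_codes():
    grid = _grid(3)
    out = build_builtup_change(Raster(grid, np.array([[0, 1, 2]])))
    np.testing.assert_array_equal(out.values, [[0, 0, 1]])
    with pytest.raises(ValueError):
        build_builtup_change(Raster(grid, np.array([[0, 3, 1]])))


def test_deforestation_passthrough(rng):
    grid = _grid(6, 4)
    v = rng.integers(0, 2, grid.shape)
    out = build_deforestation(Raster(grid, v))
    np.testing.assert_array_equal(out.values, v)
    with pytest.raises(ValueError):
        build_deforestation(Raster(grid, v + 1))


def test_annual_min_max_and_seasonality(rng):
    grid = _grid(5, 3)
    months = [Raster(grid, rng.normal(10, 5, grid.shape)) for _ in range(12)]
    mn, mx = annual_min_max_temperature(months)
    mean, sd = annual_mean_seasonality(months)
    stack = np.stack([m.values for m in months])
    np.testing.assert_allclose(mn.values, stack.min(axis=0))
    np.testing.assert_allclose(mx.values, stack.max(axis=0))
    np.testing.assert_allclose(mean.values, stack.mean(axis=0))
    np.testing.assert_allclose(sd.values, stack.std(axis=0))
    # closed form: 6/6 alternation of m +/- a has sd exactly a
    alt = [Raster(grid, np.full(grid.shape, 10.0 + (a := 3.0) * (-1) ** i)) for i in range(12)]
    _, sd_alt = annual_mean_seasonality(alt)
    np.testing.assert_allclose(sd_alt.values, 3.0)
    with pytest.raises(ValueError):
        annual_min_max_temperature(months[:11])


# ------------------------------------------------------------------- rates

def test_unidirectional_zero_and_saturation():
    grid = _grid(10)
    ext = _full_extent(grid)
    none = unidirectional_rrc(ext, Raster(grid, np.zeros(grid.shape)), 20)
    assert none.rate == 0.0
    full = unidirectional_rrc(ext, Raster(grid, np.ones(grid.shape)), 20)
    assert full.rate == pytest.approx(5.0, abs=0)  # 100/20 saturation


def test_unidirectional_three_of_ten_cells():
    grid = _grid(10)  # one latitude row -> equal-area cells
    ext = _full_extent(grid)
    change = np.zeros(grid.shape)
    change[0, [1, 4, 7]] = 1
    rec = unidirectional_rrc(ext, Raster(grid, change), 16)
    assert rec.rate == pytest.approx(100 * 0.3 / 16, rel=1e-14)  # 1.875


def test_unidirectional_bounds(rng):
    grid = _grid(8, 4, lat_min=30.0)
    ext = _full_extent(grid)
    for _ in range(5):
        change = Raster(grid, rng.integers(0, 2, grid.shape))
        rate = unidirectional_rrc(ext, change, 15).rate
        assert 0.0 <= rate <= 100.0 / 15 + 1e-12


def _stack(grid, years, values, variable="tmax", units="degC"):
    return AnnualStack(variable, list(years), grid, np.asarray(values, dtype=float), units)


def test_constant_burned_area_rate_zero():
    grid = _grid(10)
    ext = _full_extent(grid)
    years = range(2001, 2021)
    values = np.tile(np.array([[1, 1, 0, 0, 0, 0, 0, 0, 0, 0]]), (20, 1, 1))
    rec = bidirectional_rrc(ext, _stack(grid, years, values, "burned_area"), "sum_area")
    assert rec.rate == 0.0
    assert rec.nonsignificant_zeroed


def test_noiseless_burned_trend_matches_analytic_rate():
    grid = _grid(30)
    ext = _full_extent(grid)
    years = list(range(2001, 2011))
    values = np.zeros((10, 1, 30))
    for t in range(10):
        values[t, 0, : 2 + t] = 1  # burned count grows by one cell per year
    rec = bidirectional_rrc(ext, _stack(grid, years, values, "burned_area"), "sum_area")
    a = float(grid.cell_area_km2(0))
    assert rec.significant
    assert rec.rate == pytest.approx(100 * a / ext.eoo_area_km2, rel=1e-12)


def test_noiseless_climate_slope_recovered_exactly():
    grid = _grid(5, 2)
    ext = _full_extent(grid)
    years = np.arange(2000, 2020)
    base = np.full(grid.shape, 24.0)
    values = base[None] + 0.02 * (years - years[0])[:, None, None]
    rec = bidirectional_rrc(ext, _stack(grid, years, values), "weighted_mean")
    assert rec.significant
    assert rec.rate == pytest.approx(0.02, abs=1e-12)


def test_nonsignificant_noise_zeroed():
    grid = _grid(4)
    ext = _full_extent(grid)
    years = np.arange(2000, 2020)
    rng = np.random.default_rng(5)
    values = rng.normal(0, 1, (20, 1, 4))
    rec = bidirectional_rrc(ext, _stack(grid, years, values), "weighted_mean")
    if not rec.significant:
        assert rec.rate == 0.0 and rec.nonsignificant_zeroed


def test_decadal_rewindowing_recovers_same_slope():
    grid = _grid(5)
    ext = _full_extent(grid)
    years = np.arange(2000, 2021)
    values = np.full(grid.shape, 800.0)[None] + 1.5 * (years - 2000)[:, None, None]
    full = bidirectional_rrc(ext, _stack(grid, years, values, "vpd", "Pa"), "weighted_mean")
    first = bidirectional_rrc(
        ext, _stack(grid, years[:11], values[:11], "vpd", "Pa"), "weighted_mean")
    second = bidirectional_rrc(
        ext, _stack(grid, years[10:], values[10:], "vpd", "Pa"), "weighted_mean")
    assert full.rate == pytest.approx(1.5, abs=1e-12)
    assert first.rate == pytest.approx(second.rate, abs=1e-12) == pytest.approx(1.5, abs=1e-12)


def test_short_stack_rejected():
    grid = _grid(3)
    ext = _full_extent(grid)
    with pytest.raises(ValueError):
        bidirectional_rrc(ext, _stack(grid, [2000, 2001], np.zeros((2, 1, 3))), "weighted_mean")


# -------------------------------------------------- outliers / imputation

def _table(rates, threat="deforestation"):
    return records_to_table([
        RRCRecord(f"sp{i}", threat, r, "% extent/yr") for i, r in enumerate(rates)
    ])


def test_no_outliers_when_rates_equal():
    table, removed = remove_outliers(_table([1.0] * 30))
    assert removed == set()
    assert not table["outlier_removed"].any()


def test_extreme_rate_removed(rng):
    rates = list(rng.normal(1.0, 0.1, 500))
    q1, q99 = np.quantile(rates, [0.01, 0.99])
    rates.append(q99 + 10 * 3 * (q99 - q1))
    table, removed = remove_outliers(_table(rates))
    assert removed == {f"sp{len(rates) - 1}"}
    # brute-force re-check of the fence on the full data
    r = np.array(rates)
    q1, q99 = np.quantile(r, [0.01, 0.99])
    expected = {f"sp{i}" for i in np.nonzero(
        (r > q99 + 3 * (q99 - q1)) | (r < q1 - 3 * (q99 - q1)))[0]}
    assert removed == expected


def _occ_at(cells):
    rows = []
    for sp, cell_list in cells.items():
        for cx, cy in cell_list:
            rows.append((sp, cx + 0.5, cy + 0.5, "AAA"))
    return pd.DataFrame(rows, columns=["species_id", "lon", "lat", "label"])


def test_impute_single_neighbor_rate():
    occ = _occ_at({"minimal": [(0, 0)], "valued": [(0, 0)]})
    table = _table([0.7]).assign(species_id=["valued"])
    out = impute_minimal_species(occ, ["minimal"], table)
    assert out.loc[0, "rate"] == pytest.approx(0.7)
    assert out.loc[0, "imputed"] and out.loc[0, "minimal_area"]


def test_impute_median_over_cells():
    occ = _occ_at({
        "minimal": [(0, 0), (1, 0), (2, 0)],
        "a": [(0, 0)], "b": [(1, 0)], "c": [(2, 0)],
    })
    table = _table([1.0, 2.0, 9.0]).assign(species_id=["a", "b", "c"])
    out = impute_minimal_species(occ, ["minimal"], table)
    assert out.loc[0, "rate"] == 2.0  # median of cell means {1, 2, 9}


def test_impute_matches_two_stage_bruteforce(rng):
    n_valued = 12
    cells = {f"v{i}": [(int(rng.integers(0, 4)), int(rng.integers(0, 4)))
                       for _ in range(rng.integers(1, 4))] for i in range(n_valued)}
    cells["m"] = [(int(rng.integers(0, 4)), int(rng.integers(0, 4))) for _ in range(3)]
    occ = _occ_at(cells)
    rates = {f"v{i}": float(rng.normal()) for i in range(n_valued)}
    table = records_to_table([
        RRCRecord(sp, "deforestation", r, "% extent/yr") for sp, r in rates.items()])
    out = impute_minimal_species(occ, ["m"], table)
    # oracle: mean per cell over species present, then median over m's cells
    cell_vals = {}
    for sp, cl in cells.items():
        if sp == "m":
            continue
        for cell in set(cl):
            cell_vals.setdefault(cell, []).append(rates[sp])
    means = [np.mean(v) for cell, v in cell_vals.items() if cell in set(cells["m"])]
    if means:
        assert out.loc[0, "rate"] == pytest.approx(float(np.median(means)))
    else:
        assert out.empty
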