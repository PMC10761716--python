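"""Rates of recent change (RRC) per species and threat.

Six threat proxies are screened over roughly 2000-2020:

unidirectional (land conversion, counted once and never reversed) —
cropland expansion (2003 baseline, 16-year window), tree-cover decline
(any >=5 percentage-point drop between consecutive epochs, 15 years),
built-up expansion (20 years) and deforestation (20 years). The rate is
the converted area inside the refined extent as a percentage of extent
area per year::

    rate = 100 * sum(w_c * area_c, changed cells c) / EOO_area / n_years

so rates live in [0, 100/n_years] and saturate at full conversion
(5.0 %/yr for a 20-year window).

bidirectional (trends that can go either way) — burned area within the
extent per year (km^2), and annual climate variables aggregated to a
coverage-and-area-weighted extent mean. A Siegel repeated-medians trend is
fitted to the yearly series; a significant slope is the rate (burned area
re-expressed as % of extent per year), a non-significant one is exactly 0.

Also here: the epoch-map preprocessing that produces the binary conversion
layers, per-threat outlier removal (beyond 3 x (Q99 - Q1) from those
percentiles), and neighbourhood imputation of rates for minimal-area
species from co-occurring valued species on a 1-degree grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .extent import ExtentMask
from .grid import AnnualStack, Raster, check_same_grid
from .synthetic import BURNED_VARIABLE, CLIMATE_VARIABLES, UNIDIRECTIONAL_DIVISORS
from .trends import DEFAULT_ALPHA, TrendFit, siegel_slope, slope_significance

#: Unit string per threat layer.
THREAT_UNITS = {
    **{t: "% extent/yr" for t in UNIDIRECTIONAL_DIVISORS},
    BURNED_VARIABLE: "% extent/yr",
    **{v: f"{u}/yr" for v, u in CLIMATE_VARIABLES.items()},
}

#: Threat layer -> one of the six screened threat categories.
THREAT_CATEGORY = {
    **{t: t for t in UNIDIRECTIONAL_DIVISORS},
    BURNED_VARIABLE: BURNED_VARIABLE,
    **{v: "climate_change" for v in CLIMATE_VARIABLES},
}

#: Layers whose rate may be negative (two-tailed prioritization).
BIDIRECTIONAL_THREATS = frozenset({BURNED_VARIABLE, *CLIMATE_VARIABLES})

RRC_COLUMNS = [
    "species_id", "threat", "rate", "unit", "n_years", "significant",
    "nonsignificant_zeroed", "imputed", "minimal_area", "outlier_removed",
]


@dataclass(frozen=True)
class RRCRecord:
    species_id: str
    threat: str
    rate: float
    unit: str
    n_years: int | None = None
    significant: bool | None = None
    nonsignificant_zeroed: bool = False
    imputed: bool = False
    minimal_area: bool = False
    outlier_removed: bool = False

    def as_row(self) -> dict:
        return {c: getattr(self, c) for c in RRC_COLUMNS}


def records_to_table(records) -> pd.DataFrame:
    return pd.DataFrame([r.as_row() for r in records], columns=RRC_COLUMNS)


# ---------------------------------------------------------------- layer prep

def build_cropland_change(epoch_maps: list[Raster]) -> Raster:
    """Binary cropland-expansion layer from five 4-year epoch maps.

    A cell counts as expansion when it is cropland in any epoch after the
    2000-2003 baseline but was not cropland in the baseline. Window: 16
    years (2003-2019).
    """
    if len(epoch_maps) != 5:
        raise ValueError("expected five epoch layers (2000-03 ... 2016-19)")
    grid = check_same_grid(*epoch_maps)
    stack = np.stack([np.asarray(r.values, dtype=bool) for r in epoch_maps])
    post = stack[1:].any(axis=0)
    expansion = post & ~stack[0]
    return Raster(grid, expansion.astype(np.int8))


def build_treecover_decline(tc_maps: list[Raster], min_drop: float = 5.0) -> Raster:
    """Binary tree-cover-decline layer from four percent-cover epochs.

    A cell is 1 iff any consecutive comparison (2000-2005, 2005-2010,
    2010-2015) dropped by at least ``min_drop`` percentage points; gradual
    declines below the per-comparison threshold do not count. Window: 15
    years.
    """
    if len(tc_maps) != 4:
        raise ValueError("expected four tree-cover layers (2000, 2005, 2010, 2015)")
    grid = check_same_grid(*tc_maps)
    stack = np.stack([np.asarray(r.values, dtype=float) for r in tc_maps])
    if np.any((stack < 0) | (stack > 100)):
        raise ValueError("tree cover must be a percentage in [0, 100]")
    drops = stack[:-1] - stack[1:]
    declined = (drops >= min_drop).any(axis=0)
    return Raster(grid, declined.astype(np.int8))


def build_builtup_change(raster: Raster) -> Raster:
    """Binary built-up expansion from the {0,1,2} classification.

    0 = never built-up, 1 = stable built-up (not counted), 2 = expansion.
    Window: 20 years.
    """
    v = np.asarray(raster.values)
    if not np.isin(v, (0, 1, 2)).all():
        raise ValueError("built-up layer must contain only {0, 1, 2}")
    return Raster(raster.grid, (v == 2).astype(np.int8))


def build_deforestation(raster: Raster) -> Raster:
    """Binary forest-loss layer (identity pass-through, 20-year window)."""
    v = np.asarray(raster.values)
    if not np.isin(v, (0, 1)).all():
        raise ValueError("deforestation layer must be binary")
    return Raster(raster.grid, v.astype(np.int8))


def annual_min_max_temperature(monthly: list[Raster]) -> tuple[Raster, Raster]:
    """Cellwise annual minimum and maximum over 12 monthly layers."""
    if len(monthly) != 12:
        raise ValueError("expected 12 monthly layers")
    grid = check_same_grid(*monthly)
    stack = np.stack([np.asarray(r.values, dtype=float) for r in monthly])
    return Raster(grid, stack.min(axis=0)), Raster(grid, stack.max(axis=0))


def annual_mean_seasonality(monthly: list[Raster]) -> tuple[Raster, Raster]:
    """Cellwise annual mean and seasonality (population sd over 12 months)."""
    if len(monthly) != 12:
        raise ValueError("expected 12 monthly layers")
    grid = check_same_grid(*monthly)
    stack = np.stack([np.asarray(r.values, dtype=float) for r in monthly])
    return Raster(grid, stack.mean(axis=0)), Raster(grid, stack.std(axis=0))


# ------------------------------------------------------------------- rates

def unidirectional_rrc(
    extent: ExtentMask, change: Raster, n_years: int, threat: str = "change"
) -> RRCRecord:
    """Converted-area rate: % of extent per year over the threat's window."""
    if change.grid != extent.grid:
        raise ValueError("change raster is not on the extent's grid")
    if extent.eoo_area_km2 <= 0:
        raise ValueError("extent has zero area (minimal-area species)")
    changed = np.asarray(change.values)[extent.rows, extent.cols].astype(bool)
    changed_area = float(np.sum(extent.weights[changed] * extent.cell_areas_km2()[changed]))
    rate = 100.0 * changed_area / extent.eoo_area_km2 / n_years
    return RRCRecord(extent.species_id, threat, rate, THREAT_UNITS.get(threat, "% extent/yr"),
                     n_years=n_years)


def extent_yearly_series(extent: ExtentMask, stack: AnnualStack, mode: str) -> np.ndarray:
    """Yearly aggregate of a stack over an extent.

    ``sum_area``: total affected area (km^2) per year, for 0/1 indicator
    stacks (burned area). ``weighted_mean``: coverage-and-cell-area weighted
    mean of the variable, for climate stacks.
    """
    if stack.grid != extent.grid:
        raise ValueError("stack is not on the extent's grid")
    cells = stack.values[:, extent.rows, extent.cols]  # (n_years, n_cells)
    wa = extent.weights * extent.cell_areas_km2()
    if mode == "sum_area":
        return (cells.astype(bool) * wa).sum(axis=1)
    if mode == "weighted_mean":
        return (cells * wa).sum(axis=1) / wa.sum()
    raise ValueError(f"unknown aggregation mode {mode!r}")


def bidirectional_rrc(
    extent: ExtentMask,
    stack: AnnualStack,
    mode: str,
    alpha: float = DEFAULT_ALPHA,
    threat: str | None = None,
) -> RRCRecord:
    """Trend rate from a yearly series with the significance gate.

    Significant slope -> rate = slope (climate, native units/yr) or
    100 * slope / EOO_area (burned area, % of extent per yr); otherwise the
    rate is exactly 0 and flagged ``nonsignificant_zeroed``.
    """
    if stack.n_years < 3:
        raise ValueError("need at least 3 yearly layers for a trend")
    threat = threat or stack.variable
    series = extent_yearly_series(extent, stack, mode)
    fit = slope_significance(np.asarray(stack.years, dtype=float), series, alpha=alpha)
    if fit.significant:
        rate = 100.0 * fit.slope / extent.eoo_area_km2 if mode == "sum_area" else fit.slope
        zeroed = False
    else:
        rate, zeroed = 0.0, True
    return RRCRecord(
        extent.species_id, threat, float(rate), THREAT_UNITS.get(threat, ""),
        n_years=stack.n_years, significant=fit.significant, nonsignificant_zeroed=zeroed,
    )


# ------------------------------------------------- outliers and imputation

def remove_outliers(table: pd.DataFrame) -> tuple[pd.DataFrame, set[str]]:
    """Flag species whose rate is an extreme outlier for any threat.

    For each threat the fences are Q1% - 3*(Q99% - Q1%) and
    Q99% + 3*(Q99% - Q1%), computed over non-imputed, non-minimal species.
    A species outside the fences for any threat is dropped from the
    cross-status analysis: all its rows get ``outlier_removed = True``.
    Returns the updated table and the set of removed species.
    """
    table = table.copy()
    removed: set[str] = set()
    base = table[~table["imputed"] & ~table["minimal_area"]]
    for threat, g in base.groupby("threat"):
        rates = g["rate"].to_numpy(dtype=float)
        if rates.size < 3:
            continue
        q1, q99 = np.quantile(rates, [0.01, 0.99])
        spread = 3.0 * (q99 - q1)
        mask = (rates > q99 + spread) | (rates < q1 - spread)
        removed.update(g.loc[mask, "species_id"])
    table.loc[table["species_id"].isin(removed), "outlier_removed"] = True
    return table, removed


def impute_minimal_species(
    occ: pd.DataFrame,
    minimal_species: list[str],
    table: pd.DataFrame,
    grid_res: float = 1.0,
) -> pd.DataFrame:
    """Impute rates for minimal-area species from co-occurring species.

    Presence is occurrence-based: each species occupies the ``grid_res``
    (default 1 degree) cells its records fall in. Per cell and threat the
    mean rate over species with computed rates is taken; a minimal-area
    species' imputed rate is the median over its occupied cells. Cells with
    no valued species contribute nothing; a species with no informative
    cell gets no row for that threat.
    """
    occ = occ.copy()
    occ["_cell"] = list(zip(
        np.floor(occ["lon"].to_numpy(dtype=float) / grid_res).astype(int),
        np.floor(occ["lat"].to_numpy(dtype=float) / grid_res).astype(int),
    ))
    sp_cells = occ.groupby("species_id")["_cell"].agg(lambda s: set(s))
    valued = table[~table["imputed"] & ~table["minimal_area"] & ~table["outlier_removed"]]
    rows = []
    for threat, g in valued.groupby("threat"):
        rate_by_sp = dict(zip(g["species_id"], g["rate"]))
        cell_rates: dict[tuple[int, int], list[float]] = {}
        for sp, rate in rate_by_sp.items():
            for cell in sp_cells.get(sp, set()):
                cell_rates.setdefault(cell, []).append(float(rate))
        cell_mean = {cell: float(np.mean(v)) for cell, v in cell_rates.items()}
        for sp in minimal_species:
            vals = [cell_mean[c] for c in sp_cells.get(sp, set()) if c in cell_mean]
            if not vals:
                continue
            rows.append(RRCRecord(
                sp, threat, float(np.median(vals)), THREAT_UNITS.get(threat, ""),
                imputed=True, minimal_area=True,
            ))
    return records_to_table(rows)
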