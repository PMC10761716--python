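"""File formats: ESRI ASCII grids, CSV tables, GeoJSON polygons, JSON sidecars.

All gridded layers are exchanged as ESRI ASCII grids (.asc) — a plain-text
raster format readable by GDAL/QGIS — in WGS84 (EPSG:4326). Annual stacks
are one .asc per year plus a ``<variable>.json`` sidecar carrying variable
name, units and year list. Extent masks are a CSV of (cell_row, cell_col,
weight) plus a JSON header with the species id, suitable zones, extent area
and the polygon as GeoJSON. Floats are written with repr precision so that
a write/read round trip is bit-exact.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import shape as shapely_shape

from .extent import ExtentMask
from .grid import AnnualStack, GridSpec, Raster

OCCURRENCE_COLUMNS = ["species_id", "lon", "lat", "label"]


class FormatError(ValueError):
    """Malformed input file."""


# ----------------------------------------------------------- ASCII rasters

def write_ascii_grid(path, raster: Raster, fmt: str = "%.17g") -> None:
    """Write a Raster as an ESRI ASCII grid (rows north to south)."""
    grid = raster.grid
    nodata = raster.nodata if raster.nodata is not None else -9999
    header = (
        f"ncols {grid.n_cols}\n"
        f"nrows {grid.n_rows}\n"
        f"xllcorner {grid.lon_min!r}\n"
        f"yllcorner {grid.lat_min!r}\n"
        f"cellsize {grid.resolution!r}\n"
        f"NODATA_value {nodata}\n"
    )
    values = np.asarray(raster.values, dtype=float)
    values = np.where(np.isnan(values), float(nodata), values)
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, values[::-1], fmt=fmt)


def read_ascii_grid(path, dtype=float) -> Raster:
    """Read an ESRI ASCII grid; NODATA cells become NaN for float dtypes."""
    header: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, value = fh.readline().split()
            header[key.lower()] = float(value)
        values = np.loadtxt(fh, ndmin=2)
    try:
        grid = GridSpec(
            lon_min=header["xllcorner"],
            lat_min=header["yllcorner"],
            resolution=header["cellsize"],
            n_cols=int(header["ncols"]),
            n_rows=int(header["nrows"]),
        )
    except KeyError as exc:
        raise FormatError(f"missing ASCII grid header field: {exc}") from None
    values = values[::-1]
    nodata = header.get("nodata_value")
    if np.issubdtype(np.dtype(dtype), np.floating):
        if nodata is not None:
            values = np.where(values == nodata, np.nan, values)
        return Raster(grid, values.astype(dtype), nodata=np.nan)
    return Raster(grid, values.astype(dtype))


def write_stack(directory, stack: AnnualStack) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for i, year in enumerate(stack.years):
        write_ascii_grid(directory / f"{stack.variable}_{year}.asc",
                         Raster(stack.grid, stack.values[i]))
    meta = {"variable": stack.variable, "years": stack.years, "units": stack.units}
    (directory / f"{stack.variable}.json").write_text(json.dumps(meta, sort_keys=True))


def read_stack(directory, variable: str) -> AnnualStack:
    """Read an annual stack; out-of-order year files are sorted."""
    directory = Path(directory)
    meta = json.loads((directory / f"{variable}.json").read_text())
    years = sorted(int(y) for y in meta["years"])
    layers = [read_ascii_grid(directory / f"{variable}_{y}.asc") for y in years]
    grid = layers[0].grid
    values = np.stack([np.nan_to_num(l.values) for l in layers])
    return AnnualStack(variable, years, grid, values, units=meta.get("units", ""))


# ------------------------------------------------------------------ tables

def write_occurrences(path, occ: pd.DataFrame) -> None:
    occ[OCCURRENCE_COLUMNS].to_csv(path, index=False)


def read_occurrences(path) -> pd.DataFrame:
    occ = pd.read_csv(path, float_precision="round_trip")
    missing = set(OCCURRENCE_COLUMNS) - set(occ.columns)
    if missing:
        raise FormatError(f"occurrence table lacks columns {sorted(missing)}")
    bad = ~(
        occ["lon"].between(-180, 180) & occ["lat"].between(-90, 90)
    )
    if bad.any():
        raise FormatError(f"{int(bad.sum())} records have out-of-range coordinates")
    return occ[OCCURRENCE_COLUMNS]


def write_status_table(path, status: pd.DataFrame) -> None:
    status.to_csv(path, index=False)


def read_status_table(path) -> pd.DataFrame:
    status = pd.read_csv(path)
    if not {"species_id", "iucn_code"} <= set(status.columns):
        raise FormatError("status table needs species_id and iucn_code columns")
    return status[["species_id", "iucn_code"]]


# ------------------------------------------------------------ extent masks

def write_extent_mask(directory, extent: ExtentMask) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({
        "cell_row": extent.rows, "cell_col": extent.cols,
        # repr is the shortest round-trip representation; pandas' own float
        # formatting does not round-trip bit-exactly
        "weight": [repr(float(w)) for w in extent.weights],
    }).to_csv(directory / f"{extent.species_id}_cells.csv", index=False)
    header = {
        "species_id": extent.species_id,
        "suitable_zones": sorted(extent.suitable_zones),
        "eoo_area_km2": extent.eoo_area_km2,
        "grid": {
            "lon_min": extent.grid.lon_min, "lat_min": extent.grid.lat_min,
            "resolution": extent.grid.resolution,
            "n_cols": extent.grid.n_cols, "n_rows": extent.grid.n_rows,
        },
        "polygon": json.loads(shapely.to_geojson(extent.polygon)),
    }
    (directory / f"{extent.species_id}.json").write_text(
        json.dumps(header, sort_keys=True))


def read_extent_mask(directory, species_id: str) -> ExtentMask:
    directory = Path(directory)
    header = json.loads((directory / f"{species_id}.json").read_text())
    cells = pd.read_csv(directory / f"{species_id}_cells.csv", float_precision="round_trip")
    grid = GridSpec(**header["grid"])
    return ExtentMask(
        species_id=header["species_id"],
        polygon=shapely_shape(header["polygon"]),
        suitable_zones=frozenset(header["suitable_zones"]),
        grid=grid,
        rows=cells["cell_row"].to_numpy(),
        cols=cells["cell_col"].to_numpy(),
        weights=cells["weight"].to_numpy(),
    )


def write_json(path, obj) -> None:
    Path(path).write_text(json.dumps(obj, sort_keys=True, indent=1))


def read_json(path):
    return json.loads(Path(path).read_text())


# ----------------------------------------------------------- whole worlds

def save_world(directory, world) -> None:
    """Write every layer of a synthetic world (plus its ground truth)."""
    import dataclasses

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_json(directory / "config.json", dataclasses.asdict(world.config))
    (directory / "truth.json").write_text(world.truth.to_json())
    write_occurrences(directory / "occurrences.csv", world.occurrences)
    write_status_table(directory / "status.csv", world.status_table)
    write_ascii_grid(directory / "zones.asc", world.zone_raster, fmt="%d")
    write_ascii_grid(directory / "water.asc", world.water_mask, fmt="%d")
    for threat, raster in sorted(world.change_rasters.items()):
        write_ascii_grid(directory / f"change_{threat}.asc", raster, fmt="%d")
    for variable, stack in sorted(world.annual_stacks.items()):
        write_stack(directory / "stacks", stack)


def load_world(directory):
    """Read a world previously written by :func:`save_world`."""
    from .synthetic import (
        BURNED_VARIABLE, CLIMATE_VARIABLES, PlantedTruth, SyntheticConfig,
        UNIDIRECTIONAL_DIVISORS, World,
    )

    directory = Path(directory)
    raw = read_json(directory / "config.json")
    for key in ("bbox", "n_records_range", "years", "changed_fraction_range",
                "burned_slope_range"):
        raw[key] = tuple(raw[key])
    raw["slope_ranges"] = {k: tuple(v) for k, v in raw["slope_ranges"].items()}
    config = SyntheticConfig(**raw)
    truth = PlantedTruth.from_json((directory / "truth.json").read_text())
    occurrences = read_occurrences(directory / "occurrences.csv")
    status = read_status_table(directory / "status.csv")
    zones = read_ascii_grid(directory / "zones.asc", dtype=np.int32)
    water = read_ascii_grid(directory / "water.asc", dtype=np.int8)
    changes = {
        t: read_ascii_grid(directory / f"change_{t}.asc", dtype=np.int8)
        for t in sorted(UNIDIRECTIONAL_DIVISORS)
    }
    stacks = {v: read_stack(directory / "stacks", v) for v in sorted(CLIMATE_VARIABLES)}
    stacks[BURNED_VARIABLE] = read_stack(directory / "stacks", BURNED_VARIABLE)
    return World(config, truth, occurrences, zones, water, changes, stacks, status)
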