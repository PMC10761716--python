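"""Synthetic worlds with known ground truth.

Real inputs to the exposure pipeline are global occurrence databases and
decadal remote-sensing products. This module generates structurally
equivalent miniatures — clustered multi-species occurrence sets with quality
labels, a contiguous climate-zone mosaic, binary land-conversion layers with
controlled per-species changed fractions, annual climate/burned-area stacks
with planted linear trends, and an IUCN status table — together with a
:class:`PlantedTruth` record so every downstream stage can be tested against
known answers.

Layout: the grid is partitioned into one rectangular "core region" block per
species; a species' occurrence cluster, its planted land-conversion cells
and its planted climate trends all live in its block. Blocks are disjoint,
which makes planted rates recoverable species by species.

Reproducibility: a single seed expands into independent per-component
substreams via ``numpy.random.SeedSequence``; identical configs give
bit-identical worlds.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd

from .grid import AnnualStack, GridSpec, Raster

#: Occurrence-record quality codes, best (AAA) to worst (H).
QUALITY_LABELS = ("AAA", "AA", "A", "B", "C", "D", "E", "H")

DEFAULT_LABEL_PROBS = {
    "AAA": 0.30, "AA": 0.20, "A": 0.15, "B": 0.10, "C": 0.10,
    "D": 0.05, "E": 0.05, "H": 0.05,
}

#: Unidirectional land-conversion threats and the length (years) of the
#: observation window each one's source product covers.
UNIDIRECTIONAL_DIVISORS = {
    "cropland_expansion": 16,
    "treecover_decline": 15,
    "builtup_expansion": 20,
    "deforestation": 20,
}

#: Annual climate variables (trend threats) with native units.
CLIMATE_VARIABLES = {
    "tmin": "degC",
    "tmax": "degC",
    "vpd": "Pa",
    "vpd_seasonality": "Pa",
    "precip": "mm",
    "precip_seasonality": "mm",
}

BURNED_VARIABLE = "burned_area"

#: Typical background level per annual variable (intercept of the series).
_BASELINES = {
    "tmin": 4.0, "tmax": 24.0, "vpd": 800.0, "vpd_seasonality": 150.0,
    "precip": 1200.0, "precip_seasonality": 40.0,
}

#: Plausible planted trend ranges, native units per year. Magnitudes follow
#: observed per-extent extremes for trees over 2000-2020 (order 0.1 degC/yr,
#: 10 Pa/yr, 10 mm/yr at the tails).
DEFAULT_SLOPE_RANGES = {
    "tmin": (-0.02, 0.08),
    "tmax": (-0.02, 0.08),
    "vpd": (-2.0, 6.0),
    "vpd_seasonality": (-2.0, 4.0),
    "precip": (-8.0, 8.0),
    "precip_seasonality": (-3.0, 5.0),
}

DEFAULT_NOISE_SD = {
    "tmin": 0.3, "tmax": 0.3, "vpd": 15.0, "vpd_seasonality": 8.0,
    "precip": 60.0, "precip_seasonality": 8.0,
}

#: IUCN Red List category frequencies loosely matching the global tree flora
#: (roughly 13% Data Deficient, ~18% never evaluated, threatened minority).
DEFAULT_STATUS_PROBS = {
    "EX": 0.002, "EW": 0.001, "RE": 0.001, "CR": 0.03, "EN": 0.06,
    "VU": 0.08, "LR/cd": 0.002, "NT": 0.05, "LR/nt": 0.005,
    "LC": 0.45, "LR/lc": 0.010, "DD": 0.13, "NE": 0.179,
}

IUCN_CODES = tuple(DEFAULT_STATUS_PROBS)


class ConfigurationError(ValueError):
    """Invalid synthetic-world configuration."""


@dataclass
class SyntheticConfig:
    """Study conditions for one synthetic world.

    Defaults describe the standard test world: a 10 x 10 degree tropical
    window at 0.05 degree resolution, 50 species with a few dozen records
    each, four climate zones, and the 2001-2020 window of the burned-area
    record.
    """

    bbox: tuple[float, float, float, float] = (0.0, 0.0, 10.0, 10.0)
    resolution: float = 0.05
    n_species: int = 50
    n_records_range: tuple[int, int] = (30, 80)
    cluster_sd: float = 0.15
    n_zones: int = 4
    years: tuple[int, ...] = tuple(range(2001, 2021))
    seed: int = 0
    # extras beyond the minimal surface
    label_probs: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_LABEL_PROBS))
    n_minimal_species: int = 0
    water_fraction: float = 0.05
    changed_fraction_range: tuple[float, float] = (0.0, 0.6)
    slope_ranges: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_SLOPE_RANGES))
    noise_sd: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_NOISE_SD))
    burned_base_fraction: float = 0.05
    burned_slope_range: tuple[float, float] = (-0.002, 0.002)
    heavy_tail_noise: bool = False
    status_probs: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_STATUS_PROBS))

    def __post_init__(self) -> None:
        lon_min, lat_min, lon_max, lat_max = self.bbox
        if lon_max <= lon_min or lat_max <= lat_min:
            raise ConfigurationError("bbox is degenerate")
        if self.resolution <= 0:
            raise ConfigurationError("resolution must be positive")
        if self.n_species < 1:
            raise ConfigurationError("need at least one species")
        if self.n_records_range[0] < 1 or self.n_records_range[1] < self.n_records_range[0]:
            raise ConfigurationError("bad n_records_range")
        if self.n_zones < 1:
            raise ConfigurationError("need at least one zone")
        self.years = tuple(int(y) for y in self.years)
        if len(self.years) >= 2 and any(b <= a for a, b in zip(self.years, self.years[1:])):
            raise ConfigurationError("years must be strictly increasing")
        unknown = set(self.label_probs) - set(QUALITY_LABELS)
        if unknown:
            raise ConfigurationError(f"unknown quality labels {unknown}")
        if not math.isclose(sum(self.label_probs.values()), 1.0, abs_tol=1e-9):
            raise ConfigurationError("label probabilities must sum to 1")
        if not 0 <= self.water_fraction < 1:
            raise ConfigurationError("water_fraction must be in [0,1)")
        if self.n_minimal_species > self.n_species:
            raise ConfigurationError("more minimal species than species")
        lo, hi = self.changed_fraction_range
        if not (0 <= lo <= hi <= 1):
            raise ConfigurationError("changed fractions must lie in [0,1]")

    @property
    def grid(self) -> GridSpec:
        return GridSpec.from_bbox(self.bbox, self.resolution)

    def species_ids(self) -> list[str]:
        width = max(4, len(str(self.n_species)))
        return [f"sp{i:0{width}d}" for i in range(1, self.n_species + 1)]

    def rng(self, component: int) -> np.random.Generator:
        """Independent substream for one generator component."""
        return np.random.default_rng(np.random.SeedSequence(self.seed, spawn_key=(component,)))


# substream ids
_OCC, _ZONES, _WATER, _STATUS = 0, 1, 2, 3
_CHANGE_BASE, _STACK_BASE, _TRUTH = 10, 30, 50


@dataclass
class PlantedTruth:
    """Ground truth recorded alongside a generated world.

    ``regions`` maps species to its core block as a half-open cell window
    ``(row0, row1, col0, col1)``. ``changed_fraction`` holds the planted
    changed-cell fraction per unidirectional threat; ``realized_fraction``
    the realized changed *area* fraction of the block (these differ by at
    most one cell's worth). ``slopes`` holds planted trend slopes in native
    units per year (burned area: block-fraction per year).
    """

    regions: dict[str, tuple[int, int, int, int]]
    changed_fraction: dict[str, dict[str, float]]
    realized_fraction: dict[str, dict[str, float]]
    slopes: dict[str, dict[str, float]]
    noise_sd: dict[str, float]
    minimal_species: list[str]

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "PlantedTruth":
        d = json.loads(text)
        d["regions"] = {k: tuple(v) for k, v in d["regions"].items()}
        return cls(**d)


def _species_blocks(config: SyntheticConfig) -> dict[str, tuple[int, int, int, int]]:
    """Disjoint rectangular cell windows, one per species."""
    grid = config.grid
    nb = math.ceil(math.sqrt(config.n_species))
    rows_b = grid.n_rows // nb
    cols_b = grid.n_cols // nb
    if rows_b < 1 or cols_b < 1:
        raise ConfigurationError("grid too coarse for the requested species count")
    blocks = {}
    for i, sp in enumerate(config.species_ids()):
        bi, bj = divmod(i, nb)
        blocks[sp] = (bi * rows_b, (bi + 1) * rows_b, bj * cols_b, (bj + 1) * cols_b)
    return blocks


def plant_truth(config: SyntheticConfig) -> PlantedTruth:
    """Draw the planted ground truth for a world (deterministic in seed)."""
    rng = config.rng(_TRUTH)
    species = config.species_ids()
    regions = _species_blocks(config)
    lo, hi = config.changed_fraction_range
    changed = {
        threat: {sp: float(rng.uniform(lo, hi)) for sp in species}
        for threat in UNIDIRECTIONAL_DIVISORS
    }
    slopes: dict[str, dict[str, float]] = {}
    for var, (slo, shi) in config.slope_ranges.items():
        slopes[var] = {sp: float(rng.uniform(slo, shi)) for sp in species}
    blo, bhi = config.burned_slope_range
    slopes[BURNED_VARIABLE] = {sp: float(rng.uniform(blo, bhi)) for sp in species}
    minimal = species[config.n_species - config.n_minimal_species:] if config.n_minimal_species else []
    return PlantedTruth(
        regions=regions,
        changed_fraction=changed,
        realized_fraction={threat: {} for threat in UNIDIRECTIONAL_DIVISORS},
        slopes=slopes,
        noise_sd={**dict(config.noise_sd), BURNED_VARIABLE: 0.0},
        minimal_species=list(minimal),
    )


def _block_bbox(grid: GridSpec, window: tuple[int, int, int, int]) -> tuple[float, float, float, float]:
    r0, r1, c0, c1 = window
    return (
        grid.lon_min + c0 * grid.resolution,
        grid.lat_min + r0 * grid.resolution,
        grid.lon_min + c1 * grid.resolution,
        grid.lat_min + r1 * grid.resolution,
    )


def gen_occurrences(config: SyntheticConfig, truth: PlantedTruth | None = None) -> pd.DataFrame:
    """Clustered occurrence records with quality labels.

    Each species draws records from an isotropic Gaussian cluster centred in
    its core block, clipped to the block so that ranges stay disjoint.
    Species listed in ``truth.minimal_species`` get three records each to
    exercise the minimal-area path downstream.
    """
    if truth is None:
        truth = plant_truth(config)
    rng = config.rng(_OCC)
    grid = config.grid
    labels = list(config.label_probs)
    probs = np.array([config.label_probs[l] for l in labels])
    minimal = set(truth.minimal_species)
    rows = []
    nmin, nmax = config.n_records_range
    for sp in config.species_ids():
        n = 3 if sp in minimal else int(rng.integers(nmin, nmax + 1))
        w, s, e, nth = _block_bbox(grid, truth.regions[sp])
        cx, cy = (w + e) / 2, (s + nth) / 2
        lon = rng.normal(cx, config.cluster_sd, n)
        lat = rng.normal(cy, config.cluster_sd, n)
        # clip just inside the block so records stay in the species' region
        eps = grid.resolution * 1e-3
        lon = np.clip(lon, w + eps, e - eps)
        lat = np.clip(lat, s + eps, nth - eps)
        lab = rng.choice(labels, size=n, p=probs)
        for x, y, l in zip(lon, lat, lab):
            rows.append((sp, float(x), float(y), str(l)))
    return pd.DataFrame(rows, columns=["species_id", "lon", "lat", "label"])


def gen_zone_raster(config: SyntheticConfig) -> Raster:
    """Contiguous categorical mosaic: Voronoi cells of seeded centres.

    Zone ids are 1..n_zones; every grid cell is assigned to its nearest
    centre in degree space.
    """
    rng = config.rng(_ZONES)
    grid = config.grid
    lon_min, lat_min, lon_max, lat_max = config.bbox
    cx = rng.uniform(lon_min, lon_max, config.n_zones)
    cy = rng.uniform(lat_min, lat_max, config.n_zones)
    lons = grid.lon_centers()[None, :]
    lats = grid.lat_centers()[:, None]
    d2 = (lons[None, :, :] - cx[:, None, None]) ** 2 + (lats[None, :, :] - cy[:, None, None]) ** 2
    zones = np.argmin(d2, axis=0) + 1
    return Raster(grid, zones.astype(np.int32))


def gen_water_mask(config: SyntheticConfig) -> Raster:
    """Binary water mask (1 = water) with the configured wet fraction."""
    rng = config.rng(_WATER)
    grid = config.grid
    water = (rng.random(grid.shape) < config.water_fraction).astype(np.int8)
    return Raster(grid, water)


def gen_change_raster(config: SyntheticConfig, truth: PlantedTruth, threat: str) -> Raster:
    """Binary land-conversion layer with planted per-species changed fractions.

    Within each species' block, ``round(f * n_cells)`` cells are set to 1,
    so the realized changed fraction deviates from the planted one by at
    most half a cell. The realized changed *area* fraction is recorded in
    ``truth.realized_fraction[threat]``.
    """
    if threat not in UNIDIRECTIONAL_DIVISORS:
        raise ConfigurationError(f"unknown unidirectional threat {threat!r}")
    rng = config.rng(_CHANGE_BASE + sorted(UNIDIRECTIONAL_DIVISORS).index(threat))
    grid = config.grid
    values = np.zeros(grid.shape, dtype=np.int8)
    areas = grid.area_grid_km2()
    for sp in config.species_ids():
        f = truth.changed_fraction[threat][sp]
        if not 0 <= f <= 1:
            raise ConfigurationError("changed fraction outside [0,1]")
        r0, r1, c0, c1 = truth.regions[sp]
        n_cells = (r1 - r0) * (c1 - c0)
        k = int(round(f * n_cells))
        block = np.zeros(n_cells, dtype=np.int8)
        if k:
            block[rng.choice(n_cells, size=k, replace=False)] = 1
        block = block.reshape(r1 - r0, c1 - c0)
        values[r0:r1, c0:c1] = block
        block_areas = areas[r0:r1, c0:c1]
        truth.realized_fraction[threat][sp] = float(
            (block_areas * block).sum() / block_areas.sum()
        )
    return Raster(grid, values)


def gen_annual_stack(config: SyntheticConfig, truth: PlantedTruth, variable: str) -> AnnualStack:
    """Annual per-cell series with planted linear trends plus noise.

    Climate variables: ``value(year) = baseline + slope * (year - year0) +
    noise`` with the species-block slope from ``truth`` (background slope
    0). With ``noise_sd = 0`` the series is exactly linear. Burned area:
    a 0/1 indicator whose within-block burned-cell fraction follows
    ``base + slope * (year - year0)``.
    """
    if len(config.years) < 3:
        raise ConfigurationError("need at least 3 years for an annual stack")
    grid = config.grid
    years = np.array(config.years)
    t = years - years[0]
    if variable == BURNED_VARIABLE:
        rng = config.rng(_STACK_BASE + len(CLIMATE_VARIABLES))
        values = np.zeros((len(years), *grid.shape), dtype=np.int8)
        for sp in config.species_ids():
            r0, r1, c0, c1 = truth.regions[sp]
            n_cells = (r1 - r0) * (c1 - c0)
            slope = truth.slopes[BURNED_VARIABLE][sp]
            frac = np.clip(config.burned_base_fraction + slope * t, 0.0, 1.0)
            for ti, f in enumerate(frac):
                k = int(round(f * n_cells))
                block = np.zeros(n_cells, dtype=np.int8)
                if k:
                    block[rng.choice(n_cells, size=k, replace=False)] = 1
                values[ti, r0:r1, c0:c1] = block.reshape(r1 - r0, c1 - c0)
        return AnnualStack(variable, list(years), grid, values, units="indicator")

    if variable not in CLIMATE_VARIABLES:
        raise ConfigurationError(f"unknown annual variable {variable!r}")
    idx = sorted(CLIMATE_VARIABLES).index(variable)
    rng = config.rng(_STACK_BASE + idx)
    slope_map = np.zeros(grid.shape)
    for sp in config.species_ids():
        r0, r1, c0, c1 = truth.regions[sp]
        slope_map[r0:r1, c0:c1] = truth.slopes[variable][sp]
    base = _BASELINES.get(variable, 0.0)
    sd = float(truth.noise_sd.get(variable, 0.0))
    values = base + slope_map[None, :, :] * t[:, None, None]
    if sd > 0:
        if config.heavy_tail_noise:
            noise = rng.standard_t(df=3, size=values.shape) * sd
        else:
            noise = rng.normal(0.0, sd, size=values.shape)
        values = values + noise
    return AnnualStack(variable, list(years), grid, values, units=CLIMATE_VARIABLES[variable])


def gen_status_table(
    species: list[str],
    probs: Mapping[str, float] | None = None,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """One IUCN Red List category per species, sampled from ``probs``."""
    probs = dict(DEFAULT_STATUS_PROBS if probs is None else probs)
    unknown = set(probs) - set(IUCN_CODES)
    if unknown:
        raise ConfigurationError(f"unknown IUCN categories {unknown}")
    if not math.isclose(sum(probs.values()), 1.0, abs_tol=1e-9):
        raise ConfigurationError("status probabilities must sum to 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    codes = list(probs)
    p = np.array([probs[c] for c in codes])
    drawn = rng.choice(codes, size=len(species), p=p)
    return pd.DataFrame({"species_id": species, "iucn_code": drawn})


@dataclass
class World:
    """A fully generated synthetic study system."""

    config: SyntheticConfig
    truth: PlantedTruth
    occurrences: pd.DataFrame
    zone_raster: Raster
    water_mask: Raster
    change_rasters: dict[str, Raster]
    annual_stacks: dict[str, AnnualStack]
    status_table: pd.DataFrame

    @property
    def grid(self) -> GridSpec:
        return self.config.grid


def gen_world(config: SyntheticConfig) -> World:
    """Generate every layer of a synthetic world from one config."""
    truth = plant_truth(config)
    occurrences = gen_occurrences(config, truth)
    zones = gen_zone_raster(config)
    water = gen_water_mask(config)
    changes = {t: gen_change_raster(config, truth, t) for t in sorted(UNIDIRECTIONAL_DIVISORS)}
    stacks = {v: gen_annual_stack(config, truth, v) for v in sorted(CLIMATE_VARIABLES)}
    stacks[BURNED_VARIABLE] = gen_annual_stack(config, truth, BURNED_VARIABLE)
    status = gen_status_table(config.species_ids(), config.status_probs, config.rng(_STATUS))
    return World(config, truth, occurrences, zones, water, changes, stacks, status)
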