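"""End-to-end driver: QC -> extents -> rates -> prioritization -> hotspots.

The pipeline mirrors the stepwise threat-screening workflow: occurrence
quality control, minimal-area flagging, refined extent construction,
per-threat rates of recent change, outlier removal, imputation for
minimal-area species, exposure thresholds and candidate flags, congruence
with Red List status groups, and hotspot maps. The run manifest reconciles
the species accounting exactly::

    input species = analyzed + minimal-area + degenerate-hull + outlier-removed

Everything is deterministic given the configuration (and its seed).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as tio
from .extent import (
    DegenerateHullError,
    EmptyExtentError,
    ExtentMask,
    UnusableZoneError,
    extent_class,
    mcp,
    refine_extent,
    suitable_zones,
)
from .grid import GridSpec
from .hotspots import HotspotGrid, count_stack, fraction_map, threat_overlay
from .occurrences import DEFAULT_ALLOWED_LABELS, filter_quality, flag_minimal_area
from .prioritize import ThresholdSet, compute_thresholds, congruence_summary, flag_candidates
from .rrc import (
    BURNED_VARIABLE,
    CLIMATE_VARIABLES,
    THREAT_CATEGORY,
    UNIDIRECTIONAL_DIVISORS,
    bidirectional_rrc,
    impute_minimal_species,
    records_to_table,
    remove_outliers,
    unidirectional_rrc,
)
from .synthetic import World
from .trends import DEFAULT_ALPHA

__version__ = "0.1.0"

#: The six screened threat categories (overlay order).
THREAT_CATEGORIES = [
    "cropland_expansion", "treecover_decline", "builtup_expansion",
    "deforestation", BURNED_VARIABLE, "climate_change",
]


@dataclass(frozen=True)
class PipelineParams:
    """Analysis knobs (study defaults)."""

    allowed_labels: frozenset[str] = DEFAULT_ALLOWED_LABELS
    alpha: float = DEFAULT_ALPHA
    quantile: float = 0.95
    inclusion: float = 0.95
    imputation_grid_res: float = 1.0
    min_species_for_threshold: int = 20


@dataclass
class RunManifest:
    config_hash: str
    version: str
    n_input_species: int
    n_analyzed: int
    n_minimal_area: int
    n_degenerate_hull: int
    n_outlier_removed: int
    stage_counts: dict = field(default_factory=dict)
    drop_reasons: dict = field(default_factory=dict)

    @property
    def reconciles(self) -> bool:
        return self.n_input_species == (
            self.n_analyzed + self.n_minimal_area + self.n_degenerate_hull
            + self.n_outlier_removed
        )

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["reconciles"] = self.reconciles
        return d


@dataclass
class PipelineResult:
    manifest: RunManifest
    qc_occurrences: pd.DataFrame
    minimal_flags: pd.DataFrame
    extents: dict[str, ExtentMask]
    extent_classes: pd.DataFrame
    rrc_table: pd.DataFrame
    thresholds: ThresholdSet
    candidates: pd.DataFrame
    congruence: pd.DataFrame
    hotspot_total: HotspotGrid
    hotspot_priority: HotspotGrid
    hotspot_fraction: HotspotGrid
    hotspot_by_category: dict[str, HotspotGrid]
    overlay: HotspotGrid


def _config_hash(world: World, params: PipelineParams) -> str:
    payload = json.dumps(
        {"config": dataclasses.asdict(world.config), "params": {
            **dataclasses.asdict(params), "allowed_labels": sorted(params.allowed_labels)}},
        sort_keys=True, default=list,
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_pipeline(world: World, params: PipelineParams | None = None) -> PipelineResult:
    """Run every stage on a (synthetic or loaded) world."""
    params = params or PipelineParams()
    grid = world.grid
    species_ids = sorted(set(world.occurrences["species_id"]))

    # --- occurrence QC and minimal-area flags
    occ = filter_quality(world.occurrences, params.allowed_labels)
    flags = flag_minimal_area(occ, species_ids)
    minimal: set[str] = set(flags.loc[flags["flagged"], "species_id"])
    degenerate: set[str] = set()

    # --- extents
    extents: dict[str, ExtentMask] = {}
    extra_minimal_reason: dict[str, str] = {}
    grouped = dict(tuple(occ.groupby("species_id", sort=False)))
    for sp in species_ids:
        if sp in minimal:
            continue
        g = grouped[sp]
        lon, lat = g["lon"].to_numpy(float), g["lat"].to_numpy(float)
        try:
            polygon = mcp(lon, lat, inclusion=params.inclusion)
            zones = suitable_zones(lon, lat, world.zone_raster)
            extents[sp] = refine_extent(sp, polygon, zones, world.zone_raster,
                                        world.water_mask, grid)
        except DegenerateHullError:
            degenerate.add(sp)
        except (UnusableZoneError, EmptyExtentError) as exc:
            minimal.add(sp)
            extra_minimal_reason[sp] = type(exc).__name__

    flags = flags.copy()
    flags.loc[flags["species_id"].isin(minimal), "flagged"] = True
    flags.loc[
        flags["species_id"].isin(extra_minimal_reason) & flags["reason"].isna(),
        "reason",
    ] = "empty_extent"

    ext_classes = pd.DataFrame(
        [(sp, e.eoo_area_km2, extent_class(e.eoo_area_km2)) for sp, e in sorted(extents.items())],
        columns=["species_id", "eoo_area_km2", "extent_class"],
    )

    # --- rates of recent change
    records = []
    for sp, ext in sorted(extents.items()):
        for threat, divisor in sorted(UNIDIRECTIONAL_DIVISORS.items()):
            records.append(unidirectional_rrc(ext, world.change_rasters[threat], divisor, threat))
        records.append(bidirectional_rrc(
            ext, world.annual_stacks[BURNED_VARIABLE], "sum_area", params.alpha))
        for var in sorted(CLIMATE_VARIABLES):
            records.append(bidirectional_rrc(
                ext, world.annual_stacks[var], "weighted_mean", params.alpha))
    table = records_to_table(records)

    # --- outlier removal, imputation
    table, outlier_species = remove_outliers(table)
    imputed = impute_minimal_species(
        occ, sorted(minimal), table, grid_res=params.imputation_grid_res)
    if len(imputed):
        table = pd.concat([table, imputed], ignore_index=True)

    # --- prioritization
    thresholds = compute_thresholds(
        table, q=params.quantile, min_n=params.min_species_for_threshold)
    candidates = flag_candidates(table, thresholds, flags)
    candidates = candidates[~candidates["species_id"].isin(outlier_species | degenerate)]
    for category in THREAT_CATEGORIES:
        layers = [t for t, c in THREAT_CATEGORY.items() if c == category]
        cols = [t for t in layers if t in candidates.columns]
        candidates[f"cat_{category}"] = candidates[cols].any(axis=1) if cols else False
    congruence = congruence_summary(candidates, world.status_table)

    # --- hotspots
    analyzed = sorted(set(extents) - outlier_species)
    cand_idx = candidates.set_index("species_id")
    total = count_stack([extents[sp] for sp in analyzed], grid, "all_species")
    priority_ids = [
        sp for sp in analyzed if sp in cand_idx.index and bool(cand_idx.loc[sp, "priority"])
    ]
    priority = count_stack([extents[sp] for sp in priority_ids], grid, "priority_union")
    frac = fraction_map(priority, total)
    by_category: dict[str, HotspotGrid] = {}
    for category in THREAT_CATEGORIES:
        ids = [
            sp for sp in analyzed
            if sp in cand_idx.index and bool(cand_idx.loc[sp, f"cat_{category}"])
        ]
        by_category[category] = count_stack(
            [extents[sp] for sp in ids], grid, "priority_by_threat")
    overlay = threat_overlay([by_category[c] for c in THREAT_CATEGORIES])

    # --- manifest
    n_analyzed = len(analyzed)
    manifest = RunManifest(
        config_hash=_config_hash(world, params),
        version=__version__,
        n_input_species=len(species_ids),
        n_analyzed=n_analyzed,
        n_minimal_area=len(minimal),
        n_degenerate_hull=len(degenerate),
        n_outlier_removed=len(outlier_species),
        stage_counts={
            "records_in": int(len(world.occurrences)),
            "records_after_qc": int(len(occ)),
            "extents_built": len(extents),
            "rrc_rows": int(len(table)),
            "imputed_rows": int(len(imputed)),
            "priority_candidates": int(candidates["priority"].sum()),
        },
        drop_reasons={
            "minimal_area": {
                sp: (extra_minimal_reason.get(sp)
                     or flags.set_index("species_id").loc[sp, "reason"])
                for sp in sorted(minimal)
            },
            "degenerate_hull": sorted(degenerate),
            "outlier_removed": sorted(outlier_species),
        },
    )
    return PipelineResult(
        manifest=manifest,
        qc_occurrences=occ,
        minimal_flags=flags,
        extents=extents,
        extent_classes=ext_classes,
        rrc_table=table,
        thresholds=thresholds,
        candidates=candidates,
        congruence=congruence,
        hotspot_total=total,
        hotspot_priority=priority,
        hotspot_fraction=frac,
        hotspot_by_category=by_category,
        overlay=overlay,
    )


def write_outputs(result: PipelineResult, outdir) -> None:
    """Write every pipeline product as text files (deterministic)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result.qc_occurrences.to_csv(outdir / "occurrences_qc.csv", index=False)
    result.minimal_flags.to_csv(outdir / "minimal_flags.csv", index=False)
    result.extent_classes.to_csv(outdir / "extent_classes.csv", index=False)
    result.rrc_table.to_csv(outdir / "rrc.csv", index=False)
    tio.write_json(outdir / "thresholds.json", result.thresholds.as_dict())
    result.candidates.to_csv(outdir / "candidates.csv", index=False)
    result.congruence.to_csv(outdir / "congruence.csv", index=False)
    tio.write_json(outdir / "manifest.json", result.manifest.as_dict())
    for sp, ext in sorted(result.extents.items()):
        tio.write_extent_mask(outdir / "extents", ext)
    tio.write_ascii_grid(outdir / "hotspot_total.asc", result.hotspot_total.as_raster())
    tio.write_ascii_grid(outdir / "hotspot_priority.asc", result.hotspot_priority.as_raster())
    tio.write_ascii_grid(outdir / "hotspot_fraction.asc", result.hotspot_fraction.as_raster())
    for category, layer in sorted(result.hotspot_by_category.items()):
        tio.write_ascii_grid(outdir / f"hotspot_{category}.asc", layer.as_raster())
    tio.write_ascii_grid(outdir / "threat_overlay.asc", result.overlay.as_raster())
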