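"""Occurrence-record quality control, AOO, and minimal-area flagging.

Records carry the upstream data-quality codes AAA (best) through H (worst);
the analysis keeps AAA, AA, A, B and C, which excludes records with joint
coordinate-and-environment issues, unknown ranges, duplicates and missing
coordinates.

Area of occupancy (AOO) follows the Red List convention: the number of
occupied cells of a fixed 2 x 2 km grid times 4 km^2. The grid is a
world-anchored cylindrical equal-area tiling (standard parallel at the
equator, origin at lon 0 / lat 0), so the km^2 semantics hold at every
latitude.

Species with fewer than five records, an AOO under 10 km^2, or a degenerate
(zero-area) hull cannot support a convex-polygon extent; they are flagged
and routed to the imputation / by-default-priority path.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grid import EARTH_RADIUS_KM

#: Quality labels retained by default.
DEFAULT_ALLOWED_LABELS = frozenset({"AAA", "AA", "A", "B", "C"})

#: AOO grid cell edge (km) and the Red List thresholds.
AOO_CELL_KM = 2.0
MIN_AOO_KM2 = 10.0
MIN_RECORDS = 5

#: Coordinates compared for exact-duplicate collapse after rounding here.
_DUP_DECIMALS = 6


class EmptySpeciesError(ValueError):
    """An operation that needs at least one record got none."""


@dataclass(frozen=True)
class MinimalAreaFlag:
    species_id: str
    n_records: int
    aoo_km2: float
    flagged: bool
    reason: str | None  # few_records | small_aoo | degenerate_hull | None


def filter_quality(occ: pd.DataFrame, allowed=DEFAULT_ALLOWED_LABELS) -> pd.DataFrame:
    """Keep records whose quality label is allowed; collapse exact duplicates.

    Duplicate (species, lon, lat) rows — coordinates compared after rounding
    to 6 decimal places (~0.1 m) — are collapsed to their first record.
    Idempotent; species whose records are all dropped simply vanish from the
    table and are flagged later from the species list.
    """
    if not allowed:
        raise ValueError("allowed label set must be non-empty")
    out = occ[occ["label"].isin(set(allowed))].copy()
    key_lon = out["lon"].round(_DUP_DECIMALS)
    key_lat = out["lat"].round(_DUP_DECIMALS)
    dup = pd.DataFrame({"s": out["species_id"], "x": key_lon, "y": key_lat}).duplicated()
    return out[~dup.values].reset_index(drop=True)


def aoo_cell_indices(lon: np.ndarray, lat: np.ndarray) -> np.ndarray:
    """(i, j) indices of the 2x2 km equal-area AOO cell of each point.

    Lambert cylindrical equal-area: x = R * lon_rad, y = R * sin(lat_rad),
    tiled from the (0, 0) origin.
    """
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    x = EARTH_RADIUS_KM * np.radians(lon)
    y = EARTH_RADIUS_KM * np.sin(np.radians(lat))
    return np.stack(
        [np.floor(x / AOO_CELL_KM).astype(np.int64), np.floor(y / AOO_CELL_KM).astype(np.int64)],
        axis=1,
    )


def compute_aoo(lon, lat) -> float:
    """Area of occupancy in km^2: distinct occupied 2x2 km cells x 4 km^2.

    Invariant to duplicated points and point order.
    """
    lon = np.atleast_1d(np.asarray(lon, dtype=float))
    lat = np.atleast_1d(np.asarray(lat, dtype=float))
    if lon.size == 0:
        raise EmptySpeciesError("AOO is undefined for a species with no records")
    cells = aoo_cell_indices(lon, lat)
    n_cells = np.unique(cells, axis=0).shape[0]
    return float(n_cells) * AOO_CELL_KM**2


def flag_minimal_area(
    occ: pd.DataFrame,
    species_ids: list[str] | None = None,
    degenerate: set[str] | frozenset[str] = frozenset(),
) -> pd.DataFrame:
    """Per-species minimal-area flags after QC.

    A species is flagged when it has fewer than five records (strict, the
    hull-construction requirement), an AOO below 10 km^2 (strict, the
    Critically-Endangered occupancy bound), or — if listed in
    ``degenerate`` — a zero-area convex hull. Flagged species bypass the
    extent and rate stages and enter the imputation path.

    All records (including coordinate duplicates) count toward n_records;
    duplicates count once toward AOO by construction.
    """
    if species_ids is None:
        species_ids = list(pd.unique(occ["species_id"]))
    grouped = dict(tuple(occ.groupby("species_id", sort=False)))
    rows = []
    for sp in species_ids:
        g = grouped.get(sp)
        n = 0 if g is None else len(g)
        aoo = compute_aoo(g["lon"].values, g["lat"].values) if n else 0.0
        if n < MIN_RECORDS:
            flagged, reason = True, "few_records"
        elif aoo < MIN_AOO_KM2:
            flagged, reason = True, "small_aoo"
        elif sp in degenerate:
            flagged, reason = True, "degenerate_hull"
        else:
            flagged, reason = False, None
        rows.append((sp, n, aoo, flagged, reason))
    return pd.DataFrame(
        rows, columns=["species_id", "n_records", "aoo_km2", "flagged", "reason"]
    )
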