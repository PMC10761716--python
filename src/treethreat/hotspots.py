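"""Hotspot mapping: stacked species extents and multi-threat overlays.

Extents are rasterized to presence (a cell belongs to an extent when any
positive coverage weight touches it) and summed to per-cell species counts.
Dividing the count of priority candidates by the count of all rate-assessed
species gives the fraction map; cells without any assessed species are
masked (NaN). The per-threat overlay binarizes each threat's hotspot layer
to presence (a single priority species suffices) and sums the six layers,
giving 0-6 simultaneous threats per cell.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .extent import ExtentMask
from .grid import GridSpec, Raster


@dataclass
class HotspotGrid:
    """A per-cell count, fraction, or overlay layer."""

    grid: GridSpec
    values: np.ndarray
    kind: str  # all_species | priority_by_threat | priority_union | fraction | threat_overlay

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.shape != self.grid.shape:
            raise ValueError("values shape does not match grid")

    def as_raster(self) -> Raster:
        nodata = np.nan if self.values.dtype.kind == "f" else None
        return Raster(self.grid, self.values, nodata=nodata)


def rasterize_extent(extent: ExtentMask, grid: GridSpec | None = None) -> Raster:
    """Binary presence raster of one extent (1 wherever weight > 0)."""
    grid = grid or extent.grid
    if grid != extent.grid:
        raise ValueError("extent is not on the requested grid")
    values = np.zeros(grid.shape, dtype=np.int32)
    values[extent.rows, extent.cols] = 1
    return Raster(grid, values)


def count_stack(extents: list[ExtentMask], grid: GridSpec, kind: str = "all_species") -> HotspotGrid:
    """Per-cell count of overlapping extents (permutation-invariant)."""
    counts = np.zeros(grid.shape, dtype=np.int32)
    for ext in extents:
        if ext.grid != grid:
            raise ValueError("all extents must share the output grid")
        counts[ext.rows, ext.cols] += 1
    return HotspotGrid(grid, counts, kind)


def fraction_map(priority_counts: HotspotGrid, total_counts: HotspotGrid) -> HotspotGrid:
    """Priority share of the local species count; NaN where no species."""
    if priority_counts.grid != total_counts.grid:
        raise ValueError("count layers are on different grids")
    p = priority_counts.values.astype(float)
    t = total_counts.values.astype(float)
    if np.any(p > t):
        raise ValueError("priority count exceeds total count in some cell")
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(t > 0, p / t, np.nan)
    return HotspotGrid(priority_counts.grid, frac, "fraction")


def threat_overlay(per_threat_hotspots: list[HotspotGrid]) -> HotspotGrid:
    """Number of threats (0-6) with at least one priority species per cell."""
    if len(per_threat_hotspots) != 6:
        raise ValueError("expected six per-threat hotspot layers")
    grid = per_threat_hotspots[0].grid
    total = np.zeros(grid.shape, dtype=np.int32)
    for layer in per_threat_hotspots:
        if layer.grid != grid:
            raise ValueError("hotspot layers are on different grids")
        total += (np.nan_to_num(layer.values) > 0).astype(np.int32)
    return HotspotGrid(grid, total, "threat_overlay")
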