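"""Restrict analysis to potentially irrigable agricultural land.

Two gates are applied before any classification: the land-cover layer
must mark a pixel as agriculture (any cropping season), and terrain
slope must not exceed a threshold (default 20%, above which surface
irrigation is not practised).  The surviving pixels are then
partitioned by agroecological zone, because crop calendars, lookup
tables and irrigation thresholds are all calibrated per zone.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import shapely
from shapely.geometry import shape as _shapely_shape

from .raster import CategoricalMap, GridSpec, ScalarMap

__all__ = [
    "MaskLayer",
    "ZonePartition",
    "agricultural_mask",
    "partition_by_zone",
    "load_zone_polygons",
]


@dataclass
class MaskLayer:
    """Boolean include/exclude layer on the analysis grid."""

    grid: GridSpec
    include: np.ndarray

    def __post_init__(self) -> None:
        self.include = np.asarray(self.include, dtype=bool)
        if self.include.shape != self.grid.shape:
            raise ValueError("mask shape does not match grid")

    @property
    def n_included(self) -> int:
        return int(self.include.sum())


@dataclass
class ZonePartition:
    """Disjoint assignment of masked pixels to agroecological zones.

    ``pixels_by_zone`` maps zone id to an (n, 2) array of (row, col)
    indices; ``n_dropped`` counts masked pixels covered by no zone.
    """

    zone_ids: list[int]
    pixels_by_zone: dict[int, np.ndarray]
    n_dropped: int = 0

    def __post_init__(self) -> None:
        seen: set[tuple[int, int]] = set()
        for zid in self.zone_ids:
            px = self.pixels_by_zone[zid]
            pairs = {tuple(p) for p in np.asarray(px).reshape(-1, 2)}
            if seen & pairs:
                raise ValueError("zones are not disjoint")
            seen |= pairs


def agricultural_mask(
    lulc: CategoricalMap,
    ag_codes: set[int] | frozenset[int],
    slope: ScalarMap,
    slope_threshold_pct: float = 20.0,
) -> MaskLayer:
    """Include pixels that are agriculture and lie on slope <= threshold.

    Nodata in either input excludes the pixel.  All seasonal cropland
    codes should be passed in ``ag_codes``; season handling happens
    later, in phenology.
    """
    if not ag_codes:
        raise ValueError("ag_codes must be non-empty")
    if slope_threshold_pct < 0:
        raise ValueError("slope threshold must be non-negative")
    if not lulc.grid.approx_equal(slope.grid):
        raise ValueError("lulc and slope are not on the same grid")

    is_ag = np.isin(lulc.codes, list(ag_codes)) & (lulc.codes != lulc.nodata_code)
    slope_ok = (
        (slope.values <= slope_threshold_pct)
        & (slope.values != slope.grid.nodata)
        & np.isfinite(slope.values)
        & (slope.values >= 0)
    )
    return MaskLayer(lulc.grid, is_ag & slope_ok)


def load_zone_polygons(path) -> list[tuple[int, "shapely.Geometry"]]:
    """Read zone polygons from a GeoJSON FeatureCollection.

    Each feature must carry an integer ``zone_id`` property (falling
    back to the feature's position).
    """
    with open(Path(path)) as fh:
        gj = json.load(fh)
    feats = gj["features"] if gj.get("type") == "FeatureCollection" else [gj]
    out = []
    for i, feat in enumerate(feats):
        zid = int(feat.get("properties", {}).get("zone_id", i))
        out.append((zid, _shapely_shape(feat["geometry"])))
    return out


def partition_by_zone(mask: MaskLayer, zones) -> ZonePartition:
    """Assign every included pixel to exactly one zone.

    ``zones`` is either a co-registered :class:`CategoricalMap` of zone
    ids or a list of ``(zone_id, shapely polygon)`` pairs; polygon
    membership uses the pixel-center rule.  Pixels outside all zones are
    dropped and counted.  Overlapping zone polygons are an error.
    """
    rows, cols = np.nonzero(mask.include)
    if isinstance(zones, CategoricalMap):
        if not zones.grid.approx_equal(mask.grid):
            raise ValueError("zone map is not on the analysis grid")
        zcodes = zones.codes[rows, cols]
        valid = zcodes != zones.nodata_code
        pixels_by_zone = {}
        for zid in np.unique(zcodes[valid]):
            sel = valid & (zcodes == zid)
            pixels_by_zone[int(zid)] = np.column_stack([rows[sel], cols[sel]])
        n_dropped = int((~valid).sum())
        return ZonePartition(sorted(pixels_by_zone), pixels_by_zone, n_dropped)

    xs = mask.grid.origin_x + (cols + 0.5) * mask.grid.pixel_size
    ys = mask.grid.origin_y - (rows + 0.5) * mask.grid.pixel_size
    assigned = np.full(rows.shape, -1, dtype=np.int64)
    overlaps: list[tuple[int, int]] = []
    pixels_by_zone = {}
    for zid, geom in zones:
        inside = shapely.contains_xy(geom, xs, ys)
        clash = inside & (assigned >= 0)
        if clash.any():
            prev = int(assigned[clash][0])
            overlaps.append((prev, zid))
            continue
        assigned[inside] = zid
        pixels_by_zone[int(zid)] = np.column_stack([rows[inside], cols[inside]])
    if overlaps:
        pairs = ", ".join(f"{a}&{b}" for a, b in overlaps)
        raise ValueError(f"overlapping zone polygons: {pairs}")
    n_dropped = int((assigned < 0).sum())
    pixels_by_zone = {z: p for z, p in pixels_by_zone.items() if len(p)}
    return ZonePartition(sorted(pixels_by_zone), pixels_by_zone, n_dropped)
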