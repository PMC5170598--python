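"""MVCI decision-tree separation of irrigated from rainfed pixels.

Within a crop class, irrigated pixels reach a higher seasonal peak NDVI
than rainfed pixels of the same crop, because irrigation removes the
soil-moisture ceiling on canopy development.  The classifier turns that
relative gap into a class-specific threshold, with no calibration
against census statistics:

* Members of a (crop class, season window) group are divided into
  seasonal pools — subpopulations of the class, ordered by their peak
  NDVI — and the pool maxima ``NDVI_imclass(i)`` are collected.
* ``NDVI_mclass`` is the mean of the pool maxima, ``NDVI_mp`` their
  minimum, and the mean vegetation condition index is the relative
  shortfall of the weakest pool::

      MVCI = (NDVI_mp - NDVI_mclass) / NDVI_mclass          (<= 0)

* The irrigation threshold scales the weakest-pool maximum down by
  that stress fraction::

      NDVI_irclass = NDVI_mp * (1 + MVCI)

A classified pixel with seasonal peak ``v`` (its NDVI_iclass) is
labelled irrigated when ``v >= max(NDVI_irclass, 0.2)`` and the pixel
clears the weakest pool by the separation margin,
``v - NDVI_mp >= 0.15``.  Both constants are configurable.  MVCI is
applied as a fraction; multiplying by 100 only re-expresses it as the
percentage stress change for reporting.

Classes whose pixels are all alike (a single pool, or all-irrigated /
all-rainfed groups) give MVCI = 0 and a threshold at the class maximum,
so no pixel is labelled irrigated: the method is inherently relative
and stays conservative where no within-class contrast exists.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .masking import MaskLayer, ZonePartition, partition_by_zone, agricultural_mask
from .phenology import (
    CropLookupTable,
    SeasonWindows,
    collect_training_samples,
    select_training_pixels,
)
from .raster import CategoricalMap, IrrigationMap, NdviStack, ScalarMap
from .scm import CropClassMap, UNCLASSIFIED, build_signatures, classify_pixels

__all__ = [
    "ClassPoolStats",
    "compute_class_pool_stats",
    "quantile_subpools",
    "seasonal_peaks",
    "derive_class_stats",
    "classify_irrigation",
    "run_pipeline",
    "PipelineResult",
]


@dataclass
class ClassPoolStats:
    """Per (crop class, season window): the threshold quantities."""

    class_id: int
    pool_id: str
    ndvi_imclass: np.ndarray  # pool maxima, one per seasonal pool
    ndvi_mclass: float
    ndvi_mp: float
    mvci: float
    ndvi_irclass: float
    n_pixels: int = 0

    def __post_init__(self) -> None:
        self.ndvi_imclass = np.asarray(self.ndvi_imclass, dtype=float)
        if not (self.ndvi_irclass <= self.ndvi_mp + 1e-12 <= self.ndvi_mclass + 2e-12):
            raise ValueError("invariant NDVI_irclass <= NDVI_mp <= NDVI_mclass violated")

    def threshold(self, min_irclass: float = 0.2) -> float:
        return max(self.ndvi_irclass, min_irclass)


def compute_class_pool_stats(
    peaks_by_pool: Sequence[np.ndarray],
    class_id: int = 0,
    pool_id: str = "",
) -> ClassPoolStats:
    """Threshold statistics from member peak NDVI grouped into n seasonal pools.

    ``peaks_by_pool`` holds, for each of the n pools, the member
    pixels' peak NDVI; NDVI_imclass(i) is pool i's maximum.
    """
    if len(peaks_by_pool) < 1:
        raise ValueError("at least one seasonal pool required")
    imclass = []
    n_pixels = 0
    for i, peaks in enumerate(peaks_by_pool):
        arr = np.asarray(peaks, dtype=float)
        if arr.size == 0:
            raise ValueError(f"seasonal pool {i} has no member pixels")
        if not np.all(np.isfinite(arr)):
            raise ValueError(f"non-finite peak NDVI in pool {i}")
        imclass.append(float(arr.max()))
        n_pixels += arr.size
    imclass = np.array(imclass)
    mclass = float(imclass.mean())
    mp = float(imclass.min())
    if mclass == 0:
        raise ValueError("NDVI_mclass is zero; MVCI undefined")
    mvci = (mp - mclass) / mclass
    irclass = mp * (1.0 + mvci)
    return ClassPoolStats(class_id, pool_id, imclass, mclass, mp, mvci, irclass, n_pixels)


def quantile_subpools(peaks: np.ndarray, n_subpools: int = 4) -> list[np.ndarray]:
    """Split member peaks into rank-ordered seasonal subpools.

    Members are sorted by peak NDVI and cut into ``n_subpools``
    near-equal contiguous rank bins (fewer when the class is small), so
    the weakest pool's maximum tracks the rainfed end of the class's
    amplitude distribution rather than its global maximum.
    """
    arr = np.sort(np.asarray(peaks, dtype=float))
    if arr.size == 0:
        raise ValueError("no member peaks")
    k = min(n_subpools, arr.size)
    return [b for b in np.array_split(arr, k) if b.size]


def seasonal_peaks(
    ndvic: NdviStack, windows: SeasonWindows = SeasonWindows()
) -> dict[str, np.ndarray]:
    """Per-pixel peak NDVI within each disjoint season window (FS/SS/IS).

    Nodata composites are ignored; a window with no valid composite
    yields NaN.
    """
    vals = ndvic.values.astype(float)
    vals[vals == ndvic.grid.nodata] = np.nan
    out = {}
    for pool in ("FS", "SS", "IS"):
        lo, hi = windows.window(pool)
        hi = min(hi, vals.shape[0] - 1)
        if hi < lo:
            continue
        with np.errstate(all="ignore"):
            out[pool] = np.nanmax(vals[lo: hi + 1], axis=0)
    return out


def _season_detected(
    ndvic: NdviStack, windows: SeasonWindows, min_amplitude: float
) -> dict[str, np.ndarray]:
    """Boolean per pool: does the pixel swing by >= min_amplitude inside the window."""
    vals = ndvic.values.astype(float)
    vals[vals == ndvic.grid.nodata] = np.nan
    out = {}
    for pool in ("FS", "SS", "IS"):
        lo, hi = windows.window(pool)
        hi = min(hi, vals.shape[0] - 1)
        if hi < lo:
            continue
        with np.errstate(all="ignore"):
            amp = np.nanmax(vals[lo: hi + 1], axis=0) - np.nanmin(vals[lo: hi + 1], axis=0)
        out[pool] = np.nan_to_num(amp) >= min_amplitude
    return out


def derive_class_stats(
    ndvic: NdviStack,
    crop_class_map: CropClassMap,
    windows: SeasonWindows = SeasonWindows(),
    n_subpools: int = 4,
    min_amplitude: float = 0.1,
    min_group: int = 2,
) -> dict[tuple[int, str], ClassPoolStats]:
    """Eq-based thresholds per (crop class, season window) group.

    Each classified pixel contributes its peak NDVI in its best season
    window (the detected window with the largest peak); the group's
    members are split into rank subpools and fed to
    :func:`compute_class_pool_stats`.  Groups smaller than
    ``min_group`` are skipped (no irrigated labels there).
    """
    peaks = seasonal_peaks(ndvic, windows)
    detected = _season_detected(ndvic, windows, min_amplitude)
    codes = crop_class_map.codes
    stats: dict[tuple[int, str], ClassPoolStats] = {}
    best_pool, best_peak = _best_pool(peaks, detected)
    for class_id in np.unique(codes):
        if class_id == UNCLASSIFIED:
            continue
        member = codes == class_id
        for pool in peaks:
            sel = member & (best_pool == _POOL_CODES[pool])
            vals = best_peak[sel]
            vals = vals[np.isfinite(vals)]
            if vals.size < min_group:
                continue
            stats[(int(class_id), pool)] = compute_class_pool_stats(
                quantile_subpools(vals, n_subpools), int(class_id), pool
            )
    return stats


_POOL_CODES = {"FS": 0, "SS": 1, "IS": 2}


def _best_pool(peaks: dict[str, np.ndarray], detected: dict[str, np.ndarray]):
    """Per pixel: code of the detected window with the largest peak, and that peak."""
    shape = next(iter(peaks.values())).shape
    stacked = np.full((len(_POOL_CODES),) + shape, -np.inf)
    for pool, code in _POOL_CODES.items():
        if pool not in peaks:
            continue
        p = np.where(detected[pool] & np.isfinite(peaks[pool]), peaks[pool], -np.inf)
        stacked[code] = p
    best = np.argmax(stacked, axis=0)
    best_peak = np.take_along_axis(stacked, best[None], axis=0)[0]
    best = np.where(np.isfinite(best_peak), best, -1)
    return best, np.where(np.isfinite(best_peak), best_peak, np.nan)


def classify_irrigation(
    ndvic: NdviStack,
    crop_class_map: CropClassMap,
    stats: Mapping[tuple[int, str], ClassPoolStats],
    min_irclass: float = 0.2,
    min_separation: float = 0.15,
    windows: SeasonWindows = SeasonWindows(),
    min_amplitude: float = 0.1,
) -> IrrigationMap:
    """Label classified pixels irrigated (1) or not (0).

    A pixel is irrigated when, in any season window where it shows a
    detected season and its class has statistics, its window peak ``v``
    satisfies ``v >= max(NDVI_irclass, min_irclass)`` and
    ``v - NDVI_mp >= min_separation``.  Unclassified and masked-out
    pixels are 0; a pixel partially irrigated counts as fully irrigated
    (binary product semantics).
    """
    peaks = seasonal_peaks(ndvic, windows)
    detected = _season_detected(ndvic, windows, min_amplitude)
    codes = crop_class_map.codes
    label = np.zeros(codes.shape, dtype=np.uint8)
    for (class_id, pool), st in stats.items():
        if pool not in peaks:
            continue
        theta = st.threshold(min_irclass)
        v = peaks[pool]
        hit = (
            (codes == class_id)
            & detected[pool]
            & np.isfinite(v)
            & (v >= theta)
            & (v - st.ndvi_mp >= min_separation)
        )
        label[hit] = 1
    return IrrigationMap(ndvic.grid, label, ndvic.water_year_label)


# ---------------------------------------------------------------------------
# End-to-end pipeline
# ---------------------------------------------------------------------------

@dataclass
class PipelineResult:
    irrigation: IrrigationMap
    crop_classes: CategoricalMap
    mask: MaskLayer
    stats: dict[tuple[int, str], ClassPoolStats]
    report: dict

    def report_text(self) -> str:
        lines = [f"water year: {self.irrigation.water_year_label or '(unlabelled)'}"]
        lines.append(f"agricultural pixels: {self.mask.n_included}")
        lines.append(f"irrigated pixels: {self.irrigation.irrigated_count()}")
        for zid, zrep in sorted(self.report.get("zones", {}).items()):
            lines.append(f"zone {zid}:")
            for key, val in zrep.items():
                if key == "class_stats":
                    continue
                lines.append(f"  {key}: {val}")
        if self.stats:
            lines.append("class thresholds (class, window): n, imclass, mclass, mp, MVCI, irclass")
            for (cid, pool), st in sorted(self.stats.items()):
                im = ", ".join(f"{v:.4f}" for v in st.ndvi_imclass)
                lines.append(
                    f"  ({cid}, {pool}): n={st.n_pixels} imclass=[{im}] "
                    f"mclass={st.ndvi_mclass:.4f} mp={st.ndvi_mp:.4f} "
                    f"MVCI={st.mvci:.4f} irclass={st.ndvi_irclass:.4f}"
                )
        return "\n".join(lines)


def run_pipeline(
    ndvic: NdviStack,
    lulc: CategoricalMap,
    slope: ScalarMap,
    zones,
    lookup: CropLookupTable,
    ag_codes: set[int],
    slope_threshold_pct: float = 20.0,
    sample_spacing_m: float = 4000.0,
    min_members: int = 3,
    min_scm: float = 0.5,
    min_irclass: float = 0.2,
    min_separation: float = 0.15,
    windows: SeasonWindows | None = None,
    n_subpools: int = 4,
    min_amplitude: float = 0.1,
) -> PipelineResult:
    """Mask, train, classify crops, and classify irrigation, zone by zone.

    ``zones`` is a zone CategoricalMap or a list of (zone_id, polygon)
    pairs.  The run is fully deterministic: the training lattice, SCM
    scoring, and the threshold equations involve no random draws.
    """
    if windows is None:
        windows = SeasonWindows(n_composites=ndvic.n_composites)
    mask = agricultural_mask(lulc, ag_codes, slope, slope_threshold_pct)
    report: dict = {"n_agricultural": mask.n_included, "zones": {}}
    codes = np.full(mask.grid.shape, UNCLASSIFIED, dtype=np.int32)
    label = np.zeros(mask.grid.shape, dtype=np.uint8)
    all_stats: dict[tuple[int, str], ClassPoolStats] = {}
    legend: dict[int, str] = {}

    if mask.n_included == 0:
        report["note"] = "empty agricultural mask: all-zero irrigation map"
        irr = IrrigationMap(ndvic.grid, label, ndvic.water_year_label)
        classes = CategoricalMap(ndvic.grid, codes, legend, UNCLASSIFIED)
        return PipelineResult(irr, classes, mask, all_stats, report)

    partition = partition_by_zone(mask, zones)
    report["n_zone_dropped"] = partition.n_dropped
    class_offset = 0
    for zid in partition.zone_ids:
        zrep: dict = {}
        zpx = partition.pixels_by_zone[zid]
        zone_mask = np.zeros(mask.grid.shape, dtype=bool)
        zone_mask[zpx[:, 0], zpx[:, 1]] = True
        zmask = MaskLayer(mask.grid, zone_mask)
        lattice = select_training_pixels(zmask, sample_spacing_m, mask.grid.pixel_size)
        samples, train_rep = collect_training_samples(
            ndvic, lattice, lookup, zid, windows, min_amplitude=min_amplitude
        )
        zrep["training"] = train_rep
        if not samples:
            zrep["note"] = "no training samples assigned; zone left unclassified"
            report["zones"][zid] = zrep
            continue
        try:
            signatures, sig_rep = build_signatures(samples, min_members)
        except ValueError:
            zrep["note"] = "no crop reached minimum training members; zone left unclassified"
            report["zones"][zid] = zrep
            continue
        zrep["signatures"] = sig_rep
        # offset class ids so they stay unique across zones
        for s in signatures:
            s.class_id += class_offset
        class_offset += len(signatures)
        ccm = classify_pixels(ndvic, signatures, zone_mask, min_scm)
        legend.update(ccm.legend())
        codes[zone_mask] = ccm.codes[zone_mask]
        zstats = derive_class_stats(
            ndvic, ccm, windows, n_subpools, min_amplitude
        )
        irr = classify_irrigation(
            ndvic, ccm, zstats, min_irclass, min_separation, windows, min_amplitude
        )
        label[zone_mask] = irr.label[zone_mask]
        all_stats.update(zstats)
        counts = {legend.get(c, str(c)): int((ccm.codes[zone_mask] == c).sum())
                  for c in np.unique(ccm.codes[zone_mask]) if c != UNCLASSIFIED}
        zrep["class_pixels"] = counts
        zrep["irrigated_pixels"] = int(irr.label[zone_mask].sum())
        report["zones"][zid] = zrep

    irr = IrrigationMap(ndvic.grid, label, ndvic.water_year_label)
    classes = CategoricalMap(ndvic.grid, codes, legend, UNCLASSIFIED)
    return PipelineResult(irr, classes, mask, all_stats, report)
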