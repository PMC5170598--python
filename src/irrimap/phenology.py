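"""Per-pixel seasonal phenology and lookup-table crop typing.

A pixel's water-year NDVI profile (23 composites, June-May) is reduced
to one descriptor per seasonal pool: emergence and senescence composite
indices found by the cumulative-departure rule, the season duration,
and the peak NDVI re-expressed as a "height" on a 1-100 scale (peak
NDVI 0.1 maps to 1, 0.8 to 100).  Descriptors are matched against a
zone-specific lookup table — expected height, duration and sowing
window per crop, in an explicit priority order — to assign a candidate
crop type; pixels so labelled on a coarse lattice (one sample every
~4 km) become the training set for signature-based classification.

Seasonal pools are within-year windows: FS (first season, Kharif,
monsoon), SS (second season, Rabi, winter), IS (intermediate season,
Zaid, summer) and CMS (complete season, the whole water year).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .masking import MaskLayer
from .raster import NdviStack

__all__ = [
    "FlatProfileError",
    "SeasonWindows",
    "SeasonDescriptor",
    "CropCalendarEntry",
    "CropLookupTable",
    "TrainingSample",
    "scale_height",
    "cumulative_departure_dates",
    "fill_nodata_gaps",
    "select_training_pixels",
    "extract_season_descriptors",
    "assign_crop_type",
    "collect_training_samples",
    "SEASON_TO_POOL",
]

#: Cropping season to seasonal-pool label.
SEASON_TO_POOL = {"Kharif": "FS", "Rabi": "SS", "Zaid": "IS", "Annual": "CMS"}
POOL_TO_SEASON = {v: k for k, v in SEASON_TO_POOL.items()}


class FlatProfileError(ValueError):
    """Raised for a constant NDVI profile: no seasonal signal to date."""


@dataclass(frozen=True)
class SeasonWindows:
    """Composite-index windows (inclusive) of the seasonal pools.

    Defaults place Kharif at June-October (composites 0-9 of a 23-layer
    June-May stack), Rabi at November-March (10-18) and Zaid at
    April-May (19-22); CMS spans the whole year.  Zones with shifted
    calendars can override any window.
    """

    fs: tuple[int, int] = (0, 9)
    ss: tuple[int, int] = (10, 18)
    is_: tuple[int, int] = (19, 22)
    n_composites: int = 23

    @property
    def cms(self) -> tuple[int, int]:
        return (0, self.n_composites - 1)

    def window(self, pool: str) -> tuple[int, int]:
        return {"FS": self.fs, "SS": self.ss, "IS": self.is_, "CMS": self.cms}[pool]


@dataclass
class SeasonDescriptor:
    pool: str
    emergence_idx: int
    senescence_idx: int
    duration: int
    peak_ndvi: float
    height: float

    def __post_init__(self) -> None:
        if self.emergence_idx >= self.senescence_idx:
            raise ValueError("emergence must precede senescence")

    @property
    def season(self) -> str:
        return POOL_TO_SEASON.get(self.pool, "Annual")


@dataclass
class CropCalendarEntry:
    """One (zone, crop) lookup row.

    ``height_range`` is the expected 1-100 scaled peak height interval,
    ``duration_range`` the expected season length in composites, and
    ``sowing_window`` the composite interval in which emergence must
    fall.  ``priority`` orders entries within a zone: lower numbers are
    tried first (the hierarchical threshold assignment).
    ``stage_offsets`` optionally records composite offsets from sowing
    for seedling, tillering, flowering, ripening and harvest stages.
    """

    zone_id: int
    crop_name: str
    season: str
    priority: int
    height_range: tuple[float, float]
    duration_range: tuple[int, int]
    sowing_window: tuple[int, int]
    stage_offsets: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.season not in SEASON_TO_POOL:
            raise ValueError(f"unknown season {self.season!r}")
        if self.duration_range[0] < 1:
            raise ValueError("duration must be at least one composite")
        if self.height_range[0] > self.height_range[1]:
            raise ValueError("empty height interval")

    @property
    def pool(self) -> str:
        return SEASON_TO_POOL[self.season]


_LOOKUP_COLUMNS = [
    "zone_id", "crop_name", "season", "priority",
    "height_min", "height_max", "duration_min", "duration_max",
    "sowing_min", "sowing_max",
]


class CropLookupTable:
    """Priority-ordered lookup of expected crop signatures per zone."""

    def __init__(self, entries: Iterable[CropCalendarEntry]):
        self.entries = sorted(entries, key=lambda e: (e.zone_id, e.priority, e.crop_name))
        seen = set()
        for e in self.entries:
            key = (e.zone_id, e.season, e.height_range, e.duration_range)
            if key in seen:
                raise ValueError(f"duplicate lookup condition for zone {e.zone_id}: {key[1:]}")
            seen.add(key)

    def for_zone(self, zone_id: int) -> list[CropCalendarEntry]:
        return [e for e in self.entries if e.zone_id == zone_id]

    def zones(self) -> list[int]:
        return sorted({e.zone_id for e in self.entries})

    @classmethod
    def from_tsv(cls, path) -> "CropLookupTable":
        df = pd.read_csv(Path(path), sep="\t", comment="#")
        missing = set(_LOOKUP_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"lookup table missing columns: {sorted(missing)}")
        entries = [
            CropCalendarEntry(
                zone_id=int(r.zone_id),
                crop_name=str(r.crop_name),
                season=str(r.season),
                priority=int(r.priority),
                height_range=(float(r.height_min), float(r.height_max)),
                duration_range=(int(r.duration_min), int(r.duration_max)),
                sowing_window=(int(r.sowing_min), int(r.sowing_max)),
            )
            for r in df.itertuples()
        ]
        return cls(entries)

    def to_tsv(self, path) -> Path:
        rows = [
            {
                "zone_id": e.zone_id, "crop_name": e.crop_name, "season": e.season,
                "priority": e.priority,
                "height_min": e.height_range[0], "height_max": e.height_range[1],
                "duration_min": e.duration_range[0], "duration_max": e.duration_range[1],
                "sowing_min": e.sowing_window[0], "sowing_max": e.sowing_window[1],
            }
            for e in self.entries
        ]
        path = Path(path)
        pd.DataFrame(rows, columns=_LOOKUP_COLUMNS).to_csv(path, sep="\t", index=False)
        return path


@dataclass
class TrainingSample:
    row: int
    col: int
    zone_id: int
    profile: np.ndarray
    descriptors: list[SeasonDescriptor]
    crop_name: str


def scale_height(peak_ndvi: float) -> float:
    """Map peak NDVI to the 1-100 height scale.

    The attainable cropped-area peak range 0.1-0.8 is mapped linearly
    onto 1-100; values outside are clamped to the endpoints.
    """
    v = np.asarray(peak_ndvi, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("peak NDVI must be finite")
    h = np.clip(1.0 + 99.0 * (np.clip(v, 0.1, 0.8) - 0.1) / 0.7, 1.0, 100.0)
    return float(h) if np.isscalar(peak_ndvi) or v.ndim == 0 else h


def cumulative_departure_dates(profile: Sequence[float]) -> tuple[int, int]:
    """Emergence and senescence composite indices by cumulative NDVI departure.

    Departures d_t = x_t - mean(x) are accumulated; emergence is the
    (earliest) index minimising the cumulative sum — the last date of
    below-mean greenness before green-up — and senescence the earliest
    post-emergence index maximising it, where the profile falls back
    below its mean.  A constant profile has no season and raises
    :class:`FlatProfileError`.
    """
    x = np.asarray(profile, dtype=float)
    if x.ndim != 1 or x.size < 3:
        raise ValueError("profile must be 1-D with at least 3 composites")
    if not np.all(np.isfinite(x)):
        raise ValueError("profile contains non-finite values; gap-fill first")
    cum = np.cumsum(x - x.mean())
    if np.allclose(cum, 0.0, atol=1e-12):
        raise FlatProfileError("constant profile: no seasonal signal")
    emergence = int(np.argmin(cum))
    if emergence >= x.size - 1:
        raise FlatProfileError("no post-emergence greenness found")
    tail = cum[emergence + 1:]
    senescence = emergence + 1 + int(np.argmax(tail))
    return emergence, senescence


def fill_nodata_gaps(
    profile: np.ndarray, nodata: float, max_gap: int = 3
) -> np.ndarray | None:
    """Linearly interpolate nodata runs; return None if any run exceeds max_gap.

    Leading/trailing gaps are held at the nearest valid value.
    """
    x = np.asarray(profile, dtype=float)
    bad = (x == nodata) | ~np.isfinite(x)
    if not bad.any():
        return x.copy()
    if bad.all():
        return None
    # longest run of consecutive gaps
    run, longest = 0, 0
    for b in bad:
        run = run + 1 if b else 0
        longest = max(longest, run)
    if longest > max_gap:
        return None
    idx = np.arange(x.size)
    return np.interp(idx, idx[~bad], x[~bad])


def select_training_pixels(
    mask: MaskLayer, spacing_m: float = 4000.0, pixel_size_m: float = 250.0
) -> np.ndarray:
    """Deterministic training lattice: one candidate every ~spacing_m.

    Rows/cols are sampled every round(spacing/pixel_size) cells (16 for
    the 4 km / 250 m defaults), offset to the lattice center, and
    intersected with the mask.  Returns an (n, 2) array of (row, col).
    """
    if spacing_m < pixel_size_m:
        raise ValueError("spacing must be at least one pixel")
    if mask.n_included == 0:
        raise ValueError("mask is empty")
    step = max(int(round(spacing_m / pixel_size_m)), 1)
    offset = step // 2
    rows = np.arange(offset, mask.grid.n_rows, step)
    cols = np.arange(offset, mask.grid.n_cols, step)
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    keep = mask.include[rr, cc]
    return np.column_stack([rr[keep], cc[keep]])


def extract_season_descriptors(
    profile: Sequence[float],
    windows: SeasonWindows = SeasonWindows(),
    min_amplitude: float = 0.1,
) -> list[SeasonDescriptor]:
    """One descriptor per seasonal pool in which a season is detected.

    Each of FS/SS/IS is examined independently: the pool's profile
    slice must swing by at least ``min_amplitude`` NDVI and yield
    cumulative-departure dates.  If any seasonal pool fires, a CMS
    (whole-year) descriptor is appended as well.  A flat profile yields
    an empty list.
    """
    x = np.asarray(profile, dtype=float)
    out: list[SeasonDescriptor] = []
    for pool in ("FS", "SS", "IS"):
        lo, hi = windows.window(pool)
        hi = min(hi, x.size - 1)
        if hi - lo + 1 < 3:
            continue
        seg = x[lo: hi + 1]
        if seg.max() - seg.min() < min_amplitude:
            continue
        try:
            em, sen = cumulative_departure_dates(seg)
        except FlatProfileError:
            continue
        em_g, sen_g = em + lo, sen + lo
        peak = float(x[em_g: sen_g + 1].max())
        out.append(
            SeasonDescriptor(
                pool=pool,
                emergence_idx=em_g,
                senescence_idx=sen_g,
                duration=sen_g - em_g + 1,
                peak_ndvi=peak,
                height=scale_height(peak),
            )
        )
    if out:
        try:
            em, sen = cumulative_departure_dates(x)
        except FlatProfileError:
            return out
        peak = float(x[em: sen + 1].max())
        out.append(
            SeasonDescriptor(
                pool="CMS",
                emergence_idx=em,
                senescence_idx=sen,
                duration=sen - em + 1,
                peak_ndvi=peak,
                height=scale_height(peak),
            )
        )
    return out


def assign_crop_type(
    descriptors: Sequence[SeasonDescriptor],
    lookup: CropLookupTable,
    zone_id: int,
) -> str | None:
    """First lookup entry (priority order) whose conditions a descriptor meets.

    An entry matches a descriptor when the descriptor's pool equals the
    entry's season pool, its duration falls in the entry's duration
    range, its height in the height interval, and its emergence index
    in the sowing window.  No match returns None (unassigned).
    """
    entries = lookup.for_zone(zone_id)
    if not entries:
        raise ValueError(f"lookup has no entries for zone {zone_id}")
    for entry in entries:
        for d in descriptors:
            if d.pool != entry.pool:
                continue
            if not (entry.duration_range[0] <= d.duration <= entry.duration_range[1]):
                continue
            if not (entry.height_range[0] <= d.height <= entry.height_range[1]):
                continue
            if not (entry.sowing_window[0] <= d.emergence_idx <= entry.sowing_window[1]):
                continue
            return entry.crop_name
    return None


def collect_training_samples(
    ndvic: NdviStack,
    pixels: np.ndarray,
    lookup: CropLookupTable,
    zone_id: int,
    windows: SeasonWindows = SeasonWindows(),
    max_gap: int = 3,
    min_amplitude: float = 0.1,
) -> tuple[list[TrainingSample], dict]:
    """Phenology-label lattice pixels to build a zone's training set.

    Returns the assigned samples and a tally report (candidates,
    gap-rejected, flat/unassigned).
    """
    samples: list[TrainingSample] = []
    report = {"candidates": int(len(pixels)), "gap_rejected": 0, "unassigned": 0}
    for r, c in np.asarray(pixels, dtype=int):
        prof = fill_nodata_gaps(ndvic.values[:, r, c], ndvic.grid.nodata, max_gap)
        if prof is None:
            report["gap_rejected"] += 1
            continue
        descriptors = extract_season_descriptors(prof, windows, min_amplitude)
        crop = assign_crop_type(descriptors, lookup, zone_id) if descriptors else None
        if crop is None:
            report["unassigned"] += 1
            continue
        samples.append(TrainingSample(int(r), int(c), zone_id, prof, descriptors, crop))
    report["assigned"] = len(samples)
    return samples, report


def training_samples_to_frame(samples: Sequence[TrainingSample]) -> pd.DataFrame:
    """Audit export: one row per (sample, descriptor)."""
    rows = []
    for s in samples:
        for d in s.descriptors:
            rows.append(
                {
                    "row": s.row, "col": s.col, "zone_id": s.zone_id, "crop": s.crop_name,
                    "pool": d.pool, "emergence_idx": d.emergence_idx,
                    "senescence_idx": d.senescence_idx, "duration": d.duration,
                    "peak_ndvi": d.peak_ndvi, "height": d.height,
                }
            )
    return pd.DataFrame(rows)
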