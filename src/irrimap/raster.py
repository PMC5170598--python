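"""Georeferenced grid model and GeoTIFF I/O.

All layers in a pipeline run share one analysis grid described by
:class:`GridSpec`: a north-up, axis-aligned grid with 0-based row/col
indices.  Pixel (r, c) covers the half-open square

    [origin_x + c*ps, origin_x + (c+1)*ps) x (origin_y - (r+1)*ps, origin_y - r*ps]

with ``ps`` the pixel size in map units (nominally 250 m).  Rasters are
written as plain GeoTIFFs: georeferencing goes into the standard
ModelPixelScale / ModelTiepoint / GDAL_NODATA tags and the layer
semantics (kind, composite dates, integer scale factor, legend) into a
JSON ImageDescription, so files round-trip losslessly through this
module and open in any GeoTIFF-aware viewer.

Reprojection between coordinate systems is deliberately refused: inputs
must already share a CRS, and :func:`align_to_grid` only resamples
between grids expressed in that common CRS.
"""

from __future__ import annotations

import datetime as _dt
import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile

__all__ = [
    "GridSpec",
    "NdviStack",
    "CategoricalMap",
    "ScalarMap",
    "IrrigationMap",
    "read_raster",
    "write_raster",
    "build_ndvic",
    "align_to_grid",
    "water_year_window",
]

# GeoTIFF / GDAL tag codes
_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_MODEL_TIEPOINT = 33922
_TAG_GDAL_NODATA = 42113


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a north-up analysis grid."""

    n_rows: int
    n_cols: int
    origin_x: float
    origin_y: float
    pixel_size: float
    crs_id: str = "EPSG:4326"
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        if self.n_rows <= 0 or self.n_cols <= 0:
            raise ValueError("grid dimensions must be positive")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    def pixel_center(self, row: int, col: int) -> tuple[float, float]:
        """Map coordinates of the center of pixel (row, col)."""
        x = self.origin_x + (col + 0.5) * self.pixel_size
        y = self.origin_y - (row + 0.5) * self.pixel_size
        return x, y

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Arrays (xs, ys) of all pixel-center coordinates, shape (n_rows, n_cols)."""
        cols = np.arange(self.n_cols)
        rows = np.arange(self.n_rows)
        xs = self.origin_x + (cols + 0.5) * self.pixel_size
        ys = self.origin_y - (rows + 0.5) * self.pixel_size
        return np.meshgrid(xs, ys)

    def approx_equal(self, other: "GridSpec", tol: float = 1e-9) -> bool:
        return (
            self.shape == other.shape
            and self.crs_id == other.crs_id
            and abs(self.origin_x - other.origin_x) <= tol
            and abs(self.origin_y - other.origin_y) <= tol
            and abs(self.pixel_size - other.pixel_size) <= tol
        )


def _require_shape(grid: GridSpec, arr: np.ndarray, ndim_spatial_from: int) -> None:
    if arr.shape[ndim_spatial_from:] != grid.shape:
        raise ValueError(
            f"array spatial shape {arr.shape[ndim_spatial_from:]} does not match grid {grid.shape}"
        )


@dataclass
class NdviStack:
    """Water-year stack of 16-day NDVI composites (the NDVIC).

    ``values`` has shape (T, n_rows, n_cols); valid NDVI lies in [-1, 1]
    and ``grid.nodata`` marks missing cells.  Composites are stored in
    ascending date order of their *start* dates, all within one water
    year (June 1 of year Y through May 31 of year Y+1).
    """

    grid: GridSpec
    values: np.ndarray
    composite_start_dates: list[_dt.date]
    water_year_label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float32)
        if self.values.ndim != 3:
            raise ValueError("NdviStack values must be 3-D (T, rows, cols)")
        _require_shape(self.grid, self.values, 1)
        if self.values.shape[0] != len(self.composite_start_dates):
            raise ValueError("one start date required per composite")
        if self.values.shape[0] < 1:
            raise ValueError("at least one composite required")
        dates = self.composite_start_dates
        if any(b <= a for a, b in zip(dates, dates[1:])):
            raise ValueError("composite start dates must be strictly increasing")
        valid = self.values != self.grid.nodata
        finite = self.values[valid & np.isfinite(self.values)]
        if finite.size and (finite.min() < -1 - 1e-6 or finite.max() > 1 + 1e-6):
            raise ValueError("NDVI values outside [-1, 1]")

    @property
    def n_composites(self) -> int:
        return self.values.shape[0]


@dataclass
class CategoricalMap:
    """Integer-coded layer (LULC class, zone id, crop class id)."""

    grid: GridSpec
    codes: np.ndarray
    legend: dict[int, str] = field(default_factory=dict)
    nodata_code: int = -1

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int32)
        _require_shape(self.grid, self.codes, 0)


@dataclass
class ScalarMap:
    """Per-pixel real-valued layer with stated units (slope %, NDVI, reflectance)."""

    grid: GridSpec
    values: np.ndarray
    units: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float32)
        _require_shape(self.grid, self.values, 0)


@dataclass
class IrrigationMap:
    """Binary irrigated-area product: 1 = irrigated, 0 = not, on the analysis grid."""

    grid: GridSpec
    label: np.ndarray
    water_year_label: str = ""

    def __post_init__(self) -> None:
        lab = np.asarray(self.label)
        if not np.isin(np.unique(lab), [0, 1]).all():
            raise ValueError("irrigation labels must be 0/1")
        self.label = lab.astype(np.uint8)
        _require_shape(self.grid, self.label, 0)

    def irrigated_count(self) -> int:
        return int(self.label.sum())


# ---------------------------------------------------------------------------
# GeoTIFF I/O
# ---------------------------------------------------------------------------

def _geo_extratags(grid: GridSpec) -> list:
    ps = float(grid.pixel_size)
    nd = float(grid.nodata)
    nd_str = str(int(nd)) if nd.is_integer() else repr(nd)
    return [
        (_TAG_MODEL_PIXEL_SCALE, "d", 3, (ps, ps, 0.0)),
        (_TAG_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, float(grid.origin_x), float(grid.origin_y), 0.0)),
        (_TAG_GDAL_NODATA, "s", 0, nd_str),
    ]


def write_raster(obj, path) -> Path:
    """Write a raster object as a GeoTIFF.

    Multi-composite stacks are written one band (TIFF page) per
    composite, in date order.  Irrigation maps go out as single-band
    uint8 with in-extent values {0, 1}.
    """
    path = Path(path)
    meta: dict = {
        "crs_id": obj.grid.crs_id,
        "nodata": float(obj.grid.nodata),
    }
    if isinstance(obj, NdviStack):
        meta["kind"] = "ndvi_stack"
        meta["dates"] = [d.isoformat() for d in obj.composite_start_dates]
        meta["water_year"] = obj.water_year_label
        data = obj.values.astype(np.float32)
    elif isinstance(obj, IrrigationMap):
        meta["kind"] = "irrigation"
        meta["water_year"] = obj.water_year_label
        data = obj.label.astype(np.uint8)
        # uint8 product: the out-of-extent sentinel must fit the dtype
        grid_for_tags = replace(obj.grid, nodata=255.0)
        meta["nodata"] = 255.0
        tifffile.imwrite(
            path, data, photometric="minisblack",
            description=json.dumps(meta, sort_keys=True),
            extratags=_geo_extratags(grid_for_tags),
        )
        return path
    elif isinstance(obj, CategoricalMap):
        meta["kind"] = "categorical"
        meta["legend"] = {str(k): v for k, v in obj.legend.items()}
        meta["nodata_code"] = obj.nodata_code
        data = obj.codes.astype(np.int32)
    elif isinstance(obj, ScalarMap):
        meta["kind"] = "scalar"
        meta["units"] = obj.units
        data = obj.values.astype(np.float32)
    else:  # pragma: no cover - defensive
        raise TypeError(f"cannot write object of type {type(obj).__name__}")

    tifffile.imwrite(
        path,
        data,
        photometric="minisblack",
        description=json.dumps(meta, sort_keys=True),
        extratags=_geo_extratags(obj.grid),
    )
    return path


def _parse_description(page) -> dict:
    tag = page.tags.get("ImageDescription")
    if tag is None:
        return {}
    try:
        meta = json.loads(tag.value)
    except (TypeError, ValueError):
        return {}
    return meta if isinstance(meta, dict) else {}


def _grid_from_page(page, shape: tuple[int, int], meta: dict) -> GridSpec:
    scale_tag = page.tags.get(_TAG_MODEL_PIXEL_SCALE)
    tie_tag = page.tags.get(_TAG_MODEL_TIEPOINT)
    if scale_tag is not None and tie_tag is not None:
        ps = float(scale_tag.value[0])
        origin_x = float(tie_tag.value[3])
        origin_y = float(tie_tag.value[4])
    else:
        warnings.warn("no georeferencing tags found; assuming unit grid at origin")
        ps, origin_x, origin_y = 1.0, 0.0, 0.0
    nodata_tag = page.tags.get(_TAG_GDAL_NODATA)
    if nodata_tag is not None:
        nodata = float(nodata_tag.value)
    elif "nodata" in meta:
        nodata = float(meta["nodata"])
    else:
        warnings.warn("raster declares no nodata value; treating all cells as valid")
        nodata = float("nan")
    return GridSpec(
        n_rows=shape[0],
        n_cols=shape[1],
        origin_x=origin_x,
        origin_y=origin_y,
        pixel_size=ps,
        crs_id=meta.get("crs_id", "EPSG:4326"),
        nodata=nodata,
    )


def read_raster(path, band_selection: Sequence[int] | None = None):
    """Read a GeoTIFF written by :func:`write_raster` (or a plain GeoTIFF).

    Files carrying a declared integer ``scale_factor`` (the 16-bit NDVI
    archive convention, 0.0001) are converted to floats on read; nodata
    cells keep the sentinel.  Returns the object kind recorded in the
    file, falling back on dtype/band-count heuristics for foreign files.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with tifffile.TiffFile(path) as tf:
        data = tf.asarray()
        page = tf.pages[0]
        meta = _parse_description(page)
        spatial = data.shape if data.ndim == 2 else data.shape[-2:]
        grid = _grid_from_page(page, spatial, meta)

    kind = meta.get("kind")
    scale = meta.get("scale_factor")
    if scale is not None and np.issubdtype(data.dtype, np.integer):
        valid = data != grid.nodata
        scaled = data.astype(np.float32) * float(scale)
        scaled[~valid] = grid.nodata
        data = scaled

    if kind is None:
        if data.ndim == 3:
            kind = "ndvi_stack"
        elif np.issubdtype(data.dtype, np.integer):
            kind = "categorical"
        else:
            kind = "scalar"

    if kind == "ndvi_stack":
        if data.ndim == 2:
            data = data[None]
        if band_selection is not None:
            band_selection = list(band_selection)
            data = data[band_selection]
        dates_raw = meta.get("dates")
        if dates_raw is None:
            dates = [_dt.date(2000, 6, 1) + _dt.timedelta(days=16 * i) for i in range(data.shape[0])]
        else:
            dates = [_dt.date.fromisoformat(d) for d in dates_raw]
            if band_selection is not None:
                dates = [dates[i] for i in band_selection]
        return NdviStack(grid, data, dates, meta.get("water_year", ""))
    if kind == "irrigation":
        return IrrigationMap(grid, data, meta.get("water_year", ""))
    if kind == "categorical":
        legend = {int(k): v for k, v in meta.get("legend", {}).items()}
        return CategoricalMap(grid, data, legend, int(meta.get("nodata_code", -1)))
    return ScalarMap(grid, data, meta.get("units", ""))


# ---------------------------------------------------------------------------
# Water-year stacking
# ---------------------------------------------------------------------------

def water_year_window(water_year: str) -> tuple[_dt.date, _dt.date]:
    """Inclusive (start, end) dates of a water year labelled '2000-01': June 1 .. May 31."""
    try:
        year = int(water_year.split("-")[0])
    except (ValueError, IndexError) as exc:
        raise ValueError(f"cannot parse water-year label {water_year!r}") from exc
    return _dt.date(year, 6, 1), _dt.date(year + 1, 5, 31)


def build_ndvic(
    composites: Sequence[tuple[ScalarMap, _dt.date | str]],
    water_year: str,
) -> NdviStack:
    """Layer-stack single-date NDVI composites into a water-year NDVIC.

    Only composites whose *start* date falls inside the water-year
    window (June 1 of year Y through May 31 of year Y+1) are kept; they
    are sorted ascending by date.  Values are stacked exactly as given
    — no smoothing is applied.
    """
    if not composites:
        raise ValueError("no composites supplied")
    start, end = water_year_window(water_year)
    parsed: list[tuple[_dt.date, ScalarMap]] = []
    for comp, date in composites:
        if isinstance(date, str):
            date = _dt.date.fromisoformat(date)
        parsed.append((date, comp))

    grid = parsed[0][1].grid
    for date, comp in parsed:
        if not comp.grid.approx_equal(grid):
            raise ValueError(f"composite dated {date} is on a different grid")

    in_window = [(d, c) for d, c in parsed if start <= d <= end]
    if not in_window:
        raise ValueError(f"no composites fall within water year {water_year}")
    dates = [d for d, _ in in_window]
    if len(set(dates)) != len(dates):
        raise ValueError("duplicate composite dates in water-year window")
    in_window.sort(key=lambda item: item[0])

    values = np.stack([c.values for _, c in in_window])
    return NdviStack(grid, values, [d for d, _ in in_window], water_year)


# ---------------------------------------------------------------------------
# Grid alignment
# ---------------------------------------------------------------------------

def _axis_overlaps(
    n_src: int, n_tgt: int, src_size: float, tgt_size: float, offset: float
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Per target index along one axis: overlapping source indices and overlap lengths.

    Source cell i covers [offset + i*src_size, offset + (i+1)*src_size);
    target cell r covers [r*tgt_size, (r+1)*tgt_size), both in the same
    1-D axis coordinate.
    """
    out = []
    for r in range(n_tgt):
        lo = (r * tgt_size - offset) / src_size
        hi = ((r + 1) * tgt_size - offset) / src_size
        i0 = max(int(np.floor(lo + 1e-12)), 0)
        i1 = min(int(np.ceil(hi - 1e-12)), n_src)
        idx, wts = [], []
        for i in range(i0, i1):
            w = (min(hi, i + 1) - max(lo, i)) * src_size
            if w > 1e-12:
                idx.append(i)
                wts.append(w)
        out.append((np.array(idx, dtype=int), np.array(wts)))
    return out


def align_to_grid(src, target: GridSpec, rule: str):
    """Resample a categorical or scalar layer onto a target grid in the same CRS.

    ``rule='majority'``: each target pixel takes the code with the
    largest covered source area (ties broken toward the lowest code).
    ``rule='mean'``: area-weighted mean of covered source cells.  Nodata
    source cells carry no weight; fully-nodata targets get the nodata
    sentinel.  Cross-CRS requests are refused.
    """
    if src.grid.crs_id != target.crs_id:
        raise ValueError(f"CRS mismatch: {src.grid.crs_id} vs {target.crs_id}; reprojection is not supported")
    if rule not in ("majority", "mean"):
        raise ValueError(f"unknown resampling rule {rule!r}")
    if src.grid.approx_equal(target):
        if isinstance(src, CategoricalMap):
            return CategoricalMap(target, src.codes.copy(), dict(src.legend), src.nodata_code)
        return ScalarMap(target, src.values.copy(), src.units)

    g = src.grid
    row_ov = _axis_overlaps(g.n_rows, target.n_rows, g.pixel_size, target.pixel_size, target.origin_y - g.origin_y)
    col_ov = _axis_overlaps(g.n_cols, target.n_cols, g.pixel_size, target.pixel_size, g.origin_x - target.origin_x)
    if all(len(i) == 0 for i, _ in row_ov) or all(len(i) == 0 for i, _ in col_ov):
        raise ValueError("source and target grids do not overlap")

    if isinstance(src, CategoricalMap):
        out = np.full(target.shape, src.nodata_code, dtype=np.int32)
        for r, (ri, rw) in enumerate(row_ov):
            for c, (ci, cw) in enumerate(col_ov):
                if len(ri) == 0 or len(ci) == 0:
                    continue
                block = src.codes[np.ix_(ri, ci)]
                weights = np.outer(rw, cw)
                valid = block != src.nodata_code
                if not valid.any():
                    continue
                codes = block[valid]
                wts = weights[valid]
                order = np.argsort(codes, kind="stable")
                codes, wts = codes[order], wts[order]
                uniq, starts = np.unique(codes, return_index=True)
                sums = np.add.reduceat(wts, starts)
                # lowest code wins ties because uniq is sorted and argmax takes the first max
                out[r, c] = uniq[np.argmax(sums)]
        return CategoricalMap(target, out, dict(src.legend), src.nodata_code)

    out = np.full(target.shape, target.nodata, dtype=np.float64)
    for r, (ri, rw) in enumerate(row_ov):
        for c, (ci, cw) in enumerate(col_ov):
            if len(ri) == 0 or len(ci) == 0:
                continue
            block = src.values[np.ix_(ri, ci)].astype(np.float64)
            weights = np.outer(rw, cw)
            valid = (block != src.grid.nodata) & np.isfinite(block)
            if not valid.any():
                continue
            out[r, c] = np.average(block[valid], weights=weights[valid])
    return ScalarMap(target, out.astype(np.float32), src.units)
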