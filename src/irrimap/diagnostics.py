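"""Post-classification verification, aggregation and validation statistics.

Covers the reporting side of the mapping workflow: space-time spiral
curves (class-mean trajectories in RED-NIR reflectance space used to
check that irrigated and rainfed classes occupy distinct territories),
pixel-count area accounting (one 250 m cell ~ 6.25 ha), RMSE/R^2
validation of mapped areas against survey tables, and first-difference
/ standardized anomaly series for comparing irrigation with rainfall
year to year.

A transcription of the state-wise survey comparison table (DES ground
survey vs the 250 m MODIS product vs the IWMI product, period-mean mha)
ships with the package for validation exercises; see
:func:`load_table3`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd
import shapely

from .masking import MaskLayer
from .raster import IrrigationMap

__all__ = [
    "StscCurve",
    "ValidationResult",
    "AnomalySeries",
    "stsc_curves",
    "curve_separability",
    "aggregate_area",
    "AreaReport",
    "validation_stats",
    "anomaly_series",
    "load_table3",
]

#: Nominal area of one 250 m pixel in hectares.
PIXEL_AREA_HA = 6.25


@dataclass
class StscCurve:
    """Class-mean (RED, NIR) reflectance trajectory over composite dates."""

    class_id: int
    dates: list
    red: np.ndarray
    nir: np.ndarray

    def __post_init__(self) -> None:
        self.red = np.asarray(self.red, dtype=float)
        self.nir = np.asarray(self.nir, dtype=float)
        if not (len(self.dates) == self.red.size == self.nir.size):
            raise ValueError("one (RED, NIR) point per date required")
        for name, v in (("RED", self.red), ("NIR", self.nir)):
            ok = v[np.isfinite(v)]
            if ok.size and (ok.min() < 0 or ok.max() > 1):
                raise ValueError(f"{name} reflectance outside [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"date": self.dates, "class_id": self.class_id, "red": self.red, "nir": self.nir}
        )


@dataclass
class ValidationResult:
    n: int
    rmse: float
    r_squared: float
    residuals: np.ndarray

    def __post_init__(self) -> None:
        if self.rmse < 0 or self.r_squared > 1 + 1e-12:
            raise ValueError("invalid validation statistics")


@dataclass
class AnomalySeries:
    labels: list
    first_differences: np.ndarray
    standardized: np.ndarray


@dataclass
class AreaReport:
    total_ha: float
    total_mha: float
    n_irrigated: int
    polygon_fraction: dict = field(default_factory=dict)


def stsc_curves(
    red_stack: np.ndarray,
    nir_stack: np.ndarray,
    class_map: np.ndarray,
    dates: Sequence,
    class_ids: Sequence[int] | None = None,
    nodata: float = float("nan"),
) -> list[StscCurve]:
    """Space-time spiral curves: per class and date, mean RED and NIR.

    ``red_stack``/``nir_stack`` are (T, H, W) reflectance stacks
    co-registered with the (H, W) class map.  A class with zero pixels
    is an error.
    """
    red = np.asarray(red_stack, dtype=float)
    nir = np.asarray(nir_stack, dtype=float)
    if red.shape != nir.shape or red.ndim != 3:
        raise ValueError("RED and NIR stacks must be (T, rows, cols) and co-registered")
    if red.shape[0] != len(dates):
        raise ValueError("one date per composite required")
    if red.shape[1:] != np.asarray(class_map).shape:
        raise ValueError("class map not co-registered with the stacks")
    if class_ids is None:
        class_ids = [int(c) for c in np.unique(class_map) if c > 0]
    curves = []
    for cid in class_ids:
        sel = class_map == cid
        if not sel.any():
            raise ValueError(f"class {cid} has no pixels")
        r = red[:, sel]
        n = nir[:, sel]
        if not np.isnan(nodata):
            r = np.where(r == nodata, np.nan, r)
            n = np.where(n == nodata, np.nan, n)
        with np.errstate(all="ignore"):
            curves.append(StscCurve(cid, list(dates), np.nanmean(r, axis=1), np.nanmean(n, axis=1)))
    return curves


def curve_separability(a: StscCurve, b: StscCurve) -> float:
    """Mean Euclidean distance between two curves in RED-NIR space across dates."""
    if len(a.dates) != len(b.dates):
        raise ValueError("curves cover different date sets")
    d = np.hypot(a.red - b.red, a.nir - b.nir)
    return float(np.nanmean(d))


def aggregate_area(
    irr: IrrigationMap,
    pixel_area_ha: float = PIXEL_AREA_HA,
    polygons: Sequence[tuple[int | str, "shapely.Geometry"]] | None = None,
    mask: MaskLayer | None = None,
) -> AreaReport:
    """Total irrigated area and optional per-polygon irrigated fractions.

    Total = irrigated pixel count x pixel_area_ha (also reported in
    mha; 1 mha = 1e6 ha).  Per polygon the fraction is irrigated pixels
    over masked agricultural pixels, by the pixel-center rule; a
    polygon with no agricultural pixel gets fraction None.
    """
    n = irr.irrigated_count()
    total_ha = n * pixel_area_ha
    report = AreaReport(total_ha=total_ha, total_mha=total_ha / 1e6, n_irrigated=n)
    if polygons:
        grid = irr.grid
        xs, ys = grid.pixel_centers()
        for name, geom in polygons:
            inside = shapely.contains_xy(geom, xs.ravel(), ys.ravel()).reshape(grid.shape)
            if mask is not None:
                denom = int((inside & mask.include).sum())
            else:
                denom = int(inside.sum())
            if denom == 0:
                report.polygon_fraction[name] = None
                continue
            num = int((inside & (irr.label == 1)).sum())
            report.polygon_fraction[name] = num / denom
    return report


def validation_stats(observed: Sequence[float], predicted: Sequence[float]) -> ValidationResult:
    """RMSE and squared Pearson correlation between paired area estimates.

    R^2 here equals the coefficient of determination of the simple
    linear fit with intercept, the convention used when comparing
    mapped against surveyed areas.
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.ndim != 1 or obs.size < 2:
        raise ValueError("observed and predicted must be equal-length 1-D, n >= 2")
    if not (np.all(np.isfinite(obs)) and np.all(np.isfinite(pred))):
        raise ValueError("non-finite values in validation input")
    if np.ptp(obs) == 0 or np.ptp(pred) == 0:
        raise ValueError("correlation undefined for a constant vector")
    resid = pred - obs
    rmse = float(np.sqrt(np.mean(resid**2)))
    r = float(np.corrcoef(obs, pred)[0, 1])
    return ValidationResult(n=obs.size, rmse=rmse, r_squared=r**2, residuals=resid)


def anomaly_series(values: Sequence[float], labels: Sequence | None = None) -> AnomalySeries:
    """Year-over-year first differences and standardized anomalies.

    Standardization subtracts the series mean and divides by the sample
    (n-1) standard deviation, so the output has mean 0 and unit sd.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 3:
        raise ValueError("need at least 3 yearly values")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("zero standard deviation; anomalies undefined")
    if labels is None:
        labels = list(range(x.size))
    return AnomalySeries(
        labels=list(labels),
        first_differences=np.diff(x),
        standardized=(x - x.mean()) / sd,
    )


def load_table3() -> pd.DataFrame:
    """The packaged state-wise survey comparison table.

    Columns: state, des_mha (ground survey), modis_mha (this method's
    250 m product), iwmi_mha (the IWMI 250 m product); period-mean
    million hectares, one row per state.
    """
    with resources.files("irrimap.data").joinpath("table3_des_modis_iwmi.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t", comment="#")
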