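"""Deterministic synthetic scenes with the structure the method assumes.

The generator emulates the statistical premise of NDVI-based irrigation
mapping: every cropped pixel follows a double-logistic seasonal NDVI
curve with crop-specific sowing and duration, and irrigated pixels of a
crop reach a peak NDVI higher than their rainfed neighbours by a fixed
boost (default 0.2), because irrigation lifts the soil-moisture ceiling
on canopy growth.  Around the cropland it lays down matching
land-cover, slope and zone layers, RED/NIR reflectance stacks
consistent with the emitted NDVI (NDVI = (NIR-RED)/(NIR+RED) holds per
composite), and ground-truth crop and irrigation labels, so a pipeline
run can be scored against a known answer.

Everything is driven by one seeded generator with a fixed draw order,
so a given (config, seed) reproduces the scene bit for bit.  A drought
scenario scales rainfed peaks down and optionally leaves a fraction of
cropland unsown, mimicking the reduced greenness and net cropped area
of deficit years.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .phenology import CropCalendarEntry, CropLookupTable, SEASON_TO_POOL, SeasonWindows, scale_height
from .raster import CategoricalMap, GridSpec, IrrigationMap, NdviStack, ScalarMap, write_raster

__all__ = [
    "CropSpec",
    "SceneConfig",
    "SceneBundle",
    "generate_scene",
    "scenario_drought",
    "write_scene",
    "LULC_LEGEND",
    "AG_CODES",
]

#: Land-cover legend used by generated scenes.
LULC_LEGEND = {1: "Kharif crop", 2: "Rabi crop", 3: "Zaid crop", 4: "forest", 5: "bare"}
AG_CODES = {1, 2, 3}
_SEASON_CODE = {"Kharif": 1, "Rabi": 2, "Zaid": 3}


@dataclass(frozen=True)
class CropSpec:
    """Phenology of one synthetic crop.

    ``sow_idx``/``duration`` are in 16-day composites of the June-May
    water year; ``rainfed_peak`` is the peak NDVI an unirrigated pixel
    attains.  ``irrigated_peak`` defaults to rainfed_peak plus the
    scene's irrigated boost; drought scenarios pin it explicitly so
    groundwater-buffered irrigation keeps its full canopy while rainfed
    peaks drop.
    """

    name: str
    season: str
    sow_idx: int
    duration: int
    rainfed_peak: float
    irrigated_peak: float | None = None

    def peak(self, irrigated: bool, boost: float) -> float:
        if not irrigated:
            return self.rainfed_peak
        return self.irrigated_peak if self.irrigated_peak is not None else self.rainfed_peak + boost

    def __post_init__(self) -> None:
        if self.season not in SEASON_TO_POOL:
            raise ValueError(f"unknown season {self.season!r}")
        if self.duration < 3:
            raise ValueError("crop season must span at least 3 composites")


@dataclass(frozen=True)
class SceneConfig:
    """Study conditions for one synthetic scene."""

    n_rows: int = 64
    n_cols: int = 64
    seed: int = 0
    pixel_size: float = 250.0
    origin_x: float = 500_000.0
    origin_y: float = 2_000_000.0
    crs_id: str = "EPSG:32643"
    n_zones: int = 1
    crops: tuple[CropSpec, ...] = (
        CropSpec("Rice", "Kharif", sow_idx=1, duration=8, rainfed_peak=0.60),
        CropSpec("Wheat", "Rabi", sow_idx=11, duration=7, rainfed_peak=0.55),
    )
    irrigated_boost: float = 0.2
    base_ndvi: float = 0.15
    noise_sd: float = 0.02
    frac_irrigated: float = 0.5
    frac_nonag: float = 0.2
    frac_steep: float = 0.05
    sown_fraction: float = 1.0
    water_year: str = "2000-01"
    n_composites: int = 23

    def __post_init__(self) -> None:
        for frac in (self.frac_irrigated, self.frac_nonag, self.frac_steep, self.sown_fraction):
            if not 0 <= frac <= 1:
                raise ValueError("fractions must lie in [0, 1]")
        for crop in self.crops:
            if not 0 < crop.peak(True, self.irrigated_boost) <= 0.9:
                raise ValueError(
                    f"{crop.name}: irrigated peak {crop.peak(True, self.irrigated_boost)} "
                    "leaves the allowed NDVI range (0, 0.9]"
                )
        if not 0 <= self.base_ndvi < min(c.rainfed_peak for c in self.crops):
            raise ValueError("base NDVI must sit below every crop peak")

    @property
    def grid(self) -> GridSpec:
        return GridSpec(self.n_rows, self.n_cols, self.origin_x, self.origin_y,
                        self.pixel_size, self.crs_id)


@dataclass
class SceneBundle:
    config: SceneConfig
    ndvi: NdviStack
    red: np.ndarray
    nir: np.ndarray
    lulc: CategoricalMap
    slope: ScalarMap
    zones: CategoricalMap
    truth_crop: CategoricalMap
    truth_irrigation: IrrigationMap
    lookup: CropLookupTable
    ag_codes: set[int] = field(default_factory=lambda: set(AG_CODES))


def _season_shape(sow: int, duration: int, n_composites: int) -> np.ndarray:
    """Double-logistic seasonal curve on the composite grid, normalised to max 1."""
    t = np.arange(n_composites, dtype=float)
    rate = 0.6
    up = 1.0 / (1.0 + np.exp(-(t - (sow + 0.8)) / rate))
    down = 1.0 / (1.0 + np.exp(-(t - (sow + duration - 0.8)) / rate))
    shape = up - down
    return shape / shape.max()


def default_lookup(config: SceneConfig, windows: SeasonWindows | None = None) -> CropLookupTable:
    """Lookup table consistent with the generator's crops.

    Height intervals bracket the crop's rainfed-to-irrigated peak range
    with a noise margin; sowing windows and durations are the season
    window itself.  This synthetic table stands in for the
    literature-derived tables a real deployment would supply.
    """
    if windows is None:
        windows = SeasonWindows(n_composites=config.n_composites)
    entries = []
    for zid in range(1, config.n_zones + 1):
        for i, crop in enumerate(config.crops):
            lo, hi = windows.window(SEASON_TO_POOL[crop.season])
            h_rf = scale_height(crop.rainfed_peak)
            h_ir = scale_height(crop.peak(True, config.irrigated_boost))
            entries.append(
                CropCalendarEntry(
                    zone_id=zid,
                    crop_name=crop.name,
                    season=crop.season,
                    priority=i + 1,
                    height_range=(max(1.0, h_rf - 8.0), min(100.0, h_ir + 8.0)),
                    duration_range=(2, config.n_composites),
                    sowing_window=(lo, hi),
                )
            )
    return CropLookupTable(entries)


def generate_scene(config: SceneConfig) -> SceneBundle:
    """Build the full co-registered scene bundle for a config.

    Draw order is fixed (slope, land cover, crop, irrigation, sowing,
    noise), each from the same seeded generator over full-scene arrays,
    so changing a threshold parameter never shifts the random stream.
    """
    rng = np.random.default_rng(config.seed)
    grid = config.grid
    H, W, T = config.n_rows, config.n_cols, config.n_composites

    # terrain: mostly gentle, a seeded fraction too steep to irrigate
    slope_vals = rng.uniform(0.0, 8.0, size=(H, W)).astype(np.float32)
    steep = rng.random((H, W)) < config.frac_steep
    slope_vals[steep] = rng.uniform(25.0, 60.0, size=(H, W)).astype(np.float32)[steep]

    # land cover: cropland vs forest/bare
    u_nonag = rng.random((H, W))
    nonag = u_nonag < config.frac_nonag
    forest = nonag & (u_nonag < config.frac_nonag / 2)
    bare = nonag & ~forest

    crop_idx = rng.integers(0, len(config.crops), size=(H, W))
    u_irr = rng.random((H, W))
    u_sown = rng.random((H, W))
    noise = rng.normal(0.0, 1.0, size=(T, H, W))

    cropped = ~nonag
    sown = cropped & (u_sown < config.sown_fraction)
    irrigable = sown & (slope_vals <= 20.0)
    irrigated = irrigable & (u_irr < config.frac_irrigated)

    lulc_codes = np.full((H, W), 5, dtype=np.int32)
    lulc_codes[forest] = 4
    truth_crop = np.zeros((H, W), dtype=np.int32)
    ndvi = np.full((T, H, W), config.base_ndvi, dtype=float)
    ndvi[:, forest] = 0.65
    red = np.full((H, W), 0.25, dtype=float)
    red[forest] = 0.05

    for ci, crop in enumerate(config.crops):
        members = cropped & (crop_idx == ci)
        lulc_codes[members] = _SEASON_CODE[crop.season]
        grown = members & sown
        truth_crop[grown] = ci + 1
        shape = _season_shape(crop.sow_idx, crop.duration, T)
        for irr_flag, peak in (
            (False, crop.peak(False, config.irrigated_boost)),
            (True, crop.peak(True, config.irrigated_boost)),
        ):
            sel = grown & (irrigated == irr_flag)
            if not sel.any():
                continue
            prof = config.base_ndvi + (peak - config.base_ndvi) * shape
            ndvi[:, sel] = prof[:, None]
            red[sel] = 0.04 if irr_flag else 0.06

    ndvi = np.clip(ndvi + config.noise_sd * noise, -0.95, 0.95)
    # keep NIR representable in [0, 1] for each pixel's fixed RED
    ndvi = np.minimum(ndvi, (1.0 - red) / (1.0 + red) - 1e-3)
    nir = red[None, :, :] * (1.0 + ndvi) / (1.0 - ndvi)
    red_stack = np.broadcast_to(red[None, :, :], (T, H, W)).copy()

    # zones: vertical bands of equal width
    zone_codes = np.ones((H, W), dtype=np.int32)
    if config.n_zones > 1:
        edges = np.linspace(0, W, config.n_zones + 1).astype(int)
        for z in range(config.n_zones):
            zone_codes[:, edges[z]: edges[z + 1]] = z + 1

    dates = [_dt.date(int(config.water_year.split("-")[0]), 6, 1) + _dt.timedelta(days=16 * i)
             for i in range(T)]
    stack = NdviStack(grid, ndvi.astype(np.float32), dates, config.water_year)
    crop_legend = {i + 1: c.name for i, c in enumerate(config.crops)}
    return SceneBundle(
        config=config,
        ndvi=stack,
        red=red_stack.astype(np.float32),
        nir=nir.astype(np.float32),
        lulc=CategoricalMap(grid, lulc_codes, dict(LULC_LEGEND), nodata_code=-1),
        slope=ScalarMap(grid, slope_vals, units="percent"),
        zones=CategoricalMap(grid, zone_codes, nodata_code=-1),
        truth_crop=CategoricalMap(grid, truth_crop, crop_legend, nodata_code=0),
        truth_irrigation=IrrigationMap(grid, irrigated.astype(np.uint8), config.water_year),
        lookup=default_lookup(config),
    )


def scenario_drought(
    config: SceneConfig, deficit: float, reduced_sown_fraction: float = 0.0
) -> SceneBundle:
    """Drought-year scene: rainfed peaks scaled down, optional unsown cropland.

    Rainfed peak NDVI is multiplied by (1 - deficit) while irrigated
    peaks stay at their base-scene value — groundwater-buffered
    irrigation shields the canopy from the deficit — and
    ``reduced_sown_fraction`` of cropland (irrigated and rainfed alike)
    is left fallow, as in deficit years with reduced net sown area.
    ``deficit = 0`` with no sowing reduction reproduces the base scene
    exactly.
    """
    if not 0 <= deficit <= 1:
        raise ValueError("deficit must lie in [0, 1]")
    if not 0 <= reduced_sown_fraction <= 1:
        raise ValueError("reduced_sown_fraction must lie in [0, 1]")
    crops = tuple(
        replace(
            c,
            rainfed_peak=c.rainfed_peak * (1.0 - deficit),
            irrigated_peak=c.peak(True, config.irrigated_boost),
        )
        for c in config.crops
    )
    drought_cfg = replace(
        config,
        crops=crops,
        sown_fraction=config.sown_fraction * (1.0 - reduced_sown_fraction),
    )
    return generate_scene(drought_cfg)


def write_scene(bundle: SceneBundle, out_dir) -> dict[str, Path]:
    """Write every scene layer in the formats the pipeline consumes."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    grid = bundle.config.grid
    dates = bundle.ndvi.composite_start_dates
    wy = bundle.config.water_year
    paths = {
        "ndvi": write_raster(bundle.ndvi, out / "ndvi.tif"),
        "red": write_raster(NdviStack(grid, bundle.red, dates, wy), out / "red.tif"),
        "nir": write_raster(NdviStack(grid, bundle.nir, dates, wy), out / "nir.tif"),
        "lulc": write_raster(bundle.lulc, out / "lulc.tif"),
        "slope": write_raster(bundle.slope, out / "slope.tif"),
        "zones": write_raster(bundle.zones, out / "zones.tif"),
        "truth_crop": write_raster(bundle.truth_crop, out / "truth_crop.tif"),
        "truth_irrigation": write_raster(bundle.truth_irrigation, out / "truth_irrigation.tif"),
        "lookup": bundle.lookup.to_tsv(out / "lookup.tsv"),
    }
    rows, cols = np.nonzero(bundle.truth_crop.codes)
    truth = pd.DataFrame(
        {
            "row": rows,
            "col": cols,
            "crop": [bundle.truth_crop.legend[c] for c in bundle.truth_crop.codes[rows, cols]],
            "irrigated": bundle.truth_irrigation.label[rows, cols],
        }
    )
    truth_path = out / "truth.tsv"
    truth.to_csv(truth_path, sep="\t", index=False)
    paths["truth"] = truth_path
    return paths
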