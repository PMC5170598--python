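"""Declarative run configuration: schema, loading, hashing, execution.

A pipeline run is described by one YAML file (flag overrides allowed on
the command line) so the audit trail — which inputs, which thresholds,
which seed — lives in a single hashable document.  Unknown keys are
rejected.  Every artifact a run writes gets a sidecar JSON carrying the
configuration hash, so outputs can always be traced to the exact
configuration that produced them.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field

from . import irrigation as _irrigation
from .masking import load_zone_polygons
from .phenology import CropLookupTable, SeasonWindows
from .raster import read_raster, write_raster

__all__ = ["PipelineConfig", "load_config", "config_hash", "run_from_config"]


class PipelineConfig(BaseModel):
    """Schema of a pipeline run; all thresholds default to the standard values."""

    model_config = ConfigDict(extra="forbid")

    ndvi: str
    lulc: str
    slope: str
    zones: str
    lookup: str
    water_year: str = ""
    ag_codes: list[int] = Field(default_factory=lambda: [1, 2, 3])
    slope_pct: float = Field(20.0, ge=0, le=100)
    min_irclass: float = Field(0.2, ge=-1, le=1)
    min_separation: float = Field(0.15, ge=0, le=2)
    min_scm: float = Field(0.5, ge=-1, le=1)
    sample_spacing_m: float = Field(4000.0, gt=0)
    min_members: int = Field(3, ge=1)
    n_subpools: int = Field(4, ge=1)
    min_amplitude: float = Field(0.1, ge=0, le=2)
    kharif_window: tuple[int, int] = (0, 9)
    rabi_window: tuple[int, int] = (10, 18)
    zaid_window: tuple[int, int] = (19, 22)
    seed: int = 0
    out_dir: str = "irrimap_out"

    def season_windows(self, n_composites: int) -> SeasonWindows:
        return SeasonWindows(
            fs=tuple(self.kharif_window),
            ss=tuple(self.rabi_window),
            is_=tuple(self.zaid_window),
            n_composites=n_composites,
        )


def load_config(path, overrides: dict | None = None) -> PipelineConfig:
    """Read a YAML config; ``overrides`` (from CLI flags) win over file keys."""
    with open(Path(path)) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError("config file must contain a mapping")
    if overrides:
        data.update({k: v for k, v in overrides.items() if v is not None})
    return PipelineConfig(**data)


def config_hash(cfg: PipelineConfig) -> str:
    canon = json.dumps(cfg.model_dump(), sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _write_sidecar(artifact: Path, cfg_hash: str, extra: dict | None = None) -> None:
    meta = {"config_hash": cfg_hash}
    if extra:
        meta.update(extra)
    artifact.with_suffix(artifact.suffix + ".meta.json").write_text(
        json.dumps(meta, sort_keys=True, indent=1)
    )


def run_from_config(cfg: PipelineConfig) -> "_irrigation.PipelineResult":
    """Load the configured inputs and execute the full pipeline."""
    ndvic = read_raster(cfg.ndvi)
    lulc = read_raster(cfg.lulc)
    slope = read_raster(cfg.slope)
    zones_path = Path(cfg.zones)
    if zones_path.suffix.lower() in (".json", ".geojson"):
        zones = load_zone_polygons(zones_path)
    else:
        zones = read_raster(zones_path)
    lookup = CropLookupTable.from_tsv(cfg.lookup)
    windows = cfg.season_windows(ndvic.n_composites)
    return _irrigation.run_pipeline(
        ndvic,
        lulc,
        slope,
        zones,
        lookup,
        ag_codes=set(cfg.ag_codes),
        slope_threshold_pct=cfg.slope_pct,
        sample_spacing_m=cfg.sample_spacing_m,
        min_members=cfg.min_members,
        min_scm=cfg.min_scm,
        min_irclass=cfg.min_irclass,
        min_separation=cfg.min_separation,
        windows=windows,
        n_subpools=cfg.n_subpools,
        min_amplitude=cfg.min_amplitude,
    )


def write_run_outputs(result, cfg: PipelineConfig) -> dict[str, Path]:
    """Persist a pipeline result (rasters, report, sidecars) under out_dir."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    h = config_hash(cfg)
    paths = {
        "irrigation": write_raster(result.irrigation, out / "irrigation.tif"),
        "crop_classes": write_raster(result.crop_classes, out / "crop_classes.tif"),
    }
    report_path = out / "report.txt"
    report_path.write_text(result.report_text() + "\n")
    paths["report"] = report_path
    legend_path = out / "crop_classes_legend.json"
    legend_path.write_text(json.dumps(
        {str(k): v for k, v in result.crop_classes.legend.items()}, sort_keys=True, indent=1))
    paths["legend"] = legend_path
    for p in paths.values():
        _write_sidecar(p, h)
    cfg_path = out / "config_used.yaml"
    cfg_path.write_text(yaml.safe_dump(cfg.model_dump(), sort_keys=True))
    paths["config"] = cfg_path
    return paths
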