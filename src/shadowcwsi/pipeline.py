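"""End-to-end orchestration: segment, register, warp, CWSI, evaluate.

The mask is built in multispectral space and pulled onto the thermal grid
(never the reverse), so temperatures are read off the sensor grid they were
measured on and only the boolean mask is resampled.  Every stage's
parameters, timings and output checksums go into a JSON run manifest keyed
by the single seed that drives all stochastic components.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cwsi as cwsi_mod
from . import evaluation, raster_io, registration, segmentation
from .errors import ShadowCwsiError, ValidationError

__all__ = ["RunConfig", "PipelineResult", "run", "run_pipeline"]

STAGES = ["segmentation", "registration", "mask_warp",
          "reference_temps", "cwsi", "summaries"]


@dataclass
class RunConfig:
    """File-based pipeline configuration (YAML-mappable)."""

    thermal: str
    ms: str
    out_dir: str
    zones: str | None = None
    swp: str | None = None
    truth_mask: str | None = None       # thermal-grid shadow truth, optional
    ms_bands: list = field(default_factory=lambda: list("123456"))
    match_band: str = "490"
    k: int = 5
    max_iter: int = 200
    seed: int = 0
    ratio: float = 0.8
    bin_width: float = 0.02
    tolerance: float | None = None
    model: str = "similarity"
    upsample: float = 2.0
    p_low: float = 0.5
    p_high: float = 99.5

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)

    def validate(self) -> None:
        for name in ("thermal", "ms", "zones", "swp", "truth_mask"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise ValidationError(f"input {name!r} does not exist: {p}")


@dataclass
class PipelineResult:
    """In-memory outputs of one pipeline run."""

    mask: segmentation.ShadowMask            # multispectral grid
    transform: registration.PlanarTransform
    slope_stats: registration.SlopeStats
    mask_thermal: segmentation.ShadowMask    # warped onto thermal grid
    cwsi_map: cwsi_mod.CwsiMap
    zonal: pd.DataFrame | None
    metrics: dict
    manifest: dict


def _warp_layers(mask: segmentation.ShadowMask,
                 t: registration.PlanarTransform,
                 shape: tuple[int, int]) -> segmentation.ShadowMask:
    canopy, valid = registration.warp_mask(mask.canopy, t, shape)
    internal, _ = registration.warp_mask(mask.internal_shadow, t, shape)
    shadow, _ = registration.warp_mask(mask.shadow, t, shape)
    src_valid, _ = registration.warp_mask(mask.valid, t, shape)
    return segmentation.ShadowMask(
        shadow=shadow, canopy=canopy, internal_shadow=internal & canopy,
        valid=valid & src_valid)


def run(thermal: raster_io.MultibandImage, ms: raster_io.MultibandImage, *,
        zones: np.ndarray | None = None,
        vines: list[raster_io.VineRecord] | None = None,
        truth_mask: np.ndarray | None = None,
        cfg: RunConfig | None = None) -> PipelineResult:
    """Run the full workflow on in-memory rasters.

    ``zones`` and ``truth_mask`` are on the thermal grid.  Stages and their
    parameters are logged to the returned manifest; any stage failure is
    re-raised annotated with the stage name.
    """
    cfg = cfg or RunConfig(thermal="", ms="", out_dir="")
    manifest: dict = {"seed": cfg.seed, "stages": []}
    stage_outputs: dict = {}

    def _stage(name, fn):
        t0 = time.perf_counter()
        try:
            out = fn()
        except Exception as exc:
            manifest["stages"].append(
                {"name": name, "status": "failed", "error": str(exc)})
            raise ShadowCwsiError(f"stage {name!r} failed: {exc}") from exc
        manifest["stages"].append(
            {"name": name, "status": "ok",
             "seconds": round(time.perf_counter() - t0, 3)})
        return out

    mask = _stage("segmentation", lambda: segmentation.
                  build_canopy_internal_shadow_mask(
                      ms, seed=cfg.seed, k=cfg.k, max_iter=cfg.max_iter))

    def _register():
        return registration.register_pair(
            ms.band(cfg.match_band), thermal.band("TIR"),
            ratio=cfg.ratio, bin_width=cfg.bin_width,
            tolerance=cfg.tolerance, model=cfg.model, upsample=cfg.upsample)

    transform, matches, slope_stats = _stage("registration", _register)
    manifest["registration"] = {
        "n_matches": len(matches), "n_inliers": matches.n_inliers,
        "slope_mode": slope_stats.mode, "residual_rms": transform.residual_rms,
        "matrix": transform.matrix.tolist(), "model": transform.model,
    }

    mask_thermal = _stage("mask_warp", lambda: _warp_layers(
        mask, transform, thermal.shape))

    t_wet, t_dry = _stage("reference_temps", lambda: cwsi_mod.
                          extract_reference_temps(
                              thermal, mask_thermal,
                              p_low=cfg.p_low, p_high=cfg.p_high))
    manifest["reference_temps"] = {"t_wet": t_wet, "t_dry": t_dry}

    cwsi_map = _stage("cwsi", lambda: cwsi_mod.compute_cwsi(
        thermal, mask_thermal, t_wet, t_dry))

    def _summaries():
        zonal = None
        metrics: dict = {
            "t_canopy_mean": cwsi_map.t_canopy_mean,
            "t_canopy_sd": cwsi_map.t_canopy_sd,
            "n_clipped": cwsi_map.n_clipped,
        }
        if zones is not None:
            zonal = cwsi_mod.zonal_cwsi(cwsi_map, vines, zones)
            # a per-vine mean needs real support; slivers of a vine zone
            # clipped at the frame edge are not usable observations
            usable = zonal[zonal.n_pixels >= 30].dropna(
                subset=["mean_cwsi", "swp_mpa"])
            if len(usable) >= 3 and usable.mean_cwsi.nunique() > 1:
                reg = evaluation.regress_cwsi_swp(
                    usable.mean_cwsi.to_numpy(), usable.swp_mpa.to_numpy())
                metrics["cwsi_swp"] = asdict(reg)
        if truth_mask is not None:
            cm = evaluation.confusion_matrix(
                truth_mask, mask_thermal.shadow, valid=mask_thermal.valid)
            metrics["shadow_confusion"] = cm.counts.tolist()
            metrics["shadow_precision"] = evaluation.shadow_precision(cm)
            metrics["cohens_kappa"] = evaluation.cohens_kappa(cm)
        return zonal, metrics

    zonal, metrics = _stage("summaries", _summaries)
    manifest["metrics"] = _jsonable(metrics)
    return PipelineResult(mask=mask, transform=transform,
                          slope_stats=slope_stats,
                          mask_thermal=mask_thermal, cwsi_map=cwsi_map,
                          zonal=zonal, metrics=metrics, manifest=manifest)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(cfg: RunConfig) -> dict:
    """File-based wrapper: read inputs, run, write stage outputs + manifest."""
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    thermal = raster_io.read_image(cfg.thermal, band_labels=["TIR"])
    ms = raster_io.read_image(cfg.ms, band_labels=cfg.ms_bands)
    zones = None
    if cfg.zones:
        zones = raster_io.read_image(cfg.zones).pixels[:, :, 0]
    vines = raster_io.read_vine_table(cfg.swp) if cfg.swp else None
    truth = raster_io.read_mask(cfg.truth_mask) if cfg.truth_mask else None

    result = run(thermal, ms, zones=zones, vines=vines, truth_mask=truth,
                 cfg=cfg)

    raster_io.write_mask(result.mask.shadow, out / "mask.tif")
    raster_io.write_mask(result.mask.internal_shadow,
                         out / "mask_internal.tif")
    raster_io.write_mask(result.mask_thermal.sunlit_canopy,
                         out / "mask_warped.tif")
    raster_io.write_mask(result.mask_thermal.shadow,
                         out / "shadow_warped.tif")
    raster_io.write_image(raster_io.MultibandImage(
        result.cwsi_map.cwsi.astype(np.float32), ["CWSI"]),
        out / "cwsi.tif")
    with open(out / "transform.json", "w") as fh:
        json.dump({"model": result.transform.model,
                   "matrix": result.transform.matrix.tolist(),
                   "residual_rms": result.transform.residual_rms}, fh,
                  indent=2)
    if result.zonal is not None:
        result.zonal.to_csv(out / "zonal.csv", index=False)
    with open(out / "metrics.json", "w") as fh:
        json.dump(_jsonable(result.metrics), fh, indent=2)

    manifest = result.manifest
    manifest["config"] = {k: v for k, v in asdict(cfg).items()}
    manifest["outputs"] = {
        p.name: _checksum(p) for p in sorted(out.iterdir())
        if p.name != "manifest.json"
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(_jsonable(manifest), fh, indent=2)
    return manifest
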