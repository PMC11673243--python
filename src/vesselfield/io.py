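"""File formats and the end-to-end pipeline runner.

Volumes travel as NIfTI (spacing in the affine/zooms), projections as
float32 multi-page TIFF with a JSON geometry sidecar, configuration as
YAML, and every run writes a manifest (config hash, seed, package version)
so it can be reproduced from disk alone.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field as dc_field, replace
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import tifffile
import yaml

from . import __version__
from .field import FieldConfig
from .geometry import (
    ConeBeamGeometry,
    DetectorSpec,
    VolumeSpec,
    load_geometry_sidecar,
    save_geometry_sidecar,
)
from .hash_encoder import HashEncoderConfig
from .metrics import MetricsReport, evaluate
from .phantom import simulate_case
from .projector import Projection
from .reconstruct import OptimizationConfig, optimize

__all__ = [
    "read_volume",
    "write_volume",
    "read_projections",
    "write_projections",
    "RunConfig",
    "load_run_config",
    "run_pipeline",
]


def write_volume(grid: np.ndarray, spec: VolumeSpec, path: str | Path) -> None:
    """Write a volume as NIfTI with voxel spacing in the header."""
    affine = np.diag(list(spec.spacing) + [1.0])
    grid = np.asarray(grid)
    if grid.shape != tuple(spec.size):
        raise ValueError(f"grid shape {grid.shape} != volume size {spec.size}")
    dtype = np.uint8 if grid.dtype == np.uint8 or grid.dtype == bool else np.float32
    img = nib.Nifti1Image(grid.astype(dtype), affine)
    img.header.set_zooms(spec.spacing)
    nib.save(img, str(path))


def read_volume(path: str | Path) -> tuple[np.ndarray, VolumeSpec]:
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"volume file not found: {p}")
    try:
        img = nib.load(str(p))
    except Exception as exc:  # pragma: no cover - nibabel error text varies
        raise IOError(f"could not read NIfTI volume {p}: {exc}") from exc
    data = np.asarray(img.dataobj)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return data, VolumeSpec(tuple(data.shape), spacing)


def write_projections(
    projections: list[Projection], tiff_path: str | Path, sidecar_path: str | Path
) -> None:
    """Float32 multi-page TIFF (one page per view) + JSON geometry sidecar."""
    stack = np.stack([p.image for p in projections]).astype(np.float32)
    tifffile.imwrite(str(tiff_path), stack)
    save_geometry_sidecar(
        sidecar_path, [p.geometry for p in projections], projections[0].volume_ref
    )


def read_projections(
    tiff_path: str | Path, sidecar_path: str | Path
) -> list[Projection]:
    p = Path(tiff_path)
    if not p.exists():
        raise FileNotFoundError(f"projection file not found: {p}")
    stack = tifffile.imread(str(p))
    if stack.ndim == 2:
        stack = stack[None]
    geoms, vol = load_geometry_sidecar(sidecar_path)
    if len(geoms) != stack.shape[0]:
        raise ValueError(
            f"{stack.shape[0]} TIFF pages but {len(geoms)} geometries in sidecar"
        )
    return [Projection(img, g, vol) for img, g in zip(stack, geoms)]


_KNOWN_SECTIONS = {
    "seed",
    "style",
    "views",
    "scale",
    "out_dir",
    "volume",
    "detector",
    "encoder",
    "field",
    "optimization",
    "projector",
    "paths",
}


@dataclass
class RunConfig:
    """Merged configuration of one end-to-end run."""

    seed: int = 0
    style: str = "LAD"
    views: str = "clinical"
    scale: str = "test"
    out_dir: str = "run_output"
    volume: VolumeSpec | None = None
    detector: DetectorSpec | None = None
    encoder: HashEncoderConfig | None = None
    field: FieldConfig | None = None
    optimization: OptimizationConfig | None = None
    projector_step: float | None = None
    paths: dict = dc_field(default_factory=dict)

    def resolved(self) -> "RunConfig":
        """Fill unset sections from the named scale profile."""
        from .profiles import get_profile

        prof = get_profile(self.scale, seed=self.seed)
        return replace(
            self,
            volume=self.volume or prof.vol,
            detector=self.detector or prof.detector,
            encoder=self.encoder or prof.encoder,
            field=self.field or prof.field,
            optimization=self.optimization or prof.with_seed(self.seed).optimization,
        )


def load_run_config(path: str | Path) -> RunConfig:
    """Parse a YAML run configuration; unknown keys are rejected."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    unknown = set(raw) - _KNOWN_SECTIONS
    if unknown:
        raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
    kwargs: dict = {
        k: raw[k] for k in ("seed", "style", "views", "scale", "out_dir") if k in raw
    }
    if "volume" in raw:
        v = raw["volume"]
        kwargs["volume"] = VolumeSpec(tuple(v["size"]), tuple(v["spacing_mm"]))
    if "detector" in raw:
        d = raw["detector"]
        kwargs["detector"] = DetectorSpec(tuple(d["size"]), tuple(d["pixel_spacing_mm"]))
    if "encoder" in raw:
        kwargs["encoder"] = HashEncoderConfig(**raw["encoder"])
    if "field" in raw:
        kwargs["field"] = FieldConfig(**raw["field"])
    if "optimization" in raw:
        kwargs["optimization"] = OptimizationConfig(**raw["optimization"])
    if "projector" in raw:
        kwargs["projector_step"] = raw["projector"].get("step_mm")
    if "paths" in raw:
        kwargs["paths"] = dict(raw["paths"])
    return RunConfig(**kwargs)


def _config_hash(cfg: RunConfig) -> str:
    blob = json.dumps(
        {
            "seed": cfg.seed,
            "style": cfg.style,
            "views": cfg.views,
            "scale": cfg.scale,
            "volume": [cfg.volume.size, cfg.volume.spacing],
            "detector": [cfg.detector.size, cfg.detector.pixel_spacing],
            "encoder": asdict(cfg.encoder),
            "field": asdict(cfg.field),
            "optimization": asdict(cfg.optimization),
            "projector_step": cfg.projector_step,
        },
        sort_keys=True,
        default=str,
    )
    return hashlib.sha256(blob.encode()).hexdigest()


def _metric_history_frame(history) -> pd.DataFrame:
    rows = []
    for iteration, report in history:
        row = {"iteration": iteration}
        row.update(report.as_dict())
        rows.append(row)
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> dict:
    """simulate (optional) -> reconstruct -> evaluate (optional).

    Writes all artifacts plus a manifest under ``config.out_dir`` and
    returns a summary dict.  On failure the manifest records the failed
    stage before the exception propagates.
    """
    cfg = config.resolved()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "package_version": __version__,
        "seed": cfg.seed,
        "config_hash": _config_hash(cfg),
        "scale": cfg.scale,
        "style": cfg.style,
        "views": cfg.views,
        "status": "running",
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))

    try:
        ground_truth = None
        if cfg.paths.get("projections"):
            projections = read_projections(
                cfg.paths["projections"], cfg.paths["geometry"]
            )
            vol = projections[0].volume_ref
            if cfg.paths.get("ground_truth"):
                ground_truth, _ = read_volume(cfg.paths["ground_truth"])
        else:
            case = simulate_case(
                cfg.style,
                cfg.seed,
                vol=cfg.volume,
                views=cfg.views,
                detector=cfg.detector,
                projector_step=cfg.projector_step,
            )
            projections = case.projections
            ground_truth = case.ground_truth
            vol = case.vol
            write_volume(ground_truth, vol, out / "ground_truth.nii.gz")
            write_projections(
                projections, out / "projections.tif", out / "geometry.json"
            )

        result = optimize(
            projections,
            cfg.optimization,
            cfg.encoder,
            vol,
            field_cfg=cfg.field,
            ground_truth=ground_truth,
            projector_step=cfg.projector_step,
        )

        write_volume(result.occupancy.values, vol, out / "occupancy.nii.gz")
        write_volume(result.binary, vol, out / "reconstruction.nii.gz")
        pd.DataFrame(
            {"iteration": np.arange(1, len(result.loss_history) + 1),
             "loss": result.loss_history}
        ).to_csv(out / "loss_history.csv", index=False)

        summary: dict = {"final_loss": float(result.loss_history[-1])}
        if ground_truth is not None:
            report = evaluate(result.binary, ground_truth, vol.spacing)
            summary["metrics"] = report.as_dict()
            pd.DataFrame([report.as_dict()]).to_csv(out / "metrics.csv", index=False)
            if result.metric_history:
                _metric_history_frame(result.metric_history).to_csv(
                    out / "metric_history.csv", index=False
                )
        np.savez(
            out / "checkpoint.npz",
            tables=result.tables.values,
            **{
                f"layer{i}_{nm}": arr
                for i, (w, b) in enumerate(result.weights.layers, start=1)
                for nm, arr in (("W", w), ("b", b))
            },
        )
        manifest["status"] = "ok"
        manifest["summary"] = summary
        manifest_path.write_text(json.dumps(manifest, indent=2))
        return summary
    except Exception as exc:
        manifest["status"] = "failed"
        manifest["error"] = str(exc)
        manifest_path.write_text(json.dumps(manifest, indent=2))
        raise
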