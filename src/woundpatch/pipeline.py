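"""End-to-end workflow orchestration with file-based resume and a manifest.

Stages (phantom -> segment -> design -> slice -> gauge -> conform)
communicate exclusively through files in the run directory, so deleting one
stage's outputs and re-running recomputes only that stage.  A manifest
records parameters, seeds, per-stage wall time and SHA-256 checksums of
every artifact.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np

from . import __version__
from .conformality import contact_percentage, detect_voids
from .core import BinaryMask, VoxelVolume
from .gauging import gauge_meshes
from .io_formats import read_stl, read_volume, write_gcode, write_stl, write_volume
from .patch_design import ShellParams, design_patch, mask_to_mesh, mesh_to_mask
from .phantoms import (PlacedPatchSpec, WoundPhantomSpec, crater_roi,
                       make_limb_wound_phantom, make_placed_patch_phantom)
from .segmentation import invert_wound, threshold_volume
from .toolpath import PrintSettings, RegionModifier, generate_toolpath, plan_gcode

log = logging.getLogger("woundpatch")


class PipelineConfigError(ValueError):
    """Raised when the pipeline configuration is invalid, listing offending keys."""


_KNOWN_SECTIONS = {"run_dir", "seed", "phantom", "segment", "design", "slice",
                   "gauge", "conform"}


def default_config() -> dict:
    return {
        "run_dir": "woundpatch_run",
        "seed": 0,
        "phantom": {"preset": "hemisphere", "spec": {}},
        "segment": {"mode": "otsu", "roi": "auto"},
        "design": {"thickness": 4.0, "smooth_window": 3, "trim_margin": 0.0},
        "slice": {"settings": {}, "modifiers": []},
        "gauge": {"samples": 20000, "perturb_deg": 5.0,
                  "perturb_translation": [2.0, 1.0, 0.0]},
        "conform": {"min_void": 0.001, "erode_mm": 1.0},
    }


def validate_config(config: dict) -> dict:
    merged = default_config()
    bad = [k for k in config if k not in _KNOWN_SECTIONS]
    if bad:
        raise PipelineConfigError(f"unknown configuration keys: {sorted(bad)}")
    for key, value in config.items():
        if isinstance(value, dict):
            merged[key].update(value)
        else:
            merged[key] = value
    return merged


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _phantom_spec(cfg: dict, seed: int) -> WoundPhantomSpec:
    preset = cfg.get("preset", "hemisphere")
    overrides = dict(cfg.get("spec", {}))
    overrides.setdefault("seed", seed)
    if preset == "hemisphere":
        known = {f.name for f in dataclasses.fields(WoundPhantomSpec)}
        extra = {k: v for k, v in overrides.items()
                 if k in {"depth", "spacing", "noise_sd", "seed"}}
        rest = {k: v for k, v in overrides.items() if k not in extra and k in known}
        return WoundPhantomSpec.hemisphere(**extra, **rest)
    if preset == "default":
        return WoundPhantomSpec(**overrides)
    raise PipelineConfigError(f"unknown phantom preset {preset!r}")


def run_pipeline(config: dict, resume: bool = True) -> Path:
    """Run the full workflow; returns the run directory."""
    cfg = validate_config(config or {})
    run_dir = Path(cfg["run_dir"])
    run_dir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    manifest_path = run_dir / "manifest.json"
    manifest = {"version": __version__, "seed": seed, "config": _jsonable(cfg),
                "stages": {}}

    spec = _phantom_spec(cfg["phantom"], seed)

    stages = [
        ("phantom", [run_dir / "phantom.nii", run_dir / "wound_surface.stl",
                     run_dir / "phantom.json"], _stage_phantom),
        ("segment", [run_dir / "cavity_mask.nii", run_dir / "tissue_mask.nii"],
         _stage_segment),
        ("design", [run_dir / "patch.stl", run_dir / "patch_mask.nii"], _stage_design),
        ("slice", [run_dir / "patch.gcode", run_dir / "print_estimate.json"],
         _stage_slice),
        ("gauge", [run_dir / "gauge.json", run_dir / "gauge_histogram.csv",
                   run_dir / "gauge_distances.csv"], _stage_gauge),
        ("conform", [run_dir / "implanted.nii", run_dir / "conform.json"],
         _stage_conform),
    ]
    ctx = {"cfg": cfg, "spec": spec, "run_dir": run_dir, "seed": seed}
    for name, outputs, fn in stages:
        entry = {"outputs": {}}
        if resume and all(p.exists() for p in outputs):
            log.info("stage %s: outputs exist, skipping", name)
            entry["skipped"] = True
        else:
            t0 = time.perf_counter()
            log.info("stage %s: running", name)
            fn(ctx)
            entry["skipped"] = False
            entry["wall_time_s"] = round(time.perf_counter() - t0, 3)
            log.info("stage %s: done in %.1f s", name, entry["wall_time_s"])
        for p in outputs:
            entry["outputs"][p.name] = _sha256(p)
        manifest["stages"][name] = entry
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return run_dir


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def _stage_phantom(ctx) -> None:
    run_dir, spec = ctx["run_dir"], ctx["spec"]
    vol, surface = make_limb_wound_phantom(spec)
    write_volume(vol, run_dir / "phantom.nii")
    write_stl(surface, run_dir / "wound_surface.stl")
    (run_dir / "phantom.json").write_text(json.dumps(
        {"spec": _jsonable(dataclasses.asdict(spec))}, indent=2))


def _stage_segment(ctx) -> None:
    run_dir, cfg, spec = ctx["run_dir"], ctx["cfg"]["segment"], ctx["spec"]
    vol = read_volume(run_dir / "phantom.nii")
    air = threshold_volume(vol, mode=cfg.get("mode", "otsu"), value=cfg.get("value"))
    tissue = air.with_data(~air.data, label="tissue")
    roi = cfg.get("roi", "auto")
    roi = crater_roi(spec) if (isinstance(roi, str) and roi == "auto") else np.asarray(roi)
    cavity = invert_wound(tissue, roi)
    write_volume(_as_u8(cavity), run_dir / "cavity_mask.nii")
    write_volume(_as_u8(tissue), run_dir / "tissue_mask.nii")


def _as_u8(mask: BinaryMask) -> VoxelVolume:
    return VoxelVolume(mask.data.astype(np.uint8), mask.spacing, mask.origin)


def _read_mask(path: Path, label: str) -> BinaryMask:
    vol = read_volume(path)
    return BinaryMask(vol.data > 0, vol.spacing, vol.origin, label=label)


def _stage_design(ctx) -> None:
    run_dir, cfg = ctx["run_dir"], ctx["cfg"]["design"]
    cavity = _read_mask(run_dir / "cavity_mask.nii", "inverted")
    tissue = _read_mask(run_dir / "tissue_mask.nii", "tissue")
    params = ShellParams(thickness=float(cfg.get("thickness", 4.0)),
                         smooth_window=int(cfg.get("smooth_window", 3)),
                         trim_margin=float(cfg.get("trim_margin", 0.0)))
    shell, mesh = design_patch(cavity, tissue, params)
    write_volume(_as_u8(shell), run_dir / "patch_mask.nii")
    write_stl(mesh, run_dir / "patch.stl")


def _stage_slice(ctx) -> None:
    run_dir, cfg = ctx["run_dir"], ctx["cfg"]["slice"]
    mesh = read_stl(run_dir / "patch.stl")
    settings = PrintSettings(**cfg.get("settings", {}))
    modifiers = [RegionModifier(**m) for m in cfg.get("modifiers", [])]
    toolpath = generate_toolpath(mesh, settings, modifiers)
    program, estimate = plan_gcode(toolpath, settings)
    write_gcode(program, run_dir / "patch.gcode")
    (run_dir / "print_estimate.json").write_text(
        json.dumps(estimate.to_dict(), indent=2))


def _stage_gauge(ctx) -> None:
    run_dir, cfg, seed = ctx["run_dir"], ctx["cfg"]["gauge"], ctx["seed"]
    from scipy.spatial.transform import Rotation

    mesh = read_stl(run_dir / "patch.stl")
    angle = float(cfg.get("perturb_deg", 5.0))
    translation = np.asarray(cfg.get("perturb_translation", [2.0, 1.0, 0.0]), float)
    rot = Rotation.from_rotvec(np.deg2rad(angle) * np.array([0, 0, 1.0])).as_matrix()
    center = mesh.vertices.mean(axis=0)
    perturbed = dataclasses.replace(
        mesh, vertices=(mesh.vertices - center) @ rot.T + center + translation,
        provenance=mesh.provenance + "|perturbed")
    report, transform = gauge_meshes(perturbed, mesh,
                                     n_samples=int(cfg.get("samples", 20000)),
                                     seed=seed)
    (run_dir / "gauge.json").write_text(json.dumps({
        "applied_perturbation": {"rotation_deg": angle,
                                 "translation_mm": translation.tolist()},
        "recovered_rotation": transform.rotation.tolist(),
        "recovered_translation_mm": transform.translation.tolist(),
        **report.to_dict(),
    }, indent=2, default=float))
    with open(run_dir / "gauge_histogram.csv", "w") as fh:
        fh.write("bin_start_mm,count\n")
        for edge, count in zip(report.histogram_edges[:-1], report.histogram_counts):
            fh.write(f"{edge:.1f},{count}\n")
    np.savetxt(run_dir / "gauge_distances.csv", report.distances, fmt="%.6f",
               header="distance_mm", comments="")


def _stage_conform(ctx) -> None:
    run_dir, cfg = ctx["run_dir"], ctx["cfg"]["conform"]
    vol = read_volume(run_dir / "phantom.nii")
    tissue = _read_mask(run_dir / "tissue_mask.nii", "tissue")
    patch_mesh = read_stl(run_dir / "patch.stl")
    placed_spec = PlacedPatchSpec()
    implanted, _ = make_placed_patch_phantom(vol, patch_mesh, placed_spec)
    write_volume(implanted, run_dir / "implanted.nii")
    patch_mask = mesh_to_mask(patch_mesh, vol)
    voids = detect_voids(implanted, tissue, patch_mask,
                         min_void=float(cfg.get("min_void", 0.001)))
    wound_mesh = mask_to_mesh(tissue)
    report = contact_percentage(patch_mesh, wound_mesh, footprint=patch_mask,
                                erode_mm=float(cfg.get("erode_mm", 1.0)),
                                void_set=voids)
    (run_dir / "conform.json").write_text(json.dumps(report.to_dict(), indent=2))
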