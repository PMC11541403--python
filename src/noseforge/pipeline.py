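"""One-command orchestration: scan + model -> nose -> prosthesis -> mold.

Runs erase -> align -> fit -> crop -> design steps 1-11 -> export, writing
every stage product as a standalone file plus a reproducible run manifest
(input hashes, config snapshot, per-stage timings, output hashes).
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np

from . import design as dz
from . import fitting as ft
from . import shape_model as sm
from .mesh_core import LandmarkSet, RegionMask, read_mesh, write_mesh

__all__ = ["RunManifest", "PipelineError", "run_full_pipeline", "load_config"]


class PipelineError(RuntimeError):
    """A stage failure, annotated with the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunManifest:
    inputs: dict = field(default_factory=dict)      # path -> sha256
    config: dict = field(default_factory=dict)
    timings: dict = field(default_factory=dict)     # stage -> seconds
    outputs: dict = field(default_factory=dict)     # path -> sha256
    seed: int | None = None

    def write(self, path) -> None:
        with open(path, "w") as f:
            json.dump(asdict(self), f, indent=1, sort_keys=True)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def load_config(path=None) -> dict:
    """Flat key: value YAML config; keys are FitConfig/DesignParams fields."""
    if path is None:
        return {}
    import yaml

    with open(path) as f:
        data = yaml.safe_load(f) or {}
    if not isinstance(data, dict):
        raise ValueError("config must be a flat mapping of key: value pairs")
    return data


def _split_config(data: dict):
    fit_keys = {f.name for f in fields(ft.FitConfig)}
    design_keys = {f.name for f in fields(dz.DesignParams)}
    fit_kwargs = {k: v for k, v in data.items() if k in fit_keys}
    design_kwargs = {k: v for k, v in data.items() if k in design_keys}
    known = fit_keys | design_keys | {"seed"}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return ft.FitConfig(**fit_kwargs), dz.DesignParams(**design_kwargs)


def load_nostrils(path=None) -> dz.NostrilSpec:
    if path is None:
        return dz.NostrilSpec()
    with open(path) as f:
        data = json.load(f)
    items = data.get("nostrils", [])
    if not items:
        return dz.NostrilSpec()
    return dz.NostrilSpec(
        entries=np.array([it["entry"] for it in items], dtype=float),
        axes=np.array([it["axis"] for it in items], dtype=float),
        radii=np.array([it["radius"] for it in items], dtype=float),
        depths=np.array([it["depth"] for it in items], dtype=float),
    )


def run_full_pipeline(
    scan,
    landmarks,
    model,
    out_dir,
    defect_mask=None,
    config=None,
    nostrils=None,
    seed: int = 0,
) -> tuple[dz.MoldAssembly, RunManifest]:
    """Execute the complete design workflow from files to mold STLs.

    Partial outputs are preserved on failure; errors name the failing stage.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(seed=seed)

    # validate inputs up front so trivial mistakes fail before any compute
    input_paths = {"scan": scan, "landmarks": landmarks, "model": model}
    if defect_mask is not None:
        input_paths["defect_mask"] = defect_mask
    if config is not None:
        input_paths["config"] = config
    if nostrils is not None:
        input_paths["nostrils"] = nostrils
    for name, p in input_paths.items():
        if not Path(p).is_file():
            raise FileNotFoundError(f"{name} file not found: {p}")
        manifest.inputs[str(p)] = _sha256(p)

    cfg = load_config(config)
    manifest.config = dict(cfg)
    fit_config, params = _split_config(cfg)
    nostril_spec = load_nostrils(nostrils)

    def stage(name, fn, *args, **kwargs):
        t0 = time.perf_counter()
        try:
            result = fn(*args, **kwargs)
        except Exception as exc:  # noqa: BLE001 - re-raised with stage context
            manifest.timings[name] = round(time.perf_counter() - t0, 3)
            manifest.write(out_dir / "manifest.json")
            raise PipelineError(name, exc) from exc
        manifest.timings[name] = round(time.perf_counter() - t0, 3)
        return result

    mfm = stage("load_model", sm.load_model, model)
    fm = stage("read_scan", read_mesh, scan)
    fm_landmarks = stage("read_landmarks", LandmarkSet.from_json, landmarks)

    if defect_mask is not None:
        mask = RegionMask.from_json(defect_mask)
        fm = stage("erase_defect", ft.erase_region, fm, mask)

    model_landmarks = LandmarkSet(mfm.landmark_points())
    transform = stage("align", ft.rigid_align, model_landmarks, fm_landmarks)
    fit_result = stage("fit", ft.fit_model, mfm, fm, fit_config, transform)

    def emit(name, mesh):
        path = out_dir / name
        write_mesh(mesh, path)
        manifest.outputs[str(path)] = _sha256(path)
        return path

    emit("fitted_face.ply", fit_result.fitted_mesh)
    with open(out_dir / "fit_log.json", "w") as f:
        json.dump({"residual_trace_mm": fit_result.residual_trace,
                   "n_correspondences": fit_result.n_correspondences,
                   "coefficients": list(fit_result.coefficients.values)}, f, indent=1)

    if mfm.nose_vertex_ids is None:
        raise PipelineError("crop_nose", ValueError("model archive has no nose region"))
    nose_mask = RegionMask.from_indices(mfm.n_vertices, mfm.nose_vertex_ids)
    nm = stage("crop_nose", ft.crop_nose, fit_result.fitted_mesh, nose_mask)
    emit("nm.ply", nm)

    nm_blend = stage("blend_border", dz.blend_border, nm, fm, params)
    pm = stage("build_prosthesis", dz.build_prosthesis_solid, nm_blend, fm, params)
    if len(nostril_spec):
        pm = stage("sculpt_nostrils", dz.sculpt_nostrils, pm, nostril_spec, params)
    emit("pm.ply", pm)

    assembly = stage("generate_mold", dz.generate_mold, pm, params)
    paths = stage("export_mold", dz.export_mold, assembly, out_dir)
    for p in paths:
        manifest.outputs[str(p)] = _sha256(p)

    manifest.write(out_dir / "manifest.json")
    return assembly, manifest
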