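"""Run configuration: YAML scenes and acquisition settings.

Internally every length is nanometres; user-facing YAML lengths must carry a
unit suffix (``nm``, ``um``/``µm``, ``mm``) and unit-less lengths are
rejected.  Unknown keys are rejected with a message listing them, so typos
fail loudly.  A run is reproducible from its persisted config plus seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .camera import CameraConfig
from .microscope import VirtualMicroscope
from .optics import OPTICS_PRESETS, OpticsConfig, get_optics_preset
from .specimen import (
    Disk,
    EdgeTarget,
    FlatTarget,
    GridTarget,
    SpecimenField,
    blood_smear_field,
    flat_field,
    grid_field,
    knife_edge_field,
)
from .stage import StageState
from .units import format_length_nm, parse_length_nm

_SCENE_KEYS = {
    "preset", "extent", "angle_deg", "pitch", "line_width", "intensity",
    "cell_density_per_mm2", "scene_seed", "focal_surface", "primitives", "background",
}
_OPTICS_KEYS = {
    "preset", "numerical_aperture", "wavelength", "psf_fwhm", "pixel_pitch",
    "defocus_blur_coeff", "vignetting_falloff", "distortion_k", "edge_model",
}
_CAMERA_KEYS = {
    "sensor_px", "read_noise_sigma", "shot_noise_scale", "bayer", "mono",
    "compression_quality", "frame_rate_hz",
}
_STAGE_KEYS = {"step_size", "travel", "backlash_steps", "drift_rate_nm_per_hour"}
_SCAN_KEYS = {"grid", "zstack", "dz", "overlap", "autofocus", "af_range", "af_points", "af_speed_nm_per_s"}
_TIMELAPSE_KEYS = {"n_frames", "interval_s", "autofocus"}
_TOP_KEYS = {"seed", "output_dir", "scene", "optics", "camera", "stage", "scan", "timelapse"}


class ConfigError(ValueError):
    pass


def _check_keys(section: dict, allowed: set, where: str) -> None:
    unknown = sorted(set(section) - allowed)
    if unknown:
        raise ConfigError(f"unknown keys in {where}: {unknown}")


@dataclass(frozen=True)
class RunConfig:
    seed: int = 0
    output_dir: str = "simscope-out"
    scene: dict = field(default_factory=lambda: {"preset": "blood-smear"})
    optics: dict = field(default_factory=dict)
    camera: dict = field(default_factory=dict)
    stage: dict = field(default_factory=dict)
    scan: dict | None = None
    timelapse: dict | None = None


def _norm_length(raw, where: str) -> float:
    try:
        return parse_length_nm(raw)
    except ValueError as exc:
        raise ConfigError(f"{where}: {exc}") from None


def _norm_scene(raw: dict) -> dict:
    _check_keys(raw, _SCENE_KEYS, "scene")
    out = dict(raw)
    if "extent" in out:
        ext = out.pop("extent")
        if not isinstance(ext, (list, tuple)):
            ext = [ext, ext]
        out["extent_nm"] = [_norm_length(e, "scene.extent") for e in ext]
    if "pitch" in out:
        out["pitch_nm"] = _norm_length(out.pop("pitch"), "scene.pitch")
    if "line_width" in out:
        out["line_width_nm"] = _norm_length(out.pop("line_width"), "scene.line_width")
    if "focal_surface" in out:
        fs = out["focal_surface"]
        _check_keys(fs, {"a", "b", "c"}, "scene.focal_surface")
        out["focal_surface"] = {
            "a": float(fs.get("a", 0.0)),
            "b": float(fs.get("b", 0.0)),
            "c": _norm_length(fs.get("c", "0nm"), "scene.focal_surface.c"),
        }
    if "primitives" in out:
        prims = []
        for p in out["primitives"]:
            p = dict(p)
            kind = p.pop("type", None)
            if kind == "disk":
                prims.append(
                    {
                        "type": "disk",
                        "centre_nm": [_norm_length(c, "primitive.centre") for c in p.pop("centre")],
                        "radius_nm": _norm_length(p.pop("radius"), "primitive.radius"),
                        **p,
                    }
                )
            elif kind == "edge":
                out_p = {"type": "edge"}
                if "offset" in p:
                    out_p["offset_nm"] = _norm_length(p.pop("offset"), "primitive.offset")
                out_p.update(p)
                prims.append(out_p)
            else:
                raise ConfigError(f"unknown primitive type {kind!r}")
        out["primitives"] = prims
    return out


def _norm_optics(raw: dict) -> dict:
    _check_keys(raw, _OPTICS_KEYS, "optics")
    out = dict(raw)
    for key in ("wavelength", "psf_fwhm", "pixel_pitch"):
        if key in out:
            out[key + "_nm"] = _norm_length(out.pop(key), f"optics.{key}")
    return out


def _norm_stage(raw: dict) -> dict:
    _check_keys(raw, _STAGE_KEYS, "stage")
    out = dict(raw)
    for key in ("step_size", "travel"):
        if key in out:
            out[key + "_nm"] = [_norm_length(v, f"stage.{key}") for v in out.pop(key)]
    return out


def _norm_scan(raw: dict) -> dict:
    _check_keys(raw, _SCAN_KEYS, "scan")
    out = dict(raw)
    if "dz" in out:
        out["dz_nm"] = _norm_length(out.pop("dz"), "scan.dz")
    if "af_range" in out:
        out["af_range_nm"] = [_norm_length(v, "scan.af_range") for v in out.pop("af_range")]
    return out


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration (lengths normalized to nm)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    _check_keys(raw, _TOP_KEYS, "config")
    cam = dict(raw.get("camera", {}))
    _check_keys(cam, _CAMERA_KEYS, "camera")
    tl = raw.get("timelapse")
    if tl is not None:
        _check_keys(tl, _TIMELAPSE_KEYS, "timelapse")
    cfg = RunConfig(
        seed=int(raw.get("seed", 0)),
        output_dir=str(raw.get("output_dir", "simscope-out")),
        scene=_norm_scene(dict(raw.get("scene", {"preset": "blood-smear"}))),
        optics=_norm_optics(dict(raw.get("optics", {}))),
        camera=cam,
        stage=_norm_stage(dict(raw.get("stage", {}))),
        scan=None if raw.get("scan") is None else _norm_scan(dict(raw["scan"])),
        timelapse=None if tl is None else dict(tl),
    )
    _validate(cfg)
    return cfg


def _validate(cfg: RunConfig) -> None:
    from .stage import DEFAULT_TRAVEL_NM

    travel = cfg.stage.get("travel_nm", list(DEFAULT_TRAVEL_NM))
    if cfg.scan and "af_range_nm" in cfg.scan:
        lo, hi = cfg.scan["af_range_nm"]
        if hi - lo > travel[2] or max(abs(lo), abs(hi)) > travel[2] / 2:
            raise ConfigError(
                f"scan.af_range ({format_length_nm(lo)} .. {format_length_nm(hi)}) "
                f"exceeds the {format_length_nm(travel[2])} z travel"
            )


def save_config(cfg: RunConfig, path: str | Path) -> None:
    """Persist a config; lengths are written back with unit suffixes."""

    def with_units(d, length_keys):
        out = {}
        for k, v in d.items():
            if k in length_keys:
                base = k[: -len("_nm")]
                if isinstance(v, (list, tuple)):
                    out[base] = [format_length_nm(x) for x in v]
                else:
                    out[base] = format_length_nm(v)
            else:
                out[k] = v
        return out

    doc: dict = {"seed": cfg.seed, "output_dir": cfg.output_dir}
    scene = with_units(cfg.scene, {"extent_nm", "pitch_nm", "line_width_nm"})
    if "focal_surface" in scene:
        fs = scene["focal_surface"]
        scene["focal_surface"] = {"a": fs["a"], "b": fs["b"], "c": format_length_nm(fs["c"])}
    if "primitives" in scene:
        scene["primitives"] = [
            with_units(p, {"centre_nm", "radius_nm", "offset_nm"}) for p in scene["primitives"]
        ]
    doc["scene"] = scene
    doc["optics"] = with_units(cfg.optics, {"wavelength_nm", "psf_fwhm_nm", "pixel_pitch_nm"})
    doc["camera"] = dict(cfg.camera)
    doc["stage"] = with_units(cfg.stage, {"step_size_nm", "travel_nm"})
    if cfg.scan is not None:
        doc["scan"] = with_units(cfg.scan, {"dz_nm", "af_range_nm"})
    if cfg.timelapse is not None:
        doc["timelapse"] = dict(cfg.timelapse)
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)


# -- object construction ---------------------------------------------------


def build_specimen(scene: dict) -> SpecimenField:
    preset = scene.get("preset", "blood-smear")
    extent_um = tuple(np.asarray(scene.get("extent_nm", [2e6, 2e6])) / 1e3)
    fs = scene.get("focal_surface", {"a": 0.0, "b": 0.0, "c": 0.0})
    focal = (fs["a"], fs["b"], fs["c"])
    if "primitives" in scene:
        prims = []
        for p in scene["primitives"]:
            if p["type"] == "disk":
                prims.append(
                    Disk(
                        centre_um=tuple(np.asarray(p["centre_nm"]) / 1e3),
                        radius_um=p["radius_nm"] / 1e3,
                        intensity=p.get("intensity", 0.35),
                        colour=tuple(p["colour"]) if "colour" in p else None,
                    )
                )
            else:
                prims.append(
                    EdgeTarget(
                        angle_deg=p.get("angle_deg", 0.0),
                        offset_um=p.get("offset_nm", 0.0) / 1e3,
                    )
                )
        return SpecimenField(
            extent_um=extent_um,
            primitives=prims,
            focal_surface=focal,
            background=scene.get("background", 0.85),
        )
    if preset == "blood-smear":
        return blood_smear_field(
            seed=scene.get("scene_seed", 0),
            extent_um=extent_um,
            cell_density_per_mm2=scene.get("cell_density_per_mm2", 6000.0),
            focal_surface=focal,
        )
    if preset == "knife-edge":
        return knife_edge_field(
            angle_deg=scene.get("angle_deg", 1.0), extent_um=extent_um, focal_surface=focal
        )
    if preset == "grid":
        return grid_field(
            pitch_um=scene.get("pitch_nm", 10e3) / 1e3,
            line_width_um=scene.get("line_width_nm", 2e3) / 1e3,
            extent_um=extent_um,
        )
    if preset == "flat":
        return flat_field(intensity=scene.get("intensity", 0.8), extent_um=extent_um)
    raise ConfigError(
        f"unknown scene preset {preset!r}; available: blood-smear, knife-edge, grid, flat"
    )


def build_optics(optics: dict) -> OpticsConfig:
    opts = dict(optics)
    preset = opts.pop("preset", None)
    if preset is not None:
        return get_optics_preset(preset, **opts)
    return OpticsConfig(**opts)


def build_camera(camera: dict) -> CameraConfig:
    opts = dict(camera)
    if "sensor_px" in opts:
        opts["sensor_px"] = tuple(opts["sensor_px"])
    if "bayer" in opts:
        opts["bayer_enabled"] = bool(opts.pop("bayer"))
    return CameraConfig(**opts)


def build_stage(stage: dict) -> StageState:
    opts = dict(stage)
    kwargs = {}
    if "step_size_nm" in opts:
        kwargs["step_size_nm"] = opts["step_size_nm"]
    if "travel_nm" in opts:
        kwargs["travel_nm"] = opts["travel_nm"]
    if "backlash_steps" in opts:
        kwargs["backlash_steps"] = opts["backlash_steps"]
    if "drift_rate_nm_per_hour" in opts:
        kwargs["drift_rate_nm_per_hour"] = opts["drift_rate_nm_per_hour"]
    return StageState(**kwargs)


def build_microscope(cfg: RunConfig) -> VirtualMicroscope:
    """Assemble the virtual microscope a config describes."""
    return VirtualMicroscope(
        specimen=build_specimen(cfg.scene),
        optics=build_optics(cfg.optics),
        camera=build_camera(cfg.camera),
        stage=build_stage(cfg.stage),
        seed=cfg.seed,
    )


def config_dict(cfg: RunConfig) -> dict:
    return dataclasses.asdict(cfg)
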