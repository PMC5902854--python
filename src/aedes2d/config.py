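"""Scenario configuration files: YAML load/save with strict validation.

Two layouts are accepted.  The *preset* layout names a built-in scenario
and optionally overrides a few knobs::

    preset: example3:all_streets
    dx: 4.0
    days: 42
    seed_amplitude_m: 25.0

The *explicit* layout spells out the whole scenario (grid, rectangles,
per-region coefficient table, wind, boundaries, initial condition).
Unknown keys are rejected with their key path; omitted biology constants
fall back to the base table.
"""

from __future__ import annotations

import hashlib
from dataclasses import replace
from typing import Any, Mapping

import yaml

from .geometry import RegionParams
from .scenarios import (
    InitialSpec,
    PRESETS,
    ScenarioConfig,
    WindSchedule,
    get_preset,
)
from .solver import SIDES, BoundaryCondition, BoundarySpec

__all__ = ["ConfigError", "load_config", "save_config",
           "config_to_dict", "config_from_dict", "config_hash"]


class ConfigError(ValueError):
    """Schema violation in a scenario configuration."""


_PRESET_KEYS = {
    "preset", "variant", "dx", "days", "duration", "snapshots", "safety", "dt_cap_seconds",
    "record_interval", "transport_unit", "biology", "seed_amplitude_m",
    "seed_amplitude_a", "d_face",
}
_EXPLICIT_KEYS = {
    "name", "grid", "background", "rectangles", "region_params", "biology",
    "transport_unit", "bc", "wind", "initial", "duration", "days",
    "snapshots", "safety", "record_interval", "dt_cap_seconds", "d_face", "provenance",
}
_REGION_KEYS = {"psi", "vx", "vy", "Dx", "Dy", "h1", "h2"}
_INITIAL_KEYS = {"kind", "label", "rect", "center", "sigma",
                 "m_amplitude", "a_amplitude"}
_WIND_KEYS = {"mode", "day", "night", "day_start", "day_end"}


def _reject_unknown(d: Mapping[str, Any], allowed: set[str], path: str) -> None:
    unknown = set(d) - allowed
    if unknown:
        raise ConfigError(
            f"unknown key(s) {sorted(unknown)} at {path!r}; "
            f"allowed: {sorted(allowed)}"
        )


def _bc_from_dict(d: Mapping[str, Any]) -> BoundarySpec:
    _reject_unknown(d, set(SIDES), "bc")
    conds = {}
    for side, spec in d.items():
        if spec == "neumann":
            conds[side] = BoundaryCondition("neumann")
        elif isinstance(spec, Mapping) and set(spec) == {"dirichlet"}:
            conds[side] = BoundaryCondition("dirichlet", float(spec["dirichlet"]))
        else:
            raise ConfigError(
                f"bc.{side} must be 'neumann' or {{dirichlet: value}}, "
                f"got {spec!r}"
            )
    return BoundarySpec(**conds)


def _bc_to_dict(bc: BoundarySpec) -> dict[str, Any]:
    out: dict[str, Any] = {}
    for side in SIDES:
        c = getattr(bc, side)
        out[side] = "neumann" if c.kind == "neumann" else {"dirichlet": c.value}
    return out


def _wind_from_dict(d: Mapping[str, Any]) -> WindSchedule:
    _reject_unknown(d, _WIND_KEYS, "wind")
    kwargs: dict[str, Any] = {"mode": d.get("mode", "constant")}
    for win in ("day", "night"):
        if win in d:
            kwargs[win] = {lab: (float(v[0]), float(v[1]))
                           for lab, v in d[win].items()}
    for key in ("day_start", "day_end"):
        if key in d:
            kwargs[key] = float(d[key])
    return WindSchedule(**kwargs)


def _wind_to_dict(w: WindSchedule) -> dict[str, Any]:
    out: dict[str, Any] = {"mode": w.mode}
    if w.mode == "periodic":
        out["day"] = {lab: list(v) for lab, v in w.day.items()}
        out["night"] = {lab: list(v) for lab, v in w.night.items()}
        out["day_start"] = w.day_start
        out["day_end"] = w.day_end
    return out


def _initial_from_dict(d: Mapping[str, Any]) -> InitialSpec:
    _reject_unknown(d, _INITIAL_KEYS, "initial")
    kwargs = dict(d)
    if "rect" in kwargs and kwargs["rect"] is not None:
        kwargs["rect"] = tuple(float(v) for v in kwargs["rect"])
    if "center" in kwargs and kwargs["center"] is not None:
        kwargs["center"] = tuple(float(v) for v in kwargs["center"])
    return InitialSpec(**kwargs)


def _initial_to_dict(spec: InitialSpec) -> dict[str, Any]:
    out: dict[str, Any] = {"kind": spec.kind,
                           "m_amplitude": spec.m_amplitude,
                           "a_amplitude": spec.a_amplitude}
    if spec.label is not None:
        out["label"] = spec.label
    if spec.rect is not None:
        out["rect"] = list(spec.rect)
    if spec.center is not None:
        out["center"] = list(spec.center)
    if spec.sigma is not None:
        out["sigma"] = spec.sigma
    return out


def config_from_dict(d: Mapping[str, Any]) -> ScenarioConfig:
    """Build a validated :class:`ScenarioConfig` from a plain mapping."""
    if not isinstance(d, Mapping):
        raise ConfigError(f"configuration must be a mapping, got {type(d)}")
    if "preset" in d:
        return _from_preset_dict(d)
    return _from_explicit_dict(d)


def _from_preset_dict(d: Mapping[str, Any]) -> ScenarioConfig:
    _reject_unknown(d, _PRESET_KEYS, "<top level>")
    name = d["preset"]
    if "variant" in d:
        name = f"{name}:{d['variant']}"
    if name not in PRESETS:
        raise ConfigError(
            f"unknown preset {name!r}; available: {sorted(PRESETS)}"
        )
    cfg = get_preset(name, dx=float(d["dx"])) if "dx" in d else get_preset(name)
    updates: dict[str, Any] = {}
    if "days" in d or "duration" in d:
        updates["duration"] = float(d.get("days", d.get("duration")))
    if "snapshots" in d:
        updates["snapshots"] = tuple(float(s) for s in d["snapshots"])
    for key in ("safety", "record_interval", "dt_cap_seconds"):
        if key in d:
            updates[key] = float(d[key])
    if "transport_unit" in d:
        updates["transport_unit"] = str(d["transport_unit"])
    if "d_face" in d:
        updates["d_face"] = str(d["d_face"])
    if "biology" in d:
        updates["biology"] = {k: float(v) for k, v in d["biology"].items()}
    init = cfg.initial
    if "seed_amplitude_m" in d:
        init = replace(init, m_amplitude=float(d["seed_amplitude_m"]))
    if "seed_amplitude_a" in d:
        init = replace(init, a_amplitude=float(d["seed_amplitude_a"]))
    if init is not cfg.initial:
        updates["initial"] = init
    cfg = replace(cfg, **updates) if updates else cfg
    cfg.validate()
    return cfg


def _from_explicit_dict(d: Mapping[str, Any]) -> ScenarioConfig:
    _reject_unknown(d, _EXPLICIT_KEYS, "<top level>")
    for key in ("grid", "rectangles", "region_params", "initial"):
        if key not in d:
            raise ConfigError(f"missing required key {key!r}")
    grid = d["grid"]
    _reject_unknown(grid, {"Lx", "Ly", "dx"}, "grid")
    rectangles = []
    for i, rect in enumerate(d["rectangles"]):
        if len(rect) != 5:
            raise ConfigError(
                f"rectangles[{i}] must be [label, x0, y0, x1, y1]"
            )
        rectangles.append((str(rect[0]), *(float(v) for v in rect[1:])))
    region_params = {}
    for label, row in d["region_params"].items():
        _reject_unknown(row, _REGION_KEYS, f"region_params.{label}")
        region_params[label] = RegionParams(**{k: float(v)
                                               for k, v in row.items()})
    kwargs: dict[str, Any] = {
        "name": d.get("name", "custom"),
        "Lx": float(grid["Lx"]),
        "Ly": float(grid["Ly"]),
        "dx": float(grid["dx"]),
        "rectangles": tuple(rectangles),
        "region_params": region_params,
        "initial": _initial_from_dict(d["initial"]),
    }
    if "background" in d:
        kwargs["background"] = str(d["background"])
    if "biology" in d:
        kwargs["biology"] = {k: float(v) for k, v in d["biology"].items()}
    if "transport_unit" in d:
        kwargs["transport_unit"] = str(d["transport_unit"])
    if "bc" in d:
        kwargs["bc"] = _bc_from_dict(d["bc"])
    if "wind" in d:
        kwargs["wind"] = _wind_from_dict(d["wind"])
    if "days" in d or "duration" in d:
        kwargs["duration"] = float(d.get("days", d.get("duration")))
    if "snapshots" in d:
        kwargs["snapshots"] = tuple(float(s) for s in d["snapshots"])
    for key in ("safety", "record_interval", "dt_cap_seconds"):
        if key in d:
            kwargs[key] = float(d[key])
    if "d_face" in d:
        kwargs["d_face"] = str(d["d_face"])
    if "provenance" in d:
        kwargs["provenance"] = str(d["provenance"])
    cfg = ScenarioConfig(**kwargs)
    cfg.validate()
    return cfg


def config_to_dict(cfg: ScenarioConfig) -> dict[str, Any]:
    """Serialize a scenario to the explicit plain-mapping layout."""
    out: dict[str, Any] = {
        "name": cfg.name,
        "grid": {"Lx": cfg.Lx, "Ly": cfg.Ly, "dx": cfg.dx},
        "background": cfg.background,
        "rectangles": [[lab, x0, y0, x1, y1]
                       for lab, x0, y0, x1, y1 in cfg.rectangles],
        "region_params": {
            label: {"psi": row.psi, "vx": row.vx, "vy": row.vy,
                    "Dx": row.Dx, "Dy": row.Dy, "h1": row.h1, "h2": row.h2}
            for label, row in cfg.region_params.items()
        },
        "transport_unit": cfg.transport_unit,
        "bc": _bc_to_dict(cfg.bc),
        "wind": _wind_to_dict(cfg.wind),
        "initial": _initial_to_dict(cfg.initial),
        "duration": cfg.duration,
        "snapshots": list(cfg.snapshots),
        "safety": cfg.safety,
        "record_interval": cfg.record_interval,
        "dt_cap_seconds": cfg.dt_cap_seconds,
        "d_face": cfg.d_face,
    }
    if cfg.biology:
        out["biology"] = dict(cfg.biology)
    if cfg.provenance:
        out["provenance"] = cfg.provenance
    return out


def load_config(path) -> ScenarioConfig:
    """Read and validate a YAML scenario file."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if data is None:
        raise ConfigError(f"configuration file {path} is empty")
    return config_from_dict(data)


def save_config(cfg: ScenarioConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(cfg), fh, sort_keys=False)


def config_hash(cfg: ScenarioConfig) -> str:
    """SHA-256 of the canonical YAML serialization (run identity)."""
    text = yaml.safe_dump(config_to_dict(cfg), sort_keys=True)
    return hashlib.sha256(text.encode()).hexdigest()
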