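"""Scenario configuration: presets, validation and YAML/JSON loading.

A scenario fully defines one simulation: species detection parameters,
trap layout, animal density, per-site capture capacity, number of nights
between trap checks, replicate count, optional immigration, and the base
random seed.  Shipped presets for possum, stoat and ship rat mirror New
Zealand best-practice trapping layouts and published detection parameters.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path
from typing import Any, Optional

import yaml

from .detection import DetectionParams
from .grid import LayoutSpec
from .immigration import ImmigrationSpec

__all__ = [
    "ScenarioConfig",
    "ConfigError",
    "preset",
    "preset_names",
    "load_config",
    "scenario_from_dict",
]

ASSIGNMENT_MODES = ("hazard", "bernoulli")


class ConfigError(ValueError):
    """A configuration file failed validation; the message carries the
    dotted field path of the offending entry."""


@dataclass(frozen=True)
class ScenarioConfig:
    """Complete definition of one trapping simulation."""

    detection: DetectionParams
    layout: LayoutSpec
    density: float
    capacity: int
    nights: int = 30
    replicates: int = 100
    immigration: Optional[ImmigrationSpec] = None
    seed: int = 0
    truncation_sigma: float = 5.0
    assignment: str = "hazard"
    species: Optional[str] = None

    def __post_init__(self) -> None:
        if self.density < 0:
            raise ConfigError("density: must be non-negative")
        if self.nights < 1:
            raise ConfigError("nights: must be >= 1")
        if self.replicates < 1:
            raise ConfigError("replicates: must be >= 1")
        if self.capacity < 1:
            raise ConfigError("capacity: must be >= 1")
        if self.truncation_sigma < 2.45:
            raise ConfigError(
                "truncation_sigma: must be >= 2.45 to cover the 95% home range"
            )
        if self.assignment not in ASSIGNMENT_MODES:
            raise ConfigError(
                f"assignment: must be one of {ASSIGNMENT_MODES}, got {self.assignment!r}"
            )

    def replace(self, **changes: Any) -> "ScenarioConfig":
        from dataclasses import replace as _replace

        return _replace(self, **changes)

    def to_dict(self) -> dict:
        """JSON/YAML-serialisable snapshot of the scenario."""
        d = asdict(self)
        if self.immigration is not None:
            d["immigration"] = {
                "total": self.immigration.total_immigrants,
                "zone_weights": list(self.immigration.zone_weights),
            }
        return d


def preset_names() -> list[str]:
    files = resources.files("multitrap.presets")
    return sorted(p.name[:-5] for p in files.iterdir() if p.name.endswith(".yaml"))


def _load_preset_raw(name: str) -> dict:
    try:
        text = (
            resources.files("multitrap.presets").joinpath(f"{name}.yaml").read_text()
        )
    except FileNotFoundError:
        raise ConfigError(
            f"species: unknown preset {name!r}; available: {preset_names()}"
        ) from None
    return yaml.safe_load(text)


def preset(name: str) -> dict:
    """Return a preset's raw parameter dictionary (detection, layout, ...)."""
    return _load_preset_raw(name)


def _require(d: dict, key: str, path: str) -> Any:
    if key not in d or d[key] is None:
        raise ConfigError(f"{path}{key}: required field is missing")
    return d[key]


def _detection_from_dict(d: dict, path: str = "detection.") -> DetectionParams:
    try:
        return DetectionParams(
            g0=float(_require(d, "g0", path)),
            sigma=float(_require(d, "sigma", path)),
        )
    except ValueError as e:
        if isinstance(e, ConfigError):
            raise
        raise ConfigError(f"{path[:-1]}: {e}") from None


def _layout_from_dict(d: dict, path: str = "layout.") -> LayoutSpec:
    try:
        return LayoutSpec(
            trap_spacing=float(_require(d, "trap_spacing", path)),
            line_spacing=float(_require(d, "line_spacing", path)),
            traps_per_line=int(_require(d, "traps_per_line", path)),
            n_lines=int(_require(d, "n_lines", path)),
            buffer=float(_require(d, "buffer", path)),
            buffered_area=float(_require(d, "buffered_area", path)),
        )
    except ValueError as e:
        if isinstance(e, ConfigError):
            raise
        raise ConfigError(f"{path[:-1]}: {e}") from None


def _immigration_from_value(value: Any) -> Optional[ImmigrationSpec]:
    if value is None:
        return None
    if value == "default":
        return ImmigrationSpec()
    if not isinstance(value, dict):
        raise ConfigError(
            "immigration: must be null, 'default', or a mapping with "
            "keys total/zone_weights"
        )
    total = value.get("total", value.get("total_immigrants"))
    weights = value.get("zone_weights", (0.6, 0.3, 0.1))
    try:
        return ImmigrationSpec(
            total_immigrants=None if total is None else int(total),
            zone_weights=tuple(weights),
        )
    except ValueError as e:
        raise ConfigError(f"immigration: {e}") from None


def scenario_from_dict(raw: dict) -> ScenarioConfig:
    """Build a validated scenario from a plain dictionary.

    A ``species`` key pulls in a preset; any explicitly given ``detection``
    or ``layout`` block overrides the preset's values field by field.
    """
    species = raw.get("species")
    base: dict = {}
    if species is not None:
        base = _load_preset_raw(str(species))

    det_dict = {**base.get("detection", {}), **(raw.get("detection") or {})}
    lay_dict = {**base.get("layout", {}), **(raw.get("layout") or {})}
    detection = _detection_from_dict(det_dict)
    layout = _layout_from_dict(lay_dict)

    if "density" not in raw or raw["density"] is None:
        raise ConfigError("density: required field is missing")

    immigration = _immigration_from_value(raw.get("immigration"))

    return ScenarioConfig(
        detection=detection,
        layout=layout,
        density=float(raw["density"]),
        capacity=int(raw.get("capacity", 1)),
        nights=int(raw.get("nights", 30)),
        replicates=int(raw.get("replicates", 100)),
        immigration=immigration,
        seed=int(raw.get("seed", 0)),
        truncation_sigma=float(raw.get("truncation_sigma", 5.0)),
        assignment=str(raw.get("assignment", "hazard")),
        species=species,
    )


def load_config(path: str | Path) -> ScenarioConfig:
    """Load and validate a scenario from a YAML (or JSON) file."""
    path = Path(path)
    text = path.read_text()
    if path.suffix == ".json":
        raw = json.loads(text)
    else:
        raw = yaml.safe_load(text)
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    return scenario_from_dict(raw)
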