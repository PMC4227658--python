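"""Run configuration: YAML files with validated physical defaults.

A config file is a YAML mapping with optional sections ``fiber``,
``crosslinker``, ``box``, ``protocol``, ``criterion`` plus top-level
``seeds``, ``output_dir``, ``collagen_density``, ``geometry`` and
``reduced_scale``.  Omitted fields fall back to the standard collagen
defaults; unknown keys are rejected.  An empty file is a valid config
describing the default experiment.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .params import (
    BoxSpec,
    CrosslinkerParams,
    EquilibriumCriterion,
    FiberSpec,
    InvalidParameterError,
)
from .protocols import DeformationProtocol

__all__ = ["RunConfig", "ConfigError", "load_config", "dump_config"]


class ConfigError(ValueError):
    """Malformed or invalid configuration file."""


@dataclass
class RunConfig:
    """Everything needed to reproduce one simulation run."""

    fiber: FiberSpec = field(default_factory=FiberSpec)
    crosslinker: CrosslinkerParams = field(default_factory=CrosslinkerParams)
    box: BoxSpec = field(default_factory=BoxSpec)
    protocol: DeformationProtocol = field(
        default_factory=lambda: DeformationProtocol(mode="shear_y")
    )
    criterion: EquilibriumCriterion = field(
        default_factory=EquilibriumCriterion
    )
    collagen_density: float = 2.0
    geometry: str = "random"
    seeds: tuple[int, ...] = (0,)
    output_dir: str = "fibernet_out"
    reduced_scale: bool = False

    def __post_init__(self) -> None:
        if self.collagen_density <= 0:
            raise ConfigError("collagen_density must be > 0")
        if self.geometry not in ("random", "prealigned"):
            raise ConfigError("geometry must be 'random' or 'prealigned'")
        if not self.seeds:
            raise ConfigError("need at least one seed")


_SECTIONS = {
    "fiber": FiberSpec,
    "crosslinker": CrosslinkerParams,
    "box": BoxSpec,
    "protocol": DeformationProtocol,
    "criterion": EquilibriumCriterion,
}
_TOP_KEYS = {
    "collagen_density",
    "geometry",
    "seeds",
    "output_dir",
    "reduced_scale",
}


def _coerce_numbers(payload: dict) -> dict:
    # YAML 1.1 reads "32.0e6" (no sign after e) as a string; accept it
    out = {}
    for key, value in payload.items():
        if isinstance(value, str):
            try:
                value = float(value)
            except ValueError:
                pass
        out[key] = value
    return out


def _build_section(cls, payload: dict, name: str):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(payload) - known
    if unknown:
        raise ConfigError(
            f"unknown keys in section '{name}': {sorted(unknown)}"
        )
    payload = _coerce_numbers(payload)
    if cls is DeformationProtocol:
        payload = dict(payload)
        payload.setdefault("mode", "shear_y")
        tc = payload.get("test_cube")
        if tc is not None:
            payload["test_cube"] = (tuple(tc[0]), tc[1])
    try:
        return cls(**payload)
    except InvalidParameterError as err:
        raise ConfigError(f"invalid section '{name}': {err}") from err


def load_config(path: str | Path) -> RunConfig:
    """Parse and validate a YAML config; empty files give the defaults."""
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError("config must be a YAML mapping")
    unknown = set(raw) - set(_SECTIONS) - _TOP_KEYS
    if unknown:
        raise ConfigError(f"unknown top-level keys: {sorted(unknown)}")
    kwargs = {}
    for name, cls in _SECTIONS.items():
        section = raw.get(name, {})
        if not isinstance(section, dict):
            raise ConfigError(f"section '{name}' must be a mapping")
        kwargs[name] = _build_section(cls, section, name)
    for key in _TOP_KEYS:
        if key in raw:
            kwargs[key] = (
                tuple(raw[key]) if key == "seeds" else raw[key]
            )
    return RunConfig(**kwargs)


def dump_config(config: RunConfig) -> str:
    """Serialize the effective config back to YAML (the run echo)."""
    payload: dict = {}
    for name in _SECTIONS:
        obj = getattr(config, name)
        payload[name] = dataclasses.asdict(obj)
    payload.update(
        collagen_density=config.collagen_density,
        geometry=config.geometry,
        seeds=list(config.seeds),
        output_dir=config.output_dir,
        reduced_scale=config.reduced_scale,
    )
    return yaml.safe_dump(payload, sort_keys=True)
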