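"""Run-configuration files (YAML) with strict validation.

A configuration is a mapping with optional sections ``geometry``,
``medium``, ``particles``, ``force``, ``interaction``, ``source`` and
``run``, plus a top-level ``seed``.  Every omitted key takes the package
default (the rat-anatomy geometry, 310 K air, 200 nm particles, 180 min
horizon).  Unknown keys are rejected with the offending key named, so a
misspelling cannot silently fall back to a default.
"""

from dataclasses import fields, replace

import yaml

from .engine import SimulationConfig
from .errors import ConfigError
from .geometry import Geometry
from .physics import (ForceSpec, InteractionSpec, Medium, ParticleSpec,
                      medium_preset)
from .synthetic import SourceSpec

_SECTION_TYPES = {
    "geometry": Geometry,
    "medium": Medium,
    "particles": ParticleSpec,
    "force": ForceSpec,
    "interaction": InteractionSpec,
    "source": SourceSpec,
}

_RUN_KEYS = ("dt", "t_end", "record_every", "slip", "d_scale")


def _build_section(name, cls, data, path):
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError(
            f"{path}: section '{name}' must be a mapping, got {type(data).__name__}")
    data = dict(data)
    base = None
    if name == "medium" and "preset" in data:
        base = medium_preset(str(data.pop("preset")))
    allowed = {f.name for f in fields(cls)}
    unknown = set(data) - allowed
    if unknown:
        raise ConfigError(
            f"{path}: unknown key '{sorted(unknown)[0]}' in section "
            f"'{name}' (allowed: {sorted(allowed)})")
    try:
        if base is not None:
            return replace(base, **data)
        return cls(**data)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{path}: invalid section '{name}': {exc}") from exc


def config_from_dict(data: dict, path: str = "<config>") -> SimulationConfig:
    """Build and validate a SimulationConfig from a plain mapping."""
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: configuration must be a mapping")
    data = dict(data)
    if "seed" not in data:
        raise ConfigError(f"{path}: missing required key 'seed'")
    seed = data.pop("seed")

    kwargs = {"seed": int(seed)}
    for name, cls in _SECTION_TYPES.items():
        if name in data:
            kwargs[name] = _build_section(name, cls, data.pop(name), path)
    if "run" in data:
        run = data.pop("run")
        if run is None:
            run = {}
        if not isinstance(run, dict):
            raise ConfigError(f"{path}: section 'run' must be a mapping")
        unknown = set(run) - set(_RUN_KEYS)
        if unknown:
            raise ConfigError(
                f"{path}: unknown key '{sorted(unknown)[0]}' in section "
                f"'run' (allowed: {sorted(_RUN_KEYS)})")
        kwargs.update(run)
    if data:
        raise ConfigError(
            f"{path}: unknown top-level key '{sorted(data)[0]}' (allowed: "
            f"{sorted(('seed', 'run') + tuple(_SECTION_TYPES))})")

    try:
        config = SimulationConfig(**kwargs)
        config.validate()
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{path}: {exc}") from exc
    return config


def load_config(path) -> SimulationConfig:
    """Load and fully validate a YAML run configuration."""
    try:
        with open(path) as fh:
            data = yaml.safe_load(fh)
    except FileNotFoundError:
        raise ConfigError(f"configuration file not found: {path}")
    except yaml.YAMLError as exc:
        raise ConfigError(f"{path}: YAML parse error: {exc}") from exc
    return config_from_dict(data, str(path))


def config_to_dict(config: SimulationConfig) -> dict:
    """Serialise a SimulationConfig into the file mapping layout."""
    out = {"seed": int(config.seed)}
    for name, cls in _SECTION_TYPES.items():
        obj = getattr(config, name)
        out[name] = {f.name: getattr(obj, f.name) for f in fields(cls)}
    out["run"] = {
        "dt": config.dt,
        "t_end": config.t_end,
        "record_every": config.record_every,
        "slip": config.slip,
        "d_scale": config.d_scale,
    }
    return out


def dump_config(config: SimulationConfig, path) -> None:
    """Write a configuration as YAML; load_config(dump) round-trips."""
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=False)
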