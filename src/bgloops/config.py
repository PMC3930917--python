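"""Run configuration: defaults, YAML loading, validation.

A run is described by one configuration with three sections:

``model``
    Per-loop presets (the essential per-loop parameters plus every shared
    calibrated default), dopamine-circuit settings, plasticity coefficients
    and habituation parameters.  The shipped defaults reproduce the three
    loop presets verbatim; a config file overrides individual fields.
``experiment``
    Protocol name and its parameters (duration, DA conditions, repetitions,
    master seed, reward schedule).
``io``
    Output directory, sampling stride, weight-snapshot interval.

Resolution order is file > preset > defaults, and unknown keys anywhere are
rejected with their full path (typos in a parameter-heavy model must fail
loudly).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Dict, Optional

import yaml

from .agent import AgentConfig
from .loops import PRESETS, LoopSpec, loop_spec

__all__ = ["RunConfig", "load_config", "default_config_dict", "ConfigError"]


class ConfigError(ValueError):
    """A configuration file violated the schema or an invariant."""


def _loop_defaults(preset: str) -> Dict[str, float]:
    spec = loop_spec(preset)
    d = dataclasses.asdict(spec)
    d.pop("name")
    return d


def default_config_dict() -> Dict[str, Any]:
    """The fully-resolved default configuration as plain data."""
    agent_defaults = dataclasses.asdict(AgentConfig())
    return {
        "model": {
            "dt": 0.01,
            "loops": {name: _loop_defaults(name) for name in PRESETS},
            "agent": agent_defaults,
        },
        "experiment": {
            "protocol": "board-task",
            "duration": 1800.0,
            "da_percents": [0.0, 20.0, 40.0],
            "reps": 10,
            "seed": 0,
            "reward_schedule": [[1260.0, 3], [1440.0, 4], [1620.0, 5]],
        },
        "io": {
            "outdir": "runs",
            "stride": 25,
            "snapshot_interval": 60.0,
        },
    }


def _merge(base: Dict[str, Any], override: Dict[str, Any], path: str = "") -> Dict[str, Any]:
    out = dict(base)
    for key, val in override.items():
        here = f"{path}.{key}" if path else key
        if key not in base:
            raise ConfigError(f"unknown configuration key: {here}")
        if isinstance(base[key], dict):
            if not isinstance(val, dict):
                raise ConfigError(f"{here}: expected a mapping")
            out[key] = _merge(base[key], val, here)
        else:
            out[key] = val
    return out


def _validate_loop(name: str, params: Dict[str, Any]) -> None:
    def need(cond: bool, msg: str) -> None:
        if not cond:
            raise ConfigError(f"model.loops.{name}: {msg}")

    need(params["n_channels"] > 0, "n_channels must be positive")
    need(0.0 <= params["eps_striatum"] <= 1.0,
         f"eps_striatum={params['eps_striatum']} outside [0, 1]")
    need(params["lam_striatum"] >= 0, "lam_striatum must be >= 0")
    need(params["lateral_inhibition"] >= 0, "lateral_inhibition must be >= 0")
    need(params["noise_strength"] >= 0, "noise_strength must be >= 0")
    for key, val in params.items():
        if key.startswith("tau_"):
            need(val > 0, f"{key} must be > 0")
        if key.startswith("alpha_"):
            need(val > 0, f"{key} must be > 0")


@dataclass
class RunConfig:
    """A fully-resolved, validated run configuration."""

    model: Dict[str, Any]
    experiment: Dict[str, Any]
    io: Dict[str, Any]

    def loop_spec(self, preset: str, **overrides) -> LoopSpec:
        params = dict(self.model["loops"][preset])
        params.update(overrides)
        return LoopSpec(name=preset, **params)

    def agent_config(self) -> AgentConfig:
        return AgentConfig(**self.model["agent"])

    def as_dict(self) -> Dict[str, Any]:
        return {"model": self.model, "experiment": self.experiment, "io": self.io}

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.as_dict(), sort_keys=False))


def load_config(path: Optional[str] = None) -> RunConfig:
    """Load and validate a YAML config; ``None`` or an empty file gives the
    shipped defaults.  Raises :class:`ConfigError` with the offending field
    path on unknown keys or invariant violations."""
    base = default_config_dict()
    if path is not None:
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        if not isinstance(data, dict):
            raise ConfigError("top level of the config must be a mapping")
        base = _merge(base, data)
    dt = base["model"]["dt"]
    if dt <= 0:
        raise ConfigError("model.dt must be > 0")
    for name, params in base["model"]["loops"].items():
        _validate_loop(name, params)
        if dt >= min(v for k, v in params.items() if k.startswith("tau_")):
            raise ConfigError(
                f"model.loops.{name}: dt={dt} is not below the smallest tau"
            )
    agent = base["model"]["agent"]
    if agent["zeta_ctx"] < 0:
        raise ConfigError("model.agent.zeta_ctx must be >= 0")
    if agent["predictor_coeff_role"] not in ("rate", "threshold"):
        raise ConfigError(
            "model.agent.predictor_coeff_role must be 'rate' or 'threshold'"
        )
    exp = base["experiment"]
    if exp["duration"] <= 0:
        raise ConfigError("experiment.duration must be > 0")
    if exp["reps"] < 1:
        raise ConfigError("experiment.reps must be >= 1")
    return RunConfig(model=base["model"], experiment=base["experiment"],
                     io=base["io"])
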