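"""Experiment configuration: YAML in, validated dataclasses out.

A configuration file is a nested mapping with optional sections ``wing``,
``kinematics``, ``encoding``, ``sspoc``, ``solver`` and ``sweep``; every
omitted key falls back to the built-in defaults (the hawkmoth-scale plate
and the published encoder/optimiser constants).  Unknown keys are rejected
with an error naming the offender, so typos cannot silently change an
experiment.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields

import numpy as np
import yaml

from .encoding import EncodingParams
from .placement import SSPOCParams
from .wing_model import Kinematics, WingSpec

__all__ = ["SolverParams", "SweepParams", "ExperimentConfig",
           "ConfigError", "load_config", "save_config"]


class ConfigError(ValueError):
    """Configuration schema violation; the message names the bad key."""


@dataclass(frozen=True)
class SolverParams:
    """Mesh and time-integration settings."""

    nx: int = 50
    ny: int = 25
    dt: float = 2e-4
    n_cycles: int | None = None      # None = adaptive periodicity stop
    max_cycles: int = 10
    periodicity_tol: float = 0.01

    def __post_init__(self):
        if self.nx < 1 or self.ny < 1:
            raise ConfigError("solver mesh counts must be positive")
        if self.dt <= 0:
            raise ConfigError("solver.dt must be positive")


@dataclass(frozen=True)
class SweepParams:
    """Structural sweep grid (two orders of magnitude around 3 GPa)."""

    E_min: float = 0.3e9
    E_max: float = 30e9
    n_E: int = 9
    gradients: tuple = ("uniform", "gradient")
    zetas: tuple = (0.2, 1.0, 2.0)
    axes: tuple = ("roll", "pitch", "yaw")
    n_random: int = 20

    def E_grid(self) -> np.ndarray:
        return np.geomspace(self.E_min, self.E_max, self.n_E)


@dataclass(frozen=True)
class ExperimentConfig:
    """Fully-resolved parameters of one experiment."""

    wing: WingSpec = field(default_factory=WingSpec)
    kinematics: Kinematics = field(default_factory=Kinematics)
    encoding: EncodingParams = field(default_factory=EncodingParams)
    sspoc: SSPOCParams = field(default_factory=SSPOCParams)
    solver: SolverParams = field(default_factory=SolverParams)
    sweep: SweepParams = field(default_factory=SweepParams)
    seed: int = 0

    def to_dict(self) -> dict:
        d = {k: asdict(getattr(self, k)) for k in
             ("wing", "kinematics", "encoding", "sspoc", "solver", "sweep")}
        d["seed"] = self.seed
        for sec in d.values():
            if isinstance(sec, dict):
                for k, v in sec.items():
                    if isinstance(v, tuple):
                        sec[k] = list(v)
        return d

    def hash(self) -> str:
        """Stable digest of the resolved configuration."""
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


_SECTIONS = {
    "wing": WingSpec,
    "kinematics": Kinematics,
    "encoding": EncodingParams,
    "sspoc": SSPOCParams,
    "solver": SolverParams,
    "sweep": SweepParams,
}
_TUPLE_KEYS = {"gradients", "zetas", "axes"}


def _build_section(name, cls, data):
    if not isinstance(data, dict):
        raise ConfigError(f"section '{name}' must be a mapping")
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown key '{name}.{sorted(unknown)[0]}'")
    clean = {k: tuple(v) if k in _TUPLE_KEYS and isinstance(v, list) else v
             for k, v in data.items()}
    try:
        return cls(**clean)
    except (ValueError, TypeError) as exc:
        raise ConfigError(f"invalid value in section '{name}': {exc}") from exc


def load_config(path) -> ExperimentConfig:
    """Load and validate a YAML config; an empty file yields all defaults."""
    with open(path) as f:
        raw = yaml.safe_load(f)
    raw = raw or {}
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    unknown = set(raw) - set(_SECTIONS) - {"seed"}
    if unknown:
        raise ConfigError(f"unknown section '{sorted(unknown)[0]}'")
    parts = {name: _build_section(name, cls, raw.get(name, {}))
             for name, cls in _SECTIONS.items()}
    seed = raw.get("seed", 0)
    if not isinstance(seed, int):
        raise ConfigError("seed must be an integer")
    return ExperimentConfig(seed=seed, **parts)


def save_config(path, cfg: ExperimentConfig) -> None:
    """Write the fully-resolved configuration next to experiment outputs."""
    with open(path, "w") as f:
        yaml.safe_dump(cfg.to_dict(), f, sort_keys=True)
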