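"""Run configuration: one sectioned YAML/JSON file for the whole analysis.

Absent keys take the published defaults (11 states; beta_minus 0.4,
beta_plus 0.6; mu-slope 0.05, sigma2 0.7, z 0.2; 20 blocks x 28 trials with
75% match).  Unknown keys are an error (typos should not silently become
defaults), and a saved resolved config reproduces the run exactly.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .evaluation import DEFAULT_TIME_SCALE
from .markov import IntensityParams
from .quantum import HamiltonianParams
from .simulate import RatingGeneratorParams, SessionConfig
from .state_space import StateSpace

__all__ = [
    "RunConfig",
    "ErpSettings",
    "config_from_dict",
    "load_config",
    "save_config",
    "ConfigError",
]


class ConfigError(ValueError):
    """Invalid or unknown configuration content."""


@dataclass(frozen=True)
class ErpSettings:
    """Epoch-generation and ERP-stage settings."""

    noise_sd_uv: float = 5.0
    sampling_rate: float = 250.0
    tmin_ms: float = -1300.0
    tmax_ms: float = 950.0
    voltage_limit_uv: float = 100.0
    rt_limit_s: float = 2.0

    def __post_init__(self) -> None:
        if self.tmin_ms >= self.tmax_ms:
            raise ConfigError("erp.tmin_ms must be below erp.tmax_ms")
        if self.sampling_rate <= 0:
            raise ConfigError("erp.sampling_rate must be positive")
        if self.voltage_limit_uv <= 0 or self.rt_limit_s <= 0:
            raise ConfigError("erp rejection limits must be positive")


@dataclass(frozen=True)
class RunConfig:
    """Everything a full simulate -> compare -> erp run needs."""

    n_states: int = 11
    markov: IntensityParams = field(default_factory=IntensityParams)
    quantum: HamiltonianParams = field(default_factory=HamiltonianParams)
    initial_state: str = "weighted"  # 'weighted' | 'uniform'
    time_scale: float = DEFAULT_TIME_SCALE
    session: SessionConfig = field(default_factory=SessionConfig)
    ratings: RatingGeneratorParams = field(default_factory=RatingGeneratorParams)
    erp: ErpSettings = field(default_factory=ErpSettings)
    seed: int = 0
    output_dir: str = "runs/default"

    def __post_init__(self) -> None:
        if self.initial_state not in ("weighted", "uniform"):
            raise ConfigError(
                f"initial_state must be 'weighted' or 'uniform', got {self.initial_state!r}"
            )
        if self.time_scale <= 0:
            raise ConfigError("time_scale must be positive")
        StateSpace(self.n_states)  # validates n >= 2

    @property
    def space(self) -> StateSpace:
        return StateSpace(self.n_states)

    def to_dict(self) -> dict:
        return {
            "n_states": self.n_states,
            "markov": dataclasses.asdict(self.markov),
            "quantum": dataclasses.asdict(self.quantum),
            "initial_state": self.initial_state,
            "time_scale": self.time_scale,
            "session": dataclasses.asdict(self.session),
            "ratings": dataclasses.asdict(self.ratings),
            "erp": dataclasses.asdict(self.erp),
            "seed": self.seed,
            "output_dir": self.output_dir,
        }


_SECTIONS = {
    "markov": IntensityParams,
    "quantum": HamiltonianParams,
    "session": SessionConfig,
    "ratings": RatingGeneratorParams,
    "erp": ErpSettings,
}
_SCALARS = {"n_states", "initial_state", "time_scale", "seed", "output_dir"}


def _build_section(name: str, cls, payload: dict):
    if not isinstance(payload, dict):
        raise ConfigError(f"section '{name}' must be a mapping")
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = sorted(set(payload) - known)
    if unknown:
        raise ConfigError(f"unknown keys in section '{name}': {unknown}")
    try:
        return cls(**payload)
    except (ValueError, TypeError) as exc:
        raise ConfigError(f"invalid value in section '{name}': {exc}") from exc


def config_from_dict(raw: dict | None) -> RunConfig:
    raw = raw or {}
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    unknown = sorted(set(raw) - _SCALARS - set(_SECTIONS))
    if unknown:
        raise ConfigError(f"unknown config keys: {unknown}")
    kwargs = {k: raw[k] for k in _SCALARS if k in raw}
    for name, cls in _SECTIONS.items():
        if name in raw:
            kwargs[name] = _build_section(name, cls, raw[name])
    try:
        return RunConfig(**kwargs)
    except (ValueError, TypeError) as exc:
        if isinstance(exc, ConfigError):
            raise
        raise ConfigError(str(exc)) from exc


def load_config(path) -> RunConfig:
    """Load a YAML or JSON config; absent keys take the published defaults."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    text = path.read_text()
    try:
        raw = yaml.safe_load(text)  # YAML is a JSON superset
    except yaml.YAMLError as exc:
        raise ConfigError(f"could not parse {path}: {exc}") from exc
    return config_from_dict(raw)


def save_config(config: RunConfig, path) -> None:
    path = Path(path)
    payload = config.to_dict()
    if path.suffix == ".json":
        path.write_text(json.dumps(payload, indent=2))
    else:
        path.write_text(yaml.safe_dump(payload, sort_keys=False))
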