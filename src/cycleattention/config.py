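"""Run configuration: a schema-validated YAML key-value file.

Every stochastic stage receives an explicit seed; unknown keys are
rejected so a typo cannot silently fall back to a default.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, fields

import yaml

from .design import DesignSpec, Section, TrueParams
from .hologit import Priors
from .ologit import ModelSpec

__all__ = ["RunConfig", "ScoringConfig", "McmcConfig", "load_config",
           "config_to_dict"]


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class ScoringConfig:
    indicators: tuple[str, ...] = (
        "fixation_time_pct", "saccade_time_pct", "blink_freq_per_min",
        "pupil_mean_mm", "avg_fixation_ms", "avg_saccade_ms",
        "lane_fixation_share",
    )
    retention_threshold: float = 1.0
    n_levels: int = 3


@dataclass(frozen=True)
class McmcConfig:
    n_chains: int = 4
    n_iter: int = 5000
    n_warmup: int = 5000
    target_accept: float = 0.35
    priors: Priors = field(default_factory=Priors)


@dataclass(frozen=True)
class RunConfig:
    seed: int = 0
    design: DesignSpec = field(default_factory=DesignSpec)
    true_params: TrueParams = field(default_factory=TrueParams)
    model: ModelSpec = field(default_factory=ModelSpec)
    scoring: ScoringConfig = field(default_factory=ScoringConfig)
    mcmc: McmcConfig = field(default_factory=McmcConfig)
    gaze_duration_s: float = 60.0
    gaze_rate_hz: float = 50.0


def _build(cls, payload, path=""):
    """Recursively build a dataclass, rejecting unknown keys."""
    if not isinstance(payload, dict):
        raise ConfigError(f"{path or cls.__name__}: expected a mapping")
    known = {f.name: f for f in fields(cls)}
    unknown = set(payload) - set(known)
    if unknown:
        raise ConfigError(f"{path or cls.__name__}: unknown keys {sorted(unknown)}")
    kwargs = {}
    for name, value in payload.items():
        f = known[name]
        sub = f.type if isinstance(f.type, type) else None
        target = {
            "design": DesignSpec, "true_params": TrueParams,
            "model": ModelSpec, "scoring": ScoringConfig,
            "mcmc": McmcConfig, "priors": Priors,
        }.get(name, sub)
        if target is not None and dataclasses.is_dataclass(target) and isinstance(value, dict):
            kwargs[name] = _build(target, value, f"{path}{name}.")
        elif name == "sections":
            kwargs[name] = tuple(Section(**s) for s in value)
        elif name in ("gamma", "alpha", "directions", "periods",
                      "indicators", "covariates"):
            kwargs[name] = tuple(value)
        else:
            kwargs[name] = value
    return cls(**kwargs)


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    with open(path) as fh:
        payload = yaml.safe_load(fh) or {}
    return _build(RunConfig, payload)


def config_to_dict(cfg) -> dict:
    """Plain-dict snapshot (for run-directory metadata)."""
    return dataclasses.asdict(cfg)
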