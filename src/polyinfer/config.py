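"""Experiment configuration: YAML blocks, defaults, resolved dumps.

A run's full resolved configuration (defaults filled in) is written next
to its outputs so the run can be reproduced bit-identically from that
file alone.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from .circuit import CircuitConfig, RateConstants
from .environment import MarkovEnvSpec, PiecewiseEnvSpec

__all__ = ["ExperimentConfig", "load_config", "resolve_environment"]


_ENV_DEFAULTS = {
    "pi_ab": 0.95,
    "pi_ba": 0.95,
    "interval": 50.0,
    "pulse_amount": 5000,
    "n_perturbations": 50,
    "seed": 0,
}

_CIRCUIT_DEFAULTS = {
    "n_t": 20,
    "integrator_copies": 400,
    "bias_factor": None,
    "program_mode": False,
    "clamp_memory": False,
}

_ANALYSIS_DEFAULTS = {
    "sample_every": 1.0,
    "mode": "median_over_time",
    "replicates": 20,
    "settings": [[a, b] for a in (0.05, 0.5, 0.95) for b in (0.05, 0.5, 0.95)],
    "track_polymers": False,
}

_CALIBRATION_DEFAULTS = {
    "budget": 200,
    "n_eval_seeds": 3,
    "peak_scale": 100.0,
    "peak_halfsat": 2.0,
}


def _merge(defaults: dict, override: dict | None) -> dict:
    merged = dict(defaults)
    for key, value in (override or {}).items():
        if key not in defaults and key not in ("segments",):
            raise KeyError(f"unknown config key {key!r}")
        merged[key] = value
    return merged


@dataclass
class ExperimentConfig:
    """Resolved configuration for one experiment run."""

    environment: dict = field(default_factory=dict)
    circuit: dict = field(default_factory=dict)
    rates: dict = field(default_factory=dict)
    analysis: dict = field(default_factory=dict)
    calibration: dict = field(default_factory=dict)
    seed: int = 0

    @classmethod
    def from_dict(cls, raw: dict | None) -> "ExperimentConfig":
        raw = raw or {}
        env_raw = raw.get("environment") or {}
        if "segments" in env_raw:
            env = {
                "segments": [
                    _merge(_ENV_DEFAULTS, seg) for seg in env_raw["segments"]
                ],
                "seed": env_raw.get("seed", 0),
            }
        else:
            env = _merge(_ENV_DEFAULTS, env_raw)
        rate_fields = {
            f.name: f.default for f in dataclasses.fields(RateConstants)
        }
        return cls(
            environment=env,
            circuit=_merge(_CIRCUIT_DEFAULTS, raw.get("circuit")),
            rates=_merge(rate_fields, raw.get("rates")),
            analysis=_merge(_ANALYSIS_DEFAULTS, raw.get("analysis")),
            calibration=_merge(_CALIBRATION_DEFAULTS, raw.get("calibration")),
            seed=int(raw.get("seed", 0)),
        )

    def env_spec(self) -> MarkovEnvSpec | PiecewiseEnvSpec:
        return resolve_environment(self.environment)

    def rate_constants(self) -> RateConstants:
        return RateConstants(**self.rates)

    def circuit_config(self) -> CircuitConfig:
        env = self.environment
        if "segments" in env:
            first = env["segments"][0]
        else:
            first = env
        return CircuitConfig(
            pulse_hint=first["pulse_amount"],
            interval_hint=first["interval"],
            **self.circuit,
        )

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    def dump(self, path: Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(self.to_dict(), sort_keys=False)
        )


def resolve_environment(env: dict) -> MarkovEnvSpec | PiecewiseEnvSpec:
    if "segments" in env:
        segments = tuple(
            MarkovEnvSpec(
                pi_ab=s["pi_ab"],
                pi_ba=s["pi_ba"],
                interval=s["interval"],
                pulse_amount=s["pulse_amount"],
                n_perturbations=s["n_perturbations"],
                seed=0,
            )
            for s in env["segments"]
        )
        return PiecewiseEnvSpec(segments=segments, seed=env.get("seed", 0))
    return MarkovEnvSpec(
        pi_ab=env["pi_ab"],
        pi_ba=env["pi_ba"],
        interval=env["interval"],
        pulse_amount=env["pulse_amount"],
        n_perturbations=env["n_perturbations"],
        seed=env["seed"],
    )


def load_config(path: str | Path | None) -> ExperimentConfig:
    if path is None:
        return ExperimentConfig.from_dict({})
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return ExperimentConfig.from_dict(raw)
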