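"""Declarative pipeline configuration with schema validation.

A single YAML (or dict) document holds every stage parameter.  Unknown keys
are rejected with the schema path of the offending key; all values carry
defaults so an empty config is valid.  Divergence-time anchors and the
significance level are plain config values, never constants.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, fields
from typing import Any, Optional

import yaml

__all__ = ["PipelineConfig", "load_config", "config_hash"]

_SCHEMA: dict[str, dict[str, type]] = {
    "calling": {
        "alpha": float,
        "min_fold": float,
        "min_delta": float,
    },
    "network": {
        "density_convention": str,
        "hub_min": int,
        "island_max": int,
        "epoch_times_mya": dict,  # label -> mya
    },
    "flexibility": {
        "temperature": float,
        "minima_window_kcal": float,
    },
    "structure": {
        "sasa_probe_radius": float,
        "sasa_n_points": int,
        "turn_tolerance_deg": float,
        "salt_bridge_cutoff": float,
        "hbond_cutoff": float,
    },
    "simulation": {
        "n0": int,
        "p0": float,
        "gain_rate": float,
        "loss_rate": float,
        "subfunc_prob": float,
        "signal_mu": float,
        "background_mu": float,
        "noise_cv": float,
        "n_reps": int,
        "seed": int,
    },
}

_DEFAULTS: dict[str, dict[str, Any]] = {
    "calling": {"alpha": 0.05, "min_fold": 2.0, "min_delta": 0.0},
    "network": {
        "density_convention": "pairs",
        "hub_min": 5,
        "island_max": 1,
        "epoch_times_mya": {"ePIN": 180.0, "pre-PIN": 120.0, "post-PIN": 109.0},
    },
    "flexibility": {"temperature": 298.15, "minima_window_kcal": 5.0},
    "structure": {
        "sasa_probe_radius": 1.4,
        "sasa_n_points": 960,
        "turn_tolerance_deg": 30.0,
        "salt_bridge_cutoff": 4.0,
        "hbond_cutoff": 3.5,
    },
    "simulation": {
        "n0": 10,
        "p0": 0.25,
        "gain_rate": 0.001,
        "loss_rate": 0.005,
        "subfunc_prob": 0.0,
        "signal_mu": 8.0,
        "background_mu": 1.0,
        "noise_cv": 0.15,
        "n_reps": 3,
        "seed": 0,
    },
}


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class PipelineConfig:
    sections: dict[str, dict[str, Any]]

    def __getitem__(self, section: str) -> dict[str, Any]:
        return self.sections[section]

    def get(self, section: str, key: str) -> Any:
        return self.sections[section][key]


def _validate(doc: dict) -> dict[str, dict[str, Any]]:
    if not isinstance(doc, dict):
        raise ConfigError("config root must be a mapping")
    merged = {s: dict(vals) for s, vals in _DEFAULTS.items()}
    for section, values in doc.items():
        if section not in _SCHEMA:
            raise ConfigError(f"unknown config key: {section}")
        if not isinstance(values, dict):
            raise ConfigError(f"{section}: must be a mapping")
        for key, value in values.items():
            if key not in _SCHEMA[section]:
                raise ConfigError(f"unknown config key: {section}.{key}")
            expected = _SCHEMA[section][key]
            if expected is float and isinstance(value, int):
                value = float(value)
            if not isinstance(value, expected):
                raise ConfigError(
                    f"{section}.{key}: expected {expected.__name__}, "
                    f"got {type(value).__name__}"
                )
            merged[section][key] = value
    return merged


def load_config(source: Optional[Any] = None) -> PipelineConfig:
    """Load and validate a config from a YAML path/stream, dict, or None."""
    if source is None:
        doc: dict = {}
    elif isinstance(source, dict):
        doc = source
    else:
        if hasattr(source, "read"):
            doc = yaml.safe_load(source) or {}
        else:
            with open(source) as fh:
                doc = yaml.safe_load(fh) or {}
    return PipelineConfig(_validate(doc))


def config_hash(config: PipelineConfig) -> str:
    """Stable short hash of the fully-merged configuration."""
    canon = json.dumps(config.sections, sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:12]
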