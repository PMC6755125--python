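"""Run configuration: nested defaults, YAML round-trip, validation."""

from __future__ import annotations

import copy
import hashlib
import json
from pathlib import Path

import yaml

__all__ = ["DEFAULTS", "load_config", "save_config", "merge_config",
           "config_hash", "ConfigError"]


class ConfigError(ValueError):
    pass


#: every parameter has a default; stage sections mirror the pipeline modules
DEFAULTS: dict = {
    "format_version": 1,
    "seed": 0,
    "synthetic": {
        "n_domains": 2,
        "domain_radii": [20.0, 18.0, 18.0],
        "linker_lengths": [30, 30],
        "lysine_density": 0.08,
        "weights": [0.7, 0.3],
        "noise_level": 0.01,
        "n_links": 20,
        "decoy_rate": 0.0,
    },
    "poolgen": {
        "n_models": 500,
        "bond_length": 3.8,
        "clash_distance": 4.0,
        "max_regrow_attempts": 100,
    },
    "saxs": {
        "q_min": 0.006,
        "q_max": 0.5,
        "n_q": 160,
        "guinier_qrg_limit": 1.3,
        "vc_q_limit": 0.3,
        "pr_n_points": 101,
    },
    "ensemble": {
        "k_max": 10,
        "n_restarts": 4,
        "tol": 0.01,
    },
    "xlms": {
        "cutoff": 30.0,
        "min_satisfied": 1,
    },
    "csp": {
        "threshold": 0.15,
    },
}


def merge_config(base: dict, override: dict, _path: str = "") -> dict:
    """Recursive merge; unknown keys raise ConfigError naming the key."""
    out = copy.deepcopy(base)
    for key, value in override.items():
        here = f"{_path}.{key}" if _path else key
        if key not in base:
            raise ConfigError(f"unknown config key: {here}")
        if isinstance(base[key], dict):
            if not isinstance(value, dict):
                raise ConfigError(f"config key {here} must be a mapping")
            out[key] = merge_config(base[key], value, here)
        else:
            out[key] = value
    return out


def load_config(path: str | Path | None = None) -> dict:
    """Defaults, overridden by an optional YAML file."""
    if path is None:
        return copy.deepcopy(DEFAULTS)
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    if not isinstance(user, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    return merge_config(DEFAULTS, user)


def save_config(cfg: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True).encode()).hexdigest()[:16]
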