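"""Experiment configuration loading, validation and hashing."""
from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, fields
from pathlib import Path

import yaml

from .exceptions import ConfigError
from .experiments import ExperimentConfig

__all__ = ["load_config", "save_config", "config_hash"]

_FIELDS = {f.name for f in fields(ExperimentConfig)}
_LIST_FIELDS = {"fractions", "rhos"}


def load_config(path) -> ExperimentConfig:
    """Parse a YAML (or JSON; YAML is a superset) config file.

    Unknown keys are rejected by name; out-of-range values raise the same
    :class:`~biogaps.exceptions.ConfigError` the dataclass validation
    raises.  Missing keys take the documented defaults (n_runs=100,
    fraction=0.35, rho=0.75, ...).
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    raw = yaml.safe_load(path.read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError("config must be a mapping of option names to values")
    unknown = set(raw) - _FIELDS
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    for k in _LIST_FIELDS & set(raw):
        raw[k] = tuple(raw[k])
    try:
        return ExperimentConfig(**raw)
    except ConfigError:
        raise
    except (TypeError, ValueError) as exc:
        raise ConfigError(str(exc)) from exc


def save_config(config: ExperimentConfig, path) -> None:
    d = asdict(config)
    for k in _LIST_FIELDS:
        d[k] = list(d[k])
    Path(path).write_text(yaml.safe_dump(d, sort_keys=True))


def config_hash(config: ExperimentConfig) -> str:
    """SHA-256 of the canonical (key-sorted) JSON form; stable under key
    reordering in the source file."""
    d = asdict(config)
    for k in _LIST_FIELDS:
        d[k] = list(d[k])
    canon = json.dumps(d, sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()
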