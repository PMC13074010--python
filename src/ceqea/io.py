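"""Run configuration (YAML), mask serialization (JSON) and run manifests."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import yaml

from .encoder import EncoderConfig, PreprocessConfig
from .federation import FedConfig
from .optimizer import CEQEAConfig
from .quantum import BinaryMask
from .synth import SynthConfig

__all__ = ["RunConfig", "ConfigError", "load_config", "save_config", "save_mask", "load_mask", "write_manifest"]


class ConfigError(ValueError):
    """Invalid or unknown configuration content; message names the key path."""


@dataclass(frozen=True)
class RunConfig:
    """Nested run configuration with reference defaults throughout."""

    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    encoder: EncoderConfig = field(default_factory=EncoderConfig)
    ceqea: CEQEAConfig = field(default_factory=CEQEAConfig)
    federation: FedConfig = field(default_factory=FedConfig)
    synthesis: SynthConfig = field(default_factory=SynthConfig)
    seed: int = 0
    out_dir: str = "ceqea-output"


_SECTIONS = {
    "preprocess": PreprocessConfig,
    "encoder": EncoderConfig,
    "ceqea": CEQEAConfig,
    "federation": FedConfig,
    "synthesis": SynthConfig,
}


def _build_section(cls, payload: dict, path: str):
    valid = {f.name for f in fields(cls)}
    kwargs = {}
    for key, value in payload.items():
        if key not in valid:
            raise ConfigError(f"unknown configuration key '{path}.{key}'")
        if isinstance(value, list):
            value = tuple(value)
        kwargs[key] = value
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid value under '{path}': {exc}") from exc


def load_config(path) -> RunConfig:
    """Parse and validate a YAML run configuration.

    Missing sections and keys fall back to the reference defaults; an
    empty file therefore yields the all-defaults configuration.
    Unknown keys are rejected with their full key path.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    payload = yaml.safe_load(path.read_text()) or {}
    if not isinstance(payload, dict):
        raise ConfigError("top-level configuration must be a mapping")
    kwargs = {}
    for key, value in payload.items():
        if key in _SECTIONS:
            if not isinstance(value, dict):
                raise ConfigError(f"section '{key}' must be a mapping")
            kwargs[key] = _build_section(_SECTIONS[key], value, key)
        elif key in ("seed", "out_dir"):
            kwargs[key] = value
        else:
            raise ConfigError(f"unknown configuration key '{key}'")
    return RunConfig(**kwargs)


def _to_plain(obj):
    if dataclasses.is_dataclass(obj):
        return {f.name: _to_plain(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, tuple):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


def save_config(cfg: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(_to_plain(cfg), sort_keys=False))


def save_mask(mask: BinaryMask, path) -> None:
    """JSON mask format: {"n_tokens": N, "retained": [sorted indices]}."""
    payload = {"n_tokens": mask.n_tokens, "retained": sorted(int(i) for i in mask.retained_indices)}
    Path(path).write_text(json.dumps(payload, indent=2))


def load_mask(path) -> BinaryMask:
    try:
        payload = json.loads(Path(path).read_text())
        n = int(payload["n_tokens"])
        retained = payload["retained"]
    except (json.JSONDecodeError, KeyError, TypeError) as exc:
        raise ValueError(f"malformed mask file {path}: {exc}") from exc
    return BinaryMask.from_indices(n, retained)


def config_hash(cfg: RunConfig) -> str:
    return hashlib.sha256(json.dumps(_to_plain(cfg), sort_keys=True).encode()).hexdigest()[:16]


def write_manifest(cfg: RunConfig, seed: int, path) -> None:
    """Reproducibility manifest: config hash, seed, package version."""
    from . import __version__

    payload = {"config_hash": config_hash(cfg), "seed": seed, "version": __version__}
    Path(path).write_text(json.dumps(payload, indent=2))
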