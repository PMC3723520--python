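"""Flat parameter/config file handling (YAML or JSON) and resolved-config
provenance written alongside every CLI output."""

from __future__ import annotations

import json
from pathlib import Path

import yaml

from .model import ModelParameters

__all__ = ["load_mapping", "load_params", "write_resolved_config"]


def load_mapping(path) -> dict:
    """Read a flat key->value mapping from a YAML or JSON file."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: expected a flat mapping, got {type(data).__name__}")
    return data


def load_params(path) -> ModelParameters:
    """Load model parameters from a config file; keys must be exactly the
    ModelParameters field names (unknown keys are rejected)."""
    return ModelParameters.from_mapping(load_mapping(path))


def write_resolved_config(out_dir, config: dict) -> Path:
    """Write the fully resolved run configuration (plus package version) next
    to the outputs, so any run can be reproduced from its output directory."""
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    payload = dict(config)
    payload["fmbsim_version"] = __version__
    target = out_dir / "resolved_config.json"
    with open(target, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
    return target
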