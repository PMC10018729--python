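"""Run configuration: a YAML file echoed verbatim into every output directory."""

from __future__ import annotations

from pathlib import Path

import yaml

from .errors import ConfigError


def load_config(path) -> dict:
    """Load a YAML run config; the top level must be a mapping."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ConfigError(f"{path}: top level of config must be a mapping")
    return cfg


def require_section(cfg: dict, key: str) -> dict:
    if key not in cfg:
        raise ConfigError(f"config missing required section {key!r}")
    section = cfg[key]
    if not isinstance(section, dict):
        raise ConfigError(f"config section {key!r} must be a mapping")
    return section


def echo_config(cfg: dict, out_dir) -> None:
    """Write the effective config into the output directory for provenance."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    with open(out_dir / "config_used.yaml", "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
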