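"""Configuration handling: packaged data access, overrides, dotted paths."""

from __future__ import annotations

import copy
import hashlib
import io
import json
from importlib import resources
from pathlib import Path
from typing import Any

import pandas as pd
import yaml


class ConfigurationError(ValueError):
    """A scenario or compound configuration is inconsistent or incomplete."""


def _data_root():
    return resources.files("bupnet") / "data"


_yaml_cache: dict[str, dict] = {}
_csv_cache: dict[str, pd.DataFrame] = {}


def load_packaged_yaml(name: str) -> dict:
    """Load a YAML file shipped under ``bupnet/data`` (e.g. ``defaults.yaml``)."""
    if name not in _yaml_cache:
        text = (_data_root() / name).read_text(encoding="utf-8")
        _yaml_cache[name] = yaml.safe_load(text)
    return copy.deepcopy(_yaml_cache[name])


def load_packaged_csv(name: str) -> pd.DataFrame:
    if name not in _csv_cache:
        text = (_data_root() / name).read_text(encoding="utf-8")
        _csv_cache[name] = pd.read_csv(io.StringIO(text), comment="#")
    return _csv_cache[name].copy()


def load_defaults() -> dict:
    return load_packaged_yaml("defaults.yaml")


def packaged_compound_names() -> list[str]:
    comp_dir = _data_root() / "compounds"
    return sorted(p.name[: -len(".yaml")] for p in comp_dir.iterdir() if p.name.endswith(".yaml"))


def load_compound_config(name: str) -> dict:
    """Load one packaged compound file, or a user file if ``name`` is a path."""
    path = Path(name)
    if path.suffix in {".yaml", ".yml"} and path.exists():
        return yaml.safe_load(path.read_text(encoding="utf-8"))
    try:
        return load_packaged_yaml(f"compounds/{name}.yaml")
    except FileNotFoundError:
        raise ConfigurationError(f"unknown compound file: {name!r}") from None


def deep_merge(base: dict, override: dict | None) -> dict:
    """Recursively merge ``override`` into a copy of ``base``."""
    merged = copy.deepcopy(base)
    for key, value in (override or {}).items():
        if isinstance(value, dict) and isinstance(merged.get(key), dict):
            merged[key] = deep_merge(merged[key], value)
        else:
            merged[key] = copy.deepcopy(value)
    return merged


def get_path(config: dict, dotted: str) -> Any:
    """Resolve a dotted path like ``enzyme_concentrations.CYP2B6.liver``."""
    node: Any = config
    for part in dotted.split("."):
        if isinstance(node, dict):
            if part not in node:
                raise ConfigurationError(f"path {dotted!r}: no key {part!r}")
            node = node[part]
        elif isinstance(node, list):
            try:
                node = node[int(part)]
            except (ValueError, IndexError):
                raise ConfigurationError(f"path {dotted!r}: bad index {part!r}") from None
        else:
            raise ConfigurationError(f"path {dotted!r}: cannot descend into {type(node).__name__}")
    return node


def set_path(config: dict, dotted: str, value: Any) -> None:
    parts = dotted.split(".")
    node: Any = config
    for part in parts[:-1]:
        if isinstance(node, dict):
            if part not in node:
                raise ConfigurationError(f"path {dotted!r}: no key {part!r}")
            node = node[part]
        elif isinstance(node, list):
            node = node[int(part)]
        else:
            raise ConfigurationError(f"path {dotted!r}: cannot descend into {type(node).__name__}")
    last = parts[-1]
    if isinstance(node, dict):
        if last not in node:
            raise ConfigurationError(f"path {dotted!r}: no key {last!r}")
        node[last] = value
    elif isinstance(node, list):
        node[int(last)] = value
    else:
        raise ConfigurationError(f"path {dotted!r}: cannot assign into {type(node).__name__}")


def config_hash(config: dict) -> str:
    """Stable short hash of a configuration mapping, for run manifests."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
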