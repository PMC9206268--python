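"""YAML configuration loading.

One file with optional blocks ``io``, ``preprocess`` and ``simulate``;
every key falls back to the library default, so an empty (or absent) file
is valid. See ``config/default.yaml`` in the repository for an annotated
template.
"""

from __future__ import annotations

from dataclasses import fields
from pathlib import Path
from typing import Any

import yaml

from swaylab.preprocess import FilterSpec
from swaylab.sway_io import TrialDialect
from swaylab.synthetic_sway import SimulationConfig


def load_config(path: str | Path | None) -> dict[str, Any]:
    if path is None:
        return {}
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config root must be a mapping")
    return data


def _build(cls, block: dict[str, Any] | None, **overrides):
    block = dict(block or {})
    block.update({k: v for k, v in overrides.items() if v is not None})
    allowed = {f.name for f in fields(cls)}
    unknown = set(block) - allowed
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    return cls(**block)


def filter_spec(config: dict[str, Any]) -> FilterSpec:
    block = dict(config.get("preprocess") or {})
    block.pop("origin", None)  # handled by the pipeline, not the filter
    return _build(FilterSpec, block)


def origin_convention(config: dict[str, Any]) -> str:
    return (config.get("preprocess") or {}).get("origin", "trial_mean")


def trial_dialect(config: dict[str, Any]) -> TrialDialect:
    return _build(TrialDialect, config.get("io"))


def simulation_config(config: dict[str, Any], seed: int | None = None) -> SimulationConfig:
    block = dict(config.get("simulate") or {})
    if "hf_band_hz" in block:
        block["hf_band_hz"] = tuple(block["hf_band_hz"])
    return _build(SimulationConfig, block, seed=seed)
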