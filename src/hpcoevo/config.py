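"""Flat key-value (YAML) configuration for runs, sweeps and LHS ranges.

Keys use the same R-notation names as the parameter table
(``intrinsic_growth_rate_humans``, ...), so configuration files read
against the model description directly. Unknown keys are rejected by name;
missing keys fall back to the package's reference (full-coevolution)
setting. ``max_area`` accepts the token ``inf``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml

from .exceptions import ConfigError, ParameterError
from .params import HPCParams, INTEGER_FIELDS, PARAM_FIELD_NAMES

__all__ = ["RunConfig", "load_config", "save_config", "load_ranges", "load_design"]

_EXTRA_KEYS = (
    "initial_type_proportions_humans",
    "initial_type_proportions_plants",
    "output_dir",
    "verbosity",
)


@dataclass(frozen=True)
class RunConfig:
    """A validated parameter set plus optional run plumbing."""

    params: HPCParams
    initial_type_proportions_humans: tuple[float, ...] | None = None
    initial_type_proportions_plants: tuple[float, ...] | None = None
    output_dir: str | None = None
    verbosity: int = 0

    def initial_proportions(self) -> tuple[np.ndarray | None, np.ndarray | None]:
        h = (
            np.asarray(self.initial_type_proportions_humans, dtype=float)
            if self.initial_type_proportions_humans is not None
            else None
        )
        p = (
            np.asarray(self.initial_type_proportions_plants, dtype=float)
            if self.initial_type_proportions_plants is not None
            else None
        )
        return h, p


def _coerce(name: str, value):
    if name == "max_area" and isinstance(value, str):
        token = value.strip().lower().lstrip(".+")
        if token == "inf":
            return math.inf
        raise ConfigError(f"max_area: cannot parse {value!r} (use a number or 'inf')")
    if name in INTEGER_FIELDS:
        if isinstance(value, bool) or not isinstance(value, (int, float)):
            raise ConfigError(f"{name}: must be an integer, got {value!r}")
        if isinstance(value, float):
            if not value.is_integer():
                raise ConfigError(f"{name}: must be an integer, got {value!r}")
            value = int(value)
        return int(value)
    if isinstance(value, bool) or not isinstance(value, (int, float)):
        raise ConfigError(f"{name}: must be a number, got {value!r}")
    return float(value)


def _load_mapping(path) -> dict:
    text = Path(path).read_text()
    try:
        raw = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse {path}: {exc}") from exc
    if raw is None:
        return {}
    if not isinstance(raw, Mapping):
        raise ConfigError(f"{path}: expected a key-value mapping at the top level")
    return dict(raw)


def load_config(path) -> RunConfig:
    """Load and validate a run configuration file.

    An empty file yields the default (reference) setting. Unknown keys and
    bound violations raise :class:`~hpcoevo.exceptions.ConfigError` naming
    the offending key and constraint.
    """
    raw = _load_mapping(path)
    extras: dict = {}
    for key in _EXTRA_KEYS:
        if key in raw:
            extras[key] = raw.pop(key)
    param_values = {}
    for key, value in raw.items():
        if key not in PARAM_FIELD_NAMES:
            raise ConfigError(f"unknown configuration key: {key!r}")
        param_values[key] = _coerce(key, value)
    try:
        params = HPCParams(**param_values)
    except ParameterError as exc:
        raise ConfigError(str(exc)) from exc
    for key in ("initial_type_proportions_humans", "initial_type_proportions_plants"):
        if key in extras and extras[key] is not None:
            extras[key] = tuple(float(x) for x in extras[key])
    return RunConfig(params=params, **extras)


def save_config(config: RunConfig, path) -> None:
    """Write a configuration so that ``load_config`` round-trips it exactly."""
    payload: dict = dict(config.params.to_dict())
    if config.initial_type_proportions_humans is not None:
        payload["initial_type_proportions_humans"] = list(
            config.initial_type_proportions_humans
        )
    if config.initial_type_proportions_plants is not None:
        payload["initial_type_proportions_plants"] = list(
            config.initial_type_proportions_plants
        )
    if config.output_dir is not None:
        payload["output_dir"] = config.output_dir
    if config.verbosity:
        payload["verbosity"] = config.verbosity
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def load_ranges(path) -> dict[str, tuple[float, float]]:
    """Load per-parameter ``[lower, upper]`` ranges for LHS exploration."""
    raw = _load_mapping(path)
    ranges = {}
    for key, value in raw.items():
        if key not in PARAM_FIELD_NAMES:
            raise ConfigError(f"unknown parameter in ranges file: {key!r}")
        try:
            lo, hi = (float(v) for v in value)
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"{key}: expected a [lower, upper] pair") from exc
        if lo > hi:
            raise ConfigError(f"{key}: lower bound exceeds upper bound")
        ranges[key] = (lo, hi)
    if not ranges:
        raise ConfigError(f"{path}: ranges file is empty")
    return ranges


def load_design(path):
    """Load a sweep design file (``mode: grid`` with per-parameter value
    lists, or ``mode: lhs`` with ranges, ``n_samples`` and ``seed``)."""
    from .experiments import SweepDesign

    raw = _load_mapping(path)
    mode = raw.pop("mode", "grid")
    seed = int(raw.pop("seed", 0))
    n_samples = int(raw.pop("n_samples", 1))
    max_iterations = raw.pop("max_iterations", None)
    if max_iterations is not None:
        max_iterations = int(max_iterations)
    body = raw.pop("parameters", None)
    if raw:
        raise ConfigError(f"unknown design key: {sorted(raw)[0]!r}")
    if body is None:
        raise ConfigError("design file must contain a 'parameters' mapping")
    if mode == "grid":
        grids = {k: [float(v) for v in vs] for k, vs in body.items()}
        return SweepDesign.grid(grids, seed=seed, max_iterations=max_iterations)
    if mode == "lhs":
        ranges = {k: (float(v[0]), float(v[1])) for k, v in body.items()}
        return SweepDesign.lhs(
            ranges, n_samples=n_samples, seed=seed, max_iterations=max_iterations
        )
    raise ConfigError(f"unknown design mode: {mode!r}")
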