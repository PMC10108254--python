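"""Configuration handling.

A single YAML document drives the whole pipeline: every constant the method
takes from cited literature (allometric coefficients, wood-density ratios,
carbon fractions, decomposition rate constants) plus the method parameters
(chamber geometry, trap areas, class bounds) and the synthetic-landscape
design.  ``load_config`` deep-merges a user file over the packaged defaults,
so a user file only needs the keys it overrides.
"""

from __future__ import annotations

import copy
from importlib import resources
from pathlib import Path
from typing import Any, Mapping

import yaml

from .errors import ConfigError

AGE_CLASSES = ("initiation", "young", "middle_aged", "mature", "old")
SPECIES = ("pine", "spruce", "birch", "other_deciduous")
COMPONENTS = ("stem", "branches", "foliage", "coarse_roots")
PFTS = ("herbs", "shrubs", "mosses", "lichens")


def default_config() -> dict[str, Any]:
    """Return a fresh copy of the packaged default configuration."""
    text = resources.files("borealcarbon").joinpath("default_config.yaml").read_text()
    return yaml.safe_load(text)


def _deep_merge(base: dict, override: Mapping) -> dict:
    out = copy.deepcopy(base)
    for key, val in override.items():
        if key in out and isinstance(out[key], dict) and isinstance(val, Mapping):
            out[key] = _deep_merge(out[key], val)
        else:
            out[key] = copy.deepcopy(val)
    return out


def load_config(path: str | Path | None = None,
                overrides: Mapping | None = None) -> dict[str, Any]:
    """Load configuration, merging ``path`` (then ``overrides``) over defaults."""
    cfg = default_config()
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, Mapping):
            raise ConfigError(f"config file {path} is not a mapping")
        cfg = _deep_merge(cfg, user)
    if overrides:
        cfg = _deep_merge(cfg, overrides)
    validate_config(cfg)
    return cfg


def validate_config(cfg: Mapping) -> None:
    """Sanity checks that fail fast on incoherent configuration."""
    bounds = cfg["site"]["age_class_bounds"]
    for cls in AGE_CLASSES:
        if cls not in bounds:
            raise ConfigError(f"age_class_bounds missing class '{cls}'")
        lo, hi = bounds[cls]
        if not 0 <= lo <= hi:
            raise ConfigError(f"age_class_bounds for '{cls}' invalid: {lo}..{hi}")
    for sp in SPECIES:
        table = cfg["allometry"].get(sp)
        if table is None:
            raise ConfigError(f"allometry missing species '{sp}'")
        for comp in COMPONENTS:
            row = table.get(comp)
            if row is None:
                raise ConfigError(f"allometry missing ({sp}, {comp})")
            if row["c"] <= 0:
                raise ConfigError(f"allometry ({sp}, {comp}): c must be > 0")
    if cfg["site"]["plot_radius_m"] <= 0:
        raise ConfigError("plot_radius_m must be > 0")
    if not 0 < cfg["carbon"]["live_c_fraction"] <= 1:
        raise ConfigError("live_c_fraction must be in (0, 1]")
    for cls, k in _iter_decay_constants(cfg["decay_constants"]):
        if k < 0:
            raise ConfigError(f"decay constant {cls} negative")
    syn = cfg.get("synthetic", {})
    counts = syn.get("class_counts", {})
    for cls, n in counts.items():
        if n < 0:
            raise ConfigError(f"synthetic class count for '{cls}' negative")


def _iter_decay_constants(table: Mapping):
    for sp, positions in table.items():
        for pos, classes in positions.items():
            for dc, k in classes.items():
                yield (sp, pos, dc), float(k)


def age_class_of(age: int | float, bounds: Mapping[str, tuple]) -> str:
    """Map a stand age to its age class.

    Ages falling in the gaps between class ranges (the field design has
    them: e.g. 28-30 yr) are assigned to the nearest class by range midpoint
    distance so every stand maps to exactly one class.
    """
    if age < 0:
        raise ConfigError(f"stand age must be >= 0, got {age}")
    best, best_dist = None, None
    for cls in AGE_CLASSES:
        lo, hi = bounds[cls]
        if lo <= age <= hi:
            return cls
        dist = min(abs(age - lo), abs(age - hi))
        if best_dist is None or dist < best_dist:
            best, best_dist = cls, dist
    return best
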