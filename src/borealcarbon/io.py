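"""Typed CSV readers/writers for every pipeline table.

All tables are plain UTF-8 CSV with a fixed documented header, decimal
points, and fixed per-column units.  ``read_table`` validates each row
against the field invariants of its schema and reports failures with the
table name, row number and stand id.  Every writer/reader pair round-trips
to <= 1e-9 relative tolerance (floats are written at full precision).

Schemas
-------
stands.csv      stand_id, age, age_class, species_group, soil_type,
                plot_radius, additional
trees.csv       stand_id, tree_id, year, dbh, species, status, decay_class
litter.csv      stand_id, year, trap_id, dry_mass_g
understory.csv  stand_id, year, month, pft, dry_mass_g_m2
shrubgrowth.csv stand_id, year, index  (shoot-increment index for
                interannual understory scaling)
ingrowth.csv    stand_id, core_id, diameter_cm, depth_cm,
                installation_span_yr, ingrowth_dry_mass_g
deadwood.csv    stand_id, year, position, species, decay_class,
                carbon_mass_g_m2
chambers.csv    stand_id, campaign_id, timestamp, seconds, ppm, ts_c,
                swc_pct, ta_bc_c, pressure_kpa  (long format: one row per
                concentration sample, campaign metadata repeated)
soiltemp.csv    timestamp column plus one half-hourly soil-temperature
                column per stand (wide format)
drivers.csv     stand_id, slope, ns_aspect, ew_aspect, b_t, lai_max,
                o_depth, cn_ratio, bd, swc, ts, soc, ba
budgets.csv     stand_id, year + the 14 budget components in documented
                order (see domain.BUDGET_COMPONENTS)
"""

from __future__ import annotations

import logging
import time
from contextlib import contextmanager
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from .domain import (BUDGET_COMPONENTS, DEADWOOD_POSITIONS, TREE_STATUSES,
                     UNDERSTORY_MONTHS, CarbonBudget)
from .config import AGE_CLASSES, PFTS, SPECIES
from .errors import SchemaError, ValidationError

log = logging.getLogger("borealcarbon")


@contextmanager
def stage_timer(name: str):
    """Log wall-time of a pipeline stage to stderr (via the package logger)."""
    t0 = time.perf_counter()
    yield
    log.info("stage %-24s %.2f s", name, time.perf_counter() - t0)


@dataclass
class TableSchema:
    name: str
    columns: dict[str, str]                 # column -> 'str'|'int'|'float'|'opt_float'
    validators: list[Callable[[pd.DataFrame], None]] = field(default_factory=list)

    @property
    def column_names(self) -> list[str]:
        return list(self.columns)


def _check(df: pd.DataFrame, table: str, mask: pd.Series, message: str) -> None:
    """Raise a ValidationError for the first row where ``mask`` is True."""
    if mask.any():
        idx = int(np.flatnonzero(mask.to_numpy())[0])
        ctx = None
        if "stand_id" in df.columns:
            ctx = f"stand {df['stand_id'].iloc[idx]}"
        raise ValidationError(table, message, row=idx, context=ctx)


def _member_check(col: str, allowed: tuple, optional: bool = False):
    def validator(df: pd.DataFrame, _col=col, _allowed=allowed):
        vals = df[_col]
        bad = ~vals.isin(_allowed)
        if optional:
            bad &= vals.notna()
        _check(df, "", bad, f"column '{_col}' outside {{{', '.join(map(str, _allowed))}}}")
    return validator


def _nonneg(col: str):
    def validator(df: pd.DataFrame, _col=col):
        _check(df, "", df[_col] < 0, f"column '{_col}' must be >= 0")
    return validator


def _positive(col: str):
    def validator(df: pd.DataFrame, _col=col):
        _check(df, "", df[_col] <= 0, f"column '{_col}' must be > 0")
    return validator


def _validate_trees(df: pd.DataFrame) -> None:
    dead = df["status"].isin(("dead_standing", "dead_downed"))
    _check(df, "", dead & df["decay_class"].isna(),
           "dead trees require a decay_class")
    _check(df, "", (df["status"] == "live") & df["decay_class"].notna(),
           "live trees must not carry a decay_class")


def _validate_drivers(df: pd.DataFrame) -> None:
    for col in ("ns_aspect", "ew_aspect"):
        _check(df, "", df[col].abs() > 1 + 1e-12,
               f"column '{col}' must lie in [-1, 1]")
    for col in ("b_t", "o_depth", "cn_ratio", "bd", "swc", "soc", "ba", "slope"):
        _check(df, "", df[col] < 0, f"column '{col}' must be >= 0")


def _validate_budgets(df: pd.DataFrame) -> None:
    check_budget_identities(df)


SCHEMAS: dict[str, TableSchema] = {}


def _register(schema: TableSchema) -> TableSchema:
    SCHEMAS[schema.name] = schema
    return schema


STANDS = _register(TableSchema(
    "stands",
    {"stand_id": "str", "age": "int", "age_class": "str",
     "species_group": "str", "soil_type": "str", "plot_radius": "float",
     "additional": "int"},
    [_nonneg("age"), _positive("plot_radius"),
     _member_check("age_class", AGE_CLASSES),
     _member_check("species_group", ("pine", "spruce")),
     _member_check("soil_type", ("till", "sediment"))],
))

TREES = _register(TableSchema(
    "trees",
    {"stand_id": "str", "tree_id": "str", "year": "int", "dbh": "float",
     "species": "str", "status": "str", "decay_class": "opt_float"},
    [_nonneg("dbh"), _member_check("species", SPECIES),
     _member_check("status", TREE_STATUSES), _validate_trees],
))

LITTER = _register(TableSchema(
    "litter",
    {"stand_id": "str", "year": "int", "trap_id": "str", "dry_mass_g": "float"},
    [_nonneg("dry_mass_g")],
))

UNDERSTORY = _register(TableSchema(
    "understory",
    {"stand_id": "str", "year": "int", "month": "str", "pft": "str",
     "dry_mass_g_m2": "float"},
    [_nonneg("dry_mass_g_m2"), _member_check("month", UNDERSTORY_MONTHS),
     _member_check("pft", PFTS)],
))

SHRUBGROWTH = _register(TableSchema(
    "shrubgrowth",
    {"stand_id": "str", "year": "int", "index": "float"},
    [_positive("index")],
))

INGROWTH = _register(TableSchema(
    "ingrowth",
    {"stand_id": "str", "core_id": "str", "diameter_cm": "float",
     "depth_cm": "float", "installation_span_yr": "float",
     "ingrowth_dry_mass_g": "float"},
    [_positive("diameter_cm"), _positive("depth_cm"),
     _positive("installation_span_yr"), _nonneg("ingrowth_dry_mass_g")],
))

DEADWOOD = _register(TableSchema(
    "deadwood",
    {"stand_id": "str", "year": "int", "position": "str", "species": "str",
     "decay_class": "int", "carbon_mass_g_m2": "float"},
    [_member_check("position", DEADWOOD_POSITIONS),
     _member_check("species", SPECIES), _nonneg("carbon_mass_g_m2")],
))

CHAMBERS = _register(TableSchema(
    "chambers",
    {"stand_id": "str", "campaign_id": "str", "timestamp": "str",
     "seconds": "float", "ppm": "float", "ts_c": "float", "swc_pct": "float",
     "ta_bc_c": "float", "pressure_kpa": "float"},
    [_nonneg("seconds"), _positive("ppm"), _positive("pressure_kpa")],
))

DRIVERS = _register(TableSchema(
    "drivers",
    {"stand_id": "str", "slope": "float", "ns_aspect": "float",
     "ew_aspect": "float", "b_t": "float", "lai_max": "opt_float",
     "o_depth": "float", "cn_ratio": "float", "bd": "float", "swc": "float",
     "ts": "float", "soc": "float", "ba": "float"},
    [_validate_drivers],
))

BUDGETS = _register(TableSchema(
    "budgets",
    {"stand_id": "str", "year": "int",
     **{c: "float" for c in BUDGET_COMPONENTS}},
    [_validate_budgets],
))


_DTYPE_MAP = {"str": "string", "int": "int64", "float": "float64",
              "opt_float": "float64"}


def read_table(path_or_df: str | Path | pd.DataFrame,
               schema: TableSchema) -> pd.DataFrame:
    """Read and validate one table; row order preserved.

    Accepts a path to a CSV file or an in-memory DataFrame (the pipeline
    passes bundles around without touching disk).
    """
    if isinstance(path_or_df, pd.DataFrame):
        df = path_or_df.copy()
    else:
        df = pd.read_csv(path_or_df, dtype="object")
    missing = [c for c in schema.columns if c not in df.columns]
    if missing:
        raise SchemaError(schema.name, f"missing column(s): {', '.join(missing)}")
    df = df[schema.column_names]
    for col, kind in schema.columns.items():
        try:
            if kind == "str":
                df[col] = df[col].astype("string")
            elif kind == "int":
                df[col] = pd.to_numeric(df[col], errors="raise").astype("int64")
            elif kind in ("float", "opt_float"):
                df[col] = pd.to_numeric(df[col], errors="raise").astype("float64")
        except (ValueError, TypeError) as exc:
            raise ValidationError(schema.name,
                                  f"unparseable value in column '{col}': {exc}")
        if kind == "float" and df[col].isna().any():
            idx = int(np.flatnonzero(df[col].isna().to_numpy())[0])
            raise ValidationError(schema.name, f"missing value in column '{col}'",
                                  row=idx)
    for validator in schema.validators:
        try:
            validator(df)
        except ValidationError as exc:
            raise ValidationError(schema.name, str(exc).split("] ", 1)[-1],
                                  row=exc.row, context=exc.context) from None
    return df.reset_index(drop=True)


def write_table(df: pd.DataFrame, path: str | Path, schema: TableSchema) -> None:
    """Validate ``df`` against ``schema`` and write it as CSV."""
    validated = read_table(df, schema)
    validated.to_csv(path, index=False)


def read_soiltemp(path_or_df: str | Path | pd.DataFrame) -> pd.DataFrame:
    """Read the wide half-hourly soil-temperature table.

    First column is the timestamp; every further column is one stand's
    10-cm soil-temperature series (degC).
    """
    if isinstance(path_or_df, pd.DataFrame):
        df = path_or_df.copy()
    else:
        df = pd.read_csv(path_or_df)
    if df.shape[1] < 2:
        raise SchemaError("soiltemp", "needs a timestamp column and >= 1 stand column")
    first = df.columns[0]
    if first != "timestamp":
        raise SchemaError("soiltemp", f"first column must be 'timestamp', got '{first}'")
    for col in df.columns[1:]:
        df[col] = pd.to_numeric(df[col], errors="coerce")
    return df


def check_budget_identities(df: pd.DataFrame, rtol: float = 1e-9) -> None:
    """Verify the five budget identities on every row of a budgets table."""
    identities = {
        "npp_t": df["anpp_t"] + df["bnpp_t_cr"] + df["bnpp_t_fr"],
        "npp_u": df["anpp_u"] + df["bnpp_u"],
        "bnpp_fr": df["bnpp_u"] + df["bnpp_t_fr"],
        "npp": df["npp_t"] + df["npp_u"],
        "rh": df["rh_s"] + df["rh_dw"],
        "nep": df["npp"] - df["rh"],
    }
    for col, expect in identities.items():
        bad = ~np.isclose(df[col], expect, rtol=rtol, atol=1e-9)
        if bad.any():
            idx = int(np.flatnonzero(bad)[0])
            raise ValidationError(
                "budgets", f"identity for '{col}' violated "
                f"({df[col].iloc[idx]!r} vs {expect.iloc[idx]!r})",
                row=idx, context=f"stand {df['stand_id'].iloc[idx]}")
    for comp in BUDGET_COMPONENTS:
        if comp == "nep":
            continue
        bad = df[comp] < -1e-9
        if bad.any():
            idx = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValidationError("budgets", f"component '{comp}' negative",
                                  row=idx,
                                  context=f"stand {df['stand_id'].iloc[idx]}")


def write_budget_table(budgets: pd.DataFrame | list[CarbonBudget],
                       path: str | Path) -> None:
    """Write budgets.csv, refusing to emit rows that violate the identities."""
    if not isinstance(budgets, pd.DataFrame):
        budgets = pd.DataFrame([b.__dict__ for b in budgets])
    write_table(budgets, path, BUDGETS)


BUNDLE_TABLES = ("stands", "trees", "litter", "understory", "shrubgrowth",
                 "ingrowth", "deadwood", "chambers", "drivers")


def write_bundle(bundle: Mapping[str, pd.DataFrame], out_dir: str | Path) -> None:
    """Write a full measurement bundle (all campaign tables) to a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name in BUNDLE_TABLES:
        if name in bundle:
            write_table(bundle[name], out / f"{name}.csv", SCHEMAS[name])
    if "soiltemp" in bundle:
        bundle["soiltemp"].to_csv(out / "soiltemp.csv", index=False)


def read_bundle(in_dir: str | Path) -> dict[str, pd.DataFrame]:
    """Read a measurement bundle directory back into validated DataFrames."""
    src = Path(in_dir)
    bundle: dict[str, pd.DataFrame] = {}
    for name in BUNDLE_TABLES:
        f = src / f"{name}.csv"
        if f.exists():
            bundle[name] = read_table(f, SCHEMAS[name])
    f = src / "soiltemp.csv"
    if f.exists():
        bundle["soiltemp"] = read_soiltemp(f)
    return bundle
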