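"""Tree net-primary-production accounting.

Biometric tree NPP from repeated stand inventories: allometric biomass
pools per tree (ln-linear d/(d+c) family, DBH-driven), annual diameter
increments, mortality transfers to the dead-wood pool, annual litterfall
from funnel traps, and age-based imputation of tree biomass and litterfall
for recent clear-cuts.

Production convention: trees dying within an inventory interval keep their
interval growth in NPP (the growth happened) and enter the dead-wood pool
at their death-year biomass.  Harvested trees (status 'removed') leave the
accounting entirely: their biomass is dropped from both the start- and
end-of-interval live pools, so thinning does not show up as negative
production.
"""

from __future__ import annotations

import logging
import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, ValidationError

log = logging.getLogger("borealcarbon")

ABOVE_COMPONENTS = ("stem", "branches", "foliage")
KG_PER_M2_TO_MG_PER_HA = 10.0       # 1 kg m-2 = 10 Mg ha-1


def tree_biomass(dbh: float, species: str, component: str,
                 coeffs: Mapping) -> float:
    """Dry mass (kg) of one biomass component of one tree.

    ln(B) = a + b * d/(d+c) with d = DBH in cm; strictly increasing in d
    for b > 0.
    """
    if dbh < 0:
        raise ValueError(f"dbh must be >= 0, got {dbh}")
    try:
        row = coeffs[species][component]
    except KeyError:
        raise ConfigError(
            f"no allometric coefficients for ({species}, {component})")
    a, b, c = float(row["a"]), float(row["b"]), float(row["c"])
    return math.exp(a + b * dbh / (dbh + c))


def tree_biomass_above(dbh: float, species: str, coeffs: Mapping) -> float:
    """Aboveground dry mass (kg): stem + branches + foliage."""
    return sum(tree_biomass(dbh, species, comp, coeffs)
               for comp in ABOVE_COMPONENTS)


def stand_biomass_pools(trees: pd.DataFrame, plot_radius: float,
                        coeffs: Mapping,
                        dead_density_ratio: Mapping[int, float],
                        live_c_fraction: float = 0.5,
                        dead_c_fraction: Mapping[int, float] | None = None,
                        ) -> dict[str, float]:
    """Per-area biomass and carbon pools for one stand-year tree table.

    Returns a dict with live/dead, above/coarse-root pools in Mg ha-1
    (dry mass) and g C m-2.  Dead-tree pools apply the decay-class density
    ratio to the live-equivalent allometric mass and a decay-class-specific
    C fraction.  Pools are additive over trees; per-area scaling divides by
    the plot area pi * r^2.
    """
    if plot_radius <= 0:
        raise ValueError("plot_radius must be > 0")
    area_m2 = math.pi * plot_radius ** 2
    if dead_c_fraction is None:
        dead_c_fraction = {}
    pools_kg = {"live_above": 0.0, "live_cr": 0.0,
                "dead_above": 0.0, "dead_cr": 0.0}
    pools_gc = {"live_above": 0.0, "live_cr": 0.0,
                "dead_above": 0.0, "dead_cr": 0.0}
    for row in trees.itertuples(index=False):
        if row.status == "removed":
            continue
        above = tree_biomass_above(row.dbh, row.species, coeffs)
        cr = tree_biomass(row.dbh, row.species, "coarse_roots", coeffs)
        if row.status == "live":
            pools_kg["live_above"] += above
            pools_kg["live_cr"] += cr
            pools_gc["live_above"] += above * live_c_fraction
            pools_gc["live_cr"] += cr * live_c_fraction
        else:
            dc = int(row.decay_class)
            if dc not in dead_density_ratio:
                raise ValidationError(
                    "trees", f"unknown decay class {dc}",
                    context=f"stand {row.stand_id}")
            ratio = dead_density_ratio[dc]
            cfrac = dead_c_fraction.get(dc, live_c_fraction)
            pools_kg["dead_above"] += above * ratio
            pools_kg["dead_cr"] += cr * ratio
            pools_gc["dead_above"] += above * ratio * cfrac
            pools_gc["dead_cr"] += cr * ratio * cfrac
    out: dict[str, float] = {}
    for key in pools_kg:
        out[f"{key}_mg_ha"] = pools_kg[key] / area_m2 * KG_PER_M2_TO_MG_PER_HA
        out[f"{key}_gc_m2"] = pools_gc[key] / area_m2 * 1000.0
    return out


def annual_increment(dbh_by_year: Mapping[int, float] | None = None,
                     ring_widths_mm: Sequence[float] | None = None,
                     shrink_tolerance_cm: float = 0.1,
                     ) -> dict[int, float]:
    """Per-year DBH increment (cm yr-1) for one tree.

    Inventory-based: linear interpolation of DBH between inventory years;
    the increment for year y is (DBH_y - DBH_{y-1}) across the spanned
    interval.  Ring-width based: each ring is a radial increment, so the
    annual DBH increment is twice the ring width; ring series are assigned
    backwards from the last inventory year to back-cast years without
    repeated inventories.

    A shrinking DBH beyond ``shrink_tolerance_cm`` triggers a warning and
    the increment is clamped to 0 (live trees do not shrink; apparent
    shrinkage is tape/measurement error).
    """
    increments: dict[int, float] = {}
    if dbh_by_year:
        years = sorted(dbh_by_year)
        for y0, y1 in zip(years[:-1], years[1:]):
            span = y1 - y0
            delta = (dbh_by_year[y1] - dbh_by_year[y0]) / span
            if delta < 0:
                if -delta * span > shrink_tolerance_cm:
                    log.warning("DBH shrink %.2f cm over %d-%d clamped to 0",
                                -delta * span, y0, y1)
                delta = 0.0
            for y in range(y0 + 1, y1 + 1):
                increments[y] = delta
        if ring_widths_mm is not None and years:
            first = years[0]
            for i, rw in enumerate(reversed(list(ring_widths_mm))):
                y = first - i
                if y not in increments:
                    increments[y] = 2.0 * rw / 10.0   # mm radial -> cm diameter
    elif ring_widths_mm is not None:
        raise ValueError("ring-width back-casting needs at least one inventory year")
    return increments


def anpp_trees(delta_b_live_above: float, mortality_above: float,
               litterfall: float) -> float:
    """Aboveground tree NPP: live-pool change + mortality + litterfall.

    All terms g C m-2 yr-1; mortality and litterfall must be >= 0, the
    live-pool change may be negative (passed through with a warning, since
    harvest removals are excluded upstream).
    """
    if mortality_above < 0 or litterfall < 0:
        raise ValueError("mortality and litterfall must be >= 0")
    if delta_b_live_above < 0:
        log.warning("negative live aboveground pool change %.1f g C m-2 yr-1 "
                    "passed through", delta_b_live_above)
    return delta_b_live_above + mortality_above + litterfall


def bnpp_coarse_roots(delta_b_cr_live: float, mortality_cr: float) -> float:
    """Coarse-root tree NPP: live coarse-root pool change + mortality."""
    if mortality_cr < 0:
        raise ValueError("mortality must be >= 0")
    result = delta_b_cr_live + mortality_cr
    if result < 0:
        log.warning("negative coarse-root production %.1f g C m-2 yr-1 "
                    "passed through", result)
    return result


def litterfall_annual(trap_masses_g: Sequence[float], trap_area_m2: float,
                      c_fraction: float = 0.5) -> float:
    """Annual litterfall L (g C m-2 yr-1) from funnel-trap collections.

    L = c_fraction * (total dry mass) / (n_traps * trap_area).
    """
    masses = list(trap_masses_g)
    if len(masses) < 1:
        raise ValueError("need at least one litter trap")
    if trap_area_m2 <= 0:
        raise ValueError("trap_area_m2 must be > 0")
    return c_fraction * sum(masses) / (len(masses) * trap_area_m2)


def fit_age_relationship(ages: Sequence[float], values: Sequence[float]
                         ) -> tuple[float, float]:
    """Least-squares line value = intercept + slope * age through reference
    stands; used for clear-cut imputation.  Requires >= 2 points."""
    ages = np.asarray(ages, dtype=float)
    values = np.asarray(values, dtype=float)
    if ages.size < 2:
        raise ValueError("need >= 2 reference stands for an age relationship")
    slope, intercept = np.polyfit(ages, values, 1)
    return float(intercept), float(slope)


def impute_clearcut_tree_components(age: float,
                                    ref_ages: Sequence[float],
                                    ref_biomass: Sequence[float],
                                    ref_litter: Sequence[float],
                                    ) -> tuple[float, float]:
    """Impute (tree biomass, litterfall) for a recent clear-cut from the
    age relationships fitted over the remaining initiation-class stands.

    Predictions are clamped at 0 (a monotone linear fit extrapolated to
    very young ages can go negative).
    """
    b0, b1 = fit_age_relationship(ref_ages, ref_biomass)
    l0, l1 = fit_age_relationship(ref_ages, ref_litter)
    biomass = max(0.0, b0 + b1 * age)
    litter = max(0.0, l0 + l1 * age)
    return biomass, litter


def stand_production_series(trees: pd.DataFrame, litter_by_year: Mapping[int, float],
                            plot_radius: float, coeffs: Mapping,
                            dead_density_ratio: Mapping[int, float],
                            live_c_fraction: float = 0.5,
                            dead_c_fraction: Mapping[int, float] | None = None,
                            ) -> pd.DataFrame:
    """ANPP_t and BNPP_t_cr per year for one stand from its inventory table.

    For each consecutive inventory pair (y0, y1):

    * live cohort (live in both years): pool change from allometric mass;
    * mortality cohort (live at y0, dead at y1): death-year biomass counts
      as production (growth) at the live C fraction;
    * removed cohort (harvest): dropped from both sides;
    * recruits (first seen at y1): their full y1 biomass counts as ingrowth
      production.

    Returns a DataFrame indexed by year with columns anpp_t, bnpp_t_cr, l,
    delta_b_live_above, mortality_above (g C m-2 yr-1).
    """
    area_m2 = math.pi * plot_radius ** 2
    to_gc = live_c_fraction * 1000.0 / area_m2   # kg/plot -> g C m-2

    years = sorted(trees["year"].unique())
    by_year = {y: trees[trees["year"] == y].set_index("tree_id")
               for y in years}
    rows = []
    for y0, y1 in zip(years[:-1], years[1:]):
        t0, t1 = by_year[y0], by_year[y1]
        delta_above = delta_cr = 0.0
        mort_above = mort_cr = 0.0
        for tid, r1 in t1.iterrows():
            if r1["status"] == "removed":
                continue
            above1 = tree_biomass_above(r1["dbh"], r1["species"], coeffs)
            cr1 = tree_biomass(r1["dbh"], r1["species"], "coarse_roots", coeffs)
            in_prev = tid in t0.index
            r0 = t0.loc[tid] if in_prev else None
            prev_live = in_prev and r0["status"] == "live"
            if r1["status"] == "live":
                if prev_live:
                    above0 = tree_biomass_above(r0["dbh"], r0["species"], coeffs)
                    cr0 = tree_biomass(r0["dbh"], r0["species"],
                                       "coarse_roots", coeffs)
                    delta_above += above1 - above0
                    delta_cr += cr1 - cr0
                else:
                    delta_above += above1          # recruit / ingrowth
                    delta_cr += cr1
            elif prev_live:                        # died within the interval
                above0 = tree_biomass_above(r0["dbh"], r0["species"], coeffs)
                cr0 = tree_biomass(r0["dbh"], r0["species"],
                                   "coarse_roots", coeffs)
                delta_above -= above0
                delta_cr -= cr0
                mort_above += above1
                mort_cr += cr1
        span = y1 - y0
        litter = float(litter_by_year.get(y1, 0.0))
        rows.append({
            "year": y1,
            "delta_b_live_above": delta_above * to_gc / span,
            "mortality_above": mort_above * to_gc / span,
            "l": litter,
            "anpp_t": anpp_trees(delta_above * to_gc / span,
                                 mort_above * to_gc / span, litter),
            "bnpp_t_cr": bnpp_coarse_roots(delta_cr * to_gc / span,
                                           mort_cr * to_gc / span),
        })
    return pd.DataFrame(rows).set_index("year")
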