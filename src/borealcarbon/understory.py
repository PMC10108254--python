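"""Understory net primary production and fine-root partitioning.

ANPP of the understory comes from seasonal clip harvests: herb production
equals peak (August) herb biomass; shrub, moss and lichen production is the
June-to-August pool increase (floored at 0 per functional type, since
production cannot be negative).  Fine-root production (trees + understory
together, BNPP_fr) comes from ingrowth cores and is split into understory
(BNPP_u) and tree (BNPP_t_fr) shares using the root-to-shoot ratio of the
recent clear-cut stands, where tree fine roots are assumed negligible and
all ingrowth is understory.
"""

from __future__ import annotations

import logging
import math
from typing import Mapping, Sequence

import pandas as pd

from .errors import ValidationError

log = logging.getLogger("borealcarbon")


def anpp_understory(harvests: pd.DataFrame, c_fraction: float = 0.5) -> float:
    """Understory aboveground NPP (g C m-2 yr-1) from one stand's clips.

    ``harvests`` holds columns month ('june'/'august'), pft, dry_mass_g_m2.
    ANPP_u = c_fraction * [herbs_august + sum over other pfts of
    max(0, august - june)].
    """
    total = 0.0
    for pft, grp in harvests.groupby("pft"):
        masses = grp.set_index("month")["dry_mass_g_m2"]
        if pft == "herbs":
            if "august" not in masses.index:
                raise ValidationError("understory",
                                      "missing august harvest for pft 'herbs'")
            total += float(masses["august"])
        else:
            for month in ("june", "august"):
                if month not in masses.index:
                    raise ValidationError(
                        "understory", f"missing {month} harvest for pft '{pft}'")
            total += max(0.0, float(masses["august"]) - float(masses["june"]))
    return c_fraction * total


def bnpp_fineroot_from_ingrowth(cores: pd.DataFrame,
                                c_fraction: float = 0.5) -> float:
    """Fine-root production BNPP_fr (g C m-2 yr-1) from ingrowth cores.

    Per core: ingrowth dry mass / core surface area / installation span;
    stand value is the mean over cores times the C fraction.
    """
    if len(cores) < 1:
        raise ValueError("need at least one ingrowth core")
    rates = []
    for row in cores.itertuples(index=False):
        area_m2 = math.pi * (row.diameter_cm / 100.0 / 2.0) ** 2
        rates.append(row.ingrowth_dry_mass_g / area_m2 / row.installation_span_yr)
    return c_fraction * sum(rates) / len(rates)


def derive_clearcut_root_ratio(clearcut_bnpp_fr: Sequence[float],
                               clearcut_anpp_u: Sequence[float]) -> float:
    """Understory root-to-shoot ratio r_u from the recent clear-cuts.

    In clear-cuts all fine-root ingrowth is attributed to the understory,
    so r_u = BNPP_fr / ANPP_u there; the landscape value is the mean over
    valid clear-cut stands.  Stands with ANPP_u = 0 are skipped with a
    warning; no valid stand is an error.
    """
    ratios = []
    for b, a in zip(clearcut_bnpp_fr, clearcut_anpp_u):
        if a <= 0:
            log.warning("clear-cut reference with ANPP_u = 0 skipped")
            continue
        ratios.append(b / a)
    if not ratios:
        raise ValueError("no clear-cut reference stand with ANPP_u > 0")
    return sum(ratios) / len(ratios)


def partition_bnpp(bnpp_fr: float, anpp_u: float, r_u: float
                   ) -> tuple[float, float]:
    """Split total fine-root production into (BNPP_u, BNPP_t_fr).

    BNPP_u = min(r_u * ANPP_u, BNPP_fr) -- the understory share cannot
    exceed the measured total; the remainder goes to tree fine roots.
    Conserves mass exactly: BNPP_u + BNPP_t_fr = BNPP_fr.
    """
    if min(bnpp_fr, anpp_u, r_u) < 0:
        raise ValueError("all partition inputs must be >= 0")
    bnpp_u = min(r_u * anpp_u, bnpp_fr)
    return bnpp_u, bnpp_fr - bnpp_u


def apply_root_to_shoot_scaling(anpp_by_year: Mapping[int, float],
                                ratio_2018: float) -> dict[int, float]:
    """BNPP_fr per year from the single-year fine-root-to-ANPP ratio.

    The ingrowth cores give BNPP_fr for one year only; the ratio of that
    value to the same year's total ANPP is applied to every study year.
    """
    if ratio_2018 < 0:
        raise ValueError("ratio must be >= 0")
    return {y: ratio_2018 * a for y, a in anpp_by_year.items()}


def interannual_understory_scaling(anpp_u_by_pft: Mapping[str, float],
                                   index_by_year: Mapping[int, float],
                                   reference_year: int = 2017,
                                   ) -> dict[int, dict[str, float]]:
    """Scale the single-year per-pft understory production to other years.

    Shrub shoot-increment indices carry the interannual signal; all other
    functional types are scaled by the same factor (constant ratios between
    their production and that of dwarf shrubs).
    """
    ref = index_by_year.get(reference_year)
    if ref is None or ref <= 0:
        raise ValueError(f"shrub index for reference year {reference_year} "
                         "must be present and > 0")
    out: dict[int, dict[str, float]] = {}
    for year, idx in index_by_year.items():
        factor = idx / ref
        out[year] = {pft: v * factor for pft, v in anpp_u_by_pft.items()}
    return out
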