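"""Per-stand carbon-budget composition, age-class aggregation, and the
basal-area-based imputation of budgets for additional old stands."""

from __future__ import annotations

import logging
import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .config import AGE_CLASSES, age_class_of
from .domain import BUDGET_COMPONENTS, CarbonBudget
from .errors import ValidationError

log = logging.getLogger("borealcarbon")

REQUIRED_COMPONENTS = ("anpp_t", "l", "bnpp_t_cr", "bnpp_t_fr",
                       "anpp_u", "bnpp_u", "rh_s", "rh_dw")


def compose_budget(stand_id: str, year: int,
                   components: Mapping[str, float],
                   clamp_negative: bool = False) -> CarbonBudget:
    """Assemble a CarbonBudget from its eight measured components.

    The derived sums (NPP_t, NPP_u, BNPP_fr, NPP, RH, NEP) are computed
    here so the budget identities hold by construction.  Missing
    components raise an error naming the component; negative components
    are an error unless ``clamp_negative`` (then clamped to 0 with a
    warning -- used by the pipeline for small numerical negatives).
    """
    vals = {}
    for name in REQUIRED_COMPONENTS:
        if name not in components:
            raise ValidationError("budgets", f"missing component '{name}'",
                                  context=f"stand {stand_id}")
        v = float(components[name])
        if v < 0:
            if clamp_negative:
                log.warning("stand %s year %d: negative %s (%.2f) clamped "
                            "to 0", stand_id, year, name, v)
                v = 0.0
            else:
                raise ValidationError(
                    "budgets", f"component '{name}' negative ({v})",
                    context=f"stand {stand_id}")
        vals[name] = v
    npp_t = vals["anpp_t"] + vals["bnpp_t_cr"] + vals["bnpp_t_fr"]
    npp_u = vals["anpp_u"] + vals["bnpp_u"]
    bnpp_fr = vals["bnpp_u"] + vals["bnpp_t_fr"]
    npp = npp_t + npp_u
    rh = vals["rh_s"] + vals["rh_dw"]
    return CarbonBudget(stand_id=stand_id, year=year, npp_t=npp_t,
                        npp_u=npp_u, bnpp_fr=bnpp_fr, npp=npp, rh=rh,
                        nep=npp - rh, **vals)


def stand_means(budgets: pd.DataFrame) -> pd.DataFrame:
    """Multi-year mean budget per stand (the paper's 3-year means).

    Statistics and trend fits operate on these, not on single years.
    """
    cols = [c for c in BUDGET_COMPONENTS]
    return (budgets.groupby("stand_id", sort=False)[cols]
            .mean().reset_index())


def class_aggregate(budgets: pd.DataFrame, stands: pd.DataFrame,
                    fluxes: Sequence[str] = BUDGET_COMPONENTS,
                    ) -> pd.DataFrame:
    """Age-class means with two-sided Student-t 95% confidence intervals.

    Multi-year stand means are computed first, then aggregated by the
    stand's age class.  Classes with a single stand report an undefined
    (NaN) CI half-width.  Returns long format: age_class, flux, n, mean,
    ci95_half_width.
    """
    means = stand_means(budgets)
    merged = means.merge(stands[["stand_id", "age_class"]], on="stand_id",
                         how="left")
    if merged["age_class"].isna().any():
        missing = merged.loc[merged["age_class"].isna(), "stand_id"].tolist()
        raise ValidationError("budgets",
                              f"stand(s) missing from stands table: {missing}")
    rows = []
    for cls in AGE_CLASSES:
        grp = merged[merged["age_class"] == cls]
        if grp.empty:
            continue
        n = len(grp)
        for flux in fluxes:
            vals = grp[flux].to_numpy()
            mean = float(np.mean(vals))
            if n > 1:
                half = float(stats.t.ppf(0.975, n - 1)
                             * np.std(vals, ddof=1) / math.sqrt(n))
            else:
                half = float("nan")
            rows.append({"age_class": cls, "flux": flux, "n": n,
                         "mean": mean, "ci95_half_width": half})
    return pd.DataFrame(rows)


def impute_old_stand_budget(stand_id: str, year: int, ba: float,
                            anpp_t_growth: float, bnpp_t_cr: float,
                            reference: "OldStandReference",
                            ) -> CarbonBudget:
    """Budget for an additional old stand from measured tree production
    plus fixed ratios and basal-area regressions.

    Measured: the growth + mortality part of ANPP_t (inventory and coring;
    these stands carry no litter traps) and BNPP_t_cr.  Imputed: L as a
    fixed mean ratio to the growth part, then BNPP_t_fr, ANPP_u and
    BNPP_u as fixed mean ratios to the completed ANPP_t; RH_s and RH_dw
    from linear-in-BA regressions over the main stands.  The composed
    budget satisfies the budget identities by construction.
    """
    if not reference.ba_range[0] <= ba <= reference.ba_range[1]:
        log.warning("stand %s: BA %.1f m2 ha-1 outside the reference range "
                    "%.1f-%.1f (extrapolating)", stand_id, ba,
                    *reference.ba_range)
    litter = reference.litter_ratio * anpp_t_growth
    anpp_t = anpp_t_growth + litter
    comps = {
        "anpp_t": anpp_t,
        "bnpp_t_cr": bnpp_t_cr,
        "l": litter,
        "bnpp_t_fr": reference.bnpp_t_fr_ratio * anpp_t,
        "anpp_u": reference.anpp_u_ratio * anpp_t,
        "bnpp_u": reference.bnpp_u_ratio * anpp_t,
        "rh_s": max(0.0, reference.rh_s_intercept
                    + reference.rh_s_slope * ba),
        "rh_dw": max(0.0, reference.rh_dw_intercept
                     + reference.rh_dw_slope * ba),
    }
    return compose_budget(stand_id, year, comps)


class OldStandReference:
    """Fixed ratios and BA regressions derived from the main stands.

    Built from the main stands' composed budgets and basal areas; needs at
    least 5 reference stands.
    """

    def __init__(self, budgets: pd.DataFrame, ba: pd.Series):
        means = stand_means(budgets).set_index("stand_id")
        ba = ba.reindex(means.index).astype(float)
        if len(means) < 5:
            raise ValueError("need >= 5 reference stands")
        anpp_t = means["anpp_t"].to_numpy()
        growth = anpp_t - means["l"].to_numpy()

        def ratio(values, denom):
            with np.errstate(divide="ignore", invalid="ignore"):
                r = np.asarray(values, dtype=float) / denom
            r = r[np.isfinite(r)]
            return float(np.mean(r)) if r.size else 0.0

        self.litter_ratio = ratio(means["l"], growth)
        self.bnpp_t_fr_ratio = ratio(means["bnpp_t_fr"], anpp_t)
        self.anpp_u_ratio = ratio(means["anpp_u"], anpp_t)
        self.bnpp_u_ratio = ratio(means["bnpp_u"], anpp_t)
        self.rh_s_slope, self.rh_s_intercept = [
            float(v) for v in np.polyfit(ba, means["rh_s"], 1)]
        self.rh_dw_slope, self.rh_dw_intercept = [
            float(v) for v in np.polyfit(ba, means["rh_dw"], 1)]
        self.ba_range = (float(ba.min()), float(ba.max()))
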