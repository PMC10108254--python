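"""Synthetic field campaign with known ground truth.

Generates a complete measurement bundle (every pipeline input table) for a
managed boreal forest landscape emulating a 50-stand chronosequence
design: five age classes (8/9/13/14/6 stands, ages 5-211 yr), 28 pine /
22 spruce stands on 35 till / 15 sediment soils, three recent clear-cuts
without inventory-sized trees, one thinned stand and one clear-cut forced
to act as a net C source.

Ground truth is constructed forward: smooth flux-age curves set the target
production and respiration of every stand, individual trees are simulated
so that allometric bookkeeping reproduces the tree-production targets, and
every measurement (litter-trap masses, clip harvests, ingrowth cores,
chamber CO2 series, dead-wood pools) is emitted so that noise-free
processing recovers the truth exactly.  Measurement noise is multiplicative
Gaussian per observation with configurable SDs; a seed fully determines
the output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any, Mapping

import numpy as np
import pandas as pd

from . import trees as treelib
from .config import AGE_CLASSES
from .domain import BUDGET_COMPONENTS
from .errors import ConfigError

SECONDS_PER_HALFHOUR = 1800.0
G_C_PER_UMOL = 12.011e-6


def _eq6(age: float, p: Mapping[str, float]) -> float:
    x = math.log(age)
    return math.exp(p["b0"] + p["b1"] * x + p["b2"] * x * x)


def _poly2(age: float, p: Mapping[str, float]) -> float:
    return p["c0"] + p["c1"] * age + p["c2"] * age * age


def _lloyd_taylor(ts_c, r_ref, e0):
    t_k = np.asarray(ts_c, dtype=float) + 273.15
    return r_ref * np.exp(e0 * (1.0 / (283.15 - 227.13)
                                - 1.0 / (t_k - 227.13)))


@dataclass
class LandscapeTruth:
    """Ground truth behind a synthetic bundle.

    ``budgets`` holds the true per-stand per-year component fluxes (same
    columns as budgets.csv, satisfying the budget identities exactly);
    ``lloyd_taylor`` the true per-plot (R_ref, E0); ``curves`` the true
    age-curve parameters; ``r_u`` the true understory root-to-shoot ratio.
    """

    budgets: pd.DataFrame
    lloyd_taylor: pd.DataFrame
    curves: dict[str, Any]
    r_u: float
    seed: int
    noise: dict[str, float] = field(default_factory=dict)


def _design_stands(syn: Mapping, rng: np.random.Generator) -> pd.DataFrame:
    """Stand list: ages per class, species and soil assignment."""
    counts = syn["class_counts"]
    bounds = {"initiation": (5, 27), "young": (31, 58),
              "middle_aged": (61, 78), "mature": (80, 105),
              "old": (131, 211)}
    ages: list[tuple[str, int]] = []
    n_cc = int(syn.get("n_clearcuts", 0))
    for cls in AGE_CLASSES:
        n = int(counts.get(cls, 0))
        if n < 0:
            raise ConfigError(f"negative stand count for class '{cls}'")
        lo, hi = bounds[cls]
        cls_ages: list[int] = []
        if cls == "initiation" and n > 0:
            cc_ages = [5, 6, 7][:min(n_cc, n)]
            cls_ages.extend(cc_ages)
            if syn.get("include_thinned_stand") and len(cls_ages) < n:
                cls_ages.append(26)
            remaining = n - len(cls_ages)
            if remaining > 0:
                pool = [a for a in range(12, hi + 1) if a not in cls_ages]
                cls_ages.extend(sorted(rng.choice(pool, size=remaining,
                                                  replace=False).tolist()))
        elif n > 0:
            pool = list(range(lo, hi + 1))
            replace = n > len(pool)
            cls_ages = sorted(rng.choice(pool, size=n,
                                         replace=replace).tolist())
        ages.extend((cls, a) for a in cls_ages)
    n_total = len(ages)
    species = np.array(["pine"] * min(int(syn["n_pine"]), n_total)
                       + ["spruce"] * max(0, n_total - int(syn["n_pine"])))
    soils = np.array(["till"] * min(int(syn["n_till"]), n_total)
                     + ["sediment"] * max(0, n_total - int(syn["n_till"])))
    rng.shuffle(species)
    rng.shuffle(soils)
    rows = []
    for i, (cls, age) in enumerate(ages):
        rows.append({"stand_id": f"S{i + 1:02d}", "age": age,
                     "age_class": cls, "species_group": species[i],
                     "soil_type": soils[i], "plot_radius": 10.0,
                     "additional": 0})
    return pd.DataFrame(rows, columns=["stand_id", "age", "age_class",
                                       "species_group", "soil_type",
                                       "plot_radius", "additional"])


def _soil_temperature(stand_ids, years, soil_cfg, rng) -> pd.DataFrame:
    """Wide half-hourly soil-temperature table (one column per stand)."""
    start = f"{min(years)}-01-01 00:00"
    end = f"{max(years)}-12-31 23:30"
    idx = pd.date_range(start, end, freq="30min")
    doy = idx.dayofyear.to_numpy() + idx.hour.to_numpy() / 24.0
    seasonal = np.cos(2 * np.pi * (doy - soil_cfg["peak_doy"]) / 365.25)
    out = {"timestamp": idx.strftime("%Y-%m-%d %H:%M").to_numpy()}
    offsets = rng.normal(0.0, soil_cfg["stand_mean_sd_c"], size=len(stand_ids))
    for sid, off in zip(stand_ids, offsets):
        noise = rng.normal(0.0, soil_cfg["noise_sd_c"], size=idx.size)
        out[sid] = (soil_cfg["annual_mean_c"] + off
                    + soil_cfg["annual_amplitude_c"] * seasonal + noise)
    return pd.DataFrame(out)


def _annual_basis(soiltemp: pd.DataFrame, sid: str, e0: float
                  ) -> dict[int, float]:
    """Annual RH_s sum per year for R_ref = 1 (g C m-2 yr-1)."""
    ts = pd.to_datetime(soiltemp["timestamp"])
    vals = soiltemp[sid].to_numpy()
    out = {}
    for year, mask in ((y, ts.dt.year == y) for y in sorted(ts.dt.year.unique())):
        flux = _lloyd_taylor(vals[mask.to_numpy()], 1.0, e0)
        out[int(year)] = float(np.sum(flux) * SECONDS_PER_HALFHOUR
                               * G_C_PER_UMOL)
    return out


def _mult_noise(rng, sd: float, size=None):
    if sd <= 0:
        return 1.0 if size is None else np.ones(size)
    return np.maximum(1.0 + rng.normal(0.0, sd, size=size), 0.05)


def generate_landscape(config: Mapping, seed: int
                       ) -> tuple[dict[str, pd.DataFrame], LandscapeTruth]:
    """Generate a full synthetic measurement bundle plus its ground truth.

    Deterministic given ``seed``.  Returns ``(bundle, truth)`` where
    ``bundle`` maps table names (stands, trees, litter, understory,
    shrubgrowth, ingrowth, deadwood, chambers, soiltemp, drivers) to
    DataFrames ready for :func:`borealcarbon.io.write_bundle`.
    """
    rng = np.random.default_rng(seed)
    syn = config["synthetic"]
    curves = syn["true_curves"]
    part = syn["partition"]
    noise = syn["noise"]
    coeffs = config["allometry"]
    cfrac = config["carbon"]["live_c_fraction"]
    years = list(syn["years"])
    budget_years = years[1:]
    plot_radius = config["site"]["plot_radius_m"]
    area_m2 = math.pi * plot_radius ** 2
    to_gc = cfrac * 1000.0 / area_m2          # kg/plot -> g C m-2

    stands = _design_stands(syn, rng)
    n = len(stands)
    # Between-stand site-quality scatter (truth-level heterogeneity, kept
    # under noise-free processing): lognormal with mean 1.
    het = syn.get("heterogeneity", {})

    def _quality(sd: float, size: int) -> np.ndarray:
        if sd <= 0:
            return np.ones(size)
        return rng.lognormal(-sd * sd / 2.0, sd, size=size)

    q_npp = dict(zip(stands["stand_id"],
                     _quality(het.get("npp_sd", 0.0), n)))
    q_under = dict(zip(stands["stand_id"],
                       _quality(het.get("understory_sd", 0.0), n)))
    q_rhs = dict(zip(stands["stand_id"],
                     _quality(het.get("rhs_sd", 0.0), n)))
    empty = _empty_bundle()
    if n == 0:
        truth = LandscapeTruth(budgets=empty["_truth_budgets"],
                               lloyd_taylor=empty["_truth_lt"],
                               curves=dict(curves), r_u=0.0, seed=seed,
                               noise=dict(noise))
        bundle = {k: v for k, v in empty.items() if not k.startswith("_")}
        bundle["stands"] = stands
        return bundle, truth

    clearcut_ids = set(stands.loc[stands["age"] <= 7, "stand_id"])
    thinned_id = None
    if syn.get("include_thinned_stand"):
        cand = stands[(stands["age_class"] == "initiation")
                      & (stands["age"] == 26)]
        if not cand.empty:
            thinned_id = cand["stand_id"].iloc[0]
    source_cc_id = None
    if syn.get("include_source_clearcut") and clearcut_ids:
        source_cc_id = sorted(clearcut_ids)[-1]

    soiltemp = _soil_temperature(stands["stand_id"], years,
                                 syn["soil_temperature"], rng)

    # --- trees: forward simulation calibrated to the production curves ----
    struct = syn["structure"]
    tree_rows = []
    tree_truth: dict[str, dict[int, dict[str, float]]] = {}
    stand_state: dict[str, dict[str, Any]] = {}
    for s in stands.itertuples(index=False):
        sid = s.stand_id
        tree_truth[sid] = {}
        if sid in clearcut_ids:
            stand_state[sid] = {"live_above_gc": {}, "live_cr_gc": {},
                                "b_t_mg_ha": 0.4 + 0.1 * s.age,
                                "ba_m2_ha": 0.0}
            continue
        d_mean = (struct["max_quadratic_mean_dbh_cm"] * s.age
                  / (s.age + struct["dbh_age_halfsat_yr"]))
        ba_ha = (struct["max_basal_area_m2_ha"] * s.age
                 / (s.age + struct["ba_age_halfsat_yr"]))
        ba_plot = ba_ha * area_m2 / 1e4
        sigma = struct["dbh_lognormal_sigma"]
        n_trees = max(2, int(round(ba_plot / (math.pi * (d_mean / 200.0) ** 2
                                              * math.exp(sigma ** 2)))))
        dbh = np.maximum(
            d_mean * rng.lognormal(-sigma ** 2 / 2, sigma, size=n_trees), 3.0)
        minor = "birch"
        species = np.where(rng.random(n_trees) < 0.85, s.species_group, minor)
        status = np.array(["live"] * n_trees, dtype=object)
        decay = np.full(n_trees, np.nan)

        def above_mass(d, sp):
            return treelib.tree_biomass_above(d, sp, coeffs)

        def cr_mass(d, sp):
            return treelib.tree_biomass(d, sp, "coarse_roots", coeffs)

        def d_above_dd(d, sp):
            total = 0.0
            for comp in treelib.ABOVE_COMPONENTS:
                row = coeffs[sp][comp]
                b = treelib.tree_biomass(d, sp, comp, coeffs)
                total += b * row["b"] * row["c"] / (d + row["c"]) ** 2
            return total

        target_growth = (part["growth_fraction_of_npp_t"]
                         * _eq6(s.age, curves["npp_t"]) * q_npp[sid])
        live_above_gc, live_cr_gc = {}, {}
        for yi, year in enumerate(years):
            if yi > 0:
                live = status == "live"
                slope_sum = sum(d_above_dd(d, sp)
                                for d, sp in zip(dbh[live], species[live]))
                delta_d = (target_growth * area_m2
                           / (cfrac * 1000.0 * slope_sum)) if slope_sum else 0.0
                above0 = {i: above_mass(dbh[i], species[i])
                          for i in np.flatnonzero(live)}
                cr0 = {i: cr_mass(dbh[i], species[i])
                       for i in np.flatnonzero(live)}
                dbh[live] = dbh[live] + delta_d
                deaths = live & (rng.random(n_trees)
                                 < struct["mortality_rate_yr"])
                removed = np.zeros(n_trees, dtype=bool)
                if sid == thinned_id and year == years[-1]:
                    removed = live & ~deaths & (rng.random(n_trees) < 0.25)
                delta_above = delta_cr = mort_above = mort_cr = 0.0
                for i in np.flatnonzero(live):
                    a1 = above_mass(dbh[i], species[i])
                    c1 = cr_mass(dbh[i], species[i])
                    if removed[i]:
                        status[i] = "removed"
                        continue
                    if deaths[i]:
                        # live pool loses the tree; its death-year biomass
                        # enters as mortality transfer (net: its growth)
                        status[i] = "dead_standing"
                        decay[i] = 1.0
                        delta_above -= above0[i]
                        delta_cr -= cr0[i]
                        mort_above += a1
                        mort_cr += c1
                    else:
                        delta_above += a1 - above0[i]
                        delta_cr += c1 - cr0[i]
                tree_truth[sid][year] = {
                    "delta_b_live_above": delta_above * to_gc,
                    "mortality_above": mort_above * to_gc,
                    "delta_b_live_cr": delta_cr * to_gc,
                    "mortality_cr": mort_cr * to_gc,
                }
            for i in range(n_trees):
                if status[i] == "removed" and year != years[-1]:
                    continue
                tree_rows.append(
                    {"stand_id": sid, "tree_id": f"{sid}T{i + 1:03d}",
                     "year": year, "dbh": float(dbh[i]),
                     "species": str(species[i]), "status": str(status[i]),
                     "decay_class": float(decay[i]) if not np.isnan(decay[i])
                     else np.nan})
            live_mask = status == "live"
            live_above_gc[year] = sum(
                above_mass(dbh[i], species[i])
                for i in np.flatnonzero(live_mask)) * to_gc
            live_cr_gc[year] = sum(
                cr_mass(dbh[i], species[i])
                for i in np.flatnonzero(live_mask)) * to_gc
        final_live = status == "live"
        b_t_kg = sum(above_mass(dbh[i], species[i])
                     + cr_mass(dbh[i], species[i])
                     for i in np.flatnonzero(final_live))
        ba = sum(math.pi * (dbh[i] / 200.0) ** 2
                 for i in np.flatnonzero(final_live)) / area_m2 * 1e4
        stand_state[sid] = {"live_above_gc": live_above_gc,
                            "live_cr_gc": live_cr_gc,
                            "b_t_mg_ha": b_t_kg / area_m2 * 10.0,
                            "ba_m2_ha": ba}
    trees_df = pd.DataFrame(
        tree_rows, columns=["stand_id", "tree_id", "year", "dbh", "species",
                            "status", "decay_class"])

    # --- litterfall and understory truth -----------------------------------
    litter_cfg = config["litterfall"]
    litter_rows, under_rows, shrub_rows, ingrowth_rows = [], [], [], []
    truth_rows = []
    r_u = part["root_to_shoot_understory"]
    lt_cfg = syn["lloyd_taylor_truth"]
    lt_rows = []
    deadwood_rows = []
    chamber_rows = []
    camp = syn["campaigns"]
    chamber_cfg = config["chamber"]
    k_table = config["decay_constants"]
    rhdw_mode = config.get("rhdw_mode", "exponential")
    ts_index = pd.to_datetime(soiltemp["timestamp"])

    # Clear-cut tree production is defined by the same age relationship the
    # pipeline fits over the remaining initiation stands.
    init_refs = stands[(stands["age_class"] == "initiation")
                       & (~stands["stand_id"].isin(clearcut_ids))]
    ref_ages = init_refs["age"].to_numpy(dtype=float)
    ref_above = np.array([stand_state[r.stand_id]["live_above_gc"][years[-1]]
                          for r in init_refs.itertuples(index=False)])
    ref_cr = np.array([stand_state[r.stand_id]["live_cr_gc"][years[-1]]
                       for r in init_refs.itertuples(index=False)])
    ref_litter = np.array([
        litter_truth_value(r.age, curves, part) * q_npp[r.stand_id]
        for r in init_refs.itertuples(index=False)])

    for s in stands.itertuples(index=False):
        sid = s.stand_id
        age = s.age
        is_cc = sid in clearcut_ids

        litter_true = (0.0 if is_cc
                       else litter_truth_value(age, curves, part) * q_npp[sid])
        anpp_u_true = _eq6(age, curves["anpp_u"]) * q_under[sid]

        # per-year tree production truth
        tree_prod = {}
        if is_cc:
            if len(ref_ages) >= 2:
                _, slope_above = treelib.fit_age_relationship(ref_ages, ref_above)
                _, slope_cr = treelib.fit_age_relationship(ref_ages, ref_cr)
                l0, l1 = treelib.fit_age_relationship(ref_ages, ref_litter)
                litter_cc = max(0.0, l0 + l1 * age)
                anpp_t_cc = max(0.0, slope_above) + litter_cc
                bnpp_cr_cc = max(0.0, slope_cr)
            else:
                litter_cc = anpp_t_cc = bnpp_cr_cc = 0.0
            for y in budget_years:
                tree_prod[y] = {"anpp_t": anpp_t_cc, "l": litter_cc,
                                "bnpp_t_cr": bnpp_cr_cc}
        else:
            for y in budget_years:
                tt = tree_truth[sid][y]
                anpp_t = max(0.0, tt["delta_b_live_above"]
                             + tt["mortality_above"] + litter_true)
                bnpp_cr = max(0.0, tt["delta_b_live_cr"] + tt["mortality_cr"])
                tree_prod[y] = {"anpp_t": anpp_t, "l": litter_true,
                                "bnpp_t_cr": bnpp_cr}

        # fine roots: ingrowth-year totals then ratio scaling
        y_ref = budget_years[-1]
        if is_cc:
            bnpp_t_fr_ref = 0.0
        else:
            bnpp_t_fr_ref = max(
                part["min_bnpp_t_fr"],
                _eq6(age, curves["npp_t"]) * q_npp[sid]
                - tree_prod[y_ref]["anpp_t"]
                - tree_prod[y_ref]["bnpp_t_cr"])
        bnpp_u_ref = r_u * anpp_u_true
        bnpp_fr_ref = bnpp_u_ref + bnpp_t_fr_ref
        anpp_ref = tree_prod[y_ref]["anpp_t"] + anpp_u_true
        fr_ratio = bnpp_fr_ref / anpp_ref if anpp_ref > 0 else 0.0

        # respiration truth
        e0 = float(np.clip(rng.normal(lt_cfg["e0_mean"], lt_cfg["e0_sd"]),
                           50.0, 600.0))
        basis = _annual_basis(soiltemp, sid, e0)
        rhs_target = max(20.0, _poly2(age, curves["rh_s_poly"]) * q_rhs[sid])
        if sid == source_cc_id:
            rhs_target *= lt_cfg["source_clearcut_rhs_factor"]
        r_ref = rhs_target / np.mean([basis[y] for y in budget_years])
        lt_rows.append({"stand_id": sid, "r_ref": r_ref, "e0": e0})
        rhdw_true = _eq6(age, curves["rh_dw"])

        dc_standing, dc_downed = 2, 3
        k_st = float(k_table[s.species_group]["standing"][dc_standing])
        k_dn = float(k_table[s.species_group]["downed"][dc_downed])
        if rhdw_mode == "exponential":
            f_st, f_dn = 1 - math.exp(-k_st), 1 - math.exp(-k_dn)
        else:
            f_st, f_dn = k_st, k_dn
        pool_st = 0.5 * rhdw_true / f_st
        pool_dn = 0.5 * rhdw_true / f_dn

        for y in budget_years:
            rh_s_true = r_ref * basis[y]
            anpp_t = tree_prod[y]["anpp_t"]
            bnpp_fr = fr_ratio * (anpp_t + anpp_u_true)
            bnpp_u = min(r_u * anpp_u_true, bnpp_fr)
            bnpp_t_fr = bnpp_fr - bnpp_u
            npp_t = anpp_t + tree_prod[y]["bnpp_t_cr"] + bnpp_t_fr
            npp_u = anpp_u_true + bnpp_u
            npp = npp_t + npp_u
            rh = rh_s_true + rhdw_true
            truth_rows.append({
                "stand_id": sid, "year": y, "anpp_t": anpp_t,
                "l": tree_prod[y]["l"],
                "bnpp_t_cr": tree_prod[y]["bnpp_t_cr"],
                "bnpp_t_fr": bnpp_t_fr, "npp_t": npp_t,
                "anpp_u": anpp_u_true, "bnpp_u": bnpp_u, "npp_u": npp_u,
                "bnpp_fr": bnpp_fr, "npp": npp, "rh_s": rh_s_true,
                "rh_dw": rhdw_true, "rh": rh, "nep": npp - rh})

            # measurements: litter traps
            if not is_cc:
                total_mass = (litter_true / cfrac * litter_cfg["n_traps"]
                              * litter_cfg["trap_area_m2"])
                per_trap = total_mass / litter_cfg["n_traps"]
                factors = _mult_noise(rng, noise["litter_trap"],
                                      litter_cfg["n_traps"])
                for ti in range(litter_cfg["n_traps"]):
                    litter_rows.append(
                        {"stand_id": sid, "year": y,
                         "trap_id": f"L{ti + 1}",
                         "dry_mass_g": per_trap * factors[ti]})
            # dead-wood pools
            for pos, pool, dc in (("standing", pool_st, dc_standing),
                                  ("downed", pool_dn, dc_downed)):
                deadwood_rows.append(
                    {"stand_id": sid, "year": y, "position": pos,
                     "species": s.species_group, "decay_class": dc,
                     "carbon_mass_g_m2":
                         pool * float(_mult_noise(rng,
                                                  noise["deadwood_pool"]))})
            shrub_rows.append({"stand_id": sid, "year": y, "index": 1.0})

        # understory clips (single mid-campaign year)
        clip_year = budget_years[len(budget_years) // 2]
        dw_total = anpp_u_true / cfrac      # total production in dry mass
        shares = {"herbs": 0.40, "shrubs": 0.35, "mosses": 0.20,
                  "lichens": 0.05}
        june_base = {"herbs": 0.3, "shrubs": 1.5, "mosses": 1.0,
                     "lichens": 0.4}
        for pft, share in shares.items():
            prod = share * dw_total
            june = june_base[pft] * dw_total * 0.25 + (0.0 if pft == "herbs"
                                                       else 0.0)
            aug = prod if pft == "herbs" else june + prod
            for month, mass in (("june", june), ("august", aug)):
                under_rows.append(
                    {"stand_id": sid, "year": clip_year, "month": month,
                     "pft": pft,
                     "dry_mass_g_m2": mass * float(_mult_noise(
                         rng, noise["clip_mass"]))})

        # ingrowth cores
        ing = config["ingrowth"]
        core_area = math.pi * (ing["core_diameter_cm"] / 100.0 / 2.0) ** 2
        core_mass = (bnpp_fr_ref / cfrac * core_area
                     * ing["installation_span_yr"])
        for ci in range(3):
            ingrowth_rows.append(
                {"stand_id": sid, "core_id": f"C{ci + 1}",
                 "diameter_cm": ing["core_diameter_cm"],
                 "depth_cm": ing["core_depth_cm"],
                 "installation_span_yr": ing["installation_span_yr"],
                 "ingrowth_dry_mass_g":
                     core_mass * float(_mult_noise(rng,
                                                   noise["ingrowth_mass"]))})

        # chamber campaigns
        doys = np.linspace(camp["first_doy"], camp["last_doy"],
                           camp["n_per_year"]).round().astype(int)
        t_samples = np.arange(camp["n_samples"]) * camp["sample_interval_s"]
        for y in budget_years:
            for k, doy in enumerate(doys):
                stamp = (pd.Timestamp(f"{y}-01-01 12:00")
                         + pd.Timedelta(days=int(doy) - 1))
                pos = ts_index.searchsorted(stamp)
                pos = min(pos, len(ts_index) - 1)
                ts_c = float(soiltemp[sid].iloc[pos])
                flux_true = float(_lloyd_taylor(ts_c, r_ref, e0))
                flux = max(flux_true * float(_mult_noise(
                    rng, noise["chamber_flux"])), 0.0)
                ta = ts_c + 4.0
                molar = (chamber_cfg["pressure_kpa"] * 1000.0
                         / (8.314 * (ta + 273.15)))
                slope = flux / (chamber_cfg["height_m"] * molar)
                ppm = camp["co2_start_ppm"] + slope * t_samples
                for t_s, c in zip(t_samples, ppm):
                    chamber_rows.append(
                        {"stand_id": sid, "campaign_id": f"{y}-{k + 1:02d}",
                         "timestamp": stamp.strftime("%Y-%m-%d %H:%M"),
                         "seconds": float(t_s), "ppm": float(c),
                         "ts_c": ts_c, "swc_pct": float(rng.uniform(10, 50)),
                         "ta_bc_c": ta,
                         "pressure_kpa": chamber_cfg["pressure_kpa"]})

    truth_budgets = pd.DataFrame(
        truth_rows, columns=["stand_id", "year", *BUDGET_COMPONENTS])

    # --- drivers table ------------------------------------------------------
    drv_cfg = syn["drivers_truth"]
    mean_nep = truth_budgets.groupby("stand_id", sort=False)["nep"].mean()
    drv_rows = []
    aspect = rng.uniform(0, 2 * math.pi, size=n)
    lai_measured = set(rng.choice(stands["stand_id"].to_numpy(),
                                  size=min(drv_cfg["n_lai_measured"], n),
                                  replace=False).tolist())
    for i, s in enumerate(stands.itertuples(index=False)):
        sid = s.stand_id
        b_t = stand_state[sid]["b_t_mg_ha"]
        lai = (drv_cfg["lai_lmax"] * b_t / (b_t + drv_cfg["lai_halfsat_mg_ha"])
               * float(_mult_noise(rng, noise["drivers"])))
        o_depth = max(0.5, 3.0 + 0.03 * s.age
                      + rng.normal(0, 1.0))
        cn = max(12.0, drv_cfg["cn_base"]
                 + drv_cfg["cn_nep_slope"] * float(mean_nep[sid])
                 + rng.normal(0, 2.0))
        drv_rows.append({
            "stand_id": sid,
            "slope": float(rng.uniform(0, 15)),
            "ns_aspect": math.cos(aspect[i]),
            "ew_aspect": math.sin(aspect[i]),
            "b_t": b_t,
            "lai_max": lai if sid in lai_measured else np.nan,
            "o_depth": o_depth,
            "cn_ratio": cn,
            "bd": float(rng.uniform(0.5, 1.3)),
            "swc": float(rng.uniform(15, 45)),
            "ts": float(soiltemp[sid].mean()),
            "soc": max(10.0, 40.0 + 2.0 * o_depth + rng.normal(0, 8.0)),
            "ba": stand_state[sid]["ba_m2_ha"],
        })
    drivers_df = pd.DataFrame(drv_rows)

    bundle = {
        "stands": stands,
        "trees": trees_df,
        "litter": pd.DataFrame(litter_rows, columns=["stand_id", "year",
                                                     "trap_id", "dry_mass_g"]),
        "understory": pd.DataFrame(under_rows,
                                   columns=["stand_id", "year", "month",
                                            "pft", "dry_mass_g_m2"]),
        "shrubgrowth": pd.DataFrame(shrub_rows,
                                    columns=["stand_id", "year", "index"]),
        "ingrowth": pd.DataFrame(ingrowth_rows,
                                 columns=["stand_id", "core_id",
                                          "diameter_cm", "depth_cm",
                                          "installation_span_yr",
                                          "ingrowth_dry_mass_g"]),
        "deadwood": pd.DataFrame(deadwood_rows,
                                 columns=["stand_id", "year", "position",
                                          "species", "decay_class",
                                          "carbon_mass_g_m2"]),
        "chambers": pd.DataFrame(chamber_rows,
                                 columns=["stand_id", "campaign_id",
                                          "timestamp", "seconds", "ppm",
                                          "ts_c", "swc_pct", "ta_bc_c",
                                          "pressure_kpa"]),
        "soiltemp": soiltemp,
        "drivers": drivers_df,
    }
    truth = LandscapeTruth(budgets=truth_budgets,
                           lloyd_taylor=pd.DataFrame(lt_rows),
                           curves=dict(curves), r_u=r_u, seed=seed,
                           noise=dict(noise))
    return bundle, truth


def litter_truth_value(age: float, curves: Mapping, part: Mapping) -> float:
    """True annual litterfall: a fixed fraction of the tree-NPP curve."""
    return part["litter_fraction_of_npp_t"] * _eq6(age, curves["npp_t"])


def noise_free(config: Mapping) -> dict:
    """Copy of ``config`` with every measurement-noise SD set to 0."""
    import copy
    cfg = copy.deepcopy(dict(config))
    for key in cfg["synthetic"]["noise"]:
        cfg["synthetic"]["noise"][key] = 0.0
    return cfg


def _empty_bundle() -> dict[str, pd.DataFrame]:
    from .io import SCHEMAS
    out: dict[str, pd.DataFrame] = {}
    for name, schema in SCHEMAS.items():
        if name == "budgets":
            continue
        out[name] = pd.DataFrame(columns=schema.column_names)
    out["soiltemp"] = pd.DataFrame(columns=["timestamp"])
    out["_truth_budgets"] = pd.DataFrame(
        columns=["stand_id", "year", *BUDGET_COMPONENTS])
    out["_truth_lt"] = pd.DataFrame(columns=["stand_id", "r_ref", "e0"])
    return out
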