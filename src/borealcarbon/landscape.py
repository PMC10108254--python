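"""End-to-end landscape carbon-balance model.

``LandscapeModel`` wires the component modules into the full pipeline:
from raw field tables (stand list, tree inventories, litter traps, clip
harvests, ingrowth cores, dead-wood pools, chamber campaigns, soil
temperature, drivers) to per-stand annual budgets, age-class summaries,
flux-age trend curves, the rotation-forestry optimisation, and the
landscape-driver analysis.  ``fit()`` returns a ``LandscapeResults``
object carrying every intermediate product.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Callable, Mapping

import numpy as np
import pandas as pd

from . import io as iolib
from . import respiration as resp
from . import trees as treelib
from . import understory as underlib
from .budgets import (OldStandReference, class_aggregate, compose_budget,
                      impute_old_stand_budget, stand_means)
from .config import load_config
from .domain import BUDGET_COMPONENTS, ChamberMeasurement
from .errors import ValidationError
from .io import stage_timer
from .rotation import RotationModel, RotationResults
from .trends import AgeTrendModel, AgeTrendResults, nep_trend
from .drivers import LoadingMatrix, impute_lai, pca_varimax, pearson_by_class

log = logging.getLogger("borealcarbon")

ABIOTIC_BIOTIC = ("slope", "ns_aspect", "ew_aspect", "b_t", "lai_max",
                  "o_depth", "cn_ratio", "bd")
PRIMARY_FLUXES = ("npp", "npp_t", "npp_u", "rh", "rh_s", "rh_dw", "nep")


@dataclass
class LandscapeResults:
    """Everything the landscape pipeline produces.

    Attributes
    ----------
    budgets : DataFrame
        Per-stand, per-year budgets (identities hold exactly).
    stand_means : DataFrame
        Multi-year mean budget per stand (statistics operate on these).
    class_summary : DataFrame
        Age-class means with t-based 95% CIs, additional stands included.
    trend_fits : dict[str, AgeTrendResults]
        Fitted flux-age curves (npp, npp_t, npp_u, rh_dw, rh, rh_s).
    nep_curve : callable
        NEP(age) = NPP fit - RH fit, g C m-2 yr-1.
    rotation : RotationResults
        Optimum rotation age, CCP, LCSR, trajectory.
    lloyd_taylor : DataFrame
        Per-stand fitted (R_ref, E0, RMSE, n).
    r_u : float
        Understory root-to-shoot ratio from the clear-cuts.
    pca_primary, pca_secondary : LoadingMatrix
    correlations : DataFrame
        Pearson r/p of NEP and NPP_t with each driver, overall and by class.
    """

    budgets: pd.DataFrame
    stand_means: pd.DataFrame
    class_summary: pd.DataFrame
    trend_fits: dict[str, AgeTrendResults]
    nep_curve: Callable
    rotation: RotationResults
    lloyd_taylor: pd.DataFrame
    r_u: float
    pca_primary: LoadingMatrix | None
    pca_secondary: LoadingMatrix | None
    correlations: pd.DataFrame | None
    stands: pd.DataFrame = field(repr=False, default=None)

    def summary(self) -> str:
        parts = ["Landscape carbon balance", "=" * 52]
        cs = self.class_summary
        for flux in ("nep", "npp", "rh"):
            sub = cs[cs["flux"] == flux]
            line = ", ".join(
                f"{r.age_class} {r.mean:.0f}±{r.ci95_half_width:.0f}"
                if np.isfinite(r.ci95_half_width) else
                f"{r.age_class} {r.mean:.0f}"
                for r in sub.itertuples(index=False))
            parts.append(f"  {flux.upper():5s} class means (g C m-2 yr-1): {line}")
        parts.append(f"  understory root:shoot ratio r_u = {self.r_u:.3f}")
        parts.append("")
        parts.append(self.rotation.summary())
        return "\n".join(parts)

    def plot_age_trends(self, ax=None):
        """Stand-level NPP, RH and NEP against stand age with the fitted
        trend curves (NEP as the curve difference)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(7, 4.5))
        means = self.stand_means.merge(
            self.stands[["stand_id", "age"]], on="stand_id", how="inner")
        grid = np.linspace(max(1.0, means["age"].min()),
                           means["age"].max(), 300)
        for flux, color in (("npp", "tab:green"), ("rh", "tab:brown")):
            ax.scatter(means["age"], means[flux], s=18, alpha=0.6,
                       color=color, label=f"{flux.upper()} (stands)")
            ax.plot(grid, self.trend_fits[flux].predict(grid), color=color)
        ax.scatter(means["age"], means["nep"], s=18, alpha=0.6,
                   color="tab:blue", label="NEP (stands)")
        ax.plot(grid, self.nep_curve(grid), color="tab:blue")
        ax.axhline(0, color="0.6", lw=0.8)
        ax.set_xlabel("stand age (yr)")
        ax.set_ylabel("flux (g C m$^{-2}$ yr$^{-1}$)")
        ax.legend(frameon=False, fontsize=8)
        return ax

    def trend_table(self) -> pd.DataFrame:
        rows = []
        for name, fit in self.trend_fits.items():
            rows.append({"flux": name, "form": fit.form, "b0": fit.b0,
                         "b1": fit.b1, "b2": fit.b2, "rmse": fit.rmse,
                         "r2": fit.r2, "n": fit.nobs})
        return pd.DataFrame(rows)

    def to_directory(self, out_dir: str | Path) -> None:
        """Write every result table as CSV."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        iolib.write_budget_table(self.budgets, out / "budgets.csv")
        self.class_summary.to_csv(out / "class_summary.csv", index=False)
        self.trend_table().to_csv(out / "trend_fits.csv", index=False)
        self.lloyd_taylor.to_csv(out / "rh.csv", index=False)
        rot = self.rotation
        pd.DataFrame([{
            "optimum_age": rot.optimum_age, "ccp": rot.ccp,
            "cumulative_at_optimum_t_c_ha": rot.cumulative_at_optimum,
            "lcsr_t_c_ha_per_rotation": rot.lcsr,
            "harvest_rate_pct_yr": rot.harvest_rate,
            "no_interior_optimum": rot.no_interior_optimum,
            "ccp_not_reached": rot.ccp_not_reached,
        }]).to_csv(out / "rotation_summary.csv", index=False)
        rot.trajectory.to_csv(out / "trajectory.csv", index=False)
        if self.pca_primary is not None:
            self.pca_primary.loadings.to_csv(out / "loadings_primary.csv")
        if self.pca_secondary is not None:
            self.pca_secondary.loadings.to_csv(out / "loadings_secondary.csv")
        if self.correlations is not None:
            self.correlations.to_csv(out / "correlations.csv", index=False)


class LandscapeModel:
    """Full biometric + chamber carbon-balance pipeline for one landscape.

    Parameters
    ----------
    bundle : mapping of table name -> DataFrame
        The field campaign tables (see :mod:`borealcarbon.io`).
    config : mapping, optional
        Full configuration; defaults to the packaged configuration.

    Stands present in the stand list but absent from the tree table are
    treated as recent clear-cuts: their tree biomass and litterfall are
    imputed from the age relationships over the remaining initiation-class
    stands, and their fine-root ingrowth anchors the understory
    root-to-shoot ratio r_u.
    """

    def __init__(self, bundle: Mapping[str, pd.DataFrame],
                 config: Mapping | None = None):
        self.config = dict(config) if config is not None else load_config()
        self.tables: dict[str, pd.DataFrame] = {}
        for name in iolib.BUNDLE_TABLES:
            if name in bundle:
                self.tables[name] = iolib.read_table(bundle[name],
                                                     iolib.SCHEMAS[name])
        if "soiltemp" in bundle:
            self.tables["soiltemp"] = iolib.read_soiltemp(bundle["soiltemp"])

    @classmethod
    def from_directory(cls, in_dir: str | Path,
                       config: Mapping | None = None) -> "LandscapeModel":
        return cls(iolib.read_bundle(in_dir), config=config)

    # ------------------------------------------------------------------ fit
    def fit(self) -> LandscapeResults:
        cfg = self.config
        stands = self.tables["stands"]
        main = stands[stands["additional"] == 0]
        with stage_timer("tree production"):
            tree_prod, clearcut_ids = self._tree_production(main)
        with stage_timer("understory production"):
            under = self._understory_production(main, tree_prod, clearcut_ids)
        with stage_timer("heterotrophic flux"):
            rh_s, lt_table = self._soil_respiration(main)
            rh_dw = self._deadwood_respiration(main)
        with stage_timer("budget composition"):
            budgets = self._compose_budgets(main, tree_prod, under, rh_s, rh_dw)
            budgets, class_summary = self._with_additional(budgets, stands)
        with stage_timer("trend fitting"):
            fits, nep_curve = self._fit_trends(budgets, main)
        with stage_timer("rotation analysis"):
            rot_cfg = cfg["rotation"]
            rotation = RotationModel(nep_curve,
                                     horizon=rot_cfg["horizon_yr"],
                                     step=rot_cfg["step_yr"],
                                     lcsr_mode=rot_cfg["lcsr_mode"]).fit()
        pca1 = pca2 = None
        corr = None
        if "drivers" in self.tables:
            with stage_timer("driver analysis"):
                pca1, pca2, corr = self._driver_analysis(budgets, main)
        return LandscapeResults(
            budgets=budgets, stand_means=stand_means(budgets),
            class_summary=class_summary, trend_fits=fits,
            nep_curve=nep_curve, rotation=rotation, lloyd_taylor=lt_table,
            r_u=self._r_u, pca_primary=pca1, pca_secondary=pca2,
            correlations=corr, stands=stands)

    # ------------------------------------------------------- tree production
    def _tree_production(self, stands: pd.DataFrame
                         ) -> tuple[dict[str, pd.DataFrame], set[str]]:
        cfg = self.config
        coeffs = cfg["allometry"]
        cfrac = cfg["carbon"]["live_c_fraction"]
        trees = self.tables.get("trees",
                                pd.DataFrame(columns=iolib.TREES.column_names))
        litter = self.tables.get("litter")
        trap_area = cfg["litterfall"]["trap_area_m2"]

        litter_by_stand: dict[str, dict[int, float]] = {}
        if litter is not None:
            for (sid, year), grp in litter.groupby(["stand_id", "year"]):
                litter_by_stand.setdefault(str(sid), {})[int(year)] = \
                    treelib.litterfall_annual(grp["dry_mass_g"].tolist(),
                                              trap_area, cfrac)

        inventoried = set(trees["stand_id"].unique())
        out: dict[str, pd.DataFrame] = {}
        clearcut_ids: set[str] = set()
        final_pools: dict[str, tuple[float, float]] = {}
        for s in stands.itertuples(index=False):
            sid = s.stand_id
            if sid not in inventoried:
                clearcut_ids.add(sid)
                continue
            sub = trees[trees["stand_id"] == sid]
            series = treelib.stand_production_series(
                sub, litter_by_stand.get(sid, {}), s.plot_radius, coeffs,
                cfg["dead_density_ratio"], cfrac,
                cfg["carbon"]["dead_c_fraction"])
            out[sid] = series
            last_year = int(sub["year"].max())
            pools = treelib.stand_biomass_pools(
                sub[sub["year"] == last_year], s.plot_radius, coeffs,
                cfg["dead_density_ratio"], cfrac,
                cfg["carbon"]["dead_c_fraction"])
            final_pools[sid] = (pools["live_above_gc_m2"],
                                pools["live_cr_gc_m2"])

        # clear-cut imputation from the remaining initiation stands
        if clearcut_ids:
            refs = stands[(stands["age_class"] == "initiation")
                          & (~stands["stand_id"].isin(clearcut_ids))]
            if len(refs) < 2:
                raise ValidationError(
                    "stands", "need >= 2 non-clear-cut initiation stands "
                    "for clear-cut imputation")
            ref_ages = refs["age"].to_numpy(dtype=float)
            ref_above = np.array([final_pools[r][0]
                                  for r in refs["stand_id"]])
            ref_cr = np.array([final_pools[r][1] for r in refs["stand_id"]])
            ref_l = np.array([np.mean(list(litter_by_stand[r].values()))
                              for r in refs["stand_id"]])
            _, slope_above = treelib.fit_age_relationship(ref_ages, ref_above)
            _, slope_cr = treelib.fit_age_relationship(ref_ages, ref_cr)
            l0, l1 = treelib.fit_age_relationship(ref_ages, ref_l)
            years = sorted({int(y) for d in out.values() for y in d.index})
            for s in stands.itertuples(index=False):
                if s.stand_id not in clearcut_ids:
                    continue
                l_cc = max(0.0, l0 + l1 * s.age)
                anpp = max(0.0, slope_above) + l_cc
                rows = [{"year": y, "delta_b_live_above": max(0.0, slope_above),
                         "mortality_above": 0.0, "l": l_cc, "anpp_t": anpp,
                         "bnpp_t_cr": max(0.0, slope_cr)} for y in years]
                out[s.stand_id] = pd.DataFrame(rows).set_index("year")
        return out, clearcut_ids

    # ------------------------------------------------- understory production
    def _understory_production(self, stands: pd.DataFrame,
                               tree_prod: Mapping[str, pd.DataFrame],
                               clearcut_ids: set[str]) -> pd.DataFrame:
        cfg = self.config
        cfrac = cfg["carbon"]["live_c_fraction"]
        under = self.tables["understory"]
        shrub = self.tables.get("shrubgrowth")
        ingrowth = self.tables["ingrowth"]

        years = sorted({int(y) for d in tree_prod.values() for y in d.index})
        rows = []
        anpp_u_ref: dict[str, float] = {}
        bnpp_fr_ref: dict[str, float] = {}
        for s in stands.itertuples(index=False):
            sid = s.stand_id
            clips = under[under["stand_id"] == sid]
            if clips.empty:
                raise ValidationError("understory",
                                      f"no clip harvests for stand {sid}")
            clip_year = int(clips["year"].iloc[0])
            per_pft = {}
            for pft, grp in clips.groupby("pft"):
                masses = grp.set_index("month")["dry_mass_g_m2"]
                sub = grp[["month", "pft", "dry_mass_g_m2"]]
                if pft == "herbs":
                    per_pft[pft] = cfrac * float(masses.get("august", np.nan))
                else:
                    per_pft[pft] = cfrac * max(
                        0.0, float(masses.get("august", np.nan))
                        - float(masses.get("june", np.nan)))
            if any(not np.isfinite(v) for v in per_pft.values()):
                raise ValidationError("understory",
                                      f"missing month for stand {sid}")
            if shrub is not None and not shrub[shrub["stand_id"] == sid].empty:
                sub = shrub[shrub["stand_id"] == sid]
                idx = dict(zip(sub["year"].astype(int),
                               sub["index"].astype(float)))
            else:
                idx = {y: 1.0 for y in years}
            scaled = underlib.interannual_understory_scaling(
                per_pft, {y: idx.get(y, 1.0) for y in years},
                reference_year=clip_year if clip_year in years else years[0])
            anpp_u_by_year = {y: sum(scaled[y].values()) for y in years}

            cores = ingrowth[ingrowth["stand_id"] == sid]
            if cores.empty:
                raise ValidationError("ingrowth",
                                      f"no ingrowth cores for stand {sid}")
            bnpp_fr = underlib.bnpp_fineroot_from_ingrowth(cores, cfrac)
            y_ref = years[-1]
            anpp_u_ref[sid] = anpp_u_by_year[y_ref]
            bnpp_fr_ref[sid] = bnpp_fr
            for y in years:
                rows.append({"stand_id": sid, "year": y,
                             "anpp_u": anpp_u_by_year[y]})
        under_df = pd.DataFrame(rows).set_index(["stand_id", "year"])

        # root-to-shoot ratio from clear-cuts, then per-year BNPP_fr scaling
        cc = sorted(clearcut_ids)
        if cc:
            self._r_u = underlib.derive_clearcut_root_ratio(
                [bnpp_fr_ref[c] for c in cc], [anpp_u_ref[c] for c in cc])
        else:
            log.warning("no clear-cut stands: understory root:shoot ratio "
                        "defaults to 0.8")
            self._r_u = 0.8
        y_ref = years[-1]
        parts = []
        for s in stands.itertuples(index=False):
            sid = s.stand_id
            anpp_t_ref = float(tree_prod[sid].loc[y_ref, "anpp_t"])
            anpp_ref = anpp_t_ref + anpp_u_ref[sid]
            ratio = bnpp_fr_ref[sid] / anpp_ref if anpp_ref > 0 else 0.0
            anpp_by_year = {
                y: float(tree_prod[sid].loc[y, "anpp_t"])
                + float(under_df.loc[(sid, y), "anpp_u"]) for y in years}
            fr_by_year = underlib.apply_root_to_shoot_scaling(anpp_by_year,
                                                              ratio)
            for y in years:
                anpp_u = float(under_df.loc[(sid, y), "anpp_u"])
                bnpp_u, bnpp_t_fr = underlib.partition_bnpp(
                    fr_by_year[y], anpp_u, self._r_u)
                parts.append({"stand_id": sid, "year": y, "anpp_u": anpp_u,
                              "bnpp_u": bnpp_u, "bnpp_t_fr": bnpp_t_fr})
        return pd.DataFrame(parts).set_index(["stand_id", "year"])

    # --------------------------------------------------- soil respiration
    def _soil_respiration(self, stands: pd.DataFrame
                          ) -> tuple[pd.DataFrame, pd.DataFrame]:
        cfg = self.config
        ch_cfg = cfg["chamber"]
        lt_cfg = cfg["lloyd_taylor"]
        chambers = self.tables["chambers"]
        soiltemp = self.tables["soiltemp"]
        ts_index = pd.to_datetime(soiltemp["timestamp"])
        years = sorted(ts_index.dt.year.unique())

        rows = []
        lt_rows = []
        for s in stands.itertuples(index=False):
            sid = s.stand_id
            camp = chambers[chambers["stand_id"] == sid]
            if camp.empty:
                raise ValidationError("chambers",
                                      f"no campaigns for stand {sid}")
            pairs_ts, pairs_flux = [], []
            for cid, grp in camp.groupby("campaign_id"):
                m = ChamberMeasurement(
                    stand_id=sid, timestamp=str(grp["timestamp"].iloc[0]),
                    seconds=grp["seconds"].tolist(), ppm=grp["ppm"].tolist(),
                    ts_c=float(grp["ts_c"].iloc[0]),
                    swc_pct=float(grp["swc_pct"].iloc[0]),
                    ta_bc_c=float(grp["ta_bc_c"].iloc[0]),
                    pressure_kpa=float(grp["pressure_kpa"].iloc[0]),
                    base_side_m=ch_cfg["base_side_m"],
                    height_m=ch_cfg["height_m"])
                flux = resp.chamber_flux(
                    m, deadband_s=ch_cfg["deadband_s"],
                    min_points=ch_cfg["min_points"],
                    negative_tolerance=ch_cfg["negative_flux_tolerance"])
                pairs_ts.append(m.ts_c)
                pairs_flux.append(flux)
            fit = resp.LloydTaylorModel(
                pairs_ts, pairs_flux, t_ref_k=lt_cfg["t_ref_k"],
                t0_k=lt_cfg["t0_k"], e0_grid=lt_cfg["e0_grid"]).fit()
            lt_rows.append({"stand_id": sid, "r_ref": fit.r_ref,
                            "e0": fit.e0, "rmse": fit.rmse, "n": fit.nobs,
                            "converged": fit.converged})
            if sid not in soiltemp.columns:
                raise ValidationError("soiltemp",
                                      f"no temperature column for stand {sid}")
            for y in years:
                series = soiltemp.loc[ts_index.dt.year == y, sid]
                rhs = resp.annual_rhs(
                    fit, series, step_s=cfg["annual_sums"]["step_s"],
                    max_gap_fraction=cfg["annual_sums"]["max_gap_fraction"])
                rows.append({"stand_id": sid, "year": int(y), "rh_s": rhs})
        rh_s = pd.DataFrame(rows).set_index(["stand_id", "year"])["rh_s"]
        return rh_s, pd.DataFrame(lt_rows)

    def _deadwood_respiration(self, stands: pd.DataFrame) -> pd.Series:
        cfg = self.config
        deadwood = self.tables.get("deadwood")
        rows = []
        if deadwood is not None:
            for (sid, year), grp in deadwood.groupby(["stand_id", "year"]):
                rows.append({"stand_id": str(sid), "year": int(year),
                             "rh_dw": resp.annual_rhdw(
                                 grp, cfg["decay_constants"],
                                 mode=cfg.get("rhdw_mode", "exponential"))})
        if not rows:
            return pd.Series(dtype=float)
        return pd.DataFrame(rows).set_index(["stand_id", "year"])["rh_dw"]

    # ---------------------------------------------------------- composition
    def _compose_budgets(self, stands: pd.DataFrame,
                         tree_prod: Mapping[str, pd.DataFrame],
                         under: pd.DataFrame, rh_s: pd.Series,
                         rh_dw: pd.Series) -> pd.DataFrame:
        years = sorted({int(y) for d in tree_prod.values() for y in d.index})
        budget_rows = []
        for s in stands.itertuples(index=False):
            sid = s.stand_id
            for y in years:
                tp = tree_prod[sid].loc[y]
                up = under.loc[(sid, y)]
                comps = {
                    "anpp_t": float(tp["anpp_t"]), "l": float(tp["l"]),
                    "bnpp_t_cr": float(tp["bnpp_t_cr"]),
                    "bnpp_t_fr": float(up["bnpp_t_fr"]),
                    "anpp_u": float(up["anpp_u"]),
                    "bnpp_u": float(up["bnpp_u"]),
                    "rh_s": float(rh_s.loc[(sid, y)]),
                    "rh_dw": float(rh_dw.get((sid, y), 0.0)),
                }
                budget_rows.append(
                    compose_budget(sid, y, comps, clamp_negative=True).__dict__)
        return pd.DataFrame(budget_rows)[["stand_id", "year",
                                          *BUDGET_COMPONENTS]]

    def _with_additional(self, budgets: pd.DataFrame, stands: pd.DataFrame
                         ) -> tuple[pd.DataFrame, pd.DataFrame]:
        """Impute budgets for additional old stands, then class-aggregate."""
        cfg = self.config
        additional = stands[stands["additional"] == 1]
        all_budgets = budgets
        if not additional.empty:
            drivers = self.tables.get("drivers")
            if drivers is None:
                raise ValidationError("drivers",
                                      "additional stands need BA in drivers")
            ba = drivers.set_index("stand_id")["ba"]
            main_ba = ba.reindex(budgets["stand_id"].unique())
            reference = OldStandReference(budgets, main_ba)
            trees = self.tables["trees"]
            coeffs = cfg["allometry"]
            cfrac = cfg["carbon"]["live_c_fraction"]
            rows = []
            for s in additional.itertuples(index=False):
                sub = trees[trees["stand_id"] == s.stand_id]
                if sub.empty:
                    raise ValidationError(
                        "trees", f"additional stand {s.stand_id} has no "
                        "inventory")
                series = treelib.stand_production_series(
                    sub, {}, s.plot_radius, coeffs,
                    cfg["dead_density_ratio"], cfrac,
                    cfg["carbon"]["dead_c_fraction"])
                for y in series.index:
                    b = impute_old_stand_budget(
                        s.stand_id, int(y), float(ba[s.stand_id]),
                        float(series.loc[y, "anpp_t"]),
                        float(series.loc[y, "bnpp_t_cr"]), reference)
                    rows.append(b.__dict__)
            extra = pd.DataFrame(rows)[["stand_id", "year",
                                        *BUDGET_COMPONENTS]]
            all_budgets = pd.concat([budgets, extra], ignore_index=True)
        summary = class_aggregate(all_budgets, stands)
        return all_budgets, summary

    # -------------------------------------------------------------- trends
    def _fit_trends(self, budgets: pd.DataFrame, main: pd.DataFrame
                    ) -> tuple[dict[str, AgeTrendResults], Callable]:
        cfg = self.config["trends"]
        means = stand_means(budgets)
        means = means.merge(main[["stand_id", "age"]], on="stand_id",
                            how="inner")        # additional stands excluded
        if not cfg.get("include_thinned", True):
            thinned = self._thinned_stand_ids()
            means = means[~means["stand_id"].isin(thinned)]
        ages = means["age"].to_numpy(dtype=float)
        fits: dict[str, AgeTrendResults] = {}
        for flux in ("npp", "npp_t", "npp_u", "rh_dw"):
            fits[flux] = AgeTrendModel(
                ages, means[flux].to_numpy(), form="log_quadratic",
                flux=flux, min_age=cfg["min_trend_age"]).fit()
        rh_form = ("poly2_logage" if cfg["rh_form"] == "poly2_logage"
                   else "poly2")
        for flux in ("rh", "rh_s"):
            fits[flux] = AgeTrendModel(
                ages, means[flux].to_numpy(), form=rh_form, flux=flux,
                min_age=cfg["min_trend_age"]).fit()
        return fits, nep_trend(fits["npp"], fits["rh"])

    def _thinned_stand_ids(self) -> set[str]:
        trees = self.tables.get("trees")
        if trees is None:
            return set()
        return set(trees.loc[trees["status"] == "removed", "stand_id"])

    # ------------------------------------------------------------- drivers
    def _driver_analysis(self, budgets: pd.DataFrame, main: pd.DataFrame
                         ) -> tuple[LoadingMatrix, LoadingMatrix, pd.DataFrame]:
        cfg = self.config["drivers"]
        drivers = self.tables["drivers"].set_index("stand_id")
        drivers = drivers.loc[drivers.index.isin(main["stand_id"])]
        if drivers["lai_max"].isna().any():
            have = drivers[drivers["lai_max"].notna()]
            missing = drivers[drivers["lai_max"].isna()]
            drivers.loc[missing.index, "lai_max"] = impute_lai(
                missing["b_t"].to_numpy(), have["b_t"].to_numpy(),
                have["lai_max"].to_numpy())
        means = stand_means(budgets).set_index("stand_id")
        means = means.loc[means.index.isin(main["stand_id"])]
        features1 = pd.concat(
            [drivers[list(ABIOTIC_BIOTIC)], means[list(PRIMARY_FLUXES)]],
            axis=1)
        pca1 = pca_varimax(features1, n_components=cfg["n_components"],
                           tol=cfg["varimax_tol"],
                           max_iter=cfg["varimax_max_iter"])
        features2 = pd.concat(
            [drivers[list(ABIOTIC_BIOTIC)], means[["npp_t"]]], axis=1)
        pca2 = pca_varimax(features2, n_components=cfg["n_components"],
                           tol=cfg["varimax_tol"],
                           max_iter=cfg["varimax_max_iter"])
        classes = main.set_index("stand_id")["age_class"]
        corr = pearson_by_class(means[["nep", "npp_t"]],
                                drivers[list(ABIOTIC_BIOTIC)],
                                classes)
        return pca1, pca2, corr
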