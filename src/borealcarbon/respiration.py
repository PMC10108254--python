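"""Heterotrophic respiration: chamber fluxes, Lloyd-Taylor temperature
response, annual extrapolation, and dead-wood decay respiration.

Soil heterotrophic respiration (RH_s) is measured with a closed opaque
chamber on trenched plots; the flux is the OLS slope of the headspace CO2
mixing-ratio series (after a deadband) converted with the ideal-gas molar
density.  A plot-specific Lloyd-Taylor (1994) response

    R(T) = R_ref * exp(E0 * (1/(T_ref - T0) - 1/(T - T0)))

is fitted to the campaign (soil temperature, flux) pairs and integrated
over the continuous half-hourly soil-temperature record to an annual sum.
Dead-wood respiration (RH_dw) applies species- and decay-class-specific
decomposition rate constants to the standing/downed dead-wood C pools.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .domain import ChamberMeasurement
from .errors import ConfigError, ValidationError

log = logging.getLogger("borealcarbon")

R_GAS = 8.314          # J mol-1 K-1
T_REF_K = 283.15       # Lloyd & Taylor reference temperature (10 degC)
T0_K = 227.13          # Lloyd & Taylor zero-activity temperature
G_C_PER_UMOL = 12.011e-6
DEFAULT_E0_GRID = (0.0, 50.0, 100.0, 150.0, 200.0, 250.0, 300.0, 350.0,
                   400.0, 500.0)


def chamber_flux(m: ChamberMeasurement, deadband_s: float = 10.0,
                 min_points: int = 5,
                 negative_tolerance: float = 0.05) -> float:
    """CO2 efflux (umol m-2 s-1) from one closed-chamber deployment.

    flux = slope(ppm s-1, OLS over the post-deadband window)
           * (V/A) * P / (R_gas * T_air),

    with V/A the chamber height and T_air the below-canopy air temperature
    in kelvin.  Fluxes more negative than ``negative_tolerance`` trigger a
    warning; any negative result is clamped to 0 (heterotrophic respiration
    cannot be negative).
    """
    t = np.asarray(m.seconds, dtype=float)
    c = np.asarray(m.ppm, dtype=float)
    keep = t >= deadband_s
    if keep.sum() < min_points:
        raise ValidationError(
            "chambers", f"fewer than {min_points} usable points after "
            f"{deadband_s:.0f} s deadband", context=f"stand {m.stand_id}")
    slope = np.polyfit(t[keep], c[keep], 1)[0]          # ppm s-1
    molar_density = (m.pressure_kpa * 1000.0) / (R_GAS * (m.ta_bc_c + 273.15))
    flux = slope * m.volume_area_ratio_m * molar_density
    if flux < 0:
        if flux < -negative_tolerance:
            log.warning("negative chamber flux %.3f umol m-2 s-1 clamped to 0 "
                        "(stand %s)", flux, m.stand_id)
        flux = 0.0
    return float(flux)


def lloyd_taylor(ts_c, r_ref: float, e0: float,
                 t_ref_k: float = T_REF_K, t0_k: float = T0_K):
    """Evaluate the Lloyd-Taylor response at soil temperature(s) in degC."""
    t_k = np.asarray(ts_c, dtype=float) + 273.15
    out = r_ref * np.exp(e0 * (1.0 / (t_ref_k - t0_k) - 1.0 / (t_k - t0_k)))
    return out if out.ndim else float(out)


@dataclass
class LloydTaylorResults:
    """Fitted plot-specific temperature response.

    Attributes
    ----------
    r_ref : float
        Respiration at the reference temperature (umol CO2 m-2 s-1).
    e0 : float
        Activation-energy-like temperature sensitivity (K).
    rmse : float
        Root-mean-square residual of the fit (umol m-2 s-1).
    nobs : int
        Number of campaign pairs used.
    converged : bool
        False if the optimiser failed and the constant (E0 = 0) fallback
        was used.
    """

    r_ref: float
    e0: float
    rmse: float
    nobs: int
    converged: bool = True
    t_ref_k: float = T_REF_K
    t0_k: float = T0_K

    def predict(self, ts_c):
        return lloyd_taylor(ts_c, self.r_ref, self.e0, self.t_ref_k, self.t0_k)

    def annual_sum(self, ts_series, step_s: float = 1800.0,
                   max_gap_fraction: float = 0.05) -> float:
        return annual_rhs(self, ts_series, step_s=step_s,
                          max_gap_fraction=max_gap_fraction)

    def summary(self) -> str:
        lines = [
            "Lloyd-Taylor temperature response",
            "=" * 41,
            f"  R_ref (at {self.t_ref_k - 273.15:.2f} degC)"
            f" {self.r_ref:12.4f} umol m-2 s-1",
            f"  E0                  {self.e0:12.2f} K",
            f"  T0 (fixed)          {self.t0_k:12.2f} K",
            f"  RMSE                {self.rmse:12.4f} umol m-2 s-1",
            f"  n                   {self.nobs:12d}",
            f"  converged           {str(self.converged):>12s}",
        ]
        return "\n".join(lines)


class LloydTaylorModel:
    """Plot-specific soil-respiration temperature-response model.

    Parameters
    ----------
    ts_c : array-like
        Campaign soil temperatures at 10 cm (degC).
    flux : array-like
        Chamber CO2 fluxes (umol m-2 s-1).

    Fitting minimises squared error on the natural flux scale with T0 and
    T_ref fixed (only R_ref and E0 free): a deterministic coarse grid over
    E0 (conditionally optimal R_ref in closed form at each node) picks the
    start, refined by least squares.  Needs >= 4 pairs spanning >= 5 degC.
    """

    def __init__(self, ts_c, flux, t_ref_k: float = T_REF_K,
                 t0_k: float = T0_K,
                 e0_grid: Sequence[float] = DEFAULT_E0_GRID):
        self.ts_c = np.asarray(ts_c, dtype=float)
        self.flux = np.asarray(flux, dtype=float)
        self.t_ref_k = t_ref_k
        self.t0_k = t0_k
        self.e0_grid = tuple(e0_grid)
        if self.ts_c.size != self.flux.size:
            raise ValueError("ts_c and flux must have equal length")
        if self.ts_c.size < 4:
            raise ValueError("need >= 4 (Ts, flux) pairs")
        if np.ptp(self.ts_c) < 5.0:
            raise ValueError("campaign temperatures must span >= 5 degC")

    def _basis(self, e0: float) -> np.ndarray:
        return lloyd_taylor(self.ts_c, 1.0, e0, self.t_ref_k, self.t0_k)

    def _grid_start(self) -> tuple[float, float]:
        best = (np.inf, 1.0, 0.0)
        for e0 in self.e0_grid:
            g = self._basis(e0)
            denom = float(g @ g)
            r_ref = float(g @ self.flux) / denom if denom > 0 else 0.0
            r_ref = max(r_ref, 1e-12)
            sse = float(np.sum((self.flux - r_ref * g) ** 2))
            if sse < best[0]:
                best = (sse, r_ref, e0)
        return best[1], best[2]

    def fit(self) -> LloydTaylorResults:
        r0, e0_0 = self._grid_start()

        def residuals(theta):
            r_ref, e0 = theta
            return lloyd_taylor(self.ts_c, r_ref, e0,
                                self.t_ref_k, self.t0_k) - self.flux

        converged = True
        try:
            sol = optimize.least_squares(
                residuals, x0=[r0, e0_0],
                bounds=([1e-12, 0.0], [np.inf, 2000.0]),
                xtol=1e-12, ftol=1e-12, gtol=1e-12)
            r_ref, e0 = float(sol.x[0]), float(sol.x[1])
            if not sol.success or not np.isfinite([r_ref, e0]).all():
                raise RuntimeError(sol.message)
        except (RuntimeError, ValueError) as exc:
            log.warning("Lloyd-Taylor fit failed (%s); falling back to "
                        "constant model", exc)
            r_ref, e0, converged = float(np.mean(self.flux)), 0.0, False
        resid = lloyd_taylor(self.ts_c, r_ref, e0, self.t_ref_k,
                             self.t0_k) - self.flux
        rmse = float(np.sqrt(np.mean(resid ** 2)))
        return LloydTaylorResults(r_ref=r_ref, e0=e0, rmse=rmse,
                                  nobs=int(self.ts_c.size),
                                  converged=converged,
                                  t_ref_k=self.t_ref_k, t0_k=self.t0_k)


def fit_lloyd_taylor(ts_c, flux, **kwargs) -> LloydTaylorResults:
    """Functional wrapper around LloydTaylorModel(...).fit()."""
    return LloydTaylorModel(ts_c, flux, **kwargs).fit()


def annual_rhs(model: LloydTaylorResults, ts_series,
               step_s: float = 1800.0,
               max_gap_fraction: float = 0.05) -> float:
    """Annual soil heterotrophic respiration (g C m-2 yr-1).

    Evaluates the fitted response at every half-hourly soil temperature and
    sums flux * step * 12.011e-6 g/umol.  Gaps (NaNs) up to
    ``max_gap_fraction`` of the series are linearly interpolated; more is
    an error (the extrapolation would no longer cover the year).
    """
    ts = pd.Series(np.asarray(ts_series, dtype=float))
    if ts.size == 0:
        raise ValueError("empty soil-temperature series")
    gap_fraction = float(ts.isna().mean())
    if gap_fraction > max_gap_fraction:
        raise ValueError(
            f"soil-temperature series has {gap_fraction:.1%} gaps "
            f"(> {max_gap_fraction:.0%} allowed)")
    if gap_fraction > 0:
        ts = ts.interpolate(limit_direction="both")
    flux = model.predict(ts.to_numpy())
    return float(np.sum(flux) * step_s * G_C_PER_UMOL)


def annual_rhdw(pools: pd.DataFrame, k_table: Mapping,
                mode: str = "exponential") -> float:
    """Annual dead-wood heterotrophic respiration (g C m-2 yr-1).

    ``pools`` columns: position, species, decay_class, carbon_mass_g_m2.
    Annual respired fraction per pool is 1 - exp(-k) (exact single-
    exponential year step; mode 'linear' uses plain k).  All decomposed
    mass is treated as respired.
    """
    if mode not in ("exponential", "linear"):
        raise ConfigError(f"unknown rhdw mode '{mode}'")
    total = 0.0
    for row in pools.itertuples(index=False):
        try:
            k = float(k_table[row.species][row.position][int(row.decay_class)])
        except KeyError:
            raise ConfigError(
                f"no decay constant for ({row.species}, {row.position}, "
                f"class {int(row.decay_class)})")
        frac = 1.0 - math.exp(-k) if mode == "exponential" else k
        total += row.carbon_mass_g_m2 * frac
    return total


def total_rh(rh_s: float, rh_dw: float) -> float:
    """Total heterotrophic respiration: RH = RH_s + RH_dw."""
    if rh_s < 0 or rh_dw < 0:
        raise ValueError("RH components must be >= 0")
    return rh_s + rh_dw
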