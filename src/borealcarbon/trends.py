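"""Age-trend curve fitting for the flux-over-stand-age relationships.

Production fluxes (NPP, NPP_t, NPP_u, RH_dw) follow a log-quadratic form

    F(age) = exp(b0 + b1 ln(age) + b2 ln(age)^2),

fitted by Levenberg-Marquardt least squares on the natural flux scale with
a deterministic initialisation from the closed-form log-space linear
solve.  A negative b2 gives the hump shape with interior maximum at
age = exp(-b1 / (2 b2)).  Heterotrophic respiration (RH, RH_s) shows no
exponential age trend and uses an ordinary second-degree polynomial in
age (optionally in ln age).  The NEP trend is never fitted directly: it is
the difference of the NPP and RH trend curves.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy import optimize

log = logging.getLogger("borealcarbon")

FORMS = ("log_quadratic", "poly2", "poly2_logage")


@dataclass
class AgeTrendResults:
    """Fitted age trend for one flux.

    ``predict`` clamps ages below ``min_age`` to ``min_age`` (the
    log-quadratic form is undefined at age 0) and clamps polynomial flux
    predictions at 0.
    """

    flux: str
    form: str
    b0: float
    b1: float
    b2: float
    rmse: float
    r2: float
    nobs: int
    converged: bool = True
    min_age: float = 1.0

    @property
    def coefficients(self) -> tuple[float, float, float]:
        return (self.b0, self.b1, self.b2)

    def predict(self, age):
        a = np.maximum(np.asarray(age, dtype=float), self.min_age)
        if self.form == "log_quadratic":
            x = np.log(a)
            out = np.exp(self.b0 + self.b1 * x + self.b2 * x * x)
        else:
            x = np.log(a) if self.form == "poly2_logage" else a
            out = np.maximum(self.b0 + self.b1 * x + self.b2 * x * x, 0.0)
        return out if out.ndim else float(out)

    def peak_age(self) -> float | None:
        """Interior maximum of a hump-shaped log-quadratic fit (b2 < 0)."""
        if self.form == "log_quadratic" and self.b2 < 0:
            return float(np.exp(-self.b1 / (2.0 * self.b2)))
        if self.form != "log_quadratic" and self.b2 < 0:
            vertex = -self.b1 / (2.0 * self.b2)
            return float(np.exp(vertex) if self.form == "poly2_logage" else vertex)
        return None

    def summary(self) -> str:
        return (f"AgeTrend[{self.flux}] form={self.form} "
                f"b0={self.b0:.4f} b1={self.b1:.4f} b2={self.b2:.6f} "
                f"rmse={self.rmse:.2f} R2={self.r2:.3f} n={self.nobs}")


def _r2(y: np.ndarray, yhat: np.ndarray) -> float:
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    return 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0


class AgeTrendModel:
    """Flux-versus-stand-age regression model.

    Parameters
    ----------
    ages : array-like
        Stand ages in years (>= 1 for the log-quadratic form).
    values : array-like
        Per-stand flux values (3-year means), g C m-2 yr-1.
    form : str
        'log_quadratic', 'poly2' (quadratic in age) or 'poly2_logage'.
    flux : str
        Label carried into the results (e.g. 'npp').
    """

    def __init__(self, ages, values, form: str = "log_quadratic",
                 flux: str = "flux", min_age: float = 1.0):
        if form not in FORMS:
            raise ValueError(f"unknown trend form '{form}'")
        self.ages = np.asarray(ages, dtype=float)
        self.values = np.asarray(values, dtype=float)
        self.form = form
        self.flux = flux
        self.min_age = min_age
        min_n = 4 if form == "log_quadratic" else 3
        if self.ages.size < min_n:
            raise ValueError(f"need >= {min_n} stands for form '{form}'")
        if form == "log_quadratic" and (self.ages < 1).any():
            raise ValueError("log-quadratic form requires ages >= 1")

    def fit(self) -> AgeTrendResults:
        if self.form == "log_quadratic":
            return self._fit_log_quadratic()
        return self._fit_poly2()

    def _log_space_solution(self) -> np.ndarray:
        """Closed-form least squares of ln(y) on [1, ln a, (ln a)^2]."""
        x = np.log(self.ages)
        y = np.log(np.maximum(self.values, 1e-12))
        design = np.column_stack([np.ones_like(x), x, x * x])
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)
        return coef

    def _fit_log_quadratic(self) -> AgeTrendResults:
        x = np.log(self.ages)
        y = self.values
        beta0 = self._log_space_solution()

        def residuals(beta):
            return np.exp(beta[0] + beta[1] * x + beta[2] * x * x) - y

        converged = True
        try:
            sol = optimize.least_squares(residuals, x0=beta0, method="lm",
                                         xtol=1e-14, ftol=1e-14, gtol=1e-14)
            beta = sol.x
            if not (sol.success and np.isfinite(beta).all()):
                raise RuntimeError(sol.message)
        except (RuntimeError, ValueError) as exc:
            log.warning("log-quadratic fit for %s failed (%s); using "
                        "log-space solution", self.flux, exc)
            beta, converged = beta0, False
        yhat = np.exp(beta[0] + beta[1] * x + beta[2] * x * x)
        return AgeTrendResults(
            flux=self.flux, form=self.form,
            b0=float(beta[0]), b1=float(beta[1]), b2=float(beta[2]),
            rmse=float(np.sqrt(np.mean((y - yhat) ** 2))),
            r2=_r2(y, yhat), nobs=int(y.size), converged=converged,
            min_age=self.min_age)

    def _fit_poly2(self) -> AgeTrendResults:
        x = np.log(self.ages) if self.form == "poly2_logage" else self.ages
        y = self.values
        design = np.column_stack([np.ones_like(x), x, x * x])
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)
        yhat = design @ coef
        return AgeTrendResults(
            flux=self.flux, form=self.form,
            b0=float(coef[0]), b1=float(coef[1]), b2=float(coef[2]),
            rmse=float(np.sqrt(np.mean((y - yhat) ** 2))),
            r2=_r2(y, yhat), nobs=int(y.size), min_age=self.min_age)


def fit_log_quadratic(ages, values, flux: str = "flux") -> AgeTrendResults:
    """Convenience wrapper: AgeTrendModel(..., form='log_quadratic').fit()."""
    return AgeTrendModel(ages, values, form="log_quadratic", flux=flux).fit()


def fit_poly2(ages, values, flux: str = "flux",
              logage: bool = False) -> AgeTrendResults:
    """Convenience wrapper for the second-degree polynomial RH trend."""
    form = "poly2_logage" if logage else "poly2"
    return AgeTrendModel(ages, values, form=form, flux=flux).fit()


def nep_trend(npp_fit: AgeTrendResults, rh_fit: AgeTrendResults
              ) -> Callable[[np.ndarray], np.ndarray]:
    """NEP(age) as the lazy difference of the NPP and RH trend curves."""
    def nep(age):
        return npp_fit.predict(age) - rh_fit.predict(age)
    return nep
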