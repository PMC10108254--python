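"""Landscape-driver analysis.

Principal component analysis with Varimax factor rotation on the stand
drivers (and, in the primary analysis, the budget fluxes themselves),
Pearson correlations of NEP and tree NPP with the candidate drivers
overall and within age classes, and the saturating LAI-from-biomass
relationship used to fill stands without direct LAI measurements.

The PCA operates on the correlation matrix (drivers carry heterogeneous
units); loadings are eigenvectors scaled by the square root of their
eigenvalues, then Varimax-rotated with Kaiser normalisation.  Sign
convention: the largest-magnitude loading of each component is positive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import ValidationError


@dataclass
class LoadingMatrix:
    """Variables-by-components loading matrix plus explained variance."""

    loadings: pd.DataFrame          # index: variables, columns: PC1..PCk
    explained_variance: np.ndarray  # fraction of total variance, per component
    rotated: bool

    def communalities(self) -> pd.Series:
        return (self.loadings ** 2).sum(axis=1)


def _varimax(loadings: np.ndarray, tol: float = 1e-8,
             max_iter: int = 500) -> np.ndarray:
    """Varimax rotation with Kaiser normalisation (row-normalised)."""
    p, k = loadings.shape
    if k < 2:
        return loadings.copy()
    norms = np.sqrt((loadings ** 2).sum(axis=1))
    norms[norms == 0] = 1.0
    lam = loadings / norms[:, None]
    rot = np.eye(k)
    d_old = 0.0
    for _ in range(max_iter):
        lr = lam @ rot
        u, s, vt = np.linalg.svd(
            lam.T @ (lr ** 3 - lr @ np.diag((lr ** 2).sum(axis=0)) / p))
        rot = u @ vt
        d = s.sum()
        if d_old != 0 and d / d_old < 1 + tol:
            break
        d_old = d
    return (lam @ rot) * norms[:, None]


def pca_varimax(features: pd.DataFrame, n_components: int = 2,
                rotate: bool = True, tol: float = 1e-8,
                max_iter: int = 500) -> LoadingMatrix:
    """PCA of the correlation matrix with optional Varimax rotation.

    ``features`` must hold >= 3 numeric columns with no missing values;
    constant columns are an error (their correlation is undefined).
    """
    if features.shape[1] < 3:
        raise ValueError("need >= 3 variables")
    if features.isna().any().any():
        bad = features.columns[features.isna().any()].tolist()
        raise ValidationError("drivers", f"missing values in column(s): {bad}")
    stds = features.std(ddof=1)
    constant = stds[stds == 0].index.tolist()
    if constant:
        raise ValidationError("drivers",
                              f"constant column(s): {', '.join(constant)}")
    z = (features - features.mean()) / stds
    corr = np.corrcoef(z.to_numpy(), rowvar=False)
    eigvals, eigvecs = np.linalg.eigh(corr)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    eigvals = np.clip(eigvals, 0.0, None)
    k = min(n_components, features.shape[1])
    loadings = eigvecs[:, :k] * np.sqrt(eigvals[:k])
    if rotate and k >= 2:
        loadings = _varimax(loadings, tol=tol, max_iter=max_iter)
    # Deterministic sign: largest |loading| positive per component.
    for j in range(loadings.shape[1]):
        i = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1
    explained = (loadings ** 2).sum(axis=0) / features.shape[1]
    frame = pd.DataFrame(loadings, index=features.columns,
                         columns=[f"PC{j + 1}" for j in range(k)])
    return LoadingMatrix(loadings=frame, explained_variance=explained,
                         rotated=rotate and k >= 2)


def pearson_by_class(values: pd.DataFrame, drivers: pd.DataFrame,
                     grouping: pd.Series, targets: tuple = ("nep", "npp_t"),
                     min_n: int = 3) -> pd.DataFrame:
    """Pearson correlations of each target flux with each driver.

    Computed for all stands pooled ('all') and within each level of
    ``grouping`` (age classes).  Groups with n < ``min_n`` or zero
    variance in either variable are marked not-computed (NaN r and p).
    Returns long format: group, target, driver, n, r, p.
    """
    merged = values.join(drivers, how="inner")
    grouping = grouping.reindex(merged.index)
    driver_cols = [c for c in drivers.columns]
    rows = []
    groups = [("all", merged)] + [
        (str(g), sub) for g, sub in merged.groupby(grouping)]
    for gname, sub in groups:
        for target in targets:
            for driver in driver_cols:
                pair = sub[[target, driver]].dropna()
                n = len(pair)
                if n < min_n or pair[target].std() == 0 or pair[driver].std() == 0:
                    rows.append({"group": gname, "target": target,
                                 "driver": driver, "n": n,
                                 "r": np.nan, "p": np.nan})
                    continue
                r, p = stats.pearsonr(pair[target], pair[driver])
                rows.append({"group": gname, "target": target,
                             "driver": driver, "n": n,
                             "r": float(r), "p": float(p)})
    return pd.DataFrame(rows)


def fit_lai_biomass(biomass: np.ndarray, lai: np.ndarray
                    ) -> tuple[float, float]:
    """Fit the saturating LAI = L_max * B / (B + h) relationship."""
    biomass = np.asarray(biomass, dtype=float)
    lai = np.asarray(lai, dtype=float)
    if biomass.size < 3:
        raise ValueError("need >= 3 reference (biomass, LAI) pairs")

    def model(b, l_max, h):
        return l_max * b / (b + h)

    p0 = [max(lai.max(), 0.1) * 1.2, max(np.median(biomass), 1.0)]
    popt, _ = optimize.curve_fit(model, biomass, lai, p0=p0,
                                 bounds=([1e-9, 1e-9], [np.inf, np.inf]),
                                 maxfev=10000)
    return float(popt[0]), float(popt[1])


def impute_lai(biomass, reference_biomass, reference_lai):
    """Predict LAI_max from aboveground tree biomass (Mg ha-1).

    Saturating Michaelis-Menten-type fit through the reference pairs;
    predictions are non-negative and approach L_max for large biomass.
    """
    l_max, h = fit_lai_biomass(np.asarray(reference_biomass, dtype=float),
                               np.asarray(reference_lai, dtype=float))
    b = np.asarray(biomass, dtype=float)
    out = np.maximum(l_max * b / (b + h), 0.0)
    return out if out.ndim else float(out)
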