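"""Factorability diagnostics, factor-retention criteria, and exploratory
factor analysis (ML extraction, promax rotation)."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from openwmb.errors import ConfigurationError, ModelFitError


def _corr(data) -> tuple[np.ndarray, int]:
    if isinstance(data, pd.DataFrame):
        arr = data.to_numpy(dtype=float)
    else:
        arr = np.asarray(data, dtype=float)
    n, p = arr.shape
    if n <= p:
        raise ConfigurationError("need more observations than variables")
    return np.corrcoef(arr, rowvar=False), n


def kmo(data) -> dict:
    """Kaiser-Meyer-Olkin sampling adequacy from simple vs anti-image
    partial correlations. Returns the overall measure and per-variable
    values."""
    R, _ = _corr(data)
    try:
        inv = np.linalg.inv(R)
    except np.linalg.LinAlgError as exc:
        raise ConfigurationError("singular correlation matrix") from exc
    d = np.sqrt(np.diag(inv))
    partial = -inv / np.outer(d, d)
    np.fill_diagonal(partial, 0.0)
    r2 = R.copy()
    np.fill_diagonal(r2, 0.0)
    r2 = r2**2
    a2 = partial**2
    overall = r2.sum() / (r2.sum() + a2.sum())
    per_var = r2.sum(axis=0) / (r2.sum(axis=0) + a2.sum(axis=0))
    cols = list(data.columns) if isinstance(data, pd.DataFrame) else list(
        range(R.shape[0]))
    return {"overall": float(overall),
            "per_variable": pd.Series(per_var, index=cols)}


def bartlett_sphericity(data) -> dict:
    """Bartlett's test: chi2 = -(n - 1 - (2p + 5)/6) ln|R|,
    df = p(p-1)/2."""
    R, n = _corr(data)
    p = R.shape[0]
    sign, logdet = np.linalg.slogdet(R)
    if sign <= 0:
        raise ConfigurationError("singular correlation matrix")
    chi2 = -(n - 1 - (2 * p + 5) / 6.0) * logdet
    df = p * (p - 1) // 2
    return {"chi2": float(chi2), "df": int(df),
            "p_value": float(stats.chi2.sf(chi2, df))}


@dataclass(frozen=True)
class RetentionDiagnostics:
    eigenvalues: np.ndarray
    kaiser: int
    parallel: int
    parallel_thresholds: np.ndarray
    scree_elbow: int  # advisory: factors before the largest drop-off


def retention_diagnostics(data, reps: int = 1000, rng=None,
                          percentile: float = 95.0) -> RetentionDiagnostics:
    """How many factors to retain: Kaiser's criterion (eigenvalues > 1),
    parallel analysis (observed eigenvalue above the 95th percentile of
    random-data eigenvalues at the same n and p), and an advisory scree
    elbow (largest second difference of the eigenvalue profile)."""
    if reps < 100:
        raise ConfigurationError("parallel analysis needs at least 100 replicates")
    R, n = _corr(data)
    p = R.shape[0]
    eig = np.sort(np.linalg.eigvalsh(R))[::-1]
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    sim = np.empty((reps, p))
    for r in range(reps):
        x = rng.standard_normal((n, p))
        sim[r] = np.sort(np.linalg.eigvalsh(np.corrcoef(x, rowvar=False)))[::-1]
    thresholds = np.percentile(sim, percentile, axis=0)
    parallel = int(np.argmin(eig > thresholds)) if not (eig > thresholds).all() else p
    kaiser = int((eig > 1.0).sum())
    if p >= 3:
        second_diff = eig[:-2] - 2 * eig[1:-1] + eig[2:]
        scree = int(np.argmax(second_diff) + 1)
    else:
        scree = 1
    return RetentionDiagnostics(eig, kaiser, parallel, thresholds, scree)


@dataclass
class FactorSolution:
    loadings: pd.DataFrame
    uniquenesses: pd.Series
    eigenvalues: np.ndarray
    prop_variance: float
    rotation: Optional[str]
    factor_corr: Optional[pd.DataFrame]
    kmo: float
    bartlett: dict
    retention: Optional[RetentionDiagnostics]


def efa_ml(data, n_factors: int = 1, rotation_power: int = 4,
           retention: bool = False, reps: int = 1000, rng=None) -> FactorSolution:
    """ML exploratory factor analysis with promax rotation (power 4) for
    multi-factor solutions; rotation is a no-op for one factor.

    Extraction is delegated to statsmodels; loadings signs are fixed so
    each factor's loading sum is positive.
    """
    from statsmodels.multivariate.factor import Factor

    if n_factors < 1:
        raise ConfigurationError("n_factors must be at least 1")
    if isinstance(data, pd.DataFrame):
        cols = list(data.columns)
        arr = data.to_numpy(dtype=float)
    else:
        arr = np.asarray(data, dtype=float)
        cols = [f"x{i}" for i in range(arr.shape[1])]
    try:
        model = Factor(arr, n_factor=n_factors, method="ml")
        res = model.fit()
    except Exception as exc:  # noqa: BLE001
        raise ModelFitError(f"ML extraction failed: {exc}") from exc
    factor_corr = None
    rotation = None
    if n_factors > 1:
        res.rotate("promax")
        rotation = "promax"
        load = np.asarray(res.loadings)
        try:
            phi = np.asarray(res.factor_corr) if hasattr(res, "factor_corr") else None
        except Exception:  # noqa: BLE001
            phi = None
    else:
        load = np.asarray(res.loadings)
        phi = None
    signs = np.where(load.sum(axis=0) < 0, -1.0, 1.0)
    load = load * signs
    communality = (np.asarray(res.loadings) ** 2).sum(axis=1)
    uniq = 1.0 - communality
    R = np.corrcoef(arr, rowvar=False)
    eig = np.sort(np.linalg.eigvalsh(R))[::-1]
    prop_var = float(communality.sum() / arr.shape[1])
    fac_names = [f"F{i + 1}" for i in range(n_factors)]
    return FactorSolution(
        loadings=pd.DataFrame(load, index=cols, columns=fac_names),
        uniquenesses=pd.Series(uniq, index=cols),
        eigenvalues=eig,
        prop_variance=prop_var,
        rotation=rotation,
        factor_corr=(pd.DataFrame(phi, index=fac_names, columns=fac_names)
                     if phi is not None else None),
        kmo=kmo(pd.DataFrame(arr, columns=cols))["overall"],
        bartlett=bartlett_sphericity(pd.DataFrame(arr, columns=cols)),
        retention=(retention_diagnostics(pd.DataFrame(arr, columns=cols),
                                         reps=reps, rng=rng)
                   if retention else None),
    )
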