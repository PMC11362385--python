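"""Chained-equation multiple imputation with predictor restrictions, and
Rubin pooling of per-imputation estimates.

Missing working-memory scores are imputed only from other working-memory
scores, and reasoning scores only from other reasoning scores; a predictor
pair can additionally be dropped when its observed correlation is
non-significant (the convention applied to the n-back/multimodal pair).
Each variable's missing cells are drawn from a Bayesian normal linear
regression on its predictor set (the chained-equations "norm" method),
iterated over several cycles; ``m`` independent chains give the completed
datasets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from openwmb.errors import ConfigurationError


@dataclass
class ImputationSet:
    """``m`` completed tables; observed cells are identical across tables."""

    tables: list
    predictor_rules: dict
    missing_mask: pd.DataFrame

    @property
    def m(self) -> int:
        return len(self.tables)

    def pooled_mean(self) -> pd.Series:
        return pd.concat(self.tables).groupby(level=0).mean().mean()


def default_predictor_rules(df: pd.DataFrame, wm_cols: Sequence[str],
                            gf_cols: Sequence[str] = (),
                            drop_nonsignificant: bool = True,
                            alpha: float = 0.05) -> dict:
    """WM variables predicted only by WM variables, reasoning variables only
    by reasoning variables; optionally drop predictor pairs whose observed
    correlation is non-significant at ``alpha``."""
    rules = {}
    groups = [list(wm_cols)] + ([list(gf_cols)] if gf_cols else [])
    for group in groups:
        for col in group:
            preds = [c for c in group if c != col]
            if drop_nonsignificant:
                kept = []
                for c in preds:
                    pair = df[[col, c]].dropna()
                    if len(pair) < 3:
                        continue
                    r, p = stats.pearsonr(pair[col], pair[c])
                    if p < alpha:
                        kept.append(c)
                preds = kept if kept else preds  # never leave a variable stranded
            rules[col] = preds
    return rules


def _bayes_norm_draw(y, X, rng):
    """Posterior draw of (beta, sigma) for a normal linear model with a
    flat prior, then return a function imputing from it."""
    n, q = X.shape
    XtX = X.T @ X
    XtX_inv = np.linalg.pinv(XtX)
    beta_hat = XtX_inv @ X.T @ y
    resid = y - X @ beta_hat
    df_res = max(n - q, 1)
    sigma2 = float(resid @ resid) / stats.chi2.rvs(df_res, random_state=rng)
    L = np.linalg.cholesky(XtX_inv * sigma2 + 1e-12 * np.eye(q))
    beta = beta_hat + L @ rng.standard_normal(q)
    return beta, np.sqrt(sigma2)


def impute(df: pd.DataFrame, m: int = 20,
           predictor_rules: Optional[dict] = None,
           rng=None, n_cycles: int = 10) -> ImputationSet:
    """Multiply impute missing cells of ``df``.

    With no missing cells the result is ``m`` identical copies. Columns
    with 50% or more missingness are refused.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    mask = df.isna()
    frac = mask.mean()
    too_sparse = frac[frac >= 0.5]
    if not too_sparse.empty:
        raise ConfigurationError(
            f"columns exceed 50% missingness: {list(too_sparse.index)}")
    cols_with_na = [c for c in df.columns if mask[c].any()]
    if predictor_rules is None:
        predictor_rules = {c: [x for x in df.columns if x != c] for c in df.columns}
    for col in cols_with_na:
        if not predictor_rules.get(col):
            raise ConfigurationError(f"empty predictor set for {col}")

    tables = []
    for _ in range(m):
        work = df.copy()
        # initialize missing cells from observed mean + residual noise
        for col in cols_with_na:
            obs = df[col].dropna()
            n_na = int(mask[col].sum())
            work.loc[mask[col], col] = (
                obs.mean() + obs.std(ddof=1) * rng.standard_normal(n_na))
        for _cycle in range(n_cycles if cols_with_na else 0):
            for col in cols_with_na:
                preds = predictor_rules[col]
                obs_rows = ~mask[col]
                X_obs = np.column_stack(
                    [np.ones(obs_rows.sum())]
                    + [work.loc[obs_rows, c].to_numpy(dtype=float) for c in preds])
                y_obs = work.loc[obs_rows, col].to_numpy(dtype=float)
                beta, sigma = _bayes_norm_draw(y_obs, X_obs, rng)
                X_mis = np.column_stack(
                    [np.ones(int(mask[col].sum()))]
                    + [work.loc[mask[col], c].to_numpy(dtype=float) for c in preds])
                work.loc[mask[col], col] = (
                    X_mis @ beta + sigma * rng.standard_normal(X_mis.shape[0]))
        tables.append(work)
    return ImputationSet(tables, dict(predictor_rules), mask)


@dataclass(frozen=True)
class PooledEstimate:
    """Rubin's rules: pooled point estimate, within/between variance,
    total variance, pooled SE, and fraction of missing information."""

    estimate: float
    se: float
    within: float
    between: float
    total: float
    gamma: float
    m: int
    df: float


def rubin_pool(estimates: Sequence[float], ses: Sequence[float]) -> PooledEstimate:
    """Pool per-imputation estimates and standard errors.

    ``T = W + (1 + 1/m) B``; with ``m = 1`` the between term is absent and
    the result reduces to the single fit.
    """
    q = np.asarray(estimates, dtype=float)
    u = np.asarray(ses, dtype=float) ** 2
    if q.size != u.size or q.size < 1:
        raise ConfigurationError("estimates and SEs must align, length >= 1")
    m = q.size
    qbar = float(q.mean())
    wbar = float(u.mean())
    if m == 1:
        return PooledEstimate(qbar, float(np.sqrt(wbar)), wbar, 0.0, wbar,
                              0.0, 1, np.inf)
    b = float(q.var(ddof=1))
    t = wbar + (1 + 1 / m) * b
    gamma = ((1 + 1 / m) * b / t) if t > 0 else 0.0
    df = (m - 1) * (1 + wbar / ((1 + 1 / m) * b)) ** 2 if b > 0 else np.inf
    return PooledEstimate(qbar, float(np.sqrt(t)), wbar, b, t, float(gamma), m,
                          float(df))
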