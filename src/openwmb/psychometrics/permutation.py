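"""Permutation analysis: how much variance a fluid-intelligence factor
shares with WMC measured by (1) each task alone, (2) homogeneous
within-paradigm factors, and (3) heterogeneous one-task-per-paradigm
triplets.

With three complex spans, two updating tasks, and two binding tasks this
yields 7 single-task models, 3 homogeneous models (the complex-span triple
plus the equality-constrained updating and binding pairs), and
3 x 2 x 2 = 12 heterogeneous triplets — 22 models. Rows are ranked by the
shared variance R^2, with poorly fitting models listed last.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from openwmb.errors import ConfigurationError, ModelFitError, OpenWMBError
from openwmb.psychometrics.sem import ModelSpec, SemResult, fit_factor_model

#: acceptability thresholds applied to each fitted model
ACCEPT_CHI2_DF = 3.0
ACCEPT_CFI = 0.90
ACCEPT_SRMR = 0.08


@dataclass
class PermutationRow:
    indicators: tuple
    model_class: str  # single_task | homogeneous | heterogeneous
    r2: float
    chi2: float
    df: int
    p_value: float
    chi2_df: float
    cfi: float
    rmsea: float
    srmr: float
    acceptable: bool
    error: Optional[str] = None


def candidate_models(wm_cols: Sequence[str], paradigms: dict) -> list:
    """Enumerate the 22 candidate WMC measurement models."""
    by_par: dict[str, list] = {}
    for col in wm_cols:
        by_par.setdefault(paradigms[col], []).append(col)
    if set(by_par) != {"cs", "up", "bi"}:
        raise ConfigurationError(
            f"paradigm map must cover cs/up/bi, got {sorted(by_par)}")
    models = [("single_task", (col,)) for col in wm_cols]
    models += [("homogeneous", tuple(cols)) for cols in
               (by_par["cs"], by_par["up"], by_par["bi"])]
    models += [("heterogeneous", trip) for trip in
               itertools.product(by_par["cs"], by_par["up"], by_par["bi"])]
    return models


def _acceptable(fit: SemResult) -> bool:
    return (fit.df == 0 or fit.chi2_df < ACCEPT_CHI2_DF) \
        and fit.cfi >= ACCEPT_CFI and fit.srmr < ACCEPT_SRMR


def fit_wmc_gf_model(indicators: Sequence[str], data: pd.DataFrame,
                     gf_cols: Sequence[str]) -> SemResult:
    """A WMC factor over ``indicators`` correlated with a 3-indicator Gf
    factor.

    With a single indicator no WMC factor is formed: the observed task
    enters as a fourth indicator of the Gf factor (equivalently, the task
    regressed on latent Gf), and the shared variance is its squared
    standardized loading.
    """
    if len(indicators) == 1:
        spec = ModelSpec.from_dict({"GF": list(indicators) + list(gf_cols)})
    else:
        spec = ModelSpec.from_dict({"WMC": list(indicators), "GF": list(gf_cols)})
    return fit_factor_model(spec, data=data[list(indicators) + list(gf_cols)])


def shared_variance(fit: SemResult, indicators: Sequence[str]) -> float:
    """R^2 between the WMC construct (factor or single task) and Gf."""
    if len(indicators) == 1:
        return float(fit.loadings.loc[indicators[0], "GF"] ** 2)
    return float(fit.factor_corr.loc["WMC", "GF"] ** 2)


def permutation_analysis(wm_scores: pd.DataFrame, gf_scores: pd.DataFrame,
                         paradigms: Optional[dict] = None) -> pd.DataFrame:
    """Fit all 22 models and tabulate shared variance and fit.

    ``wm_scores`` must hold the 7 task columns (complete cases),
    ``gf_scores`` the 3 reasoning columns on the same index. ``paradigms``
    maps WM column -> paradigm code (cs/up/bi); the default recognizes the
    canonical task names. Per-model failures are recorded in their row
    rather than aborting the sweep.
    """
    from openwmb.responder import PARADIGM_OF

    wm_cols = list(wm_scores.columns)
    gf_cols = list(gf_scores.columns)
    if len(wm_cols) != 7 or len(gf_cols) != 3:
        raise ConfigurationError("expected 7 WM columns and 3 Gf columns")
    if paradigms is None:
        unknown = [c for c in wm_cols if c not in PARADIGM_OF]
        if unknown:
            raise ConfigurationError(
                f"cannot infer paradigms for {unknown}; pass `paradigms`")
        paradigms = {c: PARADIGM_OF[c] for c in wm_cols}
    data = pd.concat([wm_scores, gf_scores], axis=1).dropna()

    rows = []
    for model_class, indicators in candidate_models(wm_cols, paradigms):
        try:
            fit = fit_wmc_gf_model(indicators, data, gf_cols)
            r2 = shared_variance(fit, indicators)
            rows.append(PermutationRow(
                tuple(indicators), model_class, r2, fit.chi2, fit.df,
                fit.p_value, fit.chi2_df, fit.cfi, fit.rmsea, fit.srmr,
                _acceptable(fit) and fit.converged and not fit.heywood,
            ))
        except OpenWMBError as exc:
            rows.append(PermutationRow(
                tuple(indicators), model_class, np.nan, np.nan, 0, np.nan,
                np.nan, np.nan, np.nan, np.nan, False, error=str(exc)))

    df = pd.DataFrame([r.__dict__ for r in rows])
    df["indicators"] = df["indicators"].map(lambda t: "-".join(t))
    df = df.sort_values(["acceptable", "r2"], ascending=[False, False])
    return df.reset_index(drop=True)
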