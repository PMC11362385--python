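"""Internal-consistency coefficients computed at the level of individual
trials: Cronbach's alpha and McDonald's omega."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from openwmb.errors import ConfigurationError, ModelFitError
from openwmb.psychometrics.sem import ModelSpec, fit_factor_model


@dataclass(frozen=True)
class ReliabilityResult:
    alpha: float
    omega: float
    k: int
    flags: tuple = ()


def _item_matrix(items) -> np.ndarray:
    x = items.to_numpy(dtype=float) if isinstance(items, pd.DataFrame) else np.asarray(
        items, dtype=float)
    if x.ndim != 2:
        raise ConfigurationError("item matrix must be 2-dimensional")
    if x.shape[1] < 2 or x.shape[0] < 3:
        raise ConfigurationError("need at least 2 items and 3 observations")
    return x


def cronbach_alpha(items) -> float:
    """alpha = k/(k-1) * (1 - sum(item variances) / total variance)."""
    x = _item_matrix(items)
    k = x.shape[1]
    item_var = x.var(axis=0, ddof=1)
    total_var = x.sum(axis=1).var(ddof=1)
    if total_var == 0:
        warnings.warn("zero total variance: alpha is undefined")
        return np.nan
    return float(k / (k - 1) * (1.0 - item_var.sum() / total_var))


def mcdonald_omega(items) -> ReliabilityResult:
    """omega = (sum lambda)^2 / ((sum lambda)^2 + sum theta) from a
    one-factor ML solution on the item covariance matrix.

    Returns a flagged result (``omega = nan``) on non-convergence; Heywood
    cases are flagged but still reported.
    """
    x = _item_matrix(items)
    keep = x.var(axis=0, ddof=1) > 0
    flags = []
    if not keep.all():
        flags.append(f"dropped {int((~keep).sum())} zero-variance items")
        x = x[:, keep]
    k = x.shape[1]
    df = pd.DataFrame(x, columns=[f"i{j}" for j in range(k)])
    spec = ModelSpec.from_dict({"F": list(df.columns)})
    try:
        fit = fit_factor_model(spec, data=df)
    except ModelFitError as exc:
        return ReliabilityResult(cronbach_alpha(items), np.nan, k,
                                 ("non-convergence", str(exc)))
    if not fit.converged:
        flags.append("non-convergence")
    if fit.heywood:
        flags.append("Heywood case")
    lam = fit.loadings["F"].to_numpy()
    if lam.sum() < 0:
        lam = -lam
    theta = fit.uniquenesses.to_numpy()
    om = float(lam.sum() ** 2 / (lam.sum() ** 2 + theta.sum()))
    return ReliabilityResult(cronbach_alpha(items), om, k, tuple(flags))


def reliability(items) -> ReliabilityResult:
    """Trial-level alpha and omega for one task's item matrix
    (participants x trials)."""
    return mcdonald_omega(items)


def trial_item_matrix(records, task: str) -> pd.DataFrame:
    """Participants x trials correctness matrix for trial-level reliability.

    Complex spans use the 60 test memory items; the n-back uses the 36
    scored test items; updating uses per-trial digit counts (0-3); binding
    uses the 16 test judgments. The adaptive multimodal span has no fixed
    item set; its columns are per-length first-attempt successes and rows
    that never reached a length hold NaN.
    """
    from openwmb.engine import records_to_frame

    df = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    df = df[(df["task"] == task) & (df["phase"] == "test")]
    if df.empty:
        raise ConfigurationError(f"no test records for task {task!r}")
    if task in ("reading", "operation", "symmetry"):
        sub = df[df["segment"] == "memory"].copy()
        sub["item"] = (sub["block_index"].astype(str) + ":"
                       + sub["trial_index"].astype(str))
        mat = sub.pivot_table(index="participant_id", columns="item",
                              values="correct", aggfunc="first")
    elif task == "nback":
        sub = df[(df["segment"] == "item") & df["scored"]]
        mat = sub.pivot_table(index="participant_id", columns="trial_index",
                              values="correct", aggfunc="first")
    elif task == "updating":
        sub = df[df["segment"] == "trial"].copy()
        import json

        sub["n_correct"] = sub["response"].map(lambda s: json.loads(s)["n_correct"])
        # trials are presented in participant-random order; key items by
        # their content so columns align across participants
        sub["item"] = sub["stimulus"]
        mat = sub.pivot_table(index="participant_id", columns="item",
                              values="n_correct", aggfunc="first")
    elif task == "binding":
        sub = df[df["segment"] == "trial"].copy()
        sub["item"] = sub["stimulus"]
        mat = sub.pivot_table(index="participant_id", columns="item",
                              values="correct", aggfunc="first")
    elif task == "multimodal":
        sub = df[df["segment"] == "trial"].copy()
        sub = sub.sort_values("trial_index").drop_duplicates(
            ["participant_id", "set_size"], keep="first")
        mat = sub.pivot_table(index="participant_id", columns="set_size",
                              values="correct", aggfunc="first")
    else:
        raise ConfigurationError(f"unknown task {task!r}")
    return mat.astype(float)
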