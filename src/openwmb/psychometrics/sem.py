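"""Maximum-likelihood confirmatory factor analysis / SEM.

Fits covariance-structure models of the form ``Sigma = Lambda Phi Lambda' +
Theta`` (simple structure: each indicator loads on exactly one factor;
factor variances fixed to 1; all factor pairs obliquely correlated; Theta
diagonal) by minimizing the ML discrepancy

    F_ML = ln|Sigma| + tr(S Sigma^-1) - ln|S| - p

with an analytic gradient. The chi-square statistic uses the
``(N - 1) * F_ML`` convention by default (``n_scaling="n-1"``; pass
``"n"`` for the alternative). Standard errors come from the numerically
differentiated Hessian of ``F_ML``: ``acov = 2/(N-1) * H^-1``.

Observed variables can enter a structural model directly by declaring a
single-indicator factor: its loading is fixed to the indicator's standard
deviation and its uniqueness to zero, so the "factor" is the standardized
observed variable and its correlations with other factors are standardized
paths.

Two-indicator factors are identified by constraining their two loadings to
equality, the convention used for updating-only and binding-only models.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from openwmb.errors import ConfigurationError, ModelFitError

_UNIQ_FLOOR = 1e-6


@dataclass(frozen=True)
class ModelSpec:
    """A measurement/structural model: ordered mapping factor -> indicators.

    ``equal_loadings`` lists factors whose loadings are constrained equal;
    by default every two-indicator factor is so constrained (required for
    identification). All factor pairs are correlated.
    """

    factors: tuple[tuple[str, tuple[str, ...]], ...]
    equal_loadings: frozenset = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        seen = set()
        for name, inds in self.factors:
            if not inds:
                raise ConfigurationError(f"factor {name} has no indicators")
            for ind in inds:
                if ind in seen:
                    raise ConfigurationError(f"indicator {ind} loads on two factors")
                seen.add(ind)
        if self.equal_loadings is None:
            auto = frozenset(name for name, inds in self.factors if len(inds) == 2)
            object.__setattr__(self, "equal_loadings", auto)

    @property
    def indicators(self) -> tuple[str, ...]:
        return tuple(ind for _, inds in self.factors for ind in inds)

    @property
    def factor_names(self) -> tuple[str, ...]:
        return tuple(name for name, _ in self.factors)

    @classmethod
    def from_dict(cls, factors: dict, equal_loadings=None) -> "ModelSpec":
        return cls(tuple((k, tuple(v)) for k, v in factors.items()),
                   None if equal_loadings is None else frozenset(equal_loadings))


def parse_model(text: str) -> ModelSpec:
    """Parse a minimal model syntax, e.g.
    ``"WMC =~ RS OS SS NB UT MS BT; GF =~ LS NS RAPM; WMC ~~ GF"``.

    ``=~`` declares a factor's indicators; ``~~`` lines (factor
    covariances) are validated but carry no information because all factor
    pairs are correlated by default.
    """
    factors: dict[str, tuple[str, ...]] = {}
    names: set[str] = set()
    for raw in re.split(r"[;\n]", text):
        line = raw.strip()
        if not line:
            continue
        if "=~" in line:
            lhs, rhs = line.split("=~")
            name = lhs.strip()
            inds = tuple(rhs.split())
            if not name or not inds:
                raise ConfigurationError(f"malformed factor line {line!r}")
            factors[name] = inds
            names.add(name)
        elif "~~" in line:
            lhs, rhs = (s.strip() for s in line.split("~~"))
            for side in (lhs, rhs):
                if side not in names and all(side not in inds
                                             for inds in factors.values()):
                    raise ConfigurationError(
                        f"covariance line references unknown name {side!r}")
        else:
            raise ConfigurationError(f"cannot parse model line {line!r}")
    return ModelSpec.from_dict(factors)


# ---------------------------------------------------------------------------
# Parameterization
# ---------------------------------------------------------------------------

class _Parameterization:
    """Maps a free-parameter vector to (Lambda, Phi, Theta) and back."""

    def __init__(self, spec: ModelSpec, s_diag: np.ndarray):
        self.spec = spec
        inds = spec.indicators
        self.p = len(inds)
        self.m = len(spec.factors)
        self.ind_index = {name: i for i, name in enumerate(inds)}
        self.fac_index = {name: i for i, name in enumerate(spec.factor_names)}
        self.fixed_lambda = np.zeros((self.p, self.m))
        self.fixed_theta = np.full(self.p, np.nan)  # nan = free
        self.names: list[str] = []
        self.load_map: list[tuple[int, list[int]]] = []  # (factor col, rows)
        self.theta_map: list[int] = []
        self.corr_map: list[tuple[int, int]] = []
        for f, (fname, find) in enumerate(spec.factors):
            rows = [self.ind_index[i] for i in find]
            if len(find) == 1:
                # observed-as-factor: loading = sd(indicator), uniqueness 0
                j = rows[0]
                self.fixed_lambda[j, f] = np.sqrt(s_diag[j])
                self.fixed_theta[j] = 0.0
            elif fname in spec.equal_loadings:
                self.names.append(f"lambda:{fname}")
                self.load_map.append((f, rows))
            else:
                for ind, j in zip(find, rows):
                    self.names.append(f"lambda:{fname}:{ind}")
                    self.load_map.append((f, [j]))
        self.n_load = len(self.load_map)
        for j, ind in enumerate(inds):
            if np.isnan(self.fixed_theta[j]):
                self.names.append(f"theta:{ind}")
                self.theta_map.append(j)
        for f in range(self.m):
            for g in range(f + 1, self.m):
                self.names.append(
                    f"phi:{spec.factor_names[f]}:{spec.factor_names[g]}")
                self.corr_map.append((f, g))
        self.n_free = len(self.names)

    def start(self, s_diag: np.ndarray) -> np.ndarray:
        theta0 = []
        for f, rows in self.load_map:
            theta0.append(0.7 * np.sqrt(np.mean(s_diag[rows])))
        for j in self.theta_map:
            theta0.append(0.5 * s_diag[j])
        theta0.extend(0.3 for _ in self.corr_map)
        return np.array(theta0)

    def bounds(self):
        b = [(None, None)] * self.n_load
        b += [(_UNIQ_FLOOR, None)] * len(self.theta_map)
        b += [(-0.999, 0.999)] * len(self.corr_map)
        return b

    def matrices(self, theta: np.ndarray):
        lam = self.fixed_lambda.copy()
        for (f, rows), v in zip(self.load_map, theta[: self.n_load]):
            lam[rows, f] = v
        th = self.fixed_theta.copy()
        for j, v in zip(self.theta_map,
                        theta[self.n_load: self.n_load + len(self.theta_map)]):
            th[j] = v
        phi = np.eye(self.m)
        for (f, g), v in zip(self.corr_map,
                             theta[self.n_load + len(self.theta_map):]):
            phi[f, g] = phi[g, f] = v
        return lam, phi, np.nan_to_num(th)


def _fml_and_grad(theta, par: _Parameterization, S, logdet_s):
    lam, phi, th = par.matrices(theta)
    sigma = lam @ phi @ lam.T + np.diag(th)
    sign, logdet = np.linalg.slogdet(sigma)
    if sign <= 0:
        return 1e10, np.zeros_like(theta)
    sigma_inv = np.linalg.inv(sigma)
    f = logdet + np.trace(S @ sigma_inv) - logdet_s - par.p
    omega = sigma_inv @ (sigma - S) @ sigma_inv
    grad = np.empty_like(theta)
    lam_phi = lam @ phi
    k = 0
    for f_col, rows in par.load_map:
        g = 0.0
        for j in rows:
            g += 2.0 * omega[j] @ lam_phi[:, f_col]
        grad[k] = g
        k += 1
    for j in par.theta_map:
        grad[k] = omega[j, j]
        k += 1
    for f_i, g_i in par.corr_map:
        grad[k] = 2.0 * lam[:, f_i] @ omega @ lam[:, g_i]
        k += 1
    return f, grad


def _num_hessian(theta, par, S, logdet_s, h=1e-5):
    n = theta.size
    H = np.zeros((n, n))
    for k in range(n):
        step = h * max(1.0, abs(theta[k]))
        up = theta.copy(); up[k] += step
        dn = theta.copy(); dn[k] -= step
        _, gu = _fml_and_grad(up, par, S, logdet_s)
        _, gd = _fml_and_grad(dn, par, S, logdet_s)
        H[:, k] = (gu - gd) / (2 * step)
    return 0.5 * (H + H.T)


# ---------------------------------------------------------------------------
# Results
# ---------------------------------------------------------------------------

@dataclass
class SemResult:
    """Estimates and fit of one CFA/SEM."""

    spec: ModelSpec
    n: int
    estimates: pd.Series
    se: pd.Series
    loadings: pd.DataFrame  # standardized
    uniquenesses: pd.Series  # standardized
    factor_corr: pd.DataFrame
    fml: float
    chi2: float
    df: int
    p_value: float
    chi2_df: float
    cfi: float
    rmsea: float
    srmr: float
    omega: dict
    residuals: pd.DataFrame
    std_residuals: pd.DataFrame
    converged: bool
    heywood: bool

    @property
    def large_residuals(self) -> list:
        """Standardized residual cells with |z| > 2.58."""
        out = []
        z = self.std_residuals
        for i, a in enumerate(z.index):
            for j, b in enumerate(z.columns):
                if j <= i and abs(z.iloc[i, j]) > 2.58:
                    out.append((a, b, float(z.iloc[i, j])))
        return out

    def summary(self) -> str:
        lines = [
            f"chi2({self.df}) = {self.chi2:.2f}, p = {self.p_value:.3f}, "
            f"chi2/df = {self.chi2_df:.2f}",
            f"CFI = {self.cfi:.3f}, RMSEA = {self.rmsea:.3f}, SRMR = {self.srmr:.3f}",
        ]
        return "\n".join(lines)


def fit_factor_model(spec, data=None, cov=None, n: Optional[int] = None,
                     n_scaling: str = "n-1", max_restarts: int = 3) -> SemResult:
    """Fit a factor/SEM model by ML.

    Parameters
    ----------
    spec : ModelSpec, dict, or model-syntax string
    data : DataFrame of indicator scores (used to form the sample
        covariance with ddof=1), or pass ``cov`` + ``n`` directly.
    n_scaling : "n-1" (default) or "n"; multiplier of F_ML for chi-square.
    """
    if isinstance(spec, str):
        spec = parse_model(spec)
    elif isinstance(spec, dict):
        spec = ModelSpec.from_dict(spec)
    inds = list(spec.indicators)
    if data is not None:
        missing = set(inds) - set(data.columns)
        if missing:
            raise ConfigurationError(f"data lacks indicators {sorted(missing)}")
        n = len(data)
        S = np.cov(data[inds].to_numpy(dtype=float), rowvar=False, ddof=1)
    else:
        if cov is None or n is None:
            raise ConfigurationError("provide either data or (cov, n)")
        cov = pd.DataFrame(cov, index=inds, columns=inds) if not isinstance(
            cov, pd.DataFrame) else cov
        S = cov.loc[inds, inds].to_numpy(dtype=float)
    p = len(inds)
    par = _Parameterization(spec, np.diag(S))
    n_moments = p * (p + 1) // 2
    if par.n_free > n_moments:
        offenders = [name for name, f_inds in spec.factors if len(f_inds) == 2
                     and name not in spec.equal_loadings]
        raise ModelFitError(
            f"model under-identified: {par.n_free} free parameters for "
            f"{n_moments} moments"
            + (f" (unconstrained two-indicator factors: {offenders})"
               if offenders else ""))
    sign, logdet_s = np.linalg.slogdet(S)
    if sign <= 0:
        raise ModelFitError("sample covariance matrix is singular")

    rng = np.random.default_rng(0)
    best = None
    x0 = par.start(np.diag(S))
    for attempt in range(max_restarts):
        res = optimize.minimize(
            _fml_and_grad, x0, args=(par, S, logdet_s), jac=True,
            method="L-BFGS-B", bounds=par.bounds(),
            options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-8},
        )
        if best is None or res.fun < best.fun:
            best = res
        if res.success and res.fun < 1e9:
            break
        x0 = par.start(np.diag(S)) * (1 + 0.3 * rng.standard_normal(par.n_free))
        x0[par.n_load:] = np.abs(x0[par.n_load:])
    res = best
    converged = bool(res.success and res.fun < 1e9)
    theta = res.x
    lam, phi, th = par.matrices(theta)
    heywood = bool(np.any(th[par.theta_map] <= 2 * _UNIQ_FLOOR)) if par.theta_map else False

    # standard errors
    scale = max(n - 1, 1)
    H = _num_hessian(theta, par, S, logdet_s)
    try:
        acov = (2.0 / scale) * np.linalg.inv(H)
        se = np.sqrt(np.clip(np.diag(acov), 0, None))
    except np.linalg.LinAlgError:
        acov = (2.0 / scale) * np.linalg.pinv(H)
        se = np.sqrt(np.clip(np.diag(acov), 0, None))
        converged = False

    sigma = lam @ phi @ lam.T + np.diag(th)
    fml = float(res.fun)
    df = n_moments - par.n_free
    chi2 = scale * fml if n_scaling == "n-1" else n * fml
    p_value = float(stats.chi2.sf(chi2, df)) if df > 0 else 1.0

    # baseline (independence) model for CFI
    f_base = float(np.sum(np.log(np.diag(S))) - logdet_s)
    chi2_base = (scale if n_scaling == "n-1" else n) * f_base
    df_base = p * (p - 1) // 2
    num = max(chi2 - df, 0.0)
    den = max(chi2_base - df_base, chi2 - df, 0.0)
    cfi = 1.0 - (num / den if den > 0 else 0.0)
    rmsea = float(np.sqrt(max(chi2 - df, 0.0) / (df * scale))) if df > 0 else 0.0
    sd = np.sqrt(np.diag(S))
    resid = S - sigma
    std_resid_corr = resid / np.outer(sd, sd)
    iu = np.triu_indices(p)
    srmr = float(np.sqrt(np.mean(std_resid_corr[iu] ** 2)))
    # z-standardized residual covariances (normal-theory denominator)
    denom = np.sqrt((np.outer(np.diag(sigma), np.diag(sigma)) + sigma**2) / scale)
    z_resid = resid / denom

    # standardized solution
    sigma_diag = np.sqrt(np.diag(sigma))
    lam_std = lam / sigma_diag[:, None]
    th_std = th / np.diag(sigma)
    load_df = pd.DataFrame(lam_std, index=inds, columns=spec.factor_names)
    omega = {}
    for fname, f_inds in spec.factors:
        if len(f_inds) < 2:
            continue
        lsum = float(load_df.loc[list(f_inds), fname].sum())
        tsum = float(sum(th_std[par.ind_index[i]] for i in f_inds))
        omega[fname] = lsum**2 / (lsum**2 + tsum) if lsum**2 + tsum > 0 else np.nan

    return SemResult(
        spec=spec, n=n,
        estimates=pd.Series(theta, index=par.names),
        se=pd.Series(se, index=par.names),
        loadings=load_df,
        uniquenesses=pd.Series(th_std, index=inds),
        factor_corr=pd.DataFrame(phi, index=spec.factor_names,
                                 columns=spec.factor_names),
        fml=fml, chi2=float(chi2), df=df, p_value=p_value,
        chi2_df=float(chi2 / df) if df > 0 else np.nan,
        cfi=float(cfi), rmsea=rmsea, srmr=srmr, omega=omega,
        residuals=pd.DataFrame(resid, index=inds, columns=inds),
        std_residuals=pd.DataFrame(z_resid, index=inds, columns=inds),
        converged=converged, heywood=heywood,
    )
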