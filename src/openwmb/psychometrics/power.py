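"""Proactive Monte Carlo power analysis for sample-size planning.

Replicated datasets of a candidate size N are drawn from the population
factor model (multivariate normal with the model-implied covariance of the
stated loadings and unit indicator variances), the analysis model is
fitted to each, and the averaged results are checked against the standard
sample-size criteria:

* relative parameter bias <= .10 for all parameters,
* relative standard-error bias <= .10 for all parameters and <= .05 for
  the parameters of interest (the factor correlation by default),
* 95% coverage between .91 and .98,
* statistical power (Wald z against 0 at alpha = .05) of at least .80.

A run with more than 10% fit failures is invalid. ``find_min_n`` walks an
ascending grid of candidate sizes and reports the smallest N whose report
passes all criteria.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from openwmb.errors import ConfigurationError, OpenWMBError
from openwmb.psychometrics.sem import ModelSpec, fit_factor_model
from openwmb.responder import GF_TASKS, WM_TASKS, PopulationModel

MAX_FAILURE_RATE = 0.10


def wmc_gf_spec() -> ModelSpec:
    """The two-correlated-factor analysis model: WMC over the 7 WM tasks,
    Gf over the 3 reasoning tasks."""
    return ModelSpec.from_dict({"WMC": list(WM_TASKS), "GF": list(GF_TASKS)})


def population_parameters(population: PopulationModel,
                          spec: Optional[ModelSpec] = None) -> pd.Series:
    """Population value for every free parameter of the analysis model.

    Equality-constrained loadings take the mean of their stated values. A
    single-indicator factor stands for the observed task itself, so its
    population correlation with a latent factor is attenuated by the
    task's loading: ``corr(task, F) = lambda_task * rho``.
    """
    spec = spec or wmc_gf_spec()
    loadings = {**{t: population.wm_loadings[t] for t in population.wm_loadings},
                **{t: population.gf_loadings[t] for t in population.gf_loadings}}
    values = {}
    single = {}
    for fname, inds in spec.factors:
        if len(inds) == 1:
            single[fname] = loadings.get(inds[0], 1.0)
            continue
        if fname in spec.equal_loadings:
            values[f"lambda:{fname}"] = float(np.mean([loadings[i] for i in inds]))
        else:
            for ind in inds:
                values[f"lambda:{fname}:{ind}"] = loadings[ind]
    for fname, inds in spec.factors:
        if len(inds) > 1:
            for ind in inds:
                values[f"theta:{ind}"] = 1.0 - loadings[ind] ** 2
    fnames = spec.factor_names
    for i in range(len(fnames)):
        for j in range(i + 1, len(fnames)):
            rho = population.factor_corr
            rho *= single.get(fnames[i], 1.0) * single.get(fnames[j], 1.0)
            values[f"phi:{fnames[i]}:{fnames[j]}"] = rho
    return pd.Series(values)


def generation_covariance(population: PopulationModel,
                          spec: Optional[ModelSpec] = None) -> pd.DataFrame:
    """Implied covariance of the *analysis model* at its population values
    (unit indicator variances) — the generation model of a proactive Monte
    Carlo run."""
    spec = spec or wmc_gf_spec()
    values = population_parameters(population, spec)
    inds = list(spec.indicators)
    p, m = len(inds), len(spec.factors)
    lam = np.zeros((p, m))
    theta = np.zeros(p)
    for f, (fname, f_inds) in enumerate(spec.factors):
        for ind in f_inds:
            j = inds.index(ind)
            if len(f_inds) == 1:
                lam[j, f] = 1.0
                theta[j] = 0.0
            else:
                key = (f"lambda:{fname}" if fname in spec.equal_loadings
                       else f"lambda:{fname}:{ind}")
                lam[j, f] = values[key]
                theta[j] = values[f"theta:{ind}"]
    phi = np.eye(m)
    fnames = spec.factor_names
    for i in range(m):
        for j in range(i + 1, m):
            phi[i, j] = phi[j, i] = values[f"phi:{fnames[i]}:{fnames[j]}"]
    sigma = lam @ phi @ lam.T + np.diag(theta)
    return pd.DataFrame(sigma, index=inds, columns=inds)


@dataclass
class PowerReport:
    """Per-parameter Monte Carlo summary and the pass/fail verdict."""

    n: int
    reps: int
    failures: int
    table: pd.DataFrame  # per parameter: population, mean_est, rel_bias, ...
    criteria: dict
    verdict: bool
    parameters_of_interest: tuple

    def summary(self) -> str:
        ok = {k: ("pass" if v else "FAIL") for k, v in self.criteria.items()}
        lines = [f"N = {self.n}, reps = {self.reps}, failures = {self.failures}",
                 ", ".join(f"{k}: {v}" for k, v in ok.items()),
                 f"verdict: {'pass' if self.verdict else 'fail'}"]
        return "\n".join(lines)


def monte_carlo_power(population: PopulationModel, n: int, reps: int, rng=None,
                      spec: Optional[ModelSpec] = None,
                      parameters_of_interest: Sequence[str] = ("phi:WMC:GF",),
                      alpha: float = 0.05) -> PowerReport:
    """Run one Monte Carlo sample-size check at sample size ``n``."""
    if reps < 100:
        raise ConfigurationError("at least 100 replications are required")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    spec = spec or wmc_gf_spec()
    pop_values = population_parameters(population, spec)
    sigma = generation_covariance(population, spec).to_numpy()
    chol = np.linalg.cholesky(sigma)
    z_crit = stats.norm.ppf(1 - alpha / 2)

    estimates, ses = [], []
    failures = 0
    for _ in range(reps):
        x = rng.standard_normal((n, len(spec.indicators))) @ chol.T
        S = np.cov(x, rowvar=False, ddof=1)
        try:
            fit = fit_factor_model(spec, cov=pd.DataFrame(
                S, index=spec.indicators, columns=spec.indicators), n=n)
        except OpenWMBError:
            failures += 1
            continue
        if not fit.converged or fit.heywood or not np.all(np.isfinite(fit.se)):
            failures += 1
            continue
        est = fit.estimates.reindex(pop_values.index)
        # sign indeterminacy: align each factor's loading sign with the population
        for fname, inds in spec.factors:
            cols = [k for k in pop_values.index if k.startswith(f"lambda:{fname}")]
            if cols and est[cols].sum() < 0:
                est[cols] = -est[cols]
                for other in spec.factor_names:
                    for key in (f"phi:{fname}:{other}", f"phi:{other}:{fname}"):
                        if key in est.index:
                            est[key] = -est[key]
        estimates.append(est.to_numpy())
        ses.append(fit.se.reindex(pop_values.index).to_numpy())
    n_ok = len(estimates)
    if n_ok == 0:
        raise OpenWMBError("all Monte Carlo replications failed to fit")
    est = np.vstack(estimates)
    se = np.vstack(ses)
    pop = pop_values.to_numpy()

    mean_est = est.mean(axis=0)
    sd_est = est.std(axis=0, ddof=1)
    mean_se = se.mean(axis=0)
    rel_bias = (mean_est - pop) / pop
    rel_se_bias = (mean_se - sd_est) / sd_est
    lo = est - z_crit * se
    hi = est + z_crit * se
    coverage = ((lo <= pop) & (pop <= hi)).mean(axis=0)
    power = (np.abs(est / se) > z_crit).mean(axis=0)

    table = pd.DataFrame({
        "population": pop, "mean_est": mean_est, "rel_bias": rel_bias,
        "sd_est": sd_est, "mean_se": mean_se, "rel_se_bias": rel_se_bias,
        "coverage": coverage, "power": power,
    }, index=pop_values.index)

    interest = [p for p in parameters_of_interest if p in table.index]
    criteria = {
        "relative_bias": bool(np.all(np.abs(rel_bias) <= 0.10)),
        "relative_se_bias": bool(
            np.all(np.abs(rel_se_bias) <= 0.10)
            and np.all(np.abs(table.loc[interest, "rel_se_bias"]) <= 0.05)),
        "coverage": bool(np.all((coverage >= 0.91) & (coverage <= 0.98))),
        "power": bool(np.all(power >= 0.80)),
        "convergence": failures <= MAX_FAILURE_RATE * reps,
    }
    return PowerReport(n, reps, failures, table, criteria,
                       all(criteria.values()), tuple(interest))


@dataclass
class MinNResult:
    min_n: Optional[int]  # None: no grid size passed
    reports: dict  # N -> PowerReport


def find_min_n(population: PopulationModel, grid: Sequence[int], reps: int,
               rng=None, **kwargs) -> MinNResult:
    """Smallest sample size on an ascending grid with a passing verdict.

    All grid sizes are evaluated (each with an independent substream of
    the supplied rng) and their full reports returned.
    """
    grid = list(grid)
    if grid != sorted(grid):
        raise ConfigurationError("grid must be ascending")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    reports = {}
    for n in grid:
        reports[n] = monte_carlo_power(population, n, reps, rng, **kwargs)
    passing = [n for n in grid if reports[n].verdict]
    return MinNResult(passing[0] if passing else None, reports)


def stability_check(population: PopulationModel, n: int, reps: int,
                    seeds: Sequence[int] = (1, 2), **kwargs) -> dict:
    """Run the same Monte Carlo check under different seeds and compare
    verdicts (the recommended two-seed stability procedure)."""
    reports = {s: monte_carlo_power(population, n, reps,
                                    np.random.default_rng(s), **kwargs)
               for s in seeds}
    verdicts = {s: r.verdict for s, r in reports.items()}
    return {"reports": reports, "verdicts": verdicts,
            "stable": len(set(verdicts.values())) == 1}
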