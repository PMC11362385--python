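"""Synthetic participants.

Two simulation routes:

* a *trial-level* latent-ability model (:class:`AbilityResponder`) that
  drives the task engines through the responder interface and produces
  realistic long-format logs; and
* a *score-level* simulator (:func:`simulate_score_table`) that draws task
  scores directly from the factor model implied by a
  :class:`PopulationModel` — the route used by the psychometric pipeline.

The population defaults encode a dominant general working-memory-capacity
(WMC) factor with per-task loadings (reading .70, operation .66, symmetry
.73, n-back .55, updating .64, multimodal .50, binding .86), three fluid-
intelligence (Gf) indicators (letter series .71, number series .70, matrix
reasoning .76), a WMC-Gf factor correlation of .83, and a small paradigm-
specific variance share per task (10% of indicator variance by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from openwmb.errors import ConfigurationError

WM_TASKS = ("reading", "operation", "symmetry", "nback", "updating", "multimodal", "binding")
GF_TASKS = ("letter_series", "number_series", "rapm")

#: paradigm membership: complex span (cs), updating (up), binding (bi)
PARADIGM_OF = {
    "reading": "cs", "operation": "cs", "symmetry": "cs",
    "nback": "up", "updating": "up",
    "multimodal": "bi", "binding": "bi",
}

DEFAULT_WM_LOADINGS = {
    "reading": 0.70, "operation": 0.66, "symmetry": 0.73, "nback": 0.55,
    "updating": 0.64, "multimodal": 0.50, "binding": 0.86,
}
DEFAULT_GF_LOADINGS = {"letter_series": 0.71, "number_series": 0.70, "rapm": 0.76}


@dataclass(frozen=True)
class PopulationModel:
    """Population factor structure generating simulated respondents."""

    wm_loadings: dict = field(default_factory=lambda: dict(DEFAULT_WM_LOADINGS))
    gf_loadings: dict = field(default_factory=lambda: dict(DEFAULT_GF_LOADINGS))
    factor_corr: float = 0.83
    #: per-paradigm share of indicator variance ("small but non-negligible")
    paradigm_variance: dict = field(
        default_factory=lambda: {"cs": 0.10, "up": 0.10, "bi": 0.10}
    )

    def __post_init__(self):
        if not -1.0 <= self.factor_corr <= 1.0:
            raise ConfigurationError("factor correlation must lie in [-1, 1]")
        for task, lam in {**self.wm_loadings, **self.gf_loadings}.items():
            if not 0.0 < lam < 1.0:
                raise ConfigurationError(f"loading for {task} must lie in (0, 1)")
        for task in self.wm_loadings:
            lam = self.wm_loadings[task]
            pi2 = self.paradigm_variance.get(PARADIGM_OF[task], 0.0)
            if lam**2 + pi2 > 1.0:
                raise ConfigurationError(
                    f"{task}: loading^2 + paradigm variance exceeds indicator variance"
                )

    def without_paradigm_variance(self) -> "PopulationModel":
        return replace(self, paradigm_variance={"cs": 0.0, "up": 0.0, "bi": 0.0})


@dataclass(frozen=True)
class AbilityProfile:
    """Latent parameters of one simulated respondent.

    ``g`` is general WMC ability on a standard-normal scale; ``u_cs``,
    ``u_up``, ``u_bi`` are paradigm-specific abilities independent of
    ``g``; ``gf`` is fluid ability correlated ``rho`` with ``g``;
    ``e_task`` scales a stable per-task uniqueness draw; latencies are
    lognormal(``speed_mu``, ``speed_sigma``) in ms; ``lapse`` is the
    probability of a random response.
    """

    g: float
    u_cs: float
    u_up: float
    u_bi: float
    gf: float
    e_task: float = 0.45
    speed_mu: float = 6.6  # exp(6.6) ~ 735 ms median latency
    speed_sigma: float = 0.35
    lapse: float = 0.02

    def __post_init__(self):
        if self.e_task < 0 or self.speed_sigma < 0 or not 0 <= self.lapse <= 1:
            raise ConfigurationError("variance components must be non-negative")


def make_cohort(n: int, population: Optional[PopulationModel] = None,
                seed=None) -> list[AbilityProfile]:
    """Draw ``n`` ability profiles from the multivariate normal implied by
    the population model."""
    if n < 1:
        raise ConfigurationError("cohort size must be at least 1")
    population = population or PopulationModel()
    rng = np.random.default_rng(seed)
    rho = population.factor_corr
    g = rng.standard_normal(n)
    gf = rho * g + np.sqrt(max(1.0 - rho**2, 0.0)) * rng.standard_normal(n)
    u = rng.standard_normal((n, 3))
    return [
        AbilityProfile(g=float(g[i]), u_cs=float(u[i, 0]), u_up=float(u[i, 1]),
                       u_bi=float(u[i, 2]), gf=float(gf[i]))
        for i in range(n)
    ]


# ---------------------------------------------------------------------------
# Trial-level behavior model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BehaviorParams:
    """Free calibration constants mapping latent ability to trial behavior.

    No generative response model is printed for the battery; these are
    artifact choices, with defaults calibrated so that simulated cohorts
    land inside plausible descriptive bands (complex-span normalized means
    around .55-.85). ``a`` is the discrimination of the recall logistic,
    ``b`` the per-item load cost beyond set size 2, and the intercepts set
    overall difficulty per response type.
    """

    a: float = 1.1
    b: float = 0.45
    recall_intercept: float = 1.9
    processing_intercept: float = 2.2
    processing_base: float = 0.5
    nback_intercept: float = 1.1
    updating_intercept: float = 1.3
    binding_intercept: float = 1.4
    binding_delay_cost: float = 0.25
    multimodal_intercept: float = 2.4
    multimodal_load_cost: float = 0.55
    nback_fa_rate: float = 0.10


def _logistic(x: float) -> float:
    return 1.0 / (1.0 + np.exp(-x))


def respond(profile: AbilityProfile, context: dict, rng,
            population: Optional[PopulationModel] = None,
            params: Optional[BehaviorParams] = None):
    """One-shot functional form of the behavior model.

    ``context`` must carry ``task`` and ``kind`` (``judgment`` |
    ``recall_item`` | ``nback`` | ``digit``) plus ``load`` for recall items.
    Returns ``(correct: bool, latency_ms: float)``.
    """
    resp = AbilityResponder(profile, rng=rng, population=population, params=params)
    task = context["task"]
    kind = context["kind"]
    p = resp._p_correct(task, kind, context)
    rng = resp.rng
    correct = bool(rng.random() < p)
    if rng.random() < profile.lapse:
        correct = bool(rng.integers(2))
    return correct, resp._latency()


class AbilityResponder:
    """Responder-interface adapter around an :class:`AbilityProfile`.

    Per-task effective ability is
    ``theta_task = lambda_t * g + pi_p * u_p + e_task * eps_t`` with a
    stable per-task draw ``eps_t``; trial outcomes are Bernoulli with
    logistic success probabilities, latencies lognormal, and lapses
    produce uniform random responses.
    """

    def __init__(self, profile: AbilityProfile, rng=None,
                 population: Optional[PopulationModel] = None,
                 params: Optional[BehaviorParams] = None):
        self.profile = profile
        self.population = population or PopulationModel()
        self.params = params or BehaviorParams()
        self.rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
        u = {"cs": profile.u_cs, "up": profile.u_up, "bi": profile.u_bi}
        self._theta = {}
        for task in WM_TASKS:
            lam = self.population.wm_loadings[task]
            par = PARADIGM_OF[task]
            pi = np.sqrt(self.population.paradigm_variance.get(par, 0.0))
            eps = self.rng.standard_normal()
            self._theta[task] = lam * profile.g + pi * u[par] + profile.e_task * eps

    def theta(self, task: str) -> float:
        if task not in self._theta:
            raise ConfigurationError(f"unknown task {task!r}")
        return self._theta[task]

    # -- internals ----------------------------------------------------------

    def _latency(self) -> float:
        return float(np.exp(self.profile.speed_mu
                            + self.profile.speed_sigma * self.rng.standard_normal()))

    def _lapsed(self) -> bool:
        return bool(self.rng.random() < self.profile.lapse)

    def _p_correct(self, task, kind, context) -> float:
        pr = self.params
        th = self.theta(task)
        if kind == "judgment":
            if task == "binding":
                cost = pr.binding_delay_cost * (context.get("delay_ms", 1000) == 8000)
                return max(pr.processing_base,
                           _logistic(pr.a * (th + pr.binding_intercept - cost)))
            return max(pr.processing_base,
                       _logistic(pr.a * (th + pr.processing_intercept)))
        if kind == "recall_item":
            load = context.get("load", 2)
            base = (pr.multimodal_intercept if task == "multimodal"
                    else pr.recall_intercept)
            cost = (pr.multimodal_load_cost if task == "multimodal" else pr.b)
            return _logistic(pr.a * (th + base - cost * (load - 2)))
        if kind == "nback":
            if context.get("is_target", False):
                return _logistic(pr.a * (th + pr.nback_intercept))
            return 1.0 - min(0.5, max(0.01, pr.nback_fa_rate * float(np.exp(-0.5 * th))))
        if kind == "digit":
            return _logistic(pr.a * (th + pr.updating_intercept))
        raise ConfigurationError(f"unknown response kind {kind!r}")

    # -- responder interface used by the engines ----------------------------

    def judge(self, task, stimulus, truth):
        latency = self._latency()
        if self._lapsed():
            return bool(self.rng.integers(2)), latency
        ctx = {"delay_ms": stimulus.get("delay_ms")} if task == "binding" else {}
        ok = self.rng.random() < self._p_correct(task, "judgment", ctx)
        return (truth if ok else (not truth)), latency

    def recall_sequence(self, task, items):
        out = []
        load = len(items)
        for item in items:
            if self._lapsed() or not (
                self.rng.random() < self._p_correct(task, "recall_item", {"load": load})
            ):
                out.append(self._corrupt(task, item))
            else:
                out.append(item)
        return out

    def nback_press(self, stimulus, is_target):
        latency = self._latency()
        if self._lapsed():
            return bool(self.rng.integers(2)), latency
        p = self._p_correct("nback", "nback", {"is_target": is_target})
        correct = self.rng.random() < p
        return (is_target if correct else (not is_target)), latency

    def report_digits(self, spec):
        digits = []
        for true_digit in spec.final_digits:
            if self._lapsed() or not (
                self.rng.random() < self._p_correct("updating", "digit", {})
            ):
                wrong = [d for d in range(1, 10) if d != true_digit]
                digits.append(int(self.rng.choice(wrong)))
            else:
                digits.append(int(true_digit))
        return digits

    def _corrupt(self, task, item):
        from openwmb import taskgen

        if task == "multimodal":
            letter, cell = item
            n_cells = 16
            flat = int(self.rng.integers(n_cells))
            return (letter, (flat // 4, flat % 4)) if self.rng.random() < 0.5 else (
                taskgen.LETTER_ALPHABET[self.rng.integers(11)], cell)
        if task == "symmetry":
            flat = int(self.rng.integers(16))
            return [flat // 4, flat % 4]
        return taskgen.LETTER_ALPHABET[self.rng.integers(11)]


class PerfectResponder:
    """Ceiling responder: always correct, constant latency."""

    def __init__(self, latency_ms: float = 600.0):
        self.latency_ms = latency_ms

    def judge(self, task, stimulus, truth):
        return truth, self.latency_ms

    def recall_sequence(self, task, items):
        return list(items)

    def nback_press(self, stimulus, is_target):
        return is_target, self.latency_ms

    def report_digits(self, spec):
        return list(spec.final_digits)


class SilentResponder:
    """Floor responder: never answers; judgments time out, recalls are
    empty, no keys are pressed."""

    def judge(self, task, stimulus, truth):
        return None, None

    def recall_sequence(self, task, items):
        return []

    def nback_press(self, stimulus, is_target):
        return False, None

    def report_digits(self, spec):
        return [None, None, None]


# ---------------------------------------------------------------------------
# Score-level simulator
# ---------------------------------------------------------------------------

def implied_covariance(population: PopulationModel,
                       include_gf: bool = True) -> pd.DataFrame:
    """Model-implied covariance (= correlation) matrix of the indicators:
    ``x = lambda*F + pi*P + sqrt(1 - lambda^2 - pi^2)*eps`` with
    standard-normal factors and errors."""
    tasks = list(WM_TASKS) + (list(GF_TASKS) if include_gf else [])
    k = len(tasks)
    rho = population.factor_corr
    cov = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            ti, tj = tasks[i], tasks[j]
            wm_i, wm_j = ti in WM_TASKS, tj in WM_TASKS
            li = population.wm_loadings[ti] if wm_i else population.gf_loadings[ti]
            lj = population.wm_loadings[tj] if wm_j else population.gf_loadings[tj]
            c = li * lj * (1.0 if wm_i == wm_j else rho)
            if wm_i and wm_j and PARADIGM_OF[ti] == PARADIGM_OF[tj]:
                c += population.paradigm_variance.get(PARADIGM_OF[ti], 0.0)
            cov[i, j] = cov[j, i] = c
    return pd.DataFrame(cov, index=tasks, columns=tasks)


def simulate_score_table(population: Optional[PopulationModel] = None,
                         n: int = 162, seed=None,
                         include_gf: bool = True) -> pd.DataFrame:
    """Draw an n x (7 WM [+ 3 Gf]) standardized score table from the
    population factor model."""
    if n < 1:
        raise ConfigurationError("n must be at least 1")
    population = population or PopulationModel()
    rng = np.random.default_rng(seed)
    rho = population.factor_corr
    g = rng.standard_normal(n)
    gf = rho * g + np.sqrt(max(1.0 - rho**2, 0.0)) * rng.standard_normal(n)
    pf = {p: rng.standard_normal(n) for p in ("cs", "up", "bi")}
    data = {}
    for task in WM_TASKS:
        lam = population.wm_loadings[task]
        pi2 = population.paradigm_variance.get(PARADIGM_OF[task], 0.0)
        resid = 1.0 - lam**2 - pi2
        if resid < 0:
            raise ConfigurationError(f"{task}: lambda^2 + pi^2 exceeds 1")
        data[task] = (lam * g + np.sqrt(pi2) * pf[PARADIGM_OF[task]]
                      + np.sqrt(resid) * rng.standard_normal(n))
    if include_gf:
        for task in GF_TASKS:
            lam = population.gf_loadings[task]
            data[task] = lam * gf + np.sqrt(1.0 - lam**2) * rng.standard_normal(n)
    df = pd.DataFrame(data)
    df.index = [f"P{i:04d}" for i in range(n)]
    df.index.name = "participant_id"
    return df
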