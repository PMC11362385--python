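# Methods

This note documents the models, conventions, and design choices behind the
package, in the order data flows through it: stimulus generation → task
engines → simulated respondents → scoring → psychometrics.

## Stimulus generation (`openwmb.taskgen`)

All generators are pure functions of their parameters and a seeded
`numpy.random.Generator`. Grid coordinates are 0-based `(row, col)`,
row-major.

* **Letters.** Memoranda come from a fixed 11-consonant alphabet
  (b c d f g p q t v x z); within a block each letter appears at most once.
* **Equations** (operation span). Eight types cross {×, ÷} × {+, −} ×
  {correct, incorrect}. Operands are 1–9, both the first-term and final
  results lie in [1, 20], division requires divisibility. Sampling is
  uniform over the exhaustively enumerated admissible operand set of each
  type. Incorrect proposed results add a uniform offset from
  {−2, −1, +1, +2}, redrawn if the lure would fall below 1 (bounds for the
  lure itself are otherwise unconstrained).
* **Symmetry matrices.** 8×8 binary grids built by mirroring a random left
  half; asymmetric items flip exactly one mirrored cell. Black-cell count
  targets 20–28 (density is a free choice; configurable).
* **2-back sequences.** First two items are unscored lead-ins; exactly
  ⅓ of scored items repeat letter *and* cell of the item two back.
  Non-targets are sampled uniformly excluding only the full 2-back match,
  so letter-only/cell-only lures occur at their natural rate (lure
  frequency is not controlled).
* **Updating trials.** Three digits, six signed operations (two per frame,
  never two consecutive on the same frame, three sums, three
  subtractions), deltas in ±1..8 (a zero delta would update nothing, so it
  is excluded), all intermediate and final values in [1, 9]. Constructive
  sampling with rejection.
* **Binding trials.** A 4×5 grid; the four colored letters occupy a
  central display region covering three cells (a configurable mask),
  leaving 17 cells eligible for the four same-colored crosses. Mismatch
  probes move the probe to any other eligible cell.
* **Multimodal sequences.** 3–11 (letter, cell) pairs on a 4×4 grid;
  letters and cells are each distinct within a sequence ("no position used
  twice" is read as all cells distinct).
* **Sentence pool.** The reading span consumes a tab-separated pool
  (`text`, `is_correct`). Real reading-span corpora are licensed, so the
  shipped pool is *synthetic*: template sentences from word banks,
  constrained to 11–12 words and 45–57 characters, half carrying a planted
  subject–verb agreement error. It exercises the machinery; it has no
  linguistic validity.

## Task engines (`openwmb.engine`)

The engines are event-driven, not wall-clock driven: durations are log
metadata and bounds on simulated latencies. A responder object supplies
behavior via four callbacks (`judge`, `recall_sequence`, `nback_press`,
`report_digits`).

Block structure (defaults): complex spans run a 20-trial calibration, two
practice blocks of size 2, then set sizes 2–6 ascending × 3 blocks = 60
test trials; the n-back runs 8 practice + 38 test items (36 scored); memory
updating 2 + 12 trials (36 digits); binding 4 + 16 trials, four per
(match × delay∈{1000, 8000 ms}) cell; the multimodal span adapts from
length 3, incrementing on exact reproduction, stopping after two
consecutive failures at a length or success at 11 (at most 2·9 + 1 test
trials).

Conventions worth noting:

* The processing deadline is mean RT + 2.5·SD over exactly 20 calibration
  trials (sample SD, ddof = 1). Human-collected calibration latencies can
  be injected through `TaskConfig.calibration_latencies`.
* A processing judgment slower than the deadline, or a binding judgment
  slower than the 4000-ms probe window, always scores incorrect. An n-back
  press later than letter + ISI is discarded and logged with a `late`
  flag.
* Recall is scored by serial position (partial credit), matching recall
  "in presentation order".
* Equation types follow a counterbalanced schedule (shuffled 8-type
  cycles, equal counts); sentence and symmetry truth values are balanced
  50/50 within blocks.
* The updating and binding item banks are fixed across participants
  (seeded in `TaskConfig`) and shuffled per participant, mirroring the
  "same trials, random order" design.
* Symmetry-span memoranda cells are drawn without replacement within a
  block, mirroring the letter-distinctness rule (the design text is silent
  here).
* Task order comes from a cyclic Latin square over the seven tasks: across
  any 7·k consecutive participants each task occupies each position k
  times.
* Logs are long-format CSV; complex-span trials log separate `processing`
  and `memory` segments, so record identity is
  (participant, task, phase, block, trial, **segment**).

## Simulated respondents (`openwmb.responder`)

Two routes:

**Score level.** `simulate_score_table` draws indicator scores directly
from the population factor model `x = λF + πP + √(1−λ²−π²)ε` with
standard-normal factors and errors, WMC–Gf correlation ρ = .83, and a
paradigm-specific share defaulting to 10% of indicator variance (the
battery's paradigm variance is described only qualitatively, so this is a
calibration constant). This route feeds all psychometric analyses and its
sample covariance is tested against the closed-form implied covariance.

**Trial level.** `AbilityResponder` maps a latent profile to behavior:
per-task ability `θ_t = λ_t·g + π_p·u_p + e·ε_t` (stable within session),
recall success `logistic(a·(θ_t + c − b·(load − 2)))`, judgment success
`max(.5, logistic(a·(θ_t + c')))`, lognormal latencies, and a lapse
probability producing uniform random responses. The battery publishes no
generative response model, so `BehaviorParams` are free calibration
constants; the defaults were chosen once so that simulated cohorts land in
plausible descriptive bands (normalized complex-span means ≈ .63 inside
the .55–.85 band; multimodal ≈ .33). Trial-level simulation demonstrates
the full pipeline and produces a positive manifold, but it does not model
decay, interference, or strategy — passing tests say nothing about those
aspects of real data.

## Scoring (`openwmb.scoring`)

Raw scores: proportion of memory items recalled in correct serial position
(complex spans, 0–1); hits on scored target trials (n-back, 0–12; false
alarms are reported separately but never enter the raw score); correctly
reported final digits (updating, 0–36); last correctly reproduced length
(multimodal, 0 or 3–11); correct judgments (binding, 0–16). Normalization
divides by the **theoretical** maximum (observed score ranges like 3/11 =
.27 for the multimodal minimum are only consistent with theoretical
bounds). Scoring always recomputes updating correctness from the logged
stimulus and response, never from engine-side flags.

Screening: univariate |z| > 3 cells and zero scores are set missing
(screening only creates missingness); multivariate screening computes
Mahalanobis D² against χ²(p) at p < .001 on complete (post-imputation)
tables; participants scoring zero on more than one task are excluded at
table construction. Descriptives report skewness and **excess** kurtosis
(normal = 0; normality flags |skew| < 2, |kurtosis| < 4), percentiles by
linear interpolation, and Mardia's multivariate kurtosis.

## Psychometrics (`openwmb.psychometrics`)

* **Reliability.** α from the variance decomposition; ω from a one-factor
  ML solution on the trial-item matrix, `(Σλ)²/((Σλ)² + Σθ)`; Heywood
  cases and non-convergence are flagged, not silently dropped.
* **Factorability / EFA.** KMO from anti-image partial correlations;
  Bartlett's χ² = −(n−1−(2p+5)/6)·ln|R|; retention by Kaiser, parallel
  analysis (95th percentile, 1,000 replicates — both conventional
  defaults), and an advisory scree elbow. ML extraction is delegated to
  statsmodels with promax (power 4) rotation for multi-factor solutions.
* **CFA/SEM.** An in-package ML covariance-structure fitter (simple
  structure, factor variances fixed at 1, oblique factors, diagonal
  uniqueness) minimizing F_ML with an analytic gradient; standard errors
  from the numerically differentiated Hessian, `acov = 2/(N−1)·H⁻¹`.
  χ² uses the (N−1)·F_ML convention (toggleable to N). CFI against the
  independence baseline, RMSEA = √(max(χ²−df,0)/(df·(N−1))), SRMR over the
  p(p+1)/2 unique standardized residuals; residual z-values > 2.58 are
  flagged as large. Two-indicator factors are identified by
  equality-constrained loadings. Uniquenesses are floored at 10⁻⁶; an
  estimate at the floor flags a Heywood case. Single observed predictors
  in structural models enter as extra indicators of the latent factor
  (free loading + residual), which reproduces the conventional df for
  observed-variable models.
* **Imputation.** Chained equations with Bayesian normal linear models
  ("norm"), 10 cycles, m = 20 datasets by default. Predictor sets are
  restricted (WM from WM, reasoning from reasoning) and pairs with
  non-significant observed correlations can be dropped from each other's
  equations (the convention used for the n-back/multimodal pair). Rubin
  pooling: T = W̄ + (1+1/m)B with the fraction of missing information
  γ ≈ (1+1/m)B/T; m = 1 degenerates to the single fit.
* **Permutation analysis.** 22 models: 7 single tasks, 3 homogeneous
  (complex-span triple; equality-constrained updating and binding pairs),
  and 3×2×2 = 12 heterogeneous triplets. Rows carry the WMC–Gf shared
  variance R² and fit indices, ranked by R² with poorly fitting models
  last; the acceptability flag requires χ²/df < 3, CFI ≥ .90 and
  SRMR < .08.
* **Power analysis.** Proactive Monte Carlo: data generated from the
  analysis model at known population values; criteria |relative bias| ≤
  .10 (all parameters), |relative SE bias| ≤ .10 (all) and ≤ .05 (factor
  correlation), coverage ∈ [.91, .98], power ≥ .80, with runs invalidated
  by >10% fit failures. Significance uses the Wald estimate/SE ratio
  against the normal reference. `find_min_n` evaluates an ascending grid
  and returns the smallest passing N with all per-N reports; a
  two-seed stability check is available.

## Problem sizes and known sensitivities

The test suite uses n = 50,000 samples for ±.02 parameter-recovery checks,
n ≈ 5,000 for the permutation-ordering property, 12-participant trial-level
cohorts for pipeline checks, and 1,000 replications per candidate N in the
sample-size grid search.

Two limitations deserve emphasis. First, at 1,000 replications the SE-bias
criterion of the sample-size procedure carries Monte Carlo noise of
roughly ±2% against a ±5% threshold, so the minimum passing N for the
two-factor model moves by a grid step or two across seeds (typically
100–140 on the 100–180 grid); the criterion that binds is the standard
error bias of the factor correlation, whose small-sample component
(≈ −5% at N = 100) vanishes by N ≈ 2,000. A published minimum of 160 for a
whole battery additionally reflects the weakest *submodels* (e.g.
equality-constrained two-indicator factors), which pass later than the
full two-factor model; `monte_carlo_power` accepts any `ModelSpec` so the
full set of planned models can be screened. Second, the trial-level
behavior model is a pragmatic calibration device, not a cognitive theory;
conclusions about real participants should rest on the score-level model
and on real logs processed through the same pipeline.
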