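"""Computer-paced task state machines, session planning, and trial logging.

The engines are event-driven rather than wall-clock driven: presentation
durations are metadata carried in the log and bounds applied to simulated
response latencies; no real-time scheduling happens here. A *responder*
object supplies the behavior (judgments, recalls, key presses) — see
:mod:`openwmb.responder` for the interface and implementations.

Log layout: one :class:`TrialRecord` per event, long format. Complex-span
trials have a processing and a memory sub-event, distinguished by the
``segment`` field; ``(participant, task, phase, block, trial, segment)``
is unique.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, fields
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from openwmb import taskgen
from openwmb.errors import AbortedSessionError, ConfigurationError, SchemaError

#: Canonical task identifiers, battery order.
TASKS: tuple[str, ...] = (
    "reading", "operation", "symmetry", "nback", "updating", "binding", "multimodal",
)

COMPLEX_SPAN_VARIANTS = ("reading", "operation", "symmetry")

#: 4x4 grid used for symmetry-span memoranda (red-square positions).
SYMMETRY_MEMORY_GRID = (4, 4)


@dataclass(frozen=True)
class TaskConfig:
    """Timing constants (ms) and block structure for the seven tasks.

    Defaults reproduce the battery's printed design: complex spans run 15
    test blocks of set sizes 2-6 (three blocks per size, ascending; 60
    memory items), the n-back runs 8 practice + 38 test items with a third
    of scored items as targets, memory updating runs 2 practice + 12 test
    trials of 6 operations each, binding runs 4 practice + 16 test trials
    in four equal (match x delay) cells, and the multimodal span adapts
    from length 3 up to 11.
    """

    fixation_ms: int = 500
    binding_fixation_ms: int = 2000
    memory_item_ms: int = 1000
    nback_letter_ms: int = 500
    nback_isi_ms: int = 2000
    binding_study_ms: int = 5000
    binding_probe_ms: int = 4000
    updating_digit_ms: int = 2000
    updating_op_ms: int = 2000
    updating_gap_ms: int = 500
    multimodal_item_ms: int = 1000
    multimodal_isi_ms: int = 1000

    calibration_trials: int = 20
    calibration_sd_mult: float = 2.5
    span_set_sizes: tuple[int, ...] = (2, 3, 4, 5, 6)
    span_blocks_per_size: int = 3
    span_practice_blocks: int = 2
    span_practice_size: int = 2
    nback_practice: int = 8
    nback_test: int = 38
    nback_target_ratio: float = 1 / 3
    updating_practice: int = 2
    updating_test: int = 12
    binding_practice: int = 4
    binding_test: int = 16
    multimodal_start: int = 3
    multimodal_max: int = 11
    multimodal_practice_lengths: tuple[int, ...] = (3, 4)

    # All participants see the same updating and binding item banks, in
    # participant-randomized order; the banks are drawn from these seeds.
    updating_bank_seed: int = 202404
    binding_bank_seed: int = 202405

    # Injected per-variant calibration latencies (ms), e.g. collected from
    # humans; when present they override the responder's latency model.
    calibration_latencies: Optional[dict] = None

    def __post_init__(self):
        for f in fields(self):
            if f.name.endswith("_ms") and getattr(self, f.name) <= 0:
                raise ConfigurationError(f"{f.name} must be positive")
        if tuple(sorted(self.span_set_sizes)) != tuple(self.span_set_sizes):
            raise ConfigurationError("span set sizes must be ascending")
        if self.multimodal_start < 3 or self.multimodal_max > 11:
            raise ConfigurationError("multimodal lengths must stay within 3..11")

    @property
    def span_test_trials(self) -> int:
        return self.span_blocks_per_size * sum(self.span_set_sizes)

    @classmethod
    def from_yaml(cls, path) -> "TaskConfig":
        import yaml

        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        for key in ("span_set_sizes", "multimodal_practice_lengths"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass(frozen=True)
class CalibrationResult:
    """Per-participant processing deadline: mean RT + 2.5 SD over the 20
    calibration trials."""

    mean_rt: float
    sd_rt: float
    time_limit: float


def calibrate(latencies: Sequence[float], n_required: int = 20,
              sd_mult: float = 2.5) -> CalibrationResult:
    latencies = np.asarray(latencies, dtype=float)
    if latencies.size != n_required:
        raise ConfigurationError(
            f"calibration requires exactly {n_required} latencies, got {latencies.size}"
        )
    if np.any(latencies <= 0):
        raise ConfigurationError("calibration latencies must be positive")
    mean = float(latencies.mean())
    sd = float(latencies.std(ddof=1))
    return CalibrationResult(mean, sd, mean + sd_mult * sd)


# ---------------------------------------------------------------------------
# Session planning
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SessionPlan:
    participant_index: int
    task_order: tuple[str, ...]
    seeds: dict

    @property
    def participant_id(self) -> str:
        return f"P{self.participant_index:04d}"


def plan_session(participant_index: int, master_seed: int) -> SessionPlan:
    """Cyclic Latin-square task order plus per-task seeds.

    The base row is a seeded permutation of the seven tasks; participant
    ``i`` receives that row rotated by ``i`` positions, so across any seven
    consecutive participants each task occupies each ordinal position
    exactly once.
    """
    if participant_index < 0:
        raise ConfigurationError("participant_index must be non-negative")
    base_rng = np.random.default_rng(np.random.SeedSequence(master_seed))
    base = list(TASKS)
    base_rng.shuffle(base)
    shift = participant_index % len(TASKS)
    order = tuple(base[(i + shift) % len(base)] for i in range(len(base)))
    ss = np.random.SeedSequence(master_seed, spawn_key=(participant_index,))
    children = ss.spawn(len(TASKS))
    seeds = {
        task: int(child.generate_state(1, dtype=np.uint32)[0] % (2**31))
        for task, child in zip(TASKS, children)
    }
    return SessionPlan(participant_index, order, seeds)


# ---------------------------------------------------------------------------
# Trial records
# ---------------------------------------------------------------------------

LOG_COLUMNS = (
    "participant_id", "task", "phase", "block_index", "trial_index", "segment",
    "set_size", "stimulus", "response", "latency_ms", "correct", "scored",
)


@dataclass
class TrialRecord:
    participant_id: str
    task: str
    phase: str  # calibration | practice | test
    block_index: int
    trial_index: int
    segment: str  # processing | memory | item | trial | feedback
    set_size: object  # set size or condition label
    stimulus: str  # compact JSON descriptor
    response: str  # compact JSON response
    latency_ms: Optional[float]
    correct: Optional[bool]
    scored: bool


def _js(obj) -> str:
    return json.dumps(obj, separators=(",", ":"), sort_keys=True)


def records_to_frame(records: Sequence[TrialRecord]) -> pd.DataFrame:
    df = pd.DataFrame([asdict(r) for r in records], columns=list(LOG_COLUMNS))
    return df


def write_log(records, path) -> None:
    df = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    df.to_csv(path, index=False, encoding="utf-8")


def read_log(path) -> pd.DataFrame:
    df = pd.read_csv(path, encoding="utf-8")
    missing = set(LOG_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: log is missing columns {sorted(missing)}")
    return df


# ---------------------------------------------------------------------------
# Complex spans (reading / operation / symmetry)
# ---------------------------------------------------------------------------

def _balanced_bool_plan(n, rng):
    plan = [True] * (n // 2) + [False] * (n - n // 2)
    if n % 2:
        plan[n // 2] = bool(rng.integers(2))  # odd count: extra side random
    rng.shuffle(plan)
    return plan


def _equation_type_schedule(n, rng):
    """Counterbalanced equation types: shuffled 8-type cycles, so each type
    appears equally often per cycle (and truth is balanced 50/50)."""
    schedule = []
    while len(schedule) < n:
        cycle = list(taskgen.EQUATION_TYPES)
        rng.shuffle(cycle)
        schedule.extend(cycle)
    return schedule[:n]


def run_complex_span(variant, config: TaskConfig, responder, rng,
                     sentence_pool=None, participant_id="P0000"):
    """Run one complex span: calibration (20 processing judgments), two
    practice blocks of size 2, then 15 test blocks of sizes 2-6 ascending.

    Each trial interleaves a speeded processing judgment (timeout at the
    calibrated limit scores incorrect) with a memory item; recall is
    collected at block end and scored by serial position.
    """
    if variant not in COMPLEX_SPAN_VARIANTS:
        raise ConfigurationError(f"unknown complex-span variant {variant!r}")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    records: list[TrialRecord] = []

    if variant == "reading":
        if sentence_pool is None:
            sentence_pool = taskgen.default_sentence_pool()
        needed = (config.calibration_trials
                  + config.span_practice_blocks * config.span_practice_size
                  + config.span_test_trials)
        if len(sentence_pool) < needed:
            raise ConfigurationError(
                f"sentence pool has {len(sentence_pool)} items; {needed} required"
            )
        correct = [s for s in sentence_pool if s.is_correct]
        incorrect = [s for s in sentence_pool if not s.is_correct]
        rng.shuffle(correct)
        rng.shuffle(incorrect)

        def sentence_iter_factory(plan):
            for want in plan:
                yield (correct if want else incorrect).pop()
    else:
        def sentence_iter_factory(plan):
            return iter(())

    eq_schedule = iter(_equation_type_schedule(
        config.calibration_trials
        + config.span_practice_blocks * config.span_practice_size
        + config.span_test_trials, rng))

    def processing_stimulus(want_correct):
        if variant == "operation":
            eq = taskgen.make_equation(next(eq_schedule), rng)
            return ({"eq": eq.text(), "type": eq.type_code,
                     "proposed": eq.proposed_result, "answer": eq.correct_result},
                    eq.is_correct)
        if variant == "reading":
            item = next(sent_iter)
            return ({"text": item.text}, item.is_correct)
        m = taskgen.make_symmetry_matrix(bool(want_correct), rng)
        return ({"cells": [list(r) for r in m.cells], "mismatch": m.mismatch_cell},
                m.is_symmetric)

    def ask(stim, truth, phase, block, trial, limit=None, set_size=None):
        try:
            answer, latency = responder.judge(variant, stim, truth)
        except Exception as exc:  # noqa: BLE001 - aborted-session contract
            raise AbortedSessionError(
                f"responder failed during {variant} {phase}: {exc}", records
            ) from exc
        timed_out = limit is not None and (latency is None or latency > limit)
        ok = (answer is not None) and (answer == truth) and not timed_out
        records.append(TrialRecord(
            participant_id, variant, phase, block, trial, "processing",
            set_size, _js({**stim, "truth": truth}),
            _js({"answer": answer, "timed_out": timed_out}),
            latency, ok, False,
        ))
        return ok, latency

    # --- calibration -------------------------------------------------------
    plan = _balanced_bool_plan(config.calibration_trials, rng)
    sent_iter = sentence_iter_factory(plan)
    latencies = []
    for t, want in enumerate(plan):
        stim, truth = processing_stimulus(want)
        _, latency = ask(stim, truth, "calibration", 0, t)
        latencies.append(latency if latency is not None else 1.0)
    if config.calibration_latencies and variant in config.calibration_latencies:
        latencies = list(config.calibration_latencies[variant])
    cal = calibrate(latencies, config.calibration_trials, config.calibration_sd_mult)

    # --- practice + test ---------------------------------------------------
    def memoranda(k):
        if variant == "symmetry":
            n_cells = SYMMETRY_MEMORY_GRID[0] * SYMMETRY_MEMORY_GRID[1]
            flat = rng.choice(n_cells, size=k, replace=False)
            return [[int(f) // SYMMETRY_MEMORY_GRID[1], int(f) % SYMMETRY_MEMORY_GRID[1]]
                    for f in flat]
        return list(taskgen.sample_letter_sequence(k, rng))

    def run_block(phase, block_idx, size):
        nonlocal sent_iter
        plan = _balanced_bool_plan(size, rng)
        sent_iter = sentence_iter_factory(plan)
        items = memoranda(size)
        n_proc_ok = 0
        for t, want in enumerate(plan):
            stim, truth = processing_stimulus(want)
            ok, _ = ask(stim, truth, phase, block_idx, t,
                        limit=cal.time_limit, set_size=size)
            n_proc_ok += ok
            records.append(TrialRecord(
                participant_id, variant, phase, block_idx, t, "memory",
                size, _js({"item": items[t]}), "", None, None, False,
            ))
        try:
            recalled = list(responder.recall_sequence(variant, items))
        except Exception as exc:  # noqa: BLE001
            raise AbortedSessionError(
                f"responder failed during {variant} recall: {exc}", records
            ) from exc
        n_mem_ok = 0
        for t in range(size):
            resp = recalled[t] if t < len(recalled) else None
            ok = resp == items[t]
            n_mem_ok += ok
            for rec in records:
                if (rec.segment == "memory" and rec.phase == phase
                        and rec.block_index == block_idx and rec.trial_index == t):
                    rec.response = _js({"recalled": resp})
                    rec.correct = ok
                    rec.scored = phase == "test"
        records.append(TrialRecord(
            participant_id, variant, phase, block_idx, size, "feedback",
            size, _js({"recalled_correct": n_mem_ok, "processing_correct": n_proc_ok}),
            "", None, None, False,
        ))

    for b in range(config.span_practice_blocks):
        run_block("practice", b, config.span_practice_size)
    block = 0
    for size in config.span_set_sizes:
        for _ in range(config.span_blocks_per_size):
            run_block("test", block, size)
            block += 1
    return records, cal


# ---------------------------------------------------------------------------
# N-back
# ---------------------------------------------------------------------------

def run_nback(config: TaskConfig, responder, rng, participant_id="P0000"):
    """Practice (8 items) + test (38 items) 2-back blocks. A key press
    accepted during the letter or the ISI counts; later presses are
    discarded and logged with a ``late`` flag."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    records: list[TrialRecord] = []
    window = config.nback_letter_ms + config.nback_isi_ms
    for phase, n in (("practice", config.nback_practice), ("test", config.nback_test)):
        seq = taskgen.make_nback_sequence(n, config.nback_target_ratio, rng)
        n_ok = 0
        for t, item in enumerate(seq):
            try:
                pressed, latency = responder.nback_press(
                    {"letter": item.letter, "cell": list(item.cell)}, item.is_target
                )
            except Exception as exc:  # noqa: BLE001
                raise AbortedSessionError(f"responder failed during n-back: {exc}",
                                          records) from exc
            late = bool(pressed) and latency is not None and latency > window
            effective = bool(pressed) and not late
            ok = effective == item.is_target
            n_ok += ok and item.scored
            records.append(TrialRecord(
                participant_id, "nback", phase, 0, t, "item",
                "target" if item.is_target else "nontarget",
                _js({"letter": item.letter, "cell": list(item.cell),
                     "is_target": item.is_target}),
                _js({"pressed": bool(pressed), "late": late}),
                latency, ok, item.scored,
            ))
        records.append(TrialRecord(
            participant_id, "nback", phase, 0, n, "feedback", None,
            _js({"correct_trials": int(n_ok)}), "", None, None, False,
        ))
    return records


# ---------------------------------------------------------------------------
# Memory updating
# ---------------------------------------------------------------------------

def run_memory_updating(config: TaskConfig, responder, rng, participant_id="P0000"):
    """2 practice + 12 test updating trials; every participant sees the same
    item bank (drawn from ``config.updating_bank_seed``) in participant-
    randomized test order."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    bank_rng = np.random.default_rng(config.updating_bank_seed)
    bank = [taskgen.make_updating_trial(bank_rng)
            for _ in range(config.updating_practice + config.updating_test)]
    practice = bank[: config.updating_practice]
    test = bank[config.updating_practice:]
    order = rng.permutation(len(test))
    records: list[TrialRecord] = []
    for phase, trials in (("practice", practice), ("test", [test[i] for i in order])):
        total = 0
        for t, spec in enumerate(trials):
            try:
                reported = responder.report_digits(spec)
            except Exception as exc:  # noqa: BLE001
                raise AbortedSessionError(f"responder failed during updating: {exc}",
                                          records) from exc
            digits, flagged = [], False
            for v in (list(reported) + [None] * 3)[:3]:
                if isinstance(v, (int, np.integer)) and 1 <= int(v) <= 9:
                    digits.append(int(v))
                else:
                    digits.append(None)
                    flagged = True
            n_ok = sum(d == f for d, f in zip(digits, spec.final_digits))
            total += n_ok
            records.append(TrialRecord(
                participant_id, "updating", phase, 0, t, "trial", 3,
                _js({"initial": list(spec.initial_digits),
                     "ops": [[op.frame_index, op.delta] for op in spec.operations],
                     "final": list(spec.final_digits)}),
                _js({"digits": digits, "n_correct": n_ok, "invalid": flagged}),
                None, n_ok == 3, phase == "test",
            ))
        records.append(TrialRecord(
            participant_id, "updating", phase, 0, len(trials), "feedback", None,
            _js({"correct_digits": int(total)}), "", None, None, False,
        ))
    return records


# ---------------------------------------------------------------------------
# Binding and maintenance
# ---------------------------------------------------------------------------

def run_binding_task(config: TaskConfig, responder, rng, participant_id="P0000"):
    """4 practice + 16 test binding trials, four per (match x delay) cell;
    judgments slower than the 4000-ms probe window log as timeouts."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    bank_rng = np.random.default_rng(config.binding_bank_seed)
    practice = taskgen.make_binding_block(config.binding_practice, bank_rng)
    test = taskgen.make_binding_block(config.binding_test, bank_rng)
    records: list[TrialRecord] = []
    for phase, trials in (("practice", practice), ("test", test)):
        order = rng.permutation(len(trials))
        n_ok = 0
        for t, idx in enumerate(order):
            spec = trials[idx]
            stim = {
                "letters": [[lt, col] for lt, col in spec.letter_colors],
                "crosses": [[list(cell), col] for cell, col in spec.cross_cells],
                "probe_letter": spec.probe_letter,
                "probe_cell": list(spec.probe_cell),
                "delay_ms": spec.delay_ms,
            }
            try:
                answer, latency = responder.judge("binding", stim, spec.is_match)
            except Exception as exc:  # noqa: BLE001
                raise AbortedSessionError(f"responder failed during binding: {exc}",
                                          records) from exc
            timed_out = latency is None or latency > config.binding_probe_ms
            ok = (answer is not None) and (answer == spec.is_match) and not timed_out
            n_ok += ok
            cond = f"{'match' if spec.is_match else 'mismatch'}/{spec.delay_ms}"
            records.append(TrialRecord(
                participant_id, "binding", phase, 0, t, "trial", cond,
                _js({**stim, "is_match": spec.is_match}),
                _js({"answer": answer, "timed_out": timed_out}),
                latency, ok, phase == "test",
            ))
        records.append(TrialRecord(
            participant_id, "binding", phase, 0, len(trials), "feedback", None,
            _js({"correct_trials": int(n_ok)}), "", None, None, False,
        ))
    return records


# ---------------------------------------------------------------------------
# Multimodal span
# ---------------------------------------------------------------------------

def run_multimodal_span(config: TaskConfig, responder, rng, participant_id="P0000"):
    """Adaptive letter-in-grid span. Practice runs lengths 3 and 4 to
    completion; the test starts at length 3, increments on exact
    reproduction, and terminates after two consecutive failures at the same
    length or a success at length 11."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    records: list[TrialRecord] = []

    def run_trial(phase, t, length):
        seq = taskgen.make_multimodal_sequence(length, rng)
        items = [[lt, list(cell)] for lt, cell in seq.items]
        try:
            resp = list(responder.recall_sequence("multimodal", list(seq.items)))
        except Exception as exc:  # noqa: BLE001
            raise AbortedSessionError(f"responder failed during multimodal: {exc}",
                                      records) from exc
        # exact reproduction: same letters, same cells, same order
        def norm(x):
            if isinstance(x, (list, tuple)) and len(x) == 2:
                return (x[0], tuple(x[1]))
            return None
        ok = [norm(r) for r in resp] == [(lt, tuple(cell)) for lt, cell in items]
        records.append(TrialRecord(
            participant_id, "multimodal", phase, 0, t, "trial", length,
            _js({"items": items}),
            _js({"recalled": [[r[0], list(r[1])] if isinstance(r, (list, tuple)) and
                              len(r) == 2 else None for r in resp]}),
            None, ok, phase == "test",
        ))
        return ok

    t = 0
    for length in config.multimodal_practice_lengths:
        run_trial("practice", t, length)
        t += 1
    length = config.multimodal_start
    fails = 0
    t = 0
    while True:
        ok = run_trial("test", t, length)
        t += 1
        if ok:
            if length >= config.multimodal_max:
                break
            length += 1
            fails = 0
        else:
            fails += 1
            if fails >= 2:
                break
    return records


# ---------------------------------------------------------------------------
# Sessions
# ---------------------------------------------------------------------------

def run_session(plan: SessionPlan, config: TaskConfig, responder,
                sentence_pool=None) -> list[TrialRecord]:
    """Run all seven tasks in plan order and concatenate their logs."""
    if not plan.task_order:
        raise ConfigurationError("empty session plan")
    pid = plan.participant_id
    records: list[TrialRecord] = []
    try:
        for task in plan.task_order:
            rng = np.random.default_rng(plan.seeds[task])
            if task in COMPLEX_SPAN_VARIANTS:
                recs, _ = run_complex_span(task, config, responder, rng,
                                           sentence_pool=sentence_pool,
                                           participant_id=pid)
            elif task == "nback":
                recs = run_nback(config, responder, rng, participant_id=pid)
            elif task == "updating":
                recs = run_memory_updating(config, responder, rng, participant_id=pid)
            elif task == "binding":
                recs = run_binding_task(config, responder, rng, participant_id=pid)
            elif task == "multimodal":
                recs = run_multimodal_span(config, responder, rng, participant_id=pid)
            else:  # pragma: no cover
                raise ConfigurationError(f"unknown task {task!r}")
            records.extend(recs)
    except AbortedSessionError as exc:
        raise AbortedSessionError(str(exc), records + list(exc.records)) from exc
    return records


def simulate_cohort_logs(n_participants: int, master_seed: int, config: TaskConfig,
                         responder_factory, out_dir=None, sentence_pool=None):
    """Plan and run sessions for a cohort; optionally write one CSV log per
    participant. ``responder_factory(participant_index)`` supplies each
    participant's responder."""
    logs = {}
    for i in range(n_participants):
        plan = plan_session(i, master_seed)
        responder = responder_factory(i)
        records = run_session(plan, config, responder, sentence_pool=sentence_pool)
        logs[plan.participant_id] = records_to_frame(records)
        if out_dir is not None:
            out_dir = Path(out_dir)
            out_dir.mkdir(parents=True, exist_ok=True)
            write_log(logs[plan.participant_id], out_dir / f"{plan.participant_id}.csv")
    return logs
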