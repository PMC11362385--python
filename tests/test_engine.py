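"""Task-engine structure, calibration, session planning, and log I/O."""

import json

import numpy as np
import pandas as pd
import pytest

from openwmb import engine, responder, taskgen
from openwmb.errors import AbortedSessionError, ConfigurationError, SchemaError


class TestCalibration:
    def test_zero_sd_gives_mean(self):
        res = engine.calibrate([1000.0] * 20)
        assert res.time_limit == pytest.approx(1000.0)

    def test_matches_direct_formula(self):
        lats = [800.0] * 10 + [1200.0] * 10
        res = engine.calibrate(lats)
        # independent spreadsheet-style computation
        mean = sum(lats) / 20
        sd = (sum((x - mean) ** 2 for x in lats) / 19) ** 0.5
        assert res.time_limit == pytest.approx(mean + 2.5 * sd)

    def test_wrong_count_rejected(self):
        with pytest.raises(ConfigurationError):
            engine.calibrate([1000.0] * 19)


class TestSessionPlanning:
    @pytest.mark.parametrize("n,expected", [(7, 1), (14, 2)])
    def test_latin_square_balance(self, n, expected):
        plans = [engine.plan_session(i, 11) for i in range(n)]
        for pos in range(7):
            tasks_at_pos = [p.task_order[pos] for p in plans]
            for task in engine.TASKS:
                assert tasks_at_pos.count(task) == expected

    def test_deterministic(self):
        a = engine.plan_session(3, 5)
        b = engine.plan_session(3, 5)
        assert a == b

    def test_negative_index_rejected(self):
        with pytest.raises(ConfigurationError):
            engine.plan_session(-1, 5)


class TestComplexSpanStructure:
    @pytest.mark.parametrize("variant", engine.COMPLEX_SPAN_VARIANTS)
    def test_test_phase_structure(self, variant, task_config):
        records, cal = engine.run_complex_span(
            variant, task_config, responder.PerfectResponder(),
            np.random.default_rng(4))
        df = engine.records_to_frame(records)
        mem = df[(df.phase == "test") & (df.segment == "memory")]
        assert len(mem) == 60
        blocks = mem.groupby("block_index")["set_size"].first()
        assert len(blocks) == 15
        assert sorted(blocks) == [2, 2, 2, 3, 3, 3, 4, 4, 4, 5, 5, 5, 6, 6, 6]
        assert list(blocks) == sorted(blocks)  # ascending order
        cali = df[df.phase == "calibration"]
        assert len(cali) == 20
        assert cal.time_limit >= cal.mean_rt

    def test_perfect_responder_recalls_everything(self, perfect_session):
        df = perfect_session
        for variant in engine.COMPLEX_SPAN_VARIANTS:
            mem = df[(df.task == variant) & (df.phase == "test")
                     & (df.segment == "memory")]
            assert mem["correct"].all()

    def test_processing_timeout_scored_incorrect(self, task_config):
        class SlowResponder(responder.PerfectResponder):
            def judge(self, task, stimulus, truth):
                return truth, 1e9  # always beyond any calibrated limit

        cfg = engine.TaskConfig(
            calibration_latencies={"operation": [500.0] * 20})
        records, _ = engine.run_complex_span(
            "operation", cfg, SlowResponder(), np.random.default_rng(0))
        df = engine.records_to_frame(records)
        proc = df[(df.phase == "test") & (df.segment == "processing")]
        assert not proc["correct"].any()

    def test_equation_types_balanced(self, task_config):
        records, _ = engine.run_complex_span(
            "operation", task_config, responder.PerfectResponder(),
            np.random.default_rng(1))
        df = engine.records_to_frame(records)
        proc = df[(df.phase == "test") & (df.segment == "processing")]
        types = proc["stimulus"].map(lambda s: json.loads(s)["type"])
        counts = types.value_counts()
        assert set(counts.index) == set(range(1, 9))
        assert counts.max() - counts.min() <= 1

    def test_small_pool_rejected(self, task_config, rng):
        pool = taskgen.generate_placeholder_pool(20, rng)
        with pytest.raises(ConfigurationError):
            engine.run_complex_span("reading", task_config,
                                    responder.PerfectResponder(),
                                    np.random.default_rng(0),
                                    sentence_pool=pool)


class TestNBackEngine:
    def test_scored_counts_and_ceiling(self, perfect_session):
        df = perfect_session
        items = df[(df.task == "nback") & (df.phase == "test")
                   & (df.segment == "item")]
        assert len(items) == 38
        assert items["scored"].sum() == 36
        scored = items[items.scored]
        assert scored["correct"].all()

    def test_silent_responder_floor(self, task_config):
        records = engine.run_nback(task_config, responder.SilentResponder(),
                                   np.random.default_rng(0))
        df = engine.records_to_frame(records)
        scored = df[(df.phase == "test") & (df.segment == "item") & df.scored]
        hits = scored[(scored.set_size == "target") & scored.correct]
        cr = scored[(scored.set_size == "nontarget") & scored.correct]
        assert len(hits) == 0
        assert len(cr) == 24  # all non-targets correctly rejected

    def test_late_press_discarded(self, task_config):
        class LateResponder(responder.PerfectResponder):
            def nback_press(self, stimulus, is_target):
                return is_target, 99999.0  # beyond letter + ISI window

        records = engine.run_nback(task_config, LateResponder(),
                                   np.random.default_rng(0))
        df = engine.records_to_frame(records)
        scored = df[(df.phase == "test") & (df.segment == "item") & df.scored]
        targets = scored[scored.set_size == "target"]
        assert not targets["correct"].any()
        assert all(json.loads(r)["late"] for r in targets["response"])


class TestUpdatingEngine:
    def test_structure_and_ceiling(self, perfect_session):
        df = perfect_session
        trials = df[(df.task == "updating") & (df.phase == "test")
                    & (df.segment == "trial")]
        assert len(trials) == 12
        total = sum(json.loads(r)["n_correct"] for r in trials["response"])
        assert total == 36

    def test_unchanged_report_matches_zero_net_delta(self, task_config):
        class EchoInitial:
            def report_digits(self, spec):
                return list(spec.initial_digits)

        records = engine.run_memory_updating(task_config, EchoInitial(),
                                             np.random.default_rng(0))
        df = engine.records_to_frame(records)
        trials = df[(df.phase == "test") & (df.segment == "trial")]
        for _, row in trials.iterrows():
            stim = json.loads(row["stimulus"])
            # replay oracle: per-frame net delta
            net = [0, 0, 0]
            for f, d in stim["ops"]:
                net[f] += d
            expected = sum(n == 0 for n in net)
            assert json.loads(row["response"])["n_correct"] == expected

    def test_same_bank_across_participants(self, task_config):
        stims = []
        for seed in (1, 2):
            records = engine.run_memory_updating(
                task_config, responder.PerfectResponder(),
                np.random.default_rng(seed))
            df = engine.records_to_frame(records)
            trials = df[(df.phase == "test") & (df.segment == "trial")]
            stims.append(frozenset(trials["stimulus"]))
        assert stims[0] == stims[1]  # same items, order may differ


class TestBindingEngine:
    def test_structure_and_ceiling(self, perfect_session):
        df = perfect_session
        trials = df[(df.task == "binding") & (df.phase == "test")
                    & (df.segment == "trial")]
        assert len(trials) == 16
        assert trials["correct"].all()
        counts = trials["set_size"].value_counts()
        assert sorted(counts) == [4, 4, 4, 4]

    def test_timeout_is_incorrect(self, task_config):
        class SlowJudge(responder.PerfectResponder):
            def judge(self, task, stimulus, truth):
                return truth, 4500.0  # over the 4000-ms probe window

        records = engine.run_binding_task(task_config, SlowJudge(),
                                          np.random.default_rng(0))
        df = engine.records_to_frame(records)
        test = df[(df.phase == "test") & (df.segment == "trial")]
        assert not test["correct"].any()


class TestMultimodalEngine:
    def test_perfect_responder_reaches_11(self, perfect_session):
        df = perfect_session
        trials = df[(df.task == "multimodal") & (df.phase == "test")
                    & (df.segment == "trial")]
        assert trials["correct"].all()
        assert list(trials["set_size"]) == list(range(3, 12))

    def test_always_failing_terminates_after_two(self, task_config):
        class Amnesiac:
            def recall_sequence(self, task, items):
                return []

        records = engine.run_multimodal_span(task_config, Amnesiac(),
                                             np.random.default_rng(0))
        df = engine.records_to_frame(records)
        test = df[(df.phase == "test") & (df.segment == "trial")]
        assert len(test) == 2
        assert (test["set_size"] == 3).all()
        assert not test["correct"].any()

    def test_terminates_within_bound(self, task_config):
        # adaptive process can run at most 2 * 9 + 1 test trials
        for seed in range(20):
            r = np.random.default_rng(seed)

            class CoinFlip:
                def recall_sequence(self, task, items):
                    return list(items) if r.random() < 0.5 else []

            records = engine.run_multimodal_span(task_config, CoinFlip(),
                                                 np.random.default_rng(seed))
            df = engine.records_to_frame(records)
            assert len(df[(df.phase == "test") & (df.segment == "trial")]) <= 19

    @pytest.mark.parametrize("p", [0.5, 0.9])
    def test_mean_final_length_matches_absorbing_chain(self, p, task_config):
        """The adaptive staircase is a Markov chain on (length, fails);
        compare the engine's mean final score with exact enumeration."""
        from functools import lru_cache

        @lru_cache(maxsize=None)
        def expected_score(length, fails, best):
            # success w.p. p advances (absorb at 11); two fails at one
            # length absorb with the best length reached
            succ = length if length == 11 else None
            e_succ = (length if succ is not None
                      else expected_score(length + 1, 0, length))
            e_fail = (best if fails == 1
                      else expected_score(length, 1, best))
            return p * e_succ + (1 - p) * e_fail

        exact = expected_score(3, 0, 0)

        scores = []
        master = np.random.default_rng(777)
        for _ in range(800):
            r = np.random.default_rng(master.integers(2**31))

            class Bernoulli:
                def recall_sequence(self, task, items):
                    return list(items) if r.random() < p else []

            records = engine.run_multimodal_span(task_config, Bernoulli(),
                                                 np.random.default_rng(1))
            df = engine.records_to_frame(records)
            test = df[(df.phase == "test") & (df.segment == "trial")]
            ok = test[test["correct"].astype(bool)]
            scores.append(ok["set_size"].astype(int).max() if len(ok) else 0)
        mc = np.mean(scores)
        se = np.std(scores, ddof=1) / np.sqrt(len(scores))
        assert abs(mc - exact) < 4 * se + 0.05


class TestSessions:
    def test_all_seven_tasks_logged(self, perfect_session):
        assert set(perfect_session["task"].unique()) == set(engine.TASKS)

    def test_record_key_unique(self, perfect_session):
        key = perfect_session[["participant_id", "task", "phase", "block_index",
                               "trial_index", "segment"]]
        assert not key.duplicated().any()

    def test_deterministic_logs(self, task_config):
        plan = engine.plan_session(2, 7)
        a = engine.run_session(plan, task_config, responder.PerfectResponder())
        b = engine.run_session(plan, task_config, responder.PerfectResponder())
        assert engine.records_to_frame(a).equals(engine.records_to_frame(b))

    def test_empty_plan_rejected(self, task_config):
        plan = engine.SessionPlan(0, (), {})
        with pytest.raises(ConfigurationError):
            engine.run_session(plan, task_config, responder.PerfectResponder())

    def test_aborted_session_keeps_partial_log(self, task_config):
        class Crashy(responder.PerfectResponder):
            def report_digits(self, spec):
                raise RuntimeError("keyboard unplugged")

        plan = engine.plan_session(0, 42)
        with pytest.raises(AbortedSessionError) as err:
            engine.run_session(plan, task_config, Crashy())
        tasks_done = {r.task for r in err.value.records}
        before = plan.task_order[: plan.task_order.index("updating")]
        assert tasks_done >= set(before)

    def test_log_roundtrip(self, perfect_session, tmp_path):
        path = tmp_path / "log.csv"
        engine.write_log(perfect_session, path)
        back = engine.read_log(path)
        assert len(back) == len(perfect_session)
        assert list(back.columns) == list(engine.LOG_COLUMNS)

    def test_read_log_schema_validation(self, tmp_path):
        path = tmp_path / "bad.csv"
        pd.DataFrame({"a": [1]}).to_csv(path, index=False)
        with pytest.raises(SchemaError):
            engine.read_log(path)


def test_config_yaml_roundtrip(tmp_path):
    path = tmp_path / "cfg.yaml"
    path.write_text("nback_test: 20\nspan_set_sizes: [2, 3]\n")
    cfg = engine.TaskConfig.from_yaml(path)
    assert cfg.nback_test == 20
    assert cfg.span_set_sizes == (2, 3)
    path.write_text("no_such_key: 1\n")
    with pytest.raises(ConfigurationError):
        engine.TaskConfig.from_yaml(path)
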