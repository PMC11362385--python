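"""Raw scoring, normalization, log processing, screening, descriptives."""

import json

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from openwmb import engine, scoring
from openwmb.errors import ConfigurationError, SchemaError


def _rederive_score(task, df):
    """Independent recomputation of a raw score from stimulus descriptors
    and responses only (never from the stored `correct` column)."""
    test = df[(df.task == task) & (df.phase == "test")]
    if task in ("reading", "operation", "symmetry"):
        mem = test[test.segment == "memory"]
        ok = 0
        for _, row in mem.iterrows():
            stim = json.loads(row["stimulus"])["item"]
            resp = json.loads(row["response"]).get("recalled")
            ok += resp == stim
        return ok / len(mem)
    if task == "nback":
        items = test[(test.segment == "item") & test.scored]
        ok = 0
        for _, row in items.iterrows():
            stim = json.loads(row["stimulus"])
            resp = json.loads(row["response"])
            pressed = resp["pressed"] and not resp["late"]
            if stim["is_target"] and pressed:
                ok += 1
        return ok
    if task == "updating":
        trials = test[test.segment == "trial"]
        total = 0
        for _, row in trials.iterrows():
            stim = json.loads(row["stimulus"])
            digits = json.loads(row["response"])["digits"]
            # replay the operations instead of trusting the stored finals
            state = list(stim["initial"])
            for f, d in stim["ops"]:
                state[f] += d
            total += sum(d == s for d, s in zip(digits, state))
        return total
    if task == "binding":
        trials = test[test.segment == "trial"]
        ok = 0
        for _, row in trials.iterrows():
            stim = json.loads(row["stimulus"])
            resp = json.loads(row["response"])
            ok += (resp["answer"] is not None
                   and resp["answer"] == stim["is_match"]
                   and not resp["timed_out"])
        return ok
    trials = test[test.segment == "trial"]
    best = 0
    for _, row in trials.iterrows():
        stim = json.loads(row["stimulus"])["items"]
        resp = json.loads(row["response"])["recalled"]
        if resp == stim:
            best = max(best, len(stim))
    return best


class TestRawScores:
    def test_ceiling_scores(self, perfect_session):
        expected = {"reading": 1.0, "operation": 1.0, "symmetry": 1.0,
                    "nback": 12, "updating": 36, "binding": 16, "multimodal": 11}
        for task, want in expected.items():
            sub = perfect_session[perfect_session.task == task]
            assert scoring.compute_raw_score(task, sub) == want

    @pytest.mark.parametrize("task", engine.TASKS)
    def test_matches_independent_rederivation(self, task, cohort_logs):
        for pid, df in cohort_logs.items():
            sub = df[df.task == task]
            got = scoring.compute_raw_score(task, sub)
            assert got == pytest.approx(_rederive_score(task, df)), pid

    def test_mixed_tasks_rejected(self, perfect_session):
        with pytest.raises(SchemaError):
            scoring.compute_raw_score("nback", perfect_session)

    def test_scoring_idempotent(self, cohort_logs):
        df = next(iter(cohort_logs.values()))
        sub = df[df.task == "binding"]
        assert (scoring.compute_raw_score("binding", sub)
                == scoring.compute_raw_score("binding", sub))


class TestNormalization:
    def test_printed_range_endpoints(self):
        # smallest observed multimodal and updating scores on the 0-1 scale
        assert round(scoring.normalize(3, "multimodal"), 2) == 0.27
        assert round(scoring.normalize(2, "updating"), 2) == 0.06

    @pytest.mark.parametrize("task", scoring.TASK_MAX)
    def test_floor_and_ceiling(self, task):
        assert scoring.normalize(0, task) == 0.0
        assert scoring.normalize(scoring.TASK_MAX[task], task) == 1.0

    def test_order_preserving(self):
        vals = [scoring.normalize(v, "nback") for v in range(13)]
        assert vals == sorted(vals)

    def test_out_of_range_rejected(self):
        with pytest.raises(ConfigurationError):
            scoring.normalize(13, "nback")


class TestProcessLogs:
    def test_shape(self, cohort_logs):
        table = scoring.process_logs(cohort_logs, exclude_multi_zero=False)
        assert table.data.shape == (len(cohort_logs), 14)

    def test_multi_zero_participant_excluded(self, perfect_session, task_config):
        from openwmb import responder

        plan = engine.plan_session(1, 42)
        zero = engine.records_to_frame(engine.run_session(
            plan, task_config, responder.SilentResponder()))
        both = pd.concat([perfect_session, zero], ignore_index=True)
        table = scoring.process_logs(both)
        assert plan.participant_id in table.excluded
        assert plan.participant_id not in table.data.index

    def test_roundtrip(self, cohort_logs, tmp_path):
        table = scoring.process_logs(cohort_logs, exclude_multi_zero=False)
        path = tmp_path / "scores.csv"
        table.to_csv(path)
        back = scoring.ScoreTable.read_csv(path)
        pd.testing.assert_frame_equal(back.data, table.data)


class TestUnivariateScreening:
    def _table(self, values, task="nback"):
        df = pd.DataFrame({
            f"{t}_norm": values if t == task else np.full(len(values), 0.5)
            for t in engine.TASKS})
        for t in engine.TASKS:
            df[f"{t}_raw"] = df[f"{t}_norm"] * scoring.TASK_MAX[t]
        df.index = [f"P{i:04d}" for i in range(len(values))]
        return scoring.ScoreTable(df)

    def test_planted_outlier_flagged(self):
        vals = np.full(30, 0.5)
        vals[::3] += 0.01
        vals[0] = 0.5 + 5 * np.std(vals, ddof=1) * 40  # way out
        table = self._table(list(vals))
        out, report = scoring.screen_univariate(table)
        flagged = [(t, p) for t, p, _ in report.univariate]
        assert ("nback", "P0000") in flagged
        assert np.isnan(out.data.loc["P0000", "nback_norm"])

    def test_no_flags_within_one_sd(self, rng):
        vals = 0.5 + 0.05 * rng.uniform(-1, 1, size=30)
        out, report = scoring.screen_univariate(self._table(list(vals)))
        assert report.univariate == []

    def test_flags_match_brute_force_z(self, rng):
        vals = list(0.5 + 0.08 * rng.standard_normal(40))
        vals[7] = 0.99
        vals[13] = 0.01
        table = self._table(vals)
        _, report = scoring.screen_univariate(table)
        arr = np.array(vals)
        z = (arr - arr.mean()) / arr.std(ddof=1)
        expected = {f"P{i:04d}" for i in np.flatnonzero(np.abs(z) > 3)}
        got = {p for t, p, _ in report.univariate if t == "nback"}
        assert got == expected

    def test_screening_only_removes_values(self, cohort_logs):
        table = scoring.process_logs(cohort_logs, exclude_multi_zero=False)
        before = table.data.notna().sum().sum()
        out, _ = scoring.screen_univariate(table)
        assert out.data.notna().sum().sum() <= before

    def test_constant_column_skipped_with_warning(self):
        table = self._table([0.5] * 10)
        with pytest.warns(UserWarning):
            _, report = scoring.screen_univariate(table)
        assert "nback_norm" in report.skipped_columns


class TestMultivariateScreening:
    def test_center_point_retained(self, rng):
        base = rng.standard_normal((50, 3))
        base[0] = np.delete(base, 0, axis=0).mean(0)  # row 0 = grand mean
        x = pd.DataFrame(base)
        assert np.allclose(base[0], base.mean(0))
        d2 = scoring.mahalanobis_d2(x)
        assert d2.iloc[0] == pytest.approx(0.0, abs=1e-8)
        assert not any(p == x.index[0] for p, _, _ in
                       scoring.screen_multivariate(x).multivariate)

    def test_two_variable_closed_form(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0, 4.0], "b": [2.0, 1.0, 4.0, 3.0]})
        d2 = scoring.mahalanobis_d2(df)
        # hand computation with the explicit 2x2 inverse
        x = df.to_numpy()
        c = x - x.mean(0)
        S = np.cov(x, rowvar=False, ddof=1)
        det = S[0, 0] * S[1, 1] - S[0, 1] ** 2
        inv = np.array([[S[1, 1], -S[0, 1]], [-S[0, 1], S[0, 0]]]) / det
        for i in range(4):
            assert d2.iloc[i] == pytest.approx(c[i] @ inv @ c[i])

    def test_identity_covariance_reduces_to_euclidean(self, rng):
        x = rng.standard_normal((500, 4))
        x = x - x.mean(0)
        # whiten so the sample covariance is exactly the identity
        L = np.linalg.cholesky(np.cov(x, rowvar=False, ddof=1))
        x = x @ np.linalg.inv(L).T
        df = pd.DataFrame(x)
        d2 = scoring.mahalanobis_d2(df)
        eucl = (x**2).sum(axis=1)
        assert np.abs(d2.to_numpy() - eucl).max() < 1e-8

    def test_incomplete_table_rejected(self):
        df = pd.DataFrame({"a": [1.0, np.nan, 3.0], "b": [1.0, 2.0, 3.0]})
        with pytest.raises(ConfigurationError):
            scoring.mahalanobis_d2(df)


class TestDescriptives:
    def test_constant_column_reported_na(self):
        df = pd.DataFrame({"x": [0.5] * 10})
        desc = scoring.descriptives(df)
        assert desc.loc["x", "sd"] == 0
        assert np.isnan(desc.loc["x", "skew"])

    def test_standard_normal_asymptotics(self, rng):
        df = pd.DataFrame({"x": rng.standard_normal(100_000)})
        desc = scoring.descriptives(df)
        assert abs(desc.loc["x", "skew"]) < 0.05
        assert abs(desc.loc["x", "kurtosis"]) < 0.1
        assert desc.loc["x", "normal"]

    def test_percentiles_match_sorted_interpolation(self, rng):
        vals = rng.uniform(size=20)
        desc = scoring.descriptives(pd.DataFrame({"x": vals}))
        srt = np.sort(vals)
        for q in scoring.PERCENTILES:
            # order-statistic linear interpolation at rank q/100 * (n-1)
            pos = q / 100 * 19
            lo, frac = int(pos), pos - int(pos)
            want = srt[lo] + frac * (srt[min(lo + 1, 19)] - srt[lo])
            assert desc.loc["x", f"p{q}"] == pytest.approx(want)

    def test_mardia_kurtosis_on_normal_data(self, rng):
        df = pd.DataFrame(rng.standard_normal((5000, 4)))
        mk = scoring.mardia_kurtosis(df)
        assert abs(mk["kappa"]) < 1.0
        assert mk["p_value"] > 0.01
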