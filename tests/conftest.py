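import numpy as np
import pytest

from openwmb import engine, responder


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def task_config():
    return engine.TaskConfig()


@pytest.fixture(scope="session")
def perfect_session(task_config):
    """One full session run by the ceiling responder."""
    plan = engine.plan_session(0, 42)
    records = engine.run_session(plan, task_config, responder.PerfectResponder())
    return engine.records_to_frame(records)


@pytest.fixture(scope="session")
def cohort_logs(task_config):
    """Trial-level logs for a small simulated cohort (ability model)."""
    profiles = responder.make_cohort(12, seed=7)
    logs = {}
    for i, prof in enumerate(profiles):
        plan = engine.plan_session(i, 99)
        resp = responder.AbilityResponder(prof, rng=np.random.default_rng(1000 + i))
        records = engine.run_session(plan, task_config, resp)
        logs[plan.participant_id] = engine.records_to_frame(records)
    return logs
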