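import numpy as np
import pytest

from partialpress import simulate, taskgen, trialproc
from partialpress.keystream import KeyTrajectory


@pytest.fixture
def traj():
    """Factory for a KeyTrajectory from (time_ms, value) pairs."""

    def make(key_id, events, duration_ms=1500.0):
        times = [e[0] for e in events]
        values = [e[1] for e in events]
        return KeyTrajectory(key_id, times, values, duration_ms)

    return make


@pytest.fixture
def make_trial(traj):
    """Factory for a two-key CIT TrialRecord from per-key event lists."""

    def make(correct_events, incorrect_events, correct_key="e", other_key="i",
             deadline_ms=1500.0, item_type="probe", **kw):
        return trialproc.TrialRecord(
            participant_id=kw.get("participant_id", "p1"),
            trial_index=kw.get("trial_index", 0),
            task=kw.get("task", "CIT"),
            condition=kw.get("condition", "low"),
            item=kw.get("item", "x"),
            item_type=item_type,
            correct_key=correct_key,
            deadline_ms=deadline_ms,
            trajectories={
                correct_key: traj(correct_key, correct_events, deadline_ms),
                other_key: traj(other_key, incorrect_events, deadline_ms),
            },
        )

    return make


@pytest.fixture(scope="session")
def cit_experiment():
    """One simulated CIT participant with ground truth (shared, read-only)."""
    design = taskgen.generate_cit_design(seed=101)
    cfg = simulate.default_cit_config(seed=202)
    records, truth = simulate.simulate_experiment(design, cfg, "p001", seed=303)
    return design, cfg, records, truth
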