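"""Response extraction, partial-error detection, exclusions, aggregation."""

import numpy as np
import pytest

from partialpress import simulate, taskgen, trialproc
from partialpress.trialproc import (
    ExclusionPolicy,
    TrialOutcome,
    apply_exclusions,
    detect_partial_error,
    extract_response,
    flag_starts_pressed,
    participant_performance_filter,
    process_trials,
    summarize_participant,
)


class TestExtractResponse:
    def test_threshold_crossing_on_correct_key(self, make_trial):
        trial = make_trial([(300, 0.5), (340, 0.96)], [])
        out = extract_response(trial)
        assert out.rt_ms == 340
        assert out.pressed_key == "e"
        assert not out.is_error

    def test_no_crossing_is_no_response(self, make_trial):
        out = extract_response(make_trial([], []))
        assert out.rt_ms is None and out.pressed_key is None
        assert out.exclusion_reason == "no_response"

    def test_threshold_is_strict(self, make_trial):
        # exactly .95 does not count as a full press; the crossing is later
        trial = make_trial([(400, 0.95), (410, 0.96)], [])
        assert extract_response(trial).rt_ms == 410

    def test_crossing_after_deadline_ignored(self, traj):
        # key goes down only after the 1.5 s deadline (longer recording window)
        trial = trialproc.TrialRecord(
            participant_id="p1", trial_index=0, task="CIT", condition="low",
            item="x", item_type="probe", correct_key="e", deadline_ms=1500.0,
            trajectories={
                "e": traj("e", [(1600, 0.99)], duration_ms=2000.0),
                "i": traj("i", [], duration_ms=2000.0),
            },
        )
        assert extract_response(trial).rt_ms is None

    def test_wrong_key_press_is_error(self, make_trial):
        out = extract_response(make_trial([], [(500, 0.99)]))
        assert out.pressed_key == "i" and out.is_error

    def test_simultaneous_crossing_larger_value_wins(self, make_trial):
        trial = make_trial([(400, 0.97)], [(400, 0.99)])
        out = extract_response(trial)
        assert out.rt_ms == 400
        assert out.pressed_key == "i" and out.is_error

    def test_exact_tie_marked_error(self, make_trial):
        out = extract_response(make_trial([(400, 0.98)], [(400, 0.98)]))
        assert out.rt_ms == 400 and out.is_error

    def test_lower_threshold_never_slower(self, cit_experiment):
        _, _, records, _ = cit_experiment
        for rec in records[:300]:
            hi = extract_response(rec, 0.95)
            lo = extract_response(rec, 0.5)
            if hi.rt_ms is not None:
                assert lo.rt_ms is not None and lo.rt_ms <= hi.rt_ms


class TestDetectPartialError:
    def test_aborted_incorrect_press_detected(self, make_trial):
        trial = make_trial(
            [(460, 0.5), (500, 0.96)], [(240, 0.1), (250, 0.3), (270, 0.0)]
        )
        out = extract_response(trial)
        assert out.rt_ms == 500
        assert detect_partial_error(trial, out) is True

    def test_quiet_incorrect_key_is_clean(self, make_trial):
        trial = make_trial([(460, 0.5), (500, 0.96)], [])
        assert detect_partial_error(trial, extract_response(trial)) is False

    def test_movement_at_crossing_does_not_count(self, make_trial):
        # incorrect key first moves exactly at rt: strictly-before rule
        trial = make_trial([(460, 0.5), (500, 0.96)], [(500, 0.3)])
        assert detect_partial_error(trial, extract_response(trial)) is False

    def test_requires_response(self, make_trial):
        trial = make_trial([], [])
        with pytest.raises(ValueError):
            detect_partial_error(trial, extract_response(trial))


class TestStartsPressed:
    def test_early_nonzero_flags(self, make_trial):
        assert flag_starts_pressed(make_trial([], [(2, 0.1), (30, 0.0)]))

    def test_boundary_is_inclusive(self, make_trial):
        assert flag_starts_pressed(make_trial([(5, 0.1), (30, 0.0)], []))

    def test_first_movement_after_window_ok(self, make_trial):
        assert not flag_starts_pressed(make_trial([(6, 0.1), (30, 0.0)], []))

    def test_all_zero_ok(self, make_trial):
        assert not flag_starts_pressed(make_trial([], []))


def _outcome(rt=None, key=None, error=False, starts=False):
    return TrialOutcome(rt_ms=rt, pressed_key=key, is_error=error,
                        starts_pressed=starts,
                        excluded=rt is None,
                        exclusion_reason="no_response" if rt is None else "none")


class TestExclusions:
    def test_toy_set_matches_hand_enumeration(self, make_trial):
        # 10 CIT trials, 3 violating a rule each; hand-enumerated verdicts
        plan = [
            (600, False, "probe", "none"),
            (150, False, "irrelevant", "too_fast"),
            (600, True, "probe", "error"),
            (700, False, "irrelevant", "none"),
            (None, False, "probe", "no_response"),
            (500, False, "target", "target_trial"),
            (1501, False, "irrelevant", "too_slow"),
            (800, False, "probe", "none"),
            (400, False, "irrelevant", "none"),
            (900, False, "irrelevant", "none"),
        ]
        trials = []
        for rt, err, item_type, _ in plan:
            trial = make_trial([], [], item_type=item_type)
            out = _outcome(rt, None if rt is None else ("i" if err else "e"),
                           error=err)
            trials.append((trial, out))
        res = apply_exclusions(trials, ExclusionPolicy.for_task("CIT"))
        assert len(res.retained) == 5
        got = [o.exclusion_reason for _, o in trials]
        assert got == [p[3] for p in plan]
        assert res.counts == {
            "starts_pressed": 0, "no_response": 1, "too_fast": 1,
            "too_slow": 1, "error": 1, "target_trial": 1,
        }
        assert res.exclusion_fraction == 0.5

    def test_partition_is_exhaustive(self, cit_experiment):
        _, _, records, _ = cit_experiment
        res = process_trials(records)
        assert len(res.retained) + sum(res.counts.values()) == res.n_total

    def test_sternberg_bounds(self, make_trial):
        trial = make_trial([], [], task="STERNBERG", item_type="match",
                           deadline_ms=2500)
        out = _outcome(2499, "e")
        res = apply_exclusions([(trial, out)], ExclusionPolicy.for_task("STERNBERG"))
        assert len(res.retained) == 1

    def test_starts_pressed_has_top_priority(self, make_trial):
        trial = make_trial([], [], item_type="target")
        out = _outcome(150, "i", error=True, starts=True)
        apply_exclusions([(trial, out)], ExclusionPolicy.for_task("CIT"))
        assert out.exclusion_reason == "starts_pressed"

    def test_bad_policy_rejected(self):
        with pytest.raises(ValueError):
            ExclusionPolicy(rt_min_ms=-5)
        with pytest.raises(ValueError):
            ExclusionPolicy(rt_min_ms=300, rt_max_ms=200)


class TestSummaries:
    def test_participant_means(self, make_trial):
        trials = []
        for i, (rt, partial) in enumerate(
            [(500, True), (600, False), (550, False), (650, False)]
        ):
            out = _outcome(rt, "e")
            out.is_partial_error = partial
            trials.append((make_trial([], [], item_type="probe", trial_index=i), out))
        s = summarize_participant(trials)
        cell = s.cell("probe")
        assert cell.mean_rt_ms == 575
        assert cell.prop_partial == 0.25
        assert cell.n_valid == 4

    def test_empty_cell_is_absent_not_zero(self, make_trial):
        trials = [(make_trial([], [], item_type="probe"), _outcome(500, "e"))]
        s = summarize_participant(trials, item_types=["probe", "irrelevant"])
        assert s.cell("irrelevant").mean_rt_ms is None
        assert s.cell("irrelevant").prop_partial is None

    def test_mixed_participants_rejected(self, make_trial):
        trials = [
            (make_trial([], [], participant_id="a"), _outcome(500, "e")),
            (make_trial([], [], participant_id="b"), _outcome(500, "e")),
        ]
        with pytest.raises(ValueError):
            summarize_participant(trials)


class TestPerformanceFilter:
    @pytest.mark.parametrize(
        "acc, keep",
        [
            ({"match": 0.9, "intrusion": 0.55, "new": 0.8}, False),
            ({"match": 0.9, "intrusion": 0.7, "new": 0.8}, True),
            ({"match": 0.6, "intrusion": 0.6, "new": 0.6}, True),  # boundary keeps
        ],
    )
    def test_drop_rule(self, acc, keep):
        assert participant_performance_filter(acc) is keep

    def test_missing_category_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            participant_performance_filter(
                {"match": 0.9}, required_categories=["match", "intrusion", "new"]
            )


def test_zero_conflict_simulation_yields_no_partials():
    """With incorrect-key movement probability 0, prop_partial is exactly 0."""
    design = taskgen.generate_cit_design(seed=5)
    cfg = simulate.default_cit_config(seed=6)
    clean = {
        it: simulate.ItemTypeParams(p.latency, p_partial=0.0, error_rate=p.error_rate)
        for it, p in cfg.item_params.items()
    }
    cfg = simulate.SimulationConfig(item_params=clean, seed=6)
    records, _ = simulate.simulate_experiment(design, cfg, "p1", seed=7)
    res = process_trials(records)
    assert all(not o.is_partial_error for _, o in res.retained + res.excluded)
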