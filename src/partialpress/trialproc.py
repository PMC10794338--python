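"""Trial outcomes: response extraction, partial-error detection, exclusions.

A response is the first time either response key's analog value exceeds the
full-press threshold (default .95) within the response deadline.  A partial
error (partial button press) is scored when *both* response keys show analog
values > 0 before that threshold crossing — because the responded key is
necessarily nonzero on its way to the press, this amounts to the incorrect
key having moved.  Trials that begin with a partially pressed key (value > 0
within the first 5 ms) are flagged as accidental carry-over presses.

The exclusion pipeline mirrors standard RT-task practice: drop carry-over
trials, misses, anticipations (< 200 ms), deadline RTs (> 1500 ms CIT /
> 2500 ms Sternberg), response errors and — for the concealed-information
analyses — target trials; then aggregate per participant and item type.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .keystream import KeyTrajectory

__all__ = [
    "TrialRecord",
    "TrialOutcome",
    "CellSummary",
    "ParticipantSummary",
    "ExclusionPolicy",
    "ExclusionResult",
    "extract_response",
    "detect_partial_error",
    "flag_starts_pressed",
    "apply_exclusions",
    "process_trials",
    "summarize_participant",
    "participant_performance_filter",
    "outcomes_to_frame",
    "summaries_to_frame",
    "FULL_PRESS_THRESHOLD",
    "STARTS_PRESSED_WINDOW_MS",
    "RT_MIN_MS",
    "CIT_DEADLINE_MS",
    "STERNBERG_DEADLINE_MS",
    "CIT_ITEM_TYPES",
    "STERNBERG_ITEM_TYPES",
]

FULL_PRESS_THRESHOLD = 0.95
STARTS_PRESSED_WINDOW_MS = 5.0
RT_MIN_MS = 200.0
CIT_DEADLINE_MS = 1500.0
STERNBERG_DEADLINE_MS = 2500.0

CIT_ITEM_TYPES = ("probe", "irrelevant", "target")
STERNBERG_ITEM_TYPES = ("match", "intrusion", "new")

EXCLUSION_REASONS = (
    "none",
    "starts_pressed",
    "too_fast",
    "too_slow",
    "error",
    "no_response",
    "target_trial",
)

# fixed priority so per-reason counts are unambiguous
_EXCLUSION_PRIORITY = (
    "starts_pressed",
    "no_response",
    "too_fast",
    "too_slow",
    "error",
    "target_trial",
)


@dataclass
class TrialRecord:
    """One stimulus presentation with its two response-key trajectories."""

    participant_id: str
    trial_index: int
    task: str  # "CIT" | "STERNBERG"
    condition: str  # "low" | "high"
    item: str
    item_type: str
    correct_key: str
    deadline_ms: float
    trajectories: Mapping[str, KeyTrajectory]
    block: int = 0
    rsi_ms: float = 0.0

    def __post_init__(self) -> None:
        if self.deadline_ms <= 0:
            raise ValueError("deadline_ms must be positive")
        if len(self.trajectories) != 2:
            raise ValueError(
                f"trial {self.trial_index}: expected exactly two response-key "
                f"trajectories, got {sorted(self.trajectories)}"
            )
        expected = {
            "CIT": set(CIT_ITEM_TYPES),
            "STERNBERG": set(STERNBERG_ITEM_TYPES),
        }.get(self.task)
        if expected is not None and self.item_type not in expected:
            raise ValueError(
                f"item_type {self.item_type!r} invalid for task {self.task}"
            )

    @property
    def keys(self) -> tuple[str, str]:
        return tuple(sorted(self.trajectories))  # type: ignore[return-value]


@dataclass
class TrialOutcome:
    """Derived verdict for one trial.

    ``rt_ms`` and ``pressed_key`` are ``None`` exactly when no key crossed the
    full-press threshold before the deadline (a miss).
    """

    rt_ms: float | None = None
    pressed_key: str | None = None
    is_error: bool = False
    is_partial_error: bool = False
    starts_pressed: bool = False
    excluded: bool = False
    exclusion_reason: str = "none"

    def __post_init__(self) -> None:
        if (self.rt_ms is None) != (self.pressed_key is None):
            raise ValueError("rt_ms and pressed_key must be absent together")
        if self.is_partial_error and self.rt_ms is None:
            raise ValueError("a partial error requires a response")
        if self.exclusion_reason not in EXCLUSION_REASONS:
            raise ValueError(f"unknown exclusion reason {self.exclusion_reason!r}")
        if self.excluded != (self.exclusion_reason != "none"):
            raise ValueError("excluded flag inconsistent with exclusion_reason")


def extract_response(
    trial: TrialRecord, full_press_threshold: float = FULL_PRESS_THRESHOLD
) -> TrialOutcome:
    """Find the earliest full press (value strictly > threshold) by deadline.

    Works directly on the sparse event lists: under zero-order hold the signal
    can only cross a level at an event, so the first qualifying event time is
    the crossing time.  Ties across the two keys resolve to the key with the
    larger analog value at that time; an exact tie is marked as an error.
    """
    if not 0.0 < full_press_threshold < 1.0:
        raise ValueError("full_press_threshold must lie in (0, 1)")
    crossings: dict[str, float] = {}
    for key_id, traj in trial.trajectories.items():
        t = traj.first_crossing(full_press_threshold, t_max=trial.deadline_ms)
        if t is not None:
            crossings[key_id] = t
    if not crossings:
        return TrialOutcome(excluded=True, exclusion_reason="no_response")
    rt = min(crossings.values())
    winners = sorted(k for k, t in crossings.items() if t == rt)
    if len(winners) == 1:
        key = winners[0]
        return TrialOutcome(rt_ms=rt, pressed_key=key, is_error=key != trial.correct_key)
    # simultaneous crossing: larger analog value at that sample wins
    vals = {k: trial.trajectories[k].value_at(rt) for k in winners}
    vmax = max(vals.values())
    top = sorted(k for k, v in vals.items() if v == vmax)
    if len(top) == 1:
        key = top[0]
        return TrialOutcome(rt_ms=rt, pressed_key=key, is_error=key != trial.correct_key)
    return TrialOutcome(rt_ms=rt, pressed_key=top[0], is_error=True)


def detect_partial_error(
    trial: TrialRecord,
    outcome: TrialOutcome,
    onset_guard_ms: float = STARTS_PRESSED_WINDOW_MS,
) -> bool:
    """True iff both response keys were > 0 strictly before the threshold crossing.

    Each key may become nonzero at a different time; the comparison against
    ``rt_ms`` is strict (movement simultaneous with the crossing does not
    count).  Must not be called on no-response or starts-pressed trials.
    """
    if outcome.rt_ms is None:
        raise ValueError("detect_partial_error requires a responded trial")
    if flag_starts_pressed(trial, window_ms=onset_guard_ms):
        raise ValueError(
            "detect_partial_error called on a starts-pressed trial; exclude it first"
        )
    return all(
        traj.any_positive_before(outcome.rt_ms)
        for traj in trial.trajectories.values()
    )


def flag_starts_pressed(
    trial: TrialRecord, window_ms: float = STARTS_PRESSED_WINDOW_MS
) -> bool:
    """True iff any response key shows value > 0 at some t in [0, window_ms]."""
    return any(
        traj.any_positive_upto(window_ms) for traj in trial.trajectories.values()
    )


@dataclass(frozen=True)
class ExclusionPolicy:
    """Which trials to drop before aggregation.

    Defaults follow the concealed-information analyses: RTs below 200 ms or
    above the task deadline, response errors, carry-over (starts-pressed)
    trials, and — when ``exclude_targets`` — target trials, since the
    probe-vs-irrelevant contrasts do not use them.
    """

    task: str = "CIT"
    rt_min_ms: float = RT_MIN_MS
    rt_max_ms: float = CIT_DEADLINE_MS
    exclude_targets: bool = True
    exclude_errors: bool = True

    def __post_init__(self) -> None:
        if self.rt_min_ms <= 0 or self.rt_max_ms <= 0:
            raise ValueError("RT bounds must be positive")
        if self.rt_max_ms <= self.rt_min_ms:
            raise ValueError("rt_max_ms must exceed rt_min_ms")

    @classmethod
    def for_task(cls, task: str, **kw) -> "ExclusionPolicy":
        task = task.upper()
        if task == "CIT":
            return cls(task="CIT", rt_max_ms=CIT_DEADLINE_MS, **kw)
        if task == "STERNBERG":
            return cls(
                task="STERNBERG",
                rt_max_ms=STERNBERG_DEADLINE_MS,
                exclude_targets=False,
                **kw,
            )
        raise ValueError(f"unknown task {task!r}")


@dataclass
class ExclusionResult:
    retained: list[tuple[TrialRecord, TrialOutcome]]
    excluded: list[tuple[TrialRecord, TrialOutcome]]
    counts: dict[str, int]
    n_total: int

    @property
    def exclusion_fraction(self) -> float:
        return (self.n_total - len(self.retained)) / self.n_total if self.n_total else 0.0


def _classify(trial: TrialRecord, outcome: TrialOutcome, policy: ExclusionPolicy) -> str:
    """Assign the single exclusion reason in fixed priority order."""
    checks = {
        "starts_pressed": outcome.starts_pressed,
        "no_response": outcome.rt_ms is None,
        "too_fast": outcome.rt_ms is not None and outcome.rt_ms < policy.rt_min_ms,
        "too_slow": outcome.rt_ms is not None and outcome.rt_ms > policy.rt_max_ms,
        "error": policy.exclude_errors and outcome.is_error,
        "target_trial": policy.exclude_targets and trial.item_type == "target",
    }
    for reason in _EXCLUSION_PRIORITY:
        if checks[reason]:
            return reason
    return "none"


def apply_exclusions(
    trials: Sequence[tuple[TrialRecord, TrialOutcome]],
    policy: ExclusionPolicy,
) -> ExclusionResult:
    """Partition trials into retained / excluded with per-reason counts.

    Every trial receives exactly one reason; retained + per-reason counts sum
    to the total.  The input outcomes are updated in place with their reason.
    """
    counts = {r: 0 for r in _EXCLUSION_PRIORITY}
    retained: list[tuple[TrialRecord, TrialOutcome]] = []
    excluded: list[tuple[TrialRecord, TrialOutcome]] = []
    for trial, outcome in trials:
        reason = _classify(trial, outcome, policy)
        outcome.exclusion_reason = reason
        outcome.excluded = reason != "none"
        if reason == "none":
            retained.append((trial, outcome))
        else:
            counts[reason] += 1
            excluded.append((trial, outcome))
    return ExclusionResult(retained, excluded, counts, len(trials))


def process_trials(
    trials: Iterable[TrialRecord],
    policy: ExclusionPolicy | None = None,
    full_press_threshold: float = FULL_PRESS_THRESHOLD,
    starts_pressed_window_ms: float = STARTS_PRESSED_WINDOW_MS,
) -> ExclusionResult:
    """Run the full per-trial pipeline: flag, extract, score partials, exclude."""
    trials = list(trials)
    if policy is None:
        task = trials[0].task if trials else "CIT"
        policy = ExclusionPolicy.for_task(task)
    scored: list[tuple[TrialRecord, TrialOutcome]] = []
    for trial in trials:
        sp = flag_starts_pressed(trial, starts_pressed_window_ms)
        outcome = extract_response(trial, full_press_threshold)
        outcome.starts_pressed = sp
        if outcome.rt_ms is not None and not sp:
            outcome.is_partial_error = detect_partial_error(
                trial, outcome, onset_guard_ms=starts_pressed_window_ms
            )
        scored.append((trial, outcome))
    return apply_exclusions(scored, policy)


@dataclass
class CellSummary:
    n_valid: int
    mean_rt_ms: float | None
    sd_rt_ms: float | None
    prop_partial: float | None
    prop_error: float | None


@dataclass
class ParticipantSummary:
    """Per item-type aggregates over one participant's retained trials."""

    participant_id: str
    condition: str
    cells: dict[str, CellSummary] = field(default_factory=dict)

    def cell(self, item_type: str) -> CellSummary:
        return self.cells[item_type]


def summarize_participant(
    retained: Sequence[tuple[TrialRecord, TrialOutcome]],
    item_types: Sequence[str] | None = None,
) -> ParticipantSummary:
    """Mean/SD RT and partial/error proportions per item type.

    Proportions use the retained (valid) trials of that item type as the
    denominator.  An item type with no retained trials yields an absent
    (``None``-valued) cell, never zeros.
    """
    pids = {t.participant_id for t, _ in retained}
    if len(pids) > 1:
        raise ValueError(f"trials from multiple participants: {sorted(pids)}")
    pid = next(iter(pids)) if pids else ""
    cond = retained[0][0].condition if retained else ""
    if item_types is None:
        item_types = sorted({t.item_type for t, _ in retained})
    summary = ParticipantSummary(pid, cond)
    for it in item_types:
        cell_trials = [(t, o) for t, o in retained if t.item_type == it]
        n = len(cell_trials)
        if n == 0:
            summary.cells[it] = CellSummary(0, None, None, None, None)
            continue
        rts = np.array([o.rt_ms for _, o in cell_trials], dtype=float)
        summary.cells[it] = CellSummary(
            n_valid=n,
            mean_rt_ms=float(np.mean(rts)),
            sd_rt_ms=float(np.std(rts, ddof=1)) if n > 1 else None,
            prop_partial=float(np.mean([o.is_partial_error for _, o in cell_trials])),
            prop_error=float(np.mean([o.is_error for _, o in cell_trials])),
        )
    return summary


def participant_performance_filter(
    accuracy_by_category: Mapping[str, float],
    threshold: float = 0.60,
    required_categories: Sequence[str] | None = None,
) -> bool:
    """Keep (True) unless any category accuracy is strictly below threshold.

    A boundary accuracy of exactly ``threshold`` keeps the participant
    ("less than 60% correct" drops only strictly below).
    """
    if required_categories is not None:
        missing = [c for c in required_categories if c not in accuracy_by_category]
        if missing:
            raise ValueError(f"missing accuracy for categories {missing}")
    for cat, acc in accuracy_by_category.items():
        if not 0.0 <= acc <= 1.0:
            raise ValueError(f"accuracy for {cat!r} outside [0, 1]: {acc}")
    return all(acc >= threshold for acc in accuracy_by_category.values())


def outcomes_to_frame(
    trials: Sequence[tuple[TrialRecord, TrialOutcome]]
) -> pd.DataFrame:
    """One row per trial with metadata and all outcome fields."""
    rows = []
    for t, o in trials:
        rows.append(
            {
                "participant_id": t.participant_id,
                "trial_index": t.trial_index,
                "task": t.task,
                "condition": t.condition,
                "block": t.block,
                "item": t.item,
                "item_type": t.item_type,
                "correct_key": t.correct_key,
                "deadline_ms": t.deadline_ms,
                "rt_ms": o.rt_ms,
                "pressed_key": o.pressed_key,
                "is_error": o.is_error,
                "is_partial_error": o.is_partial_error,
                "starts_pressed": o.starts_pressed,
                "excluded": o.excluded,
                "exclusion_reason": o.exclusion_reason,
            }
        )
    return pd.DataFrame(rows)


def summaries_to_frame(summaries: Iterable[ParticipantSummary]) -> pd.DataFrame:
    """Long table keyed by participant x item_type (input to the ANOVA BFs)."""
    rows = []
    for s in summaries:
        for it, cell in s.cells.items():
            rows.append(
                {
                    "participant_id": s.participant_id,
                    "condition": s.condition,
                    "item_type": it,
                    "n_valid": cell.n_valid,
                    "mean_rt_ms": cell.mean_rt_ms,
                    "sd_rt_ms": cell.sd_rt_ms,
                    "prop_partial": cell.prop_partial,
                    "prop_error": cell.prop_error,
                }
            )
    return pd.DataFrame(rows)
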