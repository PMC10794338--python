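"""Change-event analog key logs and step-function trajectory reconstruction.

Analog keyboards report each key's depression as a continuous value in [0, 1]
sampled at 1000 Hz.  To keep log files small, a value is recorded only when it
changes since the last retrieval, together with its timestamp.  This module
holds the data model for such change-event logs (:class:`AnalogEvent`,
:class:`KeyTrajectory`), reconstructs the continuous per-key signal by
zero-order hold (the value is constant between recorded changes), and reads and
writes the long-CSV serialization used throughout the package.

Times are trial-relative milliseconds with stimulus onset at 0; the canonical
sampling grid is 1 ms.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AnalogEvent",
    "KeyTrajectory",
    "EventLogError",
    "read_event_log",
    "write_event_log",
    "read_trial_metadata",
    "write_trial_metadata",
    "sparsify",
    "TRIAL_METADATA_COLUMNS",
]

EVENT_LOG_COLUMNS = ["participant_id", "trial_index", "key_id", "time_ms", "value"]
TRIAL_METADATA_COLUMNS = [
    "participant_id",
    "trial_index",
    "task",
    "condition",
    "block",
    "item",
    "item_type",
    "correct_key",
    "deadline_ms",
    "rsi_ms",
]


class EventLogError(ValueError):
    """Raised for malformed or invalid event-log content."""


@dataclass(frozen=True)
class AnalogEvent:
    """One recorded change of a key's analog value.

    Attributes
    ----------
    time_ms : float
        Milliseconds from trial stimulus onset (non-negative).
    key_id : str
        Key label, e.g. ``"e"`` or ``"i"``.
    value : float
        Key depression fraction in [0, 1]; 0 = released, 1 = fully pressed.
    """

    time_ms: float
    key_id: str
    value: float

    def __post_init__(self) -> None:
        if self.time_ms < 0:
            raise EventLogError(f"event time must be non-negative, got {self.time_ms}")
        if not 0.0 <= self.value <= 1.0:
            raise EventLogError(f"analog value must lie in [0, 1], got {self.value}")


class KeyTrajectory:
    """Per-key analog value time series reconstructed from change events.

    The trajectory is defined for all t in ``[0, duration_ms]`` by
    right-continuous step interpolation: each recorded value holds until the
    next event.  Before the first event the value is 0.

    Events are stored as parallel numpy arrays (``times``, ``values``) for
    speed; :attr:`events` materializes them as :class:`AnalogEvent` objects.
    """

    __slots__ = ("key_id", "times", "values", "duration_ms")

    def __init__(
        self,
        key_id: str,
        times: Sequence[float],
        values: Sequence[float],
        duration_ms: float | None = None,
    ) -> None:
        times_arr = np.asarray(times, dtype=float)
        values_arr = np.asarray(values, dtype=float)
        if times_arr.shape != values_arr.shape or times_arr.ndim != 1:
            raise EventLogError("times and values must be 1-D arrays of equal length")
        if times_arr.size:
            if times_arr[0] < 0:
                raise EventLogError(f"key {key_id!r}: negative event time")
            if np.any(np.diff(times_arr) <= 0):
                raise EventLogError(
                    f"key {key_id!r}: event times must be strictly increasing"
                )
            if np.any((values_arr < 0) | (values_arr > 1)):
                raise EventLogError(f"key {key_id!r}: analog value outside [0, 1]")
            if np.any(np.diff(values_arr) == 0):
                raise EventLogError(
                    f"key {key_id!r}: consecutive events must change the value "
                    "(change-only recording)"
                )
        if duration_ms is None:
            duration_ms = float(times_arr[-1]) if times_arr.size else 0.0
        if duration_ms < 0 or (times_arr.size and times_arr[-1] > duration_ms):
            raise EventLogError(f"key {key_id!r}: events exceed duration_ms")
        self.key_id = key_id
        self.times = times_arr
        self.values = values_arr
        self.duration_ms = float(duration_ms)

    @classmethod
    def from_events(
        cls, key_id: str, events: Iterable[AnalogEvent], duration_ms: float | None = None
    ) -> "KeyTrajectory":
        ev = list(events)
        return cls(key_id, [e.time_ms for e in ev], [e.value for e in ev], duration_ms)

    @property
    def events(self) -> list[AnalogEvent]:
        return [
            AnalogEvent(float(t), self.key_id, float(v))
            for t, v in zip(self.times, self.values)
        ]

    def __len__(self) -> int:
        return int(self.times.size)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, KeyTrajectory):
            return NotImplemented
        return (
            self.key_id == other.key_id
            and self.duration_ms == other.duration_ms
            and np.array_equal(self.times, other.times)
            and np.array_equal(self.values, other.values)
        )

    def __repr__(self) -> str:
        return (
            f"KeyTrajectory(key_id={self.key_id!r}, n_events={len(self)}, "
            f"duration_ms={self.duration_ms})"
        )

    def value_at(self, t: float | np.ndarray) -> float | np.ndarray:
        """Analog value at time ``t`` (scalar or array), right-continuous.

        Raises
        ------
        EventLogError
            If ``t`` lies outside ``[0, duration_ms]``.
        """
        t_arr = np.asarray(t, dtype=float)
        if np.any((t_arr < 0) | (t_arr > self.duration_ms)):
            raise EventLogError(
                f"query time outside [0, {self.duration_ms}] for key {self.key_id!r}"
            )
        if self.values.size == 0:
            vals = np.zeros_like(t_arr)
        else:
            idx = np.searchsorted(self.times, t_arr, side="right") - 1
            vals = np.where(idx >= 0, self.values[np.maximum(idx, 0)], 0.0)
        if np.ndim(t) == 0:
            return float(vals)
        return vals

    def densify(self, rate_hz: float = 1000.0) -> tuple[np.ndarray, np.ndarray]:
        """Sample the step function at ``t = 0, 1/rate, 2/rate, ... <= duration``.

        Returns the sample times (ms) and values; the inverse of the
        change-only sparsification when events lie on the sampling grid.
        """
        if rate_hz <= 0:
            raise EventLogError("rate_hz must be positive")
        step = 1000.0 / rate_hz
        n = int(np.floor(self.duration_ms / step + 1e-9)) + 1
        t = np.arange(n) * step
        return t, np.asarray(self.value_at(t), dtype=float)

    # -- convenience queries used by trial processing ---------------------

    def first_crossing(self, threshold: float, t_max: float | None = None) -> float | None:
        """Earliest event time at which value > ``threshold`` (None if never).

        With step interpolation the signal can only cross a level at an event,
        so this equals the first grid time the densified signal exceeds the
        threshold.  ``t_max`` bounds the search (inclusive).
        """
        mask = self.values > threshold
        if t_max is not None:
            mask &= self.times <= t_max
        idx = np.flatnonzero(mask)
        return float(self.times[idx[0]]) if idx.size else None

    def any_positive_before(self, t: float) -> bool:
        """True iff the value is > 0 at some time strictly before ``t``."""
        return bool(np.any((self.times < t) & (self.values > 0)))

    def any_positive_upto(self, t: float) -> bool:
        """True iff the value is > 0 at some time in ``[0, t]`` (inclusive)."""
        return bool(np.any((self.times <= t) & (self.values > 0)))


def sparsify(
    sample_times: Sequence[float],
    sample_values: Sequence[float],
    key_id: str,
    duration_ms: float | None = None,
) -> KeyTrajectory:
    """Compress a dense sample sequence to change-only events.

    An event is emitted at the first sample and whenever the value differs
    from the previous sample; a leading run of zeros emits no event (the
    reconstruction defaults to 0 before the first event).
    """
    t = np.asarray(sample_times, dtype=float)
    v = np.asarray(sample_values, dtype=float)
    if t.size == 0:
        return KeyTrajectory(key_id, [], [], duration_ms or 0.0)
    keep = np.empty(t.size, dtype=bool)
    keep[0] = v[0] != 0.0
    keep[1:] = np.diff(v) != 0.0
    if duration_ms is None:
        duration_ms = float(t[-1])
    return KeyTrajectory(key_id, t[keep], v[keep], duration_ms)


TrialKey = tuple[str, int]


def read_event_log(
    path: str | Path,
    dialect: str = "long-csv",
    durations: Mapping[TrialKey, float] | None = None,
) -> list[tuple[TrialKey, dict[str, KeyTrajectory]]]:
    """Read a change-event log into per-trial, per-key trajectories.

    Parameters
    ----------
    path : path to a UTF-8 CSV with header
        ``participant_id,trial_index,key_id,time_ms,value``.
    dialect : name of the log dialect; only ``"long-csv"`` is defined.
    durations : optional mapping (participant_id, trial_index) -> trial
        duration in ms (e.g. the response deadline); defaults to the last
        event time of each trial.

    Returns trials in file order as ``((participant_id, trial_index),
    {key_id: KeyTrajectory})``.  Malformed rows raise :class:`EventLogError`
    naming the offending line number.
    """
    if dialect != "long-csv":
        raise EventLogError(f"unknown event-log dialect {dialect!r}")
    path = Path(path)
    trials: dict[TrialKey, dict[str, list[tuple[float, float, int]]]] = {}
    order: list[TrialKey] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise EventLogError(f"{path}: empty file (header row is mandatory)")
        if [h.strip() for h in header] != EVENT_LOG_COLUMNS:
            raise EventLogError(
                f"{path}: line 1: expected header {EVENT_LOG_COLUMNS}, got {header}"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) != len(EVENT_LOG_COLUMNS):
                raise EventLogError(
                    f"{path}: line {lineno}: expected {len(EVENT_LOG_COLUMNS)} fields, "
                    f"got {len(row)}"
                )
            pid, trial_s, key_id, time_s, value_s = (c.strip() for c in row)
            try:
                trial_index = int(trial_s)
                time_ms = float(time_s)
                value = float(value_s)
            except ValueError:
                raise EventLogError(f"{path}: line {lineno}: malformed numeric field")
            if not 0.0 <= value <= 1.0:
                raise EventLogError(
                    f"{path}: line {lineno}: analog value {value} outside [0, 1]"
                )
            if time_ms < 0:
                raise EventLogError(f"{path}: line {lineno}: negative time {time_ms}")
            tkey = (pid, trial_index)
            if tkey not in trials:
                trials[tkey] = {}
                order.append(tkey)
            trials[tkey].setdefault(key_id, []).append((time_ms, value, lineno))

    out: list[tuple[TrialKey, dict[str, KeyTrajectory]]] = []
    for tkey in order:
        per_key: dict[str, KeyTrajectory] = {}
        for key_id, rows in trials[tkey].items():
            times = [r[0] for r in rows]
            for (t0, _, _), (t1, _, ln) in zip(rows, rows[1:]):
                if t1 <= t0:
                    raise EventLogError(
                        f"{path}: line {ln}: non-monotone timestamp for key "
                        f"{key_id!r} in trial {tkey}"
                    )
            dur = durations.get(tkey) if durations else None
            try:
                per_key[key_id] = KeyTrajectory(
                    key_id, times, [r[1] for r in rows], dur
                )
            except EventLogError as exc:
                raise EventLogError(f"{path}: trial {tkey}: {exc}") from exc
        out.append((tkey, per_key))
    return out


def write_event_log(
    path: str | Path,
    trials: Iterable[tuple[TrialKey, Mapping[str, KeyTrajectory]]],
) -> None:
    """Write trials to the long-CSV change-event format (inverse of read)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(EVENT_LOG_COLUMNS)
        for (pid, trial_index), per_key in trials:
            for key_id in sorted(per_key):
                traj = per_key[key_id]
                for t, v in zip(traj.times, traj.values):
                    writer.writerow([pid, trial_index, key_id, _fmt(t), _fmt(v)])


def _fmt(x: float) -> str:
    # integers print without a trailing .0 so logs round-trip byte-identically
    return str(int(x)) if float(x).is_integer() else repr(float(x))


def read_trial_metadata(path: str | Path) -> pd.DataFrame:
    """Read the trial-metadata CSV, validating the required columns."""
    df = pd.read_csv(path, dtype={"participant_id": str, "correct_key": str})
    missing = [c for c in TRIAL_METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise EventLogError(f"{path}: missing trial-metadata columns {missing}")
    return df


def write_trial_metadata(path: str | Path, df: pd.DataFrame) -> None:
    missing = [c for c in TRIAL_METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise EventLogError(f"cannot write metadata, missing columns {missing}")
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
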