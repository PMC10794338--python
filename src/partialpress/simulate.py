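"""Generative model of analog key trajectories for a planned task design.

Each simulated trial draws a response latency from an ex-Gaussian distribution
(Gaussian mu/sigma convolved with an exponential of mean beta — the standard
positively skewed RT model) and builds a piecewise-linear press of the
responded key whose > .95 threshold crossing lands exactly on that latency
(rounded to the 1 ms sampling grid), so extracted RTs are directly comparable
to the injected ones.  With a per-item-type probability ``p_partial`` the
*incorrect* key additionally shows an aborted press — a small ramp up to an
amplitude strictly below the .95 response threshold and back to rest, fully
contained before the threshold crossing — which is exactly the partial-error
signature the detection pipeline looks for.  Error trials swap the roles of
the two keys; latencies beyond the deadline (or lapses) yield no response;
``starts_pressed_rate`` injects carry-over depression in the first
milliseconds of a trial.

Trajectories are sparsified to change events on the 1 ms grid, matching the
change-only recording of the acquisition hardware, and can be written to the
event-log CSVs together with a ground-truth table for recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .keystream import (
    KeyTrajectory,
    sparsify,
    write_event_log,
    write_trial_metadata,
)
from .taskgen import PlannedTrial, TaskDesign, design_to_metadata
from .trialproc import TrialRecord

__all__ = [
    "ExGaussLatency",
    "ItemTypeParams",
    "SimulationConfig",
    "simulate_trial",
    "simulate_experiment",
    "write_experiment",
    "default_cit_config",
    "default_sternberg_config",
    "GROUND_TRUTH_COLUMNS",
]

GROUND_TRUTH_COLUMNS = [
    "participant_id",
    "trial_index",
    "item_type",
    "true_rt_ms",
    "true_partial",
    "true_amp",
    "true_error",
    "true_no_response",
    "true_starts_pressed",
]


@dataclass(frozen=True)
class ExGaussLatency:
    """Ex-Gaussian latency of the full-press (> .95) threshold crossing."""

    mu_ms: float
    sigma_ms: float
    beta_ms: float

    def __post_init__(self) -> None:
        if self.sigma_ms <= 0 or self.beta_ms <= 0:
            raise ValueError("sigma_ms and beta_ms must be positive")

    def draw(self, rng: np.random.Generator, size: int | None = None):
        return (
            self.mu_ms
            + self.sigma_ms * rng.standard_normal(size)
            + rng.exponential(self.beta_ms, size)
        )

    @property
    def mean_ms(self) -> float:
        return self.mu_ms + self.beta_ms


@dataclass(frozen=True)
class ItemTypeParams:
    """Per-item-type generative parameters."""

    latency: ExGaussLatency
    p_partial: float = 0.0
    error_rate: float = 0.0

    def __post_init__(self) -> None:
        for name in ("p_partial", "error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")


@dataclass(frozen=True)
class SimulationConfig:
    """Generative parameters for one simulated session.

    ``partial_amp_range`` is capped strictly below the .95 response threshold
    so an injected aborted press can never register as a response.  The
    partial press onset is drawn relative to the responded key's movement
    onset (``partial_onset_offset_ms``) and clipped so the aborted press ends
    strictly before the threshold crossing and never enters the first
    ``onset_guard_ms`` of the trial.
    """

    item_params: Mapping[str, ItemTypeParams]
    partial_amp_range: tuple[float, float] = (0.05, 0.6)
    partial_duration_range_ms: tuple[float, float] = (40.0, 120.0)
    partial_onset_offset_ms: tuple[float, float] = (-30.0, 30.0)
    ramp_ms: float = 80.0
    release_ms: float = 60.0
    hold_ms: float = 80.0
    no_response_rate: float = 0.0
    starts_pressed_rate: float = 0.0
    onset_guard_ms: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.partial_amp_range
        if not (0.0 < lo <= hi < 0.95):
            raise ValueError(
                "partial_amp_range must lie strictly inside (0, 0.95) so partial "
                "presses never cross the response threshold"
            )
        for name in ("no_response_rate", "starts_pressed_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.ramp_ms <= 0 or self.release_ms <= 0:
            raise ValueError("ramp_ms and release_ms must be positive")

    def params_for(self, item_type: str) -> ItemTypeParams:
        try:
            return self.item_params[item_type]
        except KeyError:
            raise KeyError(f"no simulation parameters for item type {item_type!r}")


def default_cit_config(seed: int = 0) -> SimulationConfig:
    """Defaults emulating the concealed-information task's empirical pattern.

    Mean RTs near 470 ms (irrelevant) and 583 ms (probe), partial-press rates
    of about 0.5% (irrelevant) and 3% (probe), and low error rates keeping
    total probe/irrelevant exclusions near 2%.  Target parameters (higher
    partial rate and error rate; intermediate latency) reflect the YES-key
    minority response; targets are excluded from the primary contrasts anyway.
    """
    return SimulationConfig(
        item_params={
            "irrelevant": ItemTypeParams(ExGaussLatency(370, 40, 100), 0.005, 0.01),
            "probe": ItemTypeParams(ExGaussLatency(430, 50, 150), 0.029, 0.04),
            "target": ItemTypeParams(ExGaussLatency(420, 50, 130), 0.05, 0.08),
        },
        seed=seed,
    )


def default_sternberg_config(seed: int = 0) -> SimulationConfig:
    """Defaults emulating the modified Sternberg task's empirical pattern.

    Mean RTs near 940 (new), 1090 (match) and 1215 ms (intrusion); partial
    rates near 1.7% on the conflict (intrusion) and match trials and 0.2% on
    new trials; error rates dominating the ~16% exclusion fraction.
    """
    return SimulationConfig(
        item_params={
            "new": ItemTypeParams(ExGaussLatency(700, 90, 240), 0.002, 0.06),
            "match": ItemTypeParams(ExGaussLatency(800, 100, 290), 0.017, 0.16),
            "intrusion": ItemTypeParams(ExGaussLatency(900, 110, 320), 0.017, 0.155),
        },
        seed=seed,
    )


def _press_samples(
    crossing_ms: int, ramp_ms: float, hold_ms: float, release_ms: float,
    duration_ms: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Dense 1 ms samples of a full press whose first > .95 sample is crossing_ms.

    The linear 0 -> 1 rise of length ``ramp_ms`` is placed so the first grid
    sample exceeding .95 is exactly ``crossing_ms``; a plateau at 1.0 and a
    linear release back to 0 follow (clipped to the trial duration).
    """
    # start so that sample at crossing_ms is the first strictly above .95:
    # value(crossing-1) = floor(.95*ramp)/ramp <= .95 < (floor(.95*ramp)+1)/ramp
    ramp = max(2.0, ramp_ms)
    start = crossing_ms - int(np.floor(0.95 * ramp)) - 1
    t_end_ramp = start + ramp
    end = min(duration_ms, t_end_ramp + hold_ms + release_ms)
    t = np.arange(max(start, 0), np.floor(end) + 1)
    v = np.empty_like(t, dtype=float)
    rise = t <= t_end_ramp
    v[rise] = np.clip((t[rise] - start) / ramp, 0.0, 1.0)
    plateau = (t > t_end_ramp) & (t <= t_end_ramp + hold_ms)
    v[plateau] = 1.0
    fall = t > t_end_ramp + hold_ms
    v[fall] = np.clip(1.0 - (t[fall] - t_end_ramp - hold_ms) / release_ms, 0.0, 1.0)
    return t, np.round(v, 6)


def _partial_samples(
    onset_ms: int, duration_ms: float, amp: float
) -> tuple[np.ndarray, np.ndarray]:
    """Dense samples of an aborted press: rise to ``amp`` and back to 0."""
    dur = max(4, int(round(duration_ms)))
    t = np.arange(onset_ms, onset_ms + dur + 1)
    half = dur / 2.0
    frac = 1.0 - np.abs((t - onset_ms) - half) / half
    return t, np.round(np.clip(frac, 0.0, 1.0) * amp, 6)


def simulate_trial(
    planned: PlannedTrial,
    cfg: SimulationConfig,
    rng: np.random.Generator,
    participant_id: str = "sim",
    condition: str = "low",
    task: str = "CIT",
    keys: tuple[str, str] = ("e", "i"),
) -> tuple[TrialRecord, dict]:
    """Simulate one trial; returns the TrialRecord and its ground truth row."""
    params = cfg.params_for(planned.item_type)
    deadline = planned.deadline_ms
    other_key = keys[0] if planned.correct_key == keys[1] else keys[1]

    samples: dict[str, list[tuple[np.ndarray, np.ndarray]]] = {k: [] for k in keys}
    truth = {
        "participant_id": participant_id,
        "trial_index": planned.trial_index,
        "item_type": planned.item_type,
        "true_rt_ms": np.nan,
        "true_partial": False,
        "true_amp": np.nan,
        "true_error": False,
        "true_no_response": False,
        "true_starts_pressed": False,
    }

    starts_pressed = rng.random() < cfg.starts_pressed_rate
    if starts_pressed:
        # carry-over depression: positive at t = 0, released within ~30 ms
        residual = float(rng.uniform(0.05, 0.4))
        release = int(rng.integers(10, 31))
        t = np.arange(0, release + 1)
        v = np.round(residual * (1.0 - t / release), 6)
        samples[other_key].append((t, v))
        truth["true_starts_pressed"] = True

    lapse = rng.random() < cfg.no_response_rate
    latency = float(params.latency.draw(rng))
    latency_ms = int(round(latency))
    # keep the press ramp clear of the starts-pressed window
    min_latency = int(cfg.onset_guard_ms) + int(np.floor(0.95 * cfg.ramp_ms)) + 3
    latency_ms = max(latency_ms, min_latency)

    if lapse or latency_ms > deadline:
        truth["true_no_response"] = True
    else:
        is_error = rng.random() < params.error_rate
        responded = other_key if is_error else planned.correct_key
        unresponded = planned.correct_key if is_error else other_key
        truth["true_error"] = is_error
        truth["true_rt_ms"] = float(latency_ms)
        samples[responded].append(
            _press_samples(latency_ms, cfg.ramp_ms, cfg.hold_ms, cfg.release_ms,
                           deadline)
        )
        if rng.random() < params.p_partial:
            amp = float(rng.uniform(*cfg.partial_amp_range))
            dur = float(rng.uniform(*cfg.partial_duration_range_ms))
            press_onset = latency_ms - np.floor(0.95 * cfg.ramp_ms) - 1
            onset = press_onset + float(rng.uniform(*cfg.partial_onset_offset_ms))
            # contain the aborted press in (guard, crossing): end strictly before
            hi = latency_ms - dur - 1
            lo = cfg.onset_guard_ms + 1
            if hi < lo:  # fast trial: shrink the aborted press to fit
                dur = max(4.0, latency_ms - lo - 2)
                hi = latency_ms - dur - 1
            if hi >= lo:
                onset = int(round(min(max(onset, lo), hi)))
                t, v = _partial_samples(onset, dur, amp)
                samples[unresponded].append((t, v))
                truth["true_partial"] = True
                truth["true_amp"] = amp

    trajectories: dict[str, KeyTrajectory] = {}
    for key in keys:
        if samples[key]:
            t = np.concatenate([s[0] for s in samples[key]])
            v = np.concatenate([s[1] for s in samples[key]])
            order = np.argsort(t, kind="stable")
            t, v = t[order], v[order]
            t, idx = np.unique(t, return_index=True)
            v = v[idx]
            mask = (t >= 0) & (t <= deadline)
            trajectories[key] = sparsify(t[mask], v[mask], key, deadline)
        else:
            trajectories[key] = KeyTrajectory(key, [], [], deadline)

    record = TrialRecord(
        participant_id=participant_id,
        trial_index=planned.trial_index,
        task=task,
        condition=condition,
        item=planned.item,
        item_type=planned.item_type,
        correct_key=planned.correct_key,
        deadline_ms=deadline,
        trajectories=trajectories,
        block=planned.block,
        rsi_ms=planned.rsi_ms,
    )
    return record, truth


def simulate_experiment(
    design: TaskDesign,
    cfg: SimulationConfig,
    participant_id: str = "p001",
    seed: int | None = None,
    test_only: bool = True,
) -> tuple[list[TrialRecord], pd.DataFrame]:
    """Simulate every planned trial of a design for one participant.

    Reproducible: the rng derives from ``seed`` (default ``cfg.seed``).
    Returns the trial records and the ground-truth table.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    keys = tuple(sorted((design.key_yes, design.key_no)))
    trials = design.test_trials if test_only else design.all_trials
    records: list[TrialRecord] = []
    truths: list[dict] = []
    for planned in trials:
        rec, truth = simulate_trial(
            planned, cfg, rng,
            participant_id=participant_id,
            condition=design.condition,
            task=design.task,
            keys=keys,  # type: ignore[arg-type]
        )
        records.append(rec)
        truths.append(truth)
    return records, pd.DataFrame(truths, columns=GROUND_TRUTH_COLUMNS)


def write_experiment(
    out_dir: str | Path,
    design: TaskDesign,
    cfg: SimulationConfig,
    participant_id: str = "p001",
    seed: int | None = None,
    test_only: bool = True,
) -> dict[str, Path]:
    """Simulate and write event-log, trial-metadata and ground-truth CSVs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    records, truth = simulate_experiment(design, cfg, participant_id, seed, test_only)
    paths = {
        "events": out_dir / f"{participant_id}_events.csv",
        "trials": out_dir / f"{participant_id}_trials.csv",
        "truth": out_dir / f"{participant_id}_truth.csv",
    }
    write_event_log(
        paths["events"],
        (((r.participant_id, r.trial_index), r.trajectories) for r in records),
    )
    write_trial_metadata(paths["trials"], design_to_metadata(design, participant_id,
                                                            test_only=test_only))
    truth.to_csv(paths["truth"], index=False)
    return paths
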