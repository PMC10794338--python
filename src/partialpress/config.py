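"""Run configuration: thresholds, prior scales, seeds, file locations.

Defaults mirror the experimental constants: full-press threshold .95,
starts-pressed window 5 ms, RT bounds 200–1500 ms (CIT) / 200–2500 ms
(Sternberg), JZS Cauchy scales .5 (ANOVA) and .707 (t test).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .trialproc import (
    CIT_DEADLINE_MS,
    FULL_PRESS_THRESHOLD,
    RT_MIN_MS,
    STARTS_PRESSED_WINDOW_MS,
    STERNBERG_DEADLINE_MS,
)

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    task: str = "cit"  # "cit" | "sternberg"
    condition: str = "low"  # "low" | "high"
    seed: int = 1
    n_participants: int = 1
    out_dir: str = "out"

    full_press_threshold: float = FULL_PRESS_THRESHOLD
    onset_guard_ms: float = STARTS_PRESSED_WINDOW_MS
    rt_min_ms: float = RT_MIN_MS
    rt_max_ms: float | None = None  # default: task deadline

    anova_prior_scale: float = 0.5
    ttest_prior_scale: float = 0.707
    anova_samples: int = 20_000
    arcsine: bool = False

    def __post_init__(self) -> None:
        self.task = self.task.lower()
        if self.task not in ("cit", "sternberg"):
            raise ValueError(f"task must be 'cit' or 'sternberg', got {self.task!r}")
        if self.condition not in ("low", "high"):
            raise ValueError(f"condition must be 'low' or 'high', got {self.condition!r}")
        if not 0.0 < self.full_press_threshold < 1.0:
            raise ValueError("full_press_threshold must lie in (0, 1)")
        if self.rt_min_ms <= 0 or self.onset_guard_ms < 0:
            raise ValueError("RT bounds and onset guard must be positive")
        if self.rt_max_ms is None:
            self.rt_max_ms = (
                CIT_DEADLINE_MS if self.task == "cit" else STERNBERG_DEADLINE_MS
            )
        if self.rt_max_ms <= self.rt_min_ms:
            raise ValueError("rt_max_ms must exceed rt_min_ms")
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"{path}: config must be a mapping")
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)

    def resolved(self) -> dict:
        """The fully resolved configuration (logged verbatim with every run)."""
        return asdict(self)
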