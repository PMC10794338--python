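"""LexTALE vocabulary-test scoring and the arcsine variance-stabilizer."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["LexTALEResult", "lextale_score", "arcsine_transform",
           "LEXTALE_INCLUSION_CUTOFF"]

N_WORDS = 40
N_NONWORDS = 20
LEXTALE_INCLUSION_CUTOFF = 70.0


@dataclass(frozen=True)
class LexTALEResult:
    """Averaged %-correct LexTALE score with the proficiency inclusion flag."""

    words_correct: int
    nonwords_correct: int
    score: float
    included: bool


def lextale_score(words_correct: int, nonwords_correct: int) -> LexTALEResult:
    """Score the LexTALE lexical-decision test.

    The test presents 40 real words and 20 nonwords; the score averages the
    two %-correct rates: ``((2.5 * words_correct) + (5 * nonwords_correct)) / 2``,
    which weights both halves equally on a 0-100 scale.  Participants are
    included at scores strictly above 70.
    """
    for name, val, hi in (
        ("words_correct", words_correct, N_WORDS),
        ("nonwords_correct", nonwords_correct, N_NONWORDS),
    ):
        if not isinstance(val, (int, np.integer)):
            raise ValueError(f"{name} must be an integer, got {val!r}")
        if not 0 <= val <= hi:
            raise ValueError(f"{name} must lie in [0, {hi}], got {val}")
    score = ((2.5 * words_correct) + (5.0 * nonwords_correct)) / 2.0
    return LexTALEResult(
        int(words_correct), int(nonwords_correct), score,
        included=score > LEXTALE_INCLUSION_CUTOFF,
    )


def arcsine_transform(p):
    """Variance-stabilizing arcsine-square-root transform, arcsin(sqrt(p)).

    Maps proportions in [0, 1] to [0, pi/2]; used as a robustness check when
    analyzing partial-press proportions.
    """
    p_arr = np.asarray(p, dtype=float)
    if np.any((p_arr < 0) | (p_arr > 1)):
        raise ValueError("proportions must lie in [0, 1]")
    out = np.arcsin(np.sqrt(p_arr))
    return float(out) if np.ndim(p) == 0 else out
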