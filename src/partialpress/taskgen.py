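"""Trial-sequence generation for the RT-CIT and the modified Sternberg task.

The concealed-information test (CIT) design uses five information categories
(name, surname, date of birth, street, city) with six items each: one probe
(the concealed autobiographical item), one target (requires the opposite YES
response) and four irrelevants.  Three practice blocks of 30 trials precede a
test phase of 20 blocks of 30 trials — 600 test trials: 100 probes, 100
targets, 400 irrelevants — with every item shown once per block, a 1.5 s
response deadline in the test phase and a response–stimulus interval drawn
uniformly from [500, 1000] ms.

The modified Sternberg task is cued recognition: each trial presents two
three-word lists in colored frames (blue/yellow), then a probe word in one
color.  Match trials (probe in the cued list) require YES; intrusion trials
(probe in the *other* list) and new trials (probe in neither) require NO.
The 120-trial test phase is 50% match in both conditions; the low-validity
condition uses 40% intrusion / 10% new trials and the high-validity condition
15% / 35%, so responding purely on familiarity (YES iff the probe appeared in
either list) yields 60% and 85% accuracy respectively.  No word appears more
than once; cue color and within-list serial position are balanced over match
and intrusion trials.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .trialproc import (
    CIT_DEADLINE_MS,
    STERNBERG_DEADLINE_MS,
    TrialOutcome,
)

__all__ = [
    "PlannedTrial",
    "Block",
    "TaskDesign",
    "DesignError",
    "generate_cit_design",
    "generate_sternberg_design",
    "familiarity_responder_accuracy",
    "check_practice_pass",
    "default_cit_pool",
    "default_word_pool",
    "read_item_pool",
    "design_to_metadata",
    "CIT_CATEGORIES",
    "RSI_RANGE_MS",
]

CIT_CATEGORIES = ("name", "surname", "date_of_birth", "street", "city")
RSI_RANGE_MS = (500.0, 1000.0)

# practice-phase metadata: response deadlines and TOO SLOW feedback thresholds
CIT_PRACTICE_DEADLINES_MS = (10_000.0, 1500.0, 1500.0)
CIT_PRACTICE_FEEDBACK_MS = (10_000.0, 1200.0, 800.0)
STERNBERG_PRACTICE_DEADLINES_MS = (6000.0, 2500.0)
STERNBERG_PRACTICE_FEEDBACK_MS = (6000.0, 1500.0)

STERNBERG_TYPE_COUNTS = {
    # 120 trials: 50% match in both conditions; intrusion/new split by condition
    "low": {"match": 60, "intrusion": 48, "new": 12},
    "high": {"match": 60, "intrusion": 18, "new": 42},
}
CUE_COLORS = ("blue", "yellow")
LIST_LENGTH = 3
LEARN_DISPLAY_MS = 4800.0
LEARN_BLANK_MS = 800.0

# practice-repetition policy (metadata only; no interactive runtime)
MAX_PRACTICE_ATTEMPTS = 4


class DesignError(ValueError):
    """Raised when a trial design cannot be constructed from the given pool."""


@dataclass
class PlannedTrial:
    trial_index: int
    block: int
    phase: str  # "practice" | "test"
    item: str
    item_type: str
    category: str
    correct_key: str
    deadline_ms: float
    rsi_ms: float
    # Sternberg-only payload
    cue_color: str | None = None
    serial_position: int | None = None  # 1-based within the list
    cued_list: tuple[str, ...] | None = None
    other_list: tuple[str, ...] | None = None


@dataclass
class Block:
    index: int
    phase: str
    deadline_ms: float
    feedback_threshold_ms: float | None
    trials: list[PlannedTrial] = field(default_factory=list)


@dataclass
class TaskDesign:
    task: str  # "CIT" | "STERNBERG"
    condition: str  # "low" | "high"
    blocks: list[Block]
    item_pool: dict
    seed: int
    key_yes: str = "i"
    key_no: str = "e"

    @property
    def test_trials(self) -> list[PlannedTrial]:
        return [t for b in self.blocks if b.phase == "test" for t in b.trials]

    @property
    def practice_trials(self) -> list[PlannedTrial]:
        return [t for b in self.blocks if b.phase == "practice" for t in b.trials]

    @property
    def all_trials(self) -> list[PlannedTrial]:
        return [t for b in self.blocks for t in b.trials]


def default_cit_pool(n_per_category: int = 7) -> dict[str, dict]:
    """A synthetic item pool: per category one probe plus candidate items."""
    pool: dict[str, dict] = {}
    for cat in CIT_CATEGORIES:
        pool[cat] = {
            "probe": f"{cat}_probe",
            "candidates": [f"{cat}_item{i}" for i in range(1, n_per_category + 1)],
        }
    return pool


def default_word_pool(n: int = 1000) -> list[str]:
    """A synthetic noun pool large enough for a full Sternberg design."""
    return [f"word{i:04d}" for i in range(1, n + 1)]


def read_item_pool(path) -> dict[str, list[str]]:
    """Read a category-sectioned plain-text item list.

    Format: lines ``[category]`` start a section; following non-empty lines
    are items of that section.
    """
    pool: dict[str, list[str]] = {}
    current: str | None = None
    with open(path, encoding="utf-8") as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith("[") and line.endswith("]"):
                current = line[1:-1]
                pool[current] = []
            elif current is None:
                raise DesignError(f"{path}: item before any [category] header")
            else:
                pool[current].append(line)
    return pool


def generate_cit_design(
    item_pool: Mapping[str, Mapping] | None = None,
    condition: str = "low",
    seed: int = 0,
    key_yes: str = "i",
    key_no: str = "e",
) -> TaskDesign:
    """Build a full CIT design (practice + test) from a per-category pool.

    ``item_pool`` maps category -> {"probe": item, "candidates": [items]};
    per category one target and four irrelevants are drawn (seeded) from the
    candidates, so at least five candidates must remain after removing
    participant-flagged personal items.  Within-block trial order is a seeded
    permutation; every item appears exactly once per block.
    """
    if condition not in ("low", "high"):
        raise DesignError(f"condition must be 'low' or 'high', got {condition!r}")
    if item_pool is None:
        item_pool = default_cit_pool()
    rng = np.random.default_rng(seed)

    # assign roles: 1 probe, 1 target, 4 irrelevants per category
    items: list[tuple[str, str, str]] = []  # (item, item_type, category)
    for cat in CIT_CATEGORIES:
        if cat not in item_pool:
            raise DesignError(f"item pool missing category {cat!r}")
        entry = item_pool[cat]
        probe = entry["probe"]
        candidates = [c for c in entry["candidates"] if c != probe]
        if len(candidates) < 5:
            raise DesignError(
                f"category {cat!r}: need >= 5 candidate items besides the probe, "
                f"got {len(candidates)}"
            )
        picked = list(rng.choice(len(candidates), size=5, replace=False))
        target = candidates[picked[0]]
        irrelevants = [candidates[i] for i in picked[1:]]
        items.append((probe, "probe", cat))
        items.append((target, "target", cat))
        items.extend((irr, "irrelevant", cat) for irr in irrelevants)
    assert len(items) == 30

    blocks: list[Block] = []
    trial_index = 0
    phase_plan = [("practice", i) for i in range(3)] + [("test", i) for i in range(20)]
    for block_no, (phase, i) in enumerate(phase_plan):
        if phase == "practice":
            deadline = CIT_PRACTICE_DEADLINES_MS[i]
            feedback = CIT_PRACTICE_FEEDBACK_MS[i]
        else:
            deadline = CIT_DEADLINE_MS
            feedback = None
        block = Block(index=block_no, phase=phase, deadline_ms=deadline,
                      feedback_threshold_ms=feedback)
        order = rng.permutation(len(items))
        for pos in order:
            item, item_type, cat = items[pos]
            block.trials.append(
                PlannedTrial(
                    trial_index=trial_index,
                    block=block_no,
                    phase=phase,
                    item=item,
                    item_type=item_type,
                    category=cat,
                    correct_key=key_yes if item_type == "target" else key_no,
                    deadline_ms=deadline,
                    rsi_ms=float(rng.uniform(*RSI_RANGE_MS)),
                )
            )
            trial_index += 1
        blocks.append(block)
    return TaskDesign("CIT", condition, blocks, dict(item_pool), seed, key_yes, key_no)


def _balanced_assignment(n: int, levels: Sequence, rng: np.random.Generator) -> list:
    """n assignments over levels, maximally even; remainders seeded at random."""
    k = len(levels)
    base = n // k
    out = [lvl for lvl in levels for _ in range(base)]
    rest = n - base * k
    if rest:
        extra = rng.choice(k, size=rest, replace=False)
        out.extend(levels[i] for i in extra)
    rng.shuffle(out)
    return out


def generate_sternberg_design(
    word_pool: Sequence[str] | None = None,
    condition: str = "low",
    seed: int = 0,
    key_yes: str = "i",
    key_no: str = "e",
    n_practice: int = 10,
) -> TaskDesign:
    """Build a modified Sternberg design: practice + 120 test trials.

    Trial-type counts are exact per condition (low: 60/48/12 match/intrusion/
    new; high: 60/18/42) in a seeded random order.  Each trial draws six fresh
    words for its two lists (plus one for new-trial probes); no word is used
    twice anywhere in the design.  Cue color and the probe's serial position
    are balanced (maximally even, seeded remainders) over match and over
    intrusion trials separately; new trials balance cue color.
    """
    if condition not in STERNBERG_TYPE_COUNTS:
        raise DesignError(f"condition must be 'low' or 'high', got {condition!r}")
    counts = STERNBERG_TYPE_COUNTS[condition]
    n_test = sum(counts.values())
    rng = np.random.default_rng(seed)
    if word_pool is None:
        word_pool = default_word_pool()
    words_needed = (n_test + 2 * n_practice) * (2 * LIST_LENGTH) + counts["new"] + 2 * n_practice
    if len(set(word_pool)) < words_needed:
        raise DesignError(
            f"word pool too small: need {words_needed} distinct words, "
            f"got {len(set(word_pool))}"
        )
    shuffled = list(word_pool)
    rng.shuffle(shuffled)
    word_iter = iter(shuffled)

    # exact-count trial-type sequence, seeded order
    types = [t for t, c in counts.items() for _ in range(c)]
    rng.shuffle(types)

    # balanced (cue color, serial position) assignments per trial type
    combos = [(c, p) for c in CUE_COLORS for p in range(1, LIST_LENGTH + 1)]
    assign = {
        "match": _balanced_assignment(counts["match"], combos, rng),
        "intrusion": _balanced_assignment(counts["intrusion"], combos, rng),
        "new": [(c, None) for c in _balanced_assignment(counts["new"], list(CUE_COLORS), rng)],
    }
    cursors = {t: 0 for t in assign}

    def build_trial(trial_index: int, block_no: int, phase: str, trial_type: str,
                    deadline: float) -> PlannedTrial:
        cue_color, pos = assign[trial_type][cursors[trial_type]] if phase == "test" else (
            CUE_COLORS[int(rng.integers(2))],
            None if trial_type == "new" else int(rng.integers(1, LIST_LENGTH + 1)),
        )
        if phase == "test":
            cursors[trial_type] += 1
        cued = tuple(next(word_iter) for _ in range(LIST_LENGTH))
        other = tuple(next(word_iter) for _ in range(LIST_LENGTH))
        if trial_type == "match":
            item = cued[pos - 1]
        elif trial_type == "intrusion":
            item = other[pos - 1]
        else:
            item = next(word_iter)
        return PlannedTrial(
            trial_index=trial_index,
            block=block_no,
            phase=phase,
            item=item,
            item_type=trial_type,
            category="word",
            correct_key=key_yes if trial_type == "match" else key_no,
            deadline_ms=deadline,
            rsi_ms=float(rng.uniform(*RSI_RANGE_MS)),
            cue_color=cue_color,
            serial_position=pos,
            cued_list=cued,
            other_list=other,
        )

    blocks: list[Block] = []
    trial_index = 0
    # two practice blocks of n_practice trials, types drawn seeded from the
    # condition's proportions
    type_probs = np.array([counts[t] for t in ("match", "intrusion", "new")]) / n_test
    for i in range(2):
        block = Block(index=i, phase="practice",
                      deadline_ms=STERNBERG_PRACTICE_DEADLINES_MS[i],
                      feedback_threshold_ms=STERNBERG_PRACTICE_FEEDBACK_MS[i])
        for _ in range(n_practice):
            tt = ("match", "intrusion", "new")[int(rng.choice(3, p=type_probs))]
            block.trials.append(
                build_trial(trial_index, i, "practice", tt,
                            STERNBERG_PRACTICE_DEADLINES_MS[i])
            )
            trial_index += 1
        blocks.append(block)
    test_block = Block(index=2, phase="test", deadline_ms=STERNBERG_DEADLINE_MS,
                       feedback_threshold_ms=None)
    for tt in types:
        test_block.trials.append(
            build_trial(trial_index, 2, "test", tt, STERNBERG_DEADLINE_MS)
        )
        trial_index += 1
    blocks.append(test_block)
    design = TaskDesign("STERNBERG", condition, blocks, {"words": list(word_pool)},
                        seed, key_yes, key_no)
    _check_no_word_repeats(design)
    return design


def _check_no_word_repeats(design: TaskDesign) -> None:
    seen: set[str] = set()
    for t in design.all_trials:
        used = set(t.cued_list or ()) | set(t.other_list or ()) | {t.item}
        if seen & used:
            raise DesignError(f"word reused across trials: {sorted(seen & used)}")
        seen |= used


def familiarity_responder_accuracy(design: TaskDesign) -> float:
    """Accuracy of a pure familiarity policy on the test phase.

    The policy answers YES iff the probe word occurred in either memory list:
    correct on match and new trials, wrong on every intrusion trial.
    """
    if design.task != "STERNBERG":
        raise DesignError("familiarity responder is defined for Sternberg designs")
    trials = design.test_trials
    if not trials:
        raise DesignError("design has no test trials")
    correct = sum(1 for t in trials if t.item_type in ("match", "new"))
    return correct / len(trials)


def check_practice_pass(
    outcomes: Sequence[tuple[str, TrialOutcome]],
    task: str = "CIT",
    accuracy_threshold: float = 0.50,
    mean_rt_threshold_ms: float = 800.0,
) -> tuple[bool, str]:
    """Decide whether a final practice block passes.

    ``outcomes`` pairs each trial's item_type with its outcome.  Fails iff any
    item type's accuracy is below 50% or the overall mean RT of responded
    trials exceeds 800 ms (strictly).  Returns (passed, reason).
    """
    if not outcomes:
        return False, "no practice trials"
    by_type: dict[str, list[TrialOutcome]] = {}
    for item_type, o in outcomes:
        by_type.setdefault(item_type, []).append(o)
    for item_type, outs in sorted(by_type.items()):
        acc = float(np.mean([o.rt_ms is not None and not o.is_error for o in outs]))
        if acc < accuracy_threshold:
            return False, f"accuracy {acc:.2f} < {accuracy_threshold:.2f} for {item_type}"
    rts = [o.rt_ms for _, o in outcomes if o.rt_ms is not None]
    if rts:
        mean_rt = float(np.mean(rts))
        if mean_rt > mean_rt_threshold_ms:
            return False, f"mean RT {mean_rt:.0f} ms > {mean_rt_threshold_ms:.0f} ms"
    return True, "pass"


def design_to_metadata(design: TaskDesign, participant_id: str,
                       test_only: bool = True) -> pd.DataFrame:
    """Serialize a design to the trial-metadata table of the event-log I/O."""
    trials = design.test_trials if test_only else design.all_trials
    return pd.DataFrame(
        {
            "participant_id": participant_id,
            "trial_index": [t.trial_index for t in trials],
            "task": design.task,
            "condition": design.condition,
            "block": [t.block for t in trials],
            "item": [t.item for t in trials],
            "item_type": [t.item_type for t in trials],
            "correct_key": [t.correct_key for t in trials],
            "deadline_ms": [t.deadline_ms for t in trials],
            "rsi_ms": [t.rsi_ms for t in trials],
        }
    )
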