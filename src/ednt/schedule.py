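"""Trial schedules for the emotional day-night task (EDNT).

The EDNT is a hybrid Go/NoGo + Stroop-like paradigm.  Six stimuli are
formed by crossing two categories (``day`` = sun, ``night`` = moon) with
three face types (``happy``, ``angry``, ``neutral``).  Every block
presents each stimulus six times (36 trials: 18 day, 18 night).  At the
start of each block one NoGo rule is announced: in the child variant a
whole face type (so 12 of the 36 trials are NoGo), in the adult variant
a single stimulus (6 NoGo trials).  Congruent blocks map sun -> "day"
key and moon -> "night" key; incongruent blocks reverse the mapping.
The NoGo rule is drawn at random per block; by default consecutive
blocks never share a rule (see :func:`build_schedule`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CATEGORIES: tuple[str, ...] = ("day", "night")
FACES: tuple[str, ...] = ("happy", "angry", "neutral")

N_TRIALS_PER_BLOCK = 36
N_PER_CELL = 6  # presentations of each (category, face) stimulus per block


@dataclass(frozen=True)
class StimulusSpec:
    """One of the six EDNT stimuli: a category crossed with a face type."""

    category: str
    face: str

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if self.face not in FACES:
            raise ValueError(f"unknown face {self.face!r}")


STIMULI: tuple[StimulusSpec, ...] = tuple(
    StimulusSpec(c, f) for c in CATEGORIES for f in FACES
)


@dataclass(frozen=True)
class TaskVariant:
    """Structural parameters of one task version.

    ``congruency_layout[b]`` is True when block ``b+1`` uses the canonical
    sun->day / moon->night response mapping.  The child deadline is not a
    published task constant; it must exceed the longest plausible child
    response (observed child means reach ~2.7 s), and 4000 ms is used.
    """

    name: str
    n_blocks: int
    congruency_layout: tuple[bool, ...]
    response_deadline_ms: float
    nogo_rule_kind: str  # "face" (child) or "stimulus" (adult)

    def __post_init__(self) -> None:
        if self.n_blocks != len(self.congruency_layout):
            raise ValueError("n_blocks does not match congruency_layout length")


CHILD = TaskVariant(
    name="child",
    n_blocks=4,
    congruency_layout=(True, True, True, False),
    response_deadline_ms=4000.0,
    nogo_rule_kind="face",
)

ADULT = TaskVariant(
    name="adult",
    n_blocks=12,
    congruency_layout=(True,) * 6 + (False,) * 6,
    response_deadline_ms=2000.0,
    nogo_rule_kind="stimulus",
)

_VARIANTS = {"child": CHILD, "adult": ADULT}


def get_variant(name: str) -> TaskVariant:
    try:
        return _VARIANTS[name]
    except KeyError:
        raise ValueError(
            f"unknown task variant {name!r}; expected one of {sorted(_VARIANTS)}"
        ) from None


@dataclass
class BlockSchedule:
    """One block: its rule assignment and ordered trial list."""

    block_index: int  # 1-based
    congruent: bool
    nogo_rule: object  # face str (child) or StimulusSpec (adult)
    trials: list[StimulusSpec] = field(default_factory=list)
    is_nogo: list[bool] = field(default_factory=list)

    def n_go(self) -> int:
        return sum(not x for x in self.is_nogo)


def _rule_matches(rule: object, stim: StimulusSpec) -> bool:
    if isinstance(rule, StimulusSpec):
        return stim == rule
    return stim.face == rule


def build_schedule(
    variant: TaskVariant | str,
    seed: int,
    forbid_repeat_nogo: bool = True,
) -> list[BlockSchedule]:
    """Construct a full EDNT schedule.

    The NoGo rule of each block is drawn uniformly from the three face
    types (child) or six stimuli (adult); with ``forbid_repeat_nogo``
    the draw excludes the previous block's rule.  Trial order within a
    block is a seeded uniform shuffle of the 36-stimulus multiset
    (6 presentations of each stimulus).  Deterministic given ``seed``.
    """
    if isinstance(variant, str):
        variant = get_variant(variant)
    rng = np.random.default_rng(seed)
    pool: tuple = FACES if variant.nogo_rule_kind == "face" else STIMULI

    blocks: list[BlockSchedule] = []
    prev_rule: object = None
    base = [s for s in STIMULI for _ in range(N_PER_CELL)]
    for b in range(variant.n_blocks):
        options = [r for r in pool if not (forbid_repeat_nogo and r == prev_rule)]
        rule = options[rng.integers(len(options))]
        order = rng.permutation(N_TRIALS_PER_BLOCK)
        trials = [base[i] for i in order]
        blocks.append(
            BlockSchedule(
                block_index=b + 1,
                congruent=variant.congruency_layout[b],
                nogo_rule=rule,
                trials=trials,
                is_nogo=[_rule_matches(rule, s) for s in trials],
            )
        )
        prev_rule = rule
    return blocks


def schedule_to_frame(blocks: list[BlockSchedule], subject_id: str | None = None) -> pd.DataFrame:
    """Flatten a schedule into the tabular export format.

    Columns: (subject_id,) block, trial, category, face, is_nogo,
    congruent_block.  ``trial`` is 1-based within block.
    """
    rows = []
    for blk in blocks:
        for i, (stim, nogo) in enumerate(zip(blk.trials, blk.is_nogo), start=1):
            rows.append(
                {
                    "block": blk.block_index,
                    "trial": i,
                    "category": stim.category,
                    "face": stim.face,
                    "is_nogo": nogo,
                    "congruent_block": blk.congruent,
                }
            )
    frame = pd.DataFrame(rows)
    if subject_id is not None:
        frame.insert(0, "subject_id", subject_id)
    return frame


def go_trial_count(blocks: list[BlockSchedule], from_block: int = 2) -> int:
    """Number of Go trials in blocks ``from_block`` onward.

    Blocks from the second onward are the ones entering effect scoring
    (72 for the child variant, 330 for the adult variant).
    """
    return sum(b.n_go() for b in blocks if b.block_index >= from_block)


def expected_pi_proportion(variant: TaskVariant | str, forbid_repeat_nogo: bool = True) -> float:
    """PI share of Go trials for an error-free subject, in expectation.

    A Go trial is PI (previously inhibited) when its stimulus was covered
    by the preceding block's NoGo rule.  If consecutive rules must differ,
    every post-first block has a fixed PI count: child 12 of 24 Go trials
    (0.5), adult 6 of 30 (0.2).  If rules may repeat, a repeat makes the
    PI set coincide with the current NoGo set (zero PI Go trials), so the
    expectation scales by the no-repeat probability: child 2/3 * 0.5 = 1/3,
    adult 5/6 * 0.2 = 1/6.
    """
    if isinstance(variant, str):
        variant = get_variant(variant)
    if variant.nogo_rule_kind == "face":
        fixed, p_differ = 12 / 24, 2 / 3
    else:
        fixed, p_differ = 6 / 30, 5 / 6
    return fixed if forbid_repeat_nogo else fixed * p_differ
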