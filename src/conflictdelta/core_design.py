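"""Factorial structure, trial schedules and the trial record of SAT conflict experiments.

Three conflict tasks (a letter flanker task, a numeric Stroop task and a dot
Simon task) share the same factorial skeleton: three congruency conditions
(congruent / neutral / incongruent) crossed with three response-focus
conditions (speed / balanced / accuracy) that manipulate the speed-accuracy
tradeoff via adaptive response deadlines.  This module defines those factors,
the per-experiment block/trial schedules, and the universal trial record
exchanged between the simulators and the analysis code.

All reaction times are in milliseconds.  Block and trial indices are 0-based.
Response omissions are stored as an absent RT, never as a sentinel number.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Congruency",
    "ResponseFocus",
    "TARGET_ACCURACY",
    "ExperimentDesign",
    "TrialRecord",
    "ScheduleSlot",
    "make_design",
    "generate_schedule",
    "records_to_frame",
]


class Congruency(str, Enum):
    """Congruency condition of a conflict-task trial.

    The canonical reporting order is congruent < neutral < incongruent.
    """

    CONGRUENT = "congruent"
    NEUTRAL = "neutral"
    INCONGRUENT = "incongruent"


class ResponseFocus(str, Enum):
    """Response-focus (speed-accuracy tradeoff) instruction condition."""

    SPEED = "speed"
    BALANCED = "balanced"
    ACCURACY = "accuracy"


#: Desired accuracy enforced by the adaptive deadline, per response focus.
TARGET_ACCURACY: dict[ResponseFocus, float] = {
    ResponseFocus.SPEED: 0.65,
    ResponseFocus.BALANCED: 0.82,
    ResponseFocus.ACCURACY: 0.975,
}

_TASKS = ("flanker", "stroop", "simon")


@dataclass(frozen=True)
class ExperimentDesign:
    """Block/trial schedule and SAT configuration of one experiment.

    Parameters
    ----------
    task
        One of ``flanker``, ``stroop``, ``simon``.
    practice_trials
        Number of practice trials used to calibrate the response deadlines.
    trials_per_block
        Test trials per block; every block holds a single response focus.
    repetitions_per_focus
        How many blocks each response focus is run for.
    congruency_split
        Proportion of congruent/neutral/incongruent trials within a block.
        Defaults to equal thirds, the only split consistent with the block
        sizes of all three experiments.
    response_window
        Maximum time allotted for a response, ms.
    """

    task: str
    practice_trials: int
    trials_per_block: int
    repetitions_per_focus: int
    congruency_split: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    response_window: float = 2500.0

    def __post_init__(self) -> None:
        if self.task not in _TASKS:
            raise ValueError(f"unknown task {self.task!r}; valid tasks: {', '.join(_TASKS)}")
        if self.practice_trials <= 0:
            raise ValueError("practice_trials must be positive")
        if self.trials_per_block <= 0 or self.repetitions_per_focus <= 0:
            raise ValueError("trials_per_block and repetitions_per_focus must be positive")
        if len(self.congruency_split) != len(Congruency):
            raise ValueError("congruency_split needs one proportion per congruency level")
        if not np.isclose(sum(self.congruency_split), 1.0):
            raise ValueError("congruency_split must sum to 1")
        counts = [p * self.trials_per_block for p in self.congruency_split]
        if any(abs(c - round(c)) > 1e-9 for c in counts):
            raise ValueError(
                "trials_per_block must divide exactly under congruency_split "
                f"(got fractional counts {counts})"
            )

    @property
    def n_blocks(self) -> int:
        return len(ResponseFocus) * self.repetitions_per_focus

    @property
    def total_test_trials(self) -> int:
        return self.trials_per_block * self.repetitions_per_focus * len(ResponseFocus)

    def congruency_counts(self) -> dict[Congruency, int]:
        """Exact per-block trial count for each congruency level."""
        return {
            c: int(round(p * self.trials_per_block))
            for c, p in zip(Congruency, self.congruency_split)
        }


@dataclass
class TrialRecord:
    """One behavioral trial; the universal exchange unit of the package.

    ``rt`` is ``None`` for omissions (no response within the response
    window), in which case ``correct`` is False and ``exceeded_deadline``
    is True.  ``flagged_fast`` marks anticipatory responses below 150 ms;
    flagged trials are never excluded per se, but participants who produce
    too many of them are dropped at analysis time.
    """

    participant_id: str
    task: str
    focus: ResponseFocus
    congruency: Congruency
    block_index: int
    trial_index: int
    rt: float | None
    correct: bool
    deadline: float
    exceeded_deadline: bool
    flagged_fast: bool

    def __post_init__(self) -> None:
        self.focus = ResponseFocus(self.focus)
        self.congruency = Congruency(self.congruency)
        if self.rt is not None and self.rt <= 0:
            raise ValueError("rt must be positive when present")
        if self.rt is None:
            if self.correct:
                raise ValueError("an omission cannot be correct")
            if not self.exceeded_deadline:
                raise ValueError("an omission must exceed the deadline")
        else:
            if self.exceeded_deadline != (self.rt > self.deadline):
                raise ValueError("exceeded_deadline inconsistent with rt and deadline")
        if self.flagged_fast and (self.rt is None or self.rt >= 150.0):
            raise ValueError("flagged_fast requires rt < 150 ms")


class ScheduleSlot(NamedTuple):
    block_index: int
    focus: ResponseFocus
    congruency: Congruency


_PRESETS: dict[str, dict[str, int]] = {
    # flanker: 54 trials/block, 10 blocks per focus -> 1620 test trials
    "flanker": dict(practice_trials=60, trials_per_block=54, repetitions_per_focus=10),
    # stroop: 72 trials/block, 8 blocks per focus
    "stroop": dict(practice_trials=72, trials_per_block=72, repetitions_per_focus=8),
    # simon: 60 trials/block, 7 blocks per focus
    "simon": dict(practice_trials=60, trials_per_block=60, repetitions_per_focus=7),
}


def make_design(task: str) -> ExperimentDesign:
    """Return the preset :class:`ExperimentDesign` for one of the three tasks."""
    try:
        preset = _PRESETS[task]
    except KeyError:
        raise ValueError(
            f"unknown task {task!r}; valid tasks: {', '.join(_TASKS)}"
        ) from None
    return ExperimentDesign(task=task, **preset)


def generate_schedule(design: ExperimentDesign, seed: int) -> list[ScheduleSlot]:
    """Seeded random trial schedule for one participant.

    The block order is a uniform permutation of the multiset holding each
    response focus ``repetitions_per_focus`` times.  Within a block the
    congruency counts follow ``design.congruency_split`` exactly and only
    the order is randomized.  The multiset of (focus, congruency) slots is
    therefore seed-independent; the same seed reproduces the same schedule.
    """
    rng = np.random.default_rng(seed)
    blocks = np.repeat(np.arange(len(ResponseFocus)), design.repetitions_per_focus)
    rng.shuffle(blocks)
    foci = list(ResponseFocus)
    counts = design.congruency_counts()
    slots: list[ScheduleSlot] = []
    for block_index, focus_idx in enumerate(blocks):
        congruencies = np.repeat(
            np.arange(len(Congruency)), [counts[c] for c in Congruency]
        )
        rng.shuffle(congruencies)
        focus = foci[focus_idx]
        levels = list(Congruency)
        slots.extend(
            ScheduleSlot(block_index, focus, levels[ci]) for ci in congruencies
        )
    return slots


def records_to_frame(records: Sequence[TrialRecord]) -> pd.DataFrame:
    """Convert trial records to a tidy DataFrame (one row per trial)."""
    if not records:
        raise ValueError("no trial records given")
    return pd.DataFrame(
        {
            "participant_id": [r.participant_id for r in records],
            "task": [r.task for r in records],
            "focus": pd.Categorical(
                [r.focus.value for r in records], categories=[f.value for f in ResponseFocus]
            ),
            "congruency": pd.Categorical(
                [r.congruency.value for r in records],
                categories=[c.value for c in Congruency],
            ),
            "block_index": [r.block_index for r in records],
            "trial_index": [r.trial_index for r in records],
            "rt": [np.nan if r.rt is None else r.rt for r in records],
            "correct": [r.correct for r in records],
            "deadline": [r.deadline for r in records],
            "exceeded_deadline": [r.exceeded_deadline for r in records],
            "flagged_fast": [r.flagged_fast for r in records],
        }
    )
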