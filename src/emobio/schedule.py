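"""Trial schedules for the visual-stimulation and mental-imagery tasks.

Visual task: 2 blocks x 120 randomized trials (60 happy / 60 sad), each
trial 250 ms morph + 1000 ms static + 250 ms unmorph (1.5 s total), with an
inter-trial interval of 1 s plus uniform jitter up to 500 ms.

Imagery task: 2 blocks x 40 randomized trials (20 per expression), each
trial instruction (1.5 s) -> preparation (1.5 s) -> cued imagery (4 s) ->
cued neutral period (4 s, a design choice: the source material does not
print its length).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

__all__ = ["Trial", "TrialSchedule", "make_visual_schedule", "make_imagery_schedule"]

CONDITIONS = ("happy", "sad")

VISUAL_SEGMENTS = (("morph", 250.0), ("static", 1000.0), ("unmorph", 250.0))
IMAGERY_SEGMENTS = (
    ("instruction", 1500.0),
    ("preparation", 1500.0),
    ("imagery", 4000.0),
    ("neutral", 4000.0),
)

ITI_BASE_MS = 1000.0
ITI_JITTER_MS = 500.0
BLOCK_GAP_MS = 5000.0  # rest period between blocks; length is a stand-in


@dataclass(frozen=True)
class Trial:
    block: int
    condition: Literal["happy", "sad"]
    onset_ms: float
    segments: tuple[tuple[str, float], ...]

    @property
    def duration_ms(self) -> float:
        return sum(d for _, d in self.segments)


@dataclass(frozen=True)
class TrialSchedule:
    task: Literal["visual", "imagery"]
    trials: tuple[Trial, ...]

    def __len__(self) -> int:
        return len(self.trials)

    def count(self, condition: str) -> int:
        return sum(t.condition == condition for t in self.trials)

    @property
    def total_duration_ms(self) -> float:
        last = self.trials[-1]
        return last.onset_ms + last.duration_ms + ITI_BASE_MS

    def conditions(self) -> tuple[str, ...]:
        return tuple(t.condition for t in self.trials)


def _block_conditions(n_per_condition: int, rng: np.random.Generator) -> list[str]:
    conds = [c for c in CONDITIONS for _ in range(n_per_condition)]
    rng.shuffle(conds)
    return conds


def _build(
    task: str,
    segments: tuple[tuple[str, float], ...],
    n_blocks: int,
    n_per_condition: int,
    seed: int,
) -> TrialSchedule:
    rng = np.random.default_rng(seed)
    trial_len = sum(d for _, d in segments)
    trials: list[Trial] = []
    t = ITI_BASE_MS  # lead-in before the first trial
    for block in range(n_blocks):
        for cond in _block_conditions(n_per_condition, rng):
            trials.append(Trial(block=block, condition=cond, onset_ms=t, segments=segments))
            t += trial_len + ITI_BASE_MS + float(rng.uniform(0.0, ITI_JITTER_MS))
        t += BLOCK_GAP_MS
    return TrialSchedule(task=task, trials=tuple(trials))


def make_visual_schedule(seed: int, n_per_condition_per_block: int = 60) -> TrialSchedule:
    """Randomized visual-task schedule: 2 blocks, 60 happy + 60 sad each.

    ``n_per_condition_per_block`` exists for scaled-down simulations; the
    default reproduces the full 240-trial paradigm.
    """
    return _build("visual", VISUAL_SEGMENTS, 2, n_per_condition_per_block, seed)


def make_imagery_schedule(seed: int, n_per_condition_per_block: int = 20) -> TrialSchedule:
    """Randomized imagery-task schedule: 2 blocks, 20 happy + 20 sad each."""
    return _build("imagery", IMAGERY_SEGMENTS, 2, n_per_condition_per_block, seed)
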