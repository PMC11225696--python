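"""The 4x4 gaze-by-emotion stimulus search space.

The optimisation domain is a grid of 16 face stimuli: four emotional
expressions (very happy, smiling, neutral, angry) crossed with four
gaze/head directions (0 degrees = direct, 5, 45 and 90 degrees averted).
Cells are addressed by integer indices ``(emotion_idx, gaze_idx)`` in
{0..3} x {0..3} with unit grid spacing, and carry a human-readable label
of the form ``"Angry-0"`` (emotion name, gaze angle in degrees).

The space partitions into four quadrants used by the theory tests; the
5-degree row counts as *direct* gaze, as infants of this age do not
discriminate it from direct gaze.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterator

import numpy as np

EMOTION_NAMES = ("VeryHappy", "Smile", "Neutral", "Angry")
GAZE_DEGREES = (0, 5, 45, 90)

QUADRANT_NAMES = ("happy-direct", "hostile-direct", "happy-averted", "hostile-averted")


@dataclass(frozen=True, order=True)
class StimulusCoord:
    """A cell of the 4x4 emotion-by-gaze grid."""

    emotion_idx: int
    gaze_idx: int

    def __post_init__(self) -> None:
        if self.emotion_idx not in range(4) or self.gaze_idx not in range(4):
            raise ValueError(
                f"grid indices must lie in 0..3, got "
                f"({self.emotion_idx}, {self.gaze_idx})"
            )

    @property
    def label(self) -> str:
        return f"{EMOTION_NAMES[self.emotion_idx]}-{GAZE_DEGREES[self.gaze_idx]}"

    @classmethod
    def from_label(cls, label: str) -> "StimulusCoord":
        emotion, _, degrees = label.partition("-")
        try:
            return cls(EMOTION_NAMES.index(emotion), GAZE_DEGREES.index(int(degrees)))
        except (ValueError, IndexError) as exc:
            raise ValueError(f"unrecognised stimulus label {label!r}") from exc

    def to_dict(self) -> dict:
        return {
            "emotion_idx": self.emotion_idx,
            "gaze_idx": self.gaze_idx,
            "label": self.label,
        }


def grid() -> list[StimulusCoord]:
    """All 16 grid cells in lexicographic (emotion_idx, gaze_idx) order."""
    return [StimulusCoord(e, g) for e in range(4) for g in range(4)]


def iter_grid() -> Iterator[StimulusCoord]:
    yield from grid()


#: The four corners of the search space, in the canonical burn-in order.
VERYHAPPY_0 = StimulusCoord(0, 0)
VERYHAPPY_90 = StimulusCoord(0, 3)
ANGRY_0 = StimulusCoord(3, 0)
ANGRY_90 = StimulusCoord(3, 3)

CORNERS = (ANGRY_0, ANGRY_90, VERYHAPPY_0, VERYHAPPY_90)


def quadrant_of(coord: StimulusCoord) -> str:
    """Quadrant membership of a grid cell.

    Happy = very happy or smiling (emotion_idx <= 1); direct = 0 or 5 degrees
    (gaze_idx <= 1).  Every cell maps to exactly one of the four quadrants,
    4 cells each.
    """
    happy = coord.emotion_idx <= 1
    direct = coord.gaze_idx <= 1
    if happy and direct:
        return "happy-direct"
    if not happy and direct:
        return "hostile-direct"
    if happy:
        return "happy-averted"
    return "hostile-averted"


def is_direct(coord: StimulusCoord) -> bool:
    """Direct-gaze half of the space (0 and 5 degrees; 8 cells)."""
    return coord.gaze_idx <= 1


def distance_from_reference(
    coord: StimulusCoord, reference: StimulusCoord = VERYHAPPY_0
) -> float:
    """Euclidean distance between two grid cells, unit spacing per step."""
    return math.hypot(
        coord.emotion_idx - reference.emotion_idx, coord.gaze_idx - reference.gaze_idx
    )


@dataclass(frozen=True)
class BurnInSchedule:
    """Order of the four corner stimuli shown before acquisition starts."""

    mode: str  # "fixed" | "randomised"
    sequence: tuple[StimulusCoord, ...]
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("fixed", "randomised"):
            raise ValueError(f"unknown burn-in mode {self.mode!r}")
        if sorted(self.sequence) != sorted(CORNERS):
            raise ValueError("burn-in sequence must be a permutation of the 4 corners")


def burn_in_sequence(mode: str = "fixed", seed: int | None = None) -> BurnInSchedule:
    """Build a burn-in schedule.

    ``fixed`` gives the canonical order Angry-0, Angry-90, VeryHappy-0,
    VeryHappy-90 (constant across participants); ``randomised`` gives a
    seeded uniform permutation of the four corners and requires a seed.
    """
    if mode == "fixed":
        return BurnInSchedule(mode="fixed", sequence=CORNERS)
    if mode == "randomised":
        if seed is None:
            raise ValueError("randomised burn-in requires a seed")
        rng = np.random.default_rng(seed)
        order = rng.permutation(4)
        return BurnInSchedule(
            mode="randomised", sequence=tuple(CORNERS[i] for i in order), seed=seed
        )
    raise ValueError(f"unknown burn-in mode {mode!r}")
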