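"""LUBA finite-state scoring: per-motion scores, the global score, categories.

Each joint motion maps its angle (degrees) to an integer discomfort score via
a half-open interval table ``lower < angle <= upper``; the intervals tile the
whole real line, so every finite angle matches exactly one score. The global
score G sums, over the three back motions plus one arm's shoulder and elbow
motions, every score strictly above the per-motion minimum of 1, giving a
0..62 scale split into four corrective-action categories.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .core import (
    LUBA_MOTIONS,
    AngleSeries,
    ArmSelection,
    ErgoError,
    IncompleteFrameError,
    JointMotion,
    RunConfig,
    UnsupportedMotionError,
)

# Interval tables: (upper_bounds, scores). Score i applies when
# bounds[i-1] < angle <= bounds[i]; the last score covers angle > bounds[-1].
# Lateral bending and axial rotation are scored on |angle|.
_BACK_FE = ((-30.0, -20.0, -10.0, 30.0, 60.0, 90.0), (15, 8, 4, 1, 3, 6, 12))
_BACK_LB = ((10.0, 20.0, 30.0), (1, 4, 9, 13))
_BACK_AR = ((20.0, 60.0), (1, 3, 10))
_SHOULDER_FE = ((-60.0, -45.0, -20.0, 45.0, 90.0, 150.0), (10, 6, 3, 1, 3, 6, 11))
_SHOULDER_AA = ((-30.0, -10.0, 30.0, 90.0), (8, 2, 1, 3, 7))
_ELBOW_FE = ((45.0, 120.0), (1, 3, 5))

# (upper_bounds, scores, score_on_magnitude)
_TABLES: dict[JointMotion, tuple[tuple[float, ...], tuple[int, ...], bool]] = {
    JointMotion.BACK_FLEXION_EXTENSION: (*_BACK_FE, False),
    JointMotion.BACK_LATERAL_BENDING: (*_BACK_LB, True),
    JointMotion.BACK_AXIAL_ROTATION: (*_BACK_AR, True),
    JointMotion.SHOULDER_LEFT_FLEXION_EXTENSION: (*_SHOULDER_FE, False),
    JointMotion.SHOULDER_LEFT_ABDUCTION_ADDUCTION: (*_SHOULDER_AA, False),
    JointMotion.SHOULDER_RIGHT_FLEXION_EXTENSION: (*_SHOULDER_FE, False),
    JointMotion.SHOULDER_RIGHT_ABDUCTION_ADDUCTION: (*_SHOULDER_AA, False),
    JointMotion.ELBOW_LEFT_FLEXION_EXTENSION: (*_ELBOW_FE, False),
    JointMotion.ELBOW_RIGHT_FLEXION_EXTENSION: (*_ELBOW_FE, False),
}

#: Score alphabet per motion (ascending), exposed for calibration and tests.
SCORE_SCALES: dict[JointMotion, tuple[int, ...]] = {
    m: tuple(sorted(set(_TABLES[m][1]))) for m in LUBA_MOTIONS
}

MIN_SCORE = 1
#: Maximum attainable global score: table maxima over back + one arm.
MAX_GLOBAL_SCORE = 62

_ARM_MOTIONS = {
    "left": (
        JointMotion.SHOULDER_LEFT_FLEXION_EXTENSION,
        JointMotion.SHOULDER_LEFT_ABDUCTION_ADDUCTION,
        JointMotion.ELBOW_LEFT_FLEXION_EXTENSION,
    ),
    "right": (
        JointMotion.SHOULDER_RIGHT_FLEXION_EXTENSION,
        JointMotion.SHOULDER_RIGHT_ABDUCTION_ADDUCTION,
        JointMotion.ELBOW_RIGHT_FLEXION_EXTENSION,
    ),
}
_BACK_MOTIONS = (
    JointMotion.BACK_FLEXION_EXTENSION,
    JointMotion.BACK_LATERAL_BENDING,
    JointMotion.BACK_AXIAL_ROTATION,
)


class Category(str, enum.Enum):
    """Corrective-action urgency classes for the global score."""

    I = "I"
    II = "II"
    III = "III"
    IV = "IV"


CATEGORY_COLOURS = {
    Category.I: "green",
    Category.II: "yellow",
    Category.III: "orange",
    Category.IV: "red",
}


@dataclass(frozen=True)
class LubaScore:
    motion: JointMotion
    score: int

    def __post_init__(self) -> None:
        if self.score not in SCORE_SCALES[self.motion]:
            raise ErgoError(
                f"{self.score} is not a valid score for {self.motion.value}"
            )


@dataclass(frozen=True)
class GlobalScore:
    g: int
    selected_arm: str  # 'left' | 'right'
    category: Category

    def __post_init__(self) -> None:
        if not 0 <= self.g <= MAX_GLOBAL_SCORE:
            raise ErgoError(f"global score {self.g} outside [0, {MAX_GLOBAL_SCORE}]")


def score_motion(motion: JointMotion, angle: float) -> LubaScore:
    """Look up the discomfort score for one motion at one angle."""
    if motion not in _TABLES:
        raise UnsupportedMotionError(f"{motion.value} carries no LUBA score")
    if not math.isfinite(angle):
        raise ErgoError(f"angle must be finite, got {angle!r}")
    bounds, scores, use_magnitude = _TABLES[motion]
    x = abs(angle) if use_magnitude else angle
    # first interval whose inclusive upper bound is >= x
    idx = int(np.searchsorted(bounds, x, side="left"))
    return LubaScore(motion=motion, score=scores[idx])


def score_column(motion: JointMotion, angles: np.ndarray) -> np.ndarray:
    """Vectorised :func:`score_motion` over an angle array."""
    if motion not in _TABLES:
        raise UnsupportedMotionError(f"{motion.value} carries no LUBA score")
    bounds, scores, use_magnitude = _TABLES[motion]
    x = np.abs(angles) if use_magnitude else np.asarray(angles, dtype=float)
    idx = np.searchsorted(bounds, x, side="left")
    return np.asarray(scores, dtype=np.int64)[idx]


def categorize(g: int) -> Category:
    """Map a global score to its corrective-action category."""
    if g < 0:
        raise ErgoError(f"global score must be non-negative, got {g}")
    if g <= 5:
        return Category.I
    if g <= 10:
        return Category.II
    if g <= 15:
        return Category.III
    return Category.IV


def select_arm(
    scores: Mapping[JointMotion, LubaScore], policy: ArmSelection
) -> str:
    if policy is ArmSelection.LEFT:
        return "left"
    if policy is ArmSelection.RIGHT:
        return "right"
    left = sum(scores[m].score for m in _ARM_MOTIONS["left"])
    right = sum(scores[m].score for m in _ARM_MOTIONS["right"])
    return "left" if left > right else "right"  # tie goes to the right arm


def global_score(
    scores: Mapping[JointMotion, LubaScore],
    arm_selection: ArmSelection = ArmSelection.WORST_SUM,
) -> GlobalScore:
    """Sum the above-minimum scores of the back and the selected arm."""
    missing = [m.value for m in LUBA_MOTIONS if m not in scores]
    if missing:
        raise IncompleteFrameError(
            f"global score needs all nine motions; missing: {', '.join(missing)}"
        )
    arm = select_arm(scores, arm_selection)
    contributing = _BACK_MOTIONS + _ARM_MOTIONS[arm]
    g = sum(
        scores[m].score for m in contributing if scores[m].score > MIN_SCORE
    )
    return GlobalScore(g=g, selected_arm=arm, category=categorize(g))


@dataclass
class LubaSeriesResult:
    """Per-sample LUBA outputs for a whole series."""

    motion_scores: dict[JointMotion, np.ndarray]  # int arrays
    g: np.ndarray  # int array
    selected_arm: list[str]
    categories: list[Category]

    def __len__(self) -> int:
        return len(self.g)


def score_series(series: AngleSeries, config: RunConfig) -> LubaSeriesResult:
    """Score every sample of a series: per-motion scores plus the global G."""
    series.require(LUBA_MOTIONS)
    n = len(series)
    motion_scores = {
        m: score_column(m, series.column(m)) for m in LUBA_MOTIONS
    }

    left = sum(motion_scores[m] for m in _ARM_MOTIONS["left"])
    right = sum(motion_scores[m] for m in _ARM_MOTIONS["right"])
    if config.arm_selection is ArmSelection.LEFT:
        use_left = np.ones(n, dtype=bool)
    elif config.arm_selection is ArmSelection.RIGHT:
        use_left = np.zeros(n, dtype=bool)
    else:
        use_left = left > right

    def arm_sum(side: str) -> np.ndarray:
        total = np.zeros(n, dtype=np.int64)
        for m in _ARM_MOTIONS[side]:
            s = motion_scores[m]
            total += np.where(s > MIN_SCORE, s, 0)
        return total

    back = np.zeros(n, dtype=np.int64)
    for m in _BACK_MOTIONS:
        s = motion_scores[m]
        back += np.where(s > MIN_SCORE, s, 0)
    g = back + np.where(use_left, arm_sum("left"), arm_sum("right"))

    return LubaSeriesResult(
        motion_scores=motion_scores,
        g=g,
        selected_arm=["left" if u else "right" for u in use_left],
        categories=[categorize(int(v)) for v in g],
    )
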