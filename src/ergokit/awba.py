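"""Whole-body risk levels: upper-body (AULA), lower-limb (ALLA), combined (AWBA).

AULA maps sagittal back/shoulder/elbow flexion angles to a 1-4 level through a
nested finite-state machine; ALLA maps knee flexion to 2-4 (kneeling pins the
level at 3 regardless of angle; level 1 is reserved for sitting and is
unreachable here); the combined level is a 4x4 grid lookup.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np

from .core import (
    AngleSeries,
    CoverageError,
    ErgoError,
    JointMotion,
    PostureClass,
    RunConfig,
)
from .labels import PostureLabelSeries


class RiskSource(str, enum.Enum):
    AULA = "aula"
    ALLA = "alla"
    AWBA = "awba"


LEVEL_COLOURS = {1: "green", 2: "yellow", 3: "orange", 4: "red"}


@dataclass(frozen=True)
class RiskLevel:
    level: int
    source: RiskSource

    def __post_init__(self) -> None:
        if not 1 <= self.level <= 4:
            raise ErgoError(f"risk level must be in 1..4, got {self.level}")


# Combination grid: _AWBA_GRID[alla-1][aula-1].
_AWBA_GRID = (
    (1, 2, 3, 3),
    (2, 2, 3, 4),
    (3, 3, 3, 4),
    (3, 4, 4, 4),
)

_UPPER_MOTIONS = {
    "left": (
        JointMotion.SHOULDER_LEFT_FLEXION_EXTENSION,
        JointMotion.ELBOW_LEFT_FLEXION_EXTENSION,
    ),
    "right": (
        JointMotion.SHOULDER_RIGHT_FLEXION_EXTENSION,
        JointMotion.ELBOW_RIGHT_FLEXION_EXTENSION,
    ),
}

AWBA_REQUIRED_MOTIONS = (
    JointMotion.BACK_FLEXION_EXTENSION,
    JointMotion.SHOULDER_LEFT_FLEXION_EXTENSION,
    JointMotion.SHOULDER_RIGHT_FLEXION_EXTENSION,
    JointMotion.ELBOW_LEFT_FLEXION_EXTENSION,
    JointMotion.ELBOW_RIGHT_FLEXION_EXTENSION,
    JointMotion.KNEE_LEFT_FLEXION_EXTENSION,
    JointMotion.KNEE_RIGHT_FLEXION_EXTENSION,
)


def aula_level(back_fe: float, shoulder_fe: float, elbow_fe: float) -> RiskLevel:
    """Upper-body level from back, shoulder and elbow flexion (degrees)."""
    for name, value in (("back", back_fe), ("shoulder", shoulder_fe), ("elbow", elbow_fe)):
        if not math.isfinite(value):
            raise ErgoError(f"{name} flexion angle must be finite, got {value!r}")
    a, b, g = back_fe, shoulder_fe, elbow_fe
    if a <= 22.5:
        if b <= 22.5:
            level = 1
        elif b <= 72.5:
            level = 2
        elif b <= 105.0:
            level = 3
        else:
            level = 4
    elif a <= 72.5:
        if b <= 72.5:
            level = 2 if g <= 22.5 else 3
        else:
            level = 3
    else:
        level = 2
    return RiskLevel(level=level, source=RiskSource.AULA)


def alla_level(knee_fe: float, posture: PostureClass) -> RiskLevel:
    """Lower-limb level from knee flexion; kneeling overrides the angle."""
    if posture is PostureClass.KNEELING:
        return RiskLevel(level=3, source=RiskSource.ALLA)
    if not math.isfinite(knee_fe):
        raise ErgoError(f"knee flexion angle must be finite, got {knee_fe!r}")
    d = knee_fe
    if d <= 15.0:
        level = 2
    elif d <= 45.0:
        level = 3
    elif d <= 135.0:
        level = 4
    else:
        level = 3
    return RiskLevel(level=level, source=RiskSource.ALLA)


def awba_level(aula: RiskLevel, alla: RiskLevel) -> RiskLevel:
    """Combine upper- and lower-body levels via the 4x4 rule grid."""
    if aula.source is not RiskSource.AULA or alla.source is not RiskSource.ALLA:
        raise ErgoError("awba_level expects an AULA level and an ALLA level")
    return RiskLevel(
        level=_AWBA_GRID[alla.level - 1][aula.level - 1], source=RiskSource.AWBA
    )


@dataclass
class AwbaSeriesResult:
    """Per-sample risk-level triplet over a whole series."""

    aula: np.ndarray
    alla: np.ndarray
    awba: np.ndarray

    def __len__(self) -> int:
        return len(self.awba)


def awba_series(
    series: AngleSeries, labels: PostureLabelSeries, config: RunConfig
) -> AwbaSeriesResult:
    """Score every sample with AULA (worst arm), ALLA (worst knee), AWBA.

    The arm whose AULA level is higher is kept; the knee with the higher
    flexion is used for ALLA — both conservative worst-case choices.
    """
    series.require(AWBA_REQUIRED_MOTIONS)
    if len(labels) != len(series):
        raise CoverageError(
            f"labels cover {len(labels)} samples but series has {len(series)}"
        )
    back = series.column(JointMotion.BACK_FLEXION_EXTENSION)
    knee = np.maximum(
        series.column(JointMotion.KNEE_LEFT_FLEXION_EXTENSION),
        series.column(JointMotion.KNEE_RIGHT_FLEXION_EXTENSION),
    )
    n = len(series)
    aula = np.empty(n, dtype=np.int64)
    alla = np.empty(n, dtype=np.int64)
    awba = np.empty(n, dtype=np.int64)
    arm_cols = {
        side: tuple(series.column(m) for m in _UPPER_MOTIONS[side])
        for side in ("left", "right")
    }
    for i in range(n):
        upper = max(
            aula_level(back[i], arm_cols[side][0][i], arm_cols[side][1][i]).level
            for side in ("left", "right")
        )
        lower = alla_level(knee[i], labels.labels[i]).level
        aula[i] = upper
        alla[i] = lower
        awba[i] = _AWBA_GRID[lower - 1][upper - 1]
    return AwbaSeriesResult(aula=aula, alla=alla, awba=awba)
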