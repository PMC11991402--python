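"""Shared domain types: joint motions, angle series, posture classes, run config.

Angle convention: degrees throughout, flexion/abduction positive, extension/
adduction negative. Lateral bending and axial rotation are stored signed and
scored on magnitude.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Iterator, Mapping

import numpy as np
from pydantic import BaseModel, Field, field_validator


class ErgoError(ValueError):
    """Base class for all validation errors raised by this package."""


class SchemaError(ErgoError):
    """A required column or field is missing or malformed."""


class AngleParseError(ErgoError):
    """A cell that should hold an angle could not be parsed."""


class VocabularyError(ErgoError):
    """A posture label outside the eight-class vocabulary."""


class CoverageError(ErgoError):
    """Posture labels do not cover the angle series."""


class UnsupportedMotionError(ErgoError):
    """A joint motion outside the scoring method's domain."""


class IncompleteFrameError(ErgoError):
    """A frame is missing a motion required by the active method."""


class Joint(str, enum.Enum):
    BACK = "back"
    SHOULDER_LEFT = "shoulder_left"
    SHOULDER_RIGHT = "shoulder_right"
    ELBOW_LEFT = "elbow_left"
    ELBOW_RIGHT = "elbow_right"
    KNEE_LEFT = "knee_left"
    KNEE_RIGHT = "knee_right"


class Motion(str, enum.Enum):
    FLEXION_EXTENSION = "flexion_extension"
    LATERAL_BENDING = "lateral_bending"
    AXIAL_ROTATION = "axial_rotation"
    ABDUCTION_ADDUCTION = "abduction_adduction"


class JointMotion(str, enum.Enum):
    """The constructible (joint, motion) pairs.

    Only the combinations used by the scoring tables exist: three back
    motions, two per shoulder, one per elbow, one per knee — eleven in total,
    of which the nine non-knee ones carry a LUBA score and a wear index.
    """

    BACK_FLEXION_EXTENSION = "back_flexion_extension"
    BACK_LATERAL_BENDING = "back_lateral_bending"
    BACK_AXIAL_ROTATION = "back_axial_rotation"
    SHOULDER_LEFT_FLEXION_EXTENSION = "shoulder_left_flexion_extension"
    SHOULDER_LEFT_ABDUCTION_ADDUCTION = "shoulder_left_abduction_adduction"
    SHOULDER_RIGHT_FLEXION_EXTENSION = "shoulder_right_flexion_extension"
    SHOULDER_RIGHT_ABDUCTION_ADDUCTION = "shoulder_right_abduction_adduction"
    ELBOW_LEFT_FLEXION_EXTENSION = "elbow_left_flexion_extension"
    ELBOW_RIGHT_FLEXION_EXTENSION = "elbow_right_flexion_extension"
    KNEE_LEFT_FLEXION_EXTENSION = "knee_left_flexion_extension"
    KNEE_RIGHT_FLEXION_EXTENSION = "knee_right_flexion_extension"

    @property
    def joint(self) -> Joint:
        return _JOINT_OF[self]

    @property
    def motion(self) -> Motion:
        return _MOTION_OF[self]

    @property
    def side(self) -> str | None:
        """'left'/'right' for lateralised joints, None for the back."""
        name = self.joint.value
        if name.endswith("_left"):
            return "left"
        if name.endswith("_right"):
            return "right"
        return None


_JOINT_OF = {
    JointMotion.BACK_FLEXION_EXTENSION: Joint.BACK,
    JointMotion.BACK_LATERAL_BENDING: Joint.BACK,
    JointMotion.BACK_AXIAL_ROTATION: Joint.BACK,
    JointMotion.SHOULDER_LEFT_FLEXION_EXTENSION: Joint.SHOULDER_LEFT,
    JointMotion.SHOULDER_LEFT_ABDUCTION_ADDUCTION: Joint.SHOULDER_LEFT,
    JointMotion.SHOULDER_RIGHT_FLEXION_EXTENSION: Joint.SHOULDER_RIGHT,
    JointMotion.SHOULDER_RIGHT_ABDUCTION_ADDUCTION: Joint.SHOULDER_RIGHT,
    JointMotion.ELBOW_LEFT_FLEXION_EXTENSION: Joint.ELBOW_LEFT,
    JointMotion.ELBOW_RIGHT_FLEXION_EXTENSION: Joint.ELBOW_RIGHT,
    JointMotion.KNEE_LEFT_FLEXION_EXTENSION: Joint.KNEE_LEFT,
    JointMotion.KNEE_RIGHT_FLEXION_EXTENSION: Joint.KNEE_RIGHT,
}

_MOTION_OF = {
    JointMotion.BACK_FLEXION_EXTENSION: Motion.FLEXION_EXTENSION,
    JointMotion.BACK_LATERAL_BENDING: Motion.LATERAL_BENDING,
    JointMotion.BACK_AXIAL_ROTATION: Motion.AXIAL_ROTATION,
    JointMotion.SHOULDER_LEFT_FLEXION_EXTENSION: Motion.FLEXION_EXTENSION,
    JointMotion.SHOULDER_LEFT_ABDUCTION_ADDUCTION: Motion.ABDUCTION_ADDUCTION,
    JointMotion.SHOULDER_RIGHT_FLEXION_EXTENSION: Motion.FLEXION_EXTENSION,
    JointMotion.SHOULDER_RIGHT_ABDUCTION_ADDUCTION: Motion.ABDUCTION_ADDUCTION,
    JointMotion.ELBOW_LEFT_FLEXION_EXTENSION: Motion.FLEXION_EXTENSION,
    JointMotion.ELBOW_RIGHT_FLEXION_EXTENSION: Motion.FLEXION_EXTENSION,
    JointMotion.KNEE_LEFT_FLEXION_EXTENSION: Motion.FLEXION_EXTENSION,
    JointMotion.KNEE_RIGHT_FLEXION_EXTENSION: Motion.FLEXION_EXTENSION,
}

#: The nine motions scored by LUBA and tracked by the wear index (no knees).
LUBA_MOTIONS: tuple[JointMotion, ...] = (
    JointMotion.BACK_FLEXION_EXTENSION,
    JointMotion.BACK_LATERAL_BENDING,
    JointMotion.BACK_AXIAL_ROTATION,
    JointMotion.SHOULDER_LEFT_FLEXION_EXTENSION,
    JointMotion.SHOULDER_LEFT_ABDUCTION_ADDUCTION,
    JointMotion.SHOULDER_RIGHT_FLEXION_EXTENSION,
    JointMotion.SHOULDER_RIGHT_ABDUCTION_ADDUCTION,
    JointMotion.ELBOW_LEFT_FLEXION_EXTENSION,
    JointMotion.ELBOW_RIGHT_FLEXION_EXTENSION,
)

#: All scored motions once the knees are added for the whole-body method.
ALL_MOTIONS: tuple[JointMotion, ...] = LUBA_MOTIONS + (
    JointMotion.KNEE_LEFT_FLEXION_EXTENSION,
    JointMotion.KNEE_RIGHT_FLEXION_EXTENSION,
)


class PostureClass(str, enum.Enum):
    STANDING = "standing"
    REACHING = "reaching"
    STOOPING = "stooping"
    SQUATTING = "squatting"
    KNEELING = "kneeling"
    LIFTING_LOWERING = "lifting_lowering"
    CARRYING = "carrying"
    OTHERS = "others"


def validate_angle(motion: JointMotion, value: float) -> float:
    value = float(value)
    if not math.isfinite(value):
        raise AngleParseError(f"non-finite angle for {motion.value}: {value!r}")
    if abs(value) > 360.0:
        raise AngleParseError(
            f"angle out of range for {motion.value}: {value} (|angle| must be <= 360)"
        )
    return value


@dataclass(frozen=True)
class AngleFrame:
    """One time sample of all monitored joint-motion angles (degrees)."""

    t: float
    angles: Mapping[JointMotion, float]

    def __post_init__(self) -> None:
        for motion, value in self.angles.items():
            validate_angle(motion, value)

    def __getitem__(self, motion: JointMotion) -> float:
        try:
            return self.angles[motion]
        except KeyError:
            raise IncompleteFrameError(
                f"frame at t={self.t} is missing {motion.value}"
            ) from None

    def require(self, motions: tuple[JointMotion, ...]) -> None:
        missing = [m.value for m in motions if m not in self.angles]
        if missing:
            raise IncompleteFrameError(
                f"frame at t={self.t} is missing motions: {', '.join(missing)}"
            )


_T_TOL = 1e-6  # tolerated deviation from uniform sample spacing, seconds


@dataclass
class AngleSeries:
    """Uniformly sampled, time-ordered joint-angle series.

    Stored column-wise (one float array per motion) for vectorised scoring;
    :meth:`frames` provides the row-wise view.
    """

    sample_rate: float
    t: np.ndarray
    angles: dict[JointMotion, np.ndarray]

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        if self.sample_rate <= 0:
            raise SchemaError(f"sample_rate must be positive, got {self.sample_rate}")
        n = len(self.t)
        for motion, values in list(self.angles.items()):
            values = np.asarray(values, dtype=float)
            if len(values) != n:
                raise SchemaError(
                    f"column {motion.value} has {len(values)} samples, expected {n}"
                )
            if not np.all(np.isfinite(values)):
                bad = int(np.flatnonzero(~np.isfinite(values))[0])
                raise AngleParseError(
                    f"non-finite angle in {motion.value} at row {bad}"
                )
            if np.any(np.abs(values) > 360.0):
                bad = int(np.flatnonzero(np.abs(values) > 360.0)[0])
                raise AngleParseError(
                    f"angle out of range in {motion.value} at row {bad}"
                )
            self.angles[motion] = values
        if n > 1:
            dt = np.diff(self.t)
            if np.any(dt <= 0):
                raise SchemaError("time column must be strictly increasing")
            if np.any(np.abs(dt - 1.0 / self.sample_rate) > _T_TOL):
                raise SchemaError(
                    f"non-uniform sampling: expected dt={1.0 / self.sample_rate} s"
                )

    def __len__(self) -> int:
        return len(self.t)

    @property
    def dt(self) -> float:
        return 1.0 / self.sample_rate

    @property
    def duration(self) -> float:
        return len(self) * self.dt

    def motions(self) -> tuple[JointMotion, ...]:
        return tuple(self.angles)

    def require(self, motions: tuple[JointMotion, ...]) -> None:
        missing = [m.value for m in motions if m not in self.angles]
        if missing:
            raise IncompleteFrameError(
                f"series is missing required motions: {', '.join(missing)}"
            )

    def column(self, motion: JointMotion) -> np.ndarray:
        try:
            return self.angles[motion]
        except KeyError:
            raise IncompleteFrameError(
                f"series is missing {motion.value}"
            ) from None

    def frames(self) -> Iterator[AngleFrame]:
        for i in range(len(self)):
            yield AngleFrame(
                t=float(self.t[i]),
                angles={m: float(v[i]) for m, v in self.angles.items()},
            )

    @classmethod
    def from_columns(
        cls,
        angles: Mapping[JointMotion, np.ndarray],
        sample_rate: float,
        t: np.ndarray | None = None,
    ) -> "AngleSeries":
        angles = {m: np.asarray(v, dtype=float) for m, v in angles.items()}
        if not angles:
            raise SchemaError("angle series needs at least one motion column")
        n = len(next(iter(angles.values())))
        if t is None:
            t = np.arange(n, dtype=float) / sample_rate
        return cls(sample_rate=sample_rate, t=np.asarray(t, dtype=float), angles=angles)


class ScoringMethod(str, enum.Enum):
    LUBA = "luba"
    AWBA = "awba"


class ArmSelection(str, enum.Enum):
    WORST_SUM = "worst_sum"
    LEFT = "left"
    RIGHT = "right"


class RunConfig(BaseModel):
    """Validated run parameters shared by the CLI and the library API."""

    method: ScoringMethod = ScoringMethod.LUBA
    sample_rate: float = Field(default=20.0, gt=0)
    v_max: float = Field(default=0.993, gt=0, lt=1)
    t_max: float = Field(default=240.0, gt=0)
    wear_threshold: float = Field(default=0.7, gt=0, lt=1)
    initial_wear: float = Field(default=0.0, ge=0, le=1)
    arm_selection: ArmSelection = ArmSelection.WORST_SUM
    global_recovery_trigger: bool = False  # experimental; see docs
    seed: int | None = None

    @field_validator("sample_rate")
    @classmethod
    def _finite_rate(cls, v: float) -> float:
        if not math.isfinite(v):
            raise ValueError("sample_rate must be finite")
        return v
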