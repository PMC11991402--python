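"""Cumulative kinematic wear index per joint motion.

The index V in [0, 1] behaves like an RC circuit: while a motion's discomfort
score S exceeds its minimum (1), V charges as

    V(t) = 1 - (1 - V(t0)) * exp(-∫ S dt / C)

and while the score sits at the minimum V discharges as

    V(t) = V(t0) * exp(-r t / C).

C (endurance capacity) is calibrated so that holding the mid-scale score for
``t_max`` seconds charges V from 0 to ``v_max``; r (recovery rate) so that the
discharge from ``v_max`` down to ``1 - v_max`` takes the same ``t_max``:

    C = -S_avg * t_max / ln(1 - v_max)
    r = -C / t_max * ln((1 - v_max) / v_max)

With scores constant within a sample, the per-sample exponential update is
exact, not an Euler approximation, so a discrete trajectory matches the
continuous closed form on every constant-score segment.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np

from .core import (
    LUBA_MOTIONS,
    ErgoError,
    JointMotion,
    RunConfig,
    UnsupportedMotionError,
)
from .luba import MIN_SCORE, SCORE_SCALES, LubaSeriesResult


class WearPhase(str, enum.Enum):
    WEAR = "wear"
    RECOVERY = "recovery"


@dataclass(frozen=True)
class WearParams:
    motion: JointMotion
    s_avg: float
    capacity_c: float  # score * seconds
    recovery_r: float  # score units
    v_max: float
    t_max: float

    def __post_init__(self) -> None:
        if self.capacity_c <= 0 or self.recovery_r <= 0:
            raise ErgoError("capacity and recovery rate must be positive")


@dataclass
class WearTrajectory:
    motion: JointMotion
    values: np.ndarray  # per-sample V in [0, 1]
    phases: np.ndarray  # bool, True where wearing (score > minimum)
    dt: float
    threshold: float = 0.7

    def __len__(self) -> int:
        return len(self.values)

    @property
    def t(self) -> np.ndarray:
        return (np.arange(len(self.values)) + 1) * self.dt


def scale_midpoint(motion: JointMotion) -> float:
    """Midpoint (min+max)/2 of the motion's score scale."""
    if motion not in SCORE_SCALES:
        raise UnsupportedMotionError(f"{motion.value} carries no wear index")
    scale = SCORE_SCALES[motion]
    return (scale[0] + scale[-1]) / 2.0


def calibrate(
    motion: JointMotion, v_max: float = 0.993, t_max: float = 240.0
) -> WearParams:
    """Derive the endurance capacity and recovery rate for one motion."""
    if not 0.0 < v_max < 1.0:
        raise ErgoError(f"v_max must be in (0, 1), got {v_max}")
    if t_max <= 0:
        raise ErgoError(f"t_max must be positive, got {t_max}")
    s_avg = scale_midpoint(motion)
    capacity = -s_avg * t_max / math.log(1.0 - v_max)
    recovery = -capacity / t_max * math.log((1.0 - v_max) / v_max)
    return WearParams(
        motion=motion,
        s_avg=s_avg,
        capacity_c=capacity,
        recovery_r=recovery,
        v_max=v_max,
        t_max=t_max,
    )


def step(v: float, score: int, dt: float, params: WearParams) -> float:
    """Advance the wear index by one sample of constant score."""
    if not 0.0 <= v <= 1.0:
        raise ErgoError(f"wear index must be in [0, 1], got {v}")
    if dt <= 0:
        raise ErgoError(f"dt must be positive, got {dt}")
    if score > MIN_SCORE:
        return 1.0 - (1.0 - v) * math.exp(-score * dt / params.capacity_c)
    return v * math.exp(-params.recovery_r * dt / params.capacity_c)


def trajectory(
    scores: np.ndarray,
    params: WearParams,
    initial: float = 0.0,
    dt: float = 0.05,
    threshold: float = 0.7,
    phases: np.ndarray | None = None,
) -> WearTrajectory:
    """Run the wear/recovery recursion over a per-sample score sequence.

    ``values[k]`` is the index at the end of sample k, i.e. after (k+1)*dt
    seconds of exposure starting from ``initial``. ``phases`` overrides the
    default wear condition (own score above minimum); True means wear.
    """
    scores = np.asarray(scores)
    if not 0.0 <= initial <= 1.0:
        raise ErgoError(f"initial wear must be in [0, 1], got {initial}")
    n = len(scores)
    values = np.empty(n, dtype=float)
    if phases is None:
        phases = scores > MIN_SCORE
    else:
        phases = np.asarray(phases, dtype=bool)
        if len(phases) != n:
            raise ErgoError("phases must match scores in length")
    decay = math.exp(-params.recovery_r * dt / params.capacity_c)
    v = initial
    for k in range(n):
        if phases[k]:
            v = 1.0 - (1.0 - v) * math.exp(-scores[k] * dt / params.capacity_c)
        else:
            v = v * decay
        values[k] = v
    return WearTrajectory(
        motion=params.motion, values=values, phases=phases, dt=dt, threshold=threshold
    )


@dataclass(frozen=True)
class ThresholdStats:
    seconds_above: float
    fraction_above: float
    first_crossing: float | None  # seconds, or None if never crossed


def threshold_stats(traj: WearTrajectory, threshold: float | None = None) -> ThresholdStats:
    """Exact sample counting of time spent above the wear threshold."""
    if threshold is None:
        threshold = traj.threshold
    if not 0.0 < threshold < 1.0:
        raise ErgoError(f"threshold must be in (0, 1), got {threshold}")
    if len(traj) == 0:
        raise ErgoError("threshold statistics are undefined for an empty trajectory")
    above = traj.values > threshold
    count = int(above.sum())
    first = None
    if count:
        first = float(traj.t[int(np.argmax(above))])
    return ThresholdStats(
        seconds_above=count * traj.dt,
        fraction_above=count / len(traj),
        first_crossing=first,
    )


def wear_from_scores(
    luba_result: LubaSeriesResult, config: RunConfig
) -> dict[JointMotion, WearTrajectory]:
    """Wear trajectories for all nine tracked motions of a scored series.

    By default each motion wears whenever its own score exceeds 1. The
    experimental ``global_recovery_trigger`` flag instead lets every motion
    recover whenever the global score is 0 (all contributions at minimum),
    wearing otherwise at its own score.
    """
    dt = 1.0 / config.sample_rate
    out: dict[JointMotion, WearTrajectory] = {}
    for motion in LUBA_MOTIONS:
        params = calibrate(motion, v_max=config.v_max, t_max=config.t_max)
        scores = luba_result.motion_scores[motion]
        phases = luba_result.g > 0 if config.global_recovery_trigger else None
        out[motion] = trajectory(
            scores,
            params,
            initial=config.initial_wear,
            dt=dt,
            threshold=config.wear_threshold,
            phases=phases,
        )
    return out
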