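"""Synthetic labelled work trials: posture templates, scripts, generation.

Each posture class has a template of mean joint angles chosen to land in
known score bands (so expected scores are analytically known), optional
sinusoidal oscillation for cyclic postures, and Gaussian jitter. A trial
script is a sequence of (posture, duration) segments with linear angle
interpolation across transitions; generation is deterministic per seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

from .core import (
    ALL_MOTIONS,
    AngleSeries,
    ErgoError,
    JointMotion,
    PostureClass,
)
from .labels import LabelProvenance, PostureLabelSeries

JM = JointMotion


@dataclass(frozen=True)
class PostureTemplate:
    posture: PostureClass
    mean_angles: dict[JointMotion, float]
    jitter_sd: float = 3.0
    oscillation: tuple[float, float] | None = None  # (amplitude deg, freq Hz)
    #: motions the oscillation applies to (defaults to knees)
    oscillating: tuple[JointMotion, ...] = (
        JM.KNEE_LEFT_FLEXION_EXTENSION,
        JM.KNEE_RIGHT_FLEXION_EXTENSION,
    )


def _angles(**overrides: float) -> dict[JointMotion, float]:
    base = {m: 0.0 for m in ALL_MOTIONS}
    for key, value in overrides.items():
        base[JointMotion(key)] = value
    return base


# Template means are repo-defined constants placed in specific score bands;
# they are fixture design, not measurements.
TEMPLATES: dict[PostureClass, PostureTemplate] = {
    PostureClass.STANDING: PostureTemplate(
        PostureClass.STANDING, _angles()  # all neutral: minimum everywhere
    ),
    PostureClass.REACHING: PostureTemplate(
        PostureClass.REACHING,
        _angles(
            back_flexion_extension=10.0,
            shoulder_left_flexion_extension=100.0,  # shoulder fe band (90,150] -> 6
            shoulder_right_flexion_extension=100.0,
            elbow_left_flexion_extension=20.0,
            elbow_right_flexion_extension=20.0,
        ),
    ),
    PostureClass.STOOPING: PostureTemplate(
        PostureClass.STOOPING,
        _angles(
            back_flexion_extension=95.0,  # back fe band > 90 -> 12
            shoulder_left_flexion_extension=95.0,
            shoulder_right_flexion_extension=95.0,
            elbow_left_flexion_extension=30.0,
            elbow_right_flexion_extension=30.0,
            knee_left_flexion_extension=5.0,
            knee_right_flexion_extension=5.0,
        ),
    ),
    PostureClass.SQUATTING: PostureTemplate(
        PostureClass.SQUATTING,
        _angles(
            back_flexion_extension=20.0,  # back stays in the minimum band
            knee_left_flexion_extension=100.0,  # knee band (45,135] -> level 4
            knee_right_flexion_extension=100.0,
            shoulder_left_flexion_extension=30.0,
            shoulder_right_flexion_extension=30.0,
            elbow_left_flexion_extension=60.0,
            elbow_right_flexion_extension=60.0,
        ),
    ),
    PostureClass.KNEELING: PostureTemplate(
        PostureClass.KNEELING,
        _angles(
            back_flexion_extension=45.0,  # back fe band (30,60] -> 3
            knee_left_flexion_extension=120.0,
            knee_right_flexion_extension=120.0,
            shoulder_left_flexion_extension=40.0,
            shoulder_right_flexion_extension=40.0,
            elbow_left_flexion_extension=50.0,
            elbow_right_flexion_extension=50.0,
        ),
    ),
    PostureClass.LIFTING_LOWERING: PostureTemplate(
        PostureClass.LIFTING_LOWERING,
        _angles(
            back_flexion_extension=50.0,  # back fe band (30,60] -> 3
            knee_left_flexion_extension=30.0,
            knee_right_flexion_extension=30.0,
            shoulder_left_flexion_extension=50.0,
            shoulder_right_flexion_extension=50.0,
            elbow_left_flexion_extension=60.0,
            elbow_right_flexion_extension=60.0,
        ),
    ),
    PostureClass.CARRYING: PostureTemplate(
        PostureClass.CARRYING,
        _angles(
            back_flexion_extension=5.0,
            shoulder_left_flexion_extension=10.0,
            shoulder_right_flexion_extension=10.0,
            elbow_left_flexion_extension=40.0,
            elbow_right_flexion_extension=40.0,
            knee_left_flexion_extension=15.0,
            knee_right_flexion_extension=15.0,
        ),
        oscillation=(15.0, 1.0),  # gait-like knee oscillation
    ),
    PostureClass.OTHERS: PostureTemplate(
        PostureClass.OTHERS,
        _angles(
            back_flexion_extension=-15.0,  # slight back extension band -> 4
            shoulder_left_flexion_extension=-30.0,
            shoulder_right_flexion_extension=-30.0,
        ),
    ),
}


@dataclass
class TrialScript:
    segments: list[tuple[PostureClass, float]]  # (posture, duration seconds)
    transition_s: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.segments:
            raise ErgoError("a trial script needs at least one segment")
        for posture, duration in self.segments:
            if duration <= 0:
                raise ErgoError(f"segment duration must be positive, got {duration}")
        if self.duration < 1.0:
            raise ErgoError("total trial duration must be at least 1 s")

    @property
    def duration(self) -> float:
        return sum(d for _, d in self.segments)

    def to_yaml(self, path) -> None:
        data = {
            "segments": [[p.value, float(d)] for p, d in self.segments],
            "transition_s": self.transition_s,
            "seed": self.seed,
        }
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "TrialScript":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh)
        return cls(
            segments=[(PostureClass(p), float(d)) for p, d in data["segments"]],
            transition_s=float(data.get("transition_s", 0.5)),
            seed=int(data.get("seed", 0)),
        )


def generate_trial(
    script: TrialScript,
    sample_rate: float = 20.0,
    jitter_sd: float | None = None,
) -> tuple[AngleSeries, PostureLabelSeries]:
    """Synthesise an angle series and its ground-truth per-sample labels.

    Angles are the segment template mean, linearly interpolated over the
    transition window at each segment boundary, plus the template oscillation
    and Gaussian jitter. Transition samples carry the incoming segment's
    label. ``jitter_sd`` overrides every template's jitter when given.
    """
    for posture, _ in script.segments:
        if posture not in TEMPLATES:
            raise ErgoError(f"no template for posture {posture!r}")
    rng = np.random.default_rng(script.seed)
    dt = 1.0 / sample_rate
    n = int(round(script.duration * sample_rate))
    t = np.arange(n) * dt

    # per-sample segment index (transition samples belong to the new segment)
    bounds = np.cumsum([d for _, d in script.segments])
    seg_idx = np.searchsorted(bounds, t, side="right")
    seg_idx = np.minimum(seg_idx, len(script.segments) - 1)
    starts = np.concatenate([[0.0], bounds[:-1]])

    labels = [script.segments[i][0] for i in seg_idx]
    angles: dict[JointMotion, np.ndarray] = {}
    for motion in ALL_MOTIONS:
        means = np.array(
            [TEMPLATES[script.segments[i][0]].mean_angles[motion] for i in seg_idx]
        )
        # ramp from the previous segment's mean across the transition window
        if script.transition_s > 0:
            for k in range(1, len(script.segments)):
                prev_mean = TEMPLATES[script.segments[k - 1][0]].mean_angles[motion]
                in_seg = seg_idx == k
                if not in_seg.any():
                    continue
                tau = (t - starts[k]) / script.transition_s
                ramp = in_seg & (tau < 1.0)
                means[ramp] = prev_mean + (means[ramp] - prev_mean) * tau[ramp]
        osc = np.zeros(n)
        for k, (posture, _) in enumerate(script.segments):
            tpl = TEMPLATES[posture]
            if tpl.oscillation and motion in tpl.oscillating:
                amp, freq = tpl.oscillation
                mask = seg_idx == k
                osc[mask] = amp * np.sin(2 * np.pi * freq * (t[mask] - starts[k]))
        sds = np.array(
            [
                TEMPLATES[script.segments[i][0]].jitter_sd
                if jitter_sd is None
                else jitter_sd
                for i in seg_idx
            ]
        )
        noise = rng.normal(0.0, 1.0, n) * sds
        angles[motion] = np.clip(means + osc + noise, -360.0, 360.0)

    series = AngleSeries.from_columns(angles, sample_rate=sample_rate, t=t)
    label_series = PostureLabelSeries(
        labels=labels,
        sample_rate=sample_rate,
        provenance=LabelProvenance.SYNTHETIC_TRUTH,
    )
    return series, label_series


def bricklaying_script(variant: PostureClass, seed: int = 0) -> TrialScript:
    """~120 s construction trial: carry in, then work cycles in ``variant``.

    ``variant`` is the bricklaying posture (stooping, squatting, or
    kneeling). The script starts with a shared 20 s carrying segment, then
    alternates lifting/lowering, the variant posture, and brief standing
    recoveries.
    """
    if variant not in (
        PostureClass.STOOPING,
        PostureClass.SQUATTING,
        PostureClass.KNEELING,
    ):
        raise ErgoError(f"unsupported bricklaying variant: {variant!r}")
    segments: list[tuple[PostureClass, float]] = [(PostureClass.CARRYING, 20.0)]
    for _ in range(6):
        segments.append((PostureClass.LIFTING_LOWERING, 3.0))
        segments.append((variant, 11.0))
        segments.append((PostureClass.STANDING, 3.0))
    return TrialScript(segments=segments, transition_s=0.5, seed=seed)


def harvesting_script(seed: int = 0) -> TrialScript:
    """~120 s agriculture trial: carry between sites, reach and lower crops."""
    segments: list[tuple[PostureClass, float]] = []
    for _ in range(3):
        segments.append((PostureClass.CARRYING, 8.0))
        segments.append((PostureClass.REACHING, 12.0))
        segments.append((PostureClass.LIFTING_LOWERING, 8.0))
        segments.append((PostureClass.STANDING, 4.0))
    segments.append((PostureClass.STANDING, 24.0))
    return TrialScript(segments=segments, transition_s=0.5, seed=seed)
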