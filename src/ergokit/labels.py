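"""Posture label alignment and the classifier plug-in contract.

Posture labels arrive per non-overlapping 1-s window; scoring runs per
sample, so window labels are broadcast to sample resolution. Any callable
mapping a window of angle frames to a posture class can be registered as a
classifier; a deterministic angle-threshold heuristic is provided as the
reference baseline for synthetic trials.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .core import (
    AngleFrame,
    AngleSeries,
    CoverageError,
    JointMotion,
    PostureClass,
)


class LabelProvenance(str, enum.Enum):
    FILE = "file"
    CLASSIFIER = "classifier"
    SYNTHETIC_TRUTH = "synthetic_truth"


@dataclass
class PostureLabelSeries:
    """Per-sample posture classes aligned to a companion angle series."""

    labels: list[PostureClass]
    sample_rate: float
    provenance: LabelProvenance
    partial_mask: np.ndarray = field(default=None)  # True on trailing partial samples

    def __post_init__(self) -> None:
        if self.partial_mask is None:
            self.partial_mask = np.zeros(len(self.labels), dtype=bool)
        self.partial_mask = np.asarray(self.partial_mask, dtype=bool)
        if len(self.partial_mask) != len(self.labels):
            raise CoverageError("partial_mask must match labels in length")

    def __len__(self) -> int:
        return len(self.labels)


def broadcast_windows(
    window_labels: Sequence[PostureClass],
    sample_rate: float,
    n_samples: int,
    provenance: LabelProvenance = LabelProvenance.FILE,
) -> PostureLabelSeries:
    """Repeat each 1-s window label ``sample_rate`` times.

    Samples past the last full window (at most one window's worth) are
    labelled ``others`` and flagged as partial; anything beyond that is a
    coverage error.
    """
    spw = int(round(sample_rate))  # samples per 1-s window
    if spw <= 0:
        raise CoverageError(f"sample_rate must be positive, got {sample_rate}")
    covered = len(window_labels) * spw
    if n_samples > covered + spw - 1:
        raise CoverageError(
            f"{len(window_labels)} windows cover at most {covered + spw - 1} samples, "
            f"got {n_samples}"
        )
    labels: list[PostureClass] = []
    for w in window_labels:
        labels.extend([w] * spw)
    labels = labels[:n_samples]
    partial = np.zeros(n_samples, dtype=bool)
    if n_samples > covered:
        labels.extend([PostureClass.OTHERS] * (n_samples - covered))
        partial[covered:] = True
    return PostureLabelSeries(
        labels=labels,
        sample_rate=sample_rate,
        provenance=provenance,
        partial_mask=partial,
    )


def collapse_to_windows(series: PostureLabelSeries) -> list[PostureClass]:
    """Majority label per full window; inverse of :func:`broadcast_windows`."""
    spw = int(round(series.sample_rate))
    out = []
    full = len(series) // spw
    for w in range(full):
        block = series.labels[w * spw : (w + 1) * spw]
        counts: dict[PostureClass, int] = {}
        for label in block:
            counts[label] = counts.get(label, 0) + 1
        out.append(max(counts, key=lambda k: counts[k]))
    return out


# --- classifier plug-in registry -------------------------------------------

#: A classifier maps a 1-s window of frames to a posture class.
Classifier = Callable[[Sequence[AngleFrame]], PostureClass]

_CLASSIFIERS: dict[str, Classifier] = {}


def register_classifier(name: str) -> Callable[[Classifier], Classifier]:
    def deco(fn: Classifier) -> Classifier:
        _CLASSIFIERS[name] = fn
        return fn

    return deco


def get_classifier(name: str) -> Classifier:
    try:
        return _CLASSIFIERS[name]
    except KeyError:
        raise KeyError(
            f"no classifier named {name!r}; registered: {sorted(_CLASSIFIERS)}"
        ) from None


def classify_series(
    series: AngleSeries, classifier: Classifier | str = "heuristic"
) -> PostureLabelSeries:
    """Run a window classifier over a series and broadcast its labels."""
    if isinstance(classifier, str):
        classifier = get_classifier(classifier)
    spw = int(round(series.sample_rate))
    frames = list(series.frames())
    window_labels = [
        classifier(frames[w * spw : (w + 1) * spw])
        for w in range(len(series) // spw)
    ]
    return broadcast_windows(
        window_labels,
        series.sample_rate,
        len(series),
        provenance=LabelProvenance.CLASSIFIER,
    )


# --- heuristic baseline -----------------------------------------------------

# Thresholds tuned to the synthetic posture templates; magnitudes in degrees.
_KNEE_KNEELING = 110.0
_KNEE_SQUATTING = 60.0
_BACK_STOOPING = 70.0
_BACK_LIFTING = 35.0
_SHOULDER_REACHING = 70.0
_KNEE_OSC_SD = 5.0
_NEUTRAL_BAND = 25.0


def heuristic_classify(
    frame: AngleFrame, context: Sequence[AngleFrame] = ()
) -> PostureClass:
    """Deterministic rule set over joint angles and short-horizon variance.

    ``context`` is a short history (about one window) used only for the
    variance cue that separates carrying (cyclic gait) from standing. Falls
    back to ``others`` when no rule fires.
    """
    back = frame[JointMotion.BACK_FLEXION_EXTENSION]
    knee = max(
        frame[JointMotion.KNEE_LEFT_FLEXION_EXTENSION],
        frame[JointMotion.KNEE_RIGHT_FLEXION_EXTENSION],
    )
    shoulder = max(
        frame[JointMotion.SHOULDER_LEFT_FLEXION_EXTENSION],
        frame[JointMotion.SHOULDER_RIGHT_FLEXION_EXTENSION],
    )
    if knee > _KNEE_KNEELING:
        return PostureClass.KNEELING
    if knee > _KNEE_SQUATTING:
        return PostureClass.SQUATTING
    if back > _BACK_STOOPING:
        return PostureClass.STOOPING
    if back > _BACK_LIFTING:
        return PostureClass.LIFTING_LOWERING
    if shoulder > _SHOULDER_REACHING:
        return PostureClass.REACHING

    knee_sd = 0.0
    if len(context) >= 2:
        hist = [
            max(
                f[JointMotion.KNEE_LEFT_FLEXION_EXTENSION],
                f[JointMotion.KNEE_RIGHT_FLEXION_EXTENSION],
            )
            for f in context
        ]
        knee_sd = float(np.std(hist))
    if knee_sd > _KNEE_OSC_SD and back <= _BACK_LIFTING:
        return PostureClass.CARRYING
    shoulder_mag = max(
        abs(frame[JointMotion.SHOULDER_LEFT_FLEXION_EXTENSION]),
        abs(frame[JointMotion.SHOULDER_RIGHT_FLEXION_EXTENSION]),
    )
    if abs(back) <= _NEUTRAL_BAND and shoulder_mag <= _NEUTRAL_BAND and abs(knee) <= _NEUTRAL_BAND:
        return PostureClass.STANDING
    return PostureClass.OTHERS


@register_classifier("heuristic")
def _heuristic_window(frames: Sequence[AngleFrame]) -> PostureClass:
    """Window-level wrapper: classify the window midpoint with full context."""
    mid = frames[len(frames) // 2]
    return heuristic_classify(mid, context=frames)
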