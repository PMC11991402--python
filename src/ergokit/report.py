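"""Shift-level aggregation linking ergonomic risk to posture classes.

A report holds, per posture class, the fraction of the shift spent in it and
the mean global score (or whole-body risk level) it generated, alongside a
per-sample sequence track for playback plots and per-motion wear-threshold
breach statistics with the top breaching motions.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .core import (
    ErgoError,
    JointMotion,
    PostureClass,
    RunConfig,
    ScoringMethod,
)
from .labels import PostureLabelSeries
from .luba import CATEGORY_COLOURS, categorize
from .awba import LEVEL_COLOURS
from .wear import WearTrajectory, threshold_stats

SCHEMA_VERSION = 1


class ReportScope(str, enum.Enum):
    SINGLE_TRIAL = "single_trial"
    PER_SUBJECT = "per_subject"
    ALL_SUBJECTS = "all_subjects"


@dataclass
class PostureAggregate:
    time_fraction: float
    mean_score: float


@dataclass
class WearSummary:
    fraction_above: float
    seconds_above: float
    first_crossing: float | None


@dataclass
class ShiftReport:
    method: ScoringMethod
    scope: ReportScope
    per_posture: dict[PostureClass, PostureAggregate]
    wear_summary: dict[JointMotion, WearSummary]
    top_breaching_motions: list[JointMotion]
    n_trials: int = 1
    wear_threshold: float = 0.7
    # per-sample playback track; absent on merged reports
    sequence_track: dict[str, list] | None = None
    schema_version: int = SCHEMA_VERSION

    def to_dict(self) -> dict:
        return {
            "schema_version": self.schema_version,
            "method": self.method.value,
            "scope": self.scope.value,
            "n_trials": self.n_trials,
            "wear_threshold": self.wear_threshold,
            "per_posture": {
                p.value: {
                    "time_fraction": a.time_fraction,
                    "mean_score": a.mean_score,
                }
                for p, a in self.per_posture.items()
            },
            "wear_summary": {
                m.value: {
                    "fraction_above": w.fraction_above,
                    "seconds_above": w.seconds_above,
                    "first_crossing": w.first_crossing,
                }
                for m, w in self.wear_summary.items()
            },
            "top_breaching_motions": [m.value for m in self.top_breaching_motions],
            "sequence_track": self.sequence_track,
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "ShiftReport":
        return cls(
            method=ScoringMethod(data["method"]),
            scope=ReportScope(data["scope"]),
            n_trials=int(data.get("n_trials", 1)),
            wear_threshold=float(data.get("wear_threshold", 0.7)),
            per_posture={
                PostureClass(p): PostureAggregate(
                    time_fraction=a["time_fraction"], mean_score=a["mean_score"]
                )
                for p, a in data["per_posture"].items()
            },
            wear_summary={
                JointMotion(m): WearSummary(
                    fraction_above=w["fraction_above"],
                    seconds_above=w["seconds_above"],
                    first_crossing=w["first_crossing"],
                )
                for m, w in data["wear_summary"].items()
            },
            top_breaching_motions=[
                JointMotion(m) for m in data["top_breaching_motions"]
            ],
            sequence_track=data.get("sequence_track"),
            schema_version=int(data["schema_version"]),
        )


def _sample_colour(method: ScoringMethod, score: int) -> str:
    if method is ScoringMethod.LUBA:
        return CATEGORY_COLOURS[categorize(int(score))]
    return LEVEL_COLOURS[int(score)]


def build_report(
    scores: np.ndarray,
    labels: PostureLabelSeries,
    wear: Mapping[JointMotion, WearTrajectory] | None,
    config: RunConfig,
    scope: ReportScope = ReportScope.SINGLE_TRIAL,
) -> ShiftReport:
    """Aggregate per-sample scores, labels, and wear into a shift report.

    ``scores`` is the per-sample global score (LUBA) or whole-body level
    (AWBA). Trailing partial-window samples are excluded from the per-posture
    aggregates but kept in the sequence track.
    """
    scores = np.asarray(scores)
    if len(scores) != len(labels):
        raise ErgoError(
            f"scores ({len(scores)}) and labels ({len(labels)}) lengths differ"
        )
    keep = ~labels.partial_mask
    kept_labels = np.array([l.value for l in labels.labels], dtype=object)[keep]
    kept_scores = scores[keep]

    per_posture: dict[PostureClass, PostureAggregate] = {}
    total = len(kept_scores)
    for posture in PostureClass if total else ():
        mask = kept_labels == posture.value
        count = int(mask.sum())
        if count == 0:
            continue
        per_posture[posture] = PostureAggregate(
            time_fraction=count / total,
            mean_score=float(kept_scores[mask].mean()),
        )

    wear_summary: dict[JointMotion, WearSummary] = {}
    if wear:
        for motion, traj in wear.items():
            stats = threshold_stats(traj)
            wear_summary[motion] = WearSummary(
                fraction_above=stats.fraction_above,
                seconds_above=stats.seconds_above,
                first_crossing=stats.first_crossing,
            )
    top = sorted(
        (m for m in wear_summary if wear_summary[m].seconds_above > 0),
        key=lambda m: (-wear_summary[m].seconds_above, m.value),
    )[:3]

    track = {
        "score": [int(s) for s in scores],
        "posture": [l.value for l in labels.labels],
        "colour": [_sample_colour(config.method, int(s)) for s in scores],
    }
    return ShiftReport(
        method=config.method,
        scope=scope,
        per_posture=per_posture,
        wear_summary=wear_summary,
        top_breaching_motions=top,
        wear_threshold=config.wear_threshold,
        sequence_track=track,
    )


def merge_reports(
    reports: Sequence[ShiftReport], scope: ReportScope = ReportScope.ALL_SUBJECTS
) -> ShiftReport:
    """Average per-trial aggregates without pooling samples.

    Per-posture fields are unweighted means of the per-trial values, with a
    posture absent from a trial contributing a zero time fraction — so merged
    fractions need not sum to 1. Mean scores average over the trials where
    the posture occurred.
    """
    if not reports:
        raise ErgoError("cannot merge an empty report sequence")
    methods = {r.method for r in reports}
    if len(methods) > 1:
        raise ErgoError(f"cannot merge reports with mixed methods: {methods}")

    per_posture: dict[PostureClass, PostureAggregate] = {}
    for posture in PostureClass:
        present = [r.per_posture[posture] for r in reports if posture in r.per_posture]
        if not present:
            continue
        frac = sum(a.time_fraction for a in present) / len(reports)
        mean = sum(a.mean_score for a in present) / len(present)
        per_posture[posture] = PostureAggregate(time_fraction=frac, mean_score=mean)

    wear_summary: dict[JointMotion, WearSummary] = {}
    motions = sorted({m for r in reports for m in r.wear_summary}, key=lambda m: m.value)
    for motion in motions:
        entries = [r.wear_summary[motion] for r in reports if motion in r.wear_summary]
        crossings = [e.first_crossing for e in entries if e.first_crossing is not None]
        wear_summary[motion] = WearSummary(
            fraction_above=sum(e.fraction_above for e in entries) / len(entries),
            seconds_above=sum(e.seconds_above for e in entries) / len(entries),
            first_crossing=min(crossings) if crossings else None,
        )
    top = sorted(
        (m for m in wear_summary if wear_summary[m].seconds_above > 0),
        key=lambda m: (-wear_summary[m].seconds_above, m.value),
    )[:3]

    tracks = [r.sequence_track for r in reports]
    same_track = all(t == tracks[0] for t in tracks)
    return ShiftReport(
        method=reports[0].method,
        scope=scope if not (len(reports) == 1 or same_track) else reports[0].scope,
        per_posture=per_posture,
        wear_summary=wear_summary,
        top_breaching_motions=top,
        n_trials=sum(r.n_trials for r in reports) if not same_track else reports[0].n_trials,
        wear_threshold=reports[0].wear_threshold,
        sequence_track=tracks[0] if same_track else None,
    )


# --- rendering --------------------------------------------------------------

_HTML_TEMPLATE = """<!DOCTYPE html>
<html><head><meta charset="utf-8"><title>Shift report</title>
<style>
body {{ font-family: sans-serif; margin: 2em; }}
table {{ border-collapse: collapse; }}
td, th {{ border: 1px solid #999; padding: 0.3em 0.8em; }}
</style></head><body>
<h1>Work-shift ergonomic report</h1>
<p>Method: <b>{method}</b> &middot; scope: {scope} &middot; trials: {n_trials}</p>
<h2>Time and risk per posture</h2>
<table><tr><th>Posture</th><th>Time fraction</th><th>Mean score</th></tr>
{posture_rows}
</table>
<h2>Kinematic wear (threshold {threshold})</h2>
<table><tr><th>Joint motion</th><th>% time above</th><th>Seconds above</th></tr>
{wear_rows}
</table>
<p>Most breaching motions: {top}</p>
</body></html>
"""


def render(report: ShiftReport, format: str, out_dir: str | Path) -> list[Path]:
    """Write report artifacts (``json``, ``html``, or ``png_plots``)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if format == "json":
        from .io import write_report_json

        path = out_dir / "report.json"
        write_report_json(report, path)
        return [path]
    if format == "html":
        posture_rows = "\n".join(
            f"<tr><td>{p.value}</td><td>{a.time_fraction:.3f}</td>"
            f"<td>{a.mean_score:.2f}</td></tr>"
            for p, a in report.per_posture.items()
        )
        wear_rows = "\n".join(
            f"<tr><td>{m.value}</td><td>{w.fraction_above * 100:.1f}</td>"
            f"<td>{w.seconds_above:.2f}</td></tr>"
            for m, w in report.wear_summary.items()
        )
        html = _HTML_TEMPLATE.format(
            method=report.method.value,
            scope=report.scope.value,
            n_trials=report.n_trials,
            threshold=report.wear_threshold,
            posture_rows=posture_rows,
            wear_rows=wear_rows,
            top=", ".join(m.value for m in report.top_breaching_motions) or "none",
        )
        path = out_dir / "report.html"
        path.write_text(html, encoding="utf-8")
        return [path]
    if format == "png_plots":
        return _render_plots(report, out_dir)
    raise ErgoError(f"unsupported render format: {format!r}")


def _render_plots(report: ShiftReport, out_dir: Path) -> list[Path]:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    paths: list[Path] = []

    # per-posture summary: pie of time plus bar of mean score
    postures = [p for p in PostureClass if p in report.per_posture]
    if postures:
        fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(10, 4))
        fracs = [report.per_posture[p].time_fraction for p in postures]
        ax1.pie(fracs, labels=[p.value for p in postures], autopct="%.0f%%")
        ax1.set_title("Time per posture")
        means = [report.per_posture[p].mean_score for p in postures]
        ax2.bar(range(len(postures)), means)
        ax2.set_xticks(range(len(postures)))
        ax2.set_xticklabels([p.value for p in postures], rotation=45, ha="right")
        ax2.set_ylabel("mean score")
        ax2.set_title("Mean ergonomic score per posture")
        fig.tight_layout()
        path = out_dir / "summary.png"
        fig.savefig(path, dpi=100)
        plt.close(fig)
        paths.append(path)

    if report.sequence_track:
        fig, ax = plt.subplots(figsize=(10, 3))
        scores = report.sequence_track["score"]
        colours = report.sequence_track["colour"]
        t = np.arange(len(scores))
        ax.scatter(t, scores, c=colours, s=4)
        ax.set_xlabel("sample")
        ax.set_ylabel("score" if report.method is ScoringMethod.LUBA else "level")
        ax.set_title("Score and posture sequence")
        fig.tight_layout()
        path = out_dir / "sequence.png"
        fig.savefig(path, dpi=100)
        plt.close(fig)
        paths.append(path)
    return paths


def plot_wear(
    traj: WearTrajectory,
    scores: np.ndarray | None = None,
    out_path: str | Path = "wear.png",
) -> Path:
    """Wear-index timeline with red wear / green recovery shading."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(10, 3))
    t = traj.t
    ax.plot(t, traj.values, color="black", lw=1.2, label="kinematic wear")
    ax.axhline(traj.threshold, ls="--", color="grey", label="threshold")
    ax.fill_between(t, 0, 1, where=traj.phases, color="red", alpha=0.15)
    ax.fill_between(t, 0, 1, where=~traj.phases, color="green", alpha=0.15)
    if scores is not None:
        ax2 = ax.twinx()
        ax2.step(t, scores, where="post", color="tab:blue", alpha=0.6, lw=0.8)
        ax2.set_ylabel("score")
    ax.set_ylim(0, 1)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("wear index")
    ax.set_title(traj.motion.value)
    ax.legend(loc="upper left", fontsize=8)
    fig.tight_layout()
    out_path = Path(out_path)
    fig.savefig(out_path, dpi=100)
    plt.close(fig)
    return out_path
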