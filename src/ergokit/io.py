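"""Readers and writers for angle CSVs, label CSVs, YAML config, JSON reports.

CSV dialect: comma-separated UTF-8 with a mandatory header row. Angle columns
are named ``<joint>_<motion>`` (e.g. ``back_flexion_extension``); a ``t``
column in seconds is optional and reconstructed from the sample rate when
absent.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import (
    LUBA_MOTIONS,
    AngleParseError,
    AngleSeries,
    JointMotion,
    PostureClass,
    RunConfig,
    SchemaError,
    VocabularyError,
)

TIME_COLUMN = "t"

#: Columns a LUBA run must provide; knees are optional for LUBA.
REQUIRED_LUBA_COLUMNS = tuple(m.value for m in LUBA_MOTIONS)


def read_angle_series(
    path: str | Path,
    sample_rate: float = 20.0,
    required: tuple[JointMotion, ...] = LUBA_MOTIONS,
) -> AngleSeries:
    """Load a joint-angle CSV into a validated :class:`AngleSeries`.

    Raises :class:`SchemaError` naming any missing required column and
    :class:`AngleParseError` with the offending row index on bad cells.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # malformed CSV
        raise SchemaError(f"could not parse {path}: {exc}") from exc

    missing = [m.value for m in required if m.value not in df.columns]
    if missing:
        raise SchemaError(
            f"{path} is missing required column(s): {', '.join(missing)}"
        )

    known = {m.value: m for m in JointMotion}
    angles: dict[JointMotion, np.ndarray] = {}
    for name in df.columns:
        if name == TIME_COLUMN:
            continue
        if name not in known:
            continue  # unknown columns are ignored, not an error
        col = pd.to_numeric(df[name], errors="coerce").to_numpy(dtype=float)
        raw_na = df[name].isna().to_numpy()
        bad = np.flatnonzero(np.isnan(col) & ~raw_na)
        if len(bad):
            raise AngleParseError(
                f"{path}: non-numeric value in column {name} at row {int(bad[0])}"
            )
        if raw_na.any():
            raise AngleParseError(
                f"{path}: missing value in column {name} at row "
                f"{int(np.flatnonzero(raw_na)[0])}"
            )
        angles[known[name]] = col

    if not angles:
        raise SchemaError(f"{path} contains no recognised angle columns")

    t = None
    if TIME_COLUMN in df.columns:
        t = pd.to_numeric(df[TIME_COLUMN], errors="coerce").to_numpy(dtype=float)
        if np.isnan(t).any():
            raise AngleParseError(
                f"{path}: non-numeric value in column {TIME_COLUMN} at row "
                f"{int(np.flatnonzero(np.isnan(t))[0])}"
            )
    return AngleSeries.from_columns(angles, sample_rate=sample_rate, t=t)


def write_angle_series(series: AngleSeries, path: str | Path) -> None:
    """Write an angle series as CSV (with an explicit ``t`` column)."""
    data = {TIME_COLUMN: series.t}
    data.update({m.value: v for m, v in series.angles.items()})
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.9f")


def read_labels(path: str | Path) -> list[PostureClass]:
    """Read consecutive 1-s window posture labels from a one-column CSV.

    Accepts a header row (``posture`` or ``label``); every value must be one
    of the eight posture classes.
    """
    path = Path(path)
    rows: list[str] = []
    with open(path, newline="", encoding="utf-8") as fh:
        for line in fh:
            cell = line.strip().split(",")[0].strip()
            if cell:
                rows.append(cell)
    if rows and rows[0].lower() in {"posture", "label", "posture_class"}:
        rows = rows[1:]
    labels: list[PostureClass] = []
    for i, cell in enumerate(rows):
        try:
            labels.append(PostureClass(cell))
        except ValueError:
            valid = ", ".join(p.value for p in PostureClass)
            raise VocabularyError(
                f"{path}: unknown posture class {cell!r} at row {i} "
                f"(expected one of: {valid})"
            ) from None
    return labels


def write_labels(labels: list[PostureClass], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        fh.write("posture\n")
        for label in labels:
            fh.write(label.value + "\n")


def read_config(path: str | Path) -> RunConfig:
    """Load a YAML run configuration, applying defaults for absent fields."""
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise SchemaError(f"{path}: config must be a YAML mapping")
    return RunConfig(**raw)


def write_config(config: RunConfig, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(config.model_dump(mode="json"), fh, sort_keys=False)


def write_report_json(report, path: str | Path) -> None:
    """Serialise a ShiftReport to versioned JSON; re-reading round-trips."""
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(report.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_report_json(path: str | Path):
    from .report import ShiftReport

    with open(path, encoding="utf-8") as fh:
        return ShiftReport.from_dict(json.load(fh))
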