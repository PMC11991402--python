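# ergokit

Sample-wise ergonomic posture assessment for joint-angle time series from
wearable motion capture: two finite-state-machine scoring methods, a
cumulative per-joint-motion kinematic wear index with RC-circuit-style
wear/recovery dynamics, and machine- and human-readable work-shift reports
that attribute risk to posture classes.

## What it does

- **LUBA scoring** (`ergokit.luba`) — integer discomfort scores per joint
  motion (back flexion/extension, lateral bending, axial rotation; shoulder
  flexion/extension and abduction/adduction; elbow flexion/extension) from
  angle-range tables, a global score G in 0–62 over the back plus the worst
  arm (only scores above the minimum contribute), and four corrective-action
  categories (I–IV).
- **AWBA scoring** (`ergokit.awba`) — upper-body (AULA) and lower-limb
  (ALLA) risk levels 1–4 from sagittal angles, combined by a 4×4 rule grid.
  Kneeling pins the lower-limb level at 3 regardless of knee angle; level 1
  is reserved for sitting and unreachable here.
- **Kinematic wear** (`ergokit.wear`) — per-motion index V ∈ [0, 1] that
  charges exponentially while the motion's LUBA score exceeds its minimum
  and discharges otherwise. Calibrated so holding the mid-scale score for
  240 s charges V from 0 to 0.993, and the mirrored recovery takes the same
  time. Threshold-breach statistics (default threshold 0.7) by exact sample
  counting.
- **Posture labels** (`ergokit.labels`) — 1-s-window label ingestion and
  broadcast to per-sample resolution, a pluggable classifier registry, and a
  deterministic angle-threshold heuristic baseline for synthetic data.
- **Reports** (`ergokit.report`) — per-posture time fractions and mean
  scores, per-sample playback track with category/level colours
  (green/yellow/orange/red), top wear-breaching motions, cross-trial merging
  by mean-of-means, and JSON/HTML/PNG rendering.
- **Synthetic trials** (`ergokit.synth`) — labelled multi-posture trials
  (template angles + transitions + jitter) including ~120 s bricklaying
  scripts in stooping/squatting/kneeling variants and a harvesting script,
  deterministic per seed.

## CLI

```sh
# generate a synthetic labelled trial (angle CSV + 1-s window label CSV)
ergokit simulate --script bricklaying_stooping --seed 7 --out out/sim

# score it with LUBA: per-sample scores, wear CSV + plots, report.json/html
ergokit assess --angles out/sim/angles.csv --labels out/sim/labels.csv \
    --method luba --out out/run

# AWBA instead (labels are mandatory: kneeling changes the leg level)
ergokit assess --angles out/sim/angles.csv --labels out/sim/labels.csv \
    --method awba --out out/run_awba

# wear index alone, merge reports, re-render
ergokit wear --angles out/sim/angles.csv --out out/wear.csv
ergokit merge out/run/report.json other/report.json --out out/merged.json
ergokit report --report out/merged.json --format html --out out/render
```

Angle CSVs are comma-separated with a header of `<joint>_<motion>` columns
(e.g. `back_flexion_extension`, `shoulder_left_abduction_adduction`,
`knee_right_flexion_extension`) and an optional `t` column; the default
cadence is 20 Hz. Angles are degrees, flexion/abduction positive. A YAML
config (`--config`) can set `method`, `sample_rate`, `v_max`, `t_max`,
`wear_threshold`, `initial_wear`, `arm_selection`, `seed`; CLI flags
override it. Validation failures exit 2, I/O failures exit 3.

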