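"""Readers/writers for the plain-text formats used across the package.

* trace CSV: header ``time_ms,ax1,ay1,ay2[,ax2]``, one row per sample,
  accelerations in g (float) or ADC counts (int); the unit is declared by
  the caller, not stored in the file;
* study directory: one trace CSV per activity plus ``manifest.csv``
  (``file,subject_id,set_id,activity_type,label``);
* threshold YAML (``E_vec_g``, ``strategy``, ``n_mode``);
* ROC CSVs and the sweep summary YAML.

Time is milliseconds everywhere externally; all numeric headers carry
units (``_ms``, ``_g``, ``_counts``).
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .learning import LearnedThreshold
from .roc import OptRegion, ROCSurface
from .signal import AccelSeries
from .study import ActivityRecord, LabeledStudy

__all__ = [
    "read_trace",
    "write_trace",
    "read_study",
    "write_study",
    "read_threshold",
    "write_threshold",
    "write_roc",
    "read_study_spec",
]

_COL_FOR_AXIS = {"x1": "ax1", "y1": "ay1", "y2": "ay2", "x2": "ax2"}
_AXIS_FOR_COL = {v: k for k, v in _COL_FOR_AXIS.items()}


class FormatError(ValueError):
    pass


def read_trace(path, unit: str = "g") -> AccelSeries:
    """Read a trace CSV; the time column must be uniform within 1%."""
    df = pd.read_csv(path)
    if "time_ms" not in df.columns:
        raise FormatError(f"{path}: missing 'time_ms' column")
    axis_cols = [c for c in ("ax1", "ay1", "ay2", "ax2") if c in df.columns]
    required = ("ax1", "ay1", "ay2")
    for c in required:
        if c not in df.columns:
            raise FormatError(f"{path}: missing required column '{c}'")
    if len(df) < 1:
        raise FormatError(f"{path}: empty trace")
    t = df["time_ms"].to_numpy(dtype=float)
    if len(t) > 1:
        dt = np.diff(t)
        t_s = float(np.median(dt))
        if t_s <= 0:
            raise FormatError(f"{path}: non-increasing time column")
        jitter = np.abs(dt - t_s) / t_s
        if np.any(jitter > 0.01):
            row = int(np.argmax(jitter > 0.01)) + 1
            raise FormatError(
                f"{path}: non-uniform time column at row {row} "
                f"(jitter {jitter.max():.1%} > 1%)"
            )
    else:
        t_s = 27.5
    data = df[axis_cols].to_numpy(dtype=float)
    axes = tuple(_AXIS_FOR_COL[c] for c in axis_cols)
    return AccelSeries(data, axes=axes, t_s=t_s, unit=unit, start_time=float(t[0]))


def write_trace(series: AccelSeries, path):
    cols = {"time_ms": series.times}
    for i, ax in enumerate(series.axes):
        cols[_COL_FOR_AXIS[ax]] = series.data[:, i]
    df = pd.DataFrame(cols)
    df.to_csv(path, index=False, float_format="%.9g")


def write_study(study: LabeledStudy, manifest, out_dir):
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for record, row in zip(study, manifest):
        write_trace(record.series, out / row["file"])
    pd.DataFrame(manifest).to_csv(out / "manifest.csv", index=False)


def read_study(study_dir, unit: str = "g") -> LabeledStudy:
    study_dir = Path(study_dir)
    mpath = study_dir / "manifest.csv"
    if not mpath.exists():
        raise FormatError(f"no manifest.csv in {study_dir}")
    manifest = pd.read_csv(mpath, dtype=str)
    required = {"file", "subject_id", "set_id", "activity_type", "label"}
    missing = required - set(manifest.columns)
    if missing:
        raise FormatError(f"{mpath}: manifest missing columns {sorted(missing)}")
    if len(manifest) == 0:
        raise FormatError(f"{mpath}: empty manifest")
    dup = manifest["file"][manifest["file"].duplicated()]
    if len(dup):
        raise FormatError(f"{mpath}: duplicate file entry {dup.iloc[0]!r}")
    records = []
    for _, row in manifest.iterrows():
        fpath = study_dir / row["file"]
        if not fpath.exists():
            raise FormatError(f"{mpath}: references missing file {row['file']!r}")
        series = read_trace(fpath, unit=unit)
        records.append(
            ActivityRecord(
                series=series,
                label=str(row["label"]),
                activity_type=str(row["activity_type"]),
                subject_id=str(row["subject_id"]),
                set_id=str(row["set_id"]),
                source=str(row["file"]),
            )
        )
    return LabeledStudy(records)


def write_threshold(threshold: LearnedThreshold, path):
    doc = {
        "E_vec_g": [float(v) for v in threshold.e_vec],
        "strategy": threshold.strategy,
        "n_mode": threshold.n_mode,
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def read_threshold(path) -> LearnedThreshold:
    doc = yaml.safe_load(Path(path).read_text())
    return LearnedThreshold(
        e_vec=np.asarray(doc["E_vec_g"], dtype=float),
        strategy=doc.get("strategy", "per_axis_max"),
        n_mode=doc.get("n_mode", "adaptive"),
    )


def write_roc(surface: ROCSurface, out_dir, region: OptRegion | None = None):
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    thr_cols = {
        f"thr_{name}_g": [p.thresholds[i] for p in surface.points]
        for i, name in enumerate(surface.param_names)
    }
    pd.DataFrame(
        {**thr_cols,
         "tpr": [p.tpr for p in surface.points],
         "fpr": [p.fpr for p in surface.points]}
    ).to_csv(out / "roc_points.csv", index=False, float_format="%.9g")
    pd.DataFrame(surface.envelope, columns=["fpr", "tpr"]).to_csv(
        out / "envelope.csv", index=False, float_format="%.9g"
    )
    summary = {
        "mode": surface.mode,
        "auc": float(surface.auc),
        "p": int(surface.p),
        "n": int(surface.n),
    }
    if region is not None:
        summary.update(
            {
                "alpha": float(region.alpha),
                "min_fpr_at_tpr1": float(region.min_fpr_at_tpr1)
                if np.isfinite(region.min_fpr_at_tpr1)
                else None,
                "ropt_empty": bool(region.empty),
                "robustness_g": {k: float(v) for k, v in region.robustness_g.items()},
                "robustness_counts": {
                    k: int(v) for k, v in region.robustness_counts.items()
                },
            }
        )
    (out / "summary.yaml").write_text(yaml.safe_dump(summary, sort_keys=False))
    return out


def read_study_spec(path):
    from .synthetic import StudySpec

    doc = yaml.safe_load(Path(path).read_text()) or {}
    return StudySpec(**doc)
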