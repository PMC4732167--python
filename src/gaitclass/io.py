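"""On-disk layout: one CSV per trial plus a JSON manifest.

Trial CSV columns (one row per sample)::

    shank_acc_vt, shank_acc_ap, shank_acc_ml,
    shank_gyro_vt, shank_gyro_ap, shank_gyro_ml,
    waist_acc_vt, waist_acc_ap, waist_acc_ml

Manifest JSON::

    {"fs": 128, "trials": [{"subject_id": ..., "trial_id": ..., "side": ...,
      "group_label": ..., "impaired_side": ..., "csv": "<relative path>",
      "events": {"fs_idx": [...], "to_idx": [...]}, "prefiltered": true}]}

Unless a trial is flagged ``prefiltered``, every signal column is passed
through the 5 Hz zero-phase low-pass filter on load.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .datamodel import (
    AXES,
    Dataset,
    GaitEvents,
    IMUTrial,
    ValidationError,
    lowpass_filter,
)

TRIAL_COLUMNS = tuple(
    f"{sensor}_{axis}" for sensor in ("shank_acc", "shank_gyro", "waist_acc") for axis in AXES
)


def _trial_to_frame(trial: IMUTrial) -> pd.DataFrame:
    data = np.hstack([trial.shank_acc, trial.shank_gyro, trial.waist_acc])
    return pd.DataFrame(data, columns=list(TRIAL_COLUMNS))


def save_dataset(dataset: Dataset, out_dir: str | Path) -> Path:
    """Write a dataset in the CSV + manifest layout; returns the manifest path.

    Signals are written as-is and flagged ``prefiltered`` so that a reload
    does not filter them a second time.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    fs = dataset.trials[0].fs if dataset.trials else None
    for trial in dataset.trials:
        rel = f"{trial.subject_id}_{trial.trial_id}_{trial.side}.csv"
        # %.17g guarantees an exact float64 round trip
        _trial_to_frame(trial).to_csv(out_dir / rel, index=False, float_format="%.17g")
        entries.append(
            {
                "subject_id": trial.subject_id,
                "trial_id": trial.trial_id,
                "side": trial.side,
                "group_label": trial.group_label,
                "impaired_side": trial.impaired_side,
                "csv": rel,
                "events": {
                    "fs_idx": list(trial.events.foot_strikes),
                    "to_idx": list(trial.events.toe_offs),
                },
                "prefiltered": True,
            }
        )
    manifest = out_dir / "manifest.json"
    manifest.write_text(json.dumps({"fs": fs, "trials": entries}, indent=1))
    return manifest


def load_dataset(manifest_path: str | Path) -> Dataset:
    """Load and validate a dataset from a JSON manifest.

    Raises :class:`ValidationError` naming the offending trial on any missing
    column, length mismatch or malformed event annotation.
    """
    manifest_path = Path(manifest_path)
    spec = json.loads(manifest_path.read_text())
    entries = spec.get("trials", [])
    if not entries:
        raise ValidationError("empty dataset: manifest lists no trials")
    fs = float(spec.get("fs", 128.0))
    root = manifest_path.parent
    trials = []
    for entry in entries:
        ctx = f"{entry.get('subject_id')}/{entry.get('trial_id')}/{entry.get('side')}"
        csv_path = root / entry["csv"]
        if not csv_path.exists():
            raise ValidationError(f"trial {ctx}: missing CSV file {csv_path}")
        frame = pd.read_csv(csv_path, float_precision="round_trip")
        missing = [c for c in TRIAL_COLUMNS if c not in frame.columns]
        if missing:
            raise ValidationError(f"trial {ctx}: missing columns {missing}")
        cols = {c: frame[c].to_numpy(dtype=float) for c in TRIAL_COLUMNS}
        if not entry.get("prefiltered", False):
            cols = {c: lowpass_filter(v, fs) for c, v in cols.items()}
        stack = lambda sensor: np.column_stack([cols[f"{sensor}_{ax}"] for ax in AXES])
        events = entry.get("events", {})
        trial = IMUTrial(
            subject_id=str(entry["subject_id"]),
            trial_id=str(entry["trial_id"]),
            side=entry["side"],
            fs=fs,
            shank_acc=stack("shank_acc"),
            shank_gyro=stack("shank_gyro"),
            waist_acc=stack("waist_acc"),
            events=GaitEvents(events.get("fs_idx", []), events.get("to_idx", [])),
            group_label=entry.get("group_label"),
            impaired_side=entry.get("impaired_side"),
        )
        trial.validate()
        trials.append(trial)
    dataset = Dataset(trials)
    dataset.validate()
    return dataset


def save_results(results, out_dir: str | Path) -> dict[str, Path]:
    """Write evaluation output: per-passage predictions (CSV), vote tallies
    (CSV) and confusion matrices with accuracies (JSON).

    ``results`` is an :class:`~gaitclass.evaluation.EvaluationResult`.
    Returns the paths written.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    pred_frames = []
    for stream, preds in results.predictions.items():
        frame = preds.copy()
        frame.insert(0, "stream", stream)
        pred_frames.append(frame)
    columns = ["stream", "subject_id", "trial_id", "side", "true_label", "predicted_label"]
    predictions = (
        pd.concat(pred_frames, ignore_index=True)
        if pred_frames
        else pd.DataFrame(columns=columns)
    )
    paths["predictions"] = out_dir / "predictions.csv"
    predictions.to_csv(paths["predictions"], index=False)

    if getattr(results, "tallies", None) is not None and len(results.tallies):
        paths["tallies"] = out_dir / "vote_tallies.csv"
        results.tallies.to_csv(paths["tallies"], index=False)

    report = {
        stream: cm.to_dict() for stream, cm in results.confusion_matrices.items()
    }
    if getattr(results, "subject_confusion_matrices", None):
        report_subject = {
            stream: cm.to_dict()
            for stream, cm in results.subject_confusion_matrices.items()
        }
    else:
        report_subject = {}
    paths["confusion"] = out_dir / "confusion_matrices.json"
    paths["confusion"].write_text(
        json.dumps(
            {"per_passage": report, "subject_level": report_subject}, indent=1
        )
    )
    return paths


def load_results(out_dir: str | Path) -> dict:
    """Reload what :func:`save_results` wrote (round-trip convenience)."""
    out_dir = Path(out_dir)
    out = {
        "predictions": pd.read_csv(out_dir / "predictions.csv"),
        "confusion": json.loads((out_dir / "confusion_matrices.json").read_text()),
    }
    tallies = out_dir / "vote_tallies.csv"
    if tallies.exists():
        out["tallies"] = pd.read_csv(tallies)
    return out
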