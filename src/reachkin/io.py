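"""File interfaces: long-format trial CSVs and clinical-score tables.

Trial CSV schema (long format, cm / s):
    subject, session, arm, side, target, frame, time_s, marker, x_cm, y_cm, z_cm

Marker labels may use the anatomical aliases in
``reachkin.markers.MARKER_ALIASES``.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import ParseError, SchemaError
from .markers import REQUIRED_MARKERS, canonical_label
from .simulate import SimConfig, SimGroundTruth, TrialRecording
from .stats import validate_clinical

TRIAL_COLUMNS = (
    "subject", "session", "arm", "side", "target",
    "frame", "time_s", "marker", "x_cm", "y_cm", "z_cm",
)


def trial_to_frame(rec: TrialRecording) -> pd.DataFrame:
    """Flatten one recording to the long CSV schema."""
    n = rec.n_frames
    frames = np.arange(n)
    parts = []
    for label in sorted(rec.markers):
        pos = rec.markers[label]
        parts.append(
            pd.DataFrame(
                {
                    "subject": rec.subject_id,
                    "session": rec.session,
                    "arm": rec.arm,
                    "side": rec.side,
                    "target": rec.target_index,
                    "frame": frames,
                    "time_s": rec.times,
                    "marker": label,
                    "x_cm": pos[:, 0],
                    "y_cm": pos[:, 1],
                    "z_cm": pos[:, 2],
                }
            )
        )
    return pd.concat(parts, ignore_index=True)


def write_trials_csv(
    recordings: Iterable[TrialRecording], path: str | Path
) -> None:
    """Write recordings to one long-format CSV."""
    frames = [trial_to_frame(rec) for rec in recordings]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.6f")


def read_markers(path: str | Path, dialect: str = "csv_long") -> list[TrialRecording]:
    """Read trial recordings from a long-format CSV.

    ``dialect='c3d'`` is not supported by this build; convert C3D exports
    to the documented CSV schema upstream.
    """
    if dialect == "c3d":
        raise SchemaError(
            "C3D ingestion is not available in this build; export trials "
            "to the long-format CSV schema instead"
        )
    if dialect != "csv_long":
        raise SchemaError(f"unknown dialect {dialect!r}")
    path = Path(path)
    df = pd.read_csv(path)
    missing = set(TRIAL_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(
            f"{path.name}: missing columns {sorted(missing)}"
        )
    df["marker"] = df["marker"].map(canonical_label)

    recordings = []
    keys = ["subject", "session", "arm", "side", "target"]
    for key, group in df.groupby(keys, sort=True):
        subject, session, arm, side, target = key
        dup = group.duplicated(subset=["frame", "marker"])
        if dup.any():
            row = group[dup].iloc[0]
            raise ParseError(
                f"{path.name}: duplicated frame index {int(row['frame'])} "
                f"for marker {row['marker']} (trial {key})"
            )
        labels = sorted(group["marker"].unique())
        absent = sorted(set(REQUIRED_MARKERS) - set(labels))
        if absent:
            raise SchemaError(
                f"{path.name}: trial {key} misses required markers {absent}"
            )
        pivot = group.pivot(
            index="frame", columns="marker", values=["x_cm", "y_cm", "z_cm"]
        ).sort_index()
        times = (
            group.drop_duplicates("frame").set_index("frame")["time_s"].sort_index()
        )
        dt = np.diff(times.to_numpy())
        if times.size > 1 and (dt <= 0).any():
            raise ParseError(f"{path.name}: frame times not increasing (trial {key})")
        sample_rate = 1.0 / float(np.median(dt)) if times.size > 1 else 120.0
        markers = {
            label: np.column_stack(
                [pivot[("x_cm", label)], pivot[("y_cm", label)], pivot[("z_cm", label)]]
            )
            for label in labels
        }
        for label, pos in markers.items():
            if not np.isfinite(pos).all() and label in REQUIRED_MARKERS:
                bad = ~np.isfinite(pos).all(axis=1)
                if bad.all():
                    raise ParseError(
                        f"{path.name}: marker {label} has no finite frames"
                    )
        recordings.append(
            TrialRecording(
                subject_id=str(subject),
                session=str(session),
                arm=str(arm),
                side=str(side),
                target_index=int(target),
                sample_rate=round(sample_rate, 6),
                times=times.to_numpy(),
                markers=markers,
            )
        )
    return recordings


def read_clinical(path: str | Path) -> pd.DataFrame:
    """Read and validate a clinical-scores CSV (one row per subject-session)."""
    df = pd.read_csv(path)
    if "subject_id" not in df.columns and "subject" in df.columns:
        df = df.rename(columns={"subject": "subject_id"})
    try:
        return validate_clinical(df)
    except Exception as exc:  # re-tag for callers distinguishing file errors
        raise SchemaError(f"{Path(path).name}: {exc}") from exc


def write_ground_truth_json(
    path: str | Path,
    config: SimConfig,
    truths: dict[str, SimGroundTruth],
) -> None:
    """Sidecar JSON with the generating config and per-trial ground truth."""
    payload = {
        "config": asdict(config),
        "ground_truth": {k: asdict(v) for k, v in truths.items()},
    }
    Path(path).write_text(json.dumps(payload, indent=2, default=float))
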