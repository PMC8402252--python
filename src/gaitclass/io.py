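"""File formats: recording CSV, BVH, cohort manifests, feature tables.

The native dialect is a per-recording CSV with a ``time_s`` column and one
``<joint>_x/_y/_z`` triple per canonical joint (metres, SI units, comma
separated, locale-independent).  A minimal BVH writer/reader is provided
for interoperability testing: the skeleton is a flat pelvis-rooted
hierarchy whose joints carry translation channels only (world-space
positions, metres).  The reader validates rather than repairs: malformed
headers, missing joints or non-monotone time raise parse errors with line
numbers.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .features import FEATURE_COLUMNS, META_COLUMNS
from .synthetic import CANONICAL_JOINTS, GroundTruth, MotionRecording

__all__ = [
    "RecordingParseError",
    "write_recording",
    "read_recording",
    "write_cohort",
    "read_cohort",
    "write_ground_truth",
    "read_ground_truth",
    "write_features",
    "read_features",
    "write_segment_manifest",
]


class RecordingParseError(ValueError):
    """A recording file violates the expected dialect."""


# ---------------------------------------------------------------------------
# recording CSV

def write_recording(recording: MotionRecording, path: str | Path) -> Path:
    """Write a recording as CSV: time_s, then <joint>_x/_y/_z per joint."""
    path = Path(path)
    n = recording.n_samples
    data = {"time_s": np.arange(n) / recording.sampling_rate}
    for joint in CANONICAL_JOINTS:
        pos = recording.joints[joint]
        for k, axis in enumerate("xyz"):
            data[f"{joint}_{axis}"] = pos[:, k]
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.9f")
    return path


def _infer_rate(time_s: np.ndarray, path: Path) -> int:
    dt = np.diff(time_s)
    if len(dt) == 0 or np.any(dt <= 0):
        bad = int(np.argmax(dt <= 0)) + 2 if len(dt) else 1
        raise RecordingParseError(f"{path}: non-monotone time at line {bad + 1}")
    rate = round(1.0 / float(np.median(dt)))
    if rate not in (60, 120):
        raise RecordingParseError(
            f"{path}: sampling rate {rate} Hz not in {{60, 120}}"
        )
    return rate


def _read_recording_csv(
    path: Path, participant_id: str, label: str, severity: float
) -> MotionRecording:
    df = pd.read_csv(path)
    if "time_s" not in df.columns:
        raise RecordingParseError(f"{path}: missing 'time_s' column (line 1)")
    joints = {}
    for joint in CANONICAL_JOINTS:
        cols = [f"{joint}_{axis}" for axis in "xyz"]
        missing = [c for c in cols if c not in df.columns]
        if missing:
            raise RecordingParseError(
                f"{path}: missing joint column(s) {missing} (line 1)"
            )
        joints[joint] = df[cols].to_numpy(dtype=float)
    rate = _infer_rate(df["time_s"].to_numpy(dtype=float), path)
    return MotionRecording(
        participant_id=participant_id,
        label=label,
        severity=severity,
        sampling_rate=rate,
        joints=joints,
    )


# ---------------------------------------------------------------------------
# BVH (flat hierarchy, translation channels, world-space metres)

_BVH_JOINT_MAP = {
    "Hips": "pelvis",
    "LeftFoot": "left_foot",
    "RightFoot": "right_foot",
}


def write_recording_bvh(recording: MotionRecording, path: str | Path) -> Path:
    path = Path(path)
    n = recording.n_samples
    lines = [
        "HIERARCHY",
        "ROOT Hips",
        "{",
        "  OFFSET 0.0 0.0 0.0",
        "  CHANNELS 3 Xposition Yposition Zposition",
    ]
    for child in ("LeftFoot", "RightFoot"):
        lines += [
            f"  JOINT {child}",
            "  {",
            "    OFFSET 0.0 0.0 0.0",
            "    CHANNELS 3 Xposition Yposition Zposition",
            "    End Site",
            "    {",
            "      OFFSET 0.0 0.0 0.0",
            "    }",
            "  }",
        ]
    lines += [
        "}",
        "MOTION",
        f"Frames: {n}",
        f"Frame Time: {1.0 / recording.sampling_rate:.8f}",
    ]
    order = ["pelvis", "left_foot", "right_foot"]
    frames = np.hstack([recording.joints[j] for j in order])
    for row in frames:
        lines.append(" ".join(f"{v:.9f}" for v in row))
    path.write_text("\n".join(lines) + "\n")
    return path


def _read_recording_bvh(
    path: Path, participant_id: str, label: str, severity: float
) -> MotionRecording:
    lines = path.read_text().splitlines()
    joint_order: list[str] = []
    n_frames = None
    frame_time = None
    motion_start = None
    for i, raw in enumerate(lines):
        line = raw.strip()
        if line.startswith(("ROOT", "JOINT")):
            name = line.split()[1]
            if name not in _BVH_JOINT_MAP:
                raise RecordingParseError(
                    f"{path}: unmapped BVH joint {name!r} at line {i + 1}"
                )
            joint_order.append(_BVH_JOINT_MAP[name])
        elif line.startswith("CHANNELS"):
            parts = line.split()
            if parts[1] != "3" or parts[2:] != ["Xposition", "Yposition", "Zposition"]:
                raise RecordingParseError(
                    f"{path}: only 3 position channels supported (line {i + 1})"
                )
        elif line.startswith("Frames:"):
            n_frames = int(line.split(":")[1])
        elif line.startswith("Frame Time:"):
            frame_time = float(line.split(":")[1])
            motion_start = i + 1
            break
    if n_frames is None or frame_time is None or motion_start is None:
        raise RecordingParseError(f"{path}: missing MOTION header")
    missing = set(CANONICAL_JOINTS) - set(joint_order)
    if missing:
        raise RecordingParseError(f"{path}: missing joints {sorted(missing)}")
    rate = round(1.0 / frame_time)
    if rate not in (60, 120):
        raise RecordingParseError(f"{path}: frame rate {rate} Hz not in {{60, 120}}")
    rows = []
    for i, raw in enumerate(lines[motion_start : motion_start + n_frames]):
        values = raw.split()
        if len(values) != 3 * len(joint_order):
            raise RecordingParseError(
                f"{path}: bad frame at line {motion_start + i + 1}"
            )
        rows.append([float(v) for v in values])
    frames = np.asarray(rows)
    if len(frames) != n_frames:
        raise RecordingParseError(f"{path}: frame count mismatch")
    joints = {
        joint: frames[:, 3 * k : 3 * k + 3] for k, joint in enumerate(joint_order)
    }
    return MotionRecording(
        participant_id=participant_id,
        label=label,
        severity=severity,
        sampling_rate=rate,
        joints=joints,
    )


def read_recording(
    path: str | Path,
    dialect: str = "csv",
    participant_id: str = "unknown",
    label: str = "healthy",
    severity: float = 0.0,
) -> MotionRecording:
    """Read one recording; ``dialect`` is ``csv`` or ``bvh``."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "csv":
        return _read_recording_csv(path, participant_id, label, severity)
    if dialect == "bvh":
        return _read_recording_bvh(path, participant_id, label, severity)
    raise ValueError(f"unknown dialect {dialect!r}; choose 'csv' or 'bvh'")


# ---------------------------------------------------------------------------
# cohort manifest + ground truth

def write_ground_truth(truth: GroundTruth, path: str | Path) -> Path:
    path = Path(path)
    payload = {
        "contact_times": {k: v.tolist() for k, v in truth.contact_times.items()},
        "turn_intervals": [list(t) for t in truth.turn_intervals],
        "per_step_lengths": truth.per_step_lengths.tolist(),
    }
    path.write_text(json.dumps(payload))
    return path


def read_ground_truth(path: str | Path) -> GroundTruth:
    payload = json.loads(Path(path).read_text())
    return GroundTruth(
        contact_times={
            k: np.asarray(v, dtype=int) for k, v in payload["contact_times"].items()
        },
        turn_intervals=[tuple(t) for t in payload["turn_intervals"]],
        per_step_lengths=np.asarray(payload["per_step_lengths"]),
    )


def write_cohort(
    cohort: list[tuple[MotionRecording, GroundTruth]], out_dir: str | Path
) -> Path:
    """Write per-recording CSVs, ground-truth JSONs and a manifest CSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for recording, truth in cohort:
        stem = recording.participant_id
        write_recording(recording, out_dir / f"{stem}.csv")
        write_ground_truth(truth, out_dir / f"{stem}_truth.json")
        rows.append(
            {
                "participant_id": recording.participant_id,
                "label": recording.label,
                "severity": recording.severity,
                "file": f"{stem}.csv",
                "sampling_rate": recording.sampling_rate,
            }
        )
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def read_cohort(manifest_path: str | Path) -> list[tuple[MotionRecording, GroundTruth | None]]:
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    table = pd.read_csv(manifest_path)
    cohort = []
    for _, row in table.iterrows():
        rec = read_recording(
            base / row["file"],
            dialect="csv",
            participant_id=row["participant_id"],
            label=row["label"],
            severity=float(row["severity"]),
        )
        truth_path = base / f"{Path(row['file']).stem}_truth.json"
        truth = read_ground_truth(truth_path) if truth_path.exists() else None
        cohort.append((rec, truth))
    return cohort


# ---------------------------------------------------------------------------
# feature + segment tables

def write_features(table: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    cols = [c for c in META_COLUMNS + FEATURE_COLUMNS if c in table.columns]
    extra = [c for c in table.columns if c not in cols]
    table[cols + extra].to_csv(path, index=False, float_format="%.9f")
    return path


def read_features(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_segment_manifest(segments, path: str | Path) -> Path:
    path = Path(path)
    rows = [
        {
            "participant_id": seg.participant_id,
            "segment_id": i,
            "start_sample": seg.start,
            "end_sample": seg.end,
            "n_contacts": seg.contacts.n_total,
        }
        for i, seg in enumerate(segments)
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
    return path
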