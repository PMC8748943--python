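"""Plain-text I/O: event tables, R-peak tables and ECG traces as CSV.

All tables are ordinary CSV so the pipeline's intermediates stay inspectable.
An ECG trace is a two-column (time_s, voltage) or four-column
(time_s, ch1, ch2, ch3) CSV with a JSON sidecar (same path + ``.json``)
recording the sampling rate and optional ground-truth file paths.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .ecg import ECGRecording, RPeakTrain
from .errors import SchemaError

__all__ = [
    "EVENT_COLUMNS",
    "ROLES",
    "write_events_csv",
    "read_events_csv",
    "write_rpeaks_csv",
    "read_rpeaks_csv",
    "write_ecg_csv",
    "read_ecg_csv",
]

EVENT_COLUMNS = ["dyad_id", "subject_id", "block", "trial", "role", "event_time_ms"]
ROLES = ("execution", "observation")


def write_events_csv(events: pd.DataFrame, path) -> None:
    missing = [c for c in EVENT_COLUMNS if c not in events.columns]
    if missing:
        raise SchemaError(f"event table lacks columns {missing}")
    events.loc[:, EVENT_COLUMNS].to_csv(path, index=False)


def read_events_csv(path) -> pd.DataFrame:
    """Read and validate an event table; errors name file, row and column."""
    path = Path(path)
    df = pd.read_csv(path)
    for col in EVENT_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing column {col!r}")
    bad_role = ~df["role"].isin(ROLES)
    if bad_role.any():
        row = int(df.index[bad_role][0])
        raise SchemaError(
            f"{path}: row {row}, column 'role': invalid value {df.loc[row, 'role']!r} "
            f"(expected one of {ROLES})"
        )
    if df["event_time_ms"].isna().any() or (df["event_time_ms"] <= 0).any():
        row = int(df.index[df["event_time_ms"].isna() | (df["event_time_ms"] <= 0)][0])
        raise SchemaError(f"{path}: row {row}, column 'event_time_ms': non-positive or missing")
    for (dyad, subj, block, role), g in df.groupby(["dyad_id", "subject_id", "block", "role"]):
        t = g["event_time_ms"].to_numpy()
        if t.size >= 2 and not np.all(np.diff(t) > 0):
            row = int(g.index[np.flatnonzero(np.diff(t) <= 0)[0] + 1])
            raise SchemaError(
                f"{path}: row {row}, column 'event_time_ms': timestamps not strictly "
                f"increasing within dyad {dyad}, subject {subj}, block {block}, role {role}"
            )
    df["event_time_ms"] = df["event_time_ms"].astype(np.int64)
    return df


def write_rpeaks_csv(trains: dict, path) -> None:
    """Write {subject_id: RPeakTrain} to a long CSV (subject_id, rpeak_time_ms)."""
    rows = []
    for subject in sorted(trains):
        for t in trains[subject].times:
            rows.append((subject, int(t)))
    pd.DataFrame(rows, columns=["subject_id", "rpeak_time_ms"]).to_csv(path, index=False)


def read_rpeaks_csv(path) -> dict:
    path = Path(path)
    df = pd.read_csv(path)
    for col in ("subject_id", "rpeak_time_ms"):
        if col not in df.columns:
            raise SchemaError(f"{path}: missing column {col!r}")
    trains = {}
    for subject, g in df.groupby("subject_id"):
        t = g["rpeak_time_ms"].to_numpy(dtype=np.int64)
        if t.size >= 2 and not np.all(np.diff(t) > 0):
            row = int(g.index[np.flatnonzero(np.diff(t) <= 0)[0] + 1])
            raise SchemaError(
                f"{path}: row {row}, column 'rpeak_time_ms': not strictly increasing "
                f"for subject {subject}"
            )
        trains[subject] = RPeakTrain(t, subject=subject)
    return trains


def write_ecg_csv(rec: ECGRecording, path, extra_sidecar: dict | None = None) -> None:
    path = Path(path)
    t_s = rec.times_ms() / 1000.0
    if rec.n_channels == 1:
        df = pd.DataFrame({"time_s": t_s, "voltage": rec.channel(0)})
    else:
        cols = {"time_s": t_s}
        for i in range(rec.n_channels):
            cols[f"ch{i + 1}"] = rec.channel(i)
        df = pd.DataFrame(cols)
    df.to_csv(path, index=False)
    sidecar = {"fs": rec.fs, "t0_ms": rec.t0, "n_channels": rec.n_channels}
    if extra_sidecar:
        sidecar.update(extra_sidecar)
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=2, sort_keys=True))


def read_ecg_csv(path) -> ECGRecording:
    path = Path(path)
    sidecar_path = Path(str(path) + ".json")
    df = pd.read_csv(path)
    if "time_s" not in df.columns:
        raise SchemaError(f"{path}: missing column 'time_s'")
    channels = [c for c in df.columns if c != "time_s"]
    if not channels:
        raise SchemaError(f"{path}: no voltage columns found")
    if sidecar_path.exists():
        sidecar = json.loads(sidecar_path.read_text())
        fs = float(sidecar["fs"])
        t0 = float(sidecar.get("t0_ms", df["time_s"].iloc[0] * 1000.0))
    else:
        dt = np.diff(df["time_s"].to_numpy())
        fs = 1.0 / float(np.median(dt))
        t0 = float(df["time_s"].iloc[0] * 1000.0)
    data = df[channels].to_numpy()
    if data.shape[1] == 1:
        data = data[:, 0]
    return ECGRecording(data, fs, t0=t0)
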