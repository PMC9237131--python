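"""Readers and writers for the on-disk CSV/JSON formats, plus run manifests.

Every written file starts with a format-version comment line
(``# glyforecast-format v1 <schema>``); readers reject unknown major
versions. Timestamps are ISO-8601 and timezone-naive; the 5-minute CGM grid
is the canonical clock, and CGM timestamps up to 30 s off-grid are snapped
to it.
"""
from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (Channel, CgmSeries, EventLog, GroundTruth,
                        WristbandStreams, GRID_STEP)

FORMAT_VERSION = 1
SNAP_TOLERANCE_S = 30.0


class DataFormatError(ValueError):
    """Malformed on-disk data (bad header, row, or timestamp order)."""


def _header(schema: str) -> str:
    return f"# glyforecast-format v{FORMAT_VERSION} {schema}\n"


def _check_header(path: Path, schema: str) -> None:
    with open(path) as fh:
        first = fh.readline()
    if not first.startswith("# glyforecast-format v"):
        raise DataFormatError(f"{path}: missing format-version header")
    try:
        major = int(first.split("-format v", 1)[1].split()[0])
    except (IndexError, ValueError) as exc:
        raise DataFormatError(f"{path}: unparseable format header") from exc
    if major != FORMAT_VERSION:
        raise DataFormatError(f"{path}: unsupported format version {major}")
    if schema not in first:
        raise DataFormatError(f"{path}: expected schema '{schema}'")


def _write_csv(path: Path, schema: str, frame: pd.DataFrame) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(_header(schema))
        frame.to_csv(fh, index=False)


def _read_csv(path: Path, schema: str) -> pd.DataFrame:
    _check_header(Path(path), schema)
    return pd.read_csv(path, comment="#")


# ---------------------------------------------------------------------------
# CGM
# ---------------------------------------------------------------------------

def write_cgm(path, cgm: CgmSeries) -> None:
    _write_csv(Path(path), "cgm", cgm.to_frame())


def read_cgm(path) -> CgmSeries:
    """Read a CGM CSV; timestamps within 30 s of the 5-min grid are snapped
    to it, duplicates and non-monotone timestamps are rejected."""
    df = _read_csv(Path(path), "cgm")
    if list(df.columns) != ["timestamp", "glucose_mgdl"]:
        raise DataFormatError(f"{path}: expected columns timestamp,glucose_mgdl")
    glucose = pd.to_numeric(df["glucose_mgdl"], errors="coerce")
    bad = glucose.isna() & df["glucose_mgdl"].notna()
    if bad.any():
        # +3: format header line + CSV header line + 1-based data row
        raise DataFormatError(
            f"{path}: unparseable glucose value at line {int(np.argmax(bad.to_numpy())) + 3}")
    times = pd.to_datetime(df["timestamp"])
    if times.duplicated().any():
        raise DataFormatError(f"{path}: duplicate timestamps")
    if not times.is_monotonic_increasing:
        raise DataFormatError(f"{path}: timestamps not monotonically increasing")
    # snap to the 5-min grid within tolerance
    snapped = times.dt.round(GRID_STEP)
    off = (times - snapped).dt.total_seconds().abs()
    if (off > SNAP_TOLERANCE_S).any():
        line = int(np.argmax((off > SNAP_TOLERANCE_S).to_numpy())) + 3
        raise DataFormatError(f"{path}: timestamp off-grid beyond 30 s at line {line}")
    # reindex onto the full grid (gaps -> NaN)
    grid = pd.date_range(snapped.iloc[0], snapped.iloc[-1], freq=GRID_STEP)
    s = pd.Series(glucose.to_numpy(), index=snapped).reindex(grid)
    return CgmSeries(grid, s.to_numpy())


# ---------------------------------------------------------------------------
# Events
# ---------------------------------------------------------------------------

def write_events(path, events: EventLog) -> None:
    _write_csv(Path(path), "events", events.frame)


def read_events(path) -> EventLog:
    df = _read_csv(Path(path), "events")
    if list(df.columns) != list(EventLog.COLUMNS):
        raise DataFormatError(f"{path}: expected columns {','.join(EventLog.COLUMNS)}")
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    try:
        df["value"] = pd.to_numeric(df["value"])
    except (ValueError, TypeError) as exc:
        raise DataFormatError(f"{path}: unparseable event value") from exc
    return EventLog(df)


# ---------------------------------------------------------------------------
# Wristband streams
# ---------------------------------------------------------------------------

def write_stream(path, channel: Channel, name: str) -> None:
    vals = channel.values
    if vals.ndim == 1:
        frame = pd.DataFrame({"t_s": channel.sample_times_s(), "value": vals})
    else:
        frame = pd.DataFrame({"t_s": channel.sample_times_s()})
        for i in range(vals.shape[1]):
            frame[f"value_{'xyz'[i] if vals.shape[1] == 3 else i}"] = vals[:, i]
    frame.insert(0, "start", "")
    frame.loc[0, "start"] = channel.start.isoformat()
    frame.insert(1, "fs_hz", "")
    frame.loc[0, "fs_hz"] = channel.fs
    _write_csv(Path(path), f"stream-{name}", frame)


def read_stream(path, name: str) -> Channel:
    df = _read_csv(Path(path), f"stream-{name}")
    start = pd.Timestamp(df.loc[0, "start"])
    fs = float(df.loc[0, "fs_hz"])
    value_cols = [c for c in df.columns if c.startswith("value")]
    vals = df[value_cols].to_numpy(float)
    if vals.shape[1] == 1:
        vals = vals[:, 0]
    return Channel(start, fs, vals)


def write_wristband(outdir, streams: WristbandStreams) -> None:
    outdir = Path(outdir)
    for name, ch in streams.channels().items():
        write_stream(outdir / f"{name}.csv", ch, name)


def read_wristband(indir) -> WristbandStreams:
    indir = Path(indir)
    return WristbandStreams(**{name: read_stream(indir / f"{name}.csv", name)
                               for name in ("bvp", "eda", "acc", "temp")})


# ---------------------------------------------------------------------------
# Ground truth / features / generic frames
# ---------------------------------------------------------------------------

def write_ground_truth(path, truth: GroundTruth) -> None:
    payload = {
        "format_version": FORMAT_VERSION,
        "beat_times": np.asarray(truth.beat_times).tolist(),
        "true_ibis": np.asarray(truth.true_ibis).tolist(),
        "scr_onsets": np.asarray(truth.scr_onsets).tolist(),
        "scr_amplitudes": np.asarray(truth.scr_amplitudes).tolist(),
        "event_windows": [(str(a), str(b), t) for a, b, t in truth.event_windows],
    }
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(json.dumps(payload))


def read_ground_truth(path) -> GroundTruth:
    payload = json.loads(Path(path).read_text())
    if int(payload.get("format_version", -1)) != FORMAT_VERSION:
        raise DataFormatError(f"{path}: unsupported format version")
    return GroundTruth(
        beat_times=np.asarray(payload["beat_times"]),
        true_ibis=np.asarray(payload["true_ibis"]),
        scr_onsets=np.asarray(payload["scr_onsets"]),
        scr_amplitudes=np.asarray(payload["scr_amplitudes"]),
        event_windows=[(pd.Timestamp(a), pd.Timestamp(b), t)
                       for a, b, t in payload["event_windows"]],
    )


def write_features(path, frame: pd.DataFrame) -> None:
    _write_csv(Path(path), "features", frame)


def read_features(path) -> pd.DataFrame:
    df = _read_csv(Path(path), "features")
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    return df


def write_predictions(path, frame: pd.DataFrame) -> None:
    _write_csv(Path(path), "predictions", frame)


def read_predictions(path) -> pd.DataFrame:
    df = _read_csv(Path(path), "predictions")
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    return df


# ---------------------------------------------------------------------------
# Run manifest
# ---------------------------------------------------------------------------

def file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


class RunManifest:
    """One manifest per CLI run: config hash, input hashes, seed, stage log."""

    def __init__(self, config_text: str, seed: int, version: str = "0.1.0"):
        self.payload = {
            "format_version": FORMAT_VERSION,
            "config_sha256": hashlib.sha256(config_text.encode()).hexdigest(),
            "seed": seed,
            "software_version": version,
            "inputs": {},
            "stages": [],
        }

    def add_input(self, path) -> None:
        self.payload["inputs"][str(path)] = file_sha256(path)

    def log_stage(self, name: str, **info) -> None:
        self.payload["stages"].append(
            {"stage": name, "timestamp": pd.Timestamp.now().isoformat(), **info})

    def write(self, path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        Path(path).write_text(json.dumps(self.payload, indent=2))


__all__ = [
    "DataFormatError", "RunManifest", "write_cgm", "read_cgm", "write_events",
    "read_events", "write_stream", "read_stream", "write_wristband",
    "read_wristband", "write_ground_truth", "read_ground_truth",
    "write_features", "read_features", "write_predictions", "read_predictions",
    "file_sha256", "FORMAT_VERSION",
]
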