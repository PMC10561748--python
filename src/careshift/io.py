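"""Readers and writers for the delimited trial streams.

All streams are plain delimited text with explicit unit-bearing headers —
the original hardware logged serial streams, and text keeps fixtures
diffable.  The time column is stored explicitly (never inferred) so the
three native rates (62 / 120 / 600 Hz) stay unambiguous; every writer/reader
pair round-trips its own output bit-exactly (%.17g float formatting).

Formats
-------
counts.csv : ``time_s,ch01,...,chNN`` — one row per 62 Hz sample
cop.csv    : ``time_s,cop_x_mm,cop_y_mm`` — 600 Hz force-plate CoP
marker.csv : ``time_s,z_mm`` — 120 Hz head-marker height
truth.json : simulator ground truth for round-trip tests
"""

from __future__ import annotations

import json
import re
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParseError
from .seatpos import CountSeries
from .simulator import TrialRecording, TrialTruth
from .validate import CoPSeries, MarkerTrajectory

_FLOAT_FMT = "%.17g"
_TIME_COL = "time_s"
_CHAN_RE = re.compile(r"^ch(\d+)$")


def _read_csv(path) -> pd.DataFrame:
    try:
        # round_trip parsing so read(write(x)) is bit-exact
        return pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:
        raise ParseError(f"{path}: cannot parse ({exc})") from exc


def _infer_fs(t: np.ndarray, path) -> float:
    if t.size < 2:
        raise ParseError(f"{path}: need at least 2 samples")
    dt = np.diff(t)
    if np.any(dt <= 0) or np.ptp(dt) > 1e-6:
        bad = int(np.argmax(np.abs(dt - np.median(dt))))
        raise ParseError(
            f"{path}: non-uniform timestamps near row {bad + 2} "
            f"(dt {dt[bad]:.9f} s vs median {np.median(dt):.9f} s)"
        )
    fs = 1.0 / float(np.median(dt))
    return float(round(fs)) if abs(fs - round(fs)) < 1e-3 else fs


def write_counts(series: CountSeries, path) -> None:
    cols = {_TIME_COL: series.t}
    for i in range(series.n_channels):
        cols[f"ch{i + 1:02d}"] = series.counts[:, i]
    pd.DataFrame(cols).to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_counts(path) -> CountSeries:
    """Parse a counts.csv.  Channel columns are mapped by header name, so
    any column order is accepted; channel numbers must be contiguous from 1.
    """
    df = _read_csv(path)
    if _TIME_COL not in df.columns:
        raise ParseError(f"{path}: missing '{_TIME_COL}' column")
    chans = {}
    for col in df.columns:
        m = _CHAN_RE.match(col)
        if m:
            chans[int(m.group(1))] = col
    if not chans:
        raise ParseError(f"{path}: no channel columns (chNN) found")
    expected = set(range(1, len(chans) + 1))
    if set(chans) != expected:
        missing = sorted(expected - set(chans))
        raise ParseError(f"{path}: missing channel column(s) {missing}")
    t = df[_TIME_COL].to_numpy(dtype=float)
    counts = df[[chans[i] for i in sorted(chans)]].to_numpy(dtype=float)
    if np.any(counts < 0):
        row, col = np.argwhere(counts < 0)[0]
        raise ParseError(
            f"{path}: negative count at row {row + 2}, column {chans[col + 1]}"
        )
    return CountSeries(fs=_infer_fs(t, path), t=t, counts=counts)


def write_cop(series: CoPSeries, path) -> None:
    pd.DataFrame(
        {_TIME_COL: series.t, "cop_x_mm": series.cop_x, "cop_y_mm": series.cop_y}
    ).to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_cop(path) -> CoPSeries:
    df = _read_csv(path)
    for col in (_TIME_COL, "cop_x_mm", "cop_y_mm"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing '{col}' column")
    t = df[_TIME_COL].to_numpy(dtype=float)
    return CoPSeries(
        fs=_infer_fs(t, path),
        t=t,
        cop_x=df["cop_x_mm"].to_numpy(dtype=float),
        cop_y=df["cop_y_mm"].to_numpy(dtype=float),
    )


def write_marker(series: MarkerTrajectory, path) -> None:
    pd.DataFrame({_TIME_COL: series.t, "z_mm": series.z}).to_csv(
        path, index=False, float_format=_FLOAT_FMT
    )


def read_marker(path) -> MarkerTrajectory:
    df = _read_csv(path)
    for col in (_TIME_COL, "z_mm"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing '{col}' column")
    t = df[_TIME_COL].to_numpy(dtype=float)
    return MarkerTrajectory(fs=_infer_fs(t, path), t=t, z=df["z_mm"].to_numpy(dtype=float))


def write_truth(truth: TrialTruth, path) -> None:
    with open(path, "w") as fh:
        json.dump(
            {
                "seat_offset": list(truth.seat_offset),
                "descent_velocity": truth.descent_velocity,
                "contact_time": truth.contact_time,
                "head_peak_velocity": truth.head_peak_velocity,
                "designed_delta_cop": list(truth.designed_delta_cop),
            },
            fh,
            indent=2,
        )
        fh.write("\n")


def read_truth(path) -> TrialTruth:
    with open(path) as fh:
        data = json.load(fh)
    try:
        return TrialTruth(
            seat_offset=tuple(data["seat_offset"]),
            descent_velocity=float(data["descent_velocity"]),
            contact_time=float(data["contact_time"]),
            head_peak_velocity=float(data["head_peak_velocity"]),
            designed_delta_cop=tuple(data["designed_delta_cop"]),
        )
    except KeyError as exc:
        raise ParseError(f"{path}: missing truth field {exc}") from exc


def write_trial(recording: TrialRecording, out_dir) -> dict:
    """Write counts.csv, cop.csv, marker.csv and truth.json into a directory.

    Returns the path map for convenience.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": out / "counts.csv",
        "cop": out / "cop.csv",
        "marker": out / "marker.csv",
        "truth": out / "truth.json",
    }
    write_counts(recording.counts, paths["counts"])
    write_cop(recording.cop, paths["cop"])
    write_marker(recording.marker, paths["marker"])
    write_truth(recording.truth, paths["truth"])
    return {k: str(v) for k, v in paths.items()}


def read_trial(trial_dir) -> TrialRecording:
    d = Path(trial_dir)
    truth_path = d / "truth.json"
    return TrialRecording(
        counts=read_counts(d / "counts.csv"),
        cop=read_cop(d / "cop.csv"),
        marker=read_marker(d / "marker.csv"),
        truth=read_truth(truth_path) if truth_path.exists() else None,
    )
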