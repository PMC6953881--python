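"""CSV readers and writers for the pipeline's interchange formats.

All formats are plain headed CSV:

* raw recording — ``timestamp_iso8601,x_g,y_g,z_g``
* epoch series — ``timestamp,enmo_mg,wear,abnormal``
* day summary — ``subject_id,date,dow,wear_hours,overall_pa_mg,lpa_min,mvpa_bouted_min,valid``
* construct matrix (long) — ``subject_id,day_index,date,value``

A converter hook for proprietary device binaries: parse the binary with
vendor tooling into the raw-recording CSV schema above and the rest of the
pipeline applies unchanged.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .constructs import DAY_SUMMARY_COLUMNS, ConstructMatrix
from .errors import InputDataError
from .signal import EpochSeries, RawRecording

RAW_COLUMNS = ["timestamp_iso8601", "x_g", "y_g", "z_g"]
EPOCH_COLUMNS = ["timestamp", "enmo_mg", "wear", "abnormal"]

__all__ = [
    "write_raw_csv",
    "read_raw_csv",
    "write_epoch_csv",
    "read_epoch_csv",
    "write_day_summary_csv",
    "read_day_summary_csv",
    "write_construct_csv",
    "read_construct_csv",
]


def _check_columns(df: pd.DataFrame, required: list[str], what: str, path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise InputDataError(f"{what} {path}: missing columns {missing}")


def write_raw_csv(rec: RawRecording, path) -> None:
    df = pd.DataFrame(
        {
            "timestamp_iso8601": rec.sample_times().strftime("%Y-%m-%dT%H:%M:%S.%f"),
            "x_g": rec.x,
            "y_g": rec.y,
            "z_g": rec.z,
        }
    )
    df.to_csv(path, index=False, float_format="%.6f")


def read_raw_csv(path, subject_id: str | None = None) -> RawRecording:
    """Read a raw CSV; the sample rate is inferred from the median spacing."""
    try:
        df = pd.read_csv(path)
    except pd.errors.ParserError as exc:
        raise InputDataError(f"cannot parse raw CSV {path}: {exc}") from exc
    _check_columns(df, RAW_COLUMNS, "raw CSV", path)
    if len(df) < 2:
        raise InputDataError(f"raw CSV {path}: need at least 2 samples")
    ts = pd.to_datetime(df["timestamp_iso8601"])
    dt = np.median(np.diff(ts.to_numpy().astype("datetime64[ns]").astype(np.int64))) / 1e9
    if dt <= 0:
        raise InputDataError(f"raw CSV {path}: non-increasing timestamps")
    return RawRecording(
        subject_id=subject_id or Path(path).stem,
        sample_rate=1.0 / dt,
        start_time=ts.iloc[0],
        x=df["x_g"].to_numpy(),
        y=df["y_g"].to_numpy(),
        z=df["z_g"].to_numpy(),
    )


def write_epoch_csv(ep: EpochSeries, path) -> None:
    df = pd.DataFrame(
        {
            "timestamp": ep.epoch_times().strftime("%Y-%m-%dT%H:%M:%S"),
            "enmo_mg": ep.enmo,
            "wear": ep.wear.astype(int),
            "abnormal": ep.abnormal.astype(int),
        }
    )
    df.to_csv(path, index=False, float_format="%.4f")


def read_epoch_csv(path, subject_id: str | None = None) -> EpochSeries:
    try:
        df = pd.read_csv(path)
    except pd.errors.ParserError as exc:
        raise InputDataError(f"cannot parse epoch CSV {path}: {exc}") from exc
    _check_columns(df, EPOCH_COLUMNS, "epoch CSV", path)
    if len(df) < 2:
        raise InputDataError(f"epoch CSV {path}: need at least 2 epochs")
    ts = pd.to_datetime(df["timestamp"])
    epoch_len = (ts.iloc[1] - ts.iloc[0]).total_seconds()
    return EpochSeries(
        subject_id=subject_id or Path(path).stem,
        epoch_len=epoch_len,
        start_time=ts.iloc[0],
        enmo=df["enmo_mg"].to_numpy(),
        wear=df["wear"].to_numpy().astype(bool),
        abnormal=df["abnormal"].to_numpy().astype(bool),
    )


def write_day_summary_csv(days: pd.DataFrame, path) -> None:
    df = days.copy()
    df["date"] = pd.to_datetime(df["date"]).dt.strftime("%Y-%m-%d")
    df["valid"] = df["valid"].astype(int)
    df[DAY_SUMMARY_COLUMNS].to_csv(path, index=False, float_format="%.6f")


def read_day_summary_csv(path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path)
    except pd.errors.ParserError as exc:
        raise InputDataError(f"cannot parse day summary {path}: {exc}") from exc
    _check_columns(df, DAY_SUMMARY_COLUMNS, "day summary", path)
    df["date"] = pd.to_datetime(df["date"])
    df["valid"] = df["valid"].astype(bool)
    return df


def write_construct_csv(m: ConstructMatrix, path) -> None:
    long = m.to_long_frame()
    long["date"] = long["date"].dt.strftime("%Y-%m-%d")
    long.to_csv(path, index=False, float_format="%.6f")


def read_construct_csv(path, construct: str = "overall") -> ConstructMatrix:
    try:
        df = pd.read_csv(path)
    except pd.errors.ParserError as exc:
        raise InputDataError(f"cannot parse construct CSV {path}: {exc}") from exc
    _check_columns(df, ["subject_id", "day_index", "date", "value"], "construct CSV", path)
    df["date"] = pd.to_datetime(df["date"])
    pivot = df.pivot(index="subject_id", columns="day_index", values="value")
    if pivot.isna().any().any():
        raise InputDataError(f"construct CSV {path}: unbalanced matrix (missing cells)")
    dates = df.pivot(index="subject_id", columns="day_index", values="date")
    dates = dates.loc[pivot.index].to_numpy()
    dows = np.vectorize(lambda d: pd.Timestamp(d).isoweekday())(dates)
    return ConstructMatrix(
        construct=construct,
        subject_ids=pivot.index.to_numpy(),
        dates=dates,
        day_of_week=dows,
        values=pivot.to_numpy(),
    )
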