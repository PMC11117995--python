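"""Reading and writing the delimited-text formats used by the pipeline.

Two input tables drive everything:

``deployments.csv``
    ``station_id,x,y,altitude_m,start,end`` — one camera station per row,
    planar coordinates in metres, ISO-8601 timestamps.  The operational
    interval contributes ``(end - start)`` camera-days to the survey effort.

``records.csv``
    ``station_id,time,species,radial_distance_m,bearing_rad,marker_distance_m,reacted``
    — one photo frame per row.  Position fields are optional (empty cells);
    when present, ``radial_distance_m``/``bearing_rad`` give the animal's
    marker-calibrated position at first trigger and ``marker_distance_m`` the
    path length it covered across the field of view.
"""
from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = ["read_tables", "read_deployments", "read_records",
           "write_deployments", "write_records"]

DEPLOYMENT_COLUMNS = ["station_id", "x", "y", "altitude_m", "start", "end"]
RECORD_COLUMNS = ["station_id", "time", "species", "radial_distance_m",
                  "bearing_rad", "marker_distance_m", "reacted"]


def _require_columns(df: pd.DataFrame, required, what: str):
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{what}: missing column(s) {missing}")


def _parse_times(series: pd.Series, what: str) -> pd.Series:
    parsed = pd.to_datetime(series, errors="coerce", format="ISO8601")
    bad = parsed.isna() & series.notna()
    if bad.any():
        rows = list(series.index[bad])
        raise ValidationError(
            f"{what}: unparseable timestamp(s) at row(s) {rows[:10]}", rows=rows)
    return parsed


def read_deployments(path) -> pd.DataFrame:
    """Read and validate a deployment table.

    Adds a ``camera_days`` column (fractional days).  Raises
    :class:`ValidationError` on missing columns, bad timestamps, non-positive
    operational intervals or duplicated station ids.
    """
    df = pd.read_csv(path)
    _require_columns(df, DEPLOYMENT_COLUMNS, "deployments")
    df = df.copy()
    df["start"] = _parse_times(df["start"], "deployments.start")
    df["end"] = _parse_times(df["end"], "deployments.end")
    if df["station_id"].duplicated().any():
        dupes = df.loc[df["station_id"].duplicated(), "station_id"].tolist()
        raise ValidationError(f"deployments: duplicate station_id(s) {dupes}")
    span = (df["end"] - df["start"]).dt.total_seconds() / 86400.0
    bad = span <= 0
    if bad.any():
        raise ValidationError(
            f"deployments: end <= start at row(s) {list(df.index[bad])}",
            rows=list(df.index[bad]))
    df["camera_days"] = span
    return df


def read_records(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, RECORD_COLUMNS, "records")
    df = df.copy()
    df["time"] = _parse_times(df["time"], "records.time")
    for col in ("radial_distance_m", "bearing_rad", "marker_distance_m"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    df["reacted"] = df["reacted"].fillna(False).astype(bool)
    neg = df["radial_distance_m"] < 0
    if neg.any():
        raise ValidationError(
            f"records: negative radial_distance_m at row(s) {list(df.index[neg])}",
            rows=list(df.index[neg]))
    oob = df["bearing_rad"].abs() > np.pi
    if oob.any():
        raise ValidationError(
            f"records: bearing_rad outside [-pi, pi] at row(s) {list(df.index[oob])}",
            rows=list(df.index[oob]))
    return df


def read_tables(deployments_path, records_path, invalid: str = "raise"):
    """Read both tables and cross-validate records against deployments.

    Every record must name a known station and fall inside that station's
    operational interval.  With ``invalid="raise"`` (default) any violation
    raises :class:`ValidationError` naming the offending rows; with
    ``invalid="drop"`` out-of-interval records are dropped with a warning
    (unknown stations always raise).

    Returns ``(deployments, records)`` DataFrames.
    """
    if invalid not in ("raise", "drop"):
        raise ValueError(f"invalid must be 'raise' or 'drop', got {invalid!r}")
    dep = read_deployments(deployments_path)
    rec = read_records(records_path)

    known = set(dep["station_id"])
    unknown = ~rec["station_id"].isin(known)
    if unknown.any():
        raise ValidationError(
            "records: unknown station_id(s) "
            f"{sorted(rec.loc[unknown, 'station_id'].unique())} "
            f"at row(s) {list(rec.index[unknown])[:10]}",
            rows=list(rec.index[unknown]))

    interval = dep.set_index("station_id")[["start", "end"]]
    start = rec["station_id"].map(interval["start"])
    end = rec["station_id"].map(interval["end"])
    outside = (rec["time"] < start) | (rec["time"] > end)
    if outside.any():
        rows = list(rec.index[outside])
        if invalid == "raise":
            raise ValidationError(
                f"records: timestamp outside deployment interval at row(s) "
                f"{rows[:10]}", rows=rows)
        warnings.warn(f"dropping {len(rows)} record(s) outside deployment "
                      f"intervals (rows {rows[:10]}...)")
        rec = rec.loc[~outside].reset_index(drop=True)
    return dep, rec


def _iso(ts: pd.Series) -> pd.Series:
    return ts.dt.strftime("%Y-%m-%dT%H:%M:%S.%f")


def write_deployments(df: pd.DataFrame, path):
    out = df[DEPLOYMENT_COLUMNS].copy()
    out["start"] = _iso(out["start"])
    out["end"] = _iso(out["end"])
    out.to_csv(path, index=False)


def write_records(df: pd.DataFrame, path):
    out = df[RECORD_COLUMNS].copy()
    out["time"] = _iso(out["time"])
    out.to_csv(path, index=False)
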