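"""From photo frames to independent encounters and encounter rates.

Camera traps fire short bursts (here three frames retriggered at 1 s), so a
single pass of an animal through the detection zone produces a run of
closely spaced frames.  The pipeline is:

1. :func:`assemble_sequences` — merge frames at one station into picture
   sequences wherever successive gaps do not exceed ``max_gap_s``.
2. :func:`filter_independent` — apply the 30-minute independence rule per
   station (and species): a sequence is an independent encounter iff its
   start is at least ``window_min`` after the start of the last *retained*
   sequence.  A gap of exactly 30 min counts as independent.
3. :func:`encounter_rate` — Y/H with a design-based (station-level)
   bootstrap standard error.
4. :func:`rate_by_altitude` — station-level rates averaged within half-open
   500 m altitude bands.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .bootstrap import BootstrapConfig, bootstrap_se
from .errors import ValidationError

__all__ = ["assemble_sequences", "filter_independent", "encounter_rate",
           "rate_by_altitude", "EncounterSummary", "SEQUENCE_COLUMNS"]

SEQUENCE_COLUMNS = ["sequence_id", "station_id", "species", "t_start", "t_end",
                    "duration_s", "n_frames", "radial_distance_m",
                    "bearing_rad", "marker_distance_m", "reacted"]


def assemble_sequences(records: pd.DataFrame, max_gap_s: float = 120.0,
                       species: Optional[str] = None) -> pd.DataFrame:
    """Group frames into picture sequences.

    Frames at one station for one species whose successive gaps are
    ``<= max_gap_s`` belong to the same sequence.  The sequence inherits the
    first non-missing first-trigger position (``radial_distance_m``,
    ``bearing_rad``), the first non-missing ``marker_distance_m`` (the path
    length across the field of view) and a ``reacted`` flag that is true if
    any frame is flagged.

    Returns an empty, correctly typed frame for empty input.
    """
    if max_gap_s <= 0:
        raise ValueError(f"max_gap_s must be > 0, got {max_gap_s}")
    if species is not None:
        records = records[records["species"] == species]
    if len(records) == 0:
        return pd.DataFrame(columns=SEQUENCE_COLUMNS)

    rec = records.sort_values(["station_id", "species", "time"],
                              kind="mergesort").reset_index(drop=True)
    gap = rec.groupby(["station_id", "species"], sort=False)["time"].diff()
    new_seq = gap.isna() | (gap.dt.total_seconds() > max_gap_s)
    seq_id = new_seq.cumsum() - 1

    rec = rec.assign(_seq=seq_id)
    grouped = rec.groupby("_seq", sort=True)
    out = grouped.agg(
        station_id=("station_id", "first"),
        species=("species", "first"),
        t_start=("time", "first"),
        t_end=("time", "last"),
        n_frames=("time", "size"),
        radial_distance_m=("radial_distance_m", "first"),
        bearing_rad=("bearing_rad", "first"),
        marker_distance_m=("marker_distance_m", "first"),
        reacted=("reacted", "any"),
    ).reset_index(drop=True)
    # position fields: first non-null in the sequence, not merely first row
    firsts = grouped[["radial_distance_m", "bearing_rad",
                      "marker_distance_m"]].agg(
        lambda s: s.dropna().iloc[0] if s.notna().any() else np.nan)
    out[["radial_distance_m", "bearing_rad", "marker_distance_m"]] = \
        firsts.reset_index(drop=True)
    out["duration_s"] = (out["t_end"] - out["t_start"]).dt.total_seconds()
    out.insert(0, "sequence_id", np.arange(len(out)))
    return out[SEQUENCE_COLUMNS]


def filter_independent(sequences: pd.DataFrame,
                       window_min: float = 30.0) -> pd.DataFrame:
    """Mark independent encounters under the 30-minute rule.

    Greedy scan per (station, species) over start times: retain a sequence
    iff its start is ``>= window_min`` minutes after the start of the last
    retained one (the boundary itself counts as independent).  Returns a
    copy with a boolean ``independent`` column; the retained count is Y.
    Idempotent: filtering the retained set again retains everything.
    """
    if len(sequences) == 0:
        out = sequences.copy()
        out["independent"] = pd.Series(dtype=bool)
        return out
    seq = sequences.sort_values(["station_id", "species", "t_start"],
                                kind="mergesort")
    window = pd.Timedelta(minutes=window_min)
    independent = np.zeros(len(seq), dtype=bool)
    pos = 0
    for _, grp in seq.groupby(["station_id", "species"], sort=False):
        last_kept = None
        for t in grp["t_start"]:
            keep = last_kept is None or (t - last_kept) >= window
            independent[pos] = keep
            if keep:
                last_kept = t
            pos += 1
    out = seq.copy()
    out["independent"] = independent
    return out.sort_index()


@dataclass
class EncounterSummary:
    """Encounter rate Y/H with its station-bootstrap standard error."""

    Y: int
    H: float
    rate: float
    se_rate: float = 0.0
    var_rate: float = 0.0
    per_station_rates: pd.DataFrame = field(default_factory=pd.DataFrame)


def _station_effort(deployments: pd.DataFrame) -> pd.Series:
    if "camera_days" in deployments.columns:
        eff = deployments.set_index("station_id")["camera_days"]
    else:
        eff = ((deployments["end"] - deployments["start"])
               .dt.total_seconds() / 86400.0)
        eff.index = deployments["station_id"]
    if (eff <= 0).any():
        raise ValidationError("deployments with non-positive effort")
    return eff


def encounter_rate(encounters: pd.DataFrame, deployments: pd.DataFrame,
                   bootstrap: Optional[BootstrapConfig] = None
                   ) -> EncounterSummary:
    """Overall encounter rate Y/H per camera-day.

    Y counts rows flagged ``independent`` (all rows if the column is
    absent); H is the summed per-deployment effort in fractional
    camera-days.  The SE resamples *stations* with replacement and
    recomputes sum(Y*)/sum(H*), reflecting the design-based sampling unit.
    """
    effort = _station_effort(deployments)
    H = float(effort.sum())
    if H <= 0:
        raise ValidationError("total survey effort H must be > 0")
    if "independent" in encounters.columns:
        enc = encounters[encounters["independent"]]
    else:
        enc = encounters
    counts = enc.groupby("station_id").size().reindex(effort.index,
                                                      fill_value=0)
    Y = int(counts.sum())
    rate = Y / H
    per_station = pd.DataFrame({
        "station_id": effort.index,
        "Y": counts.values,
        "H": effort.values,
        "rate": counts.values / effort.values,
    }).reset_index(drop=True)

    se = var = 0.0
    if Y > 0 and bootstrap is not None and len(per_station) > 1:
        arr = per_station[["Y", "H"]].to_numpy(float)
        se, var = bootstrap_se(
            arr, lambda s: s[:, 0].sum() / s[:, 1].sum(), bootstrap)
    return EncounterSummary(Y=Y, H=H, rate=rate, se_rate=se, var_rate=var,
                            per_station_rates=per_station)


def rate_by_altitude(encounters: pd.DataFrame, deployments: pd.DataFrame,
                     bin_width_m: float = 500.0) -> pd.DataFrame:
    """Mean station-level encounter rate per half-open altitude band.

    Bands are ``[k*w, (k+1)*w)`` so a station at exactly 2000 m falls in
    the 2000–2500 band.  Stations without altitude are excluded with a
    warning.  Returns columns ``alt_lo, alt_hi, n_stations, rate, se``
    (SE = sd/sqrt(n) of station rates; 0 for singleton bands).
    """
    dep = deployments
    missing = dep["altitude_m"].isna()
    if missing.any():
        warnings.warn(
            f"excluding {int(missing.sum())} station(s) without altitude")
        dep = dep[~missing]
    summary = encounter_rate(encounters, dep, bootstrap=None)
    per = summary.per_station_rates.merge(
        dep[["station_id", "altitude_m"]], on="station_id")
    per["alt_lo"] = (np.floor(per["altitude_m"] / bin_width_m)
                     * bin_width_m)
    rows = []
    for lo, grp in per.groupby("alt_lo", sort=True):
        rates = grp["rate"].to_numpy()
        se = float(np.std(rates, ddof=1) / np.sqrt(len(rates))) \
            if len(rates) > 1 else 0.0
        rows.append({"alt_lo": float(lo), "alt_hi": float(lo) + bin_width_m,
                     "n_stations": len(rates),
                     "rate": float(rates.mean()), "se": se})
    return pd.DataFrame(rows, columns=["alt_lo", "alt_hi", "n_stations",
                                       "rate", "se"])
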