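import numpy as np
import pandas as pd
import pytest

from remcam import SimTruth, simulate


def make_deployments(n=2, camera_days=10.0, altitude=2100.0,
                     start="2020-10-01T00:00:00"):
    start = pd.Timestamp(start)
    return pd.DataFrame({
        "station_id": [f"S{i + 1}" for i in range(n)],
        "x": np.linspace(0.0, 1000.0 * (n - 1), n),
        "y": np.zeros(n),
        "altitude_m": np.full(n, float(altitude)),
        "start": start,
        "end": start + pd.Timedelta(days=camera_days),
        "camera_days": float(camera_days),
    })


def make_records(station_times, species="Ursus thibetanus", **extra):
    """Records from (station_id, seconds-from-start) pairs."""
    base = pd.Timestamp("2020-10-01T00:00:00")
    rows = []
    for sid, sec in station_times:
        rows.append({
            "station_id": sid,
            "time": base + pd.Timedelta(seconds=float(sec)),
            "species": species,
            "radial_distance_m": extra.get("radial_distance_m", np.nan),
            "bearing_rad": extra.get("bearing_rad", np.nan),
            "marker_distance_m": extra.get("marker_distance_m", np.nan),
            "reacted": extra.get("reacted", False),
        })
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def study_sim():
    """One study-scale simulated survey, reused across tests."""
    return simulate(SimTruth(seed=11))


@pytest.fixture(scope="session")
def study_sim_pool():
    """Three study-scale surveys pooled for geometry statistics."""
    return [simulate(SimTruth(seed=s)) for s in (11, 12, 13)]
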