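import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from remcam import (BootstrapConfig, ValidationError, assemble_sequences,
                    encounter_rate, filter_independent, rate_by_altitude)

from conftest import make_deployments, make_records

MIN = 60.0


# ---------------------------------------------------------------------------
# sequence assembly

@pytest.mark.parametrize("seconds,expected_n,expected_dur", [
    ([0, 1, 2], 1, 2.0),            # one burst
    ([0, 1, 200], 2, None),         # gap beyond threshold splits
    ([0, 120, 240], 1, 240.0),      # gaps exactly at threshold merge
])
def test_assemble_sequences_gap_rule(seconds, expected_n, expected_dur):
    rec = make_records([("S1", s) for s in seconds])
    seq = assemble_sequences(rec, max_gap_s=120)
    assert len(seq) == expected_n
    if expected_dur is not None:
        assert seq["duration_s"].iloc[0] == expected_dur


def test_assemble_empty_and_species_filter():
    assert len(assemble_sequences(make_records([]).iloc[:0])) == 0
    rec = pd.concat([make_records([("S1", 0)], species="bear"),
                     make_records([("S1", 0)], species="fox")],
                    ignore_index=True)
    assert len(assemble_sequences(rec)) == 2
    assert len(assemble_sequences(rec, species="bear")) == 1


def test_sequence_inherits_first_position_and_reaction():
    rec = make_records([("S1", 0), ("S1", 1), ("S1", 2)])
    rec.loc[1, "radial_distance_m"] = 3.3   # not on the very first frame
    rec.loc[1, "bearing_rad"] = -0.2
    rec.loc[2, "reacted"] = True
    seq = assemble_sequences(rec)
    assert seq["radial_distance_m"].iloc[0] == 3.3
    assert seq["bearing_rad"].iloc[0] == -0.2
    assert bool(seq["reacted"].iloc[0])


# ---------------------------------------------------------------------------
# independence filter

def _enc(station_minutes):
    rec = make_records([(s, m * MIN) for s, m in station_minutes])
    return filter_independent(assemble_sequences(rec, max_gap_s=1))


def test_independence_middle_event_dropped():
    enc = _enc([("S1", 0), ("S1", 10), ("S1", 40)])
    assert list(enc["independent"]) == [True, False, True]


def test_independence_boundary_inclusive():
    enc = _enc([("S1", 0), ("S1", 30)])
    assert list(enc["independent"]) == [True, True]


def test_independence_per_station():
    enc = _enc([("S1", 0), ("S2", 5), ("S1", 10)])
    assert int(enc["independent"].sum()) == 2


def _greedy_oracle(starts_min, window=30.0):
    """Brute-force re-statement of the greedy retention rule."""
    kept = []
    for t in sorted(starts_min):
        if not kept or t - kept[-1] >= window:
            kept.append(t)
    return len(kept)


@settings(max_examples=50, deadline=None)
@given(st.lists(st.integers(min_value=0, max_value=48 * 60), min_size=0,
                max_size=40))
def test_independence_matches_bruteforce_and_is_idempotent(minutes):
    rec = make_records([("S1", m * MIN) for m in minutes])
    seq = assemble_sequences(rec, max_gap_s=1)
    enc = filter_independent(seq)
    # duplicates collapse into one sequence during assembly
    assembled_starts = sorted(
        (enc["t_start"] - enc["t_start"].min()).dt.total_seconds() / MIN) \
        if len(enc) else []
    assert int(enc["independent"].sum()) == _greedy_oracle(assembled_starts)
    again = filter_independent(enc[enc["independent"]])
    assert again["independent"].all()


@settings(max_examples=30, deadline=None)
@given(st.lists(st.integers(min_value=0, max_value=24 * 60), min_size=1,
                max_size=30))
def test_retained_count_monotone_in_window(minutes):
    rec = make_records([("S1", m * MIN) for m in minutes])
    seq = assemble_sequences(rec, max_gap_s=1)
    ys = [int(filter_independent(seq, window_min=w)["independent"].sum())
          for w in (5, 15, 30, 60, 120)]
    assert all(a >= b for a, b in zip(ys, ys[1:]))


# ---------------------------------------------------------------------------
# encounter rate

def _encounters_at(stations, deployments):
    recs = make_records([(s, i * 3600 * 6) for i, s in enumerate(stations)])
    return filter_independent(assemble_sequences(recs))


def test_rate_is_y_over_h():
    dep = make_deployments(n=4, camera_days=107.0)  # H = 428
    stations = ["S1"] * 20 + ["S2"] * 16 + ["S3"] * 18 + ["S4"] * 12  # Y=66
    rec = make_records([(s, i * 3600 * 2) for i, s in enumerate(stations)])
    enc = filter_independent(assemble_sequences(rec))
    summary = encounter_rate(enc, dep)
    assert summary.Y == 66 and summary.H == 428.0
    assert summary.rate == pytest.approx(0.1542, abs=5e-5)
    assert summary.rate == summary.Y / summary.H


def test_zero_encounters_zero_rate():
    dep = make_deployments(n=2)
    enc = filter_independent(assemble_sequences(make_records([]).iloc[:0]))
    summary = encounter_rate(enc, dep, BootstrapConfig(B=100, seed=0))
    assert summary.Y == 0 and summary.rate == 0.0 and summary.se_rate == 0.0


def test_identical_stations_bootstrap_se_zero():
    dep = make_deployments(n=3, camera_days=10.0)
    rec = make_records([(s, h * 3600 * 5) for s in ("S1", "S2", "S3")
                        for h in range(4)])
    enc = filter_independent(assemble_sequences(rec))
    summary = encounter_rate(enc, dep, BootstrapConfig(B=200, seed=1))
    assert summary.se_rate == pytest.approx(0.0, abs=1e-12)


def test_rate_halves_when_effort_doubles():
    dep = make_deployments(n=2, camera_days=10.0)
    rec = make_records([("S1", 0), ("S2", 3600 * 5)])
    enc = filter_independent(assemble_sequences(rec))
    r1 = encounter_rate(enc, dep).rate
    dep2 = dep.copy()
    dep2["camera_days"] = 20.0
    assert encounter_rate(enc, dep2).rate == pytest.approx(r1 / 2, rel=1e-12)


def test_zero_effort_rejected():
    dep = make_deployments(n=1)
    dep["camera_days"] = 0.0
    enc = filter_independent(assemble_sequences(make_records([("S1", 0)])))
    with pytest.raises(ValidationError):
        encounter_rate(enc, dep)


def test_bootstrap_same_seed_identical():
    dep = make_deployments(n=3, camera_days=7.0)
    rec = make_records([("S1", 0), ("S1", 3600 * 3), ("S2", 3600)])
    enc = filter_independent(assemble_sequences(rec))
    cfg = BootstrapConfig(B=500, seed=42)
    a = encounter_rate(enc, dep, cfg)
    b = encounter_rate(enc, dep, cfg)
    assert a.se_rate == b.se_rate


# ---------------------------------------------------------------------------
# altitude bands

def test_one_station_per_band():
    dep = make_deployments(n=2, camera_days=10.0)
    dep["altitude_m"] = [1700.0, 2300.0]
    rec = make_records([("S1", 0), ("S1", 3600 * 10), ("S2", 0)])
    enc = filter_independent(assemble_sequences(rec))
    tab = rate_by_altitude(enc, dep)
    assert list(tab["alt_lo"]) == [1500.0, 2000.0]
    assert tab["rate"].iloc[0] == pytest.approx(0.2)
    assert tab["rate"].iloc[1] == pytest.approx(0.1)


def test_half_open_band_boundary():
    dep = make_deployments(n=2, camera_days=10.0)
    dep["altitude_m"] = [1999.0, 2000.0]
    rec = make_records([("S1", 0), ("S2", 0)])
    enc = filter_independent(assemble_sequences(rec))
    tab = rate_by_altitude(enc, dep)
    assert list(tab["alt_lo"]) == [1500.0, 2000.0]
    assert (tab["n_stations"] == 1).all()


def test_station_without_altitude_excluded():
    dep = make_deployments(n=2, camera_days=10.0)
    dep.loc[1, "altitude_m"] = np.nan
    rec = make_records([("S1", 0)])
    enc = filter_independent(assemble_sequences(rec))
    with pytest.warns(UserWarning, match="without altitude"):
        tab = rate_by_altitude(enc, dep)
    assert tab["n_stations"].sum() == 1


def test_simulated_altitude_gradient_recovered():
    """Stations in a high-rate stratum outrank a low-rate stratum."""
    dep = make_deployments(n=6, camera_days=30.0)
    dep["altitude_m"] = [1600.0] * 3 + [2600.0] * 3
    rng = np.random.default_rng(0)
    pairs = []
    for i, sid in enumerate(dep["station_id"]):
        lam = 20 if i < 3 else 4   # planted gradient: low altitude busier
        for t in np.sort(rng.uniform(0, 30 * 86400, rng.poisson(lam))):
            pairs.append((sid, t))
    enc = filter_independent(assemble_sequences(make_records(pairs)))
    tab = rate_by_altitude(enc, dep)
    assert tab.loc[tab["alt_lo"] == 1500.0, "rate"].iloc[0] > \
        tab.loc[tab["alt_lo"] == 2500.0, "rate"].iloc[0]
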