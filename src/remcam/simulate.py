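"""Agent-based camera-trap simulator with full ground truth.

The generator embodies the ideal-gas movement assumptions under which the
REM encounter-rate formula is exact: animals are placed uniformly on a
toroidal arena with uniform headings and move as a near-straight correlated
random walk at constant speed while active, standing still otherwise.
Activity follows a hard daily on/off window, so the active fraction (and
hence the day range) is known exactly.  Cameras are stationary sectors
(radius ``r_km``, full angle ``theta_rad``).

Detection is continuous in time: a 1-s movement step registers whenever its
path segment intersects a camera's sector (exact segment/arc and
segment/edge tests), so even transits shorter than one step are captured —
the mean chord through a narrow sector is much smaller than its radius and
point sampling alone would systematically miss encounters.  Each in-zone
step yields one frame at 1 Hz, emulating 3-frame bursts retriggered at 1 s,
which downstream assembly merges into one picture sequence per transit.

For each transit the recorded first-trigger position is the exact point
where the path entered the sector, and the recorded marker distance is the
path length between the first and last frame — the quantities a
marker-calibrated field protocol measures.

The expected encounter rate per camera-day is the closed form

    density * v * r * (2 + theta) / pi,   v = speed * active_fraction * 86.4,

which recovery tests compare against both the simulated record stream and
the estimates of the full pipeline.
"""
from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from numba import njit

from . import io as _io
from .errors import ValidationError

__all__ = ["SimTruth", "SimOutput", "simulate", "make_fixture", "PROFILES"]


@dataclass(frozen=True)
class SimTruth:
    """Ground truth defining one simulated survey.

    Defaults emulate the study conditions: 23 stations at least 1 km
    apart (the survey's stated design) totalling 428 camera-days, density
    1.875 ind/km^2 (arena sized so round(D x A) = 87 animals exactly),
    day range 21.39 km/day split into a 10-h nocturnal activity window
    (fraction 0.4167) at 0.59417 m/s, detection radius 4.5 m and full
    angle 0.426 rad.
    """

    density: float = 1.875            # ind / km^2
    arena: tuple = (6.4, 7.25)        # km (toroidal), round(D*A) = 87 exactly
    speed_active_ms: float = 0.59417  # m/s while active
    activity_window: tuple = (19.0, 5.0)  # hours of day, wraps midnight
    r_km: float = 0.0045
    theta_rad: float = 0.426
    n_cameras: int = 23
    duration_days: float = 428.0 / 23.0
    camera_spacing_km: float = 1.0    # minimum station separation
    dt_s: float = 1.0
    turn_kappa: float = 200.0         # CRW turning concentration (near-straight)
    reaction_prob: float = 0.05       # encounters flagged as reacting to camera
    species: str = "Ursus thibetanus"
    start: str = "2020-10-15T00:00:00"
    seed: int = 0

    def __post_init__(self):
        if self.density <= 0:
            raise ValidationError(f"density must be > 0, got {self.density}")
        if not 0 < self.theta_rad < 2 * np.pi:
            raise ValidationError(
                f"theta_rad must be in (0, 2*pi), got {self.theta_rad}")
        if self.speed_active_ms * self.dt_s > self.r_km * 1000.0 / 2.0:
            raise ValidationError(
                "time step too coarse to resolve zone transits: "
                f"speed*dt = {self.speed_active_ms * self.dt_s:.3f} m exceeds "
                f"r/2 = {self.r_km * 500.0:.3f} m")

    # -- derived quantities ---------------------------------------------
    @property
    def area_km2(self) -> float:
        return self.arena[0] * self.arena[1]

    @property
    def n_animals(self) -> int:
        return max(1, int(round(self.density * self.area_km2)))

    @property
    def realized_density(self) -> float:
        """Density actually present after rounding to whole animals."""
        return self.n_animals / self.area_km2

    @property
    def active_fraction(self) -> float:
        lo, hi = self.activity_window
        span = (hi - lo) % 24.0
        return 1.0 if span == 0 else span / 24.0

    @property
    def v_true_km_day(self) -> float:
        return self.speed_active_ms * self.active_fraction * 86.4

    @property
    def expected_rate(self) -> float:
        """Closed-form expected encounters per camera-day."""
        return (self.realized_density * self.v_true_km_day * self.r_km
                * (2.0 + self.theta_rad) / np.pi)

    def to_json(self, path):
        d = dataclasses.asdict(self)
        d["derived"] = {
            "n_animals": self.n_animals,
            "realized_density": self.realized_density,
            "active_fraction": self.active_fraction,
            "v_true_km_day": self.v_true_km_day,
            "expected_rate": self.expected_rate,
        }
        Path(path).write_text(json.dumps(d, indent=2) + "\n")

    @classmethod
    def from_json(cls, path) -> "SimTruth":
        d = json.loads(Path(path).read_text())
        d.pop("derived", None)
        d["arena"] = tuple(d["arena"])
        d["activity_window"] = tuple(d["activity_window"])
        return cls(**d)


@dataclass
class SimOutput:
    deployments: pd.DataFrame
    records: pd.DataFrame
    truth: SimTruth

    @property
    def expected_rate(self) -> float:
        return self.truth.expected_rate


def _active_steps(truth: SimTruth) -> np.ndarray:
    """Absolute step indices falling inside the daily activity window."""
    n_total = int(round(truth.duration_days * 86400.0 / truth.dt_s))
    t_day = (np.arange(n_total, dtype=np.int64) * truth.dt_s) % 86400.0
    lo, hi = (h * 3600.0 for h in truth.activity_window)
    if truth.active_fraction == 1.0:
        mask = np.ones(n_total, dtype=bool)
    elif lo <= hi:
        mask = (t_day >= lo) & (t_day < hi)
    else:  # wraps midnight
        mask = (t_day >= lo) | (t_day < hi)
    return np.flatnonzero(mask)


def _fold(angle):
    return (angle + np.pi) % (2 * np.pi) - np.pi


def _segment_hits(A, B, axis, r, theta):
    """Exact segment-vs-sector intersection for batches of steps.

    ``A``, ``B``: (..., 2) camera-relative endpoints of each step segment.
    Returns ``(hit, t_entry)``: whether the segment touches the sector
    {|p| <= r, |angle(p) - axis| <= theta/2}, and the earliest parameter
    t in [0, 1] at which it does (the entry point is A + t (B - A)).

    A segment can touch by starting inside, by crossing the bounding arc
    within the angular window, or by crossing one of the two radial edges.
    """
    h = theta / 2.0
    big = 2.0  # sentinel > 1 for "no entry"

    def inside(P):
        d2 = P[..., 0] ** 2 + P[..., 1] ** 2
        ang = _fold(np.arctan2(P[..., 1], P[..., 0]) - axis)
        return (d2 <= r * r) & (np.abs(ang) <= h)

    d = B - A
    t_entry = np.where(inside(A), 0.0, big)

    # arc crossings: |A + t d|^2 = r^2
    a_ = d[..., 0] ** 2 + d[..., 1] ** 2
    b_ = 2.0 * (A[..., 0] * d[..., 0] + A[..., 1] * d[..., 1])
    c_ = A[..., 0] ** 2 + A[..., 1] ** 2 - r * r
    disc = b_ ** 2 - 4.0 * a_ * c_
    ok = (disc >= 0) & (a_ > 0)
    sq = np.sqrt(np.where(ok, disc, 0.0))
    for sgn in (-1.0, 1.0):
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(ok, (-b_ + sgn * sq) / (2.0 * a_), big)
        P = A + t[..., None] * d
        ang = _fold(np.arctan2(P[..., 1], P[..., 0]) - axis)
        valid = ok & (t >= 0.0) & (t <= 1.0) & (np.abs(ang) <= h)
        t_entry = np.minimum(t_entry, np.where(valid, t, big))

    # edge crossings: A + t d = s (cos(axis +/- h), sin(axis +/- h))
    for sgn in (-1.0, 1.0):
        ux, uy = np.cos(axis + sgn * h), np.sin(axis + sgn * h)
        denom = d[..., 0] * uy - d[..., 1] * ux  # cross(d, u)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(np.abs(denom) > 0,
                         -(A[..., 0] * uy - A[..., 1] * ux) / denom, big)
        P = A + t[..., None] * d
        s = P[..., 0] * ux + P[..., 1] * uy
        valid = (np.abs(denom) > 0) & (t >= 0.0) & (t <= 1.0) \
            & (s >= 0.0) & (s <= r)
        t_entry = np.minimum(t_entry, np.where(valid, t, big))

    return t_entry <= 1.0, t_entry


@njit(cache=True)
def _integrate(turns, x, y, heading, step_km, W, H, K, bx, by, bh):
    """March every animal through one chunk of active steps.

    ``turns`` is (N, T); positions/headings are updated in place and the
    state at the start of every K-step block is written to ``bx, by, bh``
    so fine trajectories near a camera can be regenerated afterwards.
    """
    N, T = turns.shape
    for a in range(N):
        xa, ya, ha = x[a], y[a], heading[a]
        for s in range(T):
            if s % K == 0:
                b = s // K
                bx[b, a] = xa
                by[b, a] = ya
                bh[b, a] = ha
            ha += turns[a, s]
            xa += step_km * np.cos(ha)
            ya += step_km * np.sin(ha)
            if xa >= W:
                xa -= W
            elif xa < 0.0:
                xa += W
            if ya >= H:
                ya -= H
            elif ya < 0.0:
                ya += H
        x[a], y[a], heading[a] = xa, ya, ha


def _place_cameras(rng, arena, n_cameras, min_spacing):
    """Sequential hard-core placement: stations at least min_spacing apart
    (toroidal distance), mirroring a gridded survey design."""
    cams = np.empty((n_cameras, 2))
    placed = 0
    for _ in range(200_000):
        cand = rng.uniform(0, 1, 2) * arena
        if placed:
            d = cams[:placed] - cand
            d -= arena * np.round(d / arena)
            if (d[:, 0] ** 2 + d[:, 1] ** 2).min() < min_spacing ** 2:
                continue
        cams[placed] = cand
        placed += 1
        if placed == n_cameras:
            return cams
    raise ValidationError(
        f"cannot place {n_cameras} cameras {min_spacing} km apart in an "
        f"arena of {arena[0]:.2f} x {arena[1]:.2f} km")


def simulate(truth: SimTruth) -> SimOutput:
    """Run the simulation and emit deployment/record tables plus truth.

    All randomness flows from ``truth.seed``; identical truth gives
    bit-identical tables.  Movement is integrated in a single fused pass
    per chunk; detection uses a coarse block prefilter (an animal further
    than one block's travel plus r from every camera cannot reach any zone
    within the block), then regenerates the flagged fine trajectories and
    applies the exact per-step segment tests.
    """
    rng = np.random.default_rng(truth.seed)
    W, Hgt = truth.arena
    arena = np.array([W, Hgt])
    r, theta = truth.r_km, truth.theta_rad
    step_km = truth.speed_active_ms * truth.dt_s / 1000.0
    N = truth.n_animals

    spacing = max(truth.camera_spacing_km, 4 * r)  # zones never overlap
    cams = _place_cameras(rng, arena, truth.n_cameras, spacing)
    axes = rng.uniform(-np.pi, np.pi, truth.n_cameras)
    altitudes = np.round(rng.uniform(1550.0, 2950.0, truth.n_cameras), 0)

    start_ts = pd.Timestamp(truth.start)
    deployments = pd.DataFrame({
        "station_id": [f"CAM{i + 1:02d}" for i in range(truth.n_cameras)],
        "x": cams[:, 0] * 1000.0,
        "y": cams[:, 1] * 1000.0,
        "altitude_m": altitudes,
        "start": start_ts,
        "end": start_ts + pd.to_timedelta(truth.duration_days, unit="D"),
    })
    deployments["camera_days"] = truth.duration_days

    x = rng.uniform(0, 1, N) * W
    y = rng.uniform(0, 1, N) * Hgt
    heading = rng.uniform(-np.pi, np.pi, N)

    active = _active_steps(truth)
    n_act = active.size
    K = 256                                   # coarse prefilter block
    chunk = max(K, (int(1.2e7 / max(N, 1)) // K) * K)
    reach = r + K * step_km                   # max approach within a block
    turn_sd = 1.0 / np.sqrt(truth.turn_kappa)  # wrapped-normal turning

    # per camera: lists of (active-step index, animal, entry x, entry y)
    events = [[] for _ in range(truth.n_cameras)]
    col = np.arange(K + 1)

    for c0 in range(0, n_act, chunk):
        T = min(chunk, n_act - c0)
        turns = rng.standard_normal((N, T)) * turn_sd
        n_blocks = (T + K - 1) // K
        bx = np.empty((n_blocks, N))
        by = np.empty((n_blocks, N))
        bh = np.empty((n_blocks, N))
        _integrate(turns, x, y, heading, step_km, W, Hgt, K, bx, by, bh)

        # which (block, animal) pairs can reach any camera this block?
        flagged = np.zeros((n_blocks, N), dtype=bool)
        cam_hits = []
        for c in range(truth.n_cameras):
            dx = bx - cams[c, 0]
            dx -= W * np.round(dx / W)
            dy = by - cams[c, 1]
            dy -= Hgt * np.round(dy / Hgt)
            near = dx * dx + dy * dy <= reach * reach
            cam_hits.append(near)
            flagged |= near
        blk, anim = np.nonzero(flagged)
        if blk.size:
            # regenerate the fine trajectories of flagged pairs
            s0s = blk * K
            lens = np.minimum(K, T - s0s)
            tidx = np.minimum(s0s[:, None] + np.arange(K)[None, :], T - 1)
            tr = turns[anim[:, None], tidx]
            h = bh[blk, anim][:, None] + np.cumsum(tr, axis=1)
            fine = np.empty((blk.size, K + 1, 2))
            fine[:, 0, 0] = bx[blk, anim]
            fine[:, 0, 1] = by[blk, anim]
            np.cumsum(step_km * np.cos(h), axis=1, out=fine[:, 1:, 0])
            np.cumsum(step_km * np.sin(h), axis=1, out=fine[:, 1:, 1])
            fine[:, 1:, :] += fine[:, :1, :]
            fine %= arena
            pair_index = np.full((n_blocks, N), -1, dtype=np.int64)
            pair_index[blk, anim] = np.arange(blk.size)
            for c in range(truth.n_cameras):
                pb, pa = np.nonzero(cam_hits[c] & flagged)
                if pb.size == 0:
                    continue
                sel = pair_index[pb, pa]
                P = fine[sel] - cams[c]
                P -= arena * np.round(P / arena)
                hit, t_ent = _segment_hits(P[:, :-1], P[:, 1:], axes[c], r,
                                           theta)
                hit &= col[None, :-1] < lens[sel][:, None]
                pi, si = np.nonzero(hit)
                if pi.size == 0:
                    continue
                A = P[pi, si]
                ent = A + t_ent[pi, si, None] * (P[pi, si + 1] - A)
                events[c].append((c0 + s0s[sel][pi] + si, pa[pi], ent))

    # assemble frames camera by camera, run by run
    abs_seconds = (active + 1).astype(np.float64) * truth.dt_s
    rows = []
    for c in range(truth.n_cameras):
        if not events[c]:
            continue
        aidx = np.concatenate([e[0] for e in events[c]])
        anim = np.concatenate([e[1] for e in events[c]])
        ent = np.concatenate([e[2] for e in events[c]])
        order = np.lexsort((aidx, anim))
        aidx, anim, ent = aidx[order], anim[order], ent[order]
        new_run = np.ones(aidx.size, dtype=bool)
        new_run[1:] = (np.diff(anim) != 0) | (np.diff(aidx) != 1)
        run_id = np.cumsum(new_run) - 1
        station = deployments["station_id"].iloc[c]
        for rid in range(run_id[-1] + 1):
            sel = np.flatnonzero(run_id == rid)
            t_sel = aidx[sel]
            L = t_sel.size
            ex, ey = ent[sel[0]]
            radial = float(np.hypot(ex, ey)) * 1000.0
            bearing = float(_fold(np.arctan2(ey, ex) - axes[c]))
            marker = truth.speed_active_ms * truth.dt_s * (L - 1)
            reacted = bool(rng.random() < truth.reaction_prob)
            for j, ti in enumerate(t_sel):
                rows.append((station, abs_seconds[ti],
                             radial if j == 0 else np.nan,
                             bearing if j == 0 else np.nan,
                             marker if j == 0 else np.nan,
                             reacted))

    records = pd.DataFrame(rows, columns=["station_id", "seconds",
                                          "radial_distance_m", "bearing_rad",
                                          "marker_distance_m", "reacted"])
    records.insert(1, "time",
                   start_ts + pd.to_timedelta(records["seconds"], unit="s"))
    records.insert(2, "species", truth.species)
    records = records.drop(columns="seconds")
    records = records.sort_values(["station_id", "time"],
                                  kind="mergesort").reset_index(drop=True)
    return SimOutput(deployments=deployments, records=records, truth=truth)


PROFILES = {
    "study_like": {},
    "uniform_activity": {"activity_window": (0.0, 24.0),
                         "speed_active_ms": 21.39 / 86.4},
    "dense": {"density": 7.5},
    "sparse": {"density": 0.1, "arena": (8.0, 5.0)},
}


def make_fixture(profile: str, out_dir, seed: int = 0) -> dict:
    """Write ``deployments.csv``, ``records.csv`` and ``truth.json``.

    Profiles: ``study_like`` (the defaults), ``uniform_activity`` (active
    around the clock at the same day range), ``dense`` (4x the density) and
    ``sparse`` (density 0.1 on a larger arena).  Returns the file paths.
    """
    if profile not in PROFILES:
        raise ValidationError(f"unknown profile {profile!r}; "
                              f"choose from {sorted(PROFILES)}")
    truth = SimTruth(seed=seed, **PROFILES[profile])
    out = simulate(truth)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {"deployments": out_dir / "deployments.csv",
             "records": out_dir / "records.csv",
             "truth": out_dir / "truth.json"}
    _io.write_deployments(out.deployments, paths["deployments"])
    _io.write_records(out.records, paths["records"])
    truth.to_json(paths["truth"])
    if len(out.records) == 0:
        warnings.warn(f"profile {profile!r} produced no detections")
    return paths
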