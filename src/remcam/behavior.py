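"""Movement speed, diel activity level, and day range.

The day range v (km travelled per 24 h) is composed as

    v = mean sequence speed (m/s) x activity level p x 86.4,

where 86.4 converts m/s sustained over a full day into km/day.  The
activity level p is the proportion of the 24-h cycle the population is
active.  It is estimated from the circular distribution of detection times:
fit a kernel density f with von Mises kernels on the 24-h circle and take

    p = 1 / (2 pi * max f),

i.e. assume all animals are active at the diel peak, so the peak height
measures what fraction of the day that level of activity is sustained.

Speeds come from marker-calibrated sequences: s_i = d_i / t_i with d_i the
distance covered across the field of view and t_i the time between the
first and last frame.  Sequences in which the animal reacted to the camera
stay in the encounter count but are excluded from the speed pool.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import special

from .bootstrap import BootstrapConfig
from .errors import EstimationError

__all__ = ["sequence_speeds", "fit_activity", "day_range",
           "ActivityEstimate", "DayRangeEstimate", "times_to_radians"]

M_S_TO_KM_DAY = 86.4  # 86,400 s/day / 1000 m/km


# ---------------------------------------------------------------------------
# speeds

def sequence_speeds(sequences: pd.DataFrame) -> pd.DataFrame:
    """Per-sequence speed observations s_i = d_i / t_i.

    Uses sequences carrying a ``marker_distance_m``.  Zero-duration
    sequences (single-frame triggers) are dropped with a warning: an
    instantaneous trigger carries no speed information.  Reacted sequences
    are kept but flagged ``excluded_reaction`` so they never enter the
    average.
    """
    usable = sequences[sequences["marker_distance_m"].notna()]
    zero = usable["duration_s"] <= 0
    if zero.any():
        warnings.warn(f"dropping {int(zero.sum())} zero-duration sequence(s) "
                      "from the speed pool")
        usable = usable[~zero]
    return pd.DataFrame({
        "sequence_id": usable["sequence_id"].to_numpy(),
        "d_m": usable["marker_distance_m"].to_numpy(float),
        "t_s": usable["duration_s"].to_numpy(float),
        "speed_ms": (usable["marker_distance_m"]
                     / usable["duration_s"]).to_numpy(float),
        "excluded_reaction": usable["reacted"].to_numpy(bool),
    })


# ---------------------------------------------------------------------------
# circular activity

def times_to_radians(times) -> np.ndarray:
    """Map clock times to angles on [0, 2*pi): time-of-day * 2*pi / 24 h."""
    times = pd.Series(times)
    if np.issubdtype(times.dtype, np.number):
        return np.mod(np.asarray(times, float), 2 * np.pi)
    ts = pd.to_datetime(times)
    frac = (ts.dt.hour * 3600 + ts.dt.minute * 60 + ts.dt.second
            + ts.dt.microsecond / 1e6) / 86400.0
    return (frac.to_numpy() * 2 * np.pi) % (2 * np.pi)


def vonmises_kappa_mle(theta: np.ndarray) -> float:
    """Approximate ML concentration of a von Mises sample (Fisher 1993)."""
    C, S = np.cos(theta).mean(), np.sin(theta).mean()
    R = float(np.hypot(C, S))
    if R < 1e-8:
        return 0.0
    if R < 0.53:
        return 2 * R + R ** 3 + 5 * R ** 5 / 6
    if R < 0.85:
        return -0.4 + 1.39 * R + 0.43 / (1 - R)
    return 1.0 / (R ** 3 - 4 * R ** 2 + 3 * R)


def kernel_concentration(theta: np.ndarray, multiplier: float = 1.0) -> float:
    """Rule-of-thumb smoothing concentration for a von Mises kernel.

    Taylor's circular analogue of the normal reference rule:

        nu = [3 n k^2 I2(2k) / (4 sqrt(pi) I1(k)^2)]^(2/5)

    with k the ML von Mises concentration of the sample.  Larger nu =
    narrower kernel.  ``multiplier`` rescales the result (default 1.0).
    """
    n = len(theta)
    k = vonmises_kappa_mle(theta)
    if k < 1e-8:
        return 0.0
    num = 3 * n * k ** 2 * special.iv(2, 2 * k)
    den = 4 * np.sqrt(np.pi) * special.iv(1, k) ** 2
    return float((num / den) ** 0.4) * multiplier


def _vm_kde(grid: np.ndarray, theta: np.ndarray, nu: float) -> np.ndarray:
    """Von Mises kernel density on ``grid``; nu = 0 gives the uniform."""
    if nu < 1e-8:
        return np.full(grid.shape, 1.0 / (2 * np.pi))
    # exp(nu * cos(x - t)) / (2 pi I0(nu)), averaged over data points
    if nu > 700:  # keep exp in range; normalize via log I0
        log_i0 = nu + np.log(special.ive(0, nu))
    else:
        log_i0 = np.log(special.i0(nu))
    d = np.cos(grid[:, None] - theta[None, :])
    return np.exp(nu * d - log_i0).mean(axis=1) / (2 * np.pi)


@dataclass
class ActivityEstimate:
    """Activity level p with bootstrap uncertainty and the fitted density."""

    p: float
    se: float = 0.0
    ci_lo: float = float("nan")
    ci_hi: float = float("nan")
    bandwidth: float = 0.0          # kernel concentration nu
    n: int = 0
    p_raw: float = float("nan")     # before bootstrap bias correction
    grid: np.ndarray = field(default_factory=lambda: np.empty(0), repr=False)
    f_hat: np.ndarray = field(default_factory=lambda: np.empty(0), repr=False)
    f_lo: Optional[np.ndarray] = field(default=None, repr=False)
    f_hi: Optional[np.ndarray] = field(default=None, repr=False)

    def table(self) -> pd.DataFrame:
        """Fitted density on a time-of-day grid (hours), with CI if known."""
        out = pd.DataFrame({
            "grid_time_h": self.grid * 24 / (2 * np.pi),
            "density": self.f_hat,
        })
        out["ci_lo"] = self.f_lo if self.f_lo is not None else np.nan
        out["ci_hi"] = self.f_hi if self.f_hi is not None else np.nan
        return out


def _p_from_density(f_hat: np.ndarray) -> float:
    return float(1.0 / (2 * np.pi * f_hat.max()))


def _refined_peak(theta: np.ndarray, nu: float, grid: np.ndarray,
                  f_grid: np.ndarray) -> float:
    """Continuous maximum of the KDE via ternary search around the grid max.

    Makes the activity level invariant to rotations of the time origin
    (a pure grid max would quantize the peak location).
    """
    if nu < 1e-8:
        return float(f_grid.max())
    j = int(np.argmax(f_grid))
    span = grid[1] - grid[0]
    lo, hi = grid[j] - span, grid[j] + span
    for _ in range(30):
        m1 = lo + (hi - lo) / 3.0
        m2 = hi - (hi - lo) / 3.0
        f1 = _vm_kde(np.array([m1]), theta, nu)[0]
        f2 = _vm_kde(np.array([m2]), theta, nu)[0]
        if f1 < f2:
            lo = m1
        else:
            hi = m2
    return float(_vm_kde(np.array([0.5 * (lo + hi)]), theta, nu)[0])


def _evc_peak(theta: np.ndarray, nu: float, grid: np.ndarray,
              f_grid: np.ndarray) -> float:
    """Peak height with an extreme-value correction for max-selection bias.

    The maximum of a noisy density estimate overshoots the true peak: over
    a flat stretch of the density the estimate fluctuates with pointwise
    sd sigma = sqrt(f R(K)/n) (R(K) the kernel roughness), and taking the
    maximum selects the largest fluctuation, inflating the peak by about
    sigma * E[max of m standard normals], with m the number of effectively
    independent fluctuations along the near-peak plateau.  Both sigma and
    m are estimable from the fit: the noise correlation length of a von
    Mises kernel of concentration nu is ~ 2 sqrt(pi/nu), and the plateau
    is the region within ~2 sigma of the (corrected) maximum, iterated to
    a fixed point.  For a sharply peaked density the plateau shrinks to
    one correlation length, m -> 1, and the correction vanishes — so
    peaked diel patterns are left untouched while flat-topped schedules
    lose their systematic overshoot.
    """
    n = len(theta)
    fmax = _refined_peak(theta, nu, grid, f_grid)
    if nu < 1e-8:
        return fmax
    # kernel roughness R(K) = I0(2 nu) / (2 pi I0(nu)^2), in logs
    log_rk = (2 * nu + np.log(special.ive(0, 2 * nu))
              - np.log(2 * np.pi)
              - 2 * (nu + np.log(special.ive(0, nu))))
    sigma = np.sqrt(fmax * np.exp(log_rk) / n)
    ell = 2.0 * np.sqrt(np.pi / nu)      # noise correlation length
    delta = 0.0
    for _ in range(12):
        plateau = (f_grid >= fmax - delta - 2.0 * sigma).mean() * 2 * np.pi
        m = max(1.0, plateau / ell)
        if m <= 1.0:
            emax = 0.0
        elif m <= np.e:
            emax = 0.5 * np.sqrt(2.0 * np.log(m))
        else:
            a = np.sqrt(2.0 * np.log(m))
            emax = max(0.0, a - (np.log(np.log(m)) + np.log(4 * np.pi))
                       / (2.0 * a))
        delta = sigma * emax
    return fmax - delta


def fit_activity(detection_times, bandwidth_multiplier: float = 1.0,
                 kappa: Optional[float] = None, grid_size: int = 512,
                 bootstrap: Optional[BootstrapConfig] = None,
                 bias_correct: bool = True,
                 min_n: int = 10) -> ActivityEstimate:
    """Estimate the diel activity level from detection times.

    Parameters
    ----------
    detection_times : array-like
        Times of independent encounters, either timestamps or angles in
        radians on [0, 2*pi).  One time per encounter (not per frame), to
        avoid burst pseudo-replication.
    bandwidth_multiplier : float
        Scales the rule-of-thumb kernel concentration.
    kappa : float, optional
        Explicit kernel concentration, overriding the rule of thumb.
    bootstrap : BootstrapConfig, optional
        Resamples detection times to give an SE and CI for p and a
        pointwise band for the density curve (from up to 200 replicates).
    bias_correct : bool
        The maximum of a noisy density estimate is biased upward, which
        biases p = 1/(2*pi*max f) downward in finite samples.  When True
        (default) the peak is estimated with the extreme-value correction
        of :func:`_evc_peak`; if a bootstrap also runs, its replicates use
        the same corrected estimator and the residual bias 2*p - mean(p*)
        is removed as well (the CI is then the basic bootstrap interval).
        When False the raw peak is used with a percentile CI.

    Notes
    -----
    p is clipped to 1 (with a warning) if the fitted peak falls below the
    uniform level 1/(2*pi), which can happen numerically for flat samples.
    The bootstrap cost scales as n x B x grid_size.
    """
    theta = times_to_radians(detection_times)
    n = len(theta)
    if n < min_n:
        raise EstimationError(
            f"need at least {min_n} detection times to fit activity, got {n}")
    nu = kappa if kappa is not None else \
        kernel_concentration(theta, bandwidth_multiplier)
    grid = np.linspace(0.0, 2 * np.pi, grid_size, endpoint=False)
    f_hat = _vm_kde(grid, theta, nu)
    peak = _evc_peak if bias_correct else _refined_peak
    p_raw = float(1.0 / (2 * np.pi * _refined_peak(theta, nu, grid, f_hat)))
    p = float(1.0 / (2 * np.pi * peak(theta, nu, grid, f_hat)))
    if p > 1.0:
        warnings.warn(f"activity level {p:.3f} > 1 clipped to 1 "
                      "(fitted peak at or below the uniform density)")
        p = 1.0

    est = ActivityEstimate(p=p, p_raw=min(1.0, p_raw), bandwidth=nu, n=n,
                           grid=grid, f_hat=f_hat)
    if bootstrap is not None:
        rng = bootstrap.rng()
        reps = np.empty(bootstrap.B)
        curve_keep = min(bootstrap.B, 200)
        curves = np.empty((curve_keep, grid_size))
        for b in range(bootstrap.B):
            t = theta[rng.integers(0, n, size=n)]
            nu_b = kappa if kappa is not None else \
                kernel_concentration(t, bandwidth_multiplier)
            f_b = _vm_kde(grid, t, nu_b)
            reps[b] = min(1.0, 1.0 / (2 * np.pi * peak(t, nu_b, grid, f_b)))
            if b < curve_keep:
                curves[b] = f_b
        est.se = float(np.std(reps, ddof=1)) if bootstrap.B > 1 else 0.0
        q_lo, q_hi = np.quantile(reps, [0.025, 0.975])
        if bias_correct:
            # remove the residual bias the bootstrap world still shows
            est.p = float(min(1.0, 2.0 * p - reps.mean()))
            est.ci_lo = float(max(0.0, 2.0 * p - q_hi))
            est.ci_hi = float(min(1.0, 2.0 * p - q_lo))
        else:
            est.ci_lo, est.ci_hi = float(q_lo), float(q_hi)
        est.f_lo, est.f_hi = np.quantile(curves, [0.025, 0.975], axis=0)
    return est


# ---------------------------------------------------------------------------
# day range

@dataclass
class DayRangeEstimate:
    """Day range v = mean speed x activity level x 86.4 (km/day)."""

    v: float
    se_v: float
    mean_speed: float
    se_speed: float
    p: float
    se_p: float
    n_speeds: int
    speed_average: str = "arithmetic"


def day_range(speed_obs: pd.DataFrame, activity: ActivityEstimate,
              bootstrap: Optional[BootstrapConfig] = None,
              speed_average: str = "arithmetic") -> DayRangeEstimate:
    """Compose the day range from the speed pool and the activity level.

    ``speed_average`` is "arithmetic" (default) or "harmonic".  The SE of v
    treats mean speed and p as independent, so squared coefficients of
    variation add (delta method):

        (se_v / v)^2 = (se_s / s)^2 + (se_p / p)^2
    """
    pool = speed_obs.loc[~speed_obs["excluded_reaction"], "speed_ms"]
    pool = pool.to_numpy(float)
    if len(pool) == 0:
        raise EstimationError("no usable speed observations "
                              "(all missing, zero-duration or reacted)")
    if speed_average == "arithmetic":
        stat = np.mean
    elif speed_average == "harmonic":
        stat = lambda s: 1.0 / np.mean(1.0 / s)
    else:
        raise ValueError(f"unknown speed_average {speed_average!r}")
    mean_speed = float(stat(pool))
    se_speed = 0.0
    if bootstrap is not None and len(pool) > 1:
        from .bootstrap import bootstrap_se
        se_speed, _ = bootstrap_se(pool, stat, bootstrap)
    v = mean_speed * activity.p * M_S_TO_KM_DAY
    cv2 = 0.0
    if mean_speed > 0:
        cv2 += (se_speed / mean_speed) ** 2
    if activity.p > 0:
        cv2 += (activity.se / activity.p) ** 2
    return DayRangeEstimate(v=v, se_v=v * np.sqrt(cv2),
                            mean_speed=mean_speed, se_speed=se_speed,
                            p=activity.p, se_p=activity.se,
                            n_speeds=len(pool), speed_average=speed_average)
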