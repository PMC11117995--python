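"""The Random Encounter Model density estimator.

The REM converts the rate at which moving animals encounter stationary
camera detection zones into population density without identifying
individuals:

    D = (Y / H) * pi / (v * r * (2 + theta))

with Y/H the independent-encounter rate per camera-day, v the day range
(km/day), and (r, theta) the radius (km) and full angular width (rad) of
the sector-shaped detection zone.  r * (2 + theta) / pi is the mean profile
width the zone presents to a randomly moving animal (Cauchy's formula:
perimeter / pi for a convex region), so D * v * r * (2 + theta) / pi is the
expected encounter rate under the ideal-gas movement assumptions.

Uncertainty: component SEs come from the bootstrap, and the total SE from
the delta method for a product/quotient of independent estimates — squared
coefficients of variation add, with theta entering through (2 + theta).

:class:`REM` is the model object (built from deployment and record tables);
:meth:`REM.fit` runs the full pipeline and returns :class:`REMResults`.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import io as _io
from .bootstrap import BootstrapConfig, bootstrap_se
from .behavior import (ActivityEstimate, DayRangeEstimate, day_range,
                       fit_activity, sequence_speeds)
from .detections import (EncounterSummary, assemble_sequences,
                         encounter_rate, filter_independent)
from .errors import EstimationError, ValidationError

__all__ = ["DetectionZone", "DensityEstimate", "detection_zone",
           "rem_density", "delta_variance", "REM", "REMResults"]


# ---------------------------------------------------------------------------
# detection zone

@dataclass
class DetectionZone:
    """Effective detection-zone geometry: radius (km) and full angle (rad)."""

    r: float
    theta: float
    se_r: float = 0.0
    se_theta: float = 0.0
    n: int = 0
    method: str = "mean"

    def __post_init__(self):
        if self.r <= 0:
            raise ValidationError(f"detection radius must be > 0, got {self.r}")
        if not 0 < self.theta < 2 * np.pi:
            raise ValidationError(
                f"detection angle must be in (0, 2*pi), got {self.theta}")


def _zone_mean(d_m: np.ndarray, b_rad: np.ndarray):
    """Paper-style estimator: mean radial distance, 2 x mean |bearing|."""
    return d_m.mean() / 1000.0, 2.0 * np.abs(b_rad).mean()


def _zone_entry_corrected(d_m: np.ndarray, b_rad: np.ndarray):
    """Debiased sector geometry from first-trigger entry positions.

    For straight transits entering a sector (radius R, full angle T)
    uniformly over its boundary,

        E[d]   = R (1 + T) / (2 + T)
        E[|b|] = T (4 + T) / (4 (2 + T))

    (side entries sit at |b| = T/2 with distance uniform on [0, R]; arc
    entries sit at distance R with bearing uniform).  Inverting the second
    for T gives a quadratic; R then follows from the first.
    """
    m = d_m.mean() / 1000.0
    bbar = np.abs(b_rad).mean()
    # T^2 + 4(1 - bbar) T - 8 bbar = 0, positive root
    T = (-(4 - 4 * bbar) + np.sqrt((4 - 4 * bbar) ** 2 + 32 * bbar)) / 2.0
    R = m * (2 + T) / (1 + T)
    return R, T


_ZONE_METHODS = {"mean": _zone_mean, "entry-corrected": _zone_entry_corrected}


def detection_zone(encounters: pd.DataFrame, method: str = "mean",
                   bootstrap: Optional[BootstrapConfig] = None
                   ) -> DetectionZone:
    """Estimate the detection zone from first-trigger positions.

    ``method="mean"`` reproduces the field protocol: r is the mean radial
    distance (m -> km) and theta twice the mean absolute bearing, folding
    signed bearings into a full angular width.  ``method="entry-corrected"``
    additionally undoes the geometric bias of sampling positions where
    animals *enter* the sector (see :func:`_zone_entry_corrected`); use it
    when positions are true entry points rather than calibrated sightings.

    SEs bootstrap the positioned encounters jointly (distance, bearing).
    """
    if method not in _ZONE_METHODS:
        raise ValueError(f"unknown detection-zone method {method!r}")
    est = _ZONE_METHODS[method]
    pos = encounters.dropna(subset=["radial_distance_m", "bearing_rad"])
    if len(pos) == 0:
        raise EstimationError("no encounters carry first-trigger positions")
    d = pos["radial_distance_m"].to_numpy(float)
    b = pos["bearing_rad"].to_numpy(float)
    r, theta = est(d, b)
    se_r = se_theta = 0.0
    if bootstrap is not None and len(pos) > 1:
        arr = np.column_stack([d, b])
        se_r, _ = bootstrap_se(arr, lambda s: est(s[:, 0], s[:, 1])[0],
                               bootstrap)
        se_theta, _ = bootstrap_se(arr, lambda s: est(s[:, 0], s[:, 1])[1],
                                   bootstrap.with_seed(
                                       None if bootstrap.seed is None
                                       else bootstrap.seed + 1))
    return DetectionZone(r=r, theta=theta, se_r=se_r, se_theta=se_theta,
                         n=len(pos), method=method)


# ---------------------------------------------------------------------------
# the estimator and its variance

def rem_density(rate: float, v: float, r: float, theta: float) -> float:
    """Point density D = rate * pi / (v * r * (2 + theta)) in ind/km^2.

    ``rate`` per camera-day, ``v`` km/day, ``r`` km, ``theta`` rad.  A zero
    rate gives D = 0; any other non-positive parameter raises.
    """
    if rate < 0:
        raise ValidationError(f"encounter rate must be >= 0, got {rate}")
    if v <= 0 or r <= 0:
        raise ValidationError(f"v and r must be > 0, got v={v}, r={r}")
    if not 0 <= theta < 2 * np.pi:
        raise ValidationError(f"theta must be in [0, 2*pi), got {theta}")
    return rate * np.pi / (v * r * (2.0 + theta))


def delta_variance(D: float, rate: float, se_rate: float, v: float,
                   se_v: float, r: float, se_r: float, theta: float,
                   se_theta: float):
    """Delta-method SE of D and the squared-CV decomposition.

    cv_D^2 = (se_rate/rate)^2 + (se_v/v)^2 + (se_r/r)^2
             + (se_theta/(2+theta))^2;  se_D = D * cv_D.

    Returns ``(se_D, cv_components)`` where the dict maps parameter name to
    its squared CV contribution.
    """
    comp = {
        "rate": (se_rate / rate) ** 2 if rate > 0 else 0.0,
        "v": (se_v / v) ** 2,
        "r": (se_r / r) ** 2,
        "theta": (se_theta / (2.0 + theta)) ** 2,
    }
    cv2 = sum(comp.values())
    return D * float(np.sqrt(cv2)), comp


@dataclass
class DensityEstimate:
    """Terminal product of the pipeline: D with its propagated SE."""

    density: float
    se: float
    cv_components: dict = field(default_factory=dict)

    @property
    def cv(self) -> float:
        return self.se / self.density if self.density > 0 else 0.0


# ---------------------------------------------------------------------------
# model / results objects

class REM:
    """Random Encounter Model fitted to camera-trap tables.

    Parameters
    ----------
    deployments, records : DataFrame
        Tables in the schemas of :mod:`remcam.io`.
    species : str, optional
        Restrict to one species label before any computation.
    window_min : float
        Independence window in minutes (default 30).
    burst_gap_s : float
        Maximum within-sequence frame gap in seconds (default 120).
    zone_method : {"mean", "entry-corrected"}
        Detection-zone estimator (see :func:`detection_zone`).
    speed_average : {"arithmetic", "harmonic"}
    bandwidth_multiplier : float
        Scales the activity kernel's rule-of-thumb concentration.
    """

    def __init__(self, deployments: pd.DataFrame, records: pd.DataFrame,
                 species: Optional[str] = None, window_min: float = 30.0,
                 burst_gap_s: float = 120.0, zone_method: str = "mean",
                 speed_average: str = "arithmetic",
                 bandwidth_multiplier: float = 1.0):
        self.deployments = deployments
        self.records = records
        self.species = species
        self.window_min = window_min
        self.burst_gap_s = burst_gap_s
        self.zone_method = zone_method
        self.speed_average = speed_average
        self.bandwidth_multiplier = bandwidth_multiplier

        self.sequences = assemble_sequences(records, max_gap_s=burst_gap_s,
                                            species=species)
        self.encounters = filter_independent(self.sequences,
                                             window_min=window_min)

    @classmethod
    def from_tables(cls, deployments_path, records_path, **kwargs) -> "REM":
        dep, rec = _io.read_tables(deployments_path, records_path)
        return cls(dep, rec, **kwargs)

    def fit(self, bootstrap: Optional[BootstrapConfig] = None,
            activity: Optional[ActivityEstimate] = None) -> "REMResults":
        """Run the full pipeline and return a :class:`REMResults`.

        ``bootstrap=None`` gives point estimates with zero SEs.  An
        externally fitted ``activity`` estimate (e.g. pooled over surveys)
        can be supplied to override the within-survey fit.
        """
        bs = bootstrap
        summary = encounter_rate(self.encounters, self.deployments, bs)
        if summary.Y == 0:
            warnings.warn("no independent encounters; density is 0")
            return REMResults(model=self, encounter_summary=summary,
                              activity=None, day_range_est=None, zone=None,
                              density=DensityEstimate(0.0, 0.0), bootstrap=bs)
        ind = self.encounters[self.encounters["independent"]]
        if activity is None:
            activity = fit_activity(
                ind["t_start"], bootstrap=bs,
                bandwidth_multiplier=self.bandwidth_multiplier)
        speeds = sequence_speeds(self.encounters)
        dr = day_range(speeds, activity, bootstrap=bs,
                       speed_average=self.speed_average)
        zone = detection_zone(ind, method=self.zone_method, bootstrap=bs)
        D = rem_density(summary.rate, dr.v, zone.r, zone.theta)
        se_D, comp = delta_variance(D, summary.rate, summary.se_rate, dr.v,
                                    dr.se_v, zone.r, zone.se_r, zone.theta,
                                    zone.se_theta)
        return REMResults(model=self, encounter_summary=summary,
                          activity=activity, day_range_est=dr, zone=zone,
                          density=DensityEstimate(D, se_D, comp),
                          speeds=speeds, bootstrap=bs)


@dataclass
class REMResults:
    """Estimates, uncertainties and intermediates from a REM fit."""

    model: Optional[REM]
    encounter_summary: EncounterSummary
    activity: Optional[ActivityEstimate]
    day_range_est: Optional[DayRangeEstimate]
    zone: Optional[DetectionZone]
    density: DensityEstimate
    speeds: Optional[pd.DataFrame] = None
    bootstrap: Optional[BootstrapConfig] = None

    # -- convenience accessors ------------------------------------------
    @property
    def Y(self) -> int:
        return self.encounter_summary.Y

    @property
    def H(self) -> float:
        return self.encounter_summary.H

    @property
    def rate(self) -> float:
        return self.encounter_summary.rate

    @property
    def D(self) -> float:
        return self.density.density

    @property
    def se_D(self) -> float:
        return self.density.se

    @classmethod
    def from_parameters(cls, rate: float, v: float, r: float, theta: float,
                        se_rate: float = 0.0, se_v: float = 0.0,
                        se_r: float = 0.0, se_theta: float = 0.0,
                        Y: Optional[int] = None, H: Optional[float] = None
                        ) -> "REMResults":
        """Evaluate the REM at externally supplied parameter values.

        This is the parameter-override path: it reproduces a published
        estimate from its reported encounter rate, day range and detection
        zone without raw records.
        """
        D = rem_density(rate, v, r, theta)
        se_D, comp = delta_variance(D, rate, se_rate, v, se_v, r, se_r,
                                    theta, se_theta)
        summary = EncounterSummary(Y=Y if Y is not None else 0,
                                   H=H if H is not None else 1.0,
                                   rate=rate, se_rate=se_rate,
                                   var_rate=se_rate ** 2)
        zone = DetectionZone(r=r, theta=theta, se_r=se_r, se_theta=se_theta,
                             method="override")
        dr = DayRangeEstimate(v=v, se_v=se_v, mean_speed=float("nan"),
                              se_speed=float("nan"), p=float("nan"),
                              se_p=float("nan"), n_speeds=0)
        return cls(model=None, encounter_summary=summary, activity=None,
                   day_range_est=dr, zone=zone,
                   density=DensityEstimate(D, se_D, comp))

    # -- reporting -------------------------------------------------------
    def parameter_frame(self) -> pd.DataFrame:
        """One-row table of the REM parameters and the density estimate."""
        dr, z = self.day_range_est, self.zone
        row = {
            "Y": self.Y, "H": self.H,
            "rate_per_camday": self.rate,
            "se_rate": self.encounter_summary.se_rate,
            "v_km_day": dr.v if dr else float("nan"),
            "se_v": dr.se_v if dr else float("nan"),
            "activity_p": self.activity.p if self.activity else
                          (dr.p if dr else float("nan")),
            "se_activity": self.activity.se if self.activity else float("nan"),
            "mean_speed_ms": dr.mean_speed if dr else float("nan"),
            "r_km": z.r if z else float("nan"),
            "se_r": z.se_r if z else float("nan"),
            "theta_rad": z.theta if z else float("nan"),
            "se_theta": z.se_theta if z else float("nan"),
            "density_km2": self.D, "se_density": self.se_D,
        }
        return pd.DataFrame([row])

    def to_dict(self) -> dict:
        d = {k: (None if v is None or (isinstance(v, float) and np.isnan(v))
                 else v)
             for k, v in self.parameter_frame().iloc[0].items()}
        d["cv_components"] = self.density.cv_components
        if self.bootstrap is not None:
            d["bootstrap_B"] = self.bootstrap.B
            d["bootstrap_seed"] = self.bootstrap.seed
        return d

    def to_json(self, path=None, **extra):
        payload = self.to_dict() | extra
        text = json.dumps(payload, indent=2, default=float)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    def summary(self) -> str:
        """Human-readable fit summary."""
        es = self.encounter_summary
        lines = [
            "Random Encounter Model results",
            "=" * 46,
            f"{'Encounters (Y)':<28}{es.Y:>18}",
            f"{'Effort (H, camera-days)':<28}{es.H:>18.2f}",
            f"{'Encounter rate (/cam-day)':<28}{es.rate:>10.4f} "
            f"+/- {es.se_rate:.4f}",
        ]
        if self.day_range_est is not None:
            dr = self.day_range_est
            lines += [
                f"{'Day range v (km/day)':<28}{dr.v:>10.3f} +/- {dr.se_v:.3f}",
            ]
            if np.isfinite(dr.mean_speed):
                lines += [
                    f"{'  mean speed (m/s)':<28}{dr.mean_speed:>10.4f} "
                    f"+/- {dr.se_speed:.4f}  (n={dr.n_speeds})",
                    f"{'  activity level p':<28}{dr.p:>10.3f} +/- {dr.se_p:.3f}",
                ]
        if self.zone is not None:
            z = self.zone
            lines += [
                f"{'Detection radius r (km)':<28}{z.r:>10.5f} +/- {z.se_r:.5f}",
                f"{'Detection angle theta (rad)':<28}{z.theta:>10.4f} "
                f"+/- {z.se_theta:.4f}",
            ]
        lines += [
            "-" * 46,
            f"{'Density D (ind/km^2)':<28}{self.D:>10.4f} +/- {self.se_D:.4f}",
        ]
        if self.density.cv_components:
            comps = ", ".join(f"{k}={v:.4f}" for k, v in
                              self.density.cv_components.items())
            lines.append(f"cv^2 components: {comps}")
        return "\n".join(lines)
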