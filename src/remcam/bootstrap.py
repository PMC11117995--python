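"""Nonparametric bootstrap utilities.

All standard errors in the estimation pipeline come from resampling with
replacement: stations for the encounter rate (design-based), individual
observations for speeds and detection-zone measurements.  Everything is
seeded through :class:`BootstrapConfig` so a full run is reproducible.
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Optional

import numpy as np
import pandas as pd

__all__ = ["BootstrapConfig", "bootstrap_se", "bootstrap_ci"]


@dataclass(frozen=True)
class BootstrapConfig:
    """Settings for bootstrap resampling.

    Parameters
    ----------
    B : int
        Number of bootstrap iterations (default 10,000, the convention for
        encounter-rate and detection-zone standard errors in REM studies).
    seed : int, optional
        Seed for the resampling generator.  ``None`` draws fresh entropy.
    resample_unit : {"observation", "station"}
        Granularity of the resample.  Purely informational here; the caller
        chooses what the rows of ``sample`` represent.
    """

    B: int = 10_000
    seed: Optional[int] = None
    resample_unit: str = "observation"

    def __post_init__(self):
        if self.B < 1:
            raise ValueError(f"bootstrap iterations must be >= 1, got {self.B}")
        if self.resample_unit not in ("observation", "station"):
            raise ValueError(f"unknown resample_unit {self.resample_unit!r}")

    def with_seed(self, seed: int) -> "BootstrapConfig":
        return replace(self, seed=seed)

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def _replicates(sample, statistic: Callable, cfg: BootstrapConfig) -> np.ndarray:
    if isinstance(sample, pd.DataFrame):
        n = len(sample)
        take = lambda idx: sample.iloc[idx]
    else:
        sample = np.asarray(sample)
        n = sample.shape[0]
        take = lambda idx: sample[idx]
    if n == 0:
        raise ValueError("cannot bootstrap an empty sample")
    rng = cfg.rng()
    out = np.empty(cfg.B, dtype=float)
    for b in range(cfg.B):
        idx = rng.integers(0, n, size=n)
        out[b] = statistic(take(idx))
    return out


def bootstrap_se(sample, statistic: Callable, cfg: BootstrapConfig):
    """Bootstrap standard error and variance of ``statistic(sample)``.

    ``sample`` is resampled row-wise with replacement ``cfg.B`` times; the SE
    is the standard deviation (ddof=1) of the replicate statistics.  Returns
    ``(se, variance)``.  Seeded runs are bit-reproducible.
    """
    reps = _replicates(sample, statistic, cfg)
    se = float(np.std(reps, ddof=1)) if cfg.B > 1 else 0.0
    return se, se * se


def bootstrap_ci(sample, statistic: Callable, cfg: BootstrapConfig,
                 level: float = 0.95):
    """Bootstrap SE plus a percentile confidence interval.

    Returns ``(se, (lo, hi))`` with the interval at the requested coverage.
    """
    reps = _replicates(sample, statistic, cfg)
    se = float(np.std(reps, ddof=1)) if cfg.B > 1 else 0.0
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(reps, [alpha, 1.0 - alpha])
    return se, (float(lo), float(hi))
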