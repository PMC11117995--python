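"""Hotspot surfaces and the criteria-filtered all-subsets regression.

Hotspots: a planar kernel density surface over station points weighted by
encounter rate, using the quartic kernel

    K(u) = 3 / (pi h^2) (1 - u^2)^2  for u = d/h <= 1, else 0,

which is maximal at the point and reaches zero at the search radius h, and
integrates to one — so the raster conserves the total point weight when the
bandwidth fits inside the extent.

Regression: every non-empty subset of candidate environmental covariates
(up to ``max_vars``) is fitted by OLS against station encounter rates and
screened against criteria on adjusted R^2, coefficient p-values, VIF,
Jarque–Bera residual normality and Moran's I residual spatial
autocorrelation (inverse-distance weights, row-standardized, normal
approximation).  Variable importance summarises how often each covariate is
significant among models passing the significance screen.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.stattools import jarque_bera

__all__ = ["RasterGrid", "kde_raster", "classify_hotspots", "morans_i",
           "RegressionCriteria", "exploratory_regression"]


# ---------------------------------------------------------------------------
# raster + quartic KDE

@dataclass
class RasterGrid:
    """Row-major grid; row 0 is the top (north) row, ESRI ASCII convention."""

    origin_x: float          # x of the lower-left corner (m)
    origin_y: float          # y of the lower-left corner (m)
    cell_size: float         # m
    values: np.ndarray       # (n_rows, n_cols)

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    def cell_centers(self):
        xs = self.origin_x + (np.arange(self.n_cols) + 0.5) * self.cell_size
        ys = self.origin_y + (np.arange(self.n_rows)[::-1] + 0.5) \
            * self.cell_size
        return xs, ys

    def total_mass(self) -> float:
        return float(self.values.sum() * self.cell_size ** 2)

    def write_ascii(self, path):
        """ESRI ASCII grid (.asc): plain text, GIS-readable."""
        header = (f"ncols {self.n_cols}\n"
                  f"nrows {self.n_rows}\n"
                  f"xllcorner {self.origin_x}\n"
                  f"yllcorner {self.origin_y}\n"
                  f"cellsize {self.cell_size}\n"
                  f"NODATA_value -9999\n")
        with open(path, "w") as fh:
            fh.write(header)
            np.savetxt(fh, self.values, fmt="%.10g")

    @classmethod
    def read_ascii(cls, path) -> "RasterGrid":
        with open(path) as fh:
            hdr = {}
            for _ in range(6):
                k, v = fh.readline().split()
                hdr[k.lower()] = float(v)
            values = np.loadtxt(fh)
        values = np.atleast_2d(values)
        return cls(origin_x=hdr["xllcorner"], origin_y=hdr["yllcorner"],
                   cell_size=hdr["cellsize"], values=values)


def default_bandwidth(points: np.ndarray, multiplier: float = 2.0) -> float:
    """Twice the mean nearest-neighbour distance between points."""
    pts = np.asarray(points, float)
    if len(pts) < 2:
        raise ValueError("need >= 2 points for the bandwidth rule")
    d = np.hypot(pts[:, None, 0] - pts[None, :, 0],
                 pts[:, None, 1] - pts[None, :, 1])
    np.fill_diagonal(d, np.inf)
    return float(d.min(axis=1).mean()) * multiplier


def kde_raster(points, weights=None, bandwidth_m: float = None,
               cell_size_m: float = None, bounds=None) -> RasterGrid:
    """Quartic-kernel density surface over weighted points.

    ``points`` is (n, 2) in metres; ``weights`` default to 1.  ``bounds``
    is ``(xmin, ymin, xmax, ymax)``; by default the point bounding box
    padded by one bandwidth.  The surface is the sum of per-point kernels,
    so its integral approximates the total weight.
    """
    pts = np.atleast_2d(np.asarray(points, float))
    if bandwidth_m is None or bandwidth_m <= 0:
        raise ValueError("bandwidth_m must be a positive number")
    if cell_size_m is None or cell_size_m <= 0:
        raise ValueError("cell_size_m must be a positive number")
    if pts.size == 0:
        if bounds is None:
            raise ValueError("empty point set needs explicit bounds")
        warnings.warn("empty point set: returning a zero raster")
        w = np.array([])
    else:
        w = np.ones(len(pts)) if weights is None else np.asarray(weights,
                                                                 float)
    if bounds is None:
        bounds = (pts[:, 0].min() - bandwidth_m, pts[:, 1].min() - bandwidth_m,
                  pts[:, 0].max() + bandwidth_m, pts[:, 1].max() + bandwidth_m)
    xmin, ymin, xmax, ymax = bounds
    n_cols = max(1, int(np.ceil((xmax - xmin) / cell_size_m)))
    n_rows = max(1, int(np.ceil((ymax - ymin) / cell_size_m)))
    xs = xmin + (np.arange(n_cols) + 0.5) * cell_size_m
    ys_bottom = ymin + (np.arange(n_rows) + 0.5) * cell_size_m  # south-up

    values = np.zeros((n_rows, n_cols))
    h2 = bandwidth_m ** 2
    norm = 3.0 / (np.pi * h2)
    for (px, py), wi in zip(pts, w):
        # only cells within one bandwidth of the point
        ci = np.flatnonzero(np.abs(xs - px) <= bandwidth_m)
        ri = np.flatnonzero(np.abs(ys_bottom - py) <= bandwidth_m)
        if ci.size == 0 or ri.size == 0:
            continue
        dx = xs[ci] - px
        dy = ys_bottom[ri] - py
        u2 = (dx[None, :] ** 2 + dy[:, None] ** 2) / h2
        k = np.where(u2 <= 1.0, (1.0 - u2) ** 2, 0.0)
        values[np.ix_(ri, ci)] += wi * norm * k
    return RasterGrid(origin_x=xmin, origin_y=ymin, cell_size=cell_size_m,
                      values=values[::-1])  # flip to north-up storage


def classify_hotspots(raster: RasterGrid, n_classes: int = 5) -> RasterGrid:
    """Equal-interval classes over the positive range; zero cells = class 0.

    Returns an integer raster with classes 0..n_classes.  A flat positive
    surface collapses to a single class with a warning.
    """
    if n_classes < 2:
        raise ValueError(f"n_classes must be >= 2, got {n_classes}")
    vals = raster.values
    out = np.zeros(vals.shape, dtype=int)
    pos = vals > 0
    if pos.any():
        lo, hi = vals[pos].min(), vals[pos].max()
        if hi <= lo:
            warnings.warn("flat surface: single hotspot class")
            out[pos] = 1
        else:
            edges = np.linspace(lo, hi, n_classes + 1)
            out[pos] = np.clip(np.searchsorted(edges, vals[pos],
                                               side="left"), 1, n_classes)
    return RasterGrid(origin_x=raster.origin_x, origin_y=raster.origin_y,
                      cell_size=raster.cell_size, values=out)


# ---------------------------------------------------------------------------
# Moran's I

def morans_i(values: np.ndarray, coords: np.ndarray):
    """Global Moran's I with inverse-distance, row-standardized weights.

    Returns ``(I, expected, z, p)`` with the two-sided p-value from the
    normal approximation under the normality assumption.
    """
    x = np.asarray(values, float)
    n = len(x)
    if n < 4:
        raise ValueError("Moran's I needs at least 4 observations")
    pts = np.asarray(coords, float)
    d = np.hypot(pts[:, None, 0] - pts[None, :, 0],
                 pts[:, None, 1] - pts[None, :, 1])
    with np.errstate(divide="ignore"):
        w = 1.0 / d
    np.fill_diagonal(w, 0.0)
    w /= w.sum(axis=1, keepdims=True)  # row-standardize

    z = x - x.mean()
    s0 = w.sum()
    I = (n / s0) * (z @ w @ z) / (z @ z)
    EI = -1.0 / (n - 1)
    s1 = 0.5 * ((w + w.T) ** 2).sum()
    s2 = ((w.sum(axis=1) + w.sum(axis=0)) ** 2).sum()
    varI = ((n ** 2 * s1 - n * s2 + 3 * s0 ** 2)
            / ((n ** 2 - 1) * s0 ** 2)) - EI ** 2
    zscore = (I - EI) / np.sqrt(varI)
    from scipy.stats import norm
    p = 2.0 * norm.sf(abs(zscore))
    return float(I), float(EI), float(zscore), float(p)


# ---------------------------------------------------------------------------
# exploratory regression

@dataclass(frozen=True)
class RegressionCriteria:
    """Screening thresholds for candidate OLS models."""

    max_vars: int = 6
    min_adj_r2: float = 0.3
    max_coef_p: float = 0.05
    max_vif: float = 7.5
    min_jb_p: float = 0.1
    min_sa_p: float = 0.1


def _vifs(X: np.ndarray) -> np.ndarray:
    """VIF per column of the (constant-free) design matrix."""
    k = X.shape[1]
    if k == 1:
        return np.array([1.0])
    out = np.empty(k)
    for j in range(k):
        others = sm.add_constant(np.delete(X, j, axis=1))
        r2 = sm.OLS(X[:, j], others).fit().rsquared
        out[j] = np.inf if r2 >= 1.0 else 1.0 / (1.0 - r2)
    return out


def exploratory_regression(table: pd.DataFrame,
                           criteria: RegressionCriteria = RegressionCriteria(),
                           response: str = "encounter_rate",
                           candidates: Optional[Sequence[str]] = None,
                           coords: Optional[np.ndarray] = None,
                           importance_denominator: str = "containing"):
    """All-subsets OLS of station encounter rates on covariates.

    Fits every non-empty subset of ``candidates`` (default: all non-response
    numeric columns) up to ``criteria.max_vars`` variables, computes the
    diagnostics, and flags which models pass all criteria.  When ``coords``
    (n x 2) is given, residual spatial autocorrelation is tested with
    Moran's I; otherwise that criterion is skipped.

    Returns ``(models, importance)``:

    * ``models`` — one row per fitted model: variable set, adj R^2, max
      VIF, Jarque–Bera and Moran p-values, per-coefficient p's, ``passed``.
    * ``importance`` — per variable, the percentage of models containing
      that variable in which its coefficient is significant, plus the
      dominant coefficient sign.  With m candidates each variable appears
      in 2^(m-1) subsets (32 of the 63 models for 6 candidates), so
      importances are multiples of 100/2^(m-1).  Alternatively
      ``importance_denominator="screened"`` divides by the count of models
      whose coefficients are all significant.
    """
    if candidates is None:
        candidates = [c for c in table.columns
                      if c != response
                      and np.issubdtype(table[c].dtype, np.number)]
    candidates = list(candidates)
    if table[response].isna().any():
        raise ValueError("response contains missing values")
    n = len(table)
    if n <= criteria.max_vars + 2:
        raise ValueError(
            f"need more than max_vars + 2 = {criteria.max_vars + 2} "
            f"stations, got {n}")
    if importance_denominator not in ("screened", "containing"):
        raise ValueError(
            f"unknown importance_denominator {importance_denominator!r}")

    y = table[response].to_numpy(float)
    rows = []
    for k in range(1, min(criteria.max_vars, len(candidates)) + 1):
        for subset in combinations(candidates, k):
            X = table[list(subset)].to_numpy(float)
            try:
                fit = sm.OLS(y, sm.add_constant(X)).fit()
                vifs = _vifs(X)
            except Exception as exc:  # singular designs etc.
                warnings.warn(f"skipping subset {subset}: {exc}")
                continue
            coef_p = dict(zip(subset, fit.pvalues[1:]))
            coef_sign = dict(zip(subset, np.sign(fit.params[1:])))
            jb_p = float(jarque_bera(fit.resid)[1])
            if coords is not None:
                moran_p = morans_i(fit.resid, coords)[3]
            else:
                moran_p = float("nan")
            all_sig = all(p <= criteria.max_coef_p for p in coef_p.values())
            passed = (fit.rsquared_adj >= criteria.min_adj_r2
                      and all_sig
                      and vifs.max() <= criteria.max_vif
                      and jb_p >= criteria.min_jb_p
                      and (np.isnan(moran_p)
                           or moran_p >= criteria.min_sa_p))
            rows.append({
                "variables": "+".join(subset), "n_vars": k,
                "adj_r2": fit.rsquared_adj, "max_vif": float(vifs.max()),
                "jb_p": jb_p, "moran_p": moran_p,
                "coef_p": coef_p, "coef_sign": coef_sign,
                "all_significant": all_sig, "passed": passed,
            })
    models = pd.DataFrame(rows)

    sig_models = models[models["all_significant"]] if len(models) else models
    imp_rows = []
    for var in candidates:
        if importance_denominator == "screened":
            denom_df = sig_models
        else:
            denom_df = models[models["coef_p"].apply(lambda d: var in d)] \
                if len(models) else models
        denom = len(denom_df)
        if denom == 0:
            imp_rows.append({"variable": var, "pct_significant": 0.0,
                             "n_significant": 0, "n_models": 0, "sign": 0})
            continue
        hits = denom_df["coef_p"].apply(
            lambda d: var in d and d[var] <= criteria.max_coef_p)
        signs = denom_df.loc[hits, "coef_sign"].apply(lambda d: d[var])
        sign = int(np.sign(signs.sum())) if len(signs) else 0
        imp_rows.append({"variable": var,
                         "pct_significant": 100.0 * hits.sum() / denom,
                         "n_significant": int(hits.sum()),
                         "n_models": denom, "sign": sign})
    importance = pd.DataFrame(imp_rows).sort_values(
        "pct_significant", ascending=False).reset_index(drop=True)
    return models, importance
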