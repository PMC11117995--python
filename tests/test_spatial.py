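import numpy as np
import pandas as pd
import pytest

from remcam import (RasterGrid, RegressionCriteria, classify_hotspots,
                    exploratory_regression, kde_raster, morans_i)
from remcam.spatial import default_bandwidth


# ---------------------------------------------------------------------------
# quartic KDE raster

def test_single_point_mass_conserved():
    g = kde_raster(np.array([[0.0, 0.0]]), weights=[1.0], bandwidth_m=500.0,
                   cell_size_m=20.0)
    assert g.total_mass() == pytest.approx(1.0, rel=0.01)


def test_weights_linear_and_peak_doubles():
    pts = np.array([[0.0, 0.0], [0.0, 0.0]])
    one = kde_raster(pts[:1], weights=[1.0], bandwidth_m=300.0,
                     cell_size_m=25.0, bounds=(-400, -400, 400, 400))
    two = kde_raster(pts, weights=[1.0, 1.0], bandwidth_m=300.0,
                     cell_size_m=25.0, bounds=(-400, -400, 400, 400))
    np.testing.assert_allclose(two.values, 2 * one.values, atol=1e-12)


def test_translation_equivariance():
    pts = np.array([[100.0, 50.0], [300.0, 250.0]])
    g1 = kde_raster(pts, bandwidth_m=200.0, cell_size_m=50.0,
                    bounds=(0, 0, 400, 400))
    g2 = kde_raster(pts + 1000.0, bandwidth_m=200.0, cell_size_m=50.0,
                    bounds=(1000, 1000, 1400, 1400))
    np.testing.assert_allclose(g1.values, g2.values, atol=1e-12)


def test_matches_bruteforce_cell_sums():
    rng = np.random.default_rng(0)
    pts = rng.uniform(0, 1000, size=(12, 2))
    w = rng.uniform(0.5, 2.0, 12)
    h, cell = 350.0, 100.0
    g = kde_raster(pts, weights=w, bandwidth_m=h, cell_size_m=cell,
                   bounds=(0, 0, 1000, 1000))
    xs, ys = g.cell_centers()
    brute = np.zeros_like(g.values)
    for i, y in enumerate(ys):
        for j, x in enumerate(xs):
            d2 = ((pts[:, 0] - x) ** 2 + (pts[:, 1] - y) ** 2) / h ** 2
            k = np.where(d2 <= 1, (1 - d2) ** 2, 0.0)
            brute[i, j] = (w * 3 / (np.pi * h ** 2) * k).sum()
    np.testing.assert_allclose(g.values, brute, atol=1e-9)


def test_bandwidth_validation_and_empty_points():
    with pytest.raises(ValueError):
        kde_raster(np.array([[0.0, 0.0]]), bandwidth_m=0.0, cell_size_m=10)
    with pytest.warns(UserWarning, match="empty"):
        g = kde_raster(np.empty((0, 2)), bandwidth_m=100.0, cell_size_m=50.0,
                       bounds=(0, 0, 200, 200))
    assert g.values.sum() == 0.0


def test_default_bandwidth_rule():
    pts = np.array([[0.0, 0.0], [100.0, 0.0], [200.0, 0.0]])
    assert default_bandwidth(pts) == pytest.approx(200.0)


def test_ascii_grid_round_trip(tmp_path):
    g = kde_raster(np.array([[50.0, 50.0]]), bandwidth_m=80.0,
                   cell_size_m=25.0, bounds=(0, 0, 100, 100))
    p = tmp_path / "g.asc"
    g.write_ascii(p)
    g2 = RasterGrid.read_ascii(p)
    assert g2.cell_size == g.cell_size
    np.testing.assert_allclose(g2.values, g.values, rtol=1e-9)
    header = p.read_text().splitlines()[:6]
    assert header[0].startswith("ncols")


# ---------------------------------------------------------------------------
# hotspot classes

def test_equal_interval_classes():
    g = RasterGrid(0, 0, 10, np.array([[0.0, 5.0, 10.0]]))
    c = classify_hotspots(g, n_classes=2)
    assert list(c.values.ravel()) == [0, 1, 2]


def test_monotone_transform_preserves_class_order():
    vals = np.array([[0.0, 1.0, 3.0, 9.0]])
    c1 = classify_hotspots(RasterGrid(0, 0, 10, vals), 3).values
    c2 = classify_hotspots(RasterGrid(0, 0, 10, vals ** 2), 3).values
    order1 = np.argsort(c1.ravel(), kind="stable")
    # class labels may differ but ranking of cells cannot invert
    assert (np.diff(c1.ravel()[order1]) >= 0).all()
    assert (np.diff(c2.ravel()[order1]) >= 0).all()


def test_flat_raster_single_class():
    g = RasterGrid(0, 0, 10, np.full((2, 2), 3.3))
    with pytest.warns(UserWarning, match="flat"):
        c = classify_hotspots(g, 4)
    assert set(c.values.ravel()) == {1}


def test_hotspots_concentrate_at_planted_stations():
    """Stations given high weights dominate the top class."""
    rng = np.random.default_rng(1)
    pts = rng.uniform(0, 2000, size=(20, 2))
    w = np.full(20, 0.1)
    w[:4] = 2.0    # planted hotspot stations
    g = kde_raster(pts, weights=w, bandwidth_m=400.0, cell_size_m=50.0)
    c = classify_hotspots(g, 5)
    top = np.argwhere(c.values == 5)
    xs, ys = g.cell_centers()
    top_xy = np.column_stack([xs[top[:, 1]], ys[top[:, 0]]])
    d_hot = np.min(np.hypot(top_xy[:, 0][:, None] - pts[:4, 0],
                            top_xy[:, 1][:, None] - pts[:4, 1]), axis=1)
    assert np.median(d_hot) < 400.0


# ---------------------------------------------------------------------------
# Moran's I

def test_moran_expectation_under_independence():
    rng = np.random.default_rng(2)
    n = 25
    coords = rng.uniform(0, 100, size=(n, 2))
    Is = [morans_i(rng.standard_normal(n), coords)[0] for _ in range(300)]
    assert np.mean(Is) == pytest.approx(-1.0 / (n - 1), abs=0.02)


def test_moran_detects_spatial_trend():
    rng = np.random.default_rng(3)
    coords = rng.uniform(0, 100, size=(30, 2))
    values = coords[:, 0] + rng.normal(0, 5, 30)   # strong west-east trend
    I, EI, z, p = morans_i(values, coords)
    assert I > EI and p < 0.01


# ---------------------------------------------------------------------------
# exploratory regression

def _covariate_table(n=40, seed=4, beta_alt=-0.0008, noise=0.25):
    """Planted altitude effect with noise calibrated so the single-predictor
    fit reaches adj R^2 ~ 0.65, the quality a field regression of encounter
    rates typically attains."""
    rng = np.random.default_rng(seed)
    alt = rng.uniform(1500, 3000, n)
    tab = pd.DataFrame({
        "altitude": alt,
        "dist_settlement": rng.uniform(0, 5000, n),
        "forest_cover": rng.uniform(0, 1, n),
        "aspect": rng.uniform(0, 360, n),
        "slope": rng.uniform(0, 45, n),
        "roughness": rng.uniform(0, 1, n),
    })
    tab["encounter_rate"] = 2.6 + beta_alt * alt + rng.normal(0, noise, n)
    coords = rng.uniform(0, 10_000, size=(n, 2))
    return tab, coords


def test_all_subsets_of_six_gives_63_models():
    tab, coords = _covariate_table()
    models, _ = exploratory_regression(tab, coords=coords)
    assert len(models) == 63          # sum over k of C(6, k)
    assert models["n_vars"].max() == 6


def test_orthogonal_predictors_have_unit_vif():
    n = 32
    x1 = np.tile([1.0, -1.0], n // 2)
    x2 = np.repeat([1.0, -1.0], n // 2)
    tab = pd.DataFrame({"x1": x1, "x2": x2,
                        "encounter_rate": x1 + np.random.default_rng(5)
                        .normal(0, 0.1, n)})
    models, _ = exploratory_regression(
        tab, RegressionCriteria(max_vars=2), candidates=["x1", "x2"])
    both = models[models["variables"] == "x1+x2"].iloc[0]
    assert both["max_vif"] == pytest.approx(1.0, abs=1e-9)


def test_planted_predictor_importance():
    """A real altitude effect is flagged in every model containing it, with
    the correct (negative) sign, in every random table; pure-noise
    covariates are unimportant on average.  (Any single noise covariate
    can be chance-significant in one table at the 5% level, which then
    propagates to all 32 subsets containing it, so the noise check is an
    average over tables.)"""
    noise_imp = []
    for seed in range(8):
        tab, coords = _covariate_table(seed=seed)
        _, imp = exploratory_regression(tab, coords=coords)
        imp = imp.set_index("variable")
        assert imp.loc["altitude", "pct_significant"] == pytest.approx(100.0)
        assert imp.loc["altitude", "sign"] == -1
        noise_imp.extend(imp.loc[["slope", "roughness", "aspect"],
                                 "pct_significant"])
    assert np.mean(noise_imp) < 20.0


def test_importance_denominator_is_models_containing_variable():
    """Each of 6 candidates appears in exactly 2^5 = 32 of the 63 subsets,
    so importances are multiples of 100/32 (the granularity of the
    percentages a 6-variable all-subsets screen can report)."""
    tab, coords = _covariate_table(seed=6)
    models, imp = exploratory_regression(tab, coords=coords)
    assert (imp["n_models"] == 32).all()
    frac = imp["pct_significant"] / 100.0 * 32
    np.testing.assert_allclose(frac, np.round(frac), atol=1e-9)


def test_passed_flag_consistent_with_criteria():
    tab, coords = _covariate_table(seed=7)
    crit = RegressionCriteria()
    models, _ = exploratory_regression(tab, crit, coords=coords)
    for _, row in models.iterrows():
        manual = (row["adj_r2"] >= crit.min_adj_r2
                  and row["all_significant"]
                  and row["max_vif"] <= crit.max_vif
                  and row["jb_p"] >= crit.min_jb_p
                  and row["moran_p"] >= crit.min_sa_p)
        assert row["passed"] == manual


def test_too_few_stations_rejected():
    tab, _ = _covariate_table(n=8)
    with pytest.raises(ValueError, match="stations"):
        exploratory_regression(tab)
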