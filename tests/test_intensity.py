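"""Vertical-speed gridding, cyclic aspect smooth, GCV GAM, AIC comparison."""

import warnings

import numpy as np
import pandas as pd
import pytest

import upliftscape as u
from upliftscape.grid import Raster
from upliftscape.intensity import (ComparisonError, ConfigurationError,
                                   GAM_FRAMEWORKS, filter_percentile)
from upliftscape.suitability import SuitabilityMap
from upliftscape.terrain import PredictorStack


# ---------------------------------------------------------------------------
# gridding and outlier filter
# ---------------------------------------------------------------------------

def test_grid_vertical_speeds_hand_example():
    grid = Raster(np.zeros((4, 4)), cellsize=100.0)
    fixes = pd.DataFrame({
        "x": [50.0, 60.0, 50.0, 150.0, 5000.0],
        "y": [50.0, 50.0, 50.0, 150.0, 50.0],
        "vspeed": [2.0, 4.0, -1.0, 1.5, 9.0],
    })
    cells = u.grid_vertical_speeds(fixes, grid)
    # cell (0,0): positive values 2 and 4 -> mean 3; negative dropped;
    # cell (1,1): single value; outside-grid fix ignored
    assert len(cells) == 2
    c00 = cells[(cells["row"] == 0) & (cells["col"] == 0)].iloc[0]
    assert c00["mean_vspeed"] == pytest.approx(3.0)
    assert c00["n"] == 2
    assert c00["x"] == 50.0 and c00["y"] == 50.0
    c11 = cells[(cells["row"] == 1) & (cells["col"] == 1)].iloc[0]
    assert c11["mean_vspeed"] == pytest.approx(1.5)


def test_grid_requires_vspeed():
    with pytest.raises(ConfigurationError):
        u.grid_vertical_speeds(pd.DataFrame({"x": [1.0], "y": [1.0]}),
                               Raster(np.zeros((3, 3))))


def test_filter_percentile_oracle():
    rng = np.random.default_rng(2)
    v = rng.lognormal(0, 0.5, 10000)
    cells = pd.DataFrame({"row": 0, "col": np.arange(len(v)),
                          "mean_vspeed": v, "n": 1,
                          "x": 50.0, "y": 50.0})
    out = filter_percentile(cells, q=99.97)
    cut = np.percentile(v, 99.97)
    assert len(out) == (v <= cut).sum()
    assert out["mean_vspeed"].max() <= cut
    with pytest.raises(ConfigurationError):
        filter_percentile(cells.iloc[:50])


# ---------------------------------------------------------------------------
# GAM fitting
# ---------------------------------------------------------------------------

def _gam_stack(n=40, seed=0):
    rng = np.random.default_rng(seed)
    layers = {
        "aspect": Raster(rng.uniform(0, 360, (n, n)), cellsize=100.0),
        "ndvi": Raster(rng.uniform(-0.2, 0.9, (n, n)), cellsize=100.0),
        "dem": Raster(rng.uniform(200, 800, (n, n)), cellsize=100.0),
        "roughness": Raster(rng.uniform(0, 60, (n, n)), cellsize=100.0),
        "latitude": Raster(np.tile(np.linspace(45.6, 45.2, n)[:, None],
                                   (1, n)), cellsize=100.0),
        "land_use": Raster(rng.integers(1, 5, (n, n)).astype(float),
                           cellsize=100.0),
        "thermal_uplift": Raster(rng.uniform(0, 3, (n, n)), cellsize=100.0),
        "orographic_uplift": Raster(rng.uniform(0, 2, (n, n)), cellsize=100.0),
    }
    return PredictorStack(layers=layers)


def _quiet_fit(cells, stack, framework, **kw):
    """fit_gam with the expected absent-land-use warning suppressed."""
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*absent from the data.*")
        return u.fit_gam(cells, stack, framework, **kw)


def _cells_from(stack, response_fn, n_cells=700, seed=1, noise=0.05):
    rng = np.random.default_rng(seed)
    nr, nc = stack.grid.shape
    rows = rng.integers(0, nr, n_cells)
    cols = rng.integers(0, nc, n_cells)
    x = stack.grid.x0 + (cols + 0.5) * stack.grid.cellsize
    y = stack.grid.y0 + (rows + 0.5) * stack.grid.cellsize
    vals = {name: stack.layers[name].data[rows, cols]
            for name in stack.layers}
    sqrt_mu = response_fn(vals)
    v = np.clip(sqrt_mu + rng.normal(0, noise, n_cells), 0.05, None) ** 2
    return pd.DataFrame({"row": rows, "col": cols, "x": x, "y": y,
                         "mean_vspeed": v, "n": 10})


def test_cyclic_aspect_periodicity():
    """Fitted aspect effect is exactly periodic: f(0) == f(360)."""
    stack = _gam_stack()
    cells = _cells_from(
        stack, lambda v: 1.0 + 0.3 * np.sin(np.deg2rad(v["aspect"])), seed=3)
    fit = _quiet_fit(cells, stack, "static", select="none")
    curve = fit.smooth_curve("aspect", np.array([0.0, 90.0, 180.0, 360.0]))
    assert abs(curve[0] - curve[-1]) < 1e-6
    # recovers the planted sine shape: south (90+270 avg vs) — check the
    # planted maximum near 90 degrees exceeds the minimum near 270
    g = np.linspace(0, 360, 73)
    c = fit.smooth_curve("aspect", g)
    assert g[np.argmax(c)] == pytest.approx(90.0, abs=30.0)
    assert g[np.argmin(c)] == pytest.approx(270.0, abs=30.0)


def test_gam_recovers_latitude_trend():
    stack = _gam_stack(seed=5)
    cells = _cells_from(
        stack, lambda v: 1.0 + 0.8 * (v["latitude"] - 45.4), seed=6)
    fit = _quiet_fit(cells, stack, "static", select="none")
    g = np.linspace(45.25, 45.55, 20)
    c = fit.smooth_curve("latitude", g)
    slope = np.polyfit(g, c, 1)[0]
    assert slope > 0.3


def test_gam_constant_response_shrinks():
    """GCV on pure noise keeps the smooths near-linear (small EDF)."""
    stack = _gam_stack(seed=7)
    cells = _cells_from(stack, lambda v: np.full(len(v["aspect"]), 1.0),
                        n_cells=400, seed=8, noise=0.1)
    fit = _quiet_fit(cells, stack, "static", select="gcv")
    for name in ("ndvi", "dem", "roughness", "latitude"):
        assert fit.edf_by_term[name] < 3.5, name
    assert fit.adj_r2 < 0.1


def test_gam_guards():
    stack = _gam_stack()
    cells = _cells_from(stack, lambda v: np.full(len(v["aspect"]), 1.0),
                        n_cells=30)
    with pytest.raises(ConfigurationError):
        u.fit_gam(cells, stack, "static")
    with pytest.raises(ConfigurationError):
        u.fit_gam(cells, stack, "weird")


def test_gam_warns_on_absent_land_use():
    stack = _gam_stack(seed=9)
    # only codes 1..4 are present in _gam_stack; classes 5.. missing
    cells = _cells_from(stack, lambda v: np.full(len(v["aspect"]), 1.0),
                        n_cells=200, seed=10, noise=0.1)
    with pytest.warns(UserWarning, match="absent"):
        u.fit_gam(cells, stack, "static", select="none")


def test_dynamic_framework_parametric():
    stack = _gam_stack(seed=11)
    cells = _cells_from(stack, lambda v: 0.8 + 0.25 * v["thermal_uplift"],
                        seed=12)
    fit = u.fit_gam(cells, stack, "dynamic")
    assert fit.smoother is None
    assert "thermal_uplift" in fit.param_names
    coef = np.asarray(fit.result.params)[fit.param_names.index("thermal_uplift")]
    assert coef == pytest.approx(0.25, abs=0.05)


# ---------------------------------------------------------------------------
# framework comparison
# ---------------------------------------------------------------------------

def test_compare_frameworks_identity_and_ranking():
    stack = _gam_stack(seed=13)
    cells = _cells_from(stack, lambda v: 0.8 + 0.3 * v["thermal_uplift"],
                        seed=14)
    f_dyn = u.fit_gam(cells, stack, "dynamic")
    f_sta = _quiet_fit(cells, stack, "static", select="none")
    t = u.compare_frameworks([f_dyn, f_sta])
    assert list(t.columns[:3]) == ["framework", "aic", "adj_r2"]
    assert t["delta_aic"].iloc[0] == 0.0
    assert (t["delta_aic"] >= 0).all()
    # response planted on thermal uplift: dynamic framework wins
    assert t["framework"].iloc[0] == "dynamic"


def test_compare_rejects_different_responses():
    stack = _gam_stack(seed=15)
    a = _cells_from(stack, lambda v: np.full(len(v["aspect"]), 1.0), seed=16)
    b = a.copy()
    b["mean_vspeed"] = b["mean_vspeed"] * 1.5
    fa = u.fit_gam(a, stack, "dynamic")
    fb = u.fit_gam(b, stack, "dynamic")
    with pytest.raises(ComparisonError):
        u.compare_frameworks([fa, fb])


# ---------------------------------------------------------------------------
# intensity map
# ---------------------------------------------------------------------------

def test_predict_intensity_map_rules():
    stack = _gam_stack(seed=17)
    cells = _cells_from(stack, lambda v: 0.8 + 0.3 * v["thermal_uplift"],
                        seed=18)
    fit = u.fit_gam(cells, stack, "dynamic")
    nr, nc = stack.grid.shape
    binary = np.ones((nr, nc))
    binary[:, 0] = 0.0            # unsuitable column
    binary[:, 1] = np.nan         # unclassified column
    suit = SuitabilityMap(
        probability=stack.grid.like(np.full((nr, nc), 0.9), "p"),
        binary=stack.grid.like(binary, "b"),
        mask=np.isnan(binary), threshold=0.5)
    out = u.predict_intensity_map(fit, stack, suit).data
    assert np.isnan(out[:, 0]).all() and np.isnan(out[:, 1]).all()
    inside = out[:, 2:]
    finite = np.isfinite(inside)
    assert finite.mean() > 0.8
    assert (inside[finite] >= 0).all()
    # predictions track the planted mean on the sqrt scale
    th = stack.layers["thermal_uplift"].data[:, 2:][finite]
    r = np.corrcoef(np.sqrt(inside[finite]), 0.8 + 0.3 * th)[0, 1]
    assert r > 0.95
    # out-of-range masking: cells beyond the training thermal range are nodata
    lo, hi = fit.training_ranges["thermal_uplift"]
    over = stack.layers["thermal_uplift"].data[:, 2:] > hi
    assert np.isnan(inside[over]).all()
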