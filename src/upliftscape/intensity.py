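"""Uplift-intensity modelling: gridded positive vertical speeds and GAMs.

Positive fix-level vertical speeds (climbing in uplift) are pooled across
individuals and averaged on the 100 m predictor grid; extreme cell means
(above the 99.97th percentile) are removed.  A Gaussian GAM models the
square-root-transformed cell mean: aspect enters as an exactly periodic
cyclic cubic smooth on [0, 360]; NDVI, elevation, roughness and latitude as
penalized spline smooths; land-use classes (reference: bare soil) and, in
the dynamic/combined frameworks, the thermal and orographic uplift
potentials enter parametrically.  Smoothing weights are selected by
generalized cross-validation.  The intensity map squares the fitted
sqrt-scale prediction on cells that are suitable, within all training
predictor ranges, and within the training latitude span.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from patsy import dmatrix, build_design_matrices
import statsmodels.api as sm
from statsmodels.gam.api import GLMGam
from statsmodels.gam.smooth_basis import (GenericSmoothers,
                                          UnivariateCubicCyclicSplines,
                                          UnivariateBSplines)

from .grid import Raster
from .terrain import PredictorStack
from .suitability import SuitabilityMap
from .synthetic import LAND_USE_NAMES, LAND_USE_CODES

log = logging.getLogger(__name__)

SMOOTH_TERMS = ["aspect", "ndvi", "dem", "roughness", "latitude"]
DYNAMIC_TERMS = ["thermal_uplift", "orographic_uplift"]
REFERENCE_LAND_USE = "bare_soil"

GAM_FRAMEWORKS = {
    "static": {"smooths": SMOOTH_TERMS, "land_use": True, "dynamic": []},
    "dynamic": {"smooths": [], "land_use": False, "dynamic": DYNAMIC_TERMS},
    "combined": {"smooths": SMOOTH_TERMS, "land_use": True,
                 "dynamic": DYNAMIC_TERMS},
}


class ConfigurationError(ValueError):
    pass


class ComparisonError(ValueError):
    pass


def grid_vertical_speeds(fixes: pd.DataFrame, grid: Raster) -> pd.DataFrame:
    """Average positive fix-level vertical speeds per 100 m grid cell.

    ``fixes`` needs ``x``/``y`` and a ``vspeed`` column (see
    :func:`upliftscape.segmentation.compute_fix_metrics`).  Cells without any
    positive value are absent from the output.
    """
    if "vspeed" not in fixes.columns:
        raise ConfigurationError("fixes lack a 'vspeed' column")
    f = fixes[fixes["vspeed"] > 0]
    row, col = grid.rowcol(f["x"].to_numpy(float), f["y"].to_numpy(float))
    nr, nc = grid.shape
    ok = (row >= 0) & (row < nr) & (col >= 0) & (col < nc)
    d = pd.DataFrame({"row": row[ok], "col": col[ok],
                      "vspeed": f["vspeed"].to_numpy(float)[ok]})
    g = d.groupby(["row", "col"])["vspeed"].agg(["mean", "size"]).reset_index()
    g = g.rename(columns={"mean": "mean_vspeed", "size": "n"})
    g["x"] = grid.x0 + (g["col"] + 0.5) * grid.cellsize
    g["y"] = grid.y0 + (g["row"] + 0.5) * grid.cellsize
    return g


def filter_percentile(cells: pd.DataFrame, q: float = 99.97) -> pd.DataFrame:
    """Drop cells whose mean vertical speed exceeds the q-th percentile."""
    if len(cells) < 100:
        raise ConfigurationError("need at least 100 cells to filter outliers")
    cut = np.percentile(cells["mean_vspeed"].to_numpy(float), q)
    out = cells[cells["mean_vspeed"] <= cut].reset_index(drop=True)
    if len(cells) - len(out):
        log.info("filter_percentile: removed %d of %d cells above the "
                 "%.2f percentile (%.3f)", len(cells) - len(out), len(cells),
                 q, cut)
    return out


class _CyclicAspectSmoother(UnivariateCubicCyclicSplines):
    """Cyclic cubic spline with explicit period bounds [0, 360].

    The stock smoother derives its knot span from the data range, so the
    fitted effect is periodic over that span rather than over the compass
    circle; pinning the bounds makes f(0) == f(360) exactly.
    """

    def __init__(self, x, df, variable_name="aspect",
                 bounds=(0.0, 360.0)):
        self._bounds = bounds
        super().__init__(x, df=df, variable_name=variable_name)

    def _smooth_basis_for_single_variable(self):
        lo, hi = self._bounds
        basis = dmatrix(
            f"cc(x, df={self.df}, lower_bound={lo}, upper_bound={hi}) - 1",
            {"x": self.x})
        self.design_info = basis.design_info
        n_inner = self.df - 2 + 1
        inner = np.linspace(lo, hi, n_inner + 2)[1:-1]
        all_knots = np.r_[lo, inner, hi]
        b, d = self._get_b_and_d(all_knots)
        s = self._get_s(b, d)
        return basis, None, None, s

    def transform(self, x_new):
        return build_design_matrices([self.design_info],
                                     {"x": np.asarray(x_new, float)})[0]


@dataclass
class GamFit:
    """Fitted uplift-intensity GAM for one framework."""

    framework: str
    result: object                    # statsmodels results
    smoother: GenericSmoothers | None
    smooth_names: list[str]
    param_names: list[str]
    alpha: list[float]
    aic: float
    adj_r2: float
    edf_by_term: dict[str, float]
    n_obs: int
    training_ranges: dict[str, tuple[float, float]]
    land_use_levels: list[str]
    response_checksum: float          # guards cross-framework AIC comparison

    def smooth_curve(self, name: str, grid: np.ndarray) -> np.ndarray:
        """Fitted partial effect of one smooth term on a value grid."""
        i = self.smooth_names.index(name)
        sm_i = self.smoother.smoothers[i]
        basis = np.asarray(sm_i.transform(np.asarray(grid, float)))
        k0 = len(self.param_names)
        for j in range(i):
            k0 += self.smoother.smoothers[j].dim_basis
        coef = np.asarray(self.result.params)[k0:k0 + sm_i.dim_basis]
        return basis @ coef


def _annotate_cells(cells: pd.DataFrame, stack: PredictorStack,
                    needed: list[str]) -> pd.DataFrame:
    have = [n for n in needed if n not in cells.columns]
    if not have:
        return cells.reset_index(drop=True)
    vals = stack.extract(cells["x"].to_numpy(float), cells["y"].to_numpy(float),
                         have)
    return pd.concat([cells.reset_index(drop=True), vals], axis=1)


def _parametric_design(d: pd.DataFrame, spec: dict,
                       land_use_levels: list[str] | None = None):
    """Constant + land-use dummies (+ dynamic terms); returns (X, names, levels)."""
    cols = {"const": np.ones(len(d))}
    levels: list[str] = []
    if spec["land_use"]:
        codes = d["land_use"].astype(int)
        present = [LAND_USE_NAMES[c] for c in sorted(codes.unique())
                   if LAND_USE_NAMES[c] != REFERENCE_LAND_USE]
        if land_use_levels is None:
            levels = present
        else:
            levels = land_use_levels
        for name in levels:
            cols[f"land_use_{name}"] = (codes == LAND_USE_CODES[name]).astype(float)
    for name in spec["dynamic"]:
        cols[name] = d[name].to_numpy(float)
    X = pd.DataFrame(cols)
    return X, list(X.columns), levels


def fit_gam(cells: pd.DataFrame, stack: PredictorStack,
            framework: str = "static", df_smooth: int = 10,
            df_cyclic: int = 8, select: str = "gcv",
            alpha: list[float] | None = None) -> GamFit:
    """Fit the uplift-intensity GAM on sqrt-transformed cell means.

    ``select='gcv'`` tunes one penalty weight per smooth by coordinate-wise
    generalized cross-validation on a log-spaced grid; pass explicit
    ``alpha`` (one weight per smooth) to skip selection.  Land-use classes
    absent from the data are dropped with a warning.
    """
    if framework not in GAM_FRAMEWORKS:
        raise ConfigurationError(f"unknown framework {framework!r}")
    spec = GAM_FRAMEWORKS[framework]
    needed = list(spec["smooths"]) + list(spec["dynamic"])
    if spec["land_use"]:
        needed.append("land_use")
    d = _annotate_cells(cells, stack, needed)
    n0 = len(d)
    d = d.dropna(subset=needed + ["mean_vspeed"]).reset_index(drop=True)
    if n0 - len(d):
        log.info("fit_gam: dropped %d cells with missing predictors", n0 - len(d))
    if len(d) < 50:
        raise ConfigurationError("too few complete cells to fit the GAM")
    y = np.sqrt(d["mean_vspeed"].to_numpy(float))

    if spec["land_use"]:
        all_classes = {LAND_USE_NAMES[c] for c in d["land_use"].astype(int).unique()}
        absent = set(LAND_USE_CODES) - all_classes
        if absent:
            warnings.warn(f"land-use classes absent from the data dropped "
                          f"from the parametric terms: {sorted(absent)}",
                          stacklevel=2)
    X, param_names, levels = _parametric_design(d, spec)

    smoothers = []
    for name in spec["smooths"]:
        xcol = d[name].to_numpy(float)
        if name == "aspect":
            smoothers.append(_CyclicAspectSmoother(xcol, df=df_cyclic))
        else:
            smoothers.append(UnivariateBSplines(xcol, df=df_smooth, degree=3,
                                                variable_name=name))
    if smoothers:
        smoother = GenericSmoothers(
            d[spec["smooths"]].to_numpy(float), smoothers)
        if alpha is None:
            alpha = ([1.0] * len(smoothers) if select != "gcv"
                     else _select_alpha_gcv(y, X.to_numpy(), smoother))
        model = GLMGam(y, exog=X, smoother=smoother, alpha=alpha)
        res = model.fit()
        edf_total = float(res.edf.sum())
        edf_by_term = {}
        k0 = X.shape[1]
        edf_by_term["parametric"] = float(res.edf[:k0].sum())
        for s, name in zip(smoothers, spec["smooths"]):
            edf_by_term[name] = float(res.edf[k0:k0 + s.dim_basis].sum())
            k0 += s.dim_basis
        fitted = np.asarray(res.fittedvalues)
    else:
        smoother = None
        alpha = []
        model = sm.GLM(y, X, family=sm.families.Gaussian())
        res = model.fit()
        edf_total = float(X.shape[1])
        edf_by_term = {"parametric": edf_total}
        fitted = np.asarray(res.fittedvalues)

    n = len(y)
    rss = float(((y - fitted) ** 2).sum())
    tss_ = float(((y - y.mean()) ** 2).sum())
    adj_r2 = 1.0 - (rss / max(n - edf_total, 1.0)) / (tss_ / (n - 1))

    ranges = {name: (float(d[name].min()), float(d[name].max()))
              for name in needed if name != "land_use"}
    return GamFit(framework=framework, result=res, smoother=smoother,
                  smooth_names=list(spec["smooths"]), param_names=param_names,
                  alpha=list(np.asarray(alpha, float)), aic=float(res.aic),
                  adj_r2=float(adj_r2), edf_by_term=edf_by_term, n_obs=n,
                  training_ranges=ranges, land_use_levels=levels,
                  response_checksum=float(np.sum(y) + len(y)))


def _select_alpha_gcv(y, X, smoother, grid=None, sweeps: int = 2):
    """Coordinate-wise GCV over a log-spaced penalty grid per smooth."""
    grid = grid if grid is not None else np.logspace(-2, 7, 10)
    k = len(smoother.smoothers)
    alpha = [10.0] * k

    def gcv(a):
        res = GLMGam(y, exog=X, smoother=smoother, alpha=a).fit()
        edf = float(res.edf.sum())
        rss = float(((y - res.fittedvalues) ** 2).sum())
        n = len(y)
        return n * rss / (n - edf) ** 2

    for _ in range(sweeps):
        for j in range(k):
            scores = []
            for a in grid:
                trial = list(alpha)
                trial[j] = a
                scores.append(gcv(trial))
            alpha[j] = float(grid[int(np.argmin(scores))])
    return alpha


def compare_frameworks(fits: list[GamFit]) -> pd.DataFrame:
    """AIC ranking table of intensity GAMs fitted to the same response."""
    if len({f.n_obs for f in fits}) > 1 or \
            len({round(f.response_checksum, 6) for f in fits}) > 1:
        raise ComparisonError("fits were not computed on the same response data")
    t = pd.DataFrame({
        "framework": [f.framework for f in fits],
        "aic": [f.aic for f in fits],
        "adj_r2": [f.adj_r2 for f in fits],
    }).sort_values("aic").reset_index(drop=True)
    t["delta_aic"] = t["aic"] - t["aic"].min()
    return t


def predict_intensity_map(fit: GamFit, stack: PredictorStack,
                          suitability: SuitabilityMap) -> Raster:
    """Back-transformed intensity prediction on suitable, in-range cells.

    Cells that are unsuitable or unclassified, outside any training
    predictor range (including the latitude span), or missing a predictor
    are nodata.  Predictions are squared sqrt-scale fits, hence >= 0.
    """
    if suitability is None:
        raise ConfigurationError("a suitability map is required")
    grid = stack.grid
    nr, nc = grid.shape
    spec = GAM_FRAMEWORKS[fit.framework]
    needed = list(spec["smooths"]) + list(spec["dynamic"])
    if spec["land_use"]:
        needed.append("land_use")
    tab = pd.DataFrame({n: stack.layers[n].data.ravel().astype(float)
                        for n in needed})
    ok = ~tab.isna().any(axis=1).to_numpy()
    ok &= suitability.binary.data.ravel() == 1.0
    for name, (lo, hi) in fit.training_ranges.items():
        v = tab[name].to_numpy()
        with np.errstate(invalid="ignore"):
            ok &= (v >= lo) & (v <= hi)
    out = np.full(nr * nc, np.nan)
    if ok.any():
        sub = tab[ok]
        X, _, _ = _parametric_design(sub, spec, land_use_levels=fit.land_use_levels)
        params = np.asarray(fit.result.params)
        eta = X.to_numpy() @ params[:len(fit.param_names)]
        if fit.smoother is not None:
            k0 = len(fit.param_names)
            for s, name in zip(fit.smoother.smoothers, fit.smooth_names):
                basis = np.asarray(s.transform(sub[name].to_numpy(float)))
                eta = eta + basis @ params[k0:k0 + s.dim_basis]
                k0 += s.dim_basis
        out[ok] = np.clip(eta, 0.0, None) ** 2
    return grid.like(out.reshape(nr, nc), "uplift_intensity")
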