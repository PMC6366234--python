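"""Static terrain predictors from a DEM, layer co-registration, and a
multicollinearity screen.

Slope and aspect follow Horn's 3x3 finite-difference method (the de-facto
GIS standard).  Terrain unevenness is quantified both as roughness
(neighbourhood max - min) and the topographic position index (centre minus
mean of the 8 neighbours); slope and aspect unevenness are the 3x3 standard
deviation of slope and the 3x3 circular standard deviation of aspect.  Edge
cells, and cells whose 3x3 window touches a missing value, are set missing.
Aspect of perfectly flat cells is undefined and set missing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .grid import Raster

#: categorical landscape layers (resampled by majority vote, excluded from
#: correlation screens and from continuous range masking)
CATEGORICAL_LAYERS = {"land_use", "urban_footprint"}

TERRAIN_LAYERS = ["slope", "aspect", "roughness", "tpi",
                  "slope_unevenness", "aspect_unevenness"]


class InputError(ValueError):
    pass


@dataclass
class PredictorStack:
    """Co-registered named raster layers plus per-layer training ranges.

    ``training_ranges`` maps continuous layer names to the (min, max) observed
    at the training points; it must be populated (by
    :func:`upliftscape.suitability.assemble_observations`) before any map
    prediction is attempted.
    """

    layers: dict[str, Raster]
    training_ranges: dict[str, tuple[float, float]] | None = None
    training_categories: dict[str, set] | None = None
    categorical: set[str] = field(default_factory=lambda: set(CATEGORICAL_LAYERS))

    def __post_init__(self) -> None:
        shapes = {r.shape for r in self.layers.values()}
        cells = {r.cellsize for r in self.layers.values()}
        origins = {(r.x0, r.y0) for r in self.layers.values()}
        if len(shapes) > 1 or len(cells) > 1 or len(origins) > 1:
            raise InputError("stack layers are not co-registered")

    @property
    def grid(self) -> Raster:
        return next(iter(self.layers.values()))

    def continuous_names(self) -> list[str]:
        return [n for n in self.layers if n not in self.categorical]

    def extract(self, x, y, names: list[str] | None = None) -> pd.DataFrame:
        """Nearest-cell layer values at metric point coordinates."""
        names = names or list(self.layers)
        return pd.DataFrame({n: self.layers[n].sample(x, y) for n in names})


def _window_stack(z: np.ndarray) -> np.ndarray:
    """(9, nr, nc) stack of the 3x3 neighbourhood; NaN beyond the edge.

    Order: [NW, N, NE, W, C, E, SW, S, SE] in the row-0-north convention.
    """
    p = np.pad(z.astype(float), 1, constant_values=np.nan)
    views = []
    for dr in (0, 1, 2):
        for dc in (0, 1, 2):
            views.append(p[dr:dr + z.shape[0], dc:dc + z.shape[1]])
    return np.stack(views)


def derive_terrain(dem: Raster) -> PredictorStack:
    """Slope, aspect, roughness, TPI and unevenness layers from a DEM."""
    z = np.asarray(dem.data, float)
    if z.shape[0] < 3 or z.shape[1] < 3:
        raise InputError("DEM must be at least 3x3 cells")
    w = _window_stack(z)
    nw, n, ne, wst, c, e, sw, s, se = w
    cell = dem.cellsize

    # Horn 1981; y grows southward so "north" rows sit at smaller y
    gx = ((ne + 2 * e + se) - (nw + 2 * wst + sw)) / (8 * cell)  # dz/dx east
    gy = ((nw + 2 * n + ne) - (sw + 2 * s + se)) / (8 * cell)    # dz/dy north
    slope = np.degrees(np.arctan(np.hypot(gx, gy)))
    with np.errstate(invalid="ignore"):
        aspect = np.degrees(np.arctan2(-gx, -gy)) % 360.0  # bearing of downslope
    aspect[(gx == 0) & (gy == 0)] = np.nan  # flat: aspect undefined

    roughness = w.max(axis=0) - w.min(axis=0)
    neighbours = np.delete(w, 4, axis=0)
    tpi = c - neighbours.mean(axis=0)

    # any cell whose 3x3 window touches a missing value is itself missing
    # (Horn's stencil skips the centre, so this must be enforced explicitly)
    bad = np.isnan(w).any(axis=0)
    for a in (slope, aspect, roughness, tpi):
        a[bad] = np.nan

    slope_unev = _window_stack(slope).std(axis=0)
    aspect_unev = _circular_std_deg(_window_stack(aspect))

    def mk(a, name):
        return dem.like(a, name)

    layers = {
        "dem": dem.like(z, "dem"),
        "slope": mk(slope, "slope"),
        "aspect": mk(aspect, "aspect"),
        "roughness": mk(roughness, "roughness"),
        "tpi": mk(tpi, "tpi"),
        "slope_unevenness": mk(slope_unev, "slope_unevenness"),
        "aspect_unevenness": mk(aspect_unev, "aspect_unevenness"),
    }
    return PredictorStack(layers=layers)


def _circular_std_deg(stack: np.ndarray) -> np.ndarray:
    """Circular standard deviation (degrees) over axis 0; NaN-propagating."""
    rad = np.deg2rad(stack)
    c = np.cos(rad).mean(axis=0)
    s = np.sin(rad).mean(axis=0)
    r = np.clip(np.hypot(c, s), 1e-12, 1.0)
    return np.degrees(np.sqrt(-2.0 * np.log(r)))


def align_layers(rasters: dict[str, Raster], target_resolution: float = 100.0,
                 categorical: set[str] | None = None) -> PredictorStack:
    """Co-register layers onto a common grid at ``target_resolution``.

    Finer continuous layers are block-averaged; finer categorical layers are
    resampled by majority vote; layers coarser than the target are upsampled
    by nearest neighbour with a warning.  Layers are cropped to their common
    spatial extent.
    """
    categorical = CATEGORICAL_LAYERS if categorical is None else categorical
    if not rasters:
        raise InputError("no layers to align")
    x0 = max(r.x0 for r in rasters.values())
    y0 = max(r.y0 for r in rasters.values())
    x1 = min(r.x0 + r.shape[1] * r.cellsize for r in rasters.values())
    y1 = min(r.y0 + r.shape[0] * r.cellsize for r in rasters.values())
    if x1 - x0 < target_resolution or y1 - y0 < target_resolution:
        raise InputError("layers have no usable spatial overlap")
    nc = int((x1 - x0) // target_resolution)
    nr = int((y1 - y0) // target_resolution)

    out: dict[str, Raster] = {}
    for name, r in rasters.items():
        is_cat = name in categorical
        if r.cellsize <= target_resolution + 1e-9:
            factor = target_resolution / r.cellsize
            if abs(factor - round(factor)) > 1e-9:
                raise InputError(
                    f"layer {name!r}: resolution {r.cellsize} does not divide "
                    f"the {target_resolution} m target grid")
            f = int(round(factor))
            r0, c0 = r.rowcol(x0 + 1e-9, y0 + 1e-9)
            sub = r.data[r0:r0 + nr * f, c0:c0 + nc * f]
            blocks = sub.reshape(nr, f, nc, f)
            if is_cat:
                flat = blocks.transpose(0, 2, 1, 3).reshape(nr, nc, f * f)
                agg = stats.mode(flat, axis=2, keepdims=False).mode
            else:
                agg = blocks.astype(float).mean(axis=(1, 3))
        else:
            warnings.warn(
                f"layer {name!r} is coarser ({r.cellsize} m) than the "
                f"{target_resolution} m target; nearest-neighbour upsampling",
                stacklevel=2)
            cx = x0 + (np.arange(nc) + 0.5) * target_resolution
            cy = y0 + (np.arange(nr) + 0.5) * target_resolution
            xx, yy = np.meshgrid(cx, cy)
            agg = r.sample(xx.ravel(), yy.ravel()).reshape(nr, nc)
        out[name] = Raster(agg, cellsize=target_resolution, x0=x0, y0=y0,
                           name=name)
    return PredictorStack(layers=out, categorical=set(categorical))


def check_multicollinearity(stack: PredictorStack, points: pd.DataFrame,
                            threshold: float = 0.7) -> pd.DataFrame:
    """Pairwise |Pearson r| screen of continuous layers at point locations.

    ``points`` needs metric ``x``/``y`` columns.  Returns one row per layer
    pair whose |r| exceeds ``threshold`` (columns ``layer_a``, ``layer_b``,
    ``r``); an empty frame means the screen passed.  Layers whose extraction
    is entirely missing are reported with ``r = NaN``.
    """
    if len(points) < 10:
        raise InputError("need at least 10 points for the correlation screen")
    names = stack.continuous_names()
    if len(names) < 2:
        raise InputError("need at least 2 continuous layers")
    vals = stack.extract(points["x"].to_numpy(), points["y"].to_numpy(), names)
    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            pair = vals[[a, b]].dropna()
            if vals[a].notna().sum() == 0 or vals[b].notna().sum() == 0:
                rows.append((a, b, np.nan))
                continue
            if len(pair) < 3 or pair[a].std() == 0 or pair[b].std() == 0:
                continue
            r = float(np.corrcoef(pair[a], pair[b])[0, 1])
            if abs(r) > threshold:
                rows.append((a, b, r))
    return pd.DataFrame(rows, columns=["layer_a", "layer_b", "r"])
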