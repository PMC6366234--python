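"""Accelerometer processing: dynamic body acceleration, activity classes,
burst geolocation, and selection of flapping locations as uplift absences.

Overall dynamic body acceleration (ODBA) removes the static (gravitational)
component — here the per-axis burst mean, bursts being only 3.8 s long —
and sums the absolute dynamic residuals over the three axes.  Per burst,
the mean, sum and standard deviation of ODBA and of the z-axis dynamic
acceleration form six features; k-means with k = 3 on the standardized
features yields least / intermediate / most active classes.  Bursts in the
most-active class flying higher than 100 m above ground mark locations where
a bird flapped despite being well airborne, i.e. where uplift was absent.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .grid import Raster

log = logging.getLogger(__name__)

ODBA_FEATURES = ["odba_mean", "odba_sum", "odba_sd",
                 "dba_z_mean", "dba_z_sum", "dba_z_sd"]

ACTIVITY_LEVELS = ["least", "intermediate", "most"]


class InputError(ValueError):
    pass


class DegenerateInputError(ValueError):
    pass


def compute_odba(bursts: pd.DataFrame, static_window_s: float | None = None) -> pd.DataFrame:
    """Add the six ODBA / z-axis DBA statistics to a burst table.

    ``bursts`` must hold a ``samples`` column of (3, n) arrays (axes x, y, z).
    The static component per axis is the whole-burst mean unless
    ``static_window_s`` requests a running mean of that length (seconds,
    using the ``sampling_rate_hz`` column).
    """
    out = bursts.copy()
    stats_rows = np.empty((len(out), 6))
    for i, (_, row) in enumerate(out.iterrows()):
        s = np.asarray(row["samples"], float)
        if s.ndim != 2 or s.shape[0] != 3 or np.isnan(s).any():
            raise InputError("each burst needs complete (3, n) axis samples")
        if static_window_s is None:
            static = s.mean(axis=1, keepdims=True)
        else:
            k = max(int(round(static_window_s * row["sampling_rate_hz"])), 1)
            kernel = np.ones(k) / k
            static = np.vstack([
                np.convolve(np.pad(ax, (k // 2, k - 1 - k // 2), mode="edge"),
                            kernel, mode="valid") for ax in s])
        dyn = s - static
        odba = np.abs(dyn).sum(axis=0)
        dba_z = np.abs(dyn[2])
        stats_rows[i] = [odba.mean(), odba.sum(), odba.std(ddof=1),
                         dba_z.mean(), dba_z.sum(), dba_z.std(ddof=1)]
    out[ODBA_FEATURES] = stats_rows
    return out


def classify_activity(bursts: pd.DataFrame, k: int = 3, seed: int = 1,
                      n_init: int = 25) -> pd.DataFrame:
    """k-means activity classes from the six ODBA/DBA statistics.

    Features are standardized; clusters are ranked by their centroid
    ``odba_mean`` into least / intermediate / most active.  Deterministic
    given ``seed``.
    """
    if len(bursts) < k:
        raise InputError(f"need at least {k} bursts")
    X = bursts[ODBA_FEATURES].to_numpy(float)
    if len(np.unique(X, axis=0)) < k:
        raise DegenerateInputError(
            "fewer distinct feature vectors than clusters")
    Z = (X - X.mean(axis=0)) / np.where(X.std(axis=0) > 0, X.std(axis=0), 1.0)
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(Z)
    order = np.argsort([X[km.labels_ == c, 0].mean() for c in range(k)])
    level_of = {c: ACTIVITY_LEVELS[r] if k == 3 else str(r)
                for r, c in enumerate(order)}
    out = bursts.copy()
    out["activity_class"] = [level_of[c] for c in km.labels_]
    return out


def geolocate_bursts(bursts: pd.DataFrame, fixes: pd.DataFrame, dem: Raster,
                     max_gap_s: float = 30.0) -> pd.DataFrame:
    """Interpolate burst locations from GPS and derive height above ground.

    Location is the time-linear interpolation between the bracketing GPS
    fixes of the same individual (missing outside the GPS time span).
    Height above ground is assigned only when the nearest fix is closer than
    ``max_gap_s`` seconds: that fix's ellipsoid height minus the DEM value at
    the burst location.
    """
    out = bursts.copy()
    out["x"] = np.nan
    out["y"] = np.nan
    out["height_above_ground"] = np.nan
    out["gps_gap_s"] = np.nan
    n_outside = 0
    for ind, g in out.groupby("individual_id", sort=False):
        f = fixes[fixes["individual_id"] == ind].sort_values("timestamp")
        if f.empty:
            n_outside += len(g)
            continue
        ft = pd.to_datetime(f["timestamp"]).astype("int64").to_numpy() / 1e9
        bt = pd.to_datetime(g["timestamp"]).astype("int64").to_numpy() / 1e9
        inside = (bt >= ft[0]) & (bt <= ft[-1])
        n_outside += int((~inside).sum())
        xi = np.interp(bt, ft, f["x"].to_numpy(float))
        yi = np.interp(bt, ft, f["y"].to_numpy(float))
        xi[~inside] = np.nan
        yi[~inside] = np.nan
        j = np.searchsorted(ft, bt)
        j0 = np.clip(j - 1, 0, len(ft) - 1)
        j1 = np.clip(j, 0, len(ft) - 1)
        nearest = np.where(np.abs(bt - ft[j0]) <= np.abs(ft[j1] - bt), j0, j1)
        gap = np.abs(bt - ft[nearest])
        out.loc[g.index, "x"] = xi
        out.loc[g.index, "y"] = yi
        out.loc[g.index, "gps_gap_s"] = gap
        ok = inside & (gap < max_gap_s)
        if ok.any():
            ground = dem.sample(xi[ok], yi[ok])
            hag = f["height"].to_numpy(float)[nearest[ok]] - ground
            out.loc[g.index[ok], "height_above_ground"] = hag
    if n_outside:
        log.info("geolocate_bursts: %d bursts outside their GPS time span",
                 n_outside)
    return out


def select_flapping(bursts: pd.DataFrame,
                    min_height_m: float = 100.0) -> pd.DataFrame:
    """Uplift absences: most-active bursts above ``min_height_m`` above ground."""
    need = {"activity_class", "height_above_ground"}
    if not need <= set(bursts.columns):
        raise InputError("bursts must be classified and geolocated first")
    sel = bursts[(bursts["activity_class"] == "most")
                 & (bursts["height_above_ground"] > min_height_m)].copy()
    sel["presence"] = 0
    keep = ["individual_id", "timestamp", "x", "y",
            "height_above_ground", "presence"]
    extra = [c for c in ("lon", "lat") if c in sel.columns]
    return sel[keep[:4] + extra + keep[4:]].reset_index(drop=True)
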