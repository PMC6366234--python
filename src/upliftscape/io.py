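"""Movebank-dialect CSV readers and writers.

GPS fixes and accelerometer bursts travel as flat CSV with Movebank column
names (``individual-local-identifier``, ``timestamp``, ``location-long``,
``location-lat``, ``height-above-ellipsoid``, ``ground-speed``); ACC rows
carry the raw samples XYZ-interleaved in ``eobs:accelerations-raw`` plus the
per-axis sampling frequency.  Extra columns (burst id, truth labels) pass
through with dashes for underscores.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .grid import GeoRef

GPS_COLUMNS = {
    "individual_id": "individual-local-identifier",
    "timestamp": "timestamp",
    "lon": "location-long",
    "lat": "location-lat",
    "height": "height-above-ellipsoid",
    "ground_speed": "ground-speed",
    "burst_id": "burst-id",
    "truth_behaviour": "truth-behaviour",
}

ACC_COLUMNS = {
    "individual_id": "individual-local-identifier",
    "timestamp": "timestamp",
    "samples": "eobs:accelerations-raw",
    "sampling_rate_hz": "eobs:acceleration-sampling-frequency-per-axis",
    "truth_behaviour": "truth-behaviour",
    "truth_activity": "truth-activity",
}


def write_gps_csv(fixes: pd.DataFrame, path: str | Path) -> None:
    out = fixes[[c for c in GPS_COLUMNS if c in fixes.columns]].copy()
    out["timestamp"] = pd.to_datetime(out["timestamp"], utc=True).dt.strftime(
        "%Y-%m-%d %H:%M:%S.%f")
    out.rename(columns=GPS_COLUMNS).to_csv(path, index=False)


def read_gps_csv(path: str | Path, georef: GeoRef | None = None,
                 burst_gap_s: float = 5.0) -> pd.DataFrame:
    """Read Movebank-style GPS CSV onto the local metric grid.

    If no burst-id column is present, bursts are reconstructed per
    individual wherever the fix interval exceeds ``burst_gap_s``.
    """
    raw = pd.read_csv(path)
    inv = {v: k for k, v in GPS_COLUMNS.items()}
    df = raw.rename(columns=inv)
    df["timestamp"] = pd.to_datetime(df["timestamp"], utc=True, format="mixed")
    geo = georef or GeoRef()
    df["x"], df["y"] = geo.to_xy(df["lon"].to_numpy(), df["lat"].to_numpy())
    if "burst_id" not in df.columns:
        parts = []
        for ind, g in df.groupby("individual_id", sort=False):
            g = g.sort_values("timestamp").copy()
            gaps = g["timestamp"].diff().dt.total_seconds().fillna(0)
            g["burst_id"] = [f"{ind}_b{k}" for k in (gaps > burst_gap_s).cumsum()]
            parts.append(g)
        df = pd.concat(parts, ignore_index=True)
    return df


def write_acc_csv(bursts: pd.DataFrame, path: str | Path) -> None:
    out = bursts[[c for c in ACC_COLUMNS if c in bursts.columns]].copy()
    out["timestamp"] = pd.to_datetime(out["timestamp"], utc=True).dt.strftime(
        "%Y-%m-%d %H:%M:%S.%f")
    # XYZ-interleaved: x0 y0 z0 x1 y1 z1 ...
    out["samples"] = [
        " ".join(f"{v:.5f}" for v in np.asarray(s).T.ravel())
        for s in out["samples"]]
    out.rename(columns=ACC_COLUMNS).to_csv(path, index=False)


def read_acc_csv(path: str | Path) -> pd.DataFrame:
    raw = pd.read_csv(path)
    inv = {v: k for k, v in ACC_COLUMNS.items()}
    df = raw.rename(columns=inv)
    df["timestamp"] = pd.to_datetime(df["timestamp"], utc=True, format="mixed")
    df["samples"] = [
        np.fromiter((float(v) for v in s.split()), dtype=float)
        .reshape(-1, 3).T for s in df["samples"]]
    return df
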