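"""Minimal raster container and grid geometry.

All analysis runs on a local metric grid (metres, 100 m cells by default)
with raster row 0 at the northern edge and cell values referring to cell
centres.  A linear equirectangular georeference maps grid coordinates to
synthetic longitude/latitude so that latitude can enter the models and the
data can round-trip through Movebank-style CSV.  Rasters are stored on disk
as ESRI ASCII grids (plain text, one file per layer).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

M_PER_DEG_LAT = 111_132.0

__all__ = ["Raster", "GeoRef", "M_PER_DEG_LAT"]


@dataclass(frozen=True)
class GeoRef:
    """Local equirectangular mapping between metric grid and lon/lat.

    ``y`` is a northing measured in metres southward from the northern raster
    edge (so it grows with the row index), matching row-0-north storage.
    """

    lon_west: float = 9.0
    lat_north: float = 46.0
    lat_ref: float = 45.0

    @property
    def m_per_deg_lon(self) -> float:
        return M_PER_DEG_LAT * np.cos(np.deg2rad(self.lat_ref))

    def to_lonlat(self, x, y):
        lon = self.lon_west + np.asarray(x, float) / self.m_per_deg_lon
        lat = self.lat_north - np.asarray(y, float) / M_PER_DEG_LAT
        return lon, lat

    def to_xy(self, lon, lat):
        x = (np.asarray(lon, float) - self.lon_west) * self.m_per_deg_lon
        y = (self.lat_north - np.asarray(lat, float)) * M_PER_DEG_LAT
        return x, y


@dataclass
class Raster:
    """Single-band raster on a regular grid; NaN encodes missing cells."""

    data: np.ndarray
    cellsize: float = 100.0
    x0: float = 0.0  # west edge, metres
    y0: float = 0.0  # north edge, metres (y increases southward)
    name: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ValueError("raster data must be 2-D")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def like(self, data: np.ndarray, name: str | None = None) -> "Raster":
        return replace(self, data=np.asarray(data), name=name or self.name)

    # -- coordinate helpers -------------------------------------------------
    def rowcol(self, x, y):
        """Nearest cell indices for metric coordinates (may be out of range)."""
        col = np.floor((np.asarray(x, float) - self.x0) / self.cellsize).astype(int)
        row = np.floor((np.asarray(y, float) - self.y0) / self.cellsize).astype(int)
        return row, col

    def cell_centers(self):
        """(x, y) metric coordinates of every cell centre, as 2-D arrays."""
        nr, nc = self.shape
        x = self.x0 + (np.arange(nc) + 0.5) * self.cellsize
        y = self.y0 + (np.arange(nr) + 0.5) * self.cellsize
        return np.meshgrid(x, y)

    def sample(self, x, y):
        """Nearest-cell values at metric coordinates; NaN outside the grid."""
        row, col = self.rowcol(x, y)
        row = np.atleast_1d(row)
        col = np.atleast_1d(col)
        nr, nc = self.shape
        ok = (row >= 0) & (row < nr) & (col >= 0) & (col < nc)
        out = np.full(row.shape, np.nan)
        vals = self.data[row[ok], col[ok]]
        out[ok] = vals.astype(float)
        if np.isscalar(x) or np.ndim(x) == 0:
            return float(out[0])
        return out

    # -- text I/O -----------------------------------------------------------
    def write_ascii(self, path: str | Path, fmt: str = "%.6g",
                    nodata: float = -9999.0) -> None:
        nr, nc = self.shape
        data = np.array(self.data, dtype=float)
        data[np.isnan(data)] = nodata
        header = (
            f"ncols {nc}\nnrows {nr}\n"
            f"xllcorner {self.x0}\nyllcorner {self.y0 + nr * self.cellsize}\n"
            f"cellsize {self.cellsize}\nNODATA_value {nodata}\n"
        )
        # note: yllcorner stores the *south* edge in our southward-y frame
        with open(path, "w") as fh:
            fh.write(header)
            np.savetxt(fh, data, fmt=fmt)

    @classmethod
    def read_ascii(cls, path: str | Path, name: str = "") -> "Raster":
        meta: dict[str, float] = {}
        with open(path) as fh:
            for _ in range(6):
                key, val = fh.readline().split()
                meta[key.lower()] = float(val)
            data = np.loadtxt(fh)
        data = np.atleast_2d(data)
        nodata = meta.get("nodata_value", -9999.0)
        data[data == nodata] = np.nan
        cell = meta["cellsize"]
        y0 = meta["yllcorner"] - meta["nrows"] * cell
        return cls(data=data, cellsize=cell, x0=meta["xllcorner"], y0=y0,
                   name=name or Path(path).stem)

    def checksum(self) -> str:
        import hashlib

        return hashlib.sha256(np.ascontiguousarray(self.data).tobytes()).hexdigest()
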