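"""Environmental layers: gridded rasters, water features, and extraction.

Static layers (soil phosphorus in ppm, nitrogen in g/kg, elevation in m and
the slope derived from it) are extracted once per site; dynamic series
(EVI, day land-surface temperature, 5-day precipitation) are extracted at
the last record at or before the time of entry of each visit, never from
the future.  Rasters are plain north-up grids with a metre geotransform,
serialised as ESRI ASCII grids; water features are GeoJSON geometries
handled with shapely in the same projected CRS.

Modelling transforms follow the analysis conventions: distance to water is
square-root transformed (available area grows quadratically with distance),
and slope in degrees is log1p-transformed (many near-flat cells, few steep
ones; log1p keeps 0 degrees finite).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import mapping, shape

logger = logging.getLogger(__name__)

__all__ = [
    "StaticLayer",
    "DynamicSeries",
    "WaterFeatures",
    "read_ascii_grid",
    "extract_static",
    "extract_dynamic",
    "distance_to_water",
    "slope_from_elevation",
    "correlation_screen",
]


@dataclass
class StaticLayer:
    """A single-band north-up raster in a projected metre CRS.

    ``grid[0, 0]`` is the north-west cell; ``x0`` is the west edge and
    ``y0`` the north edge of the grid; ``cell`` the square cell size in
    metres.  Missing cells are NaN.
    """

    name: str
    grid: np.ndarray
    x0: float
    y0: float
    cell: float
    units: str = ""

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=float)
        if self.grid.ndim != 2 or self.grid.size == 0:
            raise ValueError("grid must be a non-empty 2-D array")
        if self.cell <= 0:
            raise ValueError("cell size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape

    def cell_index(self, x: np.ndarray, y: np.ndarray):
        """(row, col) of each point; -1 marks out-of-extent."""
        x = np.atleast_1d(np.asarray(x, float))
        y = np.atleast_1d(np.asarray(y, float))
        col = np.floor((x - self.x0) / self.cell).astype(int)
        row = np.floor((self.y0 - y) / self.cell).astype(int)
        nrow, ncol = self.grid.shape
        # points exactly on the east/south edge belong to the last cell
        col[(col == ncol) & np.isclose(x, self.x0 + ncol * self.cell)] = ncol - 1
        row[(row == nrow) & np.isclose(y, self.y0 - nrow * self.cell)] = nrow - 1
        bad = (col < 0) | (col >= ncol) | (row < 0) | (row >= nrow)
        row[bad] = -1
        col[bad] = -1
        return row, col

    def cell_centres(self):
        nrow, ncol = self.grid.shape
        xs = self.x0 + (np.arange(ncol) + 0.5) * self.cell
        ys = self.y0 - (np.arange(nrow) + 0.5) * self.cell
        return xs, ys

    def write_ascii(self, path, nodata: float = -9999.0) -> None:
        nrow, ncol = self.grid.shape
        g = np.where(np.isfinite(self.grid), self.grid, nodata)
        header = (
            f"ncols {ncol}\nnrows {nrow}\n"
            f"xllcorner {self.x0!r}\nyllcorner {self.y0 - nrow * self.cell!r}\n"
            f"cellsize {self.cell!r}\nNODATA_value {nodata!r}\n"
        )
        with open(path, "w") as fh:
            fh.write(header)
            np.savetxt(fh, g, fmt="%.10g")


def read_ascii_grid(path, name: str = "", units: str = "") -> StaticLayer:
    """Read an ESRI ASCII grid into a :class:`StaticLayer`."""
    meta = {}
    with open(path) as fh:
        pos = fh.tell()
        for _ in range(6):
            key, val = fh.readline().split()
            meta[key.lower()] = float(val)
        grid = np.loadtxt(fh)
    grid = np.atleast_2d(grid)
    nodata = meta.get("nodata_value")
    if nodata is not None:
        grid = np.where(grid == nodata, np.nan, grid)
    cell = meta["cellsize"]
    y0 = meta["yllcorner"] + meta["nrows"] * cell
    return StaticLayer(name or str(path), grid, meta["xllcorner"], y0, cell, units=units)


@dataclass
class DynamicSeries:
    """Time-stamped sequence of raster snapshots (strictly increasing times)."""

    name: str
    times: np.ndarray          # epoch seconds, strictly increasing
    layers: list[StaticLayer]
    cadence_days: float = 0.0

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        if len(self.times) != len(self.layers):
            raise ValueError("times and layers length mismatch")
        if len(self.times) and np.any(np.diff(self.times) <= 0):
            raise ValueError("record times must be strictly increasing")

    def write(self, directory, prefix: str | None = None) -> str:
        """Write each snapshot as .asc plus an index CSV ``timestamp,path``."""
        import os

        prefix = prefix or self.name
        rows = []
        for i, (t, layer) in enumerate(zip(self.times, self.layers)):
            fn = f"{prefix}_{i:04d}.asc"
            layer.write_ascii(os.path.join(directory, fn))
            rows.append({"timestamp": pd.Timestamp(t, unit="s", tz="UTC").isoformat(), "path": fn})
        index = os.path.join(directory, f"{prefix}_index.csv")
        pd.DataFrame(rows).to_csv(index, index=False)
        return index

    @classmethod
    def read(cls, index_csv, name: str = "", cadence_days: float = 0.0) -> "DynamicSeries":
        import os

        idx = pd.read_csv(index_csv)
        base = os.path.dirname(str(index_csv))
        times = pd.to_datetime(idx["timestamp"], utc=True).astype("int64").to_numpy() / 1e9
        layers = [read_ascii_grid(os.path.join(base, p)) for p in idx["path"]]
        return cls(name or str(index_csv), times, layers, cadence_days=cadence_days)


class WaterFeatures:
    """Permanent-water geometries (points, lines, polygons) in metres."""

    def __init__(self, geometries):
        self.geometries = list(geometries)
        self._union = shapely.union_all(self.geometries) if self.geometries else None

    def is_empty(self) -> bool:
        return self._union is None or self._union.is_empty

    def distance_to(self, x, y) -> np.ndarray:
        """Planar Euclidean distance from each (x, y) to the nearest feature."""
        if self.is_empty():
            raise ValueError("no water features")
        pts = shapely.points(np.atleast_1d(np.asarray(x, float)),
                             np.atleast_1d(np.asarray(y, float)))
        return shapely.distance(pts, self._union)

    def buffered(self, buffer: float):
        """Union of all features dilated by ``buffer`` metres (shapely geometry)."""
        if self.is_empty():
            raise ValueError("no water features")
        return self._union.buffer(buffer)

    def to_geojson(self, path) -> None:
        fc = {
            "type": "FeatureCollection",
            "features": [
                {"type": "Feature", "properties": {}, "geometry": mapping(g)}
                for g in self.geometries
            ],
        }
        with open(path, "w") as fh:
            json.dump(fc, fh)

    @classmethod
    def from_geojson(cls, path) -> "WaterFeatures":
        with open(path) as fh:
            gj = json.load(fh)
        if gj.get("type") == "FeatureCollection":
            geoms = [shape(f["geometry"]) for f in gj["features"]]
        elif gj.get("type") == "Feature":
            geoms = [shape(gj["geometry"])]
        else:
            geoms = [shape(gj)]
        return cls(geoms)


def extract_static(layer: StaticLayer, x, y) -> np.ndarray:
    """Nearest-cell value of a static layer at each point (no interpolation).

    Points outside the raster extent or in a NaN cell yield NaN and a
    warning; they are flagged, never silently filled.
    """
    x = np.atleast_1d(np.asarray(x, float))
    y = np.atleast_1d(np.asarray(y, float))
    row, col = layer.cell_index(x, y)
    out = np.full(len(x), np.nan)
    ok = row >= 0
    out[ok] = layer.grid[row[ok], col[ok]]
    n_out = int((~ok).sum())
    if n_out:
        logger.warning("%s: %d point(s) outside raster extent", layer.name, n_out)
    return out


def extract_dynamic(series: DynamicSeries, x, y, t) -> np.ndarray:
    """Value of the last record at or before time ``t`` at each point.

    ``t`` may be scalar or per-point (epoch seconds).  A query time earlier
    than the first record yields NaN (the extraction never looks into the
    future).
    """
    if len(series.layers) == 0:
        raise ValueError(f"empty dynamic series {series.name!r}")
    x = np.atleast_1d(np.asarray(x, float))
    y = np.atleast_1d(np.asarray(y, float))
    t = np.broadcast_to(np.atleast_1d(np.asarray(t, float)), x.shape)
    idx = np.searchsorted(series.times, t, side="right") - 1
    out = np.full(len(x), np.nan)
    for i in np.unique(idx):
        if i < 0:
            continue
        sel = idx == i
        out[sel] = extract_static(series.layers[i], x[sel], y[sel])
    return out


def distance_to_water(x, y, water: WaterFeatures) -> tuple[np.ndarray, np.ndarray]:
    """Distance to the nearest water feature, raw metres and sqrt(metres).

    The square-root transform corrects for the available area growing
    quadratically with distance; the transformed column is the one used in
    models.
    """
    raw = water.distance_to(x, y)
    return raw, np.sqrt(raw)


def slope_from_elevation(elev: StaticLayer) -> StaticLayer:
    """Terrain slope in degrees from an elevation grid (Horn 3x3 gradient).

    Border cells use edge replication.  The modelling transform is
    ``log1p(slope_degrees)``, applied downstream to the extracted values.
    """
    if elev.grid.shape[0] < 3 or elev.grid.shape[1] < 3:
        raise ValueError("elevation grid must be at least 3x3")
    z = np.pad(elev.grid, 1, mode="edge")
    a = z[:-2, :-2]; b = z[:-2, 1:-1]; c = z[:-2, 2:]
    d = z[1:-1, :-2];                  f = z[1:-1, 2:]
    g = z[2:, :-2];  h = z[2:, 1:-1];  i = z[2:, 2:]
    dzdx = ((c + 2 * f + i) - (a + 2 * d + g)) / (8.0 * elev.cell)
    dzdy = ((g + 2 * h + i) - (a + 2 * b + c)) / (8.0 * elev.cell)
    slope_deg = np.degrees(np.arctan(np.hypot(dzdx, dzdy)))
    return StaticLayer("slope", slope_deg, elev.x0, elev.y0, elev.cell, units="degrees")


def correlation_screen(table: pd.DataFrame, threshold: float = 0.5,
                       priority: list[str] | None = None):
    """Drop the lower-priority member of every highly collinear pair.

    Pearson correlations are computed on complete rows; for any pair with
    ``|r|`` *strictly greater* than ``threshold`` the column appearing later
    in ``priority`` is dropped (e.g. nitrogen when it tracks phosphorus).
    Constant columns have undefined correlations; they are flagged in the
    report but never dropped silently.

    Returns
    -------
    retained : list of column names
    report : DataFrame of pairwise correlations (NaN where undefined)
    """
    cols = list(table.columns)
    if len(cols) < 2:
        raise ValueError("need at least 2 columns")
    complete = table.dropna()
    if len(complete) < 3:
        raise ValueError("need at least 3 complete rows")
    if priority is None:
        priority = cols
    order = sorted(cols, key=lambda c: priority.index(c) if c in priority else len(priority))
    corr = complete.corr(method="pearson")
    constant = [c for c in cols if complete[c].nunique() <= 1]
    for c in constant:
        logger.warning("column %r is constant: correlation undefined, retained", c)
    retained: list[str] = []
    for c in order:
        if c in constant:
            retained.append(c)
            continue
        clash = [k for k in retained
                 if k not in constant and abs(corr.loc[c, k]) > threshold]
        if clash:
            logger.info("dropping %r (|r| > %g with %s)", c, threshold, clash)
        else:
            retained.append(c)
    retained = [c for c in cols if c in retained]  # original column order
    return retained, corr
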