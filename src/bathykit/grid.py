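"""Gridded elevation data model and basic queries.

The central type is :class:`BathyGrid`: a regular longitude/latitude grid of
elevation values in meters, negative below sea level (the ETOPO sign
convention).  Values sit on grid nodes (gridline registration, as in ETOPO1);
missing data are represented as NaN, never as sentinel numbers.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

__all__ = [
    "BathyGrid",
    "GeoPoint",
    "Region",
    "DepthWindow",
    "GridError",
    "make_grid",
    "get_depth",
    "subset",
    "decimate",
    "grid_summary",
    "select_records",
]

#: Sanity bound on elevation magnitude (m); Earth's relief fits well inside.
MAX_ABS_ELEVATION = 12_000.0

#: Tolerance (degrees) for judging the grid spacing regular.
SPACING_TOL = 1e-9


class GridError(ValueError):
    """Invalid grid construction or query."""


@dataclass(frozen=True)
class GeoPoint:
    """A geographic coordinate in decimal degrees."""

    lon: float
    lat: float

    def __post_init__(self) -> None:
        if not (-180.0 <= self.lon <= 180.0):
            raise GridError(f"longitude {self.lon} outside [-180, 180]")
        if not (-90.0 <= self.lat <= 90.0):
            raise GridError(f"latitude {self.lat} outside [-90, 90]")


@dataclass(frozen=True)
class Region:
    """Axis-aligned lon/lat rectangle with closed bounds.

    Regions crossing the antimeridian are rejected: ``lon1 < lon2`` is
    required within the [-180, 180] longitude domain.
    """

    lon1: float
    lon2: float
    lat1: float
    lat2: float

    def __post_init__(self) -> None:
        if not (self.lon1 < self.lon2):
            raise GridError(
                f"need lon1 < lon2 (got {self.lon1}, {self.lon2}); "
                "antimeridian-crossing regions are not supported"
            )
        if not (self.lat1 < self.lat2):
            raise GridError(f"need lat1 < lat2 (got {self.lat1}, {self.lat2})")
        for lon in (self.lon1, self.lon2):
            if not (-180.0 <= lon <= 180.0):
                raise GridError(f"longitude {lon} outside [-180, 180]")
        for lat in (self.lat1, self.lat2):
            if not (-90.0 <= lat <= 90.0):
                raise GridError(f"latitude {lat} outside [-90, 90]")

    def contains(self, lon: float, lat: float) -> bool:
        return (self.lon1 <= lon <= self.lon2) and (self.lat1 <= lat <= self.lat2)


@dataclass(frozen=True)
class DepthWindow:
    """Inclusive elevation interval [min_elev, max_elev] in signed meters.

    "Avoid waters shallower than 1000 m" is expressed as
    ``DepthWindow(-12000, -1000)``.
    """

    min_elev: float
    max_elev: float

    def __post_init__(self) -> None:
        if self.min_elev > self.max_elev:
            raise GridError(
                f"min_elev {self.min_elev} exceeds max_elev {self.max_elev}"
            )


@dataclass(frozen=True)
class BathyGrid:
    """Regular lon/lat grid of elevations (m, negative below sea level).

    ``values[i, j]`` is the elevation at ``(lat_axis[i], lon_axis[j])``.
    Both axes ascend and are evenly spaced; NaN marks missing cells.
    """

    lon_axis: np.ndarray
    lat_axis: np.ndarray
    values: np.ndarray
    meta: dict = field(default_factory=dict, compare=False)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def lon_spacing(self) -> float:
        return float(self.lon_axis[1] - self.lon_axis[0])

    @property
    def lat_spacing(self) -> float:
        return float(self.lat_axis[1] - self.lat_axis[0])

    @property
    def bounds(self) -> Region:
        return Region(
            float(self.lon_axis[0]),
            float(self.lon_axis[-1]),
            float(self.lat_axis[0]),
            float(self.lat_axis[-1]),
        )

    def node_point(self, i: int, j: int) -> GeoPoint:
        """The GeoPoint at row *i* (lat index), column *j* (lon index)."""
        return GeoPoint(float(self.lon_axis[j]), float(self.lat_axis[i]))

    def equals(self, other: "BathyGrid", atol: float = 0.0) -> bool:
        """Axis and value equality, treating NaN as equal to NaN."""
        if self.shape != other.shape:
            return False
        return (
            np.allclose(self.lon_axis, other.lon_axis, atol=max(atol, 1e-9), rtol=0)
            and np.allclose(self.lat_axis, other.lat_axis, atol=max(atol, 1e-9), rtol=0)
            and np.allclose(self.values, other.values, atol=atol, rtol=0, equal_nan=True)
        )


def _check_axis(axis: np.ndarray, name: str, lo: float, hi: float) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    if axis.ndim != 1 or axis.size < 2:
        raise GridError(f"{name} axis must be 1-D with at least 2 nodes")
    d = np.diff(axis)
    if np.any(d <= 0):
        raise GridError(f"{name} axis must be strictly increasing")
    if np.max(d) - np.min(d) > SPACING_TOL:
        raise GridError(f"{name} axis spacing irregular beyond {SPACING_TOL} degree")
    if axis[0] < lo - 1e-12 or axis[-1] > hi + 1e-12:
        raise GridError(f"{name} axis outside [{lo}, {hi}]")
    return axis


def make_grid(lon_axis, lat_axis, values, meta: dict | None = None) -> BathyGrid:
    """Build a validated :class:`BathyGrid`.

    Descending axes are accepted and flipped (together with the matching
    ``values`` dimension) so stored axes always ascend.
    """
    lon = np.asarray(lon_axis, dtype=float).copy()
    lat = np.asarray(lat_axis, dtype=float).copy()
    vals = np.asarray(values, dtype=float).copy()
    if vals.ndim != 2:
        raise GridError("values must be a 2-D matrix")
    if lon.ndim != 1 or lat.ndim != 1:
        raise GridError("axes must be 1-D vectors")
    if vals.shape != (lat.size, lon.size):
        raise GridError(
            f"values shape {vals.shape} does not match (n_lat={lat.size}, n_lon={lon.size})"
        )
    if lon.size >= 2 and lon[0] > lon[-1]:
        lon = lon[::-1].copy()
        vals = vals[:, ::-1].copy()
    if lat.size >= 2 and lat[0] > lat[-1]:
        lat = lat[::-1].copy()
        vals = vals[::-1, :].copy()
    lon = _check_axis(lon, "lon", -180.0, 180.0)
    lat = _check_axis(lat, "lat", -90.0, 90.0)
    finite = np.isfinite(vals)
    if np.any(np.isinf(vals)):
        raise GridError("infinite elevation values are not allowed")
    if np.any(np.abs(vals[finite]) >= MAX_ABS_ELEVATION):
        raise GridError(f"elevation magnitude exceeds sanity bound {MAX_ABS_ELEVATION} m")
    grid = BathyGrid(lon, lat, vals, dict(meta or {}))
    grid.lon_axis.setflags(write=False)
    grid.lat_axis.setflags(write=False)
    grid.values.setflags(write=False)
    return grid


def _nearest_index(axis: np.ndarray, x: float) -> int:
    return int(np.argmin(np.abs(axis - x)))


def get_depth(
    grid: BathyGrid,
    point: GeoPoint,
    method: Literal["bilinear", "nearest"] = "bilinear",
) -> float:
    """Elevation at an arbitrary point inside the grid extent.

    Bilinear interpolation of the 4 surrounding nodes by default; a point
    exactly on a node or gridline degenerates gracefully (weight 1 on the
    node / linear along the line).  If a neighbor is missing the nearest
    non-missing of the 4 is used instead; if all 4 are missing, NaN.
    """
    lon, lat = point.lon, point.lat
    b = grid.bounds
    if not b.contains(lon, lat):
        raise GridError(f"point ({lon}, {lat}) outside grid extent")
    if method == "nearest":
        i = _nearest_index(grid.lat_axis, lat)
        j = _nearest_index(grid.lon_axis, lon)
        return float(grid.values[i, j])
    if method != "bilinear":
        raise GridError(f"unknown interpolation method {method!r}")

    j0 = int(np.clip(np.searchsorted(grid.lon_axis, lon, side="right") - 1, 0, grid.lon_axis.size - 2))
    i0 = int(np.clip(np.searchsorted(grid.lat_axis, lat, side="right") - 1, 0, grid.lat_axis.size - 2))
    x = (lon - grid.lon_axis[j0]) / grid.lon_spacing
    y = (lat - grid.lat_axis[i0]) / grid.lat_spacing
    corners = grid.values[i0 : i0 + 2, j0 : j0 + 2]
    w = np.array([[(1 - x) * (1 - y), x * (1 - y)], [(1 - x) * y, x * y]])
    if np.all(np.isfinite(corners)):
        return float(np.sum(w * corners))
    if not np.any(np.isfinite(corners)):
        return float("nan")
    # fall back to nearest non-missing corner by geographic proximity
    best, best_d = float("nan"), np.inf
    for di in (0, 1):
        for dj in (0, 1):
            v = corners[di, dj]
            if np.isfinite(v):
                d = (y - di) ** 2 + ((x - dj) * np.cos(np.radians(lat))) ** 2
                if d < best_d:
                    best, best_d = float(v), d
    return best


def subset(grid: BathyGrid, region: Region) -> BathyGrid:
    """Restrict a grid to the nodes inside *region* (closed bounds)."""
    jmask = (grid.lon_axis >= region.lon1 - 1e-12) & (grid.lon_axis <= region.lon2 + 1e-12)
    imask = (grid.lat_axis >= region.lat1 - 1e-12) & (grid.lat_axis <= region.lat2 + 1e-12)
    if not jmask.any() or not imask.any():
        raise GridError("region does not intersect the grid extent")
    j = np.where(jmask)[0]
    i = np.where(imask)[0]
    return make_grid(
        grid.lon_axis[j[0] : j[-1] + 1],
        grid.lat_axis[i[0] : i[-1] + 1],
        grid.values[i[0] : i[-1] + 1, j[0] : j[-1] + 1],
        grid.meta,
    )


def decimate(grid: BathyGrid, factor: int) -> BathyGrid:
    """Keep every *factor*-th node along both axes, starting at index 0."""
    if not isinstance(factor, (int, np.integer)) or factor < 1:
        raise GridError(f"decimation factor must be a positive integer, got {factor!r}")
    if factor > min(grid.lon_axis.size, grid.lat_axis.size):
        raise GridError("decimation factor exceeds axis length")
    meta = dict(grid.meta)
    if "resolution_arcmin" in meta:
        meta["resolution_arcmin"] = meta["resolution_arcmin"] * factor
    return make_grid(
        grid.lon_axis[::factor], grid.lat_axis[::factor], grid.values[::factor, ::factor], meta
    )


def grid_summary(grid: BathyGrid) -> dict:
    """Basic statistics of the grid, ignoring missing cells.

    The mean is unweighted by cell area; area-weighted accounting lives in
    the geometry module (hypsometry).
    """
    vals = grid.values
    valid = np.isfinite(vals)
    n_valid = int(valid.sum())
    n_total = vals.size
    out = {
        "n_lon": int(grid.lon_axis.size),
        "n_lat": int(grid.lat_axis.size),
        "pct_missing": 100.0 * (n_total - n_valid) / n_total,
    }
    if n_valid:
        v = vals[valid]
        out.update(
            min=float(v.min()),
            max=float(v.max()),
            mean=float(v.mean()),
            pct_below_sea_level=100.0 * float((v < 0).sum()) / n_valid,
        )
    else:
        out.update(min=float("nan"), max=float("nan"), mean=float("nan"),
                   pct_below_sea_level=float("nan"))
    return out


def select_records(table: pd.DataFrame, region: Region) -> pd.DataFrame:
    """Rows of a lon/lat table whose point lies inside *region* (closed bounds).

    Original row order is preserved — the typical use is picking sampling
    records (specimens, stations) inside a study area.
    """
    cols = {c.lower(): c for c in table.columns}
    if "lon" not in cols or "lat" not in cols:
        raise GridError("table must have 'lon' and 'lat' columns")
    lon = table[cols["lon"]].astype(float)
    lat = table[cols["lat"]].astype(float)
    mask = (
        (lon >= region.lon1) & (lon <= region.lon2)
        & (lat >= region.lat1) & (lat <= region.lat2)
    )
    return table.loc[mask]
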