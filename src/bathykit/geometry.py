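"""Spherical-earth metrics: great-circle distance, projected cell areas,
and area-by-depth-zone accounting (hypsometry).

All areas are *projected* surface areas on the sphere — the area each grid
cell covers on the (spherical) sea surface — not slope-corrected seafloor
surface.  The Earth is modelled as a sphere with the authalic radius by
default; the radius is configurable through :class:`EarthModel`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grid import BathyGrid, DepthWindow, GeoPoint

__all__ = [
    "EarthModel",
    "EARTH",
    "haversine_km",
    "cell_areas",
    "zone_area",
    "hypsometry",
]


@dataclass(frozen=True)
class EarthModel:
    """Spherical earth; radius in km (default: authalic radius)."""

    radius_km: float = 6371.0088

    def __post_init__(self) -> None:
        if self.radius_km <= 0:
            raise ValueError("earth radius must be positive")


EARTH = EarthModel()


def haversine_km(p1: GeoPoint, p2: GeoPoint, earth: EarthModel = EARTH) -> float:
    """Great-circle distance between two points via the haversine formula."""
    lam1, phi1 = np.radians([p1.lon, p1.lat])
    lam2, phi2 = np.radians([p2.lon, p2.lat])
    a = (
        np.sin((phi2 - phi1) / 2) ** 2
        + np.cos(phi1) * np.cos(phi2) * np.sin((lam2 - lam1) / 2) ** 2
    )
    return float(2.0 * earth.radius_km * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0))))


def haversine_matrix_km(
    lon1, lat1, lon2, lat2, earth: EarthModel = EARTH
) -> np.ndarray:
    """Vectorized haversine (broadcasting over array inputs), in km."""
    lam1, phi1 = np.radians(lon1), np.radians(lat1)
    lam2, phi2 = np.radians(lon2), np.radians(lat2)
    a = (
        np.sin((phi2 - phi1) / 2) ** 2
        + np.cos(phi1) * np.cos(phi2) * np.sin((lam2 - lam1) / 2) ** 2
    )
    return 2.0 * earth.radius_km * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def cell_areas(grid: BathyGrid, earth: EarthModel = EARTH) -> np.ndarray:
    """Projected area (km^2) of the cell owned by each grid node.

    Nodes are gridline-registered, so each node owns the cell bounded by the
    half-spacing in each direction:

        A = R^2 * dlambda * (sin(phi_top) - sin(phi_bottom))

    with latitude bounds clipped at the poles.  Summed over a grid covering
    the full sphere this reproduces 4*pi*R^2 exactly (up to rounding).
    """
    dlon = np.radians(grid.lon_spacing)
    half = grid.lat_spacing / 2.0
    top = np.clip(grid.lat_axis + half, -90.0, 90.0)
    bot = np.clip(grid.lat_axis - half, -90.0, 90.0)
    band = earth.radius_km**2 * dlon * (np.sin(np.radians(top)) - np.sin(np.radians(bot)))
    return np.repeat(band[:, None], grid.lon_axis.size, axis=1)


def zone_area(grid: BathyGrid, window: DepthWindow, earth: EarthModel = EARTH) -> float:
    """Total projected area (km^2) of non-missing cells whose elevation lies
    within *window* (inclusive on both ends)."""
    areas = cell_areas(grid, earth)
    v = grid.values
    mask = np.isfinite(v) & (v >= window.min_elev) & (v <= window.max_elev)
    return float(areas[mask].sum())


def hypsometry(grid: BathyGrid, breaks, earth: EarthModel = EARTH) -> pd.DataFrame:
    """Distribution of projected area by elevation interval.

    *breaks* is an ascending list of elevations (m).  Intervals are
    half-open ``[b_i, b_{i+1})`` except the last, which is closed, so the
    intervals partition ``[breaks[0], breaks[-1]]`` and the per-interval
    areas sum to the area of that window.  Returns a DataFrame with columns
    ``lower``, ``upper``, ``area_km2``, ``pct`` (percent of total non-missing
    area inside the break range); missing cells are excluded and reported in
    ``df.attrs['missing_area_km2']``.
    """
    breaks = np.asarray(breaks, dtype=float)
    if breaks.size < 2:
        raise ValueError("need at least 2 breaks")
    if np.any(np.diff(breaks) <= 0):
        raise ValueError("breaks must be strictly ascending")
    areas = cell_areas(grid, earth)
    v = grid.values
    finite = np.isfinite(v)
    rows = []
    for lo, hi in zip(breaks[:-1], breaks[1:]):
        if hi == breaks[-1]:
            sel = finite & (v >= lo) & (v <= hi)
        else:
            sel = finite & (v >= lo) & (v < hi)
        rows.append({"lower": lo, "upper": hi, "area_km2": float(areas[sel].sum())})
    df = pd.DataFrame(rows)
    total = df["area_km2"].sum()
    df["pct"] = 100.0 * df["area_km2"] / total if total > 0 else 0.0
    df.attrs["missing_area_km2"] = float(areas[~finite].sum())
    df.attrs["total_area_km2"] = float(total)
    return df
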