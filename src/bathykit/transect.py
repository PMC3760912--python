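"""Depth cross-sections along great-circle segments and belt transects.

Stations are placed by spherical linear interpolation (equal arc spacing)
between the two endpoints; depths come from bilinear interpolation on the
grid, so profiles over smooth synthetic surfaces are smooth.  A belt
transect collects every grid node within a fixed great-circle cross-track
distance of the survey line.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import EARTH, EarthModel, haversine_km
from .grid import BathyGrid, GeoPoint, GridError, get_depth

__all__ = ["Profile", "sample_segment", "depth_profile", "belt_transect"]


@dataclass(frozen=True)
class Profile:
    """Along-track distances (km from start) with interpolated depths (m).

    ``outside`` flags stations that fall outside the grid extent (their
    depth is NaN).
    """

    along_km: np.ndarray
    depth: np.ndarray
    endpoints: tuple[GeoPoint, GeoPoint]
    outside: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"along_km": self.along_km, "depth": self.depth, "outside": self.outside}
        )


def _unit_vector(p: GeoPoint) -> np.ndarray:
    lam, phi = np.radians(p.lon), np.radians(p.lat)
    return np.array(
        [np.cos(phi) * np.cos(lam), np.cos(phi) * np.sin(lam), np.sin(phi)]
    )


def sample_segment(p1: GeoPoint, p2: GeoPoint, n_stations: int) -> list[GeoPoint]:
    """*n* points equally spaced in arc length along the great circle from
    p1 to p2 (endpoints included); antipodal endpoints are rejected because
    the connecting great circle is not unique."""
    if n_stations < 2:
        raise GridError("need at least 2 stations")
    u, v = _unit_vector(p1), _unit_vector(p2)
    omega = np.arccos(np.clip(np.dot(u, v), -1.0, 1.0))
    if np.pi - omega < 1e-9:
        raise GridError("endpoints are antipodal; great-circle path undefined")
    t = np.linspace(0.0, 1.0, n_stations)
    if omega < 1e-12:  # coincident endpoints: constant path
        pts = np.tile(u, (n_stations, 1))
    else:
        s = np.sin(omega)
        pts = (np.sin((1 - t)[:, None] * omega) * u + np.sin(t[:, None] * omega) * v) / s
    lats = np.degrees(np.arcsin(np.clip(pts[:, 2], -1.0, 1.0)))
    lons = np.degrees(np.arctan2(pts[:, 1], pts[:, 0]))
    out = [GeoPoint(float(lo), float(la)) for lo, la in zip(lons, lats)]
    # endpoints exactly as given (avoids 1e-16 wobble from the round trip)
    out[0], out[-1] = p1, p2
    return out


def default_n_stations(grid: BathyGrid, p1: GeoPoint, p2: GeoPoint,
                       earth: EarthModel = EARTH) -> int:
    """Station count giving roughly one station per grid cell at the
    segment midlatitude."""
    length = haversine_km(p1, p2, earth)
    midlat = 0.5 * (p1.lat + p2.lat)
    cell_km = (
        earth.radius_km
        * np.radians(min(grid.lon_spacing * np.cos(np.radians(midlat)), grid.lat_spacing))
    )
    return max(2, int(np.ceil(length / max(cell_km, 1e-9))) + 1)


def depth_profile(
    grid: BathyGrid,
    p1: GeoPoint,
    p2: GeoPoint,
    n_stations: int | None = None,
    earth: EarthModel = EARTH,
) -> Profile:
    """Bilinear depth at equally spaced stations along the p1-p2 great circle.

    Stations outside the grid get NaN depth and are flagged; if both
    endpoints are outside the extent the profile is refused.
    """
    b = grid.bounds
    if not (b.contains(p1.lon, p1.lat) or b.contains(p2.lon, p2.lat)):
        raise GridError("both endpoints lie outside the grid extent")
    if n_stations is None:
        n_stations = default_n_stations(grid, p1, p2, earth)
    stations = sample_segment(p1, p2, n_stations)
    total = haversine_km(p1, p2, earth)
    along = np.linspace(0.0, total, n_stations)
    depths = np.empty(n_stations)
    outside = np.zeros(n_stations, dtype=bool)
    for k, s in enumerate(stations):
        if b.contains(s.lon, s.lat):
            depths[k] = get_depth(grid, s, method="bilinear")
        else:
            depths[k] = np.nan
            outside[k] = True
    return Profile(along, depths, (p1, p2), outside)


def belt_transect(
    grid: BathyGrid,
    p1: GeoPoint,
    p2: GeoPoint,
    half_width_km: float,
    earth: EarthModel = EARTH,
) -> pd.DataFrame:
    """Grid nodes within *half_width_km* cross-track distance of the p1-p2
    geodesic, with along-track coordinate inside [0, segment length].

    Returns a DataFrame with columns lon, lat, depth, along_km, across_km
    (signed: positive to the left of the track), sorted by along_km.
    """
    if half_width_km <= 0:
        raise GridError("half_width_km must be positive")
    if p1.lon == p2.lon and p1.lat == p2.lat:
        raise GridError("degenerate transect: endpoints coincide")
    R = earth.radius_km
    u, v = _unit_vector(p1), _unit_vector(p2)
    # unit normal of the great-circle plane; cross-track = angle from plane
    nrm = np.cross(u, v)
    nrm = nrm / np.linalg.norm(nrm)
    LON, LAT = np.meshgrid(grid.lon_axis, grid.lat_axis)
    lam, phi = np.radians(LON), np.radians(LAT)
    px = np.cos(phi) * np.cos(lam)
    py = np.cos(phi) * np.sin(lam)
    pz = np.sin(phi)
    dot_n = px * nrm[0] + py * nrm[1] + pz * nrm[2]
    xt = np.arcsin(np.clip(dot_n, -1.0, 1.0))  # signed cross-track angle
    d13 = np.arccos(np.clip(px * u[0] + py * u[1] + pz * u[2], -1.0, 1.0))
    with np.errstate(invalid="ignore"):
        at = np.arccos(np.clip(np.cos(d13) / np.cos(xt), -1.0, 1.0))
    # along-track sign: project onto the track direction at p1
    t1 = np.cross(nrm, u)
    sgn = px * t1[0] + py * t1[1] + pz * t1[2]
    at = np.where(sgn >= 0, at, -at)
    total = haversine_km(p1, p2, earth)
    keep = (np.abs(xt) * R <= half_width_km) & (at * R >= -1e-9) & (at * R <= total + 1e-9)
    df = pd.DataFrame(
        {
            "lon": LON[keep],
            "lat": LAT[keep],
            "depth": grid.values[keep],
            "along_km": np.clip(at[keep] * R, 0.0, total),
            "across_km": xt[keep] * R,
        }
    )
    return df.sort_values(["along_km", "across_km"], kind="mergesort").reset_index(drop=True)
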