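"""Shared fixtures and independent oracles for the suite.

Oracles here deliberately re-derive quantities from first principles
(numerical integration, heap-based graph search, brute enumeration) so they
never share code paths with the implementation they check.
"""

from __future__ import annotations

import heapq
import io as _io
import math

import numpy as np
import pandas as pd
import pytest

import bathykit as bk

EARTH_R = 6371.0088


# ---------------------------------------------------------------------------
# grids

@pytest.fixture
def tiny_grid():
    """2x2 unit grid with simple values."""
    return bk.make_grid([0.0, 1.0], [0.0, 1.0], [[-10.0, -20.0], [-30.0, -40.0]])


@pytest.fixture
def ramp_grid():
    """Planar field z = -(100*lon + 50*lat): bilinear interpolation is exact."""
    return bk.generate(bk.SynthSpec(
        "ramp", bk.Region(0.0, 2.0, 0.0, 2.0), 0.25,
        params={"c0": 0.0, "cx": -100.0, "cy": -50.0}))


@pytest.fixture
def seamount_grid():
    return bk.generate(bk.SynthSpec(
        "seamount", bk.Region(-3.0, 3.0, -3.0, 3.0), 0.1,
        params={"base_depth": 5000.0, "height": 4000.0, "sigma_deg": 1.0}))


@pytest.fixture
def two_basins_grid():
    return bk.generate(bk.SynthSpec(
        "two_basins", bk.Region(-2.0, 2.0, -2.0, 2.0), 0.2))


# ---------------------------------------------------------------------------
# independent oracles

def oracle_haversine_km(lon1, lat1, lon2, lat2, radius=EARTH_R):
    """Great-circle distance via the vector (chord) formula — an
    independent route that never evaluates the haversine."""
    def unit(lon, lat):
        lam, phi = math.radians(lon), math.radians(lat)
        return (math.cos(phi) * math.cos(lam),
                math.cos(phi) * math.sin(lam),
                math.sin(phi))
    u, v = unit(lon1, lat1), unit(lon2, lat2)
    dot = max(-1.0, min(1.0, sum(a * b for a, b in zip(u, v))))
    return radius * math.acos(dot)


def oracle_cell_area_km2(lat_deg, dlon_deg, dlat_deg, radius=EARTH_R, n=2000):
    """Projected area of one node cell by dense numerical integration of
    R^2 cos(phi) dphi dlambda over the half-spacing bounds."""
    top = min(lat_deg + dlat_deg / 2.0, 90.0)
    bot = max(lat_deg - dlat_deg / 2.0, -90.0)
    phis = np.linspace(math.radians(bot), math.radians(top), n)
    band = np.trapezoid(np.cos(phis), phis)
    return radius**2 * math.radians(dlon_deg) * band


_ORACLE_STEPS = {
    4: [(0, 1), (0, -1), (1, 0), (-1, 0)],
    8: [(di, dj) for di in (-1, 0, 1) for dj in (-1, 0, 1) if (di, dj) != (0, 0)],
    16: [(di, dj) for di in (-1, 0, 1) for dj in (-1, 0, 1) if (di, dj) != (0, 0)]
        + [(1, 2), (2, 1), (-1, 2), (-2, 1), (1, -2), (2, -1), (-1, -2), (-2, -1)],
}


def oracle_shortest_path_km(grid, passable, src_ij, dst_ij, neighborhood):
    """Plain heapq Dijkstra over passable grid nodes; edge weights from the
    chord-formula distance.  Returns the length in km or None if no path."""
    n_lat, n_lon = passable.shape
    if not passable[src_ij] or not passable[dst_ij]:
        return None
    dist = {src_ij: 0.0}
    heap = [(0.0, src_ij)]
    done = set()
    while heap:
        d, node = heapq.heappop(heap)
        if node in done:
            continue
        if node == dst_ij:
            return d
        done.add(node)
        i, j = node
        for di, dj in _ORACLE_STEPS[neighborhood]:
            ii, jj = i + di, j + dj
            if 0 <= ii < n_lat and 0 <= jj < n_lon and passable[ii, jj]:
                w = oracle_haversine_km(
                    grid.lon_axis[j], grid.lat_axis[i],
                    grid.lon_axis[jj], grid.lat_axis[ii])
                nd = d + w
                if nd < dist.get((ii, jj), math.inf) - 1e-12:
                    dist[(ii, jj)] = nd
                    heapq.heappush(heap, (nd, (ii, jj)))
    return None


def make_etopo_response(region, res_arcmin=1.0, depth=-2000.0, sep=","):
    """Canned remote-service response: lon,lat,depth triples printed at
    6 decimals, gridline-registered at the requested resolution."""
    from bathykit.io import expected_shape

    n_lat, n_lon = expected_shape(region, res_arcmin)
    step = res_arcmin / 60.0
    lon = region.lon1 + step * np.arange(n_lon)
    lat = region.lat1 + step * np.arange(n_lat)
    LO = np.tile(lon, n_lat)
    LA = np.repeat(lat, n_lon)
    buf = _io.StringIO()
    df = pd.DataFrame({"lon": LO, "lat": LA, "z": np.full(LO.size, depth)})
    df.to_csv(buf, index=False, header=False, sep=sep if sep != " " else " ",
              float_format="%.6f")
    return buf.getvalue()


def random_full_grid(rng, max_n=6):
    """Small random grid with finite values, for round-trip properties."""
    n_lon = int(rng.integers(2, max_n + 1))
    n_lat = int(rng.integers(2, max_n + 1))
    d = float(rng.choice([0.1, 0.25, 0.5, 1.0]))
    lon0 = float(rng.uniform(-170, 160))
    lat0 = float(rng.uniform(-80, 70))
    vals = rng.uniform(-11000, 5000, size=(n_lat, n_lon))
    return bk.make_grid(lon0 + d * np.arange(n_lon),
                        lat0 + d * np.arange(n_lat), vals)
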