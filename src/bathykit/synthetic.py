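"""Deterministic synthetic bathymetry and site tables with known analytic
structure, so every feature of the toolkit can be exercised offline.

Each generator evaluates a closed-form surface on a regular grid and records
the analytic truths (summit location, coastline/isobath radii, strait
position) that test oracles need, so expected answers can be computed
without reading the grid back.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grid import BathyGrid, DepthWindow, GridError, Region, make_grid

__all__ = ["SynthSpec", "generate", "generate_sites"]

KINDS = ("flat", "ramp", "seamount", "island_cone", "two_basins", "archipelago")

#: guard against accidentally huge test grids
MAX_NODES = 10_000_000


@dataclass(frozen=True)
class SynthSpec:
    """Full description of a synthetic grid; the same spec always yields an
    identical grid (generators are seed-deterministic and platform-stable)."""

    kind: str
    region: Region = Region(-5.0, 5.0, -5.0, 5.0)
    resolution_deg: float = 0.1
    params: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise GridError(f"unknown synthetic kind {self.kind!r}; choose from {KINDS}")
        if self.resolution_deg <= 0:
            raise GridError("resolution_deg must be positive")


def _axes(spec: SynthSpec) -> tuple[np.ndarray, np.ndarray]:
    r, d = spec.region, spec.resolution_deg
    n_lon = int(round((r.lon2 - r.lon1) / d)) + 1
    n_lat = int(round((r.lat2 - r.lat1) / d)) + 1
    if n_lon * n_lat > MAX_NODES:
        raise GridError(f"spec would produce {n_lon * n_lat} nodes (> {MAX_NODES})")
    return r.lon1 + d * np.arange(n_lon), r.lat1 + d * np.arange(n_lat)


def generate(spec: SynthSpec) -> BathyGrid:
    """Evaluate the spec's closed-form surface on its grid.

    Analytic metadata for oracles is stored in ``grid.meta['analytic']``.
    Radial surfaces measure distance in degrees in lon/lat coordinate space
    (not great-circle km), which keeps their level sets exact circles on the
    grid — the property the contour and area oracles rely on.
    """
    lon, lat = _axes(spec)
    LON, LAT = np.meshgrid(lon, lat)
    p = spec.params
    analytic: dict = {"kind": spec.kind}

    if spec.kind == "flat":
        depth = p.get("depth", -500.0)
        Z = np.full(LON.shape, float(depth))
        analytic["depth"] = depth

    elif spec.kind == "ramp":
        # plane z = c0 + cx*lon + cy*lat (bilinear interpolation is exact on it)
        c0 = p.get("c0", -2000.0)
        cx = p.get("cx", 100.0)
        cy = p.get("cy", 50.0)
        Z = c0 + cx * LON + cy * LAT
        analytic.update(c0=c0, cx=cx, cy=cy)

    elif spec.kind == "seamount":
        # Gaussian mount on a flat abyssal plain: z = -D + H*exp(-r^2 / 2 sigma^2)
        D = p.get("base_depth", 5000.0)
        H = p.get("height", 4000.0)
        sigma = p.get("sigma_deg", 1.0)
        cx_, cy_ = p.get("center", (0.0, 0.0))
        r2 = (LON - cx_) ** 2 + (LAT - cy_) ** 2
        Z = -D + H * np.exp(-r2 / (2 * sigma**2))
        analytic.update(base_depth=D, height=H, sigma_deg=sigma, summit=(cx_, cy_),
                        summit_elev=-D + H)

    elif spec.kind == "island_cone":
        # cone: z = peak - slope*r ; coastline where z crosses 0
        peak = p.get("peak", 200.0)
        base_radius = p.get("base_radius_deg", 1.0)
        floor = p.get("floor", -4000.0)
        cx_, cy_ = p.get("center", (0.0, 0.0))
        slope = peak / base_radius  # m per degree; z=0 exactly at base_radius
        r = np.sqrt((LON - cx_) ** 2 + (LAT - cy_) ** 2)
        Z = np.maximum(peak - slope * r, floor)
        analytic.update(peak=peak, slope_m_per_deg=slope, center=(cx_, cy_),
                        coastline_radius_deg=base_radius, floor=floor)
        # radius of the isobath/contour at elevation L: r = (peak - L)/slope
        analytic["isobath_radius_deg"] = lambda level: (peak - level) / slope

    elif spec.kind == "two_basins":
        # two deep basins split by a shallow meridional ridge with exactly one
        # deep strait, so least-cost corridors are analytically predictable;
        # the ridge spans >= 3 node columns so no neighborhood (including
        # knight moves) can jump it outside the strait
        basin = p.get("basin_depth", -4000.0)
        ridge = p.get("ridge_depth", -200.0)
        strait = p.get("strait_depth", -3000.0)
        ridge_lon = p.get("ridge_lon", 0.5 * (spec.region.lon1 + spec.region.lon2))
        strait_lat = p.get("strait_lat", 0.5 * (spec.region.lat1 + spec.region.lat2))
        ridge_halfwidth = p.get("ridge_halfwidth_deg", 1.5 * spec.resolution_deg)
        Z = np.full(LON.shape, float(basin))
        on_ridge = np.abs(LON - ridge_lon) <= ridge_halfwidth + 1e-12
        Z[on_ridge] = ridge
        in_strait = on_ridge & (np.abs(LAT - strait_lat) <= spec.resolution_deg / 2 + 1e-12)
        Z[in_strait] = strait
        analytic.update(basin_depth=basin, ridge_depth=ridge, strait_depth=strait,
                        ridge_lon=ridge_lon, strait_lat=strait_lat)

    elif spec.kind == "archipelago":
        # island cones scattered on an abyssal plain; seeded placement.
        # submarine flanks are steeper than the subaerial cone so the
        # seafloor between islands returns to the abyssal floor
        n_isl = p.get("n_islands", 4)
        floor = p.get("floor", -5000.0)
        peak = p.get("peak", 500.0)
        base_radius = p.get("base_radius_deg", 0.8)
        flank_slope = p.get("flank_slope_m_per_deg", -floor / (2.0 * base_radius))
        rng = np.random.default_rng(spec.seed)
        r0 = spec.region
        margin = base_radius
        cxs = rng.uniform(r0.lon1 + margin, r0.lon2 - margin, n_isl)
        cys = rng.uniform(r0.lat1 + margin, r0.lat2 - margin, n_isl)
        slope = peak / base_radius
        Z = np.full(LON.shape, float(floor))
        for cx_, cy_ in zip(cxs, cys):
            r = np.sqrt((LON - cx_) ** 2 + (LAT - cy_) ** 2)
            zi = np.where(r <= base_radius, peak - slope * r,
                          -(r - base_radius) * flank_slope)
            Z = np.maximum(Z, np.maximum(zi, floor))
        analytic.update(floor=floor, peak=peak, base_radius_deg=base_radius,
                        flank_slope_m_per_deg=flank_slope,
                        centers=list(zip(cxs.tolist(), cys.tolist())))
    else:  # pragma: no cover - guarded in SynthSpec
        raise GridError(spec.kind)

    meta = {"source": f"synthetic:{spec.kind}",
            "resolution_arcmin": spec.resolution_deg * 60.0,
            "analytic": analytic}
    return make_grid(lon, lat, Z, meta)


def generate_sites(
    grid: BathyGrid,
    n: int,
    constraint: DepthWindow = DepthWindow(-12_000.0, 0.0),
    seed: int = 0,
) -> pd.DataFrame:
    """Draw *n* labeled sites on grid nodes satisfying *constraint*.

    Sampling is without replacement from the eligible nodes using a seeded
    generator, so the same arguments always produce the same table.
    Returns a DataFrame with columns ``label``, ``lon``, ``lat``.
    """
    if n < 1:
        raise GridError("n must be >= 1")
    v = grid.values
    ok = np.isfinite(v) & (v >= constraint.min_elev) & (v <= constraint.max_elev)
    idx = np.flatnonzero(ok)
    if idx.size == 0:
        raise GridError("no grid cell satisfies the depth constraint")
    if n > idx.size:
        raise GridError(f"requested {n} sites but only {idx.size} cells qualify")
    rng = np.random.default_rng(seed)
    chosen = np.sort(rng.choice(idx, size=n, replace=False))
    ii, jj = np.unravel_index(chosen, v.shape)
    return pd.DataFrame(
        {
            "label": [f"site{k + 1:02d}" for k in range(n)],
            "lon": grid.lon_axis[jj],
            "lat": grid.lat_axis[ii],
        }
    )
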