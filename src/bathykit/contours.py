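"""Isobath extraction (marching squares) and publication-style map rendering.

Isobath polylines are traced with marching squares using linear
interpolation along cell edges and the average-of-corners rule for saddle
cells; every vertex therefore lies on a gridline between two nodes that
bracket the contour level.
"""

from __future__ import annotations

from dataclasses import dataclass

import matplotlib

matplotlib.use("Agg")  # headless, deterministic backend

import matplotlib.colors as mcolors
import matplotlib.pyplot as plt
import numpy as np
from matplotlib.ticker import MaxNLocator
from skimage import measure

from .geometry import EARTH, EarthModel, haversine_km
from .grid import BathyGrid, GeoPoint, GridError

__all__ = ["IsobathSet", "isobaths", "expand_levels", "auto_levels", "render_map"]


@dataclass(frozen=True)
class IsobathSet:
    """All contour polylines of one elevation level.

    ``polylines`` is a list of (N, 2) arrays of (lon, lat) vertices;
    ``closed[k]`` is True when polyline k forms a loop.
    """

    level: float
    polylines: list[np.ndarray]
    closed: list[bool]

    def points(self, k: int) -> list[GeoPoint]:
        return [GeoPoint(float(lo), float(la)) for lo, la in self.polylines[k]]

    def perimeter_km(self, k: int, earth: EarthModel = EARTH) -> float:
        poly = self.polylines[k]
        return float(
            sum(
                haversine_km(GeoPoint(*poly[i]), GeoPoint(*poly[i + 1]), earth)
                for i in range(len(poly) - 1)
            )
        )


def isobaths(grid: BathyGrid, levels) -> list[IsobathSet]:
    """Marching-squares contours of the grid at each requested level.

    Levels outside the value range yield empty sets.  Vertices are returned
    in (lon, lat) order; a polyline whose ends coincide is marked closed.
    """
    levels = np.atleast_1d(np.asarray(levels, dtype=float))
    if not np.all(np.isfinite(levels)):
        raise GridError("contour levels must be finite")
    lon0, lat0 = grid.lon_axis[0], grid.lat_axis[0]
    dlon, dlat = grid.lon_spacing, grid.lat_spacing
    out = []
    for level in levels:
        polys, closed = [], []
        for rc in measure.find_contours(grid.values, level):
            lonlat = np.column_stack([lon0 + rc[:, 1] * dlon, lat0 + rc[:, 0] * dlat])
            polys.append(lonlat)
            closed.append(bool(np.allclose(rc[0], rc[-1])))
        out.append(IsobathSet(float(level), polys, closed))
    return out


def expand_levels(deep, shallow, step) -> np.ndarray:
    """Expand grouped (deep, shallow, step) triples into a flat level list.

    Each group contributes the arithmetic sequence deep, deep+step, ...
    capped at shallow; a zero step contributes the single level ``deep``.
    Groups are concatenated, deduplicated and sorted — e.g. groups
    ((-9000, -3000, 1000), (-3000, -10, 1000), (0, 0, 0)) produce 1000-m
    isobaths down to -9000 m plus the coastline at 0.
    """
    deep = np.atleast_1d(np.asarray(deep, dtype=float))
    shallow = np.atleast_1d(np.asarray(shallow, dtype=float))
    step = np.atleast_1d(np.asarray(step, dtype=float))
    if not (deep.size == shallow.size == step.size):
        raise GridError("deep, shallow and step must have equal length")
    levels: list[float] = []
    for d, s, st in zip(deep, shallow, step):
        if d > s:
            raise GridError(f"group deep {d} exceeds shallow {s}")
        if st < 0:
            raise GridError("step must be >= 0")
        if st == 0:
            levels.append(float(d))
        else:
            k = int(np.floor((s - d) / st + 1e-9))
            levels.extend((d + st * np.arange(k + 1)).tolist())
    return np.unique(np.asarray(levels))


def auto_levels(grid: BathyGrid, n: int = 6) -> np.ndarray:
    """Round-number contour levels covering the grid's value range (about
    5-8 levels) — the default when the caller names none."""
    v = grid.values[np.isfinite(grid.values)]
    if v.size == 0:
        return np.array([0.0])
    lo, hi = float(v.min()), float(v.max())
    if lo == hi:
        return np.array([lo])
    ticks = MaxNLocator(nbins=n).tick_values(lo, hi)
    return ticks[(ticks >= lo) & (ticks <= hi)]


def _default_cmap(vmin: float, vmax: float):
    """Monotone blue ramp below sea level, grey-green above, hard break at 0."""
    blues = [(0.03, 0.05, 0.35), (0.1, 0.3, 0.65), (0.55, 0.8, 0.95)]
    lands = [(0.55, 0.65, 0.5), (0.85, 0.85, 0.78), (0.98, 0.98, 0.95)]
    if vmax <= 0:
        return mcolors.LinearSegmentedColormap.from_list("sea", blues), mcolors.Normalize(vmin, vmax)
    if vmin >= 0:
        return mcolors.LinearSegmentedColormap.from_list("land", lands), mcolors.Normalize(vmin, vmax)
    f = (0.0 - vmin) / (vmax - vmin)
    stops = [(0.0, blues[0]), (f / 2, blues[1]), (max(f - 1e-6, 0.0), blues[2]),
             (f, lands[0]), ((1 + f) / 2, lands[1]), (1.0, lands[2])]
    return (
        mcolors.LinearSegmentedColormap.from_list("relief", stops),
        mcolors.Normalize(vmin, vmax),
    )


def _recycle(seq, n):
    seq = list(np.atleast_1d(seq))
    if len(seq) == 1:
        seq = seq * n
    if len(seq) != n:
        raise GridError(f"style list of length {len(seq)} does not match {n} levels")
    return seq


def render_map(
    grid: BathyGrid,
    style: dict | None = None,
    overlays: list[dict] | None = None,
    out_path: str = "map.png",
) -> str:
    """Render a heat map with isobaths and optional overlays to an image file.

    ``style`` keys (all optional): ``levels`` (contour levels; default
    auto), ``colors`` / ``widths`` / ``linestyles`` (per level, recycled
    from length 1), ``palette`` (a matplotlib colormap name or None for the
    built-in sea/land ramp), ``shading`` (bool heat map on/off, default on).

    Overlays are dicts drawn in call order above the base map:
    ``{"kind": "points", "lon": [...], "lat": [...]}``,
    ``{"kind": "path", "lon": [...], "lat": [...]}``,
    ``{"kind": "polygon", "lon": [...], "lat": [...]}``,
    ``{"kind": "label", "lon": x, "lat": y, "text": "..."}``.
    Output is deterministic for fixed inputs (no timestamps embedded).
    """
    style = dict(style or {})
    levels = np.asarray(style.get("levels", auto_levels(grid)), dtype=float)
    levels = np.unique(levels)
    v = grid.values[np.isfinite(grid.values)]
    vmin = float(v.min()) if v.size else -1.0
    vmax = float(v.max()) if v.size else 1.0

    fig, ax = plt.subplots(figsize=style.get("figsize", (7, 6)), dpi=style.get("dpi", 100))
    try:
        if style.get("shading", True):
            if style.get("palette"):
                cmap, norm = plt.get_cmap(style["palette"]), mcolors.Normalize(vmin, vmax)
            else:
                cmap, norm = _default_cmap(vmin, vmax)
            ax.pcolormesh(grid.lon_axis, grid.lat_axis, grid.values,
                          cmap=cmap, norm=norm, shading="nearest", rasterized=True)
        drawable = levels[(levels > vmin) & (levels < vmax)]
        if drawable.size:
            colors = _recycle(style.get("colors", "black"), drawable.size)
            widths = [float(w) for w in _recycle(style.get("widths", 0.5), drawable.size)]
            styles = _recycle(style.get("linestyles", "solid"), drawable.size)
            cs = ax.contour(grid.lon_axis, grid.lat_axis, grid.values,
                            levels=drawable, colors=colors, linewidths=widths,
                            linestyles=styles)
            if style.get("drawlabel", False):
                ax.clabel(cs, fontsize=7, fmt="%g")
        for ov in overlays or []:
            kind = ov.get("kind")
            if kind == "points":
                ax.plot(ov["lon"], ov["lat"], linestyle="none",
                        marker=ov.get("marker", "o"), color=ov.get("color", "red"),
                        markersize=ov.get("size", 5))
            elif kind == "path":
                ax.plot(ov["lon"], ov["lat"], color=ov.get("color", "red"),
                        linewidth=ov.get("width", 1.5))
            elif kind == "polygon":
                ax.fill(ov["lon"], ov["lat"], facecolor=ov.get("color", "none"),
                        edgecolor=ov.get("edgecolor", "red"), linewidth=ov.get("width", 1.0))
            elif kind == "label":
                ax.text(ov["lon"], ov["lat"], ov["text"], fontsize=ov.get("size", 9),
                        color=ov.get("color", "black"))
            else:
                raise GridError(f"unknown overlay kind {kind!r}")
        ax.set_xlabel("Longitude")
        ax.set_ylabel("Latitude")
        ax.set_aspect(1.0 / max(np.cos(np.radians(np.mean(grid.lat_axis))), 1e-6))
        # strip volatile metadata so identical inputs give byte-identical files
        meta: dict | None = None
        if str(out_path).lower().endswith(".svg"):
            plt.rcParams["svg.hashsalt"] = "bathykit"
            meta = {"Date": None}
        elif str(out_path).lower().endswith(".pdf"):
            meta = {"CreationDate": None}
        fig.savefig(out_path, metadata=meta)
    finally:
        plt.close(fig)
    return str(out_path)
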