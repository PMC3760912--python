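"""Depth-constrained least-cost paths and pairwise distance matrices.

A :class:`~bathykit.grid.BathyGrid` plus a depth window defines a binary
passable/impassable mask; paths travel between grid nodes along a chosen
neighborhood (rook, queen, or queen + knight moves) with each edge weighted
by the great-circle distance between its node centers — so diagonal and
knight moves are correctly longer, and correctly shorter in longitude at
high latitude.  Shortest routes are found with Dijkstra's algorithm.

The resulting site-by-site distance matrices are the "seascape" distances
used by landscape-genetics tools for isolation-by-distance analyses.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra

from .geometry import EARTH, EarthModel, haversine_km, haversine_matrix_km
from .grid import BathyGrid, DepthWindow, GeoPoint

__all__ = [
    "PassableMask",
    "LCPath",
    "SnapError",
    "NoPathError",
    "passable_mask",
    "least_cost_path",
    "lc_distance_matrix",
    "export_distances",
    "import_distances",
]

# neighborhood step sets (row, col): 4 = rook, 8 = queen, 16 = queen + knight
_STEPS = {
    4: [(0, 1), (1, 0)],
    8: [(0, 1), (1, 0), (1, 1), (1, -1)],
    16: [(0, 1), (1, 0), (1, 1), (1, -1),
         (1, 2), (2, 1), (1, -2), (2, -1)],
}


class SnapError(ValueError):
    """A site could not be snapped to a nearby passable node."""


class NoPathError(ValueError):
    """Source and destination lie in disconnected passable components."""


@dataclass(frozen=True)
class PassableMask:
    """Boolean matrix aligned with a grid; True = traversable."""

    mask: np.ndarray

    @property
    def shape(self):
        return self.mask.shape


@dataclass(frozen=True)
class LCPath:
    """An ordered chain of grid nodes and its great-circle length."""

    nodes: list[GeoPoint]
    length_km: float


def passable_mask(grid: BathyGrid, window: DepthWindow) -> PassableMask:
    """True where the elevation is non-missing and inside *window*.

    "Avoid waters shallower than 1000 m" (a classic open-ocean dispersal
    constraint) is ``DepthWindow(-12000, -1000)``.
    """
    v = grid.values
    return PassableMask(np.isfinite(v) & (v >= window.min_elev) & (v <= window.max_elev))


def _build_graph(grid: BathyGrid, mask: np.ndarray, neighborhood: int, earth: EarthModel):
    """Sparse symmetric graph over passable nodes, haversine edge weights."""
    if neighborhood not in _STEPS:
        raise ValueError(f"neighborhood must be one of {sorted(_STEPS)}")
    n_lat, n_lon = mask.shape
    rows_i, cols_i, wts = [], [], []
    LON = np.broadcast_to(grid.lon_axis, (n_lat, n_lon))
    LAT = np.broadcast_to(grid.lat_axis[:, None], (n_lat, n_lon))
    flat = np.arange(n_lat * n_lon).reshape(n_lat, n_lon)
    for di, dj in _STEPS[neighborhood]:
        # slices of the source block such that (i+di, j+dj) stays in range
        si = slice(max(0, -di), n_lat - max(0, di))
        sj = slice(max(0, -dj), n_lon - max(0, dj))
        ti = slice(max(0, di), n_lat - max(0, -di))
        tj = slice(max(0, dj), n_lon - max(0, -dj))
        ok = mask[si, sj] & mask[ti, tj]
        if not ok.any():
            continue
        w = haversine_matrix_km(LON[si, sj][ok], LAT[si, sj][ok],
                                LON[ti, tj][ok], LAT[ti, tj][ok], earth)
        rows_i.append(flat[si, sj][ok])
        cols_i.append(flat[ti, tj][ok])
        wts.append(w)
    n = n_lat * n_lon
    if not rows_i:
        return coo_matrix((n, n)).tocsr()
    r = np.concatenate(rows_i)
    c = np.concatenate(cols_i)
    w = np.concatenate(wts)
    g = coo_matrix((np.concatenate([w, w]), (np.concatenate([r, c]), np.concatenate([c, r]))),
                   shape=(n, n))
    return g.tocsr()


def _snap(grid: BathyGrid, mask: np.ndarray, point: GeoPoint, earth: EarthModel) -> int:
    """Flat index of the nearest passable node within Chebyshev radius 1 of
    the nearest node; deterministic tie-break by row-major index."""
    i = int(np.argmin(np.abs(grid.lat_axis - point.lat)))
    j = int(np.argmin(np.abs(grid.lon_axis - point.lon)))
    n_lat, n_lon = mask.shape
    best = None
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            ii, jj = i + di, j + dj
            if 0 <= ii < n_lat and 0 <= jj < n_lon and mask[ii, jj]:
                d = haversine_km(point, grid.node_point(ii, jj), earth)
                key = (d, ii * n_lon + jj)
                if best is None or key < best:
                    best = key
    if best is None:
        raise SnapError(
            f"no passable node within one cell of ({point.lon}, {point.lat})"
        )
    return best[1]


def least_cost_path(
    grid: BathyGrid,
    mask: PassableMask,
    src: GeoPoint,
    dst: GeoPoint,
    neighborhood: int = 16,
    earth: EarthModel = EARTH,
) -> LCPath:
    """Shortest passable route between two sites.

    Endpoints snap to the nearest passable node within one cell; raises
    :class:`SnapError` if none exists and :class:`NoPathError` if the snapped
    nodes are disconnected.  Ties are broken deterministically, so identical
    inputs always yield the identical path.
    """
    m = mask.mask
    if m.shape != grid.shape:
        raise ValueError("mask shape does not match grid")
    s = _snap(grid, m, src, earth)
    t = _snap(grid, m, dst, earth)
    n_lon = grid.lon_axis.size
    if s == t:
        i, j = divmod(s, n_lon)
        return LCPath([grid.node_point(i, j)], 0.0)
    graph = _build_graph(grid, m, neighborhood, earth)
    dist, pred = dijkstra(graph, directed=False, indices=s, return_predecessors=True)
    if not np.isfinite(dist[t]):
        raise NoPathError("no passable route connects the two sites")
    chain = [t]
    while chain[-1] != s:
        chain.append(int(pred[chain[-1]]))
    chain.reverse()
    pts = [grid.node_point(*divmod(k, n_lon)) for k in chain]
    return LCPath(pts, float(dist[t]))


def lc_distance_matrix(
    grid: BathyGrid,
    window: DepthWindow,
    sites: list[GeoPoint],
    neighborhood: int = 16,
    earth: EarthModel = EARTH,
) -> np.ndarray:
    """Symmetric matrix of least-cost distances (km) between sites.

    Unreachable pairs get ``inf`` and a single warning listing them; a site
    that cannot be snapped raises :class:`SnapError` naming its index.
    """
    if len(sites) < 2:
        raise ValueError("need at least 2 sites")
    m = passable_mask(grid, window).mask
    nodes = []
    for k, p in enumerate(sites):
        try:
            nodes.append(_snap(grid, m, p, earth))
        except SnapError as e:
            raise SnapError(f"site {k}: {e}") from None
    graph = _build_graph(grid, m, neighborhood, earth)
    dist = dijkstra(graph, directed=False, indices=nodes)
    out = dist[:, nodes]
    # same snapped node => zero distance even if dijkstra returns 0 anyway
    out = np.minimum(out, out.T)  # enforce exact symmetry against fp jitter
    np.fill_diagonal(out, 0.0)
    bad = [(i, j) for i in range(len(sites)) for j in range(i + 1, len(sites))
           if not np.isfinite(out[i, j])]
    if bad:
        warnings.warn(f"unreachable site pairs (reported as inf): {bad}", stacklevel=2)
    return out


def export_distances(matrix: np.ndarray, labels: list[str], stream,
                     format: str = "square_csv") -> int:
    """Write a labeled distance matrix as CSV; returns rows written.

    ``square_csv`` is a full labeled symmetric matrix; ``long_csv`` has one
    ``site_i,site_j,km`` row per unordered pair (i < j) — the layout expected
    by landscape-genetics tools.  Infinite distances serialize as ``Inf``.
    """
    matrix = np.asarray(matrix, dtype=float)
    n = matrix.shape[0]
    if matrix.shape != (n, n) or len(labels) != n:
        raise ValueError("labels length must match a square matrix")

    def fmt(x: float) -> str:
        return "Inf" if np.isinf(x) else repr(float(x))

    if format == "square_csv":
        stream.write("," + ",".join(labels) + "\n")
        for i in range(n):
            stream.write(labels[i] + "," + ",".join(fmt(matrix[i, j]) for j in range(n)) + "\n")
        return n
    if format == "long_csv":
        stream.write("site_i,site_j,km\n")
        rows = 0
        for i in range(n):
            for j in range(i + 1, n):
                stream.write(f"{labels[i]},{labels[j]},{fmt(matrix[i, j])}\n")
                rows += 1
        return rows
    raise ValueError(f"unknown format {format!r}")


def import_distances(stream) -> tuple[np.ndarray, list[str]]:
    """Read back a ``square_csv`` distance matrix (inverse of export)."""
    df = pd.read_csv(stream, index_col=0, float_precision="round_trip")
    labels = [str(c) for c in df.columns]
    mat = df.to_numpy(dtype=float)
    return mat, labels
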