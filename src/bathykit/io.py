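"""Read/write grids in standard formats, fetch ETOPO subsets over HTTP,
and maintain a local single-file tile database for fast regional queries.

Formats supported:

* xyz ASCII — three columns (lon, lat, depth), comma- or whitespace-
  separated, optional header, ``#`` comment lines;
* GeoTIFF — single band, geographic (lon/lat) CRS, gridline-registered;
* netCDF — CF-style ``lon``/``lat`` coordinates with one elevation variable;
* SQLite tile database — an index table of tile bounds plus one compressed
  payload per tile, convenient for querying subsets of very large grids.

Network access goes through an injectable ``transport`` callable so the
entire test suite runs offline; sentinel no-data values (−9999, −32768 by
default) are translated to missing on ingest.
"""

from __future__ import annotations

import hashlib
import io as _io
import sqlite3
import urllib.request
import warnings
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .grid import BathyGrid, GridError, Region, make_grid, subset

__all__ = [
    "read_xyz",
    "write_xyz",
    "export_raster",
    "import_raster",
    "read_grid",
    "write_grid",
    "EtopoConfig",
    "EtopoError",
    "fetch_etopo",
    "build_tile_db",
    "query_tile_db",
]

#: sentinel values translated to missing on ingest
DEFAULT_SENTINELS = (-9999.0, -32768.0)


# ---------------------------------------------------------------------------
# xyz ASCII

def _as_text(source):
    if hasattr(source, "read"):
        return source.read()
    return Path(source).read_text()


def _regularize_axis(u: np.ndarray, name: str) -> np.ndarray:
    """Snap a near-regular coordinate axis to exact even spacing.

    Coordinates printed at limited decimal precision jitter by up to half a
    unit in the last place; jitter below 1% of the spacing is treated as
    rounding noise and snapped, anything larger is a genuinely irregular
    grid and rejected.
    """
    d = np.diff(u)
    spacing = float(np.median(d))
    if spacing <= 0:
        raise GridError(f"{name} axis not increasing")
    jitter = float(np.max(d) - np.min(d))
    if jitter <= 1e-9:
        return u
    if jitter > 0.01 * spacing:
        raise GridError(f"{name} spacing irregular beyond tolerance "
                        f"(jitter {jitter:g} deg at spacing {spacing:g} deg)")
    span = float(u[-1] - u[0])
    spacing = span / (u.size - 1)
    return u[0] + spacing * np.arange(u.size)


def _axis_index(axis: np.ndarray, coords: np.ndarray) -> np.ndarray:
    spacing = float(axis[1] - axis[0])
    idx = np.rint((coords - axis[0]) / spacing).astype(int)
    if np.any(idx < 0) or np.any(idx >= axis.size):
        raise GridError("coordinate falls outside the inferred axis")
    return idx


def read_xyz(source, delimiter: str | None = None,
             sentinels=DEFAULT_SENTINELS) -> BathyGrid:
    """Parse lon/lat/depth triples into a grid.

    The unique sorted lon and lat values become the axes; coordinate
    combinations absent from the file become missing cells.  If the first
    line is non-numeric it is treated as a header and lon/lat/depth-like
    column names are honored; otherwise column order is assumed to be
    longitude, latitude, depth.  Duplicate coordinates keep the last value,
    with a warning.
    """
    text = _as_text(source)
    lines = [ln for ln in text.splitlines() if ln.strip() and not ln.lstrip().startswith("#")]
    if not lines:
        raise GridError("empty xyz input")

    def tokens(ln: str) -> list[str]:
        if delimiter:
            return [t.strip() for t in ln.split(delimiter)]
        return ln.replace(",", " ").split()

    first = tokens(lines[0])

    def numeric(tok: str) -> bool:
        try:
            float(tok)
            return True
        except ValueError:
            return False

    n_numeric = sum(numeric(t) for t in first)
    if 0 < n_numeric < len(first):
        raise GridError(f"malformed first line (mixed numeric/text): {lines[0]!r}")
    has_header = n_numeric == 0
    body = lines[1:] if has_header else lines
    if has_header:
        names = [t.lower() for t in first]

        def find(*keys):
            for k, nm in enumerate(names):
                if any(key in nm for key in keys):
                    return k
            return None

        ci = (find("lon", "x"), find("lat", "y"),
              find("depth", "elev", "z", "alt"))
        if None in ci:
            ci = (0, 1, 2)
    else:
        ci = (0, 1, 2)

    if not body:
        raise GridError("xyz input has a header but no data rows")
    sep = delimiter if delimiter else None
    body_text = "\n".join(body)
    if sep is None:
        body_text = body_text.replace(",", " ")
        sep = None
    try:
        data = np.loadtxt(_io.StringIO(body_text), delimiter=sep, ndmin=2)
    except ValueError as e:
        raise GridError(f"malformed xyz data: {e}") from None
    if data.shape[1] < 3:
        raise GridError("xyz rows must have at least 3 fields")
    arr = data[:, list(ci)]
    lon_u = np.unique(arr[:, 0])
    lat_u = np.unique(arr[:, 1])
    if lon_u.size < 2 or lat_u.size < 2:
        raise GridError("need at least 2 distinct longitudes and latitudes")
    lon_u = _regularize_axis(lon_u, "lon")
    lat_u = _regularize_axis(lat_u, "lat")
    vals = np.full((lat_u.size, lon_u.size), np.nan)
    jj = _axis_index(lon_u, arr[:, 0])
    ii = _axis_index(lat_u, arr[:, 1])
    if np.unique(ii * lon_u.size + jj).size < len(arr):
        warnings.warn("duplicate coordinates in xyz input; last value wins", stacklevel=2)
    vals[ii, jj] = arr[:, 2]  # later rows overwrite earlier ones
    for s in sentinels or ():
        vals[vals == s] = np.nan
    return make_grid(lon_u, lat_u, vals, {"source": "xyz"})


def write_xyz(grid: BathyGrid, stream) -> int:
    """Write one ``lon lat depth`` row per non-missing node, longitude-major
    order, full float precision.  Returns the number of rows written."""
    n = 0
    for j, lon in enumerate(grid.lon_axis):
        for i, lat in enumerate(grid.lat_axis):
            v = grid.values[i, j]
            if np.isfinite(v):
                stream.write(f"{float(lon)!r} {float(lat)!r} {float(v)!r}\n")
                n += 1
    return n


# ---------------------------------------------------------------------------
# GeoTIFF (tifffile) and netCDF (xarray, scipy engine)

_TAG_PIXELSCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_GEOKEYS = 34735


def _export_geotiff(grid: BathyGrid, path) -> None:
    import tifffile

    data = grid.values[::-1, :].astype(np.float64)  # row 0 = northernmost
    dlon, dlat = grid.lon_spacing, grid.lat_spacing
    # PixelIsPoint: tiepoint maps raster (0,0) to the NW node itself
    tiepoint = (0.0, 0.0, 0.0, float(grid.lon_axis[0]), float(grid.lat_axis[-1]), 0.0)
    geokeys = (1, 1, 0, 3,
               1024, 0, 1, 2,      # model type: geographic
               1025, 0, 1, 2,      # raster type: PixelIsPoint
               2048, 0, 1, 4326)   # geographic CRS: WGS84
    tifffile.imwrite(
        path, data,
        extratags=[
            (_TAG_PIXELSCALE, "d", 3, (dlon, dlat, 0.0)),
            (_TAG_TIEPOINT, "d", 6, tiepoint),
            (_TAG_GEOKEYS, "H", len(geokeys), geokeys),
        ],
    )


def _geokey(geokeys, key):
    # GeoKeyDirectory: header of 4 shorts then (key, location, count, value)
    for k in range(4, len(geokeys), 4):
        if geokeys[k] == key:
            return geokeys[k + 3]
    return None


def _import_geotiff(path) -> BathyGrid:
    import tifffile

    with tifffile.TiffFile(path) as tf:
        if len(tf.pages) != 1:
            raise GridError("multi-band raster: expected a single band")
        page = tf.pages[0]
        spp = page.tags.get("SamplesPerPixel")
        if spp is not None and spp.value != 1:
            raise GridError("multi-band raster: expected a single band")
        for tag in (_TAG_PIXELSCALE, _TAG_TIEPOINT):
            if tag not in page.tags:
                raise GridError("raster lacks georeferencing tags")
        geokeys = page.tags[_TAG_GEOKEYS].value if _TAG_GEOKEYS in page.tags else ()
        model = _geokey(geokeys, 1024)
        if model is not None and model != 2:
            raise GridError(
                "projected raster: reproject to geographic lon/lat with "
                "external raster tooling before import"
            )
        raster_type = _geokey(geokeys, 1025) or 2
        dlon, dlat = page.tags[_TAG_PIXELSCALE].value[:2]
        tp = page.tags[_TAG_TIEPOINT].value
        lon0, lat_top = tp[3], tp[4]
        if raster_type == 1:  # PixelIsArea: values at cell centers
            lon0 += dlon / 2.0
            lat_top -= dlat / 2.0
        data = page.asarray().astype(float)
    n_lat, n_lon = data.shape
    lon = lon0 + dlon * np.arange(n_lon)
    lat = lat_top - dlat * np.arange(n_lat)  # descending; make_grid flips
    return make_grid(lon, lat, data, {"source": str(path)})


def _export_netcdf(grid: BathyGrid, path) -> None:
    import xarray as xr

    ds = xr.Dataset(
        {"elevation": (("lat", "lon"), grid.values.astype(np.float64))},
        coords={"lon": grid.lon_axis, "lat": grid.lat_axis},
    )
    ds["elevation"].attrs.update(units="m", positive="up",
                                 long_name="elevation relative to sea level")
    ds["lon"].attrs.update(units="degrees_east", standard_name="longitude")
    ds["lat"].attrs.update(units="degrees_north", standard_name="latitude")
    ds.to_netcdf(path, engine="scipy")


def _import_netcdf(path) -> BathyGrid:
    import xarray as xr

    with xr.open_dataset(path, engine="scipy") as ds:
        data_vars = list(ds.data_vars)
        if len(data_vars) != 1:
            raise GridError(f"expected exactly 1 elevation variable, found {data_vars}")
        var = ds[data_vars[0]]
        dims = [d.lower() for d in var.dims]
        if "lon" not in dims or "lat" not in dims:
            raise GridError("netCDF variable lacks lon/lat coordinates")
        var = var.transpose(var.dims[dims.index("lat")], var.dims[dims.index("lon")])
        lon = ds[var.dims[1]].values.astype(float)
        lat = ds[var.dims[0]].values.astype(float)
        vals = var.values.astype(float)
    return make_grid(lon, lat, vals, {"source": str(path)})


def export_raster(grid: BathyGrid, path) -> str:
    """Write the grid as a single-band georeferenced raster.

    The format follows the file extension: ``.tif``/``.tiff`` for GeoTIFF,
    ``.nc`` for netCDF.  Rasters are north-up; the round trip through
    :func:`import_raster` is lossless.
    """
    suffix = Path(path).suffix.lower()
    if suffix in (".tif", ".tiff"):
        _export_geotiff(grid, path)
    elif suffix == ".nc":
        _export_netcdf(grid, path)
    else:
        raise GridError(f"unsupported raster extension {suffix!r} (use .tif/.tiff/.nc)")
    return str(path)


def import_raster(path) -> BathyGrid:
    """Read a single-band geographic raster (GeoTIFF or netCDF) as a grid."""
    suffix = Path(path).suffix.lower()
    if suffix in (".tif", ".tiff"):
        return _import_geotiff(path)
    if suffix == ".nc":
        return _import_netcdf(path)
    raise GridError(f"unsupported raster extension {suffix!r} (use .tif/.tiff/.nc)")


def read_grid(path) -> BathyGrid:
    """Read a grid from any supported file by extension (.xyz/.csv/.txt,
    .tif/.tiff, .nc)."""
    suffix = Path(path).suffix.lower()
    if suffix in (".xyz", ".csv", ".txt"):
        return read_xyz(path)
    return import_raster(path)


def write_grid(grid: BathyGrid, path) -> str:
    """Write a grid to any supported file by extension."""
    suffix = Path(path).suffix.lower()
    if suffix in (".xyz", ".csv", ".txt"):
        with open(path, "w") as fh:
            write_xyz(grid, fh)
        return str(path)
    return export_raster(grid, path)


# ---------------------------------------------------------------------------
# ETOPO subset fetch

class EtopoError(RuntimeError):
    """Remote grid service failure or inconsistent response."""


@dataclass(frozen=True)
class EtopoConfig:
    """Endpoint and retry policy for the remote grid service.

    The URL scheme of the hosting service has changed over the years, so the
    endpoint is a config value with ``{lon1} {lon2} {lat1} {lat2} {res}``
    placeholders rather than a constant.
    """

    endpoint: str = (
        "https://gis.ngdc.noaa.gov/arcgis/rest/services/DEM_mosaics/etopo"
        "?bbox={lon1},{lat1},{lon2},{lat2}&resolution={res}&format=xyz"
    )
    retries: int = 3
    cache_dir: str | None = None


def _default_transport(url: str) -> str:
    with urllib.request.urlopen(url, timeout=60) as resp:  # pragma: no cover
        return resp.read().decode()


def expected_shape(region: Region, resolution_arcmin: float) -> tuple[int, int]:
    """(n_lat, n_lon) for a gridline-registered subset: span*60/res + 1."""
    n_lon = int(round((region.lon2 - region.lon1) * 60.0 / resolution_arcmin)) + 1
    n_lat = int(round((region.lat2 - region.lat1) * 60.0 / resolution_arcmin)) + 1
    return n_lat, n_lon


def fetch_etopo(
    region: Region,
    resolution_arcmin: float = 1.0,
    transport=None,
    cache_dir=None,
    config: EtopoConfig | None = None,
) -> BathyGrid:
    """Fetch a gridline-registered subset of the global relief model.

    The parsed response (comma- or whitespace-separated lon/lat/depth
    triples) must match the node-count formula ``span * 60 / res + 1`` on
    both axes or an :class:`EtopoError` is raised.  Results are cached on
    disk keyed by (region, resolution); repeated calls never touch the
    network.  ``transport`` is any ``url -> text`` callable (tests inject a
    canned responder); transient failures are retried.
    """
    if resolution_arcmin <= 0:
        raise GridError("resolution must be positive")
    config = config or EtopoConfig()
    cache_dir = cache_dir or config.cache_dir
    key = hashlib.sha256(
        f"{region.lon1},{region.lon2},{region.lat1},{region.lat2},{resolution_arcmin}".encode()
    ).hexdigest()[:24]
    cache_file = Path(cache_dir) / f"etopo_{key}.npz" if cache_dir else None
    if cache_file is not None and cache_file.exists():
        with np.load(cache_file) as z:
            return make_grid(z["lon"], z["lat"], z["values"],
                             {"source": "etopo:cache", "resolution_arcmin": resolution_arcmin})
    transport = transport or _default_transport
    url = config.endpoint.format(lon1=region.lon1, lon2=region.lon2,
                                 lat1=region.lat1, lat2=region.lat2,
                                 res=resolution_arcmin)
    last_err: Exception | None = None
    text = None
    for _ in range(max(1, config.retries)):
        try:
            text = transport(url)
            break
        except Exception as e:  # noqa: BLE001 - transport failures are opaque
            last_err = e
    if text is None:
        raise EtopoError(f"transport failed after {config.retries} retries: {last_err}")
    grid = read_xyz(_io.StringIO(text))
    n_lat, n_lon = expected_shape(region, resolution_arcmin)
    if grid.shape != (n_lat, n_lon):
        raise EtopoError(
            f"response grid {grid.shape} inconsistent with request "
            f"(expected {(n_lat, n_lon)})"
        )
    grid = make_grid(grid.lon_axis, grid.lat_axis, grid.values,
                     {"source": "etopo", "resolution_arcmin": resolution_arcmin})
    if cache_file is not None:
        cache_file.parent.mkdir(parents=True, exist_ok=True)
        np.savez_compressed(cache_file, lon=grid.lon_axis, lat=grid.lat_axis,
                            values=grid.values)
    return grid


# ---------------------------------------------------------------------------
# SQLite tile database

_SCHEMA = """
CREATE TABLE meta (key TEXT PRIMARY KEY, value TEXT);
CREATE TABLE tiles (
    tile_id INTEGER PRIMARY KEY,
    lon_min REAL, lon_max REAL, lat_min REAL, lat_max REAL,
    n_lon INTEGER, n_lat INTEGER,
    payload BLOB
);
CREATE INDEX tiles_bounds ON tiles (lon_min, lon_max, lat_min, lat_max);
"""


def _pack(grid: BathyGrid) -> bytes:
    buf = _io.BytesIO()
    np.savez(buf, lon=grid.lon_axis, lat=grid.lat_axis, values=grid.values)
    return zlib.compress(buf.getvalue(), level=6)


def _unpack(blob: bytes) -> BathyGrid:
    with np.load(_io.BytesIO(zlib.decompress(blob))) as z:
        return make_grid(z["lon"], z["lat"], z["values"])


def _merge_slivers(bins: np.ndarray) -> np.ndarray:
    """Merge axis bins holding fewer than 2 nodes into a neighbor and
    relabel consecutively, so every tile is a valid >=2-node grid."""
    bins = bins.copy()
    while True:
        uniq, counts = np.unique(bins, return_counts=True)
        small = uniq[counts < 2]
        if small.size == 0 or uniq.size == 1:
            break
        b = small[0]
        target = uniq[uniq < b][-1] if np.any(uniq < b) else uniq[uniq > b][0]
        bins[bins == b] = target
    # relabel to 0..k-1 preserving order
    uniq = np.unique(bins)
    remap = {u: k for k, u in enumerate(uniq)}
    return np.array([remap[b] for b in bins], dtype=int)


def build_tile_db(source, db_path, tile_deg: float, force: bool = False) -> int:
    """Split a grid into non-overlapping tiles of about *tile_deg* degrees
    and store them in a single-file SQLite database.

    *source* is a :class:`BathyGrid` or a path readable by
    :func:`read_grid`.  Tiles partition the node set (each node belongs to
    exactly one tile), so stitching them back is lossless.  Returns the
    number of tiles written; refuses to overwrite an existing file unless
    ``force`` is set.
    """
    grid = source if isinstance(source, BathyGrid) else read_grid(source)
    if tile_deg <= 0:
        raise GridError("tile_deg must be positive")
    db_path = Path(db_path)
    if db_path.exists():
        if not force:
            raise GridError(f"{db_path} exists; pass force=True to rebuild")
        db_path.unlink()
    lon, lat = grid.lon_axis, grid.lat_axis
    n_tiles_lon = max(1, int(np.ceil((lon[-1] - lon[0]) / tile_deg - 1e-9)))
    n_tiles_lat = max(1, int(np.ceil((lat[-1] - lat[0]) / tile_deg - 1e-9)))
    jbin = _merge_slivers(
        np.clip(((lon - lon[0]) / tile_deg).astype(int), 0, n_tiles_lon - 1))
    ibin = _merge_slivers(
        np.clip(((lat - lat[0]) / tile_deg).astype(int), 0, n_tiles_lat - 1))
    n_tiles_lon = int(jbin.max()) + 1
    n_tiles_lat = int(ibin.max()) + 1
    con = sqlite3.connect(db_path)
    try:
        con.executescript(_SCHEMA)
        con.execute("INSERT INTO meta VALUES ('tile_deg', ?)", (str(tile_deg),))
        con.execute("INSERT INTO meta VALUES ('resolution_arcmin', ?)",
                    (str(grid.meta.get("resolution_arcmin", grid.lon_spacing * 60.0)),))
        tile_id = 0
        for bi in range(n_tiles_lat):
            ii = np.where(ibin == bi)[0]
            if ii.size < 1:
                continue
            for bj in range(n_tiles_lon):
                jj = np.where(jbin == bj)[0]
                if jj.size < 1:
                    continue
                sub_lon = lon[jj[0]: jj[-1] + 1]
                sub_lat = lat[ii[0]: ii[-1] + 1]
                if sub_lon.size < 2 or sub_lat.size < 2:  # pragma: no cover
                    raise GridError("internal error: sliver tile after merging")
                tile = make_grid(sub_lon, sub_lat,
                                 grid.values[ii[0]: ii[-1] + 1, jj[0]: jj[-1] + 1])
                tile_id += 1
                con.execute(
                    "INSERT INTO tiles VALUES (?,?,?,?,?,?,?,?)",
                    (tile_id, float(sub_lon[0]), float(sub_lon[-1]),
                     float(sub_lat[0]), float(sub_lat[-1]),
                     sub_lon.size, sub_lat.size, _pack(tile)),
                )
        con.commit()
    finally:
        con.close()
    return tile_id


def query_tile_db(db_path, region: Region) -> BathyGrid:
    """Load only the tiles intersecting *region*, stitch them, and subset.

    The result is identical to calling :func:`~bathykit.grid.subset` on the
    original grid the database was built from.
    """
    db_path = Path(db_path)
    if not db_path.exists():
        raise GridError(f"tile database {db_path} does not exist")
    con = sqlite3.connect(db_path)
    try:
        rows = con.execute(
            "SELECT payload FROM tiles WHERE lon_max >= ? AND lon_min <= ? "
            "AND lat_max >= ? AND lat_min <= ? ORDER BY tile_id",
            (region.lon1, region.lon2, region.lat1, region.lat2),
        ).fetchall()
    finally:
        con.close()
    if not rows:
        raise GridError("region does not intersect the stored extent")
    tiles = [_unpack(r[0]) for r in rows]
    lon_all = np.unique(np.concatenate([t.lon_axis for t in tiles]))
    lat_all = np.unique(np.concatenate([t.lat_axis for t in tiles]))
    vals = np.full((lat_all.size, lon_all.size), np.nan)
    for t in tiles:
        j0 = np.searchsorted(lon_all, t.lon_axis[0])
        i0 = np.searchsorted(lat_all, t.lat_axis[0])
        vals[i0: i0 + t.lat_axis.size, j0: j0 + t.lon_axis.size] = t.values
    stitched = make_grid(lon_all, lat_all, vals, {"source": f"tiledb:{db_path.name}"})
    return subset(stitched, region)
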