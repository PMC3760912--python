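# bathykit

Tools for importing, querying, analyzing and plotting gridded bathymetric
and topographic data, aimed at marine ecologists and landscape/seascape
geneticists who need publication-quality maps and *spatially explicit*
distances: not straight lines through land, but realistic shortest paths
constrained by depth.

## What it does

The central object is a **bathymetric grid**: elevation in meters on a
regular longitude/latitude grid, negative below sea level (the ETOPO sign
convention), values at grid nodes (gridline registration). Around it the
package provides:

- **Import/export** — lon/lat/depth ASCII (xyz), single-band GeoTIFF and
  netCDF rasters, subsets of the NOAA ETOPO relief model fetched over HTTP
  (with on-disk caching and an injectable transport so everything is
  testable offline), and a single-file SQLite tile database for fast
  regional queries of very large grids.
- **Queries** — bilinear/nearest depth at a point, rectangular subsets,
  decimation, summaries, and selection of sampling records inside a region.
- **Spherical geometry** — great-circle (haversine) distances
  `d = 2R·asin√(sin²(Δφ/2) + cosφ₁·cosφ₂·sin²(Δλ/2))`,
  projected cell areas `A = R²·Δλ·(sinφ_top − sinφ_bot)`, depth-zone areas
  (e.g. the bathyal zone, 1000–4000 m) and hypsometric tables.
- **Connectivity** — least-cost paths over the grid graph (rook / queen /
  queen+knight neighborhoods) with edges weighted by great-circle length,
  restricted to cells inside a depth window ("avoid waters shallower than
  1000 m"), plus symmetric site-by-site distance matrices exportable as CSV
  for landscape-genetics software.
- **Transects** — depth profiles along great-circle segments (equal
  arc-length stations, bilinear depths) and belt transects (all nodes
  within a cross-track half-width of a survey line).
- **Isobaths & maps** — marching-squares contour extraction, grouped
  `deep/shallow/step` level expansion, and deterministic heat-map rendering
  with per-level isobath styling and point/path/polygon/label overlays.
- **Synthetic seafloors** — seeded generators (flat, ramp, Gaussian
  seamount, conical island, two basins joined by one strait, archipelago)
  with closed-form structure, used throughout the test suite as analytic
  ground truth.

## Worked example

```python
import bathykit as bk

# a two-basin seascape: deep basins split by a shallow ridge with one strait
grid = bk.generate(bk.SynthSpec("two_basins", bk.Region(-2, 2, -2, 2), 0.1))
print(bk.grid_summary(grid))

# depth-constrained distance between one site in each basin
src, dst = bk.GeoPoint(-1.5, 1.0), bk.GeoPoint(1.5, 1.0)
mask = bk.passable_mask(grid, bk.DepthWindow(-12000, -1000))
path = bk.least_cost_path(grid, mask, src, dst)
print(f"haversine: {bk.haversine_km(src, dst):.1f} km")
print(f"least-cost (avoiding <1000 m): {path.length_km:.1f} km "
      f"({len(path.nodes)} nodes)")

# projected area of the bathyal zone (1000-4000 m depth)
bathyal = bk.zone_area(grid, bk.DepthWindow(-4000, -1000))
print(f"bathyal zone area: {bathyal:.0f} km^2")
```

prints

```
{'n_lon': 41, 'n_lat': 41, 'pct_missing': 0.0, 'min': -4000.0, 'max': -200.0,
 'mean': -3726.948245092207, 'pct_below_sea_level': 100.0}
haversine: 333.5 km
least-cost (avoiding <1000 m): 405.9 km (21 nodes)
bathyal zone area: 192966 km^2
```

The straight-line distance (333.5 km) crosses the shallow ridge; the
least-cost route (405.9 km) detours through the only strait deeper than
1000 m — the kind of distance one would correlate with genetic
differentiation in an isolation-by-distance analysis.

The same operations are available from the shell via the umbrella
executable:

```sh
bathykit synth --kind two_basins --resolution 0.1 -o basins.nc
bathykit area --grid basins.nc --min -4000 --max -1000 --json
bathykit lcp --grid basins.nc --from -1.5 1.0 --to 1.5 1.0 --avoid-shallower 1000 -o path.csv
bathykit map --grid basins.nc --levels -3000,-1000 -o basins.png
```

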