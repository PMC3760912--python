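# Methods

This note documents the models, numerical choices and limitations behind
bathykit, in the spirit of a package vignette.

## Data model

A grid is node-registered: elevations sit at gridline intersections, as in
ETOPO1, and each node "owns" the cell bounded by the half-spacing in each
direction. Axes must ascend and be evenly spaced; construction tolerates
spacing jitter up to 1e-9°, and the ASCII reader additionally snaps axes
whose jitter is below 1% of the spacing (coordinates printed at, say, six
decimals wobble by half a unit in the last place; treating that as
irregularity would reject virtually every real xyz export). Elevations are
signed meters, negative below sea level; |z| must stay below 12 000 m,
a sanity bound comfortably outside Earth's relief. Missing data are NaN
throughout — sentinel values (−9999, −32768, configurable) are translated
on ingest and never stored.

Longitudes live in [−180, 180] and regions may not cross the antimeridian;
wrap-around would make "inside a rectangle" ambiguous, and none of the
intended workflows need it. Rectangular queries use closed bounds on all
four sides, and this is consistent between `subset`, `select_records` and
the tile database.

## Spherical geometry

The Earth is a sphere of authalic radius 6371.0088 km (configurable through
`EarthModel`). A sphere rather than an ellipsoid keeps every quantity
closed-form — quarter great circle πR/2, cell areas that telescope exactly
to 4πR² on a global grid — at a cost of ≲0.5% versus WGS84 distances, well
below the discretization error of grid-constrained paths.

Projected cell area is A = R²·Δλ·(sin φ_top − sin φ_bot) with the latitude
band clipped at the poles. This is *projected* (sea-surface) area, not
slope-corrected seafloor area. `zone_area` uses an inclusive window on both
ends; `hypsometry` uses half-open bins [b_i, b_{i+1}) with the last bin
closed, so bins partition the break range and areas are conserved to
rounding. Missing cells contribute no area and are reported separately.

## Least-cost paths

The passable set is binary: a cell is traversable iff its elevation is
non-missing and inside the depth window. There is no continuous resistance
weighting — the avoid/allow formulation matches how depth constraints are
stated in practice ("avoid water shallower than 1000 m" ≡ window
[−12000, −1000]).

Edges connect neighboring passable nodes under a 4- (rook), 8- (queen) or
16-neighborhood (queen + knight moves, the default, which reduces
grid-direction bias); each edge is weighted by the great-circle distance
between node centers, so diagonal and knight steps are automatically longer
and east–west steps automatically shorten toward the poles. Shortest routes
come from Dijkstra's algorithm on the sparse graph; ties resolve
deterministically (row-major node order), so identical inputs give
identical paths. Knight moves connect node pairs two columns apart without
examining intervening cells; consequently a barrier must be at least three
nodes wide to be impassable under the 16-neighborhood, and the two-basin
generator builds its ridge that wide.

Sites snap to the nearest passable node within a Chebyshev radius of one
cell of the nearest node; farther than that is an error (`SnapError`)
rather than a silent long-range snap. Disconnected endpoints raise
`NoPathError`; in distance matrices unreachable pairs are reported as
infinity (serialized `Inf`) with a warning, because dropping pairs would
silently corrupt downstream matrix-based analyses.

Grid paths overestimate true geodesics by up to the cell diagonal per step;
with the 16-neighborhood the worst-case direction bias is about 2%.

## Transects

Stations are placed by spherical linear interpolation, giving exactly equal
arc spacing; the default station count puts roughly one station per grid
cell at the segment midlatitude. Depths are bilinear, matching `get_depth`,
so profiles over planar surfaces are exact and profiles over smooth
surfaces are smooth. Belt transects use the standard spherical cross-track
(asin of the normal component) and along-track (arccos ratio) formulas;
membership is |cross-track| ≤ half-width and along-track within
[0, segment length]. Cross-sections follow great circles, not straight
lines in lon/lat space; over a few degrees the difference is at most a few
cells at mid-latitudes.

## Isobaths and maps

Contours come from marching squares with linear interpolation along cell
edges and the average-of-corners rule in saddle cells (different saddle
rules produce different polylines; this one is symmetric and standard).
Every vertex therefore interpolates bilinearly to the contour level to
machine precision. Grouped level expansion turns (deep, shallow, step)
triples into arithmetic sequences, deduplicated and sorted, with step 0
meaning the single level `deep` — the idiom for adding a coastline at 0.
When no levels are given, round-number levels covering the value range
(about 5–8, via a tick locator) are chosen; this heuristic is this
package's own.

Rendering uses a monotone blue ramp below 0 and a grey-green ramp above,
with a hard break at the coastline, fully overridable per call. Output
files are deterministic: the Agg backend is forced and volatile metadata
(PDF creation dates, SVG hash salts) is stripped, so identical inputs give
byte-identical files — a property the test suite checks by hashing.

## Remote subsets and the tile database

ETOPO subset requests are gridline-registered, so a span of s degrees at
r arc-minutes yields s·60/r + 1 nodes per axis; responses that do not match
this arithmetic are rejected. The endpoint URL is configuration, not a
constant (the hosting service has changed its URL scheme over time), the
transport is an injectable `url -> text` callable so tests and offline runs
use canned responders, transient failures are retried (3 attempts by
default), and results are cached on disk keyed by region and resolution.

The tile database is a single SQLite file with a `tiles` index table
(id, bounds, dimensions) and one zlib-compressed payload per tile. Tiles
partition the node set — each node belongs to exactly one tile — so
stitching tiles that intersect a query region and subsetting reproduces the
in-memory `subset` result exactly; axis bins that would produce one-node
sliver tiles are merged into their neighbor. The schema is this package's
own design.

## Synthetic seafloors

Generators evaluate closed-form surfaces and record their analytic
structure in grid metadata, so tests can compute expected answers without
reading the grid: the Gaussian seamount (z = −D + H·e^{−r²/2σ²}, default
basin 5000 m, height 4000 m, σ = 1°) for area and profile oracles; the
conical island (peak 200 m, coastline radius 1°, so the isobath at level L
is a circle of radius (peak − L)/slope) for contour oracles; the two-basin
seascape (basins −4000 m, ridge −200 m and three nodes wide, one strait at
−3000 m) for connectivity oracles with a known corridor. Radial generators
measure distance in lon/lat degrees, keeping level sets exact circles on
the grid. All randomness (archipelago placement, site sampling) flows
through one seeded generator; the same spec always reproduces the identical
grid, bit for bit, across platforms.

What the generators do not emulate: fractal roughness, measurement noise,
data gaps with realistic geometry, and ellipsoidal effects. Passing tests
therefore demonstrate correctness of the algorithms under known geometry,
not robustness to survey artifacts in real compilations.

## Test and verification scale

Shortest-path correctness is verified against a first-principles heapq
Dijkstra (with chord-formula edge weights, a different distance route than
the implementation's haversine) exhaustively over all masks of a 5×5 grid
with up to three blocked cells and a seeded sample of several hundred
heavier masks, across all three neighborhoods — about 7 500 path problems.
Metric axioms are checked on 10⁴ random point triples, tile-database
equivalence on 100 random regions, and area oracles by dense numerical
integration of R²cos φ. These sizes keep the full suite under a minute
while covering every branch the small cases can reach.
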