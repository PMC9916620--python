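# Methods

This note documents the models and procedures implemented in
`corridorscape`, the assumptions behind them, the parameters that matter,
and the numerical conventions chosen where a convention was genuinely open.

## 1. Toxic load

Resistance to insect movement is parameterized primarily from pesticide
lethality. For each land class *c* and year *y*, the per-acre toxic load is

    L(c, y) = Σ_chemicals  pounds(chem, c, y) × 453,592,370 µg/lb
              ─────────────────────────────────────────────────────
                        LD50(chem) [µg/bee] × acres(c)

i.e. the number of honey-bee contact LD50 doses applied per acre. The
underlying assumptions: lethality to honey bees proxies for hostility to
pollinating insects generally; application pounds aggregate across a class's
whole acreage (no within-class spatial structure); unreported uses (e.g.
residential applications, treated seed) are absent, so urban and some crop
loads are underestimates. A class with records in some years but not others
gets load 0 for the silent years — absence of a report means no reported
application, and near-zero loads are legitimate (rice-like crops). Classes
with no records in any year are excluded with a warning. Three annual loads
collapse to scenario loads: low = minimum, medium = median, high = maximum.

## 2. Load → resistance

Natural habitat defines the baseline resistance 1 (isolation-by-distance).
Urban land is anchored at resistance 8, from a landscape-genetics model of
bumble-bee differentiation in which urban cover (resistance 0.8, the mean
of its 0.7–0.9 supported range) is eight-fold more resistant than natural
cover (0.1). Every load-bearing class is scaled linearly:

    R(c, level) = clamp( round( L(c, level) / L(urban, level) × A(level) ), 1, 100 )

with per-level urban anchors A = 7/8/9 (the urban row's own low/medium/high
values), rounding half-up, floor 1, cap 100. Whether the original analysis
scaled the low/high loads against the low/high urban loads or always
against the medium urban load is not recorded; per-level anchoring keeps
the urban row self-consistent and is the default, with
`per_level_anchor=False` available as a switch. A side effect of per-level
anchoring is that a class whose load varies less across years than the
urban load can end up with an inverted low/medium/high triple; since levels
are defined as ordered scenarios, inverted triples are sorted into order
with a logged warning.

Classes without usable application data carry expert values (shipped
defaults: agricultural margin 7/15/20, urban greenspace 7/15/20, bare soil
20/40/100, urban impervious 10/40/100, water 100/100/100, natural and
grassland 1/1/1); expert rows are flagged `expert` in the output table.
"Other" is the rounded mean of all computed crop resistances per level.
The published Central Valley table ships as a reference fixture
(`data/table1_resistance.csv`) and can be rasterized directly.

## 3. Margin experiments

Three recodings of the land-cover grid, crossed with the three resistance
levels (nine scenarios):

* **restored** — every margin cell becomes natural habitat (hedgerow
  restoration at its optimistic limit);
* **current** — identity;
* **none** — fields extend over their margins: each margin cell takes the
  class of its nearest crop cell (Euclidean distance between cell centers;
  ties broken by row-major crop-cell order, a deterministic convention —
  the original description says only that fields were "extended in space").

## 4. Cost distance and least-cost paths

The cell graph is 8-connected; moving between neighbouring cells *i*, *j*
costs `(r_i + r_j)/2 × d_ij` with `d_ij` = 1 orthogonally and √2 diagonally
(cell units). This is the de-facto GIS Cost Distance convention and matches
"cells traversed × cost" units; accumulated costs are therefore unitless
multiples of cell traversals, while path lengths are reported separately in
meters/km. Nodata cells are impassable. Accumulated costs are computed with
Dijkstra's algorithm on the sparse cell graph (scipy's compiled
implementation); backlink direction codes (1 = east, clockwise to 8 =
north-east) are then re-derived from the accumulated surface — each reached
cell's predecessor is the neighbour minimizing neighbour-cost + move-cost,
with ties broken by lowest row-major cell index — so traced paths are
platform-reproducible and do not depend on solver internals. Tests verify
the engine against an independently enumerated networkx graph oracle on
hundreds of small random grids.

## 5. The corridor experiment

Source points are placed along the west perimeter line at fixed arc-length
spacing (count = ⌊length/spacing⌋ + 1, including the start vertex), and
destination points along the east line. Every west–east pair within a
Euclidean cap is connected; one Dijkstra run per unique source cell serves
all of that source's destinations. To decouple results from exact point
placement the experiment runs `n_iterations` times: iteration 1 uses the
canonical un-jittered points (so the nominal configuration is always
represented — switchable), later iterations displace every point uniformly
within a disc, rejection-sampling until the point lands on a valid cell
(after 100 failed draws the original point is kept, with a warning). Each
point has its own RNG stream derived from (master seed, stage, iteration,
point index), so jitter is identical across scenarios and independent of
other points' rejections. Unreachable pairs are dropped with a logged
warning (how the original analysis handled them is unreported).

Full-valley defaults: 5 km spacing, 125 km pairing cap, 5 km jitter,
20 iterations. The desk-scale configuration (`desk_scale_run_config`)
divides the distance parameters by ten (500 m / 12.5 km / 500 m, 5
iterations) to preserve the points-per-perimeter (~12) and
partners-per-point structure on the default 9 km × 6 km synthetic
landscape; the nine-scenario experiment then completes in well under a
minute on one CPU.

## 6. Metrics

All metrics treat a path as a sequence of cell-to-cell *moves* (graph
edges), canonicalized so direction does not matter; overlap is shared
moves, not shared cells, because two paths crossing at a point share no
corridor length. A move is inside the inner study area when both its cells
are (its midpoint lies on the shared edge/corner of the two cells). Per
scenario:

* **total path length** (km) — Σ Euclidean path lengths, duplicates counted;
* **unique path length** (km) — length of the distinct inner-area move set;
* **mean distance to path** (km) — Euclidean distance transform of the
  rasterized path cells, averaged over inner cells; undefined (reported
  missing, never 0) when no path exists;
* **mean convergent paths** — mean number of distinct paths per inner path
  cell;
* **commonality** — length-weighted fractions of the three resistance
  levels' move-set union shared by 3 / exactly 2 / 1 level(s); computed
  over the full extent by default (inner-only available) since the original
  choice is unstated;
* **composition** — each move's length attributed to the land-cover group
  of the cell it enters (crops pooled, the three urban classes pooled); the
  first cell of a path contributes nothing, so fractions sum to 1.
  Composition always uses the *original* land-cover map: a restored margin
  is still an agricultural margin, which is what makes "how much do paths
  use margins" answerable across scenarios.

Metrics are computed per iteration and then averaged (the aggregation order
is unstated in the original; per-iteration-then-mean also yields an sd
across iterations, which is reported alongside).

## 7. Synthetic landscape generator

The generator emulates the *structure* the analysis assumes, not any real
geography: an inner agricultural matrix of axis-aligned rectangular crop
parcels (side 26–34 cells ≈ 780–1020 m), each ringed by a 1-cell (30 m)
agricultural margin, interleaved with urban blocks (with greenspace and
impervious sub-blocks), water bodies and natural patches, inside an outer
natural/grassland perimeter ring. Placement is a greedy row-band scan:
proposals (type drawn from remaining area quotas, size randomized) are
accepted only if parcel-plus-ring collides with nothing already placed,
and crop placement stops at the target fraction or parcel count. Default
inner-area composition targets mirror the study region's agricultural core
— crop 0.65, margin 0.09 (emergent from parcel geometry rather than a
dial: a 1-cell ring around a ~30-cell parcel is ~14% of its area), urban
0.10, water 0.01, natural 0.04 — and realized fractions stay within ±3
percentage points of target across seeds. Default chemicals are six
moderately-to-highly bee-toxic actives with realistic contact LD50s
(spinosad's 0.0029 µg/bee among them); per-crop application intensities
relative to the urban baseline are chosen to span the published resistance
range from rice-like (~1) to citrus-like (~92) at the medium level.
Interannual variation is lognormal with cv = 0.3 (mean-one factors;
cv = 0 reproduces identical years). Acreage uses 1 cell at 30 m = 900 m² =
0.2223948 acre.

What the generator does *not* emulate — and therefore what passing tests do
not show about real data: irregular parcel geometry and road networks,
spatial autocorrelation of crop types, the NDVI-based urban
subclassification, conservation-land overlays, pesticide drift, and the
two-orders-of-magnitude larger extent of the real valley. Absolute
published magnitudes (millions of km of total path length, 205 + 205
source points) are functions of that extent and are out of reach at desk
scale; the experiment instead reproduces the *directional* results —
restored margins give more unique corridor length, shorter distances to
corridors, less convergence, and a far higher margin share of path length,
with margin elimination ≈ current conditions.

## 8. Determinism and seeds

All randomness flows from one master seed through
`SeedSequence([master_seed, stage_code, *keys])` (stage codes: landscape 1,
pesticide tables 2, west jitter 3, east jitter 4; keys are iteration and
point indices). Every artifact is a pure function of (configs, master
seed); `run-all` twice with the same seed produces byte-identical CSVs and
GeoJSON, and the manifest records configs, seed derivation and SHA-256
digests of every artifact.

## 9. Numerical conventions and degenerate inputs

* Rounding is half-up everywhere a whole-number resistance is produced
  (consistent with the published 11.76 → 12 example; documented for exact
  ties).
* Grid coordinates: row-major, 0-based, cell centers at
  origin + (index + 0.5) × cell size; origin is the lower-left corner
  (ESRI ASCII convention).
* Cost ties: equal-cost predecessors resolve to the lowest flat cell index.
* Floating point: traced path cost equals the accumulated cost at the
  destination to 1e-9 relative; oracle comparisons use the same tolerance.
* Degenerate inputs raise typed errors: empty chemical lists, zero-length
  perimeter lines, empty source sets, sources entirely on nodata, grids too
  small for the requested parcels, unmapped class codes (named in the
  message), out-of-range expert overrides, destinations that are
  unreachable (signalled; callers drop the pair with a warning).
* ESRI ASCII grids carry no CRS tag; a cell size under 0.01 is taken to
  indicate degree units and rejected (projected meter CRS required).

## 10. Known limitations

Least-cost paths assume cost accrues cell by cell — appropriate for insects
that move between adjacent 30 m cells over generations, not for strong
long-distance dispersers. Resistance from contact LD50 ignores exposure
routes, sublethal effects, drift and species differences; expert-valued
classes carry wide low–high spreads precisely because they are guesses.
The land-cover and crop layers are static (no rotation). Connectivity here
is descriptive (corridor geometry), not demographic or genetic prediction.
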