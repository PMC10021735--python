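# Methods

## Scope and coordinate frame

All computation is planar, in kilometres, in an arbitrary projected frame;
inputs are assumed already projected and no geodetic arithmetic is done.
Polygons are single exterior rings (no holes); multi-part land masses are
separate island records.  Distances are carried at full precision and
rounded half-up to two decimals only at the reporting layer (plain
banker's rounding would print a 73.085 km mean as 73.08 rather than the
tabular convention 73.09).

## Population allocation

District census totals are distributed across residential clusters
proportionally to cluster polygon area (dasymetric allocation with area as
the ancillary variable).  Allocations are kept real-valued: rounding to
whole persons would break exact conservation of the census total, and all
downstream quantities (shares, z) are ratios for which fractional persons
are harmless.

## Access classification

A residence needs a naval leg for facility kind *k* iff

1. its centroid lies more than `road_proximity_km` (default **5 km**) from
   the nearest road **on its own island** — Euclidean distance to road
   geometry, not network distance, because the rule exists precisely for
   residences off the network; or
2. its island hosts no same-district facility of kind *k*.

District restriction is a hard filter by default (public-sector referral
rules bind patients to their district); `district_restriction=False`
relaxes it for counterfactual analysis.

## Land routing

Road centerlines are exploded into straight edges; vertices within
`snap_tolerance_km` (default **1 m**) are merged (union-find on a grid
hash).  Residences and facilities attach by a perpendicular access link to
the nearest point of the nearest edge *on their island* (restricting
candidates to the island prevents a coastal point from attaching to a road
across a sea gap); the attachment point splits the edge and the link
length counts toward the reported distance — off-road residences can
legitimately be up to 5 km from the network and ignoring the link would
under-report their journey.  The closest facility minimises access link +
Dijkstra path + facility link over same-district facilities of the kind;
ties break to the smallest facility id.

## Water routing

The sea distance between two coastal points is the length of the shortest
planar path whose interior crosses no island interior.  Island polygons
are closed obstacles: paths may touch and run along boundaries (docks sit
on them).  Since such a shortest path only turns at obstacle vertices, it
is computed exactly with a visibility graph over all island vertices plus
the two query points.  Numerically, "crossing an interior" is tested
against islands shrunk by 1e-6 km (1 mm), so boundary-tracing edges are
admissible without epsilon-free predicate logic.  The static
vertex-to-vertex graph is built once per region and reused; query results
are cached.

A combined route has three legs:

* **residence → water-access point** (segment C or D): candidates are the
  island's ports/docks plus beaches within `beach_adjacency_km` (default
  **0.5 km**) of the residence polygon; beaches are departure points only.
  The leg is network-routed when the residence is road-connected and the
  point reachable by road, else straight-line.
* **water-access point → facility hub** (E or F): the hub is the port or
  dock nearest to the facility (beaches ineligible).
* **hub → facility** (G or H): Euclidean when within 1 km (hubs are
  typically adjacent to their facility), otherwise routed on the road
  graph; this reproduces the empirical pattern of mostly-small but
  occasionally tens-of-km final legs.

Facility choice minimises the three-leg total by default.  A greedy
`chained` mode (facility whose hub is nearest by water from the already
chosen departure point) is provided for comparison with per-leg "nearest"
constructions; the two can disagree when a nearer-by-water hub serves a
facility with a long final leg.

## District statistics

Segment statistics (N, mean, SE = sd/√N, median, min, max) are computed
per district over each segment letter present.  Access shares c/e are
population-weighted; the naval shares are exact complements (1 − c,
1 − e), so the conservation identity holds to the bit.  Route-type mean
distances are **unweighted over residential centroids by default** — each
centroid is one observation, consistent with segment Ns being centroid
counts — while an optional population-weighted mode exists; the split
(population-weighted shares, centroid-weighted means) is the only reading
consistent with both the head-count and the distance summaries of the
source registries this layout mirrors.  The total-distance score is

    z = c·d + c_nav·d_nav + e·f + e_nav·f_nav

with shares as fractions in [0, 1] (z is then a km-scale quantity) and
absent route-type means contributing zero.  The "all routes" district
summary is the unweighted mean of the present route-type means (two for a
district with no naval routes, four otherwise), and province aggregates
are unweighted means over districts with data.  Mean separation across
districts uses pairwise equal-variance two-sample t-tests at alpha = 0.05
summarised as a compact letter display (descending means, "A" highest,
insert-and-absorb letter construction, groups with <2 observations
excluded with a warning).  No multiple-testing correction is applied — the
display mirrors the uncorrected pairwise convention of descriptive
public-health tables.

## Workforce weighting and equity

Staff weights are persons-per-worker standards normalised to the nurse
standard: 2500/855 ≈ 2.92, 1000/855 ≈ 1.17, 1.  District availability is
x (puskesmas) and y (hospitals) = weighted workers per 1,000 population;
a district with no facilities of a type gets 0 for it.  The equity index
is

    equity = z / mean(x, y)

— strictly increasing in distance, strictly decreasing in either
availability term, low = excellent.  The printed formula this models is
typographically ambiguous; the chosen form matches the stated direction
and the per-1,000 framing of the availability maps, and an alternate
reciprocal form `equity = z · mean(1/x, 1/y)` is exposed as
`equity_form="ratio"`.  The two orderings coincide whenever x = y and are
empirically close otherwise; only the ranking direction is asserted in
tests, not the arithmetic of either form against external values.
Districts are ranked ascending; ties break alphabetically by name.

## 2SFCA comparator

Plain two-step floating catchment area with a fixed Euclidean buffer
(default **10 km**, no distance decay): facility supply ratio = weighted
workforce (or facility count with `supply="counts"`) over the summed
population of residences whose centroid lies in the buffer; residence
accessibility = sum of ratios of in-range facilities.  Residences covered
by no buffer are `in_range=False` with undefined (NaN) accessibility —
outside the buffers the method has no information and zero would be a
false value.

## Synthetic archipelagos

The seeded generator emulates the structure the analysis assumes: 3
districts by default, each a vertical band of sea holding 2–4 islands
(noisy-ellipse convex hulls, ≥2 km sea gaps, rejection-sampled placement
with an explicit infeasibility error), ~100 residences per district
(~300 total — the default study size, small squares placed inland),
per-island road networks as Euclidean minimum spanning trees over interior
points with access spurs connecting a `road_coverage` fraction (default
0.8) of residences (the spur foot splits the target segment so junctions
are topologically noded), hospitals on the largest islands and 1–3
puskesmas per district round-robin across islands (so some islands lack a
puskesmas and most lack a hospital, producing both land and naval route
classes), beaches every 4 km of coastline, one port per island, one dock
at the coast point nearest each facility, and uniformly sampled staffing
(puskesmas 0–2 physicians, 2–10 nurses, 1–6 midwives; hospitals 2–12 /
10–40 / 2–12).  One integer seed drives a single `numpy` generator; no
global random state is touched, and identical config + seed yields
byte-identical output files.

What the generator does **not** emulate: coastline fractality, bathymetry
and real sailing routes, population gravity (residences are
area-uniform within islands), road condition/travel time, and the
two-order-of-magnitude facility counts of a real province.  Passing tests
therefore demonstrate correctness of the computation on structurally
faithful inputs, not calibration of the synthetic numbers to any real
region's values.

A hand-crafted toy region (two districts, three axis-aligned islands)
ships with fully hand-derived expected values for every route leg,
summary, and equity term; the end-to-end suite asserts them exactly.

## Numerical choices

* Point-on-island tests use a 1e-9 km tolerance; water-access points must
  lie within 0.5 km of an island boundary.
* All tie-breaks are deterministic: smallest facility/access-point id,
  alphabetical district name.
* Degenerate inputs raise early with the entity named: zero-area
  polygons, landlocked residences, facility islands without docks,
  districts with zero workforce (equity is NaN for them and the rest of
  the bundle is still produced), empty 2SFCA catchments (excluded with a
  warning).
* Disconnection is a value, not an error, for graph distances (+inf);
  route construction converts it into a named error only when no eligible
  facility is reachable at all.

## Verification strategy and problem sizes

Routing primitives are verified against independent oracles: Dijkstra
against Floyd–Warshall on twenty random 50-node graphs; the visibility
graph against a 16-neighbourhood raster Dijkstra (0.5 km cells, knight
moves bounding the grid-metric distortion at ~3%) on 200 random obstructed
pairs; polygon area and centroid against Monte-Carlo sampling (≥10⁶
points); endpoint snapping against a brute-force union-find.  Aggregation
arithmetic is verified against the published Maluku district figures
bundled as the worked example (province means, all-routes row, access
percentages, staffing weights and totals reproduce the printed values at
printed precision).  Conservation, complement, monotonicity and
determinism invariants run across seeded random configurations (100 random
allocation vectors, 50 equity perturbations, multiple generated regions).
The default end-to-end problem size is 3 districts / ~300 residences,
which the full pipeline completes in a few seconds.

## Known limitations

* Water paths are geometric shortest paths; real vessels follow routes,
  schedules, currents and weather.
* The equity index's exact functional form is a modelling choice (see
  above); cross-study comparisons should use rankings, which are
  unit-invariant, rather than raw index values.
* The 2SFCA comparator deliberately uses straight-line buffers, not
  travel distance, so its scores are not comparable across regions with
  very different barrier geometry.
* Facility adequacy against per-facility minimum-staffing rules is out of
  scope (the index uses aggregate weighted staff only).
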