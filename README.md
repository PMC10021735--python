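# archaccess

Healthcare accessibility and equity analysis for archipelagic regions.

In island provinces such as Maluku (Indonesia), the journey from home to a
health facility often combines roads and open water: residents more than
5 km from a road, or living on an island without the facility they need,
must travel to a dock or beach, cross the sea, and land at the port nearest
to the facility.  `archaccess` is a library + CLI for public-health and
GIS analysts that quantifies this: it allocates census populations to
residential clusters, routes every cluster to its district's nearest
puskesmas (primary health centre) and hospital over land and water,
summarises distances per district, and combines them with health-workforce
availability into a per-district equity index, with a two-step floating
catchment area (2SFCA) comparator.

## Model

For each district, with route-type shares and mean distances

- *c*, *e* — population shares reaching puskesmas / hospital by land
  (*c_nav* = 1 − *c*, *e_nav* = 1 − *e* are the land+naval shares),
- *d*, *f* — mean land distances to puskesmas / hospital (km), and
  *d_nav*, *f_nav* their land+naval analogues,

the population-weighted total travel distance is

```
z = c·d + c_nav·d_nav + e·f + e_nav·f_nav        [km]
```

Health workers are weighted by national staffing standards normalised to
the nurse standard (1:2500 / 1:1000 / 1:855 persons per physician /
midwife / nurse), giving per-facility weighted staff

```
mu = 2.92·physicians + 1.17·midwives + 1.00·nurses
```

District availability terms x (puskesmas) and y (hospitals) are weighted
workers per 1,000 population, and the equity index is

```
equity = z / mean(x, y)        (low = excellent, high = severe)
```

Routes decompose into segment types A–H: A/B residence→facility by land;
C/D residence→nearest water-access point; E/F water-access point→facility
dock over water (a shortest path avoiding all island interiors, computed
exactly on a visibility graph over island vertices); G/H facility
dock→facility.  District restriction is a hard filter (patients use
facilities of their own district); `--cross-district` relaxes it.

## Worked example

The hand-crafted toy archipelago (two districts, three islands; every leg
checkable by hand) runs end to end:

```python
import archaccess as aa

region = aa.toy_fixture()
results = aa.AccessibilityModel(region).fit()
print(results.summary())
```

prints

```
Healthcare accessibility summary
======================================================================
Alpha (population 300)
  reach puskesmas by land: 66.67%   hospital by land: 66.67%
  mean km (puskesmas land / hospital land / puskesmas naval / hospital naval): 7.00 / 7.00 / 28.18 / 36.18
  z = 30.79 km   all-routes mean = 19.59 km
Beta (population 50)
  reach puskesmas by land: 100.00%   hospital by land: 0.00%
  mean km (puskesmas land / hospital land / puskesmas naval / hospital naval): 7.00 / - / - / -
  z = 7.00 km   all-routes mean = 7.00 km
----------------------------------------------------------------------
Equity ranking (low value = excellent):
  1. Beta: equity 0.131 (z 7.00 km, x 106.80, y 0.00 per 1,000)
  2. Alpha: equity 0.959 (z 30.79 km, x 20.30, y 43.93 per 1,000)
```

Two of Alpha's three clusters reach both facilities by road (means 7.00 km
each); the third lives on a facility-free island and crosses the water
around the main island's corner (28.18 km to the puskesmas, 36.18 km to
the hospital), so one third of Alpha's population carries the naval
distances into z.  Beta has a puskesmas 7 km away but no hospital in its
district, so its hospital share is naval-class and unreachable until the
district restriction is relaxed.  Beta's small z and strong
staff-per-1,000 make it rank first.

Synthetic multi-island regions with the same structure (sparse roads,
coastal access points, heterogeneous staffing) come from the seeded
generator:

```python
region = aa.generate_region(aa.GeneratorConfig(seed=1))
results = aa.AccessibilityModel(region).fit()
```

or from the CLI: `archaccess simulate --seed 1 --out region/` then
`archaccess run --in region/ --out results/`.

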