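"""Seeded synthetic archipelagos and a hand-crafted toy region.

``generate_region`` builds multi-island study regions with the structural
features the analysis assumes: several administrative districts, convex-ish
islands (perturbed ellipses) separated by sea gaps, sparse per-island road
networks (Euclidean minimum spanning trees over interior points, plus
access spurs for a configurable fraction of residences), beaches at fixed
spacing along every coastline, one port per island, one dock next to every
facility, and facilities with heterogeneous staffing.  A single integer
seed drives one reproducible random stream.

``toy_fixture`` is a fixed two-district, three-island region whose
coordinates are chosen so that every route leg is computable by hand; the
expected values ship with the fixture as :data:`TOY_EXPECTED`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial.distance import pdist, squareform
from shapely.geometry import LineString, MultiPoint, Point, Polygon, box

from .core import (
    District,
    Facility,
    Island,
    ResidenceCluster,
    StudyRegion,
    WaterAccessPoint,
)

__all__ = ["GeneratorConfig", "generate_region", "toy_fixture", "TOY_EXPECTED"]


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the synthetic-archipelago generator.

    Ranges are inclusive ``(low, high)`` bounds sampled per district,
    island or facility.  ``road_coverage`` is the fraction of residences
    that get a spur connecting them to their island's road network.
    """

    n_districts: int = 3
    islands_per_district: tuple[int, int] = (2, 4)
    residences_per_district: tuple[int, int] = (90, 110)
    road_coverage: float = 0.8
    puskesmas_per_district: tuple[int, int] = (1, 3)
    hospitals_per_district: tuple[int, int] = (1, 1)
    population_per_district: tuple[int, int] = (30_000, 300_000)
    puskesmas_physicians: tuple[int, int] = (0, 2)
    puskesmas_nurses: tuple[int, int] = (2, 10)
    puskesmas_midwives: tuple[int, int] = (1, 6)
    hospital_physicians: tuple[int, int] = (2, 12)
    hospital_nurses: tuple[int, int] = (10, 40)
    hospital_midwives: tuple[int, int] = (2, 12)
    beach_spacing_km: float = 4.0
    sea_gap_km: float = 2.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_districts < 1:
            raise ValueError("n_districts must be >= 1")
        if not (0.0 <= self.road_coverage <= 1.0):
            raise ValueError("road_coverage must lie in [0, 1]")
        if self.beach_spacing_km <= 0:
            raise ValueError("beach_spacing_km must be positive")
        if self.sea_gap_km < 0:
            raise ValueError("sea_gap_km must be non-negative")
        for name in (
            "islands_per_district",
            "residences_per_district",
            "puskesmas_per_district",
            "hospitals_per_district",
            "population_per_district",
            "puskesmas_physicians",
            "puskesmas_nurses",
            "puskesmas_midwives",
            "hospital_physicians",
            "hospital_nurses",
            "hospital_midwives",
        ):
            lo, hi = getattr(self, name)
            if lo < 0 or hi < lo:
                raise ValueError(f"{name} must satisfy 0 <= low <= high")
        if self.islands_per_district[0] < 1:
            raise ValueError("each district needs at least one island")


# geometry of the generator canvas: one vertical band of sea per district
_ZONE_W = 70.0
_ZONE_H = 70.0
_ZONE_MARGIN = 2.0


def _perturbed_ellipse(
    rng: np.random.Generator, cx: float, cy: float, a: float, b: float, theta: float
) -> Polygon:
    """Convex island polygon: noisy ellipse vertices, convex-hulled."""
    n = 18
    ang = np.linspace(0, 2 * math.pi, n, endpoint=False)
    radii = 1.0 + rng.uniform(-0.15, 0.15, size=n)
    xs = a * radii * np.cos(ang)
    ys = b * radii * np.sin(ang)
    ct, st = math.cos(theta), math.sin(theta)
    px = cx + ct * xs - st * ys
    py = cy + st * xs + ct * ys
    return MultiPoint(list(zip(px, py))).convex_hull


def _sample_point_inside(
    rng: np.random.Generator, poly: Polygon, margin: float, attempts: int = 200
) -> Point:
    inner = poly.buffer(-margin)
    if inner.is_empty:
        inner = poly.buffer(-margin / 4)
    if inner.is_empty:
        return poly.centroid
    minx, miny, maxx, maxy = inner.bounds
    for _ in range(attempts):
        p = Point(rng.uniform(minx, maxx), rng.uniform(miny, maxy))
        if inner.covers(p):
            return p
    return inner.representative_point()


def generate_region(config: GeneratorConfig) -> StudyRegion:
    """Generate a :class:`StudyRegion` honouring every domain invariant.

    Identical config (including seed) yields an identical region.  Raises
    ``ValueError`` naming the constraint when the config is geometrically
    infeasible (e.g. islands cannot be placed at the required sea gap).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    districts: list[District] = []
    islands: list[Island] = []
    residences: list[ResidenceCluster] = []
    roads: list[LineString] = []
    waps: list[WaterAccessPoint] = []
    facilities: list[Facility] = []
    island_district: dict[str, str] = {}
    island_road_points: dict[str, list[Point]] = {}

    for di in range(config.n_districts):
        did = f"D{di + 1}"
        x0 = di * _ZONE_W
        zone = box(x0 + _ZONE_MARGIN, _ZONE_MARGIN, x0 + _ZONE_W - _ZONE_MARGIN, _ZONE_H - _ZONE_MARGIN)
        districts.append(
            District(
                id=did,
                name=f"District {di + 1}",
                polygon=zone,
                total_population=int(rng.integers(*config.population_per_district, endpoint=True)),
            )
        )

        n_isl = int(rng.integers(*config.islands_per_district, endpoint=True))
        placed: list[Polygon] = []
        for ii in range(n_isl):
            ok = False
            for _ in range(300):
                a = rng.uniform(6.0, 13.0)
                b = rng.uniform(4.0, 9.0)
                theta = rng.uniform(0, math.pi)
                r_max = max(a, b) * 1.2
                cx = rng.uniform(x0 + _ZONE_MARGIN + r_max, x0 + _ZONE_W - _ZONE_MARGIN - r_max)
                cy = rng.uniform(_ZONE_MARGIN + r_max, _ZONE_H - _ZONE_MARGIN - r_max)
                poly = _perturbed_ellipse(rng, cx, cy, a, b, theta)
                if all(
                    poly.distance(other.polygon) > config.sea_gap_km for other in islands
                ):
                    ok = True
                    break
            if not ok:
                raise ValueError(
                    f"infeasible config: cannot place island {ii + 1} of district "
                    f"{did} with a {config.sea_gap_km} km sea gap; reduce "
                    "islands_per_district or sea_gap_km"
                )
            iid = f"{did}-I{ii + 1}"
            islands.append(Island(iid, poly))
            island_district[iid] = did
            placed.append(poly)

        d_islands = [isl for isl in islands if island_district[isl.id] == did]
        d_islands_by_area = sorted(d_islands, key=lambda i: -i.polygon.area)

        # roads: Euclidean MST over interior points, one network per island
        for isl in d_islands:
            n_pts = max(3, int(round(math.sqrt(isl.polygon.area))))
            pts = [_sample_point_inside(rng, isl.polygon, 1.0) for _ in range(n_pts)]
            coords = np.array([(p.x, p.y) for p in pts])
            dm = squareform(pdist(coords))
            mst = minimum_spanning_tree(dm).tocoo()
            for i, j in zip(mst.row, mst.col):
                seg = LineString([coords[i], coords[j]])
                if seg.length > 1e-9:
                    roads.append(seg)
            island_road_points[isl.id] = pts

        # facilities sit on road points: hospitals on the largest islands,
        # puskesmas round-robin across all of the district's islands
        n_p = int(rng.integers(*config.puskesmas_per_district, endpoint=True))
        n_h = int(rng.integers(*config.hospitals_per_district, endpoint=True))
        used: dict[str, set[int]] = {isl.id: set() for isl in d_islands}

        def _facility_site(isl: Island) -> Point:
            pts = island_road_points[isl.id]
            free = [k for k in range(len(pts)) if k not in used[isl.id]]
            if free:
                k = int(rng.choice(free))
                used[isl.id].add(k)
                return pts[k]
            p = pts[int(rng.integers(len(pts)))]
            return Point(p.x + rng.uniform(-0.1, 0.1), p.y + rng.uniform(-0.1, 0.1))

        for hi in range(n_h):
            isl = d_islands_by_area[hi % len(d_islands_by_area)]
            loc = _facility_site(isl)
            facilities.append(
                Facility(
                    id=f"{did}-H{hi + 1}",
                    kind="hospital",
                    district_id=did,
                    location=loc,
                    physicians=int(rng.integers(*config.hospital_physicians, endpoint=True)),
                    nurses=int(rng.integers(*config.hospital_nurses, endpoint=True)),
                    midwives=int(rng.integers(*config.hospital_midwives, endpoint=True)),
                )
            )
        for pi in range(n_p):
            isl = d_islands_by_area[pi % len(d_islands_by_area)]
            loc = _facility_site(isl)
            facilities.append(
                Facility(
                    id=f"{did}-P{pi + 1}",
                    kind="puskesmas",
                    district_id=did,
                    location=loc,
                    physicians=int(rng.integers(*config.puskesmas_physicians, endpoint=True)),
                    nurses=int(rng.integers(*config.puskesmas_nurses, endpoint=True)),
                    midwives=int(rng.integers(*config.puskesmas_midwives, endpoint=True)),
                )
            )

        # residences: area-proportional across islands, small squares inland
        n_res = int(rng.integers(*config.residences_per_district, endpoint=True))
        areas = np.array([isl.polygon.area for isl in d_islands])
        shares = areas / areas.sum()
        counts = rng.multinomial(n_res, shares)
        ri = 0
        for isl, cnt in zip(d_islands, counts):
            for _ in range(int(cnt)):
                half = rng.uniform(0.15, 0.45)
                c = _sample_point_inside(rng, isl.polygon, margin=half + 0.3)
                poly = box(c.x - half, c.y - half, c.x + half, c.y + half)
                ri += 1
                residences.append(
                    ResidenceCluster.from_polygon(f"{did}-R{ri}", did, poly)
                )

        # access spurs for the covered fraction of residences
        d_res = [r for r in residences if r.district_id == did]
        n_cov = int(round(config.road_coverage * len(d_res)))
        cov_idx = rng.choice(len(d_res), size=n_cov, replace=False) if n_cov else []
        for k in cov_idx:
            r = d_res[int(k)]
            isl = next(i for i in d_islands if i.polygon.covers(r.centroid) or i.polygon.distance(r.centroid) < 1e-9)
            cand = [(idx, ln) for idx, ln in enumerate(roads) if ln.intersects(isl.polygon)]
            if not cand:
                continue
            idx, best = min(cand, key=lambda c: c[1].distance(r.centroid))
            t = best.project(r.centroid)
            proj = best.interpolate(t)
            # node the junction: split the target segment at the spur foot
            # so the spur is topologically connected, not just coincident
            if 1e-9 < t < best.length - 1e-9:
                cs = list(best.coords)
                roads[idx] = LineString([cs[0], (proj.x, proj.y)])
                roads.append(LineString([(proj.x, proj.y), cs[-1]]))
            spur = LineString([(r.centroid.x, r.centroid.y), (proj.x, proj.y)])
            if spur.length > 1e-9:
                roads.append(spur)

    # water access: beaches at fixed spacing, a port per island, and a dock
    # next to every facility
    for isl in islands:
        ext = isl.polygon.exterior
        per = ext.length
        n_b = max(1, int(per // config.beach_spacing_km))
        for bi in range(n_b):
            loc = ext.interpolate(bi * config.beach_spacing_km)
            waps.append(WaterAccessPoint(f"{isl.id}-beach{bi + 1}", "beach", Point(loc.x, loc.y)))
        ploc = ext.interpolate(rng.uniform(0, per))
        waps.append(WaterAccessPoint(f"{isl.id}-port", "port", Point(ploc.x, ploc.y)))
    isl_by_id = {i.id: i for i in islands}
    for f in facilities:
        host = next(
            i for i in islands if i.polygon.covers(f.location) or i.polygon.distance(f.location) < 1e-9
        )
        ext = isl_by_id[host.id].polygon.exterior
        loc = ext.interpolate(ext.project(f.location))
        waps.append(WaterAccessPoint(f"{f.id}-dock", "dock", Point(loc.x, loc.y)))

    return StudyRegion(
        districts=districts,
        islands=islands,
        residences=residences,
        roads=roads,
        water_access_points=waps,
        facilities=facilities,
    )


# ---------------------------------------------------------------------------
# toy fixture with hand-computable route legs
# ---------------------------------------------------------------------------

_SQ5 = math.sqrt(125.0)  # corner detour leg used by the fixture's water routes

#: Hand-computed expected values for :func:`toy_fixture` (all km, except
#: fractions/scores).  Derivations:
#:
#: * R1 (centroid (10,7)) attaches to the road at (10,5): puskesmas route
#:   2.0; hospital route 2.0 + 8.0 = 10.0.
#: * R3 (centroid (2,1)) attaches at (2,5): puskesmas 4.0 + 8.0 = 12.0,
#:   hospital 4.0.
#: * R2 (centroid (32,5), island without roads or facilities) departs from
#:   dock K3 (30,5), leg 2.0.  The straight line to either hub crosses
#:   island I1 ((0,0)–(20,20) square), so water legs round its corner
#:   (20,0): to puskesmas hub K1 (10,0): sqrt(125) + 10; to hospital hub
#:   K2 (2,0): sqrt(125) + 18.  Both hubs are 5 km from their facility
#:   along the road (G = H = 5.0).
#: * R4 (centroid (2,36)) attaches at (2,35): puskesmas 1.0 + 6.0 = 7.0;
#:   district Beta has no hospital, so hospital access is naval-class and
#:   unreachable within the district.
TOY_EXPECTED = {
    "R1": {"puskesmas_land": 2.0, "hospital_land": 10.0},
    "R3": {"puskesmas_land": 12.0, "hospital_land": 4.0},
    "R2": {
        "puskesmas": {"C": 2.0, "E": _SQ5 + 10.0, "G": 5.0, "total": 2.0 + _SQ5 + 10.0 + 5.0},
        "hospital": {"D": 2.0, "F": _SQ5 + 18.0, "H": 5.0, "total": 2.0 + _SQ5 + 18.0 + 5.0},
        "wap": "K3",
        "puskesmas_hub": "K1",
        "hospital_hub": "K2",
    },
    "R4": {"puskesmas_land": 7.0},
    "alpha": {
        "population": 300,
        "per_cluster_population": 100.0,
        "c": 2.0 / 3.0,
        "e": 2.0 / 3.0,
        "d": 7.0,
        "f": 7.0,
        "d_nav": 2.0 + _SQ5 + 10.0 + 5.0,
        "f_nav": 2.0 + _SQ5 + 18.0 + 5.0,
        "mu_puskesmas": 6.09,   # 1*2.92 + 1*1.17 + 2*1
        "mu_hospital": 13.18,   # 2*2.92 + 2*1.17 + 5*1
        "x": 6.09 / 300 * 1000,
        "y": 13.18 / 300 * 1000,
    },
    "beta": {
        "population": 50,
        "c": 1.0,
        "e": 0.0,
        "e_nav": 1.0,
        "d": 7.0,
        "z": 7.0,
        "mu_puskesmas": 5.34,   # 0*2.92 + 2*1.17 + 3*1
        "x": 5.34 / 50 * 1000,
        "y": 0.0,
    },
}


def toy_fixture() -> StudyRegion:
    """Fixed two-district, three-island region with hand-computed routes.

    District Alpha spans a large road-served island (with one puskesmas and
    one hospital on the road) and a small facility-free island whose single
    residence must travel by water around the big island's corner.
    District Beta is a single island with a puskesmas but no hospital.
    See :data:`TOY_EXPECTED` for the documented expected values.
    """
    i1 = Island("I1", box(0, 0, 20, 20))
    i2 = Island("I2", box(30, 0, 40, 10))
    i3 = Island("I3", box(0, 30, 10, 40))
    alpha = District("alpha", "Alpha", box(-1, -1, 45, 25), 300)
    beta = District("beta", "Beta", box(-1, 29, 11, 41), 50)
    roads = [
        LineString([(2, 5), (10, 5)]),
        LineString([(10, 5), (18, 5)]),
        LineString([(2, 35), (8, 35)]),
    ]
    facilities = [
        Facility("H1", "hospital", "alpha", Point(2, 5), physicians=2, nurses=5, midwives=2),
        Facility("P1", "puskesmas", "alpha", Point(10, 5), physicians=1, nurses=2, midwives=1),
        Facility("P2", "puskesmas", "beta", Point(8, 35), physicians=0, nurses=3, midwives=2),
    ]
    waps = [
        WaterAccessPoint("K1", "dock", Point(10, 0)),
        WaterAccessPoint("K2", "dock", Point(2, 0)),
        WaterAccessPoint("K3", "dock", Point(30, 5)),
        WaterAccessPoint("K4", "dock", Point(8, 30)),
    ]
    residences = [
        ResidenceCluster.from_polygon("R1", "alpha", box(9.5, 6.5, 10.5, 7.5)),
        ResidenceCluster.from_polygon("R2", "alpha", box(31.5, 4.5, 32.5, 5.5)),
        ResidenceCluster.from_polygon("R3", "alpha", box(1.5, 0.5, 2.5, 1.5)),
        ResidenceCluster.from_polygon("R4", "beta", box(1.5, 35.5, 2.5, 36.5)),
    ]
    return StudyRegion(
        districts=[alpha, beta],
        islands=[i1, i2, i3],
        residences=residences,
        roads=roads,
        water_access_points=waps,
        facilities=facilities,
    )
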