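"""Water-borne routing: access points, facility hubs, and sea distances.

Sea travel between two coastal points is modelled as the shortest planar
path that does not cross any island interior.  Such a path is a polyline
whose interior vertices are island-polygon corners, so it is found exactly
with a visibility graph over the island vertices plus the two query points,
followed by Dijkstra search.  Paths may touch island boundaries (docks sit
on them) and may run along a polygon edge, but never cross an interior.

A combined land+naval route has three legs:

* residence → nearest water-access point (segment C for puskesmas-bound
  journeys, D for hospital-bound), over roads when the residence is
  road-connected, else straight-line;
* water-access point → facility hub over water (segment E / F);
* hub → facility on land (segment G / H), Euclidean when within 1 km,
  otherwise routed over the road graph.

Beaches count as departure points only (and only within 0.5 km of the
residence polygon); the arrival hub must be a port or dock.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
from shapely.geometry import LineString, Point, Polygon
from shapely.strtree import STRtree

from .core import Facility, ResidenceCluster, StudyRegion
from .landroute import (
    DEFAULT_ROAD_PROXIMITY_KM,
    LandRouter,
    nearest_road_distance,
)

__all__ = [
    "NavalRoute",
    "WaterRouter",
    "water_distance",
    "nearest_water_access",
    "facility_hub",
    "combined_route",
    "NavalRouter",
    "DEFAULT_BEACH_ADJACENCY_KM",
    "HUB_EUCLIDEAN_CUTOFF_KM",
]

DEFAULT_BEACH_ADJACENCY_KM = 0.5

#: Below this hub→facility separation the final leg is taken as Euclidean;
#: above it the leg is routed on the road graph (facility docks are usually
#: adjacent to their facility, but not always).
HUB_EUCLIDEAN_CUTOFF_KM = 1.0

_EPS = 1e-9


@dataclass(frozen=True)
class NavalRoute:
    """A three-leg land+naval route (segments C/E/G or D/F/H)."""

    residence_id: str
    facility_id: str
    facility_kind: str
    wap_id: str
    hub_id: str
    leg_residence_to_wap: float
    leg_water: float
    leg_dock_to_facility: float

    @property
    def total_km(self) -> float:
        return self.leg_residence_to_wap + self.leg_water + self.leg_dock_to_facility

    @property
    def segment_labels(self) -> tuple[str, str, str]:
        return ("C", "E", "G") if self.facility_kind == "puskesmas" else ("D", "F", "H")


class WaterRouter:
    """Exact shortest water distances around island obstacles.

    The static vertex-to-vertex visibility graph is built once; each query
    adds the two endpoints and runs Dijkstra.  Queries are cached.
    """

    def __init__(self, islands: list[Polygon]):
        self.islands = islands
        # shrink interiors by a hair so paths may touch/trace boundaries
        self._shrunk = [p.buffer(-1e-6) for p in islands]
        self._shrunk = [p for p in self._shrunk if not p.is_empty]
        self._tree = STRtree(self._shrunk) if self._shrunk else None
        verts: list[tuple[float, float]] = []
        seen: set[tuple[float, float]] = set()
        for p in islands:
            for c in p.exterior.coords[:-1]:
                c = (c[0], c[1])
                if c not in seen:
                    seen.add(c)
                    verts.append(c)
        self._verts = verts
        self._static: nx.Graph | None = None
        self._cache: dict[tuple, float] = {}

    # -- geometry ------------------------------------------------------

    def _blocked(self, a: tuple[float, float], b: tuple[float, float]) -> bool:
        if self._tree is None or a == b:
            return False
        seg = LineString([a, b])
        for idx in self._tree.query(seg):
            if seg.intersects(self._shrunk[int(idx)]):
                return True
        return False

    def _inside_land(self, p: tuple[float, float]) -> bool:
        if self._tree is None:
            return False
        pt = Point(p)
        return any(self._shrunk[int(i)].contains(pt) for i in self._tree.query(pt))

    def _static_graph(self) -> nx.Graph:
        if self._static is None:
            g = nx.Graph()
            vs = self._verts
            g.add_nodes_from(range(len(vs)))
            for i in range(len(vs)):
                for j in range(i + 1, len(vs)):
                    if not self._blocked(vs[i], vs[j]):
                        g.add_edge(i, j, length=math.dist(vs[i], vs[j]))
            self._static = g
        return self._static

    # -- queries -------------------------------------------------------

    def distance(self, p: Point, q: Point) -> float:
        """Shortest water distance p→q in km (``+inf`` if fully enclosed).

        Raises
        ------
        ValueError
            If either endpoint lies strictly inside an island.
        """
        a, b = (p.x, p.y), (q.x, q.y)
        key = (a, b) if a <= b else (b, a)
        if key in self._cache:
            return self._cache[key]
        for name, pt in (("p", a), ("q", b)):
            if self._inside_land(pt):
                raise ValueError(f"endpoint {name} lies strictly inside an island")
        if not self._blocked(a, b):
            d = math.dist(a, b)
        else:
            g = self._static_graph().copy()
            na, nb = "src", "dst"
            g.add_node(na)
            g.add_node(nb)
            for i, v in enumerate(self._verts):
                if not self._blocked(a, v):
                    g.add_edge(na, i, length=math.dist(a, v))
                if not self._blocked(b, v):
                    g.add_edge(nb, i, length=math.dist(b, v))
            try:
                d = nx.dijkstra_path_length(g, na, nb, weight="length")
            except nx.NetworkXNoPath:
                d = math.inf
        self._cache[key] = d
        return d


def water_distance(p: Point, q: Point, islands: list[Polygon]) -> float:
    """Shortest land-avoiding water distance between two points (km)."""
    return WaterRouter(islands).distance(p, q)


def nearest_water_access(
    residence: ResidenceCluster,
    region: StudyRegion,
    road_proximity_km: float = DEFAULT_ROAD_PROXIMITY_KM,
    beach_adjacency_km: float = DEFAULT_BEACH_ADJACENCY_KM,
    land_router: LandRouter | None = None,
) -> tuple:
    """Nearest usable departure point and its land leg (segment C/D).

    Candidates are the ports/docks of the residence's island plus any beach
    within ``beach_adjacency_km`` of the residence polygon.  The land leg is
    measured over the road network when the residence is road-connected and
    the candidate is reachable by road; otherwise it is the straight-line
    centroid→point distance.  Ties break toward the smallest id.

    Returns ``(WaterAccessPoint, leg_km)``.
    """
    island = region.island_containing(residence.centroid)
    if island is None:
        raise ValueError(f"residence {residence.id} lies on no island")
    candidates = list(region.waps_on_island(island, kinds=("port", "dock")))
    for w in region.water_access_points:
        if w.kind == "beach" and residence.polygon.distance(w.location) <= beach_adjacency_km:
            if w not in candidates:
                candidates.append(w)
    if not candidates:
        raise ValueError(f"landlocked residence {residence.id}: island has no water access")

    road_connected = (
        nearest_road_distance(residence.centroid, region.roads_on_island(island))
        <= road_proximity_km
    )
    best = None
    for w in sorted(candidates, key=lambda w: w.id):
        straight = residence.centroid.distance(w.location)
        leg = straight
        if road_connected and land_router is not None and land_router.network.n_edges:
            rlink = land_router.residence_link(residence)
            wnode, wlink = land_router.network.attach(w.location, within=island.polygon)
            net = rlink.link_km + land_router.network.shortest_path_length(rlink.node, wnode) + wlink
            if math.isfinite(net):
                leg = net
        if best is None or leg < best[1] - 1e-12:
            best = (w, leg)
    return best


def facility_hub(facility: Facility, region: StudyRegion):
    """The port/dock serving as the facility's naval arrival hub.

    Beaches are ineligible.  The hub is the port or dock on the facility's
    island with minimum Euclidean distance to the facility; ties break
    toward the smallest id.
    """
    island = region.island_containing(facility.location)
    if island is None:
        raise ValueError(f"facility {facility.id} lies on no island")
    docks = region.waps_on_island(island, kinds=("port", "dock"))
    if not docks:
        raise ValueError(f"facility {facility.id}: no port or dock on its island")
    return min(docks, key=lambda w: (facility.location.distance(w.location), w.id))


class NavalRouter:
    """Combined land+naval routing context with shared caches."""

    def __init__(
        self,
        region: StudyRegion,
        land_router: LandRouter | None = None,
        water_router: WaterRouter | None = None,
        road_proximity_km: float = DEFAULT_ROAD_PROXIMITY_KM,
        beach_adjacency_km: float = DEFAULT_BEACH_ADJACENCY_KM,
        cross_district: bool = False,
        mode: str = "total",
    ):
        if mode not in ("total", "chained"):
            raise ValueError("mode must be 'total' or 'chained'")
        self.region = region
        self.mode = mode
        self.road_proximity_km = road_proximity_km
        self.beach_adjacency_km = beach_adjacency_km
        self.cross_district = cross_district
        self.land = land_router or LandRouter(region, cross_district=cross_district)
        self.water = water_router or WaterRouter([i.polygon for i in region.islands])
        self._hub_cache: dict[str, object] = {}
        self._gleg_cache: dict[str, float] = {}

    def hub(self, facility: Facility):
        if facility.id not in self._hub_cache:
            self._hub_cache[facility.id] = facility_hub(facility, self.region)
        return self._hub_cache[facility.id]

    def hub_leg(self, facility: Facility) -> float:
        """Hub→facility land leg (segment G/H)."""
        if facility.id not in self._gleg_cache:
            hub = self.hub(facility)
            straight = hub.location.distance(facility.location)
            if straight <= HUB_EUCLIDEAN_CUTOFF_KM or not self.land.network.n_edges:
                leg = straight
            else:
                leg = self.land.point_to_facility_km(hub.location, facility)
                if not math.isfinite(leg):
                    leg = straight
            self._gleg_cache[facility.id] = leg
        return self._gleg_cache[facility.id]

    def route(self, residence: ResidenceCluster, facility_kind: str) -> NavalRoute:
        """Best combined route for one residence (segments C/E/G or D/F/H).

        In ``total`` mode the facility minimises the three-leg sum; in
        ``chained`` mode it is chosen greedily by the shortest water leg
        from the residence's nearest water-access point, mirroring per-leg
        "nearest" chaining.
        """
        if self.cross_district:
            candidates = [f for f in self.region.facilities if f.kind == facility_kind]
        else:
            candidates = self.region.facilities_in_district(
                residence.district_id, facility_kind
            )
        if not candidates:
            raise ValueError(
                f"no eligible facility: residence {residence.id} has no "
                f"{facility_kind} in district {residence.district_id}"
            )
        wap, leg_c = nearest_water_access(
            residence,
            self.region,
            road_proximity_km=self.road_proximity_km,
            beach_adjacency_km=self.beach_adjacency_km,
            land_router=self.land,
        )
        options = []
        for f in sorted(candidates, key=lambda f: f.id):
            hub = self.hub(f)
            leg_w = self.water.distance(wap.location, hub.location)
            leg_g = self.hub_leg(f)
            total = leg_c + leg_w + leg_g
            options.append((f, hub, leg_w, leg_g, total))
        if self.mode == "total":
            f, hub, leg_w, leg_g, total = min(options, key=lambda o: (o[4], o[0].id))
        else:
            f, hub, leg_w, leg_g, total = min(options, key=lambda o: (o[2], o[4], o[0].id))
        if not math.isfinite(total):
            raise ValueError(
                f"residence {residence.id}: unroutable water leg to every "
                f"{facility_kind} in district {residence.district_id}"
            )
        return NavalRoute(
            residence_id=residence.id,
            facility_id=f.id,
            facility_kind=facility_kind,
            wap_id=wap.id,
            hub_id=hub.id,
            leg_residence_to_wap=leg_c,
            leg_water=leg_w,
            leg_dock_to_facility=leg_g,
        )


def combined_route(
    residence: ResidenceCluster,
    facility_kind: str,
    region: StudyRegion,
    mode: str = "total",
    **kwargs,
) -> NavalRoute:
    """One-shot convenience wrapper around :class:`NavalRouter`."""
    return NavalRouter(region, mode=mode, **kwargs).route(residence, facility_kind)
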