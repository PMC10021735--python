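"""Road-graph construction and district-restricted closest-facility routing.

The road network is modelled as an undirected graph whose nodes are road
vertices (endpoints snapped within a small tolerance) and whose edge
weights are Euclidean segment lengths in km.  Residences and facilities
attach to the graph by a perpendicular access link to the nearest point of
the nearest edge; that point splits the edge and the link length counts
toward the reported route distance.

Access classification follows two rules: a residence needs a naval leg
for a given facility kind iff it lies more than ``road_proximity_km``
(default 5 km) from the nearest road on its island, or its island hosts no
same-district facility of that kind.  Within-district restriction is a hard
filter (patients must use facilities of their own district); it can be
relaxed with ``cross_district=True``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
from shapely.geometry import LineString, Point
from shapely.strtree import STRtree

from .core import Facility, ResidenceCluster, StudyRegion

__all__ = [
    "RoadNetwork",
    "AccessLink",
    "LandRoute",
    "build_road_graph",
    "nearest_road_distance",
    "classify_access",
    "shortest_land_distance",
    "closest_facility_land",
    "LandRouter",
    "DEFAULT_ROAD_PROXIMITY_KM",
    "DEFAULT_SNAP_TOLERANCE_KM",
]

DEFAULT_ROAD_PROXIMITY_KM = 5.0
DEFAULT_SNAP_TOLERANCE_KM = 0.001


@dataclass(frozen=True)
class AccessLink:
    """Perpendicular link from an off-road point to its attachment node."""

    point_id: str
    node: int
    link_km: float


@dataclass(frozen=True)
class LandRoute:
    """A land-only residence→facility route (segment A or B)."""

    residence_id: str
    facility_id: str
    facility_kind: str
    distance_km: float


def _snap_vertices(
    coords: list[tuple[float, float]], tol: float
) -> dict[tuple[float, float], tuple[float, float]]:
    """Cluster vertices closer than ``tol`` (union-find on a grid hash)."""
    parent: dict[int, int] = {}

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    for i in range(len(coords)):
        parent[i] = i
    cell: dict[tuple[int, int], list[int]] = {}
    inv = 1.0 / tol if tol > 0 else 0.0
    for i, (x, y) in enumerate(coords):
        cell.setdefault((int(math.floor(x * inv)), int(math.floor(y * inv))), []).append(i)
    for i, (x, y) in enumerate(coords):
        cx, cy = int(math.floor(x * inv)), int(math.floor(y * inv))
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for j in cell.get((cx + dx, cy + dy), ()):
                    if j > i and math.dist(coords[i], coords[j]) <= tol:
                        union(i, j)
    return {coords[i]: coords[find(i)] for i in range(len(coords))}


class RoadNetwork:
    """Undirected road graph with Euclidean edge lengths (km).

    Nodes are integers carrying a ``pos`` attribute; edges carry ``length``.
    ``attach`` splits an edge in place, so build one instance per routing
    context.
    """

    def __init__(self, graph: nx.Graph):
        self.graph = graph
        self._pos = {n: d["pos"] for n, d in graph.nodes(data=True)}
        self._rebuild_edge_index()

    def _rebuild_edge_index(self) -> None:
        self._edges = list(self.graph.edges())
        self._edge_geoms = [
            LineString([self._pos[u], self._pos[v]]) for u, v in self._edges
        ]
        self._tree = STRtree(self._edge_geoms) if self._edge_geoms else None

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def node_point(self, node: int) -> Point:
        return Point(self._pos[node])

    def nearest_edge(
        self, point: Point, within=None
    ) -> tuple[tuple[int, int], Point, float]:
        """(edge, nearest point on edge, distance) for the closest edge.

        ``within`` optionally restricts candidates to edges intersecting a
        geometry (typically the entity's island, so coastal points never
        attach to a road across a sea gap); when no edge intersects it the
        restriction is dropped.
        """
        if self._tree is None:
            raise ValueError("empty road network")
        if within is not None:
            cand = [int(i) for i in self._tree.query(within)]
            cand = [i for i in cand if self._edge_geoms[i].intersects(within)]
        else:
            cand = []
        if cand:
            idx = min(cand, key=lambda i: self._edge_geoms[i].distance(point))
        else:
            idx = int(self._tree.nearest(point))
        geom = self._edge_geoms[idx]
        proj = geom.interpolate(geom.project(point))
        return self._edges[idx], proj, point.distance(proj)

    def attach(self, point: Point, within=None) -> tuple[int, float]:
        """Attach ``point`` to the network via its nearest edge.

        Returns ``(node_id, link_km)``.  If the projection falls on an
        existing node the node is reused; otherwise the edge is split at
        the projection point.  ``within`` restricts the candidate edges as
        in :meth:`nearest_edge`.
        """
        (u, v), proj, link = self.nearest_edge(point, within=within)
        for node in (u, v):
            if math.dist(self._pos[node], (proj.x, proj.y)) <= 1e-9:
                return node, link
        w = max(self.graph.nodes, default=-1) + 1
        pu, pv = self._pos[u], self._pos[v]
        self.graph.remove_edge(u, v)
        self.graph.add_node(w, pos=(proj.x, proj.y))
        self._pos[w] = (proj.x, proj.y)
        self.graph.add_edge(u, w, length=math.dist(pu, (proj.x, proj.y)))
        self.graph.add_edge(w, v, length=math.dist((proj.x, proj.y), pv))
        self._rebuild_edge_index()
        return w, link

    def shortest_path_length(self, u: int, v: int) -> float:
        return shortest_land_distance(self.graph, u, v)

    def shortest_path_lengths_from(self, source: int) -> dict[int, float]:
        return nx.single_source_dijkstra_path_length(self.graph, source, weight="length")


def build_road_graph(
    segments: list[LineString],
    snap_tolerance_km: float = DEFAULT_SNAP_TOLERANCE_KM,
) -> RoadNetwork:
    """Build a :class:`RoadNetwork` from road centerlines.

    Multi-vertex centerlines are exploded into straight edges; all vertices
    within ``snap_tolerance_km`` of each other are merged into one node.
    Zero-length edges (after merging) are dropped.
    """
    pieces: list[tuple[tuple[float, float], tuple[float, float]]] = []
    verts: list[tuple[float, float]] = []
    seen: set[tuple[float, float]] = set()
    for seg in segments:
        cs = list(seg.coords)
        for a, b in zip(cs, cs[1:]):
            a, b = (a[0], a[1]), (b[0], b[1])
            if a == b:
                continue
            pieces.append((a, b))
            for p in (a, b):
                if p not in seen:
                    seen.add(p)
                    verts.append(p)
    rep = _snap_vertices(verts, snap_tolerance_km)
    node_id: dict[tuple[float, float], int] = {}
    g = nx.Graph()
    for a, b in pieces:
        ra, rb = rep[a], rep[b]
        if ra == rb:
            continue  # collapsed by snapping
        for p in (ra, rb):
            if p not in node_id:
                node_id[p] = len(node_id)
                g.add_node(node_id[p], pos=p)
        length = math.dist(ra, rb)
        u, v = node_id[ra], node_id[rb]
        if g.has_edge(u, v):
            g[u][v]["length"] = min(g[u][v]["length"], length)
        else:
            g.add_edge(u, v, length=length)
    return RoadNetwork(g)


def nearest_road_distance(point: Point, roads: list[LineString]) -> float:
    """Minimum Euclidean distance from ``point`` to any road geometry.

    An empty road set yields ``+inf`` ("no road on this island").
    """
    if not roads:
        return math.inf
    return min(seg.distance(point) for seg in roads)


def classify_access(
    residence: ResidenceCluster,
    facility_kind: str,
    region: StudyRegion,
    road_proximity_km: float = DEFAULT_ROAD_PROXIMITY_KM,
) -> str:
    """``"land"`` or ``"land_naval"`` access class for one residence/kind.

    Naval access is needed iff the residence sits more than
    ``road_proximity_km`` from the nearest road *on its island*, or its
    island hosts no same-district facility of ``facility_kind``.
    """
    island = region.island_containing(residence.centroid)
    if island is None:
        raise ValueError(f"residence {residence.id} lies on no island")
    d_road = nearest_road_distance(residence.centroid, region.roads_on_island(island))
    if d_road > road_proximity_km:
        return "land_naval"
    has_kind = any(
        island.polygon.distance(f.location) <= 1e-9
        for f in region.facilities_in_district(residence.district_id, facility_kind)
    )
    return "land" if has_kind else "land_naval"


def shortest_land_distance(graph: nx.Graph, origin: int, dest: int) -> float:
    """Length of the shortest road path; ``+inf`` when disconnected."""
    try:
        return nx.dijkstra_path_length(graph, origin, dest, weight="length")
    except nx.NetworkXNoPath:
        return math.inf


class LandRouter:
    """Shared routing context: one road graph with all facilities attached.

    Residences are attached lazily; attachment nodes are cached by id so
    repeated queries stay cheap.
    """

    def __init__(
        self,
        region: StudyRegion,
        snap_tolerance_km: float = DEFAULT_SNAP_TOLERANCE_KM,
        cross_district: bool = False,
    ):
        self.region = region
        self.cross_district = cross_district
        self.network = build_road_graph(region.roads, snap_tolerance_km)
        self._facility_links: dict[str, AccessLink] = {}
        for f in region.facilities:
            node, link = self.network.attach(f.location, within=self._island_of(f.location))
            self._facility_links[f.id] = AccessLink(f.id, node, link)
        self._residence_links: dict[str, AccessLink] = {}

    def _island_of(self, point: Point):
        isl = self.region.island_containing(point)
        return None if isl is None else isl.polygon

    def facility_link(self, facility: Facility) -> AccessLink:
        return self._facility_links[facility.id]

    def residence_link(self, residence: ResidenceCluster) -> AccessLink:
        if residence.id not in self._residence_links:
            node, link = self.network.attach(
                residence.centroid, within=self._island_of(residence.centroid)
            )
            self._residence_links[residence.id] = AccessLink(residence.id, node, link)
        return self._residence_links[residence.id]

    def point_to_facility_km(self, point: Point, facility: Facility) -> float:
        """Access-link + road distance from an arbitrary point to a facility.

        The point attaches to roads on the facility's island (it is a hub
        on that island's coast)."""
        node, link = self.network.attach(point, within=self._island_of(facility.location))
        flink = self._facility_links[facility.id]
        return link + self.network.shortest_path_length(node, flink.node) + flink.link_km

    def eligible_facilities(self, residence: ResidenceCluster, kind: str) -> list[Facility]:
        if self.cross_district:
            return [f for f in self.region.facilities if f.kind == kind]
        return self.region.facilities_in_district(residence.district_id, kind)

    def route(self, residence: ResidenceCluster, facility_kind: str) -> LandRoute:
        """District-restricted closest facility by road (segments A/B).

        Ties on distance break toward the smallest facility id.
        """
        candidates = self.eligible_facilities(residence, facility_kind)
        if not candidates:
            raise ValueError(
                f"no eligible facility: residence {residence.id} has no "
                f"{facility_kind} in district {residence.district_id}"
            )
        rlink = self.residence_link(residence)
        dists = self.network.shortest_path_lengths_from(rlink.node)
        best: tuple[float, str] | None = None
        best_fac: Facility | None = None
        for f in sorted(candidates, key=lambda f: f.id):
            flink = self._facility_links[f.id]
            total = rlink.link_km + dists.get(flink.node, math.inf) + flink.link_km
            if best is None or total < best[0] - 1e-12:
                best = (total, f.id)
                best_fac = f
        assert best is not None and best_fac is not None
        if math.isinf(best[0]):
            raise ValueError(
                f"residence {residence.id}: no road path to any "
                f"{facility_kind} in district {residence.district_id}"
            )
        return LandRoute(residence.id, best_fac.id, facility_kind, best[0])


def closest_facility_land(
    residence: ResidenceCluster,
    facility_kind: str,
    region: StudyRegion,
    snap_tolerance_km: float = DEFAULT_SNAP_TOLERANCE_KM,
) -> LandRoute:
    """One-shot convenience wrapper around :class:`LandRouter`."""
    return LandRouter(region, snap_tolerance_km).route(residence, facility_kind)
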