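"""Road-graph construction, classification and closest-facility routing."""

import itertools
import math

import networkx as nx
import numpy as np
import pytest
from shapely.geometry import LineString, Point, box

from archaccess import (
    Facility,
    ResidenceCluster,
    build_road_graph,
    classify_access,
    closest_facility_land,
    nearest_road_distance,
    shortest_land_distance,
)
from archaccess.landroute import LandRouter
from archaccess.synthetic import TOY_EXPECTED


class TestBuildRoadGraph:
    def test_shared_endpoint(self):
        net = build_road_graph([LineString([(0, 0), (1, 0)]), LineString([(1, 0), (2, 0)])])
        assert (net.n_nodes, net.n_edges) == (3, 2)

    def test_tolerance_merge(self):
        net = build_road_graph(
            [LineString([(0, 0), (1, 0)]), LineString([(1.0005, 0), (2, 0)])],
            snap_tolerance_km=0.001,
        )
        assert (net.n_nodes, net.n_edges) == (3, 2)

    def test_below_tolerance_not_merged(self):
        net = build_road_graph(
            [LineString([(0, 0), (1, 0)]), LineString([(1.005, 0), (2, 0)])],
            snap_tolerance_km=0.001,
        )
        assert net.n_nodes == 4

    def test_random_soup_matches_union_find_oracle(self, rng):
        """Node count equals a brute-force union-find over endpoint pairs."""
        tol = 0.05
        segs = []
        pts = rng.uniform(0, 10, size=(40, 2))
        for i in range(0, 40, 2):
            a, b = pts[i], pts[i + 1]
            if math.dist(a, b) > 1e-6:
                segs.append(LineString([tuple(a), tuple(b)]))
        net = build_road_graph(segs, snap_tolerance_km=tol)

        # oracle: union endpoints pairwise by distance, count classes/edges
        endpoints = [tuple(c) for s in segs for c in (s.coords[0], s.coords[-1])]
        parent = list(range(len(endpoints)))

        def find(i):
            while parent[i] != i:
                i = parent[i]
            return i

        for i, j in itertools.combinations(range(len(endpoints)), 2):
            if math.dist(endpoints[i], endpoints[j]) <= tol:
                parent[find(j)] = find(i)
        classes = {find(i) for i in range(len(endpoints))}
        edges = {
            tuple(sorted((find(2 * k), find(2 * k + 1))))
            for k in range(len(segs))
            if find(2 * k) != find(2 * k + 1)
        }
        assert net.n_nodes == len(classes)
        assert net.n_edges == len(edges)


class TestNearestRoadDistance:
    def test_point_on_road(self):
        assert nearest_road_distance(Point(0.5, 0), [LineString([(0, 0), (1, 0)])]) == 0.0

    def test_perpendicular_distance(self):
        assert nearest_road_distance(Point(0, 6), [LineString([(-5, 0), (5, 0)])]) == pytest.approx(6.0)

    def test_empty_roads_is_infinite(self):
        assert nearest_road_distance(Point(0, 0), []) == math.inf

    def test_brute_force_oracle(self, rng):
        """Matches an exhaustive per-segment minimum over 100 segments."""
        from archaccess.core import point_segment_distance

        segs = []
        coords = rng.uniform(0, 50, size=(100, 4))
        for x1, y1, x2, y2 in coords:
            segs.append(LineString([(x1, y1), (x2, y2)]))
        for _ in range(20):
            p = rng.uniform(0, 50, size=2)
            expected = min(
                point_segment_distance(p[0], p[1], x1, y1, x2, y2)
                for x1, y1, x2, y2 in coords
            )
            assert nearest_road_distance(Point(*p), segs) == pytest.approx(expected)


class TestClassifyAccess:
    def test_far_from_road_needs_naval(self, toy):
        """A residence over 5 km from its island's roads is naval-class."""
        # R2's island (I2) has no roads at all: distance is infinite
        r2 = next(r for r in toy.residences if r.id == "R2")
        assert classify_access(r2, "puskesmas", toy) == "land_naval"

    def test_island_with_facility_is_land(self, toy):
        r1 = next(r for r in toy.residences if r.id == "R1")
        assert classify_access(r1, "puskesmas", toy) == "land"

    def test_island_without_hospital_needs_naval(self, toy):
        """Near a road, puskesmas on the island, but no hospital: the
        hospital journey still needs a naval leg."""
        r4 = next(r for r in toy.residences if r.id == "R4")
        assert classify_access(r4, "puskesmas", toy) == "land"
        assert classify_access(r4, "hospital", toy) == "land_naval"

    def test_threshold_exactly_five_km(self, toy):
        # 4 km from the road: land; pushing the threshold under 4: naval
        r3 = next(r for r in toy.residences if r.id == "R3")
        assert classify_access(r3, "puskesmas", toy, road_proximity_km=5.0) == "land"
        assert classify_access(r3, "puskesmas", toy, road_proximity_km=3.9) == "land_naval"


class TestShortestLandDistance:
    def test_chain(self):
        g = nx.Graph()
        g.add_edge("a", "b", length=2.0)
        g.add_edge("b", "c", length=3.0)
        assert shortest_land_distance(g, "a", "c") == pytest.approx(5.0)

    def test_triangle_shortcut(self):
        g = nx.Graph()
        g.add_edge("a", "b", length=1.0)
        g.add_edge("b", "c", length=1.0)
        g.add_edge("a", "c", length=3.0)
        assert shortest_land_distance(g, "a", "c") == pytest.approx(2.0)

    def test_disconnected_is_infinite(self):
        g = nx.Graph()
        g.add_edge("a", "b", length=1.0)
        g.add_node("z")
        assert shortest_land_distance(g, "a", "z") == math.inf

    def test_floyd_warshall_oracle(self, rng):
        """Dijkstra distances equal an all-pairs dynamic-programming oracle."""
        n = 50
        g = nx.gnm_random_graph(n, 120, seed=4)
        for u, v in g.edges:
            g[u][v]["length"] = float(rng.uniform(0.1, 10.0))
        dist = dict(nx.floyd_warshall(g, weight="length"))
        for _ in range(20):
            u, v = rng.integers(0, n, size=2)
            expected = dist[int(u)][int(v)]
            assert shortest_land_distance(g, int(u), int(v)) == pytest.approx(expected)

    def test_metric_properties(self, rng):
        g = nx.gnm_random_graph(25, 60, seed=9)
        for u, v in g.edges:
            g[u][v]["length"] = float(rng.uniform(0.1, 5.0))
        nodes = list(g.nodes)
        for _ in range(15):
            u, v, w = rng.choice(nodes, size=3)
            duv = shortest_land_distance(g, int(u), int(v))
            assert duv == pytest.approx(shortest_land_distance(g, int(v), int(u)))
            duw = shortest_land_distance(g, int(u), int(w))
            dvw = shortest_land_distance(g, int(v), int(w))
            if all(map(math.isfinite, (duv, duw, dvw))):
                assert duw <= duv + dvw + 1e-9

    def test_adding_edge_never_increases_distance(self, rng):
        g = nx.path_graph(12)
        for u, v in g.edges:
            g[u][v]["length"] = 1.0
        before = {
            (u, v): shortest_land_distance(g, u, v)
            for u in g.nodes
            for v in g.nodes
        }
        g.add_edge(0, 11, length=float(rng.uniform(0.1, 20.0)))
        for (u, v), d in before.items():
            assert shortest_land_distance(g, u, v) <= d + 1e-9


class TestClosestFacilityLand:
    def test_toy_documented_routes(self, toy):
        r1 = next(r for r in toy.residences if r.id == "R1")
        route = closest_facility_land(r1, "puskesmas", toy)
        assert route.facility_id == "P1"
        assert route.distance_km == pytest.approx(TOY_EXPECTED["R1"]["puskesmas_land"])
        route_h = closest_facility_land(r1, "hospital", toy)
        assert route_h.facility_id == "H1"
        assert route_h.distance_km == pytest.approx(TOY_EXPECTED["R1"]["hospital_land"])

    def test_coincident_residence_and_facility(self, toy):
        r = ResidenceCluster.from_polygon("RX", "alpha", box(9.5, 4.5, 10.5, 5.5))
        # centroid (10, 5) sits exactly on puskesmas P1's road node
        route = closest_facility_land(r, "puskesmas", toy)
        assert route.facility_id == "P1"
        assert route.distance_km == pytest.approx(0.0, abs=1e-9)

    def test_equidistant_tie_breaks_to_smallest_id(self, toy):
        import dataclasses

        region = dataclasses.replace(toy)
        # second puskesmas mirrored so R1 is exactly between the two
        region.facilities = toy.facilities + [
            Facility("P9", "puskesmas", "alpha", Point(10, 5))
        ]
        r1 = next(r for r in region.residences if r.id == "R1")
        route = closest_facility_land(r1, "puskesmas", region)
        assert route.facility_id == "P1"

    def test_no_eligible_facility_raises(self, toy):
        r4 = next(r for r in toy.residences if r.id == "R4")
        with pytest.raises(ValueError, match="no eligible facility"):
            closest_facility_land(r4, "hospital", toy)

    def test_closest_beats_every_alternative(self, toy):
        """Exhaustive check of the minimiser over all eligible facilities."""
        router = LandRouter(toy)
        r3 = next(r for r in toy.residences if r.id == "R3")
        route = router.route(r3, "puskesmas")
        rlink = router.residence_link(r3)
        for f in toy.facilities_in_district("alpha", "puskesmas"):
            flink = router.facility_link(f)
            alt = (
                rlink.link_km
                + router.network.shortest_path_length(rlink.node, flink.node)
                + flink.link_km
            )
            assert route.distance_km <= alt + 1e-9
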