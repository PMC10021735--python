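"""Domain model for archipelagic healthcare-accessibility analysis.

All coordinates are planar, in kilometres, in an arbitrary projected frame
(inputs are assumed to be already projected; geodetic computation is out of
scope).  Polygons are single exterior rings without holes; multi-part land
masses are modelled as multiple :class:`Island` records.

The container type :class:`StudyRegion` bundles the six entity classes the
pipeline consumes: administrative districts with census totals, island
polygons, residential clusters, road centerlines, water-access points
(ports, docks, beaches) and health facilities (puskesmas — Indonesian
primary health centres — and hospitals) with essential-staff counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from shapely.geometry import LineString, Point, Polygon
from shapely.strtree import STRtree

__all__ = [
    "District",
    "Island",
    "ResidenceCluster",
    "WaterAccessPoint",
    "Facility",
    "StudyRegion",
    "Violation",
    "validate_region",
    "polygon_area",
    "centroid",
    "WAP_KINDS",
    "FACILITY_KINDS",
    "COAST_TOLERANCE_KM",
]

#: Allowed water-access-point kinds.  Beaches are departure points only;
#: ports and docks may additionally serve as facility hubs.
WAP_KINDS = ("port", "dock", "beach")

#: Allowed facility kinds.
FACILITY_KINDS = ("puskesmas", "hospital")

#: A water-access point must sit on an island boundary or within this
#: distance of one (0.5 km).
COAST_TOLERANCE_KM = 0.5

#: Geometric slack for "lies on an island" point-in-polygon tests, to
#: absorb floating-point jitter from centroid computation and generators.
_ON_ISLAND_EPS = 1e-9


def polygon_area(polygon: Polygon) -> float:
    """Planar (shoelace) area of a simple polygon, in km².

    Raises
    ------
    ValueError
        If the polygon is self-intersecting or otherwise invalid.
    """
    if not polygon.is_valid:
        raise ValueError("invalid (self-intersecting?) polygon")
    return polygon.area


def centroid(polygon: Polygon) -> Point:
    """Area centroid of a simple polygon with positive area.

    Raises
    ------
    ValueError
        If the polygon is invalid or degenerate (zero area).
    """
    if not polygon.is_valid:
        raise ValueError("invalid (self-intersecting?) polygon")
    if polygon.area == 0.0:
        raise ValueError("degenerate polygon with zero area")
    return polygon.centroid


@dataclass(frozen=True)
class District:
    id: str
    name: str
    polygon: Polygon
    total_population: int


@dataclass(frozen=True)
class Island:
    id: str
    polygon: Polygon


@dataclass(frozen=True)
class ResidenceCluster:
    """A residential polygon with its area centroid and allocated population.

    ``population`` starts at 0 and is filled in by dasymetric allocation of
    the district census total proportional to polygon area.
    """

    id: str
    district_id: str
    polygon: Polygon
    centroid: Point
    population: float = 0.0

    @classmethod
    def from_polygon(
        cls,
        id: str,
        district_id: str,
        polygon: Polygon,
        population: float = 0.0,
    ) -> "ResidenceCluster":
        return cls(id, district_id, polygon, centroid(polygon), population)

    def with_population(self, population: float) -> "ResidenceCluster":
        return ResidenceCluster(
            self.id, self.district_id, self.polygon, self.centroid, population
        )

    @property
    def area_km2(self) -> float:
        return polygon_area(self.polygon)


@dataclass(frozen=True)
class WaterAccessPoint:
    id: str
    kind: str  # port | dock | beach
    location: Point


@dataclass(frozen=True)
class Facility:
    id: str
    kind: str  # puskesmas | hospital
    district_id: str
    location: Point
    physicians: int = 0
    nurses: int = 0
    midwives: int = 0


@dataclass
class StudyRegion:
    """All input entities of one study region plus cached spatial lookups."""

    districts: list[District] = field(default_factory=list)
    islands: list[Island] = field(default_factory=list)
    residences: list[ResidenceCluster] = field(default_factory=list)
    roads: list[LineString] = field(default_factory=list)
    water_access_points: list[WaterAccessPoint] = field(default_factory=list)
    facilities: list[Facility] = field(default_factory=list)

    # ---- lookups -----------------------------------------------------

    def __post_init__(self) -> None:
        self._island_tree: STRtree | None = None

    def district_by_id(self, district_id: str) -> District:
        for d in self.districts:
            if d.id == district_id:
                return d
        raise KeyError(f"unknown district {district_id!r}")

    def island_containing(self, point: Point) -> Island | None:
        """The island whose polygon covers ``point`` (boundary counts), or None."""
        if self._island_tree is None:
            self._island_tree = STRtree([isl.polygon for isl in self.islands])
        if not self.islands:
            return None
        for idx in self._island_tree.query(point.buffer(_ON_ISLAND_EPS)):
            isl = self.islands[int(idx)]
            if isl.polygon.distance(point) <= _ON_ISLAND_EPS:
                return isl
        return None

    def residences_in_district(self, district_id: str) -> list[ResidenceCluster]:
        return [r for r in self.residences if r.district_id == district_id]

    def facilities_in_district(
        self, district_id: str, kind: str | None = None
    ) -> list[Facility]:
        return [
            f
            for f in self.facilities
            if f.district_id == district_id and (kind is None or f.kind == kind)
        ]

    def waps_on_island(
        self, island: Island, kinds: tuple[str, ...] = WAP_KINDS
    ) -> list[WaterAccessPoint]:
        out = []
        for w in self.water_access_points:
            if w.kind not in kinds:
                continue
            if island.polygon.distance(w.location) <= COAST_TOLERANCE_KM:
                out.append(w)
        return out

    def roads_on_island(self, island: Island) -> list[LineString]:
        """Road geometries intersecting the island polygon."""
        return [seg for seg in self.roads if seg.intersects(island.polygon)]

    def with_residences(self, residences: list[ResidenceCluster]) -> "StudyRegion":
        return StudyRegion(
            districts=self.districts,
            islands=self.islands,
            residences=residences,
            roads=self.roads,
            water_access_points=self.water_access_points,
            facilities=self.facilities,
        )


@dataclass(frozen=True)
class Violation:
    """One invariant violation found by :func:`validate_region`."""

    entity: str
    rule: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.entity}: {self.rule}"


def validate_region(region: StudyRegion) -> list[Violation]:
    """Check every domain invariant; return a (possibly empty) violation list.

    Violations are reported, never raised, so a caller can audit a whole
    data set in one pass.
    """
    out: list[Violation] = []
    district_ids = [d.id for d in region.districts]
    seen: set[str] = set()
    for d in region.districts:
        if d.id in seen:
            out.append(Violation(f"district:{d.id}", "duplicate district id"))
        seen.add(d.id)
        if not d.polygon.is_valid:
            out.append(Violation(f"district:{d.id}", "polygon is not simple"))
        if d.total_population < 0:
            out.append(Violation(f"district:{d.id}", "negative population"))

    for isl in region.islands:
        if not isl.polygon.is_valid:
            out.append(Violation(f"island:{isl.id}", "polygon is not simple"))
    # pairwise disjoint interiors; STRtree keeps this near-linear
    tree = STRtree([isl.polygon for isl in region.islands])
    for i, isl in enumerate(region.islands):
        for j in tree.query(isl.polygon.buffer(-1e-12)):
            j = int(j)
            if j <= i:
                continue
            other = region.islands[j]
            inter = isl.polygon.intersection(other.polygon)
            if inter.area > 1e-12:
                out.append(
                    Violation(
                        f"island:{isl.id}",
                        f"interior overlaps island {other.id}",
                    )
                )

    dset = set(district_ids)
    for r in region.residences:
        if r.district_id not in dset:
            out.append(
                Violation(f"residence:{r.id}", f"unknown district_id {r.district_id!r}")
            )
        if r.population < 0:
            out.append(Violation(f"residence:{r.id}", "negative population"))
        if not r.polygon.is_valid:
            out.append(Violation(f"residence:{r.id}", "polygon is not simple"))
        else:
            true_c = r.polygon.centroid
            if true_c.distance(r.centroid) > 1e-6:
                out.append(
                    Violation(f"residence:{r.id}", "centroid is not the area centroid")
                )
        if region.island_containing(r.centroid) is None:
            out.append(Violation(f"residence:{r.id}", "centroid lies on no island"))

    for seg in region.roads:
        if seg.length <= 0:
            out.append(Violation("road", "zero-length road segment"))

    for w in region.water_access_points:
        if w.kind not in WAP_KINDS:
            out.append(Violation(f"wap:{w.id}", f"unknown kind {w.kind!r}"))
        if region.islands:
            dmin = min(isl.polygon.boundary.distance(w.location) for isl in region.islands)
            if dmin > COAST_TOLERANCE_KM:
                out.append(
                    Violation(
                        f"wap:{w.id}",
                        f"{dmin:.3f} km from the nearest island boundary "
                        f"(limit {COAST_TOLERANCE_KM} km)",
                    )
                )

    for f in region.facilities:
        if f.kind not in FACILITY_KINDS:
            out.append(Violation(f"facility:{f.id}", f"unknown kind {f.kind!r}"))
        if f.district_id not in dset:
            out.append(
                Violation(f"facility:{f.id}", f"unknown district_id {f.district_id!r}")
            )
        for attr in ("physicians", "nurses", "midwives"):
            if getattr(f, attr) < 0:
                out.append(Violation(f"facility:{f.id}", f"negative {attr} count"))
        if region.island_containing(f.location) is None:
            out.append(Violation(f"facility:{f.id}", "location lies on no island"))

    return out


def point_segment_distance(px: float, py: float, ax: float, ay: float, bx: float, by: float) -> float:
    """Euclidean distance from point (px,py) to segment (ax,ay)-(bx,by)."""
    vx, vy = bx - ax, by - ay
    wx, wy = px - ax, py - ay
    seg2 = vx * vx + vy * vy
    if seg2 == 0.0:
        return math.hypot(wx, wy)
    t = max(0.0, min(1.0, (wx * vx + wy * vy) / seg2))
    return math.hypot(px - (ax + t * vx), py - (ay + t * vy))
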