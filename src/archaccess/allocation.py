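"""Dasymetric (area-proportional) allocation of district census totals.

Each district's census total is split across its residential clusters in
proportion to cluster polygon area:

    population_i = total * area_i / sum_j area_j

Allocations are kept as reals; rounding to whole persons would break exact
conservation of the district total and is left to presentation layers.
"""

from __future__ import annotations

from .core import District, ResidenceCluster

__all__ = ["allocate_population", "allocate_region"]


def allocate_population(
    district: District, clusters: list[ResidenceCluster]
) -> dict[str, float]:
    """Area-proportional share of ``district.total_population`` per cluster.

    Returns a mapping cluster id -> allocated population (real-valued).

    Raises
    ------
    ValueError
        If no clusters are given, a cluster belongs to another district,
        or the total cluster area is zero.
    """
    if not clusters:
        raise ValueError(f"district {district.id}: no residence clusters")
    for c in clusters:
        if c.district_id != district.id:
            raise ValueError(
                f"cluster {c.id} belongs to district {c.district_id}, "
                f"not {district.id}"
            )
    areas = [c.area_km2 for c in clusters]
    total_area = sum(areas)
    if total_area <= 0.0:
        raise ValueError(f"district {district.id}: zero total cluster area")
    return {
        c.id: district.total_population * a / total_area
        for c, a in zip(clusters, areas)
    }


def allocate_region(region) -> "object":
    """Return a copy of ``region`` with populations allocated in every district."""
    alloc: dict[str, float] = {}
    for d in region.districts:
        clusters = region.residences_in_district(d.id)
        if clusters:
            alloc.update(allocate_population(d, clusters))
    residences = [
        r.with_population(alloc.get(r.id, r.population)) for r in region.residences
    ]
    return region.with_residences(residences)
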