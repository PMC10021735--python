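"""Two-step floating catchment area (2SFCA) comparator.

Plain 2SFCA with a fixed-radius Euclidean buffer (default 10 km) and no
distance decay:

* step 1 — each facility j gets a supply ratio
  ``R_j = supply_j / sum(population_i : d(i, j) <= radius)``;
* step 2 — each residence i gets
  ``accessibility_i = sum(R_j : d(i, j) <= radius)``.

Supply is the weighted workforce by default (physicians 2.92, midwives
1.17, nurses 1.00) or a flat facility count of 1 with ``supply="counts"``.
Residences inside no buffer are flagged ``in_range=False`` and their
accessibility is undefined (NaN), not zero — outside the buffers the
method has no information.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

from .core import StudyRegion
from .equity import facility_mu

__all__ = ["FcaScore", "two_step_fca", "DEFAULT_FCA_RADIUS_KM"]

DEFAULT_FCA_RADIUS_KM = 10.0


@dataclass(frozen=True)
class FcaScore:
    residence_id: str
    accessibility: float  # NaN when not in range of any facility
    in_range: bool


def two_step_fca(
    region: StudyRegion,
    facility_kind: str,
    radius_km: float = DEFAULT_FCA_RADIUS_KM,
    supply: str = "workforce",
    weights: tuple[float, float, float] | None = None,
) -> dict[str, FcaScore]:
    """2SFCA accessibility per residence for one facility kind.

    Buffer membership is centroid-in-circle (Euclidean).  Facilities with
    an empty catchment are excluded with a warning (their supply reaches
    nobody).  Returns residence id -> :class:`FcaScore`.
    """
    if radius_km <= 0:
        raise ValueError("radius must be positive")
    if supply not in ("workforce", "counts"):
        raise ValueError("supply must be 'workforce' or 'counts'")
    facilities = [f for f in region.facilities if f.kind == facility_kind]
    if not facilities:
        raise ValueError(f"no {facility_kind} in region")

    ratios: dict[str, float] = {}
    for f in facilities:
        demand = sum(
            r.population
            for r in region.residences
            if r.centroid.distance(f.location) <= radius_km
        )
        if demand <= 0:
            warnings.warn(f"facility {f.id}: empty catchment, excluded")
            continue
        supply_j = facility_mu(f, weights) if supply == "workforce" else 1.0
        ratios[f.id] = supply_j / demand

    out: dict[str, FcaScore] = {}
    for r in region.residences:
        in_range = [
            f for f in facilities if r.centroid.distance(f.location) <= radius_km
        ]
        if not in_range:
            out[r.id] = FcaScore(r.id, math.nan, False)
        else:
            acc = sum(ratios.get(f.id, 0.0) for f in in_range)
            out[r.id] = FcaScore(r.id, acc, True)
    return out
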