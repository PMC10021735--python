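"""District-level accessibility statistics.

Routes are decomposed into the eight segment types used throughout the
reporting layer:

====== ==========================================================
letter leg
====== ==========================================================
A      residence → puskesmas, land only
B      residence → hospital, land only
C / D  residence → nearest water-access point (puskesmas / hospital bound)
E / F  water-access point → facility hub, over water
G / H  facility hub → facility (puskesmas / hospital)
====== ==========================================================

Per district the module produces descriptive segment statistics
(N/mean/SE/median/min/max), the access-class proportions ``c``/``e`` (share
of population reaching puskesmas/hospital by land; ``c_nav``/``e_nav`` are
the complements), the four route-type mean distances ``d``/``f`` (land) and
``d_nav``/``f_nav`` (land+naval), and the population-weighted total-distance
score

    z = c·d + c_nav·d_nav + e·f + e_nav·f_nav

with absent route types contributing zero.  Access proportions are
population-weighted; route-type means are unweighted over residential
centroids by default (each centroid one observation, matching segment
counts), with an optional population-weighted mode.

Mean separation across districts uses pairwise two-sample equal-variance
t-tests summarised as a compact letter display: groups ordered by
descending mean, "A" for the highest; groups sharing a letter are not
significantly different at the chosen alpha.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .landroute import LandRoute
from .navalroute import NavalRoute
from .util import round_half_up

__all__ = [
    "SegmentStats",
    "DistrictSummary",
    "RouteSet",
    "segment_stats",
    "district_mean_distances",
    "access_proportions",
    "weighted_total_distance",
    "all_routes_mean",
    "province_aggregate",
    "letter_groups",
    "SEGMENT_LETTERS",
]

SEGMENT_LETTERS = ("A", "B", "C", "D", "E", "F", "G", "H")


@dataclass(frozen=True)
class SegmentStats:
    district_id: str
    segment: str
    n: int
    mean: float
    standard_error: float | None
    median: float
    min: float
    max: float


@dataclass
class DistrictSummary:
    """Route-type proportions, mean distances and the z score of one district.

    ``None`` distance fields mean "no routes of that type" (printed as "-").
    """

    district_id: str
    c: float = 0.0
    c_nav: float = 0.0
    e: float = 0.0
    e_nav: float = 0.0
    d: float | None = None
    d_nav: float | None = None
    f_: float | None = None
    f_nav: float | None = None
    n_land_puskesmas: float = 0.0
    n_naval_puskesmas: float = 0.0
    n_land_hospital: float = 0.0
    n_naval_hospital: float = 0.0

    @property
    def z(self) -> float:
        return weighted_total_distance(self)

    @property
    def all_routes_mean(self) -> float:
        return all_routes_mean([self.d, self.f_, self.d_nav, self.f_nav])


@dataclass
class RouteSet:
    """All computed routes of a region, keyed for aggregation.

    ``land[(residence_id, kind)]`` holds a :class:`LandRoute`;
    ``naval[(residence_id, kind)]`` a :class:`NavalRoute`;
    ``unreachable`` lists (residence_id, kind) pairs whose district offers
    no facility of that kind (their population still counts in the naval
    access class).
    """

    land: dict[tuple[str, str], LandRoute]
    naval: dict[tuple[str, str], NavalRoute]
    unreachable: list[tuple[str, str]]

    def segment_legs(self, region) -> pd.DataFrame:
        """Long-form table: district_id, residence_id, segment, km."""
        rows = []
        rdist = {r.id: r.district_id for r in region.residences}
        for (rid, kind), route in self.land.items():
            label = "A" if kind == "puskesmas" else "B"
            rows.append((rdist[rid], rid, label, route.distance_km))
        for (rid, kind), route in self.naval.items():
            la, lw, lg = route.segment_labels
            d = rdist[rid]
            rows.append((d, rid, la, route.leg_residence_to_wap))
            rows.append((d, rid, lw, route.leg_water))
            rows.append((d, rid, lg, route.leg_dock_to_facility))
        return pd.DataFrame(rows, columns=["district_id", "residence_id", "segment", "km"])


def segment_stats(legs: pd.DataFrame, district_id: str) -> list[SegmentStats]:
    """Descriptive statistics of each segment letter present in a district.

    ``legs`` is the long-form table from :meth:`RouteSet.segment_legs`.
    The standard error is the sample standard deviation over √N, omitted
    when N = 1.
    """
    sub = legs[legs["district_id"] == district_id]
    if sub.empty:
        raise ValueError(f"no routes in district {district_id}")
    out = []
    for seg in SEGMENT_LETTERS:
        vals = sub.loc[sub["segment"] == seg, "km"].to_numpy(dtype=float)
        if vals.size == 0:
            continue
        se = float(np.std(vals, ddof=1) / math.sqrt(vals.size)) if vals.size > 1 else None
        out.append(
            SegmentStats(
                district_id=district_id,
                segment=seg,
                n=int(vals.size),
                mean=float(np.mean(vals)),
                standard_error=se,
                median=float(np.median(vals)),
                min=float(np.min(vals)),
                max=float(np.max(vals)),
            )
        )
    return out


def _mean(pairs: list[tuple[float, float]], weighted: bool) -> float | None:
    """Mean of (value, weight) pairs; unweighted ignores the weights."""
    if not pairs:
        return None
    if weighted:
        tw = sum(w for _, w in pairs)
        if tw == 0:
            return float(np.mean([v for v, _ in pairs]))
        return sum(v * w for v, w in pairs) / tw
    return float(np.mean([v for v, _ in pairs]))


def district_mean_distances(
    routes: RouteSet,
    region,
    district_id: str,
    population_weighted: bool = False,
) -> dict[str, float | None]:
    """The four route-type mean distances of one district.

    Keys: ``puskesmas_land``, ``hospital_land``, ``puskesmas_naval``,
    ``hospital_naval`` (naval values are land+naval totals).  A route type
    with no members maps to ``None`` (a "-" cell).
    """
    pops = {r.id: r.population for r in region.residences}
    ids = {r.id for r in region.residences_in_district(district_id)}
    buckets: dict[str, list[tuple[float, float]]] = {
        "puskesmas_land": [],
        "hospital_land": [],
        "puskesmas_naval": [],
        "hospital_naval": [],
    }
    for (rid, kind), route in routes.land.items():
        if rid in ids:
            buckets[f"{kind}_land"].append((route.distance_km, pops[rid]))
    for (rid, kind), route in routes.naval.items():
        if rid in ids:
            buckets[f"{kind}_naval"].append((route.total_km, pops[rid]))
    return {k: _mean(v, population_weighted) for k, v in buckets.items()}


def access_proportions(
    region,
    classifications: dict[tuple[str, str], str],
    district_id: str,
) -> dict[str, float]:
    """Population-weighted access-class shares and head-counts.

    ``classifications`` maps (residence_id, kind) -> "land" | "land_naval".
    Returns c, c_nav, e, e_nav (fractions summing to 1 per kind) and the
    corresponding population head-counts.
    """
    res = region.residences_in_district(district_id)
    total = sum(r.population for r in res)
    heads = {"puskesmas_land": 0.0, "puskesmas_naval": 0.0, "hospital_land": 0.0, "hospital_naval": 0.0}
    for r in res:
        for kind in ("puskesmas", "hospital"):
            cls = classifications[(r.id, kind)]
            key = f"{kind}_{'land' if cls == 'land' else 'naval'}"
            heads[key] += r.population
    if total == 0:
        return {"c": 0.0, "c_nav": 0.0, "e": 0.0, "e_nav": 0.0, **heads, "population": 0.0}
    c = heads["puskesmas_land"] / total
    e = heads["hospital_land"] / total
    # naval shares as exact complements so c + c_nav == 1 holds to the bit
    return {
        "c": c,
        "c_nav": 1.0 - c,
        "e": e,
        "e_nav": 1.0 - e,
        **heads,
        "population": total,
    }


def weighted_total_distance(summary: DistrictSummary) -> float:
    """The population-weighted total-distance score

        z = c·d + c_nav·d_nav + e·f + e_nav·f_nav

    with fractions in [0, 1] and absent route-type means contributing 0.
    """
    terms = (
        (summary.c, summary.d),
        (summary.c_nav, summary.d_nav),
        (summary.e, summary.f_),
        (summary.e_nav, summary.f_nav),
    )
    return sum(frac * dist for frac, dist in terms if dist is not None)


def all_routes_mean(route_type_means: list[float | None]) -> float:
    """Unweighted mean of the route-type means that are present."""
    present = [m for m in route_type_means if m is not None]
    if not present:
        raise ValueError("no route-type means present")
    return float(np.mean(present))


def province_aggregate(values: list[float | None], report: bool = False) -> float:
    """Province-level value: unweighted mean over districts with data.

    With ``report=True`` the result is rounded half-up to 2 decimals, the
    convention of the reporting layer.
    """
    present = [v for v in values if v is not None]
    if not present:
        raise ValueError("no district values present")
    m = float(np.mean(present))
    return round_half_up(m, 2) if report else m


def letter_groups(
    samples: dict[str, "np.ndarray"],
    alpha: float = 0.05,
) -> dict[str, str]:
    """Compact letter display from pairwise equal-variance t-tests.

    Groups are ordered by descending mean ("A" marks the highest mean);
    two groups share a letter iff their means are *not* significantly
    different at ``alpha``.  Letters are built with the insert-and-absorb
    algorithm.  Groups with fewer than 2 observations are excluded with a
    warning.

    Returns a mapping group name -> letter string (e.g. ``"AB"``).
    """
    usable = {}
    for name, vals in samples.items():
        vals = np.asarray(vals, dtype=float)
        if vals.size < 2:
            warnings.warn(f"group {name!r} has <2 observations; excluded")
            continue
        usable[name] = vals
    if len(usable) < 2:
        raise ValueError("need at least 2 groups with >=2 observations")

    names = sorted(usable, key=lambda n: -float(np.mean(usable[n])))
    k = len(names)
    differs = np.zeros((k, k), dtype=bool)
    for i in range(k):
        for j in range(i + 1, k):
            _, p = stats.ttest_ind(usable[names[i]], usable[names[j]], equal_var=True)
            differs[i, j] = differs[j, i] = bool(p < alpha)

    # insert-and-absorb: letters are sets of group indices, each a maximal
    # clique of "not significantly different"
    letters: list[set[int]] = [{0}]
    for g in range(1, k):
        placed = False
        for s in letters:
            if not any(differs[g, m] for m in s):
                s.add(g)
                placed = True
        if not placed:
            # start a new letter seeded with g plus every earlier group
            # it does not differ from
            new = {g} | {m for m in range(g) if not differs[g, m]}
            letters.append(new)
    # absorb letters fully contained in another
    letters = [s for i, s in enumerate(letters)
               if not any(i != j and s < t for j, t in enumerate(letters))]
    letters.sort(key=lambda s: min(s))

    alphabet = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
    out = {name: "" for name in names}
    for li, s in enumerate(letters):
        for g in sorted(s):
            out[names[g]] += alphabet[li % len(alphabet)]
    return out
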