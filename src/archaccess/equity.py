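"""Health-workforce weighting and the district healthcare-equity index.

Staff are weighted by the Indonesian national staffing standards
(1 physician : 2,500 residents, 1 midwife : 1,000, 1 nurse : 855),
normalised to the nurse standard, giving weights 2.92 : 1.17 : 1.00.
A facility's weighted workforce is

    mu = physicians·2.92 + midwives·1.17 + nurses·1.00

District availability terms are weighted workers per 1,000 population,
separately for puskesmas (x) and hospitals (y).  The equity index combines
availability with the population-weighted total travel distance z:

    equity = z / mean(x, y)          (default, "availability" form)
    equity = z · mean(1/x, 1/y)      (alternate, "ratio" form)

Low values are excellent (short distances, plentiful staff); high values
are severe.  Districts are ranked ascending (rank 1 = best equity).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .core import Facility

__all__ = [
    "StaffingStandard",
    "WorkforceIndex",
    "EquityScore",
    "standard_weights",
    "weighted_workforce",
    "availability_terms",
    "equity_index",
    "rank_districts",
    "DEFAULT_STANDARD",
]


@dataclass(frozen=True)
class StaffingStandard:
    """National persons-per-worker staffing standards."""

    persons_per_physician: float = 2500.0
    persons_per_midwife: float = 1000.0
    persons_per_nurse: float = 855.0


DEFAULT_STANDARD = StaffingStandard()


@dataclass(frozen=True)
class WorkforceIndex:
    district_id: str
    mu_puskesmas: float
    mu_hospital: float
    a: int  # number of puskesmas
    b: int  # number of hospitals
    x: float  # puskesmas availability (weighted workers per 1,000 pop)
    y: float  # hospital availability


@dataclass(frozen=True)
class EquityScore:
    district_id: str
    district_name: str
    z: float
    x: float
    y: float
    equity_value: float
    rank: int = 0


def standard_weights(
    standard: StaffingStandard = DEFAULT_STANDARD, report: bool = True
) -> tuple[float, float, float]:
    """(physician, midwife, nurse) weights from a staffing standard.

    Each weight is the persons-per-worker standard divided by the nurse
    standard; with ``report=True`` (default) weights are rounded to the
    2-decimal convention (2500/1000/855 → 2.92, 1.17, 1.00).
    """
    for v in (
        standard.persons_per_physician,
        standard.persons_per_midwife,
        standard.persons_per_nurse,
    ):
        if v <= 0:
            raise ValueError("staffing standards must be positive")
    ws = (
        standard.persons_per_physician / standard.persons_per_nurse,
        standard.persons_per_midwife / standard.persons_per_nurse,
        1.0,
    )
    return tuple(round(w, 2) for w in ws) if report else ws


def weighted_workforce(
    physicians: int,
    midwives: int,
    nurses: int,
    weights: tuple[float, float, float] | None = None,
) -> float:
    """Weighted staff total mu = physicians·w_p + midwives·w_m + nurses·w_n."""
    if min(physicians, midwives, nurses) < 0:
        raise ValueError("staff counts must be non-negative")
    wp, wm, wn = weights if weights is not None else standard_weights()
    return physicians * wp + midwives * wm + nurses * wn


def facility_mu(
    facility: Facility, weights: tuple[float, float, float] | None = None
) -> float:
    return weighted_workforce(
        facility.physicians, facility.midwives, facility.nurses, weights
    )


def availability_terms(
    population: float,
    facilities: list[Facility],
    weights: tuple[float, float, float] | None = None,
    per: float = 1000.0,
) -> tuple[float, float]:
    """(x, y): weighted workers per ``per`` population, by facility type.

    x sums puskesmas staff, y hospital staff; a district without a
    facility type gets availability 0 for it.
    """
    if population <= 0:
        raise ValueError("population must be positive")
    mu_p = sum(facility_mu(f, weights) for f in facilities if f.kind == "puskesmas")
    mu_h = sum(facility_mu(f, weights) for f in facilities if f.kind == "hospital")
    return mu_p / population * per, mu_h / population * per


def workforce_index(
    district_id: str,
    population: float,
    facilities: list[Facility],
    weights: tuple[float, float, float] | None = None,
) -> WorkforceIndex:
    x, y = availability_terms(population, facilities, weights)
    mu_p = sum(facility_mu(f, weights) for f in facilities if f.kind == "puskesmas")
    mu_h = sum(facility_mu(f, weights) for f in facilities if f.kind == "hospital")
    return WorkforceIndex(
        district_id=district_id,
        mu_puskesmas=mu_p,
        mu_hospital=mu_h,
        a=sum(1 for f in facilities if f.kind == "puskesmas"),
        b=sum(1 for f in facilities if f.kind == "hospital"),
        x=x,
        y=y,
    )


def equity_index(z: float, x: float, y: float, form: str = "availability") -> float:
    """Combined equity value; strictly worse (larger) with distance,
    strictly better (smaller) with workforce availability.

    ``availability``: z / mean(x, y).  ``ratio``: z · mean(1/x, 1/y)
    (harmonic-style alternative; infinite-availability terms contribute 0).
    """
    if z < 0:
        raise ValueError("z must be non-negative")
    if x <= 0 and y <= 0:
        raise ValueError("no workforce in district (x = y = 0)")
    if form == "availability":
        return z / ((x + y) / 2.0)
    if form == "ratio":
        inv = [(1.0 / v) if v > 0 else math.inf for v in (x, y)]
        finite = [i for i in inv if math.isfinite(i)]
        return z * (sum(finite) / 2.0)
    raise ValueError(f"unknown equity form {form!r}")


def rank_districts(scores: list[EquityScore]) -> list[EquityScore]:
    """Ascending by equity value (rank 1 = best); ties break by name."""
    if not scores:
        raise ValueError("no equity scores to rank")
    ordered = sorted(scores, key=lambda s: (s.equity_value, s.district_name))
    return [
        EquityScore(s.district_id, s.district_name, s.z, s.x, s.y, s.equity_value, i + 1)
        for i, s in enumerate(ordered)
    ]
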