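"""End-to-end orchestration: allocate → classify → route → summarise →
workforce/equity → 2SFCA.

``run_pipeline`` executes the stages in order on a validated region and
returns a :class:`ResultBundle` of tidy DataFrames (Table-1-shaped district
summary, Table-2-shaped segment statistics, route table, workforce/equity
table, 2SFCA scores) plus a run log recording every threshold and mode
used.  Identical region + config yields identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import metrics
from .allocation import allocate_region
from .core import StudyRegion, validate_region
from .equity import EquityScore, equity_index, rank_districts, standard_weights, workforce_index
from .fca import two_step_fca, DEFAULT_FCA_RADIUS_KM
from .landroute import DEFAULT_ROAD_PROXIMITY_KM, DEFAULT_SNAP_TOLERANCE_KM, LandRouter, classify_access
from .metrics import DistrictSummary, RouteSet
from .navalroute import DEFAULT_BEACH_ADJACENCY_KM, NavalRouter, WaterRouter
from .util import round_half_up

__all__ = ["PipelineConfig", "ResultBundle", "run_pipeline", "StageError"]


@dataclass(frozen=True)
class PipelineConfig:
    """All tunables of one pipeline run (every threshold is a key here,
    never hard-coded downstream)."""

    road_proximity_km: float = DEFAULT_ROAD_PROXIMITY_KM
    beach_adjacency_km: float = DEFAULT_BEACH_ADJACENCY_KM
    fca_radius_km: float = DEFAULT_FCA_RADIUS_KM
    snap_tolerance_km: float = DEFAULT_SNAP_TOLERANCE_KM
    district_restriction: bool = True
    equity_form: str = "availability"  # or "ratio"
    mean_mode: str = "centroid"  # or "population"
    naval_mode: str = "total"  # or "chained"
    fca_supply: str = "workforce"  # or "counts"

    def validate(self) -> None:
        for name in ("road_proximity_km", "beach_adjacency_km", "fca_radius_km", "snap_tolerance_km"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.equity_form not in ("availability", "ratio"):
            raise ValueError("equity_form must be 'availability' or 'ratio'")
        if self.mean_mode not in ("centroid", "population"):
            raise ValueError("mean_mode must be 'centroid' or 'population'")
        if self.naval_mode not in ("total", "chained"):
            raise ValueError("naval_mode must be 'total' or 'chained'")
        if self.fca_supply not in ("workforce", "counts"):
            raise ValueError("fca_supply must be 'workforce' or 'counts'")


class StageError(RuntimeError):
    """A pipeline stage failed; message names the stage and entity."""


@dataclass
class ResultBundle:
    region: StudyRegion
    config: PipelineConfig
    allocations: pd.DataFrame
    classifications: dict[tuple[str, str], str]
    routes: RouteSet
    route_table: pd.DataFrame
    segment_table: pd.DataFrame
    district_summaries: dict[str, DistrictSummary]
    district_table: pd.DataFrame
    equity_table: pd.DataFrame
    equity_scores: list[EquityScore]
    fca_table: pd.DataFrame
    log: list[str] = field(default_factory=list)

    def write(self, directory: str | Path) -> None:
        """Write the CSV bundle and run log to ``directory``."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.allocations.to_csv(directory / "allocations.csv", index=False)
        self.route_table.to_csv(directory / "routes.csv", index=False)
        self.segment_table.to_csv(directory / "segment_stats.csv", index=False)
        self.district_table.to_csv(directory / "district_summary.csv", index=False)
        self.equity_table.to_csv(directory / "equity.csv", index=False)
        self.fca_table.to_csv(directory / "fca.csv", index=False)
        from .io import export_district_geojson

        export_district_geojson(
            self.region, self.district_table, directory / "district_summary.geojson"
        )
        (directory / "run_log.txt").write_text("\n".join(self.log) + "\n")


def _stage(log: list[str], name: str):
    log.append(f"stage: {name}")


def run_pipeline(region: StudyRegion, config: PipelineConfig | None = None) -> ResultBundle:
    """Run every stage on ``region``; see module docstring for the order.

    Residence/kind pairs whose district offers no facility of that kind
    are recorded as unreachable (their population still counts in the
    naval access class); any other stage failure aborts with a
    :class:`StageError` naming the stage and entity.
    """
    config = config or PipelineConfig()
    config.validate()
    log: list[str] = [f"config: {asdict(config)}"]

    _stage(log, "validate")
    violations = validate_region(region)
    if violations:
        raise StageError(
            f"validate: region has {len(violations)} invariant violation(s); "
            f"first: {violations[0]}"
        )

    _stage(log, "allocate")
    try:
        region = allocate_region(region)
    except ValueError as exc:
        raise StageError(f"allocate: {exc}") from exc
    allocations = pd.DataFrame(
        [
            {
                "cluster_id": r.id,
                "district_id": r.district_id,
                "area_km2": r.area_km2,
                "population": r.population,
            }
            for r in region.residences
        ]
    )

    _stage(log, "classify")
    classifications: dict[tuple[str, str], str] = {}
    for r in region.residences:
        for kind in ("puskesmas", "hospital"):
            try:
                classifications[(r.id, kind)] = classify_access(
                    r, kind, region, road_proximity_km=config.road_proximity_km
                )
            except ValueError as exc:
                raise StageError(f"classify: residence {r.id}: {exc}") from exc
    for d in region.districts:
        n_land = sum(
            1
            for r in region.residences_in_district(d.id)
            if classifications[(r.id, "puskesmas")] == "land"
        )
        n_tot = len(region.residences_in_district(d.id))
        log.append(
            f"classify: district {d.id}: {n_land}/{n_tot} residences land-class (puskesmas)"
        )

    _stage(log, "route")
    land_router = LandRouter(
        region,
        snap_tolerance_km=config.snap_tolerance_km,
        cross_district=not config.district_restriction,
    )
    naval_router = NavalRouter(
        region,
        land_router=land_router,
        water_router=WaterRouter([i.polygon for i in region.islands]),
        road_proximity_km=config.road_proximity_km,
        beach_adjacency_km=config.beach_adjacency_km,
        cross_district=not config.district_restriction,
        mode=config.naval_mode,
    )
    land_routes, naval_routes, unreachable = {}, {}, []
    for r in region.residences:
        for kind in ("puskesmas", "hospital"):
            eligible = (
                [f for f in region.facilities if f.kind == kind]
                if not config.district_restriction
                else region.facilities_in_district(r.district_id, kind)
            )
            if not eligible:
                unreachable.append((r.id, kind))
                continue
            try:
                if classifications[(r.id, kind)] == "land":
                    land_routes[(r.id, kind)] = land_router.route(r, kind)
                else:
                    naval_routes[(r.id, kind)] = naval_router.route(r, kind)
            except ValueError as exc:
                raise StageError(f"route: residence {r.id} ({kind}): {exc}") from exc
    routes = RouteSet(land=land_routes, naval=naval_routes, unreachable=unreachable)
    log.append(
        f"route: {len(land_routes)} land routes, {len(naval_routes)} combined "
        f"land+naval routes, {len(unreachable)} residence/kind pairs without an "
        "eligible in-district facility"
    )

    rows = []
    for (rid, kind), lr in land_routes.items():
        label = "A" if kind == "puskesmas" else "B"
        rows.append((rid, lr.facility_id, kind, "land", label, lr.distance_km))
    for (rid, kind), nr in naval_routes.items():
        la, lw, lg = nr.segment_labels
        rows.append((rid, nr.facility_id, kind, "land_naval", la, nr.leg_residence_to_wap))
        rows.append((rid, nr.facility_id, kind, "land_naval", lw, nr.leg_water))
        rows.append((rid, nr.facility_id, kind, "land_naval", lg, nr.leg_dock_to_facility))
    route_table = pd.DataFrame(
        rows,
        columns=["residence_id", "facility_id", "kind", "mode", "segment", "distance_km"],
    ).sort_values(["residence_id", "kind", "segment"], ignore_index=True)

    _stage(log, "summarize")
    legs = routes.segment_legs(region)
    seg_rows = []
    summaries: dict[str, DistrictSummary] = {}
    dist_rows = []
    for d in region.districts:
        if not legs[legs["district_id"] == d.id].empty:
            for s in metrics.segment_stats(legs, d.id):
                seg_rows.append(
                    {
                        "district_id": s.district_id,
                        "segment": s.segment,
                        "n": s.n,
                        "mean": s.mean,
                        "standard_error": s.standard_error,
                        "median": s.median,
                        "min": s.min,
                        "max": s.max,
                    }
                )
        props = metrics.access_proportions(region, classifications, d.id)
        means = metrics.district_mean_distances(
            routes, region, d.id, population_weighted=(config.mean_mode == "population")
        )
        summary = DistrictSummary(
            district_id=d.id,
            c=props["c"],
            c_nav=props["c_nav"],
            e=props["e"],
            e_nav=props["e_nav"],
            d=means["puskesmas_land"],
            d_nav=means["puskesmas_naval"],
            f_=means["hospital_land"],
            f_nav=means["hospital_naval"],
            n_land_puskesmas=props["puskesmas_land"],
            n_naval_puskesmas=props["puskesmas_naval"],
            n_land_hospital=props["hospital_land"],
            n_naval_hospital=props["hospital_naval"],
        )
        summaries[d.id] = summary
        has_any_mean = any(
            m is not None for m in (summary.d, summary.f_, summary.d_nav, summary.f_nav)
        )
        dist_rows.append(
            {
                "district_id": d.id,
                "name": d.name,
                "population": props["population"],
                "c": summary.c,
                "c_nav": summary.c_nav,
                "e": summary.e,
                "e_nav": summary.e_nav,
                "pop_puskesmas_land": props["puskesmas_land"],
                "pop_puskesmas_naval": props["puskesmas_naval"],
                "pop_hospital_land": props["hospital_land"],
                "pop_hospital_naval": props["hospital_naval"],
                "mean_puskesmas_land_km": summary.d,
                "mean_hospital_land_km": summary.f_,
                "mean_puskesmas_naval_km": summary.d_nav,
                "mean_hospital_naval_km": summary.f_nav,
                "z_km": summary.z,
                "all_routes_mean_km": summary.all_routes_mean if has_any_mean else math.nan,
            }
        )
    segment_table = pd.DataFrame(seg_rows)
    district_table = pd.DataFrame(dist_rows)

    _stage(log, "equity")
    weights = standard_weights()
    log.append(f"equity: staffing weights (physician, midwife, nurse) = {weights}")
    eq_rows, scores = [], []
    for d in region.districts:
        facs = region.facilities_in_district(d.id)
        summary = summaries[d.id]
        row = {"district_id": d.id, "name": d.name, "z_km": summary.z}
        try:
            wi = workforce_index(d.id, d.total_population, facs, weights)
            value = equity_index(summary.z, wi.x, wi.y, form=config.equity_form)
            row.update(
                {
                    "mu_puskesmas": wi.mu_puskesmas,
                    "mu_hospital": wi.mu_hospital,
                    "n_puskesmas": wi.a,
                    "n_hospitals": wi.b,
                    "x": wi.x,
                    "y": wi.y,
                    "equity_value": value,
                }
            )
            scores.append(EquityScore(d.id, d.name, summary.z, wi.x, wi.y, value))
        except ValueError as exc:
            log.append(f"equity: district {d.id}: {exc}")
            row["equity_value"] = math.nan
        eq_rows.append(row)
    scores = rank_districts(scores) if scores else []
    ranks = {s.district_id: s.rank for s in scores}
    equity_table = pd.DataFrame(eq_rows)
    equity_table["rank"] = equity_table["district_id"].map(ranks).astype("Int64")

    _stage(log, "fca")
    log.append(
        f"fca: radius {config.fca_radius_km} km, supply {config.fca_supply!r}"
    )
    fca_rows = []
    for kind in ("puskesmas", "hospital"):
        if not any(f.kind == kind for f in region.facilities):
            log.append(f"fca: no {kind} in region, skipped")
            continue
        for rid, score in two_step_fca(
            region, kind, radius_km=config.fca_radius_km, supply=config.fca_supply
        ).items():
            fca_rows.append(
                {
                    "residence_id": rid,
                    "facility_kind": kind,
                    "accessibility": score.accessibility,
                    "in_range": score.in_range,
                }
            )
    fca_table = pd.DataFrame(fca_rows)

    return ResultBundle(
        region=region,
        config=config,
        allocations=allocations,
        classifications=classifications,
        routes=routes,
        route_table=route_table,
        segment_table=segment_table,
        district_summaries=summaries,
        district_table=district_table,
        equity_table=equity_table,
        equity_scores=scores,
        fca_table=fca_table,
        log=log,
    )


def report_table(district_table: pd.DataFrame) -> pd.DataFrame:
    """Reporting view of the district summary: km and % half-up to 2 d.p."""
    out = district_table.copy()
    for col in out.columns:
        if col.endswith("_km"):
            out[col] = out[col].map(lambda v: round_half_up(v, 2) if pd.notna(v) else v)
    for col in ("c", "c_nav", "e", "e_nav"):
        out[col + "_pct"] = (out[col] * 100).map(lambda v: round_half_up(v, 2))
    return out
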