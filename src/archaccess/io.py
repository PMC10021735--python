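"""Readers and writers for the package's GeoJSON/CSV dialect.

Each entity class is stored as one GeoJSON FeatureCollection (RFC 7946
structure, but coordinates are projected kilometres, not lon/lat — a
documented deviation) with ids, kinds, district ids, populations and staff
counts carried as feature properties:

* ``districts.geojson`` — Polygon; id, name, total_population
* ``islands.geojson`` — Polygon; id
* ``residences.geojson`` — Polygon; id, district_id, population
* ``roads.geojson`` — LineString
* ``water_access_points.geojson`` — Point; id, kind
* ``facilities.geojson`` — Point; id, kind, district_id, physicians,
  nurses, midwives

Optionally, ``district_population.csv`` (district_id, population) and
``staffing.csv`` (facility_id, physicians, nurses, midwives) override the
corresponding GeoJSON properties, mirroring how census totals and registry
staffing tables arrive separately from the geodata.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

from shapely.geometry import LineString, Point, Polygon, shape
from shapely.geometry import mapping as geom_mapping

from .core import (
    District,
    Facility,
    Island,
    ResidenceCluster,
    StudyRegion,
    WaterAccessPoint,
    FACILITY_KINDS,
    WAP_KINDS,
)

__all__ = ["read_region", "write_region", "export_district_geojson", "SchemaError"]

_FILES = {
    "districts": "districts.geojson",
    "islands": "islands.geojson",
    "residences": "residences.geojson",
    "roads": "roads.geojson",
    "water_access_points": "water_access_points.geojson",
    "facilities": "facilities.geojson",
}


class SchemaError(ValueError):
    """An input file violates the documented schema."""


def _fc(features: list[dict]) -> dict:
    return {"type": "FeatureCollection", "features": features}


def _feature(geom, props: dict) -> dict:
    return {"type": "Feature", "geometry": geom_mapping(geom), "properties": props}


def write_region(region: StudyRegion, directory: str | Path) -> None:
    """Write a region to ``directory`` in the documented dialect.

    Output is deterministic (sorted keys, plain ``repr`` floats), so the
    same region always produces byte-identical files.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    collections = {
        "districts": [
            _feature(d.polygon, {"id": d.id, "name": d.name, "total_population": d.total_population})
            for d in region.districts
        ],
        "islands": [_feature(i.polygon, {"id": i.id}) for i in region.islands],
        "residences": [
            _feature(r.polygon, {"id": r.id, "district_id": r.district_id, "population": r.population})
            for r in region.residences
        ],
        "roads": [_feature(seg, {}) for seg in region.roads],
        "water_access_points": [
            _feature(w.location, {"id": w.id, "kind": w.kind})
            for w in region.water_access_points
        ],
        "facilities": [
            _feature(
                f.location,
                {
                    "id": f.id,
                    "kind": f.kind,
                    "district_id": f.district_id,
                    "physicians": f.physicians,
                    "nurses": f.nurses,
                    "midwives": f.midwives,
                },
            )
            for f in region.facilities
        ],
    }
    for key, feats in collections.items():
        path = directory / _FILES[key]
        path.write_text(json.dumps(_fc(feats), sort_keys=True, indent=1) + "\n")

    with open(directory / "district_population.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["district_id", "name", "population"])
        for d in region.districts:
            w.writerow([d.id, d.name, d.total_population])
    with open(directory / "staffing.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["facility_id", "kind", "district_id", "physicians", "nurses", "midwives"])
        for f in region.facilities:
            w.writerow([f.id, f.kind, f.district_id, f.physicians, f.nurses, f.midwives])


def _load_fc(directory: Path, key: str) -> list[dict]:
    path = directory / _FILES[key]
    if not path.exists():
        raise SchemaError(f"missing input file {path}")
    try:
        data = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise SchemaError(f"{path}: not valid JSON ({exc})") from exc
    if data.get("type") != "FeatureCollection":
        raise SchemaError(f"{path}: expected a FeatureCollection")
    return data.get("features", [])


def _prop(feat: dict, name: str, path: str, idx: int):
    props = feat.get("properties") or {}
    if name not in props:
        raise SchemaError(f"{path} feature {idx}: missing property {name!r}")
    return props[name]


def _int_prop(feat: dict, name: str, path: str, idx: int, minimum: int | None = 0) -> int:
    val = _prop(feat, name, path, idx)
    try:
        out = int(val)
    except (TypeError, ValueError):
        raise SchemaError(f"{path} feature {idx}: non-numeric {name!r}: {val!r}")
    if minimum is not None and out < minimum:
        raise SchemaError(f"{path} feature {idx}: negative {name!r}")
    return out


def read_region(directory: str | Path) -> StudyRegion:
    """Read a region written in the documented dialect.

    Raises :class:`SchemaError` naming file, feature and field on any
    schema violation (unknown kinds, missing ids, negative counts, wrong
    geometry types).
    """
    directory = Path(directory)

    def geom(feat: dict, want: type, path: str, idx: int):
        g = shape(feat.get("geometry") or {})
        if not isinstance(g, want):
            raise SchemaError(
                f"{path} feature {idx}: expected {want.__name__}, got {g.geom_type}"
            )
        return g

    districts = []
    p = _FILES["districts"]
    for i, feat in enumerate(_load_fc(directory, "districts")):
        districts.append(
            District(
                id=str(_prop(feat, "id", p, i)),
                name=str(_prop(feat, "name", p, i)),
                polygon=geom(feat, Polygon, p, i),
                total_population=_int_prop(feat, "total_population", p, i),
            )
        )

    islands = []
    p = _FILES["islands"]
    for i, feat in enumerate(_load_fc(directory, "islands")):
        islands.append(Island(str(_prop(feat, "id", p, i)), geom(feat, Polygon, p, i)))

    residences = []
    p = _FILES["residences"]
    for i, feat in enumerate(_load_fc(directory, "residences")):
        poly = geom(feat, Polygon, p, i)
        pop = _prop(feat, "population", p, i)
        try:
            pop = float(pop)
        except (TypeError, ValueError):
            raise SchemaError(f"{p} feature {i}: non-numeric population {pop!r}")
        if pop < 0:
            raise SchemaError(f"{p} feature {i}: negative population")
        residences.append(
            ResidenceCluster.from_polygon(
                str(_prop(feat, "id", p, i)), str(_prop(feat, "district_id", p, i)), poly, pop
            )
        )

    roads = []
    p = _FILES["roads"]
    for i, feat in enumerate(_load_fc(directory, "roads")):
        roads.append(geom(feat, LineString, p, i))

    waps = []
    p = _FILES["water_access_points"]
    for i, feat in enumerate(_load_fc(directory, "water_access_points")):
        kind = str(_prop(feat, "kind", p, i))
        if kind not in WAP_KINDS:
            raise SchemaError(f"{p} feature {i}: unknown water-access kind {kind!r}")
        waps.append(WaterAccessPoint(str(_prop(feat, "id", p, i)), kind, geom(feat, Point, p, i)))

    facilities = []
    p = _FILES["facilities"]
    for i, feat in enumerate(_load_fc(directory, "facilities")):
        kind = str(_prop(feat, "kind", p, i))
        if kind not in FACILITY_KINDS:
            raise SchemaError(f"{p} feature {i}: unknown facility kind {kind!r}")
        facilities.append(
            Facility(
                id=str(_prop(feat, "id", p, i)),
                kind=kind,
                district_id=str(_prop(feat, "district_id", p, i)),
                location=geom(feat, Point, p, i),
                physicians=_int_prop(feat, "physicians", p, i),
                nurses=_int_prop(feat, "nurses", p, i),
                midwives=_int_prop(feat, "midwives", p, i),
            )
        )

    # CSV overrides (census totals and registry staffing often ship apart
    # from the geodata)
    pop_csv = directory / "district_population.csv"
    if pop_csv.exists():
        with open(pop_csv, newline="") as fh:
            for row_i, row in enumerate(csv.DictReader(fh)):
                did = row.get("district_id")
                try:
                    pop = int(float(row.get("population", "")))
                except ValueError:
                    raise SchemaError(f"{pop_csv} row {row_i}: non-numeric population")
                if pop < 0:
                    raise SchemaError(f"{pop_csv} row {row_i}: negative population")
                districts = [
                    District(d.id, d.name, d.polygon, pop) if d.id == did else d
                    for d in districts
                ]
    staff_csv = directory / "staffing.csv"
    if staff_csv.exists():
        with open(staff_csv, newline="") as fh:
            for row_i, row in enumerate(csv.DictReader(fh)):
                fid = row.get("facility_id")
                counts = {}
                for col in ("physicians", "nurses", "midwives"):
                    try:
                        counts[col] = int(float(row.get(col, "")))
                    except ValueError:
                        raise SchemaError(f"{staff_csv} row {row_i}: non-numeric {col}")
                    if counts[col] < 0:
                        raise SchemaError(f"{staff_csv} row {row_i}: negative {col}")
                facilities = [
                    Facility(f.id, f.kind, f.district_id, f.location, **counts)
                    if f.id == fid
                    else f
                    for f in facilities
                ]

    return StudyRegion(
        districts=districts,
        islands=islands,
        residences=residences,
        roads=roads,
        water_access_points=waps,
        facilities=facilities,
    )


def export_district_geojson(region: StudyRegion, attributes, path: str | Path) -> None:
    """Write district polygons with per-district attributes (choropleth-ready).

    ``attributes`` is a DataFrame with a ``district_id`` column; all its
    other columns become feature properties.
    """
    rows = {str(r["district_id"]): r for _, r in attributes.iterrows()}
    feats = []
    for d in region.districts:
        props = {"id": d.id, "name": d.name}
        row = rows.get(d.id)
        if row is not None:
            for k, v in row.items():
                if k == "district_id":
                    continue
                if hasattr(v, "item"):
                    v = v.item()
                if isinstance(v, float) and v != v:  # NaN -> null
                    v = None
                props[k] = v
        feats.append(_feature(d.polygon, props))
    Path(path).write_text(json.dumps(_fc(feats), sort_keys=True, indent=1) + "\n")
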