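"""Readers and writers for the native CSV-directory and JSON-bundle dialects.

CSV directory layout (UTF-8, comma-separated, mandatory header row):

====================  ====================================================
file                  columns
====================  ====================================================
maps.csv              map_id,citation
regions.csv           map_id,acronym
relations.csv         map_a,region_a,code,map_b,region_b,pdc,ref
injections.csv        study_id,injection_id,direction,map_id,acronym,
                      spillover,pdc  (spillover: semicolon-separated
                      acronyms within the same map)
labeled_sites.csv     study_id,injection_id,map_id,acronym,density,extent,pdc
studies.csv           study_id,citation
====================  ====================================================

The JSON bundle is a single object with keys ``maps``, ``relations`` and
``studies`` mirroring the same fields.  Unknown columns are ignored with a
logged warning; writes are canonically ordered, so rewriting the same
dataset is byte-identical.

Free-text density words from the literature ("dense", "sparse", ...) are
normalized to ordinal codes at read time via a configurable synonym table;
everywhere else the engine uses the codes only.
"""

from __future__ import annotations

import csv
import json
import logging
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping

from .errors import FormatError, ReferentialError
from .model import (
    PDC,
    BrainMap,
    Dataset,
    DensityCode,
    Direction,
    ExtentCode,
    Injection,
    InterMapRelation,
    LabeledSite,
    RegionId,
    RelationCode,
    Study,
)

__all__ = [
    "DatasetFormat",
    "read_dataset",
    "write_dataset",
    "DEFAULT_DENSITY_TEXT_MAP",
]

log = logging.getLogger(__name__)


class DatasetFormat(Enum):
    CSV_DIR = "csv"
    JSON_BUNDLE = "json"


#: Reader-side normalization of free-text density words; editable via config.
DEFAULT_DENSITY_TEXT_MAP: dict[str, DensityCode] = {
    "dense": DensityCode.STRONG,
    "strong": DensityCode.STRONG,
    "heavy": DensityCode.STRONG,
    "moderate": DensityCode.MODERATE,
    "intermediate": DensityCode.MODERATE,
    "sparse": DensityCode.WEAK,
    "weak": DensityCode.WEAK,
    "light": DensityCode.WEAK,
    "no": DensityCode.ABSENT,
    "none": DensityCode.ABSENT,
    "absent": DensityCode.ABSENT,
}

_CSV_COLUMNS = {
    "maps.csv": ["map_id", "citation"],
    "regions.csv": ["map_id", "acronym"],
    "relations.csv": ["map_a", "region_a", "code", "map_b", "region_b", "pdc", "ref"],
    "injections.csv": [
        "study_id",
        "injection_id",
        "direction",
        "map_id",
        "acronym",
        "spillover",
        "pdc",
    ],
    "labeled_sites.csv": [
        "study_id",
        "injection_id",
        "map_id",
        "acronym",
        "density",
        "extent",
        "pdc",
    ],
    "studies.csv": ["study_id", "citation"],
}


def _parse_pdc(token: str, where: str) -> PDC:
    token = token.strip()
    if not token:
        return PDC.UNSTATED
    try:
        return PDC[token.upper()]
    except KeyError:
        raise FormatError(f"{where}: unknown PDC level {token!r}") from None


def _parse_density(
    token: str, where: str, text_map: Mapping[str, DensityCode]
) -> DensityCode:
    token = token.strip()
    if not token:
        # Positive labeling with unstated amount; readers pair this with the
        # extent column, and the validator flags inconsistencies.
        return DensityCode.PRESENT_UNKNOWN
    try:
        return DensityCode(token.upper() if token.upper() == "U" else token)
    except ValueError:
        pass
    try:
        return DensityCode[token.upper()]
    except KeyError:
        pass
    mapped = text_map.get(token.lower())
    if mapped is not None:
        return mapped
    raise FormatError(f"{where}: cannot interpret density {token!r}")


def _parse_extent(token: str, where: str) -> ExtentCode:
    token = token.strip()
    if not token:
        return ExtentCode.U
    aliases = {"complete": "C", "partial": "P", "none": "N"}
    token = aliases.get(token.lower(), token.upper())
    try:
        return ExtentCode(token)
    except ValueError:
        raise FormatError(f"{where}: unknown extent code {token!r}") from None


def _parse_direction(token: str, where: str) -> Direction:
    t = token.strip().upper()
    if t in ("A", "ANTEROGRADE"):
        return Direction.ANTEROGRADE
    if t in ("R", "RETROGRADE"):
        return Direction.RETROGRADE
    raise FormatError(f"{where}: unknown tracer direction {token!r}")


def _parse_code(token: str, where: str) -> RelationCode:
    try:
        return RelationCode(token.strip().upper())
    except ValueError:
        raise FormatError(f"{where}: unknown relation code {token!r}") from None


def _read_csv(path: Path, name: str) -> list[tuple[int, dict[str, str]]]:
    fpath = path / name
    if not fpath.exists():
        raise FormatError(f"missing required file {name} in {path}")
    required = _CSV_COLUMNS[name]
    rows: list[tuple[int, dict[str, str]]] = []
    with open(fpath, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        missing = [c for c in required if c not in header]
        if missing:
            raise FormatError(
                f"{name}: missing required column(s) {', '.join(missing)}"
            )
        extra = [c for c in header if c not in required]
        if extra:
            log.warning("%s: ignoring unknown column(s) %s", name, ", ".join(extra))
        for i, row in enumerate(reader, start=2):
            rows.append((i, {k: (row.get(k) or "") for k in required}))
    return rows


def _check_referential(d: Dataset, origin: Mapping[RegionId, str]) -> Dataset:
    regions = d.region_index()
    problems = []
    for rel in d.relations:
        for r in (rel.region_a, rel.region_b):
            if r not in regions:
                problems.append(f"{origin.get(r, 'relations')}: undeclared region {r}")
    for s in d.studies:
        inj_ids = {i.injection_id for i in s.injections}
        for inj in s.injections:
            for r in (inj.primary_site,) + inj.spillover_sites:
                if r not in regions:
                    problems.append(
                        f"{origin.get(r, 'injections')}: undeclared region {r}"
                    )
        for site in s.labeled_sites:
            if site.region not in regions:
                problems.append(
                    f"{origin.get(site.region, 'labeled_sites')}: "
                    f"undeclared region {site.region}"
                )
            if site.injection_id not in inj_ids:
                problems.append(
                    f"study {s.study_id}: labeled site in {site.region} "
                    f"references unknown injection {site.injection_id!r}"
                )
    if problems:
        raise ReferentialError("; ".join(sorted(set(problems))[:20]))
    return d


def _read_csv_dir(
    path: Path, density_text_map: Mapping[str, DensityCode]
) -> Dataset:
    maps_rows = _read_csv(path, "maps.csv")
    regions_rows = _read_csv(path, "regions.csv")
    relations_rows = _read_csv(path, "relations.csv")
    studies_rows = _read_csv(path, "studies.csv")
    injections_rows = _read_csv(path, "injections.csv")
    sites_rows = _read_csv(path, "labeled_sites.csv")

    origin: dict[RegionId, str] = {}
    regions_by_map: dict[str, list[RegionId]] = {}
    for lineno, row in regions_rows:
        rid = RegionId(row["map_id"], row["acronym"])
        regions_by_map.setdefault(rid.map_id, []).append(rid)
        origin.setdefault(rid, f"regions.csv row {lineno}")

    maps = []
    for lineno, row in maps_rows:
        map_id = row["map_id"].strip()
        if not map_id:
            raise FormatError(f"maps.csv row {lineno}: empty map_id")
        maps.append(
            BrainMap(
                map_id=map_id,
                regions=tuple(regions_by_map.get(map_id, ())),
                citation=row["citation"],
            )
        )

    relations = []
    for lineno, row in relations_rows:
        where = f"relations.csv row {lineno}"
        ra = RegionId(row["map_a"], row["region_a"])
        rb = RegionId(row["map_b"], row["region_b"])
        origin.setdefault(ra, where)
        origin.setdefault(rb, where)
        relations.append(
            InterMapRelation(
                region_a=ra,
                region_b=rb,
                code=_parse_code(row["code"], where),
                pdc=_parse_pdc(row["pdc"], where),
                ref=row["ref"],
            )
        )

    injections: dict[str, list[Injection]] = {}
    for lineno, row in injections_rows:
        where = f"injections.csv row {lineno}"
        primary = RegionId(row["map_id"], row["acronym"])
        origin.setdefault(primary, where)
        spillover = tuple(
            RegionId(row["map_id"], acr)
            for acr in (t.strip() for t in row["spillover"].split(";"))
            if acr
        )
        for r in spillover:
            origin.setdefault(r, where)
        injections.setdefault(row["study_id"], []).append(
            Injection(
                study_id=row["study_id"],
                injection_id=row["injection_id"],
                direction=_parse_direction(row["direction"], where),
                primary_site=primary,
                spillover_sites=spillover,
                pdc=_parse_pdc(row["pdc"], where),
            )
        )

    sites: dict[str, list[LabeledSite]] = {}
    for lineno, row in sites_rows:
        where = f"labeled_sites.csv row {lineno}"
        rid = RegionId(row["map_id"], row["acronym"])
        origin.setdefault(rid, where)
        extent = _parse_extent(row["extent"], where)
        density = _parse_density(row["density"], where, density_text_map)
        if extent is ExtentCode.N and density is DensityCode.PRESENT_UNKNOWN:
            density = DensityCode.ABSENT
        sites.setdefault(row["study_id"], []).append(
            LabeledSite(
                study_id=row["study_id"],
                injection_id=row["injection_id"],
                region=rid,
                density=density,
                extent=extent,
                pdc=_parse_pdc(row["pdc"], where),
            )
        )

    studies = []
    for lineno, row in studies_rows:
        sid = row["study_id"].strip()
        if not sid:
            raise FormatError(f"studies.csv row {lineno}: empty study_id")
        studies.append(
            Study(
                study_id=sid,
                citation=row["citation"],
                injections=tuple(injections.get(sid, ())),
                labeled_sites=tuple(sites.get(sid, ())),
            )
        )

    d = Dataset(tuple(maps), tuple(relations), tuple(studies)).canonical()
    return _check_referential(d, origin)


def _dataset_to_obj(d: Dataset) -> dict:
    d = d.canonical()
    return {
        "maps": [
            {
                "map_id": m.map_id,
                "citation": m.citation,
                "regions": [r.acronym for r in m.regions],
            }
            for m in d.maps
        ],
        "relations": [
            {
                "map_a": r.region_a.map_id,
                "region_a": r.region_a.acronym,
                "code": r.code.value,
                "map_b": r.region_b.map_id,
                "region_b": r.region_b.acronym,
                "pdc": r.pdc.name,
                "ref": r.ref,
            }
            for r in d.relations
        ],
        "studies": [
            {
                "study_id": s.study_id,
                "citation": s.citation,
                "injections": [
                    {
                        "injection_id": i.injection_id,
                        "direction": i.direction.value,
                        "map_id": i.primary_site.map_id,
                        "acronym": i.primary_site.acronym,
                        "spillover": [r.acronym for r in i.spillover_sites],
                        "pdc": i.pdc.name,
                    }
                    for i in s.injections
                ],
                "labeled_sites": [
                    {
                        "injection_id": ls.injection_id,
                        "map_id": ls.region.map_id,
                        "acronym": ls.region.acronym,
                        "density": ls.density.value,
                        "extent": ls.extent.value,
                        "pdc": ls.pdc.name,
                    }
                    for ls in s.labeled_sites
                ],
            }
            for s in d.studies
        ],
    }


def _obj_to_dataset(
    obj: dict, density_text_map: Mapping[str, DensityCode]
) -> Dataset:
    where = "json bundle"
    for key in ("maps", "relations", "studies"):
        if key not in obj:
            raise FormatError(f"{where}: missing top-level key {key!r}")
    maps = tuple(
        BrainMap(
            map_id=m["map_id"],
            regions=tuple(RegionId(m["map_id"], a) for a in m.get("regions", [])),
            citation=m.get("citation", ""),
        )
        for m in obj["maps"]
    )
    relations = tuple(
        InterMapRelation(
            region_a=RegionId(r["map_a"], r["region_a"]),
            region_b=RegionId(r["map_b"], r["region_b"]),
            code=_parse_code(r["code"], where),
            pdc=_parse_pdc(r.get("pdc", ""), where),
            ref=r.get("ref", ""),
        )
        for r in obj["relations"]
    )
    studies = []
    for s in obj["studies"]:
        sid = s["study_id"]
        injections = tuple(
            Injection(
                study_id=sid,
                injection_id=i["injection_id"],
                direction=_parse_direction(i["direction"], where),
                primary_site=RegionId(i["map_id"], i["acronym"]),
                spillover_sites=tuple(
                    RegionId(i["map_id"], a) for a in i.get("spillover", [])
                ),
                pdc=_parse_pdc(i.get("pdc", ""), where),
            )
            for i in s.get("injections", [])
        )
        sites = []
        for ls in s.get("labeled_sites", []):
            extent = _parse_extent(ls.get("extent", ""), where)
            density = _parse_density(ls.get("density", ""), where, density_text_map)
            if extent is ExtentCode.N and density is DensityCode.PRESENT_UNKNOWN:
                density = DensityCode.ABSENT
            sites.append(
                LabeledSite(
                    study_id=sid,
                    injection_id=ls["injection_id"],
                    region=RegionId(ls["map_id"], ls["acronym"]),
                    density=density,
                    extent=extent,
                    pdc=_parse_pdc(ls.get("pdc", ""), where),
                )
            )
        sites = tuple(sites)
        studies.append(
            Study(
                study_id=sid,
                citation=s.get("citation", ""),
                injections=injections,
                labeled_sites=sites,
            )
        )
    d = Dataset(maps, relations, tuple(studies)).canonical()
    return _check_referential(d, {})


def read_dataset(
    path: str | Path,
    format: DatasetFormat | None = None,
    density_text_map: Mapping[str, DensityCode] | None = None,
) -> Dataset:
    """Read and validate a dataset from a CSV directory or JSON bundle.

    When ``format`` is omitted it is inferred: directories are CSV, files
    JSON.  Raises :class:`FormatError` on dialect problems (naming the file,
    column, and row) and :class:`ReferentialError` on undeclared regions or
    dangling injection references.
    """
    path = Path(path)
    text_map = dict(density_text_map or DEFAULT_DENSITY_TEXT_MAP)
    if format is None:
        format = DatasetFormat.CSV_DIR if path.is_dir() else DatasetFormat.JSON_BUNDLE
    if format is DatasetFormat.CSV_DIR:
        return _read_csv_dir(path, text_map)
    try:
        obj = json.loads(path.read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise FormatError(f"{path}: not valid JSON ({exc})") from None
    return _obj_to_dataset(obj, text_map)


def _write_csv(path: Path, name: str, rows: Iterable[Iterable[str]]) -> None:
    with open(path / name, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(_CSV_COLUMNS[name])
        for row in rows:
            writer.writerow(list(row))


def write_dataset(
    d: Dataset, path: str | Path, format: DatasetFormat = DatasetFormat.CSV_DIR
) -> Path:
    """Write a dataset in the native dialect with canonical ordering.

    Maps sort by map_id, regions by acronym, relations lexicographically —
    two writes of the same dataset are byte-identical.
    """
    path = Path(path)
    d = d.canonical()
    if format is DatasetFormat.JSON_BUNDLE:
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(
            json.dumps(_dataset_to_obj(d), indent=2, sort_keys=True) + "\n",
            encoding="utf-8",
        )
        return path

    path.mkdir(parents=True, exist_ok=True)
    _write_csv(path, "maps.csv", ((m.map_id, m.citation) for m in d.maps))
    _write_csv(
        path,
        "regions.csv",
        ((r.map_id, r.acronym) for m in d.maps for r in m.regions),
    )
    _write_csv(
        path,
        "relations.csv",
        (
            (
                r.region_a.map_id,
                r.region_a.acronym,
                r.code.value,
                r.region_b.map_id,
                r.region_b.acronym,
                r.pdc.name,
                r.ref,
            )
            for r in d.relations
        ),
    )
    _write_csv(
        path, "studies.csv", ((s.study_id, s.citation) for s in d.studies)
    )
    _write_csv(
        path,
        "injections.csv",
        (
            (
                i.study_id,
                i.injection_id,
                i.direction.value,
                i.primary_site.map_id,
                i.primary_site.acronym,
                ";".join(r.acronym for r in i.spillover_sites),
                i.pdc.name,
            )
            for s in d.studies
            for i in s.injections
        ),
    )
    _write_csv(
        path,
        "labeled_sites.csv",
        (
            (
                ls.study_id,
                ls.injection_id,
                ls.region.map_id,
                ls.region.acronym,
                ls.density.value,
                ls.extent.value,
                ls.pdc.name,
            )
            for s in d.studies
            for ls in s.labeled_sites
        ),
    )
    return path
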