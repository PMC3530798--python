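"""Dataset validation: typed findings, errors vs warnings.

ERROR findings are invariant violations (referential breaks, duplicate
identifiers, inconsistent codes) that make downstream computation
ill-defined.  WARNING findings mark data that is legal but limits what the
engine can do — unstated precision codes, or maps with no inter-map
relations (which can never participate in cross-map propagation).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

from .model import Dataset, DensityCode, ExtentCode, PDC

__all__ = ["Severity", "Finding", "ValidationReport", "validate_dataset"]


class Severity(Enum):
    ERROR = "ERROR"
    WARNING = "WARNING"


@dataclass(frozen=True)
class Finding:
    severity: Severity
    code: str
    message: str

    def __str__(self) -> str:
        return f"{self.severity.value} [{self.code}] {self.message}"


@dataclass(frozen=True)
class ValidationReport:
    findings: tuple[Finding, ...]

    @property
    def errors(self) -> tuple[Finding, ...]:
        return tuple(f for f in self.findings if f.severity is Severity.ERROR)

    @property
    def warnings(self) -> tuple[Finding, ...]:
        return tuple(f for f in self.findings if f.severity is Severity.WARNING)

    @property
    def ok(self) -> bool:
        return not self.errors

    def __iter__(self):
        return iter(self.findings)

    def __len__(self) -> int:
        return len(self.findings)


def validate_dataset(d: Dataset) -> ValidationReport:
    """Check every model invariant; report findings rather than raising.

    The error list is empty iff the dataset satisfies all type invariants;
    a fuzzing-style test asserts that every single-field corruption of a
    valid dataset is detected.
    """
    findings: list[Finding] = []

    def err(code: str, msg: str) -> None:
        findings.append(Finding(Severity.ERROR, code, msg))

    def warn(code: str, msg: str) -> None:
        findings.append(Finding(Severity.WARNING, code, msg))

    seen_maps: set[str] = set()
    for m in d.maps:
        if not m.map_id.strip():
            err("EMPTY_MAP_ID", "brain map with empty map_id")
        if m.map_id in seen_maps:
            err("DUP_MAP_ID", f"duplicate map_id {m.map_id!r}")
        seen_maps.add(m.map_id)
        acronyms: set[str] = set()
        for r in m.regions:
            if not r.acronym:
                err("EMPTY_ACRONYM", f"map {m.map_id!r} has a region with empty acronym")
            if r.map_id != m.map_id:
                err(
                    "FOREIGN_REGION",
                    f"map {m.map_id!r} lists region {r} of another map",
                )
            if r.acronym in acronyms:
                err(
                    "DUP_ACRONYM",
                    f"map {m.map_id!r}: duplicate acronym {r.acronym!r}",
                )
            acronyms.add(r.acronym)

    regions = d.region_index()
    related_maps: set[str] = set()
    for rel in d.relations:
        pair = f"{rel.region_a} {rel.code.value} {rel.region_b}"
        if rel.region_a.map_id == rel.region_b.map_id:
            err(
                "INTRA_MAP_RELATION",
                f"relation within a single map: {pair}",
            )
        for r in (rel.region_a, rel.region_b):
            if r not in regions:
                err("DANGLING_REGION", f"relation references undeclared region {r}")
        if rel.pdc is PDC.UNSTATED:
            warn("UNSTATED_PDC", f"relation {pair} has no precision code")
        related_maps.update((rel.region_a.map_id, rel.region_b.map_id))

    seen_studies: set[str] = set()
    for s in d.studies:
        if not s.study_id.strip():
            err("EMPTY_STUDY_ID", "study with empty study_id")
        if s.study_id in seen_studies:
            err("DUP_STUDY_ID", f"duplicate study_id {s.study_id!r}")
        seen_studies.add(s.study_id)

        inj_ids: set[str] = set()
        for inj in s.injections:
            if inj.injection_id in inj_ids:
                err(
                    "DUP_INJECTION_ID",
                    f"study {s.study_id!r}: duplicate injection_id "
                    f"{inj.injection_id!r}",
                )
            inj_ids.add(inj.injection_id)
            if inj.study_id != s.study_id:
                err(
                    "FOREIGN_INJECTION",
                    f"study {s.study_id!r} lists injection of study "
                    f"{inj.study_id!r}",
                )
            if inj.primary_site in inj.spillover_sites:
                err(
                    "SPILLOVER_PRIMARY",
                    f"study {s.study_id!r}: primary site {inj.primary_site} "
                    "repeated in spillover",
                )
            for r in (inj.primary_site,) + inj.spillover_sites:
                if r not in regions:
                    err(
                        "DANGLING_REGION",
                        f"injection {s.study_id}/{inj.injection_id} references "
                        f"undeclared region {r}",
                    )
            if inj.pdc is PDC.UNSTATED:
                warn(
                    "UNSTATED_PDC",
                    f"injection {s.study_id}/{inj.injection_id} has no "
                    "precision code",
                )

        for site in s.labeled_sites:
            where = f"study {s.study_id!r}, site {site.region}"
            if site.study_id != s.study_id:
                err("FOREIGN_SITE", f"{where}: labeled site of another study")
            if site.injection_id not in inj_ids:
                err(
                    "DANGLING_INJECTION",
                    f"{where}: unknown injection {site.injection_id!r}",
                )
            if site.region not in regions:
                err("DANGLING_REGION", f"{where}: undeclared region")
            absent = site.density is DensityCode.ABSENT
            none_extent = site.extent is ExtentCode.N
            if absent != none_extent:
                err(
                    "DENSITY_EXTENT_MISMATCH",
                    f"{where}: density {site.density.value} with extent "
                    f"{site.extent.value} (ABSENT iff extent N)",
                )
            if site.pdc is PDC.UNSTATED:
                warn("UNSTATED_PDC", f"{where}: no precision code")

    if len(seen_maps) > 1:
        for m in d.maps:
            if m.map_id not in related_maps:
                warn(
                    "ISOLATED_MAP",
                    f"map {m.map_id!r} has no inter-map relations and cannot "
                    "participate in cross-map propagation",
                )

    return ValidationReport(tuple(findings))
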