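"""Domain model for textual tract-tracing statements.

The engine is deliberately coordinate-free: a brain region is nothing but a
named entry of a named parcellation (brain map), and everything downstream —
inter-map relations, injections, labeled sites — refers to regions by
``(map_id, acronym)`` pairs.  Macaque tracing literature reports results in
exactly this form ("the injection was in area X of map M"), and the large
inter-subject variability of macaque anatomy makes stereotaxic coordinates
less reliable than nomenclature, so no spatial geometry appears anywhere in
the model.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum, IntEnum

__all__ = [
    "PDC",
    "Direction",
    "DensityCode",
    "ExtentCode",
    "RelationCode",
    "RegionId",
    "BrainMap",
    "InterMapRelation",
    "Injection",
    "LabeledSite",
    "Study",
    "Dataset",
]


class PDC(IntEnum):
    """Precision-of-description code.

    Ordinal tag recording how precisely a publication states a fact (a site
    location, a relation).  Higher values are more precise; comparisons use
    the integer order, and :data:`PDC.UNSTATED` is the default for missing
    values.  Only the order is consumed downstream (conflict tie-breaking,
    evidence weighting), never the absolute level.
    """

    UNSTATED = 0
    TEXT_ONLY = 1
    FIGURE_ONLY = 2
    TEXT_AND_FIGURE = 3
    EXPLICIT = 4


class Direction(Enum):
    """Tracer transport direction.

    Anterograde tracers travel from the injected cell bodies to axon
    terminals (revealing projection targets); retrograde tracers travel from
    terminals back to cell bodies (revealing projection origins).
    """

    ANTEROGRADE = "ANTEROGRADE"
    RETROGRADE = "RETROGRADE"


class DensityCode(Enum):
    """Ordinal labeled-site density: absent < weak < moderate < strong.

    ``PRESENT_UNKNOWN`` ("U") records positive labeling whose amount was not
    stated — common in the literature, where labeled sites are rarely
    counted.  It participates in aggregation as "positive but unquantified".
    """

    ABSENT = "0"
    WEAK = "1"
    MODERATE = "2"
    STRONG = "3"
    PRESENT_UNKNOWN = "U"

    @property
    def level(self) -> int | None:
        """Integer strength 0–3, or None for PRESENT_UNKNOWN."""
        return None if self is DensityCode.PRESENT_UNKNOWN else int(self.value)

    @property
    def is_positive(self) -> bool:
        return self is not DensityCode.ABSENT


class ExtentCode(Enum):
    """How much of a region is covered by labeled sites.

    C (complete), P (partial) and N (none) are the statement-level codes the
    literature supports directly.  Relational inference additionally needs
    X — label is present but its extent within the region cannot be
    determined — and U, no information at all.  Distinguishing X from U keeps
    sound positive inferences (e.g. a completely labeled region forces label
    into every region it overlaps) separate from genuine ignorance.
    """

    C = "C"
    P = "P"
    X = "X"
    N = "N"
    U = "U"

    @property
    def is_positive(self) -> bool:
        return self in (ExtentCode.C, ExtentCode.P, ExtentCode.X)


class RelationCode(Enum):
    """Qualitative spatial relation between two regions (RCC5).

    I — identical; S — proper subregion of; L — proper superregion of;
    O — partial overlap; D — disjoint.  The four literature codes (I/S/L/O)
    are extended with an explicit D so that the algebra closes: compositions
    such as S∘D are determinate only when disjointness is first-class, and
    the atom-set oracle needs a code for every configuration.
    """

    I = "I"  # noqa: E741 - the field's standard one-letter code
    S = "S"
    L = "L"
    O = "O"  # noqa: E741
    D = "D"


@dataclass(frozen=True, order=True)
class RegionId:
    """A named region within a named brain map.

    Comparison is case-sensitive; constructors trim surrounding whitespace.
    """

    map_id: str
    acronym: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "map_id", self.map_id.strip())
        object.__setattr__(self, "acronym", self.acronym.strip())

    def __str__(self) -> str:
        return f"{self.map_id}:{self.acronym}"


@dataclass(frozen=True)
class BrainMap:
    """A parcellation: an ordered collection of named regions plus citation."""

    map_id: str
    regions: tuple[RegionId, ...]
    citation: str = ""


@dataclass(frozen=True)
class InterMapRelation:
    """A primary (literature-stated) relation between regions of two maps.

    These statements are how competing and evolving parcellations are tied
    together; they are usually published by the paper that introduces the
    modified map, hence the ``ref`` literature source and the PDC.
    """

    region_a: RegionId
    region_b: RegionId
    code: RelationCode
    pdc: PDC = PDC.UNSTATED
    ref: str = ""

    def __str__(self) -> str:
        return f"{self.region_a} {self.code.value} {self.region_b} [{self.ref}]"


@dataclass(frozen=True)
class Injection:
    """One tracer injection: primary site, optional spillover, direction."""

    study_id: str
    injection_id: str
    direction: Direction
    primary_site: RegionId
    spillover_sites: tuple[RegionId, ...] = ()
    pdc: PDC = PDC.UNSTATED


@dataclass(frozen=True)
class LabeledSite:
    """Observed labeling in one region for one injection.

    ``density`` is ABSENT iff ``extent`` is N (an explicit negative finding).
    """

    study_id: str
    injection_id: str
    region: RegionId
    density: DensityCode
    extent: ExtentCode
    pdc: PDC = PDC.UNSTATED


@dataclass(frozen=True)
class Study:
    """The textual-statement record of one published tracing experiment."""

    study_id: str
    citation: str
    injections: tuple[Injection, ...] = ()
    labeled_sites: tuple[LabeledSite, ...] = ()


@dataclass(frozen=True)
class Dataset:
    """A complete input bundle: maps, inter-map relations, tracing studies."""

    maps: tuple[BrainMap, ...] = ()
    relations: tuple[InterMapRelation, ...] = ()
    studies: tuple[Study, ...] = ()

    def region_index(self) -> frozenset[RegionId]:
        return frozenset(r for m in self.maps for r in m.regions)

    def map_ids(self) -> frozenset[str]:
        return frozenset(m.map_id for m in self.maps)

    def regions_of(self, map_id: str) -> tuple[RegionId, ...]:
        for m in self.maps:
            if m.map_id == map_id:
                return m.regions
        from .errors import DomainError

        raise DomainError(f"unknown brain map {map_id!r}")

    def canonical(self) -> "Dataset":
        """Deterministically ordered copy (stable across runs and platforms).

        Maps sort by map_id, regions by acronym, relations and studies
        lexicographically; used by the writers to guarantee byte-stable
        output.
        """
        maps = tuple(
            BrainMap(
                m.map_id,
                tuple(sorted(m.regions, key=lambda r: r.acronym)),
                m.citation,
            )
            for m in sorted(self.maps, key=lambda m: m.map_id)
        )
        relations = tuple(
            sorted(
                self.relations,
                key=lambda r: (r.region_a, r.region_b, r.code.value, -r.pdc, r.ref),
            )
        )
        studies = tuple(
            Study(
                s.study_id,
                s.citation,
                tuple(sorted(s.injections, key=lambda i: i.injection_id)),
                tuple(
                    sorted(
                        s.labeled_sites,
                        key=lambda ls: (ls.injection_id, ls.region),
                    )
                ),
            )
            for s in sorted(self.studies, key=lambda s: s.study_id)
        )
        return Dataset(maps, relations, studies)
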