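"""ORT: propagation of tracing statements into a user-selected brain map.

A tracing study reports its injection and labeled sites in whatever
parcellation its authors used.  To combine studies, every statement must be
re-expressed in one target map.  The objective relational transformation
does this through resolved inter-map relations plus extent logic: e.g. if
region A is completely covered by labeled sites and B is a subregion of A,
then B is completely covered too.

The contract of every rule here is *soundness, not completeness*: a positive
(label present) or negative (label absent) claim is emitted only when the
set semantics of the relation forces it; anything else degrades to X
("present, extent undetermined") or U ("no information").
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Collection

from .errors import DomainError
from .model import (
    PDC,
    DensityCode,
    Direction,
    ExtentCode,
    Injection,
    LabeledSite,
    RegionId,
    RelationCode,
    Study,
)
from .relations import DerivedRelation, RelationMatrix

__all__ = [
    "Attribution",
    "OrtConfig",
    "SiteContribution",
    "InjectionAttribution",
    "ProjectedStatement",
    "extent_contribution",
    "combine_extents",
    "density_contribution",
    "transform_labeled_site",
    "transform_injection",
    "project_study",
]

_C, _P, _X, _N, _U = (
    ExtentCode.C,
    ExtentCode.P,
    ExtentCode.X,
    ExtentCode.N,
    ExtentCode.U,
)

# extent_contribution rule table.  Key: (relation of TARGET region relative
# to the SOURCE/labeled region, extent observed in the source region).
# Soundness rationale per row:
#   I: identical tissue, claim carries over verbatim.
#   S (target inside source): complete and none carry down; partial in the
#      source says nothing about which part, so only U is sound.
#   L (target contains source): any label in the source is label in the
#      target (X), but completeness never lifts; an empty source leaves the
#      rest of the target unknown (U).
#   O: a completely labeled source forces label into the shared tissue (X);
#      every other observation is uninformative about the target.
#   D: disjoint tissue, never informative.
_EXTENT_RULE: dict[tuple[RelationCode, ExtentCode], ExtentCode] = {}
for _e in ExtentCode:
    _EXTENT_RULE[(RelationCode.I, _e)] = _e
    _EXTENT_RULE[(RelationCode.D, _e)] = _U
_EXTENT_RULE.update(
    {
        (RelationCode.S, _C): _C,
        (RelationCode.S, _P): _U,
        (RelationCode.S, _X): _U,
        (RelationCode.S, _N): _N,
        (RelationCode.S, _U): _U,
        (RelationCode.L, _C): _X,
        (RelationCode.L, _P): _X,
        (RelationCode.L, _X): _X,
        (RelationCode.L, _N): _U,
        (RelationCode.L, _U): _U,
        (RelationCode.O, _C): _X,
        (RelationCode.O, _P): _U,
        (RelationCode.O, _X): _U,
        (RelationCode.O, _N): _U,
        (RelationCode.O, _U): _U,
    }
)


def extent_contribution(rel: RelationCode, e: ExtentCode) -> ExtentCode:
    """Extent forced in a target region related to a labeled source region.

    ``rel`` is the relation of the *target* region relative to the *source*
    (labeled) region.  Only claims forced by set semantics are emitted.
    """
    return _EXTENT_RULE[(rel, e)]


class Attribution(Enum):
    """Confidence with which a target region hosts an injection.

    EXACT — identical to an injected region; WITHIN — lies wholly inside
    injected territory; PARTIAL — shares some tissue with it (superregion or
    overlap).
    """

    EXACT = "EXACT"
    WITHIN = "WITHIN"
    PARTIAL = "PARTIAL"


_ATTRIBUTION_OF = {
    RelationCode.I: Attribution.EXACT,
    RelationCode.S: Attribution.WITHIN,
    RelationCode.L: Attribution.PARTIAL,
    RelationCode.O: Attribution.PARTIAL,
}

_ATTR_RANK = {Attribution.EXACT: 0, Attribution.WITHIN: 1, Attribution.PARTIAL: 2}


@dataclass(frozen=True)
class OrtConfig:
    """Tunable propagation behaviour.

    density_homogeneity
        When a target region is a subregion of a completely labeled source
        region, assume the source's density holds throughout and inherit it
        (flagged as inferred).  Mirrors common usage; turn off for strictly
        conservative output (density U instead).
    attribution_relations
        Which relation codes may attribute an injection to a target region.
        The full set is the permissive default; restrict to {I} (or {I, S})
        when only regions certainly inside the injected territory should
        count as projection sources.
    """

    density_homogeneity: bool = True
    attribution_relations: frozenset[RelationCode] = frozenset(
        {RelationCode.I, RelationCode.S, RelationCode.L, RelationCode.O}
    )


@dataclass(frozen=True)
class SiteContribution:
    """What one labeled site implies for one target-map region."""

    target: RegionId
    relation_used: RelationCode
    extent: ExtentCode
    density: DensityCode
    inferred: bool
    chain: DerivedRelation | None  # None for the identity contribution
    site: LabeledSite


@dataclass(frozen=True)
class InjectionAttribution:
    """One target-map region attributed as (part of) the injected territory."""

    region: RegionId
    attribution: Attribution
    relation_used: RelationCode
    injected_region: RegionId
    chain: DerivedRelation | None


@dataclass(frozen=True)
class ProjectedStatement:
    """A directed connection statement expressed in the target map.

    ``source`` is the region of projection origin and ``target`` the region
    of termination: for anterograde tracers the injection site projects to
    the labeled sites, for retrograde tracers the labeled sites project to
    the injection site.  ``pdc`` is the worst precision among every
    contributing statement (injection, site, and all relation links used):
    a chain is only as precise as its weakest link.
    """

    study_id: str
    injection_id: str
    source: RegionId
    target: RegionId
    density: DensityCode
    extent: ExtentCode
    attribution: Attribution
    pdc: PDC
    citation: str = ""
    direction: Direction = Direction.ANTEROGRADE
    site_contribution: SiteContribution | None = None
    injection_attribution: InjectionAttribution | None = None
    density_inferred: bool = False


def combine_extents(
    contribs: Collection[ExtentCode],
) -> tuple[ExtentCode, bool]:
    """Combine extent evidence from several sources for one region.

    Returns ``(extent, conflict)``.  Positive evidence dominates: C beats
    everything, then P, then X; an explicit N survives only in the absence
    of any positive claim; no evidence at all is U.  When both N and a
    positive code occur the positive code is returned and the conflict flag
    set — on oracle-consistent inputs this cannot happen, so the flag marks
    genuinely contradictory source data.
    """
    cs = set(contribs)
    conflict = _N in cs and any(c.is_positive for c in cs)
    for code in (_C, _P, _X, _N):
        if code in cs:
            return code, conflict
    return _U, conflict


def density_contribution(
    rel: RelationCode,
    extent_result: ExtentCode,
    d: DensityCode,
    homogeneity: bool = True,
) -> tuple[DensityCode, bool]:
    """Density implied for the target region; returns (density, inferred).

    Identity carries density over exactly.  A subregion of a completely
    labeled region inherits the source density only under the homogeneity
    assumption (flagged inferred); any other positive outcome is U since the
    fraction of label falling into the target is unknown; an N outcome is an
    explicit absence.
    """
    if rel is RelationCode.I:
        return d, False
    if extent_result is _N:
        return DensityCode.ABSENT, False
    if rel is RelationCode.S and extent_result is _C:
        if homogeneity:
            return d, True
        return DensityCode.PRESENT_UNKNOWN, False
    if extent_result.is_positive:
        return DensityCode.PRESENT_UNKNOWN, False
    return DensityCode.PRESENT_UNKNOWN, False


def transform_labeled_site(
    site: LabeledSite,
    target_map: str,
    m: RelationMatrix,
    config: OrtConfig | None = None,
    known_maps: Collection[str] | None = None,
) -> tuple[SiteContribution, ...]:
    """Re-express one labeled site in the target map.

    Emits one contribution per target-map region whose resolved relation to
    the site's region is known (plus the identity contribution when the site
    already lies in the target map).  Requires a resolved (conflict-free)
    matrix.
    """
    config = config or OrtConfig()
    if known_maps is not None and target_map not in known_maps:
        raise DomainError(f"unknown target map {target_map!r}")

    out: list[SiteContribution] = []
    if site.region.map_id == target_map:
        out.append(
            SiteContribution(
                target=site.region,
                relation_used=RelationCode.I,
                extent=site.extent,
                density=site.density,
                inferred=False,
                chain=None,
                site=site,
            )
        )
    for target, code in m.pairs_with_second(site.region):
        if target.map_id != target_map or target == site.region:
            continue
        extent = extent_contribution(code, site.extent)
        density, inferred = density_contribution(
            code, extent, site.density, config.density_homogeneity
        )
        support = m.support(target, site.region, code)
        out.append(
            SiteContribution(
                target=target,
                relation_used=code,
                extent=extent,
                density=density,
                inferred=inferred,
                chain=support[0] if support else None,
                site=site,
            )
        )
    return tuple(sorted(out, key=lambda c: c.target))


def transform_injection(
    inj: Injection,
    target_map: str,
    m: RelationMatrix,
    config: OrtConfig | None = None,
    known_maps: Collection[str] | None = None,
) -> tuple[InjectionAttribution, ...]:
    """Target-map regions attributed as hosting the injected territory.

    The injected territory is the primary site plus spillover.  A target
    region is attributed when its resolved relation to any injected region
    is one of the configured attribution codes: I → EXACT, S → WITHIN,
    L/O → PARTIAL.  Disjoint regions never attribute.  When several injected
    regions attribute the same target region, the strongest attribution is
    kept.
    """
    config = config or OrtConfig()
    if known_maps is not None and target_map not in known_maps:
        raise DomainError(f"unknown target map {target_map!r}")

    injected = (inj.primary_site,) + tuple(inj.spillover_sites)
    best: dict[RegionId, InjectionAttribution] = {}

    def offer(att: InjectionAttribution) -> None:
        cur = best.get(att.region)
        if cur is None or _ATTR_RANK[att.attribution] < _ATTR_RANK[cur.attribution]:
            best[att.region] = att

    for q in injected:
        if q.map_id == target_map and RelationCode.I in config.attribution_relations:
            offer(
                InjectionAttribution(
                    region=q,
                    attribution=Attribution.EXACT,
                    relation_used=RelationCode.I,
                    injected_region=q,
                    chain=None,
                )
            )
        for target, code in m.pairs_with_second(q):
            if target.map_id != target_map or target == q:
                continue
            if code not in config.attribution_relations or code is RelationCode.D:
                continue
            support = m.support(target, q, code)
            offer(
                InjectionAttribution(
                    region=target,
                    attribution=_ATTRIBUTION_OF[code],
                    relation_used=code,
                    injected_region=q,
                    chain=support[0] if support else None,
                )
            )
    return tuple(sorted(best.values(), key=lambda a: a.region))


def _chain_pdc(chain: DerivedRelation | None) -> PDC:
    return PDC.EXPLICIT if chain is None else chain.pdc


def project_study(
    s: Study,
    target_map: str,
    m: RelationMatrix,
    config: OrtConfig | None = None,
    known_maps: Collection[str] | None = None,
) -> tuple[ProjectedStatement, ...]:
    """All directed statements a study supports in the target map.

    Every injection is attributed to target regions, every labeled site with
    a determinate transformed extent is paired with each attributed region,
    and the tracer direction decides orientation: anterograde statements run
    injection → label, retrograde statements label → injection.  Sites whose
    transformed extent is N become explicit absence statements (density
    ABSENT) — a negative finding carries information; extent U contributes
    nothing.
    """
    config = config or OrtConfig()
    out: list[ProjectedStatement] = []
    sites_by_injection: dict[str, list[LabeledSite]] = {}
    for site in s.labeled_sites:
        sites_by_injection.setdefault(site.injection_id, []).append(site)

    for inj in s.injections:
        attributions = transform_injection(inj, target_map, m, config, known_maps)
        if not attributions:
            continue
        for site in sites_by_injection.get(inj.injection_id, ()):
            for contrib in transform_labeled_site(
                site, target_map, m, config, known_maps
            ):
                if contrib.extent is ExtentCode.U:
                    continue
                density = (
                    DensityCode.ABSENT
                    if contrib.extent is ExtentCode.N
                    else contrib.density
                )
                for att in attributions:
                    pdc = min(
                        inj.pdc,
                        site.pdc,
                        _chain_pdc(contrib.chain),
                        _chain_pdc(att.chain),
                    )
                    if inj.direction is Direction.ANTEROGRADE:
                        source, target = att.region, contrib.target
                    else:
                        source, target = contrib.target, att.region
                    out.append(
                        ProjectedStatement(
                            study_id=s.study_id,
                            injection_id=inj.injection_id,
                            source=source,
                            target=target,
                            density=density,
                            extent=contrib.extent,
                            attribution=att.attribution,
                            pdc=pdc,
                            citation=s.citation,
                            direction=inj.direction,
                            site_contribution=contrib,
                            injection_attribution=att,
                            density_inferred=contrib.inferred,
                        )
                    )
    return tuple(
        sorted(
            out,
            key=lambda st: (
                st.source,
                st.target,
                st.study_id,
                st.injection_id,
                st.extent.value,
                st.density.value,
            ),
        )
    )
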