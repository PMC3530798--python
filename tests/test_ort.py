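"""ORT propagation: extent/density rules, transforms, study projection."""

from __future__ import annotations

from itertools import product

import pytest

from ortex import (
    Attribution,
    DensityCode,
    Direction,
    ExtentCode,
    Injection,
    LabeledSite,
    OrtConfig,
    PDC,
    RelationCode,
    ResolutionPolicy,
    close_relations,
    combine_extents,
    density_contribution,
    extent_contribution,
    project_study,
    relation_from_sets,
    resolve_conflicts,
    transform_injection,
    transform_labeled_site,
)

from conftest import region, rel

I, S, L, O, D = RelationCode  # noqa: E741
C, P, X, N, U = ExtentCode


@pytest.mark.parametrize(
    "relation, extent, expected",
    [
        (S, C, C),  # complete coverage carries down into subregions
        (S, N, N),
        (S, P, U),
        (L, C, X),  # label must be present, completeness does not lift
        (L, P, X),
        (L, N, U),
        (O, C, X),
        (O, P, U),
        (D, C, U),
    ],
)
def test_extent_rule_table(relation, extent, expected):
    assert extent_contribution(relation, extent) is expected


@pytest.mark.parametrize("e", list(ExtentCode))
def test_identity_passes_extent_through(e):
    assert extent_contribution(I, e) is e


def test_extent_rules_are_sound_by_exhaustive_enumeration():
    """Every C/N/X claim holds in every atom-set model of the relation.

    Enumerates all (target, source, labeling) triples over a 4-atom
    universe; the observed source extent is fed through the rule and the
    claim checked against the actual label in the target.
    """
    atoms = range(4)
    subsets = [
        frozenset(s)
        for mask in range(1, 16)
        for s in [{i for i in atoms if mask >> i & 1}]
    ]
    labelings = [
        frozenset(s)
        for mask in range(16)
        for s in [{i for i in atoms if mask >> i & 1}]
    ]
    checked = 0
    for target, source, labeled in product(subsets, subsets, labelings):
        if target == source:
            relation = I
        else:
            relation = relation_from_sets(target, source)
        in_source = source & labeled
        if not in_source:
            observed = N
        elif in_source == source:
            observed = C
        else:
            observed = P
        claim = extent_contribution(relation, observed)
        in_target = target & labeled
        if claim is C:
            assert in_target == target, (target, source, labeled)
        elif claim is N:
            assert not in_target, (target, source, labeled)
        elif claim in (P, X):
            assert in_target, (target, source, labeled)
        checked += 1
    assert checked == 15 * 15 * 16


@pytest.mark.parametrize(
    "contribs, expected, conflict",
    [
        ([C], C, False),
        ([X, N], X, True),
        ([], U, False),
        ([N, N], N, False),
        ([P, X, U], P, False),
        ([C, N, P], C, True),
    ],
)
def test_combine_extents(contribs, expected, conflict):
    assert combine_extents(contribs) == (expected, conflict)


def test_density_rules():
    assert density_contribution(I, C, DensityCode.STRONG) == (
        DensityCode.STRONG,
        False,
    )
    # homogeneity: subregion of a completely labeled region inherits density
    assert density_contribution(S, C, DensityCode.MODERATE) == (
        DensityCode.MODERATE,
        True,
    )
    assert density_contribution(
        S, C, DensityCode.MODERATE, homogeneity=False
    ) == (DensityCode.PRESENT_UNKNOWN, False)
    assert density_contribution(O, X, DensityCode.STRONG) == (
        DensityCode.PRESENT_UNKNOWN,
        False,
    )
    assert density_contribution(S, N, DensityCode.ABSENT) == (
        DensityCode.ABSENT,
        False,
    )


def _resolved(relations):
    return resolve_conflicts(close_relations(relations), ResolutionPolicy())


def test_transform_site_identity_projection():
    b = region("M1", "B")
    site = LabeledSite("s", "i", b, DensityCode.STRONG, C, PDC.EXPLICIT)
    (contrib,) = transform_labeled_site(site, "M1", _resolved([]))
    assert contrib.target == b
    assert contrib.extent is C and contrib.density is DensityCode.STRONG
    assert contrib.relation_used is I and contrib.chain is None


def test_transform_site_complete_coverage_descends_to_subregion():
    a, a1 = region("M1", "A"), region("M2", "A1")
    m = _resolved([rel(a1, a, "S")])
    site = LabeledSite("s", "i", a, DensityCode.MODERATE, C, PDC.EXPLICIT)
    (contrib,) = transform_labeled_site(site, "M2", m)
    assert contrib.target == a1
    assert contrib.extent is C
    assert contrib.density is DensityCode.MODERATE and contrib.inferred


def test_transform_site_absence_does_not_cross_overlap():
    a, b2 = region("M1", "A"), region("M2", "B")
    m = _resolved([rel(b2, a, "O")])
    site = LabeledSite("s", "i", a, DensityCode.ABSENT, N, PDC.EXPLICIT)
    (contrib,) = transform_labeled_site(site, "M2", m)
    assert contrib.extent is U


def test_transform_site_unknown_target_map():
    from ortex import DomainError

    site = LabeledSite(
        "s", "i", region("M1", "B"), DensityCode.STRONG, C, PDC.EXPLICIT
    )
    with pytest.raises(DomainError):
        transform_labeled_site(site, "M9", _resolved([]), known_maps={"M1"})


def test_transform_injection_attributions():
    a = region("M1", "A")
    t_id, t_sub, t_over, t_dis = (
        region("M2", "TI"),
        region("M2", "TS"),
        region("M2", "TO"),
        region("M2", "TD"),
    )
    m = _resolved(
        [
            rel(t_id, a, "I"),
            rel(t_sub, a, "S"),
            rel(t_over, a, "O"),
            rel(t_dis, a, "D"),
        ]
    )
    inj = Injection("s", "i", Direction.ANTEROGRADE, a, (), PDC.EXPLICIT)
    atts = {x.region: x.attribution for x in transform_injection(inj, "M2", m)}
    assert atts == {
        t_id: Attribution.EXACT,
        t_sub: Attribution.WITHIN,
        t_over: Attribution.PARTIAL,
    }
    restricted = transform_injection(
        inj, "M2", m, OrtConfig(attribution_relations=frozenset({I, S}))
    )
    assert {x.region for x in restricted} == {t_id, t_sub}


def _native_study(direction=Direction.ANTEROGRADE, spillover=()):
    a, b, c = region("M1", "A"), region("M1", "B"), region("M1", "C")
    return (
        region("M1", "A"),
        (
            LabeledSite("s", "i", b, DensityCode.STRONG, C, PDC.EXPLICIT),
            LabeledSite("s", "i", c, DensityCode.ABSENT, N, PDC.EXPLICIT),
        ),
        direction,
        spillover,
    )


def _study_of(primary, sites, direction, spillover):
    from ortex import Study

    return Study(
        "s",
        "cite",
        (Injection("s", "i", direction, primary, tuple(spillover), PDC.EXPLICIT),),
        sites,
    )


def test_project_study_native_map_reproduces_statements():
    primary, sites, direction, spillover = _native_study()
    study = _study_of(primary, sites, direction, spillover)
    stmts = project_study(study, "M1", _resolved([]))
    assert {(s.source, s.target, s.density, s.extent) for s in stmts} == {
        (primary, sites[0].region, DensityCode.STRONG, C),
        (primary, sites[1].region, DensityCode.ABSENT, N),
    }
    assert all(s.attribution is Attribution.EXACT for s in stmts)


def test_retrograde_projection_transposes_statements():
    primary, sites, _, _ = _native_study()
    antero = project_study(
        _study_of(primary, sites, Direction.ANTEROGRADE, ()), "M1", _resolved([])
    )
    retro = project_study(
        _study_of(primary, sites, Direction.RETROGRADE, ()), "M1", _resolved([])
    )
    assert {(s.source, s.target) for s in retro} == {
        (t, s) for (s, t) in {(x.source, x.target) for x in antero}
    }


def test_spillover_attributes_second_source():
    primary, sites, direction, _ = _native_study()
    spill = region("M1", "D")
    study = _study_of(primary, sites, direction, (spill,))
    stmts = project_study(study, "M1", _resolved([]))
    assert {s.source for s in stmts} == {primary, spill}


def test_statement_pdc_is_worst_link():
    a, b, a2 = region("M1", "A"), region("M1", "B"), region("M2", "A2")
    m = _resolved([rel(a2, a, "S", pdc=PDC.TEXT_ONLY)])
    study = _study_of(
        a,
        (LabeledSite("s", "i", a, DensityCode.STRONG, C, PDC.EXPLICIT),),
        Direction.ANTEROGRADE,
        (),
    )
    stmts = project_study(study, "M2", m)
    # both source and target cross the TEXT_ONLY relation chain
    assert stmts and all(s.pdc is PDC.TEXT_ONLY for s in stmts)


def test_coarsening_relations_only_degrades_claims(atlas_suite):
    """Deleting relations never turns a determinate claim into a
    contradictory one; statements can only disappear or soften to X/U."""
    from ortex import Direction, simulate_study

    u, maps, rels, _ = atlas_suite[2]
    full = resolve_conflicts(close_relations(rels), ResolutionPolicy())
    thinned = resolve_conflicts(
        close_relations(rels[::2]), ResolutionPolicy()
    )
    target = maps[0]
    study = simulate_study(
        u, maps[-1], "R1", Direction.ANTEROGRADE, seed=3
    )
    strong = {C: C, N: N}
    full_claims = {
        (s.source, s.target): s.extent
        for s in project_study(study, target.map_id, full)
        if s.extent in strong
    }
    thin_claims = {
        (s.source, s.target): s.extent
        for s in project_study(study, target.map_id, thinned)
        if s.extent in strong
    }
    for key, extent in thin_claims.items():
        assert full_claims.get(key, extent) is extent
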