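"""Synthetic atlas generators: universes, partitions, corruption, simulation."""

from __future__ import annotations

import numpy as np
import pytest

from ortex import (
    CorruptionSpec,
    DensityCode,
    Direction,
    DomainError,
    ExtentCode,
    RelationCode,
    corrupt_relations,
    exact_relations,
    generate_lineage,
    generate_map,
    generate_universe,
    ground_truth_matrix,
    make_dataset,
    relation_from_sets,
    simulate_study,
    validate_dataset,
)
from ortex.synth import AtomMap, AtomUniverse


def test_universe_edge_prob_extremes():
    u0 = generate_universe(5, 0.0, seed=1)
    assert not u0.truth.any()
    u1 = generate_universe(5, 1.0, seed=1)
    off_diag = ~np.eye(5, dtype=bool)
    assert (u1.truth[off_diag] > 0).all()
    assert (np.diag(u1.truth) == 0).all()


def test_universe_seed_reproducibility():
    a = generate_universe(12, 0.3, seed=7)
    b = generate_universe(12, 0.3, seed=7)
    assert np.array_equal(a.truth, b.truth)
    c = generate_universe(12, 0.3, seed=8)
    assert not np.array_equal(a.truth, c.truth)


def test_universe_rejects_bad_args():
    with pytest.raises(DomainError):
        generate_universe(0, 0.5, seed=1)
    with pytest.raises(DomainError):
        generate_universe(5, 1.5, seed=1)


def test_generate_map_is_a_partition():
    u = generate_universe(20, 0.1, seed=2)
    m = generate_map(u, 6, seed=3)
    atoms = [a for p in m.regions.values() for a in p]
    assert sorted(atoms) == list(range(20))
    assert len(atoms) == len(set(atoms))
    assert all(p for p in m.regions.values())


def test_generate_map_extremes_and_errors():
    u = generate_universe(4, 0.1, seed=2)
    singletons = generate_map(u, 4, seed=1)
    assert all(len(p) == 1 for p in singletons.regions.values())
    whole = generate_map(u, 1, seed=1)
    assert set(whole.regions) == {"R1"}
    with pytest.raises(DomainError):
        generate_map(u, 5, seed=1)


def test_lineage_maps_partition_and_relate():
    u = generate_universe(30, 0.1, seed=4)
    maps = generate_lineage(u, 4, 6, seed=5)
    assert [m.map_id for m in maps] == ["M1", "M2", "M3", "M4"]
    for m in maps:
        assert sorted(a for p in m.regions.values() for a in p) == list(range(30))
    codes = {
        r.code
        for i in range(4)
        for j in range(i + 1, 4)
        for r in exact_relations(maps[i], maps[j], omit_disjoint=False)
    }
    # lineage evolution must exercise identity, nesting and disjointness
    assert {RelationCode.I, RelationCode.S, RelationCode.L, RelationCode.D} <= codes


def test_exact_relations_match_set_oracle_and_omit_disjoint():
    u = generate_universe(15, 0.1, seed=6)
    m1, m2 = generate_lineage(u, 2, 4, seed=7)
    rels = exact_relations(m1, m2, omit_disjoint=False)
    assert len(rels) == 16
    for r in rels:
        assert (
            relation_from_sets(
                m1.regions[r.region_a.acronym], m2.regions[r.region_b.acronym]
            )
            is r.code
        )
    sparse = exact_relations(m1, m2, omit_disjoint=True)
    assert all(r.code is not RelationCode.D for r in sparse)
    assert len(sparse) < len(rels)


def test_split_map_yields_subregions_of_parent():
    u = AtomUniverse(4, np.zeros((4, 4), dtype=np.uint8))
    parent = AtomMap("MA", {"A": frozenset({0, 1}), "B": frozenset({2, 3})})
    child = AtomMap(
        "MB",
        {"A1": frozenset({0}), "A2": frozenset({1}), "B": frozenset({2, 3})},
    )
    codes = {
        (r.region_a.acronym, r.region_b.acronym): r.code
        for r in exact_relations(child, parent)
    }
    assert codes == {
        ("A1", "A"): RelationCode.S,
        ("A2", "A"): RelationCode.S,
        ("B", "B"): RelationCode.I,
    }


def test_corruption_counts_and_manifest():
    u = generate_universe(40, 0.1, seed=8)
    maps = generate_lineage(u, 3, 8, seed=9)
    rels = [
        r
        for i in range(3)
        for j in range(i + 1, 3)
        for r in exact_relations(maps[i], maps[j])
    ]
    n = len(rels)
    spec = CorruptionSpec(drop_fraction=0.1, conflict_fraction=0.05, seed=10)
    out, manifest = corrupt_relations(rels, spec)
    assert len(manifest.dropped) == int(0.1 * n)
    assert len(manifest.altered) == int(0.05 * n)
    assert len(out) == n - len(manifest.dropped)
    for orig, new in manifest.altered:
        assert orig.code is not new.code
        assert (orig.region_a, orig.region_b) == (new.region_a, new.region_b)
    # reproducible
    out2, _ = corrupt_relations(rels, spec)
    assert out == out2


def test_corruption_noop_spec_returns_input():
    u = generate_universe(10, 0.1, seed=8)
    maps = generate_lineage(u, 2, 3, seed=9)
    rels = exact_relations(maps[0], maps[1])
    out, manifest = corrupt_relations(rels, CorruptionSpec(0, 0, seed=1))
    assert out == tuple(rels)
    assert manifest.dropped == () and manifest.altered == ()


def test_corruption_spec_validates_fractions():
    with pytest.raises(DomainError):
        CorruptionSpec(drop_fraction=1.2)


def test_simulate_study_hand_checked_single_edge():
    truth = np.zeros((2, 2), dtype=np.uint8)
    truth[0, 1] = 3  # atom 0 projects strongly to atom 1
    u = AtomUniverse(2, truth)
    m = AtomMap("M1", {"R1": frozenset({0}), "R2": frozenset({1})})

    antero = simulate_study(u, m, "R1", Direction.ANTEROGRADE, seed=1)
    by_region = {s.region.acronym: s for s in antero.labeled_sites}
    assert by_region["R2"].extent is ExtentCode.C
    assert by_region["R2"].density is DensityCode.STRONG
    assert by_region["R1"].extent is ExtentCode.N

    retro = simulate_study(u, m, "R2", Direction.RETROGRADE, seed=1)
    by_region = {s.region.acronym: s for s in retro.labeled_sites}
    assert by_region["R1"].extent is ExtentCode.C
    assert by_region["R2"].extent is ExtentCode.N


def test_simulate_study_on_empty_universe_reports_all_absent():
    u = generate_universe(8, 0.0, seed=1)
    m = generate_map(u, 3, seed=2)
    study = simulate_study(u, m, "R1", Direction.ANTEROGRADE, seed=3)
    assert all(s.extent is ExtentCode.N for s in study.labeled_sites)
    assert all(s.density is DensityCode.ABSENT for s in study.labeled_sites)


def test_simulate_study_is_seed_deterministic():
    u = generate_universe(10, 0.4, seed=1)
    m = generate_map(u, 3, seed=2)
    s1 = simulate_study(u, m, "R2", Direction.ANTEROGRADE, seed=5)
    s2 = simulate_study(u, m, "R2", Direction.ANTEROGRADE, seed=5)
    assert s1 == s2


def test_ground_truth_matrix_singleton_map_equals_atom_truth():
    u = generate_universe(6, 0.5, seed=11)
    m = generate_map(u, 6, seed=12)
    gt = ground_truth_matrix(u, m)
    atom_of = {acr: next(iter(p)) for acr, p in m.regions.items()}
    for (src, tgt), cell in gt.cells.items():
        expected = int(u.truth[atom_of[src.acronym], atom_of[tgt.acronym]])
        assert (cell.density.level or 0) == expected


def test_ground_truth_all_absent_universe():
    u = generate_universe(9, 0.0, seed=1)
    m = generate_map(u, 3, seed=2)
    gt = ground_truth_matrix(u, m)
    assert all(c.density is DensityCode.ABSENT for c in gt.cells.values())


def test_merging_regions_never_lowers_max_density():
    u = generate_universe(12, 0.3, seed=13)
    fine = generate_map(u, 6, seed=14)
    merged_parts = sorted(fine.regions.values(), key=min)
    coarse = AtomMap(
        "MC",
        {
            "R1": merged_parts[0] | merged_parts[1],
            "R2": merged_parts[2] | merged_parts[3],
            "R3": merged_parts[4] | merged_parts[5],
        },
    )
    gt_f = ground_truth_matrix(u, fine)
    gt_c = ground_truth_matrix(u, coarse)
    containing = {
        acr_f: acr_c
        for acr_f, pf in fine.regions.items()
        for acr_c, pc in coarse.regions.items()
        if pf <= pc
    }
    for (src, tgt), cell in gt_f.cells.items():
        coarse_cell = gt_c.cells[
            (coarse.region_id(containing[src.acronym]),
             coarse.region_id(containing[tgt.acronym]))
        ]
        assert (coarse_cell.density.level or 0) >= (cell.density.level or 0)


def test_make_dataset_is_valid():
    u = generate_universe(20, 0.2, seed=15)
    maps = generate_lineage(u, 3, 5, seed=16)
    rels = [
        r
        for i in range(3)
        for j in range(i + 1, 3)
        for r in exact_relations(maps[i], maps[j])
    ]
    studies = [
        simulate_study(u, maps[0], acr, Direction.ANTEROGRADE, seed=17)
        for acr in maps[0].sorted_acronyms()
    ]
    d = make_dataset(maps, rels, studies)
    report = validate_dataset(d)
    assert report.ok and not report.warnings
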