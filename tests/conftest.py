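"""Shared fixtures: hand-built micro-datasets and seeded synthetic atlases."""

from __future__ import annotations

import pytest

from ortex import (
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
    exact_relations,
    generate_lineage,
    generate_universe,
)


def region(map_id: str, acronym: str) -> RegionId:
    return RegionId(map_id, acronym)


def rel(a, b, code, pdc=PDC.EXPLICIT, ref="src") -> InterMapRelation:
    return InterMapRelation(a, b, RelationCode(code), pdc, ref)


@pytest.fixture
def two_map_dataset() -> Dataset:
    """Two maps over the same tissue: M2 splits M1's region A into A1/A2.

    One anterograde study in M1: injection in A, dense labeling in B,
    explicitly nothing in C.
    """
    a, b, c = region("M1", "A"), region("M1", "B"), region("M1", "C")
    a1, a2, b2, c2 = (
        region("M2", "A1"),
        region("M2", "A2"),
        region("M2", "B"),
        region("M2", "C"),
    )
    maps = (
        BrainMap("M1", (a, b, c), "atlas one"),
        BrainMap("M2", (a1, a2, b2, c2), "atlas two"),
    )
    relations = (
        rel(a1, a, "S"),
        rel(a2, a, "S"),
        rel(b2, b, "I"),
        rel(c2, c, "I"),
    )
    study = Study(
        study_id="st1",
        citation="virtual study 1",
        injections=(
            Injection("st1", "inj1", Direction.ANTEROGRADE, a, (), PDC.EXPLICIT),
        ),
        labeled_sites=(
            LabeledSite(
                "st1", "inj1", b, DensityCode.STRONG, ExtentCode.C, PDC.EXPLICIT
            ),
            LabeledSite(
                "st1", "inj1", c, DensityCode.ABSENT, ExtentCode.N, PDC.EXPLICIT
            ),
        ),
    )
    return Dataset(maps, relations, (study,)).canonical()


@pytest.fixture(scope="session")
def atlas_suite():
    """Seeded random synthetic atlases with exact relations, for oracle tests.

    Sizes span 10–50 atoms and 2–5 maps; each entry is (universe, maps,
    relations, atom_sets) with atom_sets indexing every region's ground
    truth atom membership.
    """
    suite = []
    for i in range(100):
        n_atoms = 10 + (i * 7) % 41
        n_maps = 2 + i % 4
        n_regions = min(3 + i % 5, n_atoms)
        u = generate_universe(n_atoms, edge_prob=0.2, seed=1000 + i)
        maps = generate_lineage(u, n_maps, n_regions, seed=2000 + i)
        rels = [
            r
            for a in range(len(maps))
            for b in range(a + 1, len(maps))
            for r in exact_relations(maps[a], maps[b])
        ]
        atom_sets = {
            m.region_id(acr): m.regions[acr] for m in maps for acr in m.regions
        }
        suite.append((u, maps, tuple(rels), atom_sets))
    return suite
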