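"""Synthetic atlases with atom-level ground truth.

Real tracing literature degrades cellular-resolution results to textual
statements about named regions.  This module builds the reverse direction
for testing: an *atom universe* of indivisible tissue units with known
micro-connectivity, several parcellations of it (each region a disjoint
atom set), exact or deliberately corrupted inter-map relations, and
simulated tracing studies rendered as the same textual statements the
engine ingests.  Because region membership and connectivity are known at
the atom level, every relational and propagation inference the engine makes
can be checked against exact set semantics.

Maps can be drawn independently at random, but real nomenclatures evolve by
splitting and merging predecessors' regions; :func:`generate_lineage`
emulates that, which is what makes identity/subregion chains (and hence
non-trivial closure) common, as they are in the literature.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import DomainError
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
    Study,
)
from .relations import relation_from_sets

__all__ = [
    "AtomUniverse",
    "AtomMap",
    "CorruptionSpec",
    "CorruptionManifest",
    "generate_universe",
    "generate_map",
    "generate_lineage",
    "exact_relations",
    "corrupt_relations",
    "simulate_study",
    "ground_truth_matrix",
    "make_dataset",
]

_DENSITY_BY_LEVEL = {
    0: DensityCode.ABSENT,
    1: DensityCode.WEAK,
    2: DensityCode.MODERATE,
    3: DensityCode.STRONG,
}


@dataclass(frozen=True)
class AtomUniverse:
    """Ground-truth substrate: n atoms and their directed micro-connectivity.

    ``truth[i, j]`` holds the ordinal density (0–3) of the projection from
    atom i to atom j; the diagonal is 0 (no atom-level self-projection).
    """

    n_atoms: int
    truth: np.ndarray  # (n, n) uint8, levels 0..3

    def density(self, i: int, j: int) -> DensityCode:
        return _DENSITY_BY_LEVEL[int(self.truth[i, j])]


@dataclass(frozen=True)
class AtomMap:
    """A parcellation of the universe: acronym -> disjoint non-empty atom set.

    The union need not cover every atom (partial maps are legal), though the
    generators here produce full coverings.
    """

    map_id: str
    regions: Mapping[str, frozenset[int]]

    def region_id(self, acronym: str) -> RegionId:
        return RegionId(self.map_id, acronym)

    def atoms_of(self, acronym: str) -> frozenset[int]:
        try:
            return self.regions[acronym]
        except KeyError:
            raise DomainError(
                f"unknown region {acronym!r} in map {self.map_id!r}"
            ) from None

    def sorted_acronyms(self) -> list[str]:
        return sorted(self.regions)


@dataclass(frozen=True)
class CorruptionSpec:
    """Statement-level degradation applied to exact relations.

    ``drop_fraction`` of relations are withheld (sparse literature);
    ``conflict_fraction`` have their code replaced by a uniformly chosen
    *different* code (collation errors).  The published observation that a
    few percent of collated relations conflict motivates the default scale
    used in tests.
    """

    drop_fraction: float = 0.0
    conflict_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("drop_fraction", "conflict_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise DomainError(f"{name} must be in [0, 1], got {v}")


@dataclass(frozen=True)
class CorruptionManifest:
    """Exactly which relations were dropped or altered (for assertions)."""

    dropped: tuple[InterMapRelation, ...]
    altered: tuple[tuple[InterMapRelation, InterMapRelation], ...]  # (orig, new)


def generate_universe(
    n_atoms: int, edge_prob: float, seed: int
) -> AtomUniverse:
    """Random micro-connectivity: each ordered atom pair connects with
    probability ``edge_prob``, density uniform over weak/moderate/strong."""
    if n_atoms < 1:
        raise DomainError(f"n_atoms must be >= 1, got {n_atoms}")
    if not 0.0 <= edge_prob <= 1.0:
        raise DomainError(f"edge_prob must be in [0, 1], got {edge_prob}")
    rng = np.random.default_rng(seed)
    present = rng.random((n_atoms, n_atoms)) < edge_prob
    levels = rng.integers(1, 4, size=(n_atoms, n_atoms), dtype=np.uint8)
    truth = np.where(present, levels, 0).astype(np.uint8)
    np.fill_diagonal(truth, 0)
    return AtomUniverse(n_atoms=n_atoms, truth=truth)


def _name_partition(map_id: str, parts: Iterable[frozenset[int]]) -> AtomMap:
    # Deterministic naming: regions ordered by their smallest atom.
    ordered = sorted(parts, key=min)
    return AtomMap(
        map_id=map_id,
        regions={f"R{i + 1}": frozenset(p) for i, p in enumerate(ordered)},
    )


def generate_map(
    u: AtomUniverse, n_regions: int, seed: int, map_id: str = "M1"
) -> AtomMap:
    """Random partition of all atoms into ``n_regions`` non-empty regions."""
    if not 1 <= n_regions <= u.n_atoms:
        raise DomainError(
            f"n_regions must be in [1, {u.n_atoms}], got {n_regions}"
        )
    rng = np.random.default_rng(seed)
    atoms = rng.permutation(u.n_atoms)
    # n_regions-1 distinct cut points yield non-empty contiguous blocks.
    cuts = (
        np.sort(rng.choice(np.arange(1, u.n_atoms), n_regions - 1, replace=False))
        if n_regions > 1
        else np.array([], dtype=int)
    )
    parts = [frozenset(int(a) for a in blk) for blk in np.split(atoms, cuts)]
    return _name_partition(map_id, parts)


def generate_lineage(
    u: AtomUniverse,
    n_maps: int,
    n_regions: int,
    seed: int,
    churn: int | None = None,
) -> list[AtomMap]:
    """A family of parcellations related by splitting and merging.

    The first map is a random partition; each successor applies ``churn``
    region splits and ``churn`` merges of random region pairs (keeping the
    region count constant), the way nomenclatures historically evolve.
    Untouched regions stay identical across maps, splits create subregion /
    superregion relations, and split-then-merge across steps creates partial
    overlaps — together exercising every relation code.
    """
    if n_maps < 1:
        raise DomainError(f"n_maps must be >= 1, got {n_maps}")
    if churn is None:
        churn = max(1, n_regions // 5)
    rng = np.random.default_rng(seed)
    maps = [generate_map(u, n_regions, seed, map_id="M1")]
    parts = sorted(maps[0].regions.values(), key=min)
    for k in range(2, n_maps + 1):
        parts = [set(p) for p in parts]
        for _ in range(churn):
            # split a random region with >= 2 atoms
            candidates = [i for i, p in enumerate(parts) if len(p) >= 2]
            if not candidates:
                break
            i = int(rng.choice(candidates))
            atoms = sorted(parts[i])
            k_split = int(rng.integers(1, len(atoms)))
            chosen = rng.choice(len(atoms), size=k_split, replace=False)
            piece = {atoms[c] for c in chosen}
            parts[i] -= piece
            parts.append(piece)
        for _ in range(churn):
            if len(parts) < 2:
                break
            i, j = (int(x) for x in rng.choice(len(parts), size=2, replace=False))
            merged = parts[i] | parts[j]
            parts = [p for idx, p in enumerate(parts) if idx not in (i, j)]
            parts.append(merged)
        frozen = [frozenset(p) for p in parts]
        maps.append(_name_partition(f"M{k}", frozen))
        parts = sorted(frozen, key=min)
    return maps


def exact_relations(
    a: AtomMap,
    b: AtomMap,
    omit_disjoint: bool = True,
    pdc: PDC = PDC.EXPLICIT,
) -> tuple[InterMapRelation, ...]:
    """Oracle-exact relations for every cross-map region pair.

    Disjoint pairs are omitted by default — the literature states relations
    between regions that occupy shared territory, and rarely bothers to
    declare unrelated regions disjoint.
    """
    if a.map_id == b.map_id:
        raise DomainError("exact_relations needs two distinct maps")
    ref = f"atlas:{a.map_id}-{b.map_id}"
    out = []
    for ra in a.sorted_acronyms():
        for rb in b.sorted_acronyms():
            code = relation_from_sets(a.regions[ra], b.regions[rb])
            if omit_disjoint and code.value == "D":
                continue
            out.append(
                InterMapRelation(
                    region_a=a.region_id(ra),
                    region_b=b.region_id(rb),
                    code=code,
                    pdc=pdc,
                    ref=ref,
                )
            )
    return tuple(out)


def corrupt_relations(
    rels: Sequence[InterMapRelation], spec: CorruptionSpec
) -> tuple[tuple[InterMapRelation, ...], CorruptionManifest]:
    """Degrade a relation list per the spec; returns (relations, manifest).

    Drops ``floor(drop_fraction * n)`` relations uniformly at random, then
    replaces the codes of ``floor(conflict_fraction * n)`` of the remaining
    ones with a uniformly chosen different code.  Fully reproducible per
    seed; the manifest lists every injected error so tests can assert
    detection.
    """
    from .model import RelationCode

    rng = np.random.default_rng(spec.seed)
    rels = list(rels)
    n = len(rels)
    n_drop = int(spec.drop_fraction * n)
    n_alter = int(spec.conflict_fraction * n)
    order = list(rng.permutation(n)) if n else []
    drop_idx = set(order[:n_drop])
    alter_idx = set(order[n_drop : n_drop + n_alter])

    codes = list(RelationCode)
    kept: list[InterMapRelation] = []
    dropped: list[InterMapRelation] = []
    altered: list[tuple[InterMapRelation, InterMapRelation]] = []
    for i, rel in enumerate(rels):
        if i in drop_idx:
            dropped.append(rel)
            continue
        if i in alter_idx:
            others = [c for c in codes if c is not rel.code]
            new_code = others[int(rng.integers(len(others)))]
            new_rel = InterMapRelation(
                rel.region_a, rel.region_b, new_code, rel.pdc, rel.ref
            )
            altered.append((rel, new_rel))
            kept.append(new_rel)
        else:
            kept.append(rel)
    return tuple(kept), CorruptionManifest(tuple(dropped), tuple(altered))


def simulate_study(
    u: AtomUniverse,
    m: AtomMap,
    injected_region: str,
    direction: Direction,
    seed: int,
    pdc: PDC = PDC.EXPLICIT,
    density_u_fraction: float = 0.0,
) -> Study:
    """Render one virtual tracing experiment as textual statements.

    The tracer fills every atom of the injected region.  Anterograde
    transport labels each atom receiving a projection from the injected
    atoms; retrograde labels each atom projecting into them.  Per region of
    the study's own map, extent is C when all its atoms are labeled, P when
    some are, N when none; density is the strongest labeled atom in the
    region (hot spots dominate textual "dense labeling" statements).  With
    ``density_u_fraction`` > 0, that fraction of positive sites is reported
    with unquantified density, as the literature often does.
    """
    atoms = sorted(m.atoms_of(injected_region))
    if direction is Direction.ANTEROGRADE:
        labeled = u.truth[atoms, :].max(axis=0)
    else:
        labeled = u.truth[:, atoms].max(axis=1)

    rng = np.random.default_rng(seed)
    study_id = f"{m.map_id}-{injected_region}-{direction.value[:1]}"
    injection_id = "inj1"
    injection = Injection(
        study_id=study_id,
        injection_id=injection_id,
        direction=direction,
        primary_site=m.region_id(injected_region),
        spillover_sites=(),
        pdc=pdc,
    )
    sites = []
    for acronym in m.sorted_acronyms():
        ratoms = sorted(m.regions[acronym])
        values = labeled[ratoms]
        n_pos = int((values > 0).sum())
        if n_pos == 0:
            extent, density = ExtentCode.N, DensityCode.ABSENT
        else:
            extent = ExtentCode.C if n_pos == len(ratoms) else ExtentCode.P
            density = _DENSITY_BY_LEVEL[int(values.max())]
            if density_u_fraction and rng.random() < density_u_fraction:
                density = DensityCode.PRESENT_UNKNOWN
        sites.append(
            LabeledSite(
                study_id=study_id,
                injection_id=injection_id,
                region=m.region_id(acronym),
                density=density,
                extent=extent,
                pdc=pdc,
            )
        )
    return Study(
        study_id=study_id,
        citation=f"synthetic tracing of {m.map_id}:{injected_region} "
        f"({direction.value.lower()})",
        injections=(injection,),
        labeled_sites=tuple(sites),
    )


def ground_truth_matrix(u: AtomUniverse, m: AtomMap):
    """The exact macro-connectome of a map, straight from atom truth.

    Cell (R, S): density is the strongest atom-to-atom projection from R
    into S (ABSENT when there is none); extent describes how completely S
    receives label from R — C when every atom of S receives a projection
    from R, P when some do, N when none.  This matches what a perfect
    anterograde experiment injected into R would report for S.
    """
    from .builder import AggregationPolicy, ConnectivityMatrix, MatrixCell

    acronyms = m.sorted_acronyms()
    cells: dict[tuple[RegionId, RegionId], MatrixCell] = {}
    for ra in acronyms:
        src_atoms = sorted(m.regions[ra])
        received = u.truth[src_atoms, :].max(axis=0)
        for rb in acronyms:
            tgt_atoms = sorted(m.regions[rb])
            values = received[tgt_atoms]
            n_pos = int((values > 0).sum())
            if n_pos == 0:
                density, extent = DensityCode.ABSENT, ExtentCode.N
            else:
                density = _DENSITY_BY_LEVEL[int(values.max())]
                extent = (
                    ExtentCode.C if n_pos == len(tgt_atoms) else ExtentCode.P
                )
            key = (m.region_id(ra), m.region_id(rb))
            cells[key] = MatrixCell(
                source=key[0],
                target=key[1],
                density=density,
                extent=extent,
                n_statements=0,
                conflict=False,
                statements=(),
                contributing=(),
            )
    return ConnectivityMatrix(
        target_map=m.map_id,
        cells=cells,
        policy_used=AggregationPolicy(),
        regions=tuple(m.region_id(a) for a in acronyms),
    )


def make_dataset(
    maps: Sequence[AtomMap],
    relations: Sequence[InterMapRelation] = (),
    studies: Sequence[Study] = (),
) -> Dataset:
    """Assemble the engine-facing dataset for a synthetic atlas."""
    brain_maps = tuple(
        BrainMap(
            map_id=m.map_id,
            regions=tuple(m.region_id(a) for a in m.sorted_acronyms()),
            citation=f"synthetic parcellation {m.map_id}",
        )
        for m in maps
    )
    return Dataset(
        maps=brain_maps, relations=tuple(relations), studies=tuple(studies)
    ).canonical()
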