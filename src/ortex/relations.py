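"""Qualitative relation calculus over brain parcellations.

Regions of competing brain maps are related by the five RCC5 codes
(identical, proper subregion, proper superregion, partial overlap,
disjoint).  Primary relations come from the literature; this module closes
them under composition to an all-pairs relation structure, detects pairs for
which the literature (or its collation) is self-contradictory, and resolves
such conflicts under a configurable policy — including the two historically
used precedences (identity-wins and subregion-wins).

The composition table is grounded set-theoretically: regions are modelled as
non-empty atom sets and ``compose_codes(c1, c2)`` returns exactly the codes
realizable for (A, C) given A c1 B and B c2 C.  The shipped table is a frozen
literal, but :func:`composition_table_by_enumeration` recomputes it by brute
force over small universes so tests can machine-verify every entry rather
than trust a transcription.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from enum import Enum
from typing import AbstractSet, Collection, Mapping

from .errors import ConflictError, DomainError
from .model import PDC, InterMapRelation, RegionId, RelationCode

__all__ = [
    "RelationCodeSet",
    "DerivedRelation",
    "Conflict",
    "RelationMatrix",
    "PolicyKind",
    "ResolutionPolicy",
    "invert_code",
    "compose_codes",
    "relation_from_sets",
    "composition_table_by_enumeration",
    "close_relations",
    "detect_conflicts",
    "resolve_conflicts",
    "ALL_CODES",
]

_I, _S, _L, _O, _D = (
    RelationCode.I,
    RelationCode.S,
    RelationCode.L,
    RelationCode.O,
    RelationCode.D,
)

ALL_CODES: frozenset[RelationCode] = frozenset(RelationCode)

#: Canonical code order used for deterministic reports and tie-breaking.
CODE_ORDER = {_I: 0, _S: 1, _L: 2, _O: 3, _D: 4}

RelationCodeSet = frozenset  # non-empty subset of the five codes

_INVERSE = {_I: _I, _S: _L, _L: _S, _O: _O, _D: _D}


def invert_code(c: RelationCode) -> RelationCode:
    """Converse relation: ``A c B`` iff ``B invert(c) A``.  An involution."""
    return _INVERSE[c]


def _cs(codes: str) -> frozenset[RelationCode]:
    return frozenset(RelationCode(ch) for ch in codes)


# RCC5 composition: A c1 B and B c2 C constrain A ? C to exactly this set.
# Machine-verified against composition_table_by_enumeration (see tests);
# 5 atoms suffice to realize every listed outcome.
_COMPOSE: dict[tuple[RelationCode, RelationCode], frozenset[RelationCode]] = {
    (_I, _I): _cs("I"),
    (_I, _S): _cs("S"),
    (_I, _L): _cs("L"),
    (_I, _O): _cs("O"),
    (_I, _D): _cs("D"),
    (_S, _I): _cs("S"),
    (_S, _S): _cs("S"),
    (_S, _L): _cs("ISLOD"),
    (_S, _O): _cs("SOD"),
    (_S, _D): _cs("D"),
    (_L, _I): _cs("L"),
    (_L, _S): _cs("ISLO"),
    (_L, _L): _cs("L"),
    (_L, _O): _cs("LO"),
    (_L, _D): _cs("LOD"),
    (_O, _I): _cs("O"),
    (_O, _S): _cs("SO"),
    (_O, _L): _cs("LOD"),
    (_O, _O): _cs("ISLOD"),
    (_O, _D): _cs("LOD"),
    (_D, _I): _cs("D"),
    (_D, _S): _cs("SOD"),
    (_D, _L): _cs("D"),
    (_D, _O): _cs("SOD"),
    (_D, _D): _cs("ISLOD"),
}


def compose_codes(c1: RelationCode, c2: RelationCode) -> frozenset[RelationCode]:
    """Codes realizable for (A, C) given ``A c1 B`` and ``B c2 C``.

    A singleton result is a determinate inference ("a subregion of a
    subregion is still a subregion"); larger sets mean the configuration is
    underdetermined and nothing is propagated.
    """
    return _COMPOSE[(c1, c2)]


def relation_from_sets(a: AbstractSet, b: AbstractSet) -> RelationCode:
    """The set-theoretic oracle grounding the calculus.

    I iff a == b; S iff a ⊊ b; L iff a ⊋ b; D iff a ∩ b = ∅; O otherwise.
    Exactly one code applies to any pair of non-empty sets.
    """
    if not a or not b:
        raise DomainError("regions must be non-empty atom sets")
    if a == b:
        return _I
    if a < b:
        return _S
    if a > b:
        return _L
    if not (a & b):
        return _D
    return _O


def composition_table_by_enumeration(
    max_atoms: int = 5,
) -> dict[tuple[RelationCode, RelationCode], frozenset[RelationCode]]:
    """Recompute the composition table by exhaustive set enumeration.

    Enumerates all triples (A, B, C) of non-empty subsets of universes of
    1..max_atoms atoms and collects, for each (rel(A,B), rel(B,C)), the set
    of observed rel(A,C).  Independent of the frozen table by construction.
    """
    table: dict[tuple[RelationCode, RelationCode], set[RelationCode]] = {
        (c1, c2): set() for c1 in RelationCode for c2 in RelationCode
    }
    for n in range(1, max_atoms + 1):
        subsets = [
            frozenset(i for i in range(n) if mask >> i & 1)
            for mask in range(1, 1 << n)
        ]
        for a, b, c in itertools.product(subsets, repeat=3):
            table[(relation_from_sets(a, b), relation_from_sets(b, c))].add(
                relation_from_sets(a, c)
            )
    return {k: frozenset(v) for k, v in table.items()}


@dataclass(frozen=True)
class DerivedRelation:
    """A relation claim supported by a chain of primary statements.

    ``chain`` is the ordered sequence of primary inter-map relations whose
    composition yields ``code``; a chain of length 1 is (the possibly
    inverted reading of) a primary statement itself.  Chains are the
    provenance that lets any derived claim be traced back to literature
    sources.
    """

    region_a: RegionId
    region_b: RegionId
    code: RelationCode
    chain: tuple[InterMapRelation, ...]

    @property
    def primary(self) -> bool:
        return len(self.chain) == 1

    @property
    def pdc(self) -> PDC:
        """Precision of the whole chain = its least precise link."""
        return min((link.pdc for link in self.chain), default=PDC.UNSTATED)


@dataclass(frozen=True)
class Conflict:
    """A region pair supported by two or more distinct determinate codes."""

    region_a: RegionId
    region_b: RegionId
    competing: Mapping[RelationCode, tuple[DerivedRelation, ...]]

    def codes(self) -> frozenset[RelationCode]:
        return frozenset(self.competing)

    def core_statements(self) -> tuple[InterMapRelation, ...]:
        """The primary statements involved, deduplicated and ordered."""
        seen: dict[InterMapRelation, None] = {}
        for derivs in self.competing.values():
            for d in derivs:
                for link in d.chain:
                    seen.setdefault(link, None)
        return tuple(
            sorted(seen, key=lambda r: (r.region_a, r.region_b, r.code.value))
        )


class PolicyKind(Enum):
    IDENTITY_PREFERENCE = "identity"
    SUBREGION_PREFERENCE = "subregion"
    STRICT = "strict"
    REPORT_ONLY = "report"


@dataclass(frozen=True)
class ResolutionPolicy:
    """How conflicting relation codes for a pair are reduced to one.

    IDENTITY_PREFERENCE keeps an identity claim when present (the historical
    default); SUBREGION_PREFERENCE lets subregion claims prevail over
    identity; STRICT refuses to resolve; REPORT_ONLY leaves the matrix
    untouched.  When the headline preference does not decide, and
    ``pdc_tiebreak`` is on, the code with the most precisely described
    supporting chain wins; remaining ties fall to shortest chain, then to
    the fixed code order I < S < L < O < D.
    """

    kind: PolicyKind = PolicyKind.IDENTITY_PREFERENCE
    pdc_tiebreak: bool = True


@dataclass
class RelationMatrix:
    """All-pairs relation structure with full provenance.

    ``entries`` maps an ordered region pair to, per determinate code, the
    tuple of supporting derived relations.  The structure is inverse
    symmetric: (B, A) carries the inverted codes of (A, B).  After closure a
    pair may carry several competing codes; after resolution under any
    non-report policy each pair carries at most one.
    """

    entries: dict[
        tuple[RegionId, RegionId],
        dict[RelationCode, tuple[DerivedRelation, ...]],
    ] = field(default_factory=dict)
    conflicts: tuple[Conflict, ...] = ()
    max_chain: int = 8

    def codes_for(self, a: RegionId, b: RegionId) -> frozenset[RelationCode]:
        return frozenset(self.entries.get((a, b), ()))

    def code(self, a: RegionId, b: RegionId) -> RelationCode | None:
        """The resolved code for (a, b), or None if absent/ambiguous."""
        codes = self.entries.get((a, b))
        if not codes or len(codes) > 1:
            return None
        return next(iter(codes))

    def support(
        self, a: RegionId, b: RegionId, code: RelationCode
    ) -> tuple[DerivedRelation, ...]:
        return self.entries.get((a, b), {}).get(code, ())

    @property
    def is_resolved(self) -> bool:
        return all(len(codes) == 1 for codes in self.entries.values())

    def pairs_with_second(
        self, b: RegionId
    ) -> tuple[tuple[RegionId, RelationCode], ...]:
        """(first region, code) for every determinate entry ending at b.

        Backed by a lazily built index; the matrix must not be mutated
        after first use.
        """
        index = self.__dict__.get("_by_second_index")
        if index is None:
            index: dict[RegionId, list] = {}
            for (x, y), codes in self.entries.items():
                if len(codes) == 1:
                    index.setdefault(y, []).append((x, next(iter(codes))))
            index = {k: tuple(v) for k, v in index.items()}
            self.__dict__["_by_second_index"] = index
        return index.get(b, ())


def _chain_key(chain: tuple[InterMapRelation, ...]):
    return (
        len(chain),
        tuple(
            (r.region_a, r.region_b, r.code.value, int(r.pdc), r.ref)
            for r in chain
        ),
    )


def close_relations(
    relations: Collection[InterMapRelation], max_chain: int = 8
) -> RelationMatrix:
    """Fixed-point closure of primary relations under RCC5 composition.

    Seeds the matrix with every primary statement and its converse, then
    repeatedly composes adjacent determinate claims, recording a derived
    relation only when the composed code set is a singleton.  Iteration is
    round-based (semi-naive): a round composes every claim discovered in the
    previous round against everything known, so the result depends only on
    the set of inputs, never on their order.  Chains longer than
    ``max_chain`` primary links are not pursued, which guarantees
    termination even on cyclic, self-contradictory inputs; supporting chains
    are retained per (pair, code) for provenance, recorded in the round in
    which that (pair, code) claim is first derived.
    """
    if max_chain < 1:
        raise DomainError(f"max_chain must be >= 1, got {max_chain}")

    entries: dict[
        tuple[RegionId, RegionId], dict[RelationCode, list]
    ] = {}

    def add(a, b, code, chain) -> bool:
        codes = entries.setdefault((a, b), {})
        is_new = code not in codes
        if is_new:
            codes[code] = [chain]
        return is_new

    def add_chain(a, b, code, chain) -> None:
        chains = entries[(a, b)][code]
        if chain not in chains:
            chains.append(chain)

    frontier: set[tuple[RegionId, RegionId]] = set()
    for rel in relations:
        if rel.region_a == rel.region_b:
            continue
        add(rel.region_a, rel.region_b, rel.code, (rel,))
        add_chain(rel.region_a, rel.region_b, rel.code, (rel,))
        add(rel.region_b, rel.region_a, invert_code(rel.code), (rel,))
        add_chain(rel.region_b, rel.region_a, invert_code(rel.code), (rel,))
        frontier.add((rel.region_a, rel.region_b))
        frontier.add((rel.region_b, rel.region_a))

    by_first: dict[RegionId, set[tuple[RegionId, RegionId]]] = {}
    by_second: dict[RegionId, set[tuple[RegionId, RegionId]]] = {}
    for pair in entries:
        by_first.setdefault(pair[0], set()).add(pair)
        by_second.setdefault(pair[1], set()).add(pair)

    while frontier:
        # For each (A,B) in the frontier: compose with (B,C) on the right
        # and (Z,A) on the left.  Both factors' codes are taken claim by
        # claim, so competing codes each propagate their own consequences.
        produced: dict[
            tuple[RegionId, RegionId, RelationCode],
            list,
        ] = {}

        def consider(left_pair, right_pair):
            a, b = left_pair
            b2, c = right_pair
            if a == c:
                return
            for c1, chains1 in entries[left_pair].items():
                for c2, chains2 in entries[right_pair].items():
                    composed = _COMPOSE[(c1, c2)]
                    if len(composed) != 1:
                        continue
                    (code,) = composed
                    for ch1 in chains1:
                        for ch2 in chains2:
                            if len(ch1) + len(ch2) > max_chain:
                                continue
                            produced.setdefault((a, c, code), []).append(
                                ch1 + ch2
                            )

        for pair in frontier:
            for right in by_first.get(pair[1], ()):
                consider(pair, right)
            for left in by_second.get(pair[0], ()):
                if left not in frontier:  # frontier x frontier done above
                    consider(left, pair)

        # Canonicalize to unordered pairs and sort before insertion so the
        # recorded chains are identical regardless of input order or hash
        # randomization.
        merged: dict[tuple[RegionId, RegionId, RelationCode], set] = {}
        for (a, c, code), chains in produced.items():
            if (a, c) <= (c, a):
                merged.setdefault((a, c, code), set()).update(chains)
            else:
                merged.setdefault((c, a, invert_code(code)), set()).update(
                    tuple(reversed(ch)) for ch in chains
                )

        frontier = set()
        for a, c, code in sorted(
            merged, key=lambda k: (k[0], k[1], CODE_ORDER[k[2]])
        ):
            chains = sorted(merged[(a, c, code)], key=_chain_key)
            if add(a, c, code, chains[0]):
                inv = invert_code(code)
                add(c, a, inv, tuple(reversed(chains[0])))
                for ch in chains:
                    add_chain(a, c, code, ch)
                    add_chain(c, a, inv, tuple(reversed(ch)))
                frontier.add((a, c))
                frontier.add((c, a))
                for pair in ((a, c), (c, a)):
                    by_first.setdefault(pair[0], set()).add(pair)
                    by_second.setdefault(pair[1], set()).add(pair)

    final: dict[
        tuple[RegionId, RegionId],
        dict[RelationCode, tuple[DerivedRelation, ...]],
    ] = {}
    for (a, b), codes in entries.items():
        final[(a, b)] = {
            code: tuple(
                DerivedRelation(a, b, code, ch)
                for ch in sorted(chains, key=_chain_key)
            )
            for code, chains in sorted(
                codes.items(), key=lambda kv: CODE_ORDER[kv[0]]
            )
        }
    m = RelationMatrix(entries=final, max_chain=max_chain)
    m.conflicts = detect_conflicts(m)
    return m


def detect_conflicts(m: RelationMatrix) -> tuple[Conflict, ...]:
    """One conflict per unordered pair carrying >= 2 determinate codes.

    Each conflict retains every supporting chain, so the core primary
    statements involved can be read off; output is sorted lexicographically
    by region for reproducible reports.
    """
    out = []
    for (a, b), codes in m.entries.items():
        if len(codes) < 2 or (b, a) < (a, b):
            continue
        out.append(
            Conflict(
                a,
                b,
                {
                    code: derivs
                    for code, derivs in sorted(
                        codes.items(), key=lambda kv: CODE_ORDER[kv[0]]
                    )
                },
            )
        )
    return tuple(sorted(out, key=lambda c: (c.region_a, c.region_b)))


def _best_support_key(derivs: tuple[DerivedRelation, ...], pdc_tiebreak: bool):
    best_pdc = max((d.pdc for d in derivs), default=PDC.UNSTATED)
    shortest = min((len(d.chain) for d in derivs), default=10**9)
    if pdc_tiebreak:
        return (-best_pdc, shortest)
    return (shortest,)


def _winner(
    codes: dict[RelationCode, tuple[DerivedRelation, ...]],
    policy: ResolutionPolicy,
) -> RelationCode:
    if policy.kind is PolicyKind.IDENTITY_PREFERENCE and _I in codes:
        return _I
    if policy.kind is PolicyKind.SUBREGION_PREFERENCE:
        sub = [c for c in (_S, _L) if c in codes]
        if len(sub) == 1:
            return sub[0]
        if len(sub) == 2:
            return min(
                sub,
                key=lambda c: (
                    _best_support_key(codes[c], policy.pdc_tiebreak),
                    CODE_ORDER[c],
                ),
            )
    return min(
        codes,
        key=lambda c: (
            _best_support_key(codes[c], policy.pdc_tiebreak),
            CODE_ORDER[c],
        ),
    )


def resolve_conflicts(
    m: RelationMatrix, policy: ResolutionPolicy
) -> RelationMatrix:
    """Reduce every conflicted pair to a single code per the policy.

    Resolution is applied per unordered pair in its canonical (sorted)
    orientation and mirrored to the converse orientation, so the resolved
    matrix stays inverse-symmetric and satisfies the at-most-one-code
    invariant.  The conflict list is carried along unchanged for audit.
    """
    conflicts = m.conflicts or detect_conflicts(m)
    if policy.kind is PolicyKind.REPORT_ONLY:
        return m
    if policy.kind is PolicyKind.STRICT and conflicts:
        raise ConflictError(conflicts)

    entries = dict(m.entries)
    for (a, b), codes in m.entries.items():
        if len(codes) < 2 or (b, a) < (a, b):
            continue
        win = _winner(codes, policy)
        entries[(a, b)] = {win: codes[win]}
        inv = invert_code(win)
        rev = m.entries.get((b, a), {})
        entries[(b, a)] = {
            inv: rev.get(
                inv,
                tuple(
                    DerivedRelation(b, a, inv, tuple(reversed(d.chain)))
                    for d in codes[win]
                ),
            )
        }
    return RelationMatrix(entries=entries, conflicts=conflicts, max_chain=m.max_chain)
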