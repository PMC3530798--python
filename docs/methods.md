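# Methods

This note documents the models, rules, and numerical choices behind
`ortex`, and what the synthetic-atlas tests do and do not establish about
real tracing data.

## Relation calculus

Regions are modelled as unknown non-empty sets of tissue. Between any two
regions exactly one of five qualitative relations holds: identical (I),
proper subregion (S), proper superregion (L), partial overlap (O), disjoint
(D). S and L are strict — equality is always reported as I — so the five
codes are mutually exclusive and jointly exhaustive, which is what lets a
set-theoretic oracle (`relation_from_sets`) assign a unique code to any
configuration.

The tracing literature names only the first four; disjointness is usually
left implicit as the absence of a statement. The engine makes D first-class
because the algebra does not close without it: compositions such as S ∘ D
and D ∘ L are determinate only when disjointness can be expressed, and
"spatially disjoint" must not be conflated with "never compared". With D
included the calculus coincides with the RCC5 partial-overlap calculus.

The composition table (`compose_codes`) maps each ordered code pair to the
exact set of codes realizable for (A, C) given A c1 B and B c2 C. The
shipped table is a frozen literal; `composition_table_by_enumeration`
recomputes it by enumerating every triple of non-empty subsets of universes
of 1–5 atoms, and the test suite asserts equality in both inclusion
directions. Five atoms suffice to realize every outcome, so the enumeration
is exact, not a sample.

## Closure

`close_relations` seeds the matrix with every primary statement plus its
converse and iterates semi-naive composition rounds to a fixed point:
a round composes every claim discovered in the previous round against
everything known, left and right. Only singleton (determinate) composition
results are recorded; indeterminate knowledge cannot support propagation
and is discarded rather than stored. Consequences:

- **Order invariance.** The result depends only on the set of inputs.
  Chains recorded for a claim are canonicalized (merged across both
  orientations, sorted) before insertion, so even the provenance lists are
  identical across runs and input permutations.
- **Termination.** New (pair, code) claims are finite; chains are not
  extended beyond `max_chain` primary links (default 8 — real map lineages
  are shallow, and the cap guarantees termination even on cyclic,
  self-contradictory inputs). On conflict-free inputs the default is never
  binding in our test sizes.
- **Conflict semantics.** Each claim composes independently, so
  contradictory inputs propagate their separate consequences, which can
  force additional codes onto a pair beyond the directly contradicting two.
  This is intentional: a conflict report should reflect everything the
  contradiction infects, and each competing code carries its full chain so
  the core primary statements can be read off.

Conflict resolution is applied per unordered pair in canonical orientation
and mirrored, preserving inverse symmetry and the at-most-one-code
invariant. The two headline policies reproduce the historical precedents
(identity-wins; subregion-wins). When the headline preference does not
decide, the tie-break order is: most precise supporting chain (chain PDC =
worst link; best chain wins), then shortest chain, then the fixed code
order I < S < L < O < D. This tie-break order is a design choice of this
engine; it is recorded in output provenance via the policy field.

## ORT propagation rules

`extent_contribution(rel, e)` gives the extent forced in a target region
standing in relation `rel` to a labeled source region with observed extent
`e`. The contract is soundness, not completeness: C (complete) and N (none)
are claimed only when set semantics forces them; positive-but-undetermined
evidence becomes X; everything else U. The table is verified by exhaustive
enumeration of all (target, source, labeling) triples over a 4-atom
universe. Two codes extend the literature's complete/partial/none
vocabulary: X ("present, extent undetermined") and U ("no information").
Without them the engine would have to either guess or silently drop sound
inferences such as "a completely labeled region forces label into every
region it overlaps".

Density is conservative: identity passes density through; a subregion of a
completely labeled source inherits the source density only under an
explicit homogeneity assumption (default on, flagged `inferred`,
configurable off); every other positive outcome is "present, unquantified".
How density should move through non-identity relations is not settled
practice, so the engine makes the assumption auditable rather than
implicit.

Injection attribution maps I → EXACT, S → WITHIN, L/O → PARTIAL, D → never.
The default set {I, S, L, O} is permissive, matching how collated databases
attribute liberally and qualify with the attribution code; restricting to
{I} gives attributions that are provably sound under the complete-uptake
model (the tracer fills the whole injected region, so a labeled site proves
only that *some* injected atom projects there — a WITHIN attribution to a
proper subregion can be a false positive). Statement PDC is the minimum
over injection, site, and every relation link used: a chain is as precise
as its weakest link.

## Aggregation

Cells combine statements per policy: MAX keeps the strongest stated
density; PDC-precedence (default) first restricts to the most precisely
described statements, then MAX; VOTE takes the mode with ties to the
stronger code. "Present, unquantified" ranks between absent and weak for
tie purposes: it asserts presence but cannot outrank a stated level.
Explicit absences co-occurring with positives flag the cell as a conflict,
keep the positive value, and retain both sides in provenance.
Unexamined pairs are never materialized — "no data" and "explicitly
absent" remain distinct.

## Synthetic atlases: what they emulate, what they do not

The generator inverts the real degradation process: it starts from
atom-level ground truth (directed ordinal micro-connectivity on 10–400
indivisible tissue units) and renders perfect textual statements from it.
Maps are partitions of the universe; lineages evolve by region splits and
merges (`churn` per generation, default n_regions/5), because independently
random partitions almost never stand in I/S/L relation — it is the
evolutionary structure of real nomenclatures that makes relation chains
informative. Region density in a simulated statement is the maximum of its
atoms (textual "dense labeling" reports hot spots), extent is
complete/partial/none coverage of the region's atoms, and the ground-truth
matrix defines cell (R, S) by the same receiver-coverage semantics: extent
C means every atom of S receives label from R, which is exactly what a
perfect anterograde experiment injected into R reports.

Defaults: `edge_prob` 0.2 at desk scale (tens of atoms) keeps positive and
absent cells both common; the corruption scale used in conflict tests is
5% of relations, echoing the few-percent conflict rate observed in real
collated databases; PDC is EXPLICIT unless degraded deliberately.

Passing these tests shows the engine's inferences are sound and complete
relative to its stated rules, on data whose statements are internally
consistent. It does not show robustness to the failure modes of real
literature that the generator omits: inter-subject anatomical variability,
partial brain coverage of maps, reporting biases, misassigned acronyms, or
laminar structure (out of scope entirely).

## Numerical and procedural choices

- Identifier comparison is case-sensitive after whitespace trimming;
  acronym case is meaningful in real nomenclatures.
- Writers emit canonically sorted output (maps by id, regions by acronym,
  relations lexicographically); reads return canonical datasets, so
  write → read → write is byte-stable and diffs are meaningful.
- Missing density with positive extent reads as "present, unquantified";
  missing density with extent N reads as absent. Free-text density words
  are normalized only at the reader boundary, via an editable synonym
  table.
- The desk-scale benchmark (1,000 regions across 10 maps, 400 atoms,
  closure plus projection plus matrix build) was sized to exercise the
  all-pairs machinery well beyond test fixtures while staying in seconds;
  the acceptance script reports its measured runtime.
- All randomness flows through `numpy.random.default_rng` with explicit
  seeds; every generator is reproducible per seed.

## Known limitations

- Conflict resolution is per region pair; a globally consistent relation
  assignment (e.g. maximum-satisfiability over all pairs) is out of scope.
- Indeterminate composition results are dropped, not stored as disjunctive
  knowledge; a constraint-propagation variant could refine them but the
  at-most-one-relation target makes singleton propagation the right
  default.
- The homogeneity assumption can overstate subregion densities; it is
  flagged per statement but not propagated as an uncertainty measure.
- Laminar origin/termination patterns, quantified cell counts, and
  cell-type-specific tracers are explicitly out of scope.
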