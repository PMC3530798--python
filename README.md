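# ortex

Coordinate-free macro-connectome construction from axonal tract-tracing
statements.

## The problem

Decades of tract-tracing experiments in the macaque report their results as
textual statements — "the injection was in area A, with spillover to area B";
"dense labeling was observed in area C" — each expressed in whatever brain
parcellation (nomenclature) its authors used. Competing and evolving brain
maps mean the same tissue carries different names across studies, and the
large inter-subject variability of macaque anatomy makes stereotaxic
coordinates unreliable as a common frame. The literature instead ties maps
together with *inter-map relations*: qualitative statements such as "A is
identical to B" or "B is a subregion of C".

`ortex` is the computational engine for turning such collated statements into
a single directed connectivity matrix in a user-selected parcellation, with
every cell traceable back to its literature sources. It is aimed at
neuroinformaticians curating tracing databases and at modellers who consume
the resulting macro-connectomes.

## The model

**Relation algebra.** Regions are treated as unknown non-empty sets of
tissue; a relation between two regions is one of the five RCC5 codes

| code | meaning |
|------|-------------------------|
| I    | identical               |
| S    | proper subregion of     |
| L    | proper superregion of   |
| O    | partial overlap         |
| D    | disjoint                |

Primary relations from the literature are closed under composition
(`S ∘ S = S` — a subregion of a subregion is still a subregion; `S ∘ D = D`;
indeterminate compositions such as `O ∘ O` propagate nothing) to an all-pairs
relation matrix. The composition table is grounded in set semantics and
machine-verified against exhaustive enumeration of atom-set models. In
theory each region pair admits at most one relation; where the closure
derives competing codes the pair is reported as a **conflict** and resolved
under an explicit policy — identity-wins, subregion-wins, strict (refuse),
or report-only — with precision-of-description (PDC) tie-breaking.

**ORT propagation.** Tracing statements move into the target map through the
resolved relations using sound extent inference: if A is completely covered
by labeled sites and B ⊊ A, then B is completely covered too; label in A
forces label into any region containing or overlapping all of A; everything
not forced degrades to "present, extent undetermined" (X) or "no
information" (U). Anterograde statements run injection → label, retrograde
label → injection. Explicit negative findings (extent N) are propagated as
explicit absences and kept distinct from missing data.

**Aggregation.** Statements from many studies are grouped per directed
region pair and combined under MAX, PDC-precedence, or VOTE policies into
ordinal densities (absent < weak < moderate < strong, plus
present-unquantified). Each cell keeps its full provenance tree:
statements → injections/sites → relation chains → primary literature
relations.

**Synthetic atlases.** `ortex.synth` generates atom-level ground truth —
regions as atom sets, maps as partitions evolving by splits and merges,
simulated studies rendered as the same textual statements — so every
inference the engine makes can be checked against exact set semantics.

## Worked example

Generate a synthetic three-map atlas (5% of inter-map relations corrupted),
validate it, list conflicts, and build the matrix in map `M1`:

```
$ ortex simulate --atoms 30 --maps 3 --regions-per-map 6 --edge-prob 0.15 \
    --conflict-frac 0.05 --seed 42 --out atlas
3 maps, 22 relations, 18 studies -> atlas

$ ortex validate atlas
0 error(s), 0 warning(s)

$ ortex conflicts atlas --out conflicts.csv
3 conflict(s) -> conflicts.csv

$ head -3 conflicts.csv
map_a,region_a,code,map_b,region_b,chain_refs
M1,R1,I,M2,R1,atlas:M1-M3;atlas:M2-M3
M1,R1,O,M2,R1,atlas:M1-M2
```

The corrupted primary statement (`M1:R1 O M2:R1`, ref `atlas:M1-M2`)
contradicts the identity derivable through map M3 — exactly the kind of
core conflict a curator wants listed. Building and reading the matrix:

```
$ ortex matrix atlas --target-map M1 --agg pdc --format edges --out edges.csv
36 cell(s) -> edges.csv

$ head -4 edges.csv
source,target,density,extent,n_statements,conflict
R1,R1,0,N,3,0
R1,R2,3,P,2,0
R1,R3,2,P,3,0
```

`R1→R2` is a strong (3) connection supported by 2 statements; `R1→R1,0,N`
is an explicit negative finding, not missing data (unexamined pairs are
simply absent). `ortex trace matrix.json --source R1 --target R2` (after a
`--format json` export) prints the cell's provenance tree down to each
study citation and the primary relation chains used.

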