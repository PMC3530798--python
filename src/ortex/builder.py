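"""Aggregate projected statements into a provenance-traceable connectome.

The product is the macro-connectome: a directed region-by-region matrix in
the chosen parcellation, each cell an ordinal connection strength plus
coverage extent, a statement count, a contradiction flag, and a provenance
tree that bottoms out in the raw study rows and primary inter-map relations
— so any cell can be traced all the way down to its literature sources.

Two kinds of "no connection" are kept apart deliberately: a cell that is
absent from the matrix was never examined (no data), while a materialized
cell with density ABSENT records an explicit negative finding.  Conflating
the two is a classic failure mode of collated connectivity matrices.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Collection

import networkx as nx

from .errors import CellNotFoundError, DomainError
from .model import DensityCode, ExtentCode, RegionId
from .ort import ProjectedStatement
from .relations import ResolutionPolicy

__all__ = [
    "AggregationKind",
    "AggregationPolicy",
    "MatrixCell",
    "ConnectivityMatrix",
    "ExportFormat",
    "build_matrix",
    "trace_cell",
    "export_matrix",
]


class AggregationKind(Enum):
    MAX = "max"
    PDC_PRECEDENCE = "pdc"
    VOTE = "vote"


@dataclass(frozen=True)
class AggregationPolicy:
    """How multiple statements for one cell combine into one density.

    MAX keeps the strongest reported density; PDC_PRECEDENCE first restricts
    to the most precisely described statements and then takes MAX (precision
    codes give some data more importance than others); VOTE takes the modal
    density, ties resolved toward the stronger code.
    """

    kind: AggregationKind = AggregationKind.PDC_PRECEDENCE
    report_conflicts: bool = True


#: Tie/strength order for aggregation: unquantified-positive sits between
#: ABSENT and WEAK — it asserts presence but cannot outrank a stated level.
_DENSITY_RANK = {
    DensityCode.ABSENT: 0,
    DensityCode.PRESENT_UNKNOWN: 1,
    DensityCode.WEAK: 2,
    DensityCode.MODERATE: 3,
    DensityCode.STRONG: 4,
}


@dataclass(frozen=True)
class MatrixCell:
    source: RegionId
    target: RegionId
    density: DensityCode
    extent: ExtentCode
    n_statements: int
    conflict: bool
    statements: tuple[ProjectedStatement, ...]
    contributing: tuple[ProjectedStatement, ...]


@dataclass
class ConnectivityMatrix:
    """Directed ordinal connectivity in one target parcellation."""

    target_map: str
    cells: dict[tuple[RegionId, RegionId], MatrixCell]
    policy_used: AggregationPolicy
    relation_policy_used: ResolutionPolicy | None = None
    regions: tuple[RegionId, ...] = ()

    def cell(self, source: RegionId, target: RegionId) -> MatrixCell:
        try:
            return self.cells[(source, target)]
        except KeyError:
            raise CellNotFoundError(
                f"no data for {source} -> {target}"
            ) from None


def _aggregate_density(
    stmts: Collection[ProjectedStatement], policy: AggregationPolicy
) -> tuple[DensityCode, tuple[ProjectedStatement, ...]]:
    """Combined density and the statements that actually contributed."""
    stmts = list(stmts)
    positives = [s for s in stmts if s.density.is_positive]
    if not positives:
        return DensityCode.ABSENT, tuple(stmts)
    pool = positives
    if policy.kind is AggregationKind.PDC_PRECEDENCE:
        best = max(s.pdc for s in pool)
        pool = [s for s in pool if s.pdc == best]
    if policy.kind is AggregationKind.VOTE:
        counts = Counter(s.density for s in pool)
        top = max(counts.values())
        density = max(
            (d for d, c in counts.items() if c == top),
            key=_DENSITY_RANK.__getitem__,
        )
        return density, tuple(s for s in pool if s.density is density)
    density = max((s.density for s in pool), key=_DENSITY_RANK.__getitem__)
    contributing = [s for s in pool if s.density is density]
    return density, tuple(contributing)


def build_matrix(
    stmts: Collection[ProjectedStatement],
    policy: AggregationPolicy | None = None,
    target_map: str | None = None,
    regions: tuple[RegionId, ...] = (),
    relation_policy: ResolutionPolicy | None = None,
) -> ConnectivityMatrix:
    """Group statements by (source, target) and combine per policy.

    Cells mixing explicit-absence and positive statements keep the positive
    density and are flagged as conflicts, with both sides retained in
    provenance.  Extent combines across all statements of the cell.  Output
    ordering is deterministic.
    """
    from .ort import combine_extents

    policy = policy or AggregationPolicy()
    maps = {s.source.map_id for s in stmts} | {s.target.map_id for s in stmts}
    if target_map is None:
        if len(maps) > 1:
            raise DomainError(f"statements span several target maps: {sorted(maps)}")
        target_map = next(iter(maps), "")
    elif maps - {target_map}:
        raise DomainError(
            f"statements outside target map {target_map!r}: {sorted(maps - {target_map})}"
        )

    groups: dict[tuple[RegionId, RegionId], list[ProjectedStatement]] = {}
    for s in stmts:
        groups.setdefault((s.source, s.target), []).append(s)

    cells: dict[tuple[RegionId, RegionId], MatrixCell] = {}
    for key in sorted(groups):
        group = sorted(
            groups[key],
            key=lambda s: (s.study_id, s.injection_id, s.density.value, s.extent.value),
        )
        density, contributing = _aggregate_density(group, policy)
        extent, extent_conflict = combine_extents([s.extent for s in group])
        has_absent = any(not s.density.is_positive for s in group)
        has_positive = any(s.density.is_positive for s in group)
        cells[key] = MatrixCell(
            source=key[0],
            target=key[1],
            density=density,
            extent=extent,
            n_statements=len(group),
            conflict=(has_absent and has_positive) or extent_conflict,
            statements=tuple(group),
            contributing=contributing,
        )
    return ConnectivityMatrix(
        target_map=target_map,
        cells=cells,
        policy_used=policy,
        relation_policy_used=relation_policy,
        regions=regions,
    )


def _chain_record(chain) -> list[dict]:
    if chain is None:
        return []
    return [
        {
            "map_a": link.region_a.map_id,
            "region_a": link.region_a.acronym,
            "code": link.code.value,
            "map_b": link.region_b.map_id,
            "region_b": link.region_b.acronym,
            "pdc": link.pdc.name,
            "ref": link.ref,
        }
        for link in chain.chain
    ]


def _statement_record(s: ProjectedStatement) -> dict:
    rec = {
        "study_id": s.study_id,
        "citation": s.citation,
        "injection_id": s.injection_id,
        "direction": s.direction.value,
        "source": str(s.source),
        "target": str(s.target),
        "density": s.density.value,
        "extent": s.extent.value,
        "attribution": s.attribution.value,
        "pdc": s.pdc.name,
        "density_inferred": s.density_inferred,
    }
    if s.site_contribution is not None:
        sc = s.site_contribution
        rec["native_site"] = {
            "region": str(sc.site.region),
            "density": sc.site.density.value,
            "extent": sc.site.extent.value,
            "pdc": sc.site.pdc.name,
            "relation_used": sc.relation_used.value,
            "relation_chain": _chain_record(sc.chain),
        }
    if s.injection_attribution is not None:
        ia = s.injection_attribution
        rec["injection_site"] = {
            "injected_region": str(ia.injected_region),
            "attribution": ia.attribution.value,
            "relation_used": ia.relation_used.value,
            "relation_chain": _chain_record(ia.chain),
        }
    return rec


def trace_cell(
    m: ConnectivityMatrix, source: RegionId, target: RegionId
) -> dict:
    """Full provenance tree for one cell, down to the literature sources.

    The tree lists every underlying statement — including explicit-absence
    statements on conflicted cells — with its study citation, injection,
    native-map site, and the primary relation chains used, and separately
    marks the statements that determined the cell value under the
    aggregation policy.
    """
    cell = m.cell(source, target)
    contributing = {id(s) for s in cell.contributing}
    return {
        "source": str(source),
        "target": str(target),
        "target_map": m.target_map,
        "value": {
            "density": cell.density.value,
            "extent": cell.extent.value,
            "n_statements": cell.n_statements,
            "conflict": cell.conflict,
        },
        "aggregation": m.policy_used.kind.value,
        "statements": [
            dict(
                _statement_record(s),
                contributed=(id(s) in contributing),
            )
            for s in cell.statements
        ],
    }


class ExportFormat(Enum):
    CSV_DENSE = "csv"
    CSV_EDGES = "edges"
    GRAPHML = "graphml"
    JSON_FULL = "json"


def _density_token(d: DensityCode) -> str:
    return "X" if d is DensityCode.PRESENT_UNKNOWN else d.value


def _ordered_regions(m: ConnectivityMatrix) -> list[RegionId]:
    if m.regions:
        return sorted(m.regions)
    seen = {r for key in m.cells for r in key}
    return sorted(seen)


def export_matrix(
    m: ConnectivityMatrix, path: str | Path, format: ExportFormat
) -> Path:
    """Write the matrix in one of the standard exchange formats.

    CSV_DENSE is a square grid (entries 0–3 for ordinal densities, X for
    present-unquantified, empty for no data); CSV_EDGES one row per
    materialized cell; GRAPHML a directed graph with density/extent edge
    attributes; JSON_FULL everything including per-cell provenance.  Output
    is byte-stable for a given matrix.
    """
    path = Path(path)
    regions = _ordered_regions(m)
    if format is ExportFormat.CSV_DENSE:
        lines = ["," + ",".join(r.acronym for r in regions)]
        for src in regions:
            row = [src.acronym]
            for tgt in regions:
                cell = m.cells.get((src, tgt))
                row.append("" if cell is None else _density_token(cell.density))
            lines.append(",".join(row))
        path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    elif format is ExportFormat.CSV_EDGES:
        lines = ["source,target,density,extent,n_statements,conflict"]
        for key in sorted(m.cells):
            c = m.cells[key]
            lines.append(
                f"{c.source.acronym},{c.target.acronym},"
                f"{_density_token(c.density)},{c.extent.value},"
                f"{c.n_statements},{int(c.conflict)}"
            )
        path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    elif format is ExportFormat.GRAPHML:
        g = nx.DiGraph()
        g.graph["target_map"] = m.target_map
        for r in regions:
            g.add_node(r.acronym, map=r.map_id)
        for key in sorted(m.cells):
            c = m.cells[key]
            g.add_edge(
                c.source.acronym,
                c.target.acronym,
                density=_density_token(c.density),
                extent=c.extent.value,
                n_statements=c.n_statements,
                conflict=int(c.conflict),
            )
        nx.write_graphml(g, path)
    elif format is ExportFormat.JSON_FULL:
        doc = {
            "target_map": m.target_map,
            "aggregation": m.policy_used.kind.value,
            "relation_policy": (
                m.relation_policy_used.kind.value
                if m.relation_policy_used
                else None
            ),
            "regions": [str(r) for r in regions],
            "cells": [
                trace_cell(m, *key) for key in sorted(m.cells)
            ],
        }
        path.write_text(
            json.dumps(doc, indent=2, sort_keys=True) + "\n", encoding="utf-8"
        )
    else:  # pragma: no cover - exhaustive enum
        raise DomainError(f"unknown export format {format!r}")
    return path
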