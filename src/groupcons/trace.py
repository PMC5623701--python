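"""Simplified evolutionary trace.

The evolutionary trace partitions a sequence dendrogram into P subgroups by
cutting its deepest branches and flags alignment columns that are invariant
inside every subgroup.  Such *trace* columns are candidates for functional
sites; a trace column where at least two subgroups hold different residues
is additionally *group-specific* — the residue identity itself distinguishes
the subgroups.

The dendrogram comes from UPGMA on the same distance matrix used for the NJ
tree (see :mod:`groupcons.phylo`).  By default a subgroup containing any gap
at a column is not invariant there (gaps break invariance); the permissive
``ignore_gaps`` mode judges invariance over non-gap members only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .alignment import GAP, UNKNOWN, Alignment
from .phylo import Dendrogram


@dataclass(frozen=True)
class TracePartition:
    """P disjoint subgroups of leaf ids covering all leaves."""

    subgroups: tuple[frozenset[str], ...]

    def __post_init__(self) -> None:
        all_ids: set[str] = set()
        for sg in self.subgroups:
            if not sg:
                raise ValueError("empty subgroup")
            if all_ids & sg:
                raise ValueError("overlapping subgroups")
            all_ids |= sg
        if not self.subgroups:
            raise ValueError("no subgroups")

    @property
    def P(self) -> int:
        return len(self.subgroups)

    @property
    def leaves(self) -> frozenset[str]:
        return frozenset().union(*self.subgroups)


def partition_tree(dendrogram: Dendrogram, P: int) -> TracePartition:
    """Cut the dendrogram's P-1 highest merges, yielding P subgroups.

    Equivalent to removing the P-1 deepest internal nodes of the ultrametric
    tree.  Subgroups are ordered (and any height ties resolved) by their
    smallest member name, so the result is deterministic.
    """
    n = len(dendrogram.ids)
    if not 1 <= P <= n:
        raise ValueError(f"P must lie in 1..{n}")
    # executing all but the last P-1 linkage merges leaves exactly P clusters;
    # scipy linkage rows are in non-decreasing height order for UPGMA
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    clusters: dict[int, set[int]] = {i: {i} for i in range(n)}
    next_id = n
    for row in dendrogram.linkage[: n - P]:
        a, b = find(int(row[0])), find(int(row[1]))
        merged = clusters.pop(a) | clusters.pop(b)
        parent.append(next_id)
        parent[a] = parent[b] = next_id
        clusters[next_id] = merged
        next_id += 1
    groups = [frozenset(dendrogram.ids[i] for i in members)
              for members in clusters.values()]
    groups.sort(key=lambda sg: min(sg))
    return TracePartition(tuple(groups))


def _subgroup_residue(column: str, rows: list[int], ignore_gaps: bool,
                      ) -> str | None:
    """The single residue a subgroup carries at a column, or None."""
    chars = {column[r] for r in rows}
    if ignore_gaps:
        chars -= {GAP, UNKNOWN}
        if not chars:
            return None
    elif chars & {GAP, UNKNOWN}:
        return None
    if len(chars) != 1:
        return None
    return next(iter(chars))


def trace_residues(alignment: Alignment, partition: TracePartition,
                   ignore_gaps: bool = False) -> pd.DataFrame:
    """Per-column trace classification.

    Returns a table with the 1-based column index, a ``trace`` flag (every
    subgroup internally invariant), a ``group_specific`` flag (trace and at
    least two subgroups differ), and the residue carried by each subgroup
    (empty when not invariant).  Output does not depend on sequence order or
    subgroup order.
    """
    missing = partition.leaves - set(alignment.ids)
    if missing:
        raise ValueError(f"partition ids not in alignment: {sorted(missing)}")
    subgroup_rows = [
        sorted(alignment.ids.index(s) for s in sg) for sg in partition.subgroups]
    names = [f"subgroup_{k + 1}" for k in range(partition.P)]
    records = []
    for i in range(1, alignment.n_columns + 1):
        col = alignment.column(i)
        residues = [_subgroup_residue(col, rows, ignore_gaps)
                    for rows in subgroup_rows]
        is_trace = all(r is not None for r in residues)
        distinct = len(set(residues)) if is_trace else 0
        rec = {"index": i, "trace": is_trace,
               "group_specific": is_trace and distinct >= 2}
        rec.update({name: (r or "") for name, r in zip(names, residues)})
        records.append(rec)
    return pd.DataFrame.from_records(records)
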