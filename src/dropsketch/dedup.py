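"""Directional UMI deduplication per (cell, gene) group.

PCR amplification inflates read counts per molecule, and sequencing
errors in the UMI splinter one molecule into several near-identical
UMIs. The directional method connects UMI A to UMI B when they differ
at exactly one position and count(A) >= factor * count(B) - 1 (factor 2
by default): a sequencing-error UMI should be markedly rarer than the
true UMI it derives from. Molecules are the clusters reached by
expanding from unvisited UMIs in descending count order.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass
from typing import Iterable

from .read_mapping import MappingRecord


@dataclass(frozen=True)
class MoleculeCount:
    cell: str
    gene: str
    molecules: int


def _hamming1(a: str, b: str) -> bool:
    # assumes equal lengths (validated by caller)
    diff = 0
    for x, y in zip(a, b):
        if x != y:
            diff += 1
            if diff > 1:
                return False
    return diff == 1


def directional_edges(counts: dict[str, int], factor: int) -> dict[str, list[str]]:
    """Directed adjacency A→B: Hamming(A,B)=1 and count(A) >= factor*count(B)-1."""
    if factor < 1:
        raise ValueError("factor must be >= 1")
    umis = list(counts)
    if len({len(u) for u in umis}) > 1:
        raise ValueError("UMIs of unequal length in one group")
    edges: dict[str, list[str]] = {u: [] for u in umis}
    for i, a in enumerate(umis):
        for b in umis[i + 1 :]:
            if not _hamming1(a, b):
                continue
            if counts[a] >= factor * counts[b] - 1:
                edges[a].append(b)
            if counts[b] >= factor * counts[a] - 1:
                edges[b].append(a)
    return edges


def count_molecules(
    counts: dict[str, int], factor: int
) -> tuple[int, list[str]]:
    """Number of molecules in a UMI-count group, with representative UMIs.

    UMIs are visited in descending count (ties lexicographic); each
    unvisited UMI seeds a breadth-first expansion along directional
    edges, and the number of expansions started is the molecule count.
    """
    if not counts:
        raise ValueError("empty UMI group")
    edges = directional_edges(counts, factor)
    order = sorted(counts, key=lambda u: (-counts[u], u))
    visited: set[str] = set()
    reps: list[str] = []
    for seed in order:
        if seed in visited:
            continue
        reps.append(seed)
        queue = deque([seed])
        visited.add(seed)
        while queue:
            u = queue.popleft()
            for v in edges[u]:
                if v not in visited:
                    visited.add(v)
                    queue.append(v)
    return len(reps), reps


def dedup_cell(records: Iterable[MappingRecord], factor: int) -> list[MoleculeCount]:
    """Collapse one cell's mapped records into per-gene molecule counts.

    Records are grouped by gene; a UMI string recurring under two genes
    counts once per gene.
    """
    groups: dict[str, dict[str, int]] = {}
    cell: str | None = None
    for rec in records:
        if not rec.mapped:
            continue
        if cell is None:
            cell = rec.cb
        elif rec.cb != cell:
            raise ValueError("dedup_cell received records from multiple cells")
        umis = groups.setdefault(rec.gene, {})
        umis[rec.umi] = umis.get(rec.umi, 0) + 1
    if cell is None:
        return []
    out = []
    for gene in sorted(groups):
        n, _reps = count_molecules(groups[gene], factor)
        out.append(MoleculeCount(cell=cell, gene=gene, molecules=n))
    return out
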