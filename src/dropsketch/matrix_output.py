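"""Sparse gene-cell count matrix assembly and writers.

Rows are cells (sorted lexicographically by barcode — deterministic
regardless of processing order), columns are genes in taxonomy order,
and values are deduplicated molecule counts. Two dialects are written:
a native 0-based TSV of (cell_index, gene_index, count) triplets, and
MatrixMarket coordinate format (1-based), each alongside barcodes.tsv
and genes.tsv index files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import scipy.io
import scipy.sparse as sp

from .dedup import MoleculeCount
from .taxonomy import Taxonomy


@dataclass
class CountMatrix:
    """COO triplets plus the row (cell) and column (gene) orderings."""

    triplets: list[tuple[int, int, int]]
    cell_ids: list[str]
    gene_ids: list[str]

    @property
    def shape(self) -> tuple[int, int]:
        return (len(self.cell_ids), len(self.gene_ids))

    @property
    def nnz(self) -> int:
        return len(self.triplets)

    def total_molecules(self) -> int:
        return sum(c for _, _, c in self.triplets)

    def to_coo(self) -> sp.coo_matrix:
        if self.triplets:
            rows, cols, data = map(np.array, zip(*self.triplets))
        else:
            rows = cols = data = np.empty(0, dtype=int)
        return sp.coo_matrix((data, (rows, cols)), shape=self.shape)

    def to_dict(self) -> dict[tuple[str, str], int]:
        """{(cell, gene): molecules} view, convenient for truth comparison."""
        return {
            (self.cell_ids[i], self.gene_ids[j]): c for i, j, c in self.triplets
        }

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CountMatrix):
            return NotImplemented
        return (
            self.triplets == other.triplets
            and self.cell_ids == other.cell_ids
            and self.gene_ids == other.gene_ids
        )


def assemble_matrix(
    molecule_counts: Iterable[MoleculeCount], taxonomy: Taxonomy
) -> CountMatrix:
    """Order molecule counts into a deterministic sparse matrix.

    Cells sorted by barcode; gene columns follow the taxonomy's gene
    order (genes with zero counts keep their column). Triplets are
    emitted row-major.
    """
    per_pair: dict[tuple[str, str], int] = {}
    for mc in molecule_counts:
        key = (mc.cell, mc.gene)
        if key in per_pair:
            raise ValueError(f"duplicate molecule count for (cell, gene) {key}")
        per_pair[key] = mc.molecules
    cell_ids = sorted({cell for cell, _ in per_pair})
    cell_index = {c: i for i, c in enumerate(cell_ids)}
    gene_index = taxonomy.gene_index()
    triplets = []
    for (cell, gene), count in per_pair.items():
        if gene not in gene_index:
            raise KeyError(f"gene {gene!r} absent from taxonomy")
        triplets.append((cell_index[cell], gene_index[gene], count))
    triplets.sort()
    return CountMatrix(
        triplets=triplets, cell_ids=cell_ids, gene_ids=list(taxonomy.gene_order)
    )


def write_matrix(
    matrix: CountMatrix, outdir: str | Path, dialect: str = "native"
) -> list[Path]:
    """Write the matrix plus barcodes.tsv / genes.tsv index files.

    ``native``: matrix.coo.tsv with 0-based ``cell_index gene_index
    count`` lines. ``matrixmarket``: matrix.mtx in 1-based coordinate
    integer format. Returns the paths written.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if dialect == "native":
        mpath = outdir / "matrix.coo.tsv"
        with open(mpath, "wt") as fh:
            for i, j, c in matrix.triplets:
                fh.write(f"{i}\t{j}\t{c}\n")
    elif dialect == "matrixmarket":
        mpath = outdir / "matrix.mtx"
        with open(mpath, "wt") as fh:
            fh.write("%%MatrixMarket matrix coordinate integer general\n")
            fh.write(f"{len(matrix.cell_ids)} {len(matrix.gene_ids)} {matrix.nnz}\n")
            for i, j, c in matrix.triplets:
                fh.write(f"{i + 1} {j + 1} {c}\n")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    bpath = outdir / "barcodes.tsv"
    with open(bpath, "wt") as fh:
        for cb in matrix.cell_ids:
            fh.write(cb + "\n")
    gpath = outdir / "genes.tsv"
    with open(gpath, "wt") as fh:
        for g in matrix.gene_ids:
            fh.write(g + "\n")
    return [mpath, bpath, gpath]


def read_matrix(outdir: str | Path, dialect: str = "native") -> CountMatrix:
    """Read back what :func:`write_matrix` wrote."""
    outdir = Path(outdir)
    with open(outdir / "barcodes.tsv") as fh:
        cell_ids = [line.strip() for line in fh if line.strip()]
    with open(outdir / "genes.tsv") as fh:
        gene_ids = [line.strip() for line in fh if line.strip()]
    triplets: list[tuple[int, int, int]] = []
    if dialect == "native":
        with open(outdir / "matrix.coo.tsv") as fh:
            for line in fh:
                if line.strip():
                    i, j, c = map(int, line.split())
                    triplets.append((i, j, c))
    elif dialect == "matrixmarket":
        coo = scipy.io.mmread(outdir / "matrix.mtx").tocoo()
        triplets = sorted(
            (int(i), int(j), int(c)) for i, j, c in zip(coo.row, coo.col, coo.data)
        )
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return CountMatrix(triplets=triplets, cell_ids=cell_ids, gene_ids=gene_ids)
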