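"""Three-stage pipeline: whitelist → mapping → deduplication → output.

Each stage completes before the next starts (the whitelist must exist
before any barcode is corrected; all reads must be mapped before a
cell can be deduplicated). Work is split into read batches; with
``threads > 1`` batches are mapped on a thread pool whose results are
merged in submission order, so the output is identical for any thread
count and any batch size.
"""

from __future__ import annotations

import itertools
import json
import logging
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from .barcodes import (
    BarcodeCorrector,
    BarcodeCounts,
    Whitelist,
    build_whitelist,
    count_barcodes,
)
from .dedup import MoleculeCount, dedup_cell
from .io_formats import ReadPair, read_fastq_pairs
from .matrix_output import CountMatrix, assemble_matrix, write_matrix
from .params import Params
from .read_mapping import DiscardReason, MappingRecord, map_read
from .reference_db import Database

logger = logging.getLogger("dropsketch")


@dataclass
class RunSummary:
    """Per-stage observability counters, written as run_summary.json."""

    reads_total: int = 0
    whitelist_size: int = 0
    mapped: int = 0
    discarded: dict[str, int] = field(
        default_factory=lambda: {r.value: 0 for r in DiscardReason}
    )
    cells: int = 0
    molecules: int = 0
    nnz: int = 0

    def to_dict(self) -> dict:
        return {
            "reads_total": self.reads_total,
            "whitelist_size": self.whitelist_size,
            "mapped": self.mapped,
            "discarded": dict(self.discarded),
            "cells": self.cells,
            "molecules": self.molecules,
            "nnz": self.nnz,
        }


def _batches(pairs: Iterable[ReadPair], size: int) -> Iterator[list[ReadPair]]:
    it = iter(pairs)
    while batch := list(itertools.islice(it, size)):
        yield batch


def run_pipeline(
    db: Database,
    r1_path: str | Path,
    r2_path: str | Path,
    params: Params | None = None,
    *,
    whitelist: Whitelist | None = None,
    threads: int = 1,
    batch_size: int = 10_000,
) -> tuple[CountMatrix, RunSummary, Whitelist]:
    """Run whitelist, mapping and dedup stages over one read set.

    A precomputed ``whitelist`` skips stage 1 (e.g. a known barcode
    list). Output is independent of ``threads`` and ``batch_size``.
    """
    params = params or db.params
    summary = RunSummary()

    # stage 1: whitelist (barrier: completes before any mapping)
    if whitelist is None:
        counts = BarcodeCounts()
        for batch in _batches(read_fastq_pairs(r1_path, r2_path), batch_size):
            counts.merge(count_barcodes(batch, params))
        whitelist = build_whitelist(counts, params.whitelist_fraction)
        logger.info("whitelist: %d barcodes from %d reads", len(whitelist), counts.total)
    summary.whitelist_size = len(whitelist)

    # stage 2: mapping (order-preserving merge of batch results)
    corrector = BarcodeCorrector(whitelist, params.hamming_only)

    def map_batch(batch: list[ReadPair]) -> list[MappingRecord]:
        return [map_read(db, p, whitelist, params, corrector) for p in batch]

    by_cell: dict[str, list[MappingRecord]] = {}
    batches = _batches(read_fastq_pairs(r1_path, r2_path), batch_size)
    if threads > 1:
        with ThreadPoolExecutor(max_workers=threads) as pool:
            results: Iterable[list[MappingRecord]] = pool.map(map_batch, batches)
            record_lists = list(results)
    else:
        record_lists = [map_batch(b) for b in batches]
    for records in record_lists:
        for rec in records:
            summary.reads_total += 1
            if rec.mapped:
                summary.mapped += 1
                by_cell.setdefault(rec.cb, []).append(rec)
            else:
                summary.discarded[rec.reason.value] += 1
    logger.info("mapping: %d/%d reads mapped", summary.mapped, summary.reads_total)

    # stage 3: dedup per cell (barrier: all mapping done above)
    molecule_counts: list[MoleculeCount] = []
    for cell in sorted(by_cell):
        molecule_counts.extend(dedup_cell(by_cell[cell], params.dedup_factor))
    matrix = assemble_matrix(molecule_counts, db.taxonomy)
    summary.cells = len(matrix.cell_ids)
    summary.molecules = matrix.total_molecules()
    summary.nnz = matrix.nnz
    logger.info(
        "dedup: %d molecules in %d cells (%d nonzeros)",
        summary.molecules,
        summary.cells,
        summary.nnz,
    )
    return matrix, summary, whitelist


def run_to_dir(
    db: Database,
    r1_path: str | Path,
    r2_path: str | Path,
    outdir: str | Path,
    params: Params | None = None,
    *,
    whitelist: Whitelist | None = None,
    dialect: str = "native",
    threads: int = 1,
    batch_size: int = 10_000,
    dump_whitelist: str | Path | None = None,
) -> tuple[CountMatrix, RunSummary]:
    """run_pipeline + write matrix, index files and run_summary.json."""
    matrix, summary, wl = run_pipeline(
        db,
        r1_path,
        r2_path,
        params,
        whitelist=whitelist,
        threads=threads,
        batch_size=batch_size,
    )
    outdir = Path(outdir)
    write_matrix(matrix, outdir, dialect=dialect)
    with open(outdir / "run_summary.json", "wt") as fh:
        json.dump(summary.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    if dump_whitelist is not None:
        wl.to_tsv(dump_whitelist)
    return matrix, summary
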