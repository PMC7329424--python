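"""Read → gene assignment by sketch lookup and range accumulation.

Mate 2 is windowed and sketched with exactly the reference's settings,
each feature is looked up in the database, and hits are accumulated per
transcript over runs of r consecutive reference windows — a read is a
contiguous piece of one transcript, so its true hits land in adjacent
windows while spurious hits scatter. The best window-range sum is the
mapping score; transcripts at or above the threshold become candidates,
and a read is kept only when all candidates agree on a single gene.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable

from .barcodes import BarcodeCorrector, Whitelist, split_read1
from .io_formats import ReadPair
from .params import Params
from .reference_db import Database, sequence_sketches
from .taxonomy import Taxonomy


class DiscardReason(str, Enum):
    MALFORMED = "malformed"
    CB_UNMATCHED = "cb_unmatched"
    UNMAPPED = "unmapped"
    AMBIGUOUS_GENE = "ambiguous_gene"


@dataclass(frozen=True)
class MappingRecord:
    """Outcome for one read: (cb, umi, gene, score) or a typed discard."""

    cb: str | None = None
    umi: str | None = None
    gene: str | None = None
    score: int | None = None
    reason: DiscardReason | None = None

    @property
    def mapped(self) -> bool:
        return self.reason is None


def sketch_read(seq: str, params: Params) -> list[tuple[int, list[int]]]:
    """(window_index, sketch) list for a read; empty if len(seq) < k."""
    if len(seq) < params.k:
        return []
    return sequence_sketches(seq, params)


def lookup_hits(
    db: Database, read_sketches: list[tuple[int, list[int]]]
) -> dict[int, dict[int, int]]:
    """Per-transcript window→hit-count accumulators.

    Every feature occurrence in every read window contributes one hit to
    each stored location of that feature; duplicated feature values
    across read windows therefore count multiply. Features absent from
    the table (never sketched, or capped away) contribute nothing.
    """
    acc: dict[int, dict[int, int]] = {}
    table = db.table
    for _win, sketch in read_sketches:
        for feature in sketch:
            locs = table.get(feature)
            if locs is None:
                continue
            for tx_index, win_index in locs:
                windows = acc.setdefault(tx_index, {})
                windows[win_index] = windows.get(win_index, 0) + 1
    return acc


def best_range_score(window_hits: dict[int, int], r: int) -> int:
    """Max sum of hits over any r consecutive window indices.

    Absent windows count zero; an optimal range can always start at a
    hit window, so only those starts are scanned.
    """
    if r < 1:
        raise ValueError("range r must be >= 1")
    if not window_hits:
        return 0
    items = sorted(window_hits.items())
    best = 0
    n = len(items)
    j = 0
    for i, (start, _) in enumerate(items):
        if j < i:
            j = i
        while j < n and items[j][0] < start + r:
            j += 1
        total = sum(c for _, c in items[i:j])
        if total > best:
            best = total
    return best


def select_candidates(scores: dict[int, int], threshold: int) -> dict[int, int]:
    """Transcripts whose score meets the (inclusive) threshold."""
    if threshold < 1:
        raise ValueError("threshold must be >= 1")
    return {tx: sc for tx, sc in scores.items() if sc >= threshold}


def resolve_gene(
    candidates: dict[int, int], db: Database
) -> tuple[str, int] | None | DiscardReason:
    """Collapse candidate transcripts to one gene.

    No candidates → None (unmapped). One gene among all candidates →
    (gene, max score). Two or more genes → AMBIGUOUS_GENE.
    """
    if not candidates:
        return None
    genes = {db.gene_of_transcript_index(tx) for tx in candidates}
    if len(genes) > 1:
        return DiscardReason.AMBIGUOUS_GENE
    return genes.pop(), max(candidates.values())


def score_read(db: Database, seq: str, params: Params | None = None) -> dict[int, int]:
    """Per-transcript mapping scores of one cDNA sequence."""
    params = params or db.params
    sketches = sketch_read(seq, params)
    acc = lookup_hits(db, sketches)
    return {tx: best_range_score(windows, params.r) for tx, windows in acc.items()}


def map_read(
    db: Database,
    pair: ReadPair,
    whitelist: Whitelist,
    params: Params | None = None,
    corrector: BarcodeCorrector | None = None,
) -> MappingRecord:
    """Full per-read pipeline: barcode, sketch, lookup, score, resolve.

    Discard precedence: malformed (mate 1 too short for CB+UMI, or mate
    2 shorter than k) → cb_unmatched → unmapped → ambiguous_gene.
    """
    params = params or db.params
    rec = split_read1(pair.mate1_seq, params)
    if rec is None or len(pair.mate2_seq) < params.k:
        return MappingRecord(reason=DiscardReason.MALFORMED)
    if corrector is not None:
        cb = corrector(rec.cb)
    else:
        from .barcodes import correct_barcode

        cb = correct_barcode(rec.cb, whitelist, params.hamming_only)
    if cb is None:
        return MappingRecord(umi=rec.umi, reason=DiscardReason.CB_UNMATCHED)
    scores = score_read(db, pair.mate2_seq, params)
    resolved = resolve_gene(select_candidates(scores, params.threshold), db)
    if resolved is None:
        return MappingRecord(cb=cb, umi=rec.umi, reason=DiscardReason.UNMAPPED)
    if resolved is DiscardReason.AMBIGUOUS_GENE:
        return MappingRecord(cb=cb, umi=rec.umi, reason=DiscardReason.AMBIGUOUS_GENE)
    gene, score = resolved
    return MappingRecord(cb=cb, umi=rec.umi, gene=gene, score=score)
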