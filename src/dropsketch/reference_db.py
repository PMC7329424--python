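"""Minhash feature database over a reference transcriptome.

Each transcript is cut into windows of size w placed every t bases; a
window is represented by its sketch — the s smallest h1 hashes of its
canonical k-mers. Every sketch feature is stored in a multi-value hash
table mapping the feature to the (transcript, window) locations where
it occurs. Features hitting more than ``max_locations`` locations are
discarded outright: they are too promiscuous to discriminate between
transcripts and would dominate lookup cost.

Windows and positions are 0-based half-open throughout.
"""

from __future__ import annotations

import gzip
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np

from .hashing import kmer_hashes
from .io_formats import SequenceRecord, _DeterministicGzipWriter
from .params import Params
from .taxonomy import Taxonomy

_DB_FORMAT = "dropsketch-db"
_DB_VERSION = 1


class DatabaseFormatError(ValueError):
    """Unreadable or wrong-format database file."""


@dataclass(frozen=True)
class WindowSpan:
    """Half-open [start, end) span of one window on a sequence."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"empty window span [{self.start}, {self.end})")


def window_spans(length: int, params: Params) -> list[WindowSpan]:
    """Window spans covering a sequence of the given length.

    Span i is [i*t, min(i*t + w, length)); the union covers the whole
    sequence and every k-mer start position falls in at least one span.
    Sequences shorter than k get a single (k-mer-free) span.
    """
    if length < 1:
        raise ValueError("sequence length must be >= 1")
    k, w, t = params.k, params.w, params.t
    if length < k:
        return [WindowSpan(0, length)]
    m = (length - k) // t + 1
    return [WindowSpan(i * t, min(i * t + w, length)) for i in range(m)]


def sketch_window(sequence: str, span: WindowSpan, params: Params) -> list[int]:
    """Sketch of one window: the s smallest distinct k-mer hashes, ascending."""
    sub = sequence[span.start : span.end]
    valid, hashes = kmer_hashes(sub, params.k)
    if not valid.any():
        return []
    distinct = np.unique(hashes[valid])
    return [int(h) for h in distinct[: params.s]]


def sequence_sketches(sequence: str, params: Params) -> list[tuple[int, list[int]]]:
    """(window_index, sketch) for every window of a sequence.

    Hashes all k-mers once and slices per window — identical output to
    calling :func:`sketch_window` span by span.
    """
    L = len(sequence)
    if L < 1:
        return []
    spans = window_spans(L, params)
    k, s = params.k, params.s
    valid, hashes = kmer_hashes(sequence, k)
    out: list[tuple[int, list[int]]] = []
    for i, span in enumerate(spans):
        lo = span.start
        hi = span.end - k + 1  # k-mer start positions within the span
        if hi <= lo:
            out.append((i, []))
            continue
        v = valid[lo:hi]
        if not v.any():
            out.append((i, []))
            continue
        distinct = np.unique(hashes[lo:hi][v])
        out.append((i, [int(h) for h in distinct[:s]]))
    return out


# feature -> ordered list of (transcript_index, window_index)
FeatureTable = dict[int, list[tuple[int, int]]]


def cap_features(table: FeatureTable, max_locations: int) -> FeatureTable:
    """Drop every feature stored at more than ``max_locations`` locations."""
    return {f: locs for f, locs in table.items() if len(locs) <= max_locations}


@dataclass
class Database:
    """The queryable reference: feature table + taxonomy + window layout."""

    params: Params
    table: FeatureTable
    taxonomy: Taxonomy
    transcript_ids: list[str]
    transcript_window_counts: list[int]

    def gene_of_transcript_index(self, tx_index: int) -> str:
        return self.taxonomy.gene_of(self.transcript_ids[tx_index])


def build_database(
    transcripts: Iterable[SequenceRecord],
    taxonomy: Taxonomy,
    params: Params,
) -> Database:
    """Sketch every window of every transcript into the feature table.

    Transcripts are processed in input order; each sketch feature is
    appended with its (transcript, window) location, then over-occupied
    features are removed per ``params.max_locations``. A transcript id
    missing from the taxonomy is an error.
    """
    table: FeatureTable = {}
    transcript_ids: list[str] = []
    window_counts: list[int] = []
    for tx_index, rec in enumerate(transcripts):
        if rec.id not in taxonomy.tx2gene:
            raise KeyError(f"transcript {rec.id!r} not present in the taxonomy")
        transcript_ids.append(rec.id)
        sketches = sequence_sketches(rec.sequence, params)
        window_counts.append(len(sketches))
        for win_index, sketch in sketches:
            for feature in sketch:
                table.setdefault(feature, []).append((tx_index, win_index))
    table = cap_features(table, params.max_locations)
    return Database(
        params=params,
        table=table,
        taxonomy=taxonomy,
        transcript_ids=transcript_ids,
        transcript_window_counts=window_counts,
    )


def save_database(db: Database, path: str | Path) -> None:
    """Serialize a database (gzipped JSON with a format/version tag)."""
    payload = {
        "format": _DB_FORMAT,
        "version": _DB_VERSION,
        "params": db.params.to_dict(),
        "taxonomy": db.taxonomy.to_dict(),
        "transcript_ids": db.transcript_ids,
        "transcript_window_counts": db.transcript_window_counts,
        # JSON objects preserve insertion order, so the feature walk and
        # each location list round-trip exactly
        "table": {str(f): [[t, w] for t, w in locs] for f, locs in db.table.items()},
    }
    # always gzipped, deterministic bytes (mtime=0) regardless of extension
    with _DeterministicGzipWriter(path) as fh:
        json.dump(payload, fh)


def load_database(path: str | Path) -> Database:
    """Load a database written by :func:`save_database`.

    Raises DatabaseFormatError on wrong magic, wrong version or a
    truncated/corrupt file.
    """
    try:
        with gzip.open(path, "rt") as fh:
            payload = json.load(fh)
    except (OSError, EOFError, json.JSONDecodeError, UnicodeDecodeError) as e:
        raise DatabaseFormatError(f"{path}: not a readable database file: {e}") from e
    if not isinstance(payload, dict) or payload.get("format") != _DB_FORMAT:
        raise DatabaseFormatError(f"{path}: missing {_DB_FORMAT!r} format tag")
    if payload.get("version") != _DB_VERSION:
        raise DatabaseFormatError(
            f"{path}: unsupported database version {payload.get('version')!r}"
        )
    return Database(
        params=Params.from_dict(payload["params"]),
        table={
            int(f): [(int(t), int(w)) for t, w in locs]
            for f, locs in payload["table"].items()
        },
        taxonomy=Taxonomy.from_dict(payload["taxonomy"]),
        transcript_ids=list(payload["transcript_ids"]),
        transcript_window_counts=list(payload["transcript_window_counts"]),
    )
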