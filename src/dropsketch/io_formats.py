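"""Readers and writers for FASTA references, paired FASTQ reads and GTF.

Thin wrappers around Biopython's parsers that add the error contracts
the pipeline relies on (pair-count mismatches name the file that ended
first, malformed FASTA headers name the line) and transparent gzip
handling. Mate pairing is positional: record n of R1 pairs with record
n of R2, as produced by Chromium demultiplexing — read names are never
parsed.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.SeqIO.QualityIO import FastqGeneralIterator
from gffutils.feature import feature_from_line

from .taxonomy import Taxonomy, TaxonomyError


class FormatError(ValueError):
    """Malformed input file."""


@dataclass(frozen=True)
class SequenceRecord:
    """One FASTA record: id = first whitespace token, uppercased sequence."""

    id: str
    sequence: str


@dataclass(frozen=True)
class ReadPair:
    """One positional mate pair; mate 1 carries CB+UMI, mate 2 cDNA."""

    name: str
    mate1_seq: str
    mate2_seq: str
    mate1_qual: str | None = None
    mate2_qual: str | None = None


def _open_text(path: str | Path) -> io.TextIOBase:
    """Open plain or gzipped text transparently (by magic bytes)."""
    path = Path(path)
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_fasta(path: str | Path) -> Iterator[SequenceRecord]:
    """Stream FASTA records in file order; multi-line sequences joined.

    Raises FormatError (naming the line) if the first non-blank line is
    not a ``>`` header, or FileNotFoundError for a missing file.
    """
    with _open_text(path) as fh:
        # SeqIO treats leading junk permissively; enforce the header contract
        pos = fh.tell()
        for lineno, line in enumerate(fh, start=1):
            if line.strip():
                if not line.startswith(">"):
                    raise FormatError(
                        f"{path}: line {lineno}: expected FASTA header starting "
                        f"with '>', got {line.strip()[:30]!r}"
                    )
                break
        fh.seek(pos)
        for rec in SeqIO.parse(fh, "fasta"):
            yield SequenceRecord(id=rec.id, sequence=str(rec.seq).upper())


class _DeterministicGzipWriter(io.TextIOWrapper):
    """Gzip text writer with mtime=0 and no filename in the header, so
    identical content produces identical bytes run to run."""

    def __init__(self, path: str | Path):
        self._raw_file = open(path, "wb")
        gz = gzip.GzipFile(filename="", fileobj=self._raw_file, mode="wb", mtime=0)
        super().__init__(gz)

    def close(self) -> None:
        super().close()
        if not self._raw_file.closed:
            self._raw_file.close()


def _open_write(path: str | Path) -> io.TextIOBase:
    if str(path).endswith(".gz"):
        return _DeterministicGzipWriter(path)
    return open(path, "wt")


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    with _open_write(path) as fh:
        for rec in records:
            fh.write(f">{rec.id}\n{rec.sequence}\n")


def read_fastq_pairs(path_r1: str | Path, path_r2: str | Path) -> Iterator[ReadPair]:
    """Stream positionally-paired reads from two FASTQ files.

    Gzip is handled transparently. A record-count mismatch raises
    FormatError stating which file ended first; malformed 4-line blocks
    surface as FormatError too.
    """
    with _open_text(path_r1) as f1, _open_text(path_r2) as f2:
        it1 = FastqGeneralIterator(f1)
        it2 = FastqGeneralIterator(f2)
        n = 0
        while True:
            try:
                rec1 = next(it1, None)
            except ValueError as e:
                raise FormatError(f"{path_r1}: malformed FASTQ record: {e}") from e
            try:
                rec2 = next(it2, None)
            except ValueError as e:
                raise FormatError(f"{path_r2}: malformed FASTQ record: {e}") from e
            if rec1 is None and rec2 is None:
                return
            if rec1 is None:
                raise FormatError(
                    f"{path_r1} ended after {n} records but {path_r2} has more"
                )
            if rec2 is None:
                raise FormatError(
                    f"{path_r2} ended after {n} records but {path_r1} has more"
                )
            n += 1
            title1, seq1, qual1 = rec1
            _title2, seq2, qual2 = rec2
            yield ReadPair(
                name=title1.split()[0] if title1 else "",
                mate1_seq=seq1.upper(),
                mate2_seq=seq2.upper(),
                mate1_qual=qual1,
                mate2_qual=qual2,
            )


def write_fastq(records: Iterable[tuple[str, str, str]], path: str | Path) -> None:
    """Write (name, sequence, quality) triples as 4-line FASTQ records."""
    with _open_write(path) as fh:
        for name, seq, qual in records:
            fh.write(f"@{name}\n{seq}\n+\n{qual}\n")


def parse_gtf_tx2gene(path: str | Path) -> Taxonomy:
    """Extract the transcript→gene taxonomy from a GTF annotation.

    Any feature row carrying both ``transcript_id`` and ``gene_id`` is
    used; gene order is order of first appearance. Both ``key "value";``
    and ``key value;`` attribute dialects are accepted (delegated to
    gffutils' line parser). A transcript annotated to two different
    genes raises TaxonomyError; a row with transcript_id but no gene_id
    raises FormatError.
    """
    tax = Taxonomy()
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if line.count("\t") < 8:
                raise FormatError(f"{path}: line {lineno}: expected 9 tab-separated columns")
            try:
                feat = feature_from_line(line)
            except Exception as e:  # gffutils raises assorted parse errors
                raise FormatError(f"{path}: line {lineno}: {e}") from e
            tx_ids = feat.attributes.get("transcript_id", [])
            if not tx_ids:
                continue
            gene_ids = feat.attributes.get("gene_id", [])
            if not gene_ids:
                raise FormatError(
                    f"{path}: line {lineno}: transcript_id without gene_id"
                )
            tax.add(tx_ids[0], gene_ids[0])
    return tax
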