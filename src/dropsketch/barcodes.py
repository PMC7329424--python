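"""Cell-barcode extraction, whitelisting and error correction.

The whitelist is built from the data itself: barcodes are sorted by
count descending, an inclusive prefix sum is taken in that order, and a
barcode is admitted while its prefix sum stays strictly below
``fraction`` of all reads. Rare barcodes — the error tail — fall beyond
the cutoff and are instead rescued at mapping time by matching against
the whitelist within edit distance one.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import edlib

from .io_formats import ReadPair
from .params import Params


@dataclass(frozen=True)
class BarcodeRecord:
    cb: str
    umi: str


@dataclass
class BarcodeCounts:
    """Exact-string CB counts over all well-formed mate-1 reads."""

    counts: Counter = field(default_factory=Counter)
    total: int = 0
    malformed: int = 0

    def add(self, cb: str) -> None:
        self.counts[cb] += 1
        self.total += 1

    def merge(self, other: "BarcodeCounts") -> "BarcodeCounts":
        self.counts.update(other.counts)
        self.total += other.total
        self.malformed += other.malformed
        return self


def split_read1(seq: str, params: Params) -> BarcodeRecord | None:
    """CB = first cb_len bases, UMI = next umi_len; None if too short.

    Trailing bases beyond cb_len + umi_len are ignored (mate 1 may carry
    extra cycles).
    """
    need = params.cb_len + params.umi_len
    if len(seq) < need:
        return None
    return BarcodeRecord(cb=seq[: params.cb_len], umi=seq[params.cb_len : need])


def count_barcodes(pairs: Iterable[ReadPair], params: Params) -> BarcodeCounts:
    counts = BarcodeCounts()
    for pair in pairs:
        rec = split_read1(pair.mate1_seq, params)
        if rec is None:
            counts.malformed += 1
            continue
        counts.add(rec.cb)
    return counts


@dataclass
class Whitelist:
    """The inferred set of true cell barcodes, with their read counts."""

    members: set[str] = field(default_factory=set)
    counts: dict[str, int] = field(default_factory=dict)

    def __contains__(self, cb: str) -> bool:
        return cb in self.members

    def __len__(self) -> int:
        return len(self.members)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "wt") as fh:
            for cb in sorted(self.members):
                fh.write(f"{cb}\t{self.counts.get(cb, 0)}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "Whitelist":
        members: set[str] = set()
        counts: dict[str, int] = {}
        with open(path) as fh:
            for line in fh:
                parts = line.split()
                if not parts:
                    continue
                members.add(parts[0])
                counts[parts[0]] = int(parts[1]) if len(parts) > 1 else 0
        return cls(members=members, counts=counts)

    @classmethod
    def from_members(cls, members: Iterable[str]) -> "Whitelist":
        ms = set(members)
        return cls(members=ms, counts={m: 0 for m in ms})


def build_whitelist(counts: BarcodeCounts, fraction: float) -> Whitelist:
    """Sorted prefix-sum whitelist.

    Barcodes ordered by count descending (ties lexicographic ascending);
    a barcode is admitted iff its inclusive prefix sum is strictly below
    ``fraction * total``. Deterministic for a fixed count table.
    """
    if not (0 < fraction <= 1):
        raise ValueError("fraction must be in (0, 1]")
    cutoff = fraction * counts.total
    ordered = sorted(counts.counts.items(), key=lambda kv: (-kv[1], kv[0]))
    members: set[str] = set()
    kept: dict[str, int] = {}
    prefix = 0
    for cb, n in ordered:
        prefix += n
        if prefix < cutoff:
            members.add(cb)
            kept[cb] = n
        else:
            break
    return Whitelist(members=members, counts=kept)


def _within_one(a: str, b: str, hamming_only: bool) -> bool:
    if hamming_only:
        if len(a) != len(b):
            return False
        return sum(x != y for x, y in zip(a, b)) <= 1
    return edlib.align(a, b, task="distance", k=1)["editDistance"] != -1


def correct_barcode(
    cb: str, whitelist: Whitelist, hamming_only: bool = False
) -> str | None:
    """Exact whitelist member, unique edit-distance-1 rescue, or None.

    Among whitelist members within edit distance one, a single candidate
    — or the unique candidate with the strictly highest whitelist count
    — wins; ties are discarded as unresolvable.
    """
    if cb in whitelist:
        return cb
    candidates = [m for m in whitelist.members if _within_one(cb, m, hamming_only)]
    if not candidates:
        return None
    if len(candidates) == 1:
        return candidates[0]
    ranked = sorted(candidates, key=lambda m: -whitelist.counts.get(m, 0))
    best, second = ranked[0], ranked[1]
    if whitelist.counts.get(best, 0) > whitelist.counts.get(second, 0):
        return best
    return None


class BarcodeCorrector:
    """Memoized correct_barcode for streaming pipelines."""

    def __init__(self, whitelist: Whitelist, hamming_only: bool = False):
        self.whitelist = whitelist
        self.hamming_only = hamming_only
        self._cache: dict[str, str | None] = {}

    def __call__(self, cb: str) -> str | None:
        if cb in self.whitelist:
            return cb
        try:
            return self._cache[cb]
        except KeyError:
            res = correct_barcode(cb, self.whitelist, self.hamming_only)
            self._cache[cb] = res
            return res
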