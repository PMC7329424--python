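"""Canonical k-mer encoding and the h1 feature hash.

k-mers are packed 2 bits per base (A=0, C=1, G=2, T=3) and canonicalized
as min(code, code of reverse complement), so a read sequenced antisense
to its transcript produces the same features. The feature hash h1 is the
splitmix64 finalizer applied to the canonical code; it is fixed so that
every database and every documented example is bit-reproducible.

k-mers containing any base outside {A,C,G,T} are skipped.
"""

from __future__ import annotations

import numpy as np

_M64 = np.uint64(0xFFFFFFFFFFFFFFFF)

# base -> 2-bit code; complements satisfy code(comp(b)) == 3 - code(b)
_CODE_LUT = np.full(256, -1, dtype=np.int8)
for _b, _c in zip(b"ACGT", (0, 1, 2, 3)):
    _CODE_LUT[_b] = _c


def splitmix64(x: np.ndarray | int) -> np.ndarray | int:
    """splitmix64 finalizer (Steele et al. mix function) on uint64."""
    with np.errstate(over="ignore"):  # uint64 multiply wraps mod 2^64 by design
        z = np.asarray(x, dtype=np.uint64)
        z = z ^ (z >> np.uint64(30))
        z = (z * np.uint64(0xBF58476D1CE4E5B9)) & _M64
        z = z ^ (z >> np.uint64(27))
        z = (z * np.uint64(0x94D049BB133111EB)) & _M64
        z = z ^ (z >> np.uint64(31))
    return z


def base_codes(seq: str) -> np.ndarray:
    """2-bit codes of a nucleotide string; -1 marks non-ACGT bases."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _CODE_LUT[raw]


def canonical_kmer_codes(seq: str, k: int) -> np.ndarray:
    """Canonical 2-bit codes of every k-mer of ``seq``.

    Returns an int64 array of length len(seq) - k + 1 (empty for shorter
    sequences, as seen through view semantics below) where entry i is
    the canonical code of seq[i:i+k], or -1 if that k-mer contains a
    non-ACGT base.
    """
    L = len(seq)
    n = L - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    codes = base_codes(seq)
    valid = codes >= 0
    ucodes = np.where(valid, codes, 0).astype(np.uint64)

    fwd = np.zeros(n, dtype=np.uint64)
    rev = np.zeros(n, dtype=np.uint64)
    for j in range(k):
        fwd += ucodes[j : j + n] << np.uint64(2 * (k - 1 - j))
        # reverse complement: base j of the k-mer lands at position k-1-j
        rev += (np.uint64(3) - ucodes[j : j + n]) << np.uint64(2 * j)
    canon = np.minimum(fwd, rev).astype(np.int64)

    # a k-mer is invalid if any of its k bases is invalid
    ok = np.ones(n, dtype=bool)
    for j in range(k):
        ok &= valid[j : j + n]
    canon[~ok] = -1
    return canon


def kmer_hashes(seq: str, k: int) -> tuple[np.ndarray, np.ndarray]:
    """h1 hash of every k-mer of ``seq``.

    Returns ``(valid, hashes)``: a boolean mask over k-mer start
    positions and a uint64 array of the corresponding h1 values
    (entries where ``valid`` is False are meaningless).
    """
    canon = canonical_kmer_codes(seq, k)
    valid = canon >= 0
    hashes = splitmix64(canon.astype(np.uint64))
    return valid, hashes


def encode_canonical_kmer(kmer: str, k: int | None = None) -> int | None:
    """Canonical 2-bit code of one k-mer, or None if it contains non-ACGT.

    ``k`` defaults to len(kmer); passing a mismatching k is a usage error.
    """
    if k is not None and len(kmer) != k:
        raise ValueError(f"expected k-mer of length {k}, got {len(kmer)}")
    canon = canonical_kmer_codes(kmer, len(kmer))
    c = int(canon[0])
    return None if c < 0 else c


def hash_kmer(kmer: str) -> int | None:
    """h1 of one k-mer (canonical), or None for k-mers with non-ACGT."""
    c = encode_canonical_kmer(kmer)
    if c is None:
        return None
    return int(splitmix64(np.uint64(c)))
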