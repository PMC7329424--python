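"""Pipeline tunables.

All knobs that influence the database, the mapping score and the
deduplication live in one :class:`Params` object so that the reference
database and the reads are guaranteed to be sketched under identical
settings.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, field


def default_window_size(read_length: int, k: int) -> int:
    """Window size derived from read length: floor((R + k - 1) / 2).

    For the common Chromium v2 read length R=98 and k=16 this gives 56.
    """
    return (read_length + k - 1) // 2


def default_stride(w: int, k: int) -> int:
    """Stride t = w - k + 1: consecutive windows share no k-mer start."""
    return w - k + 1


def default_range(read_length: int, k: int, t: int) -> int:
    """Accumulation range r = floor((R - k - 1) / t) + 2.

    This is the largest number of reference stride bins the R - k + 1
    k-mer start positions of a contiguously aligned read can intersect,
    i.e. the smallest range that never splits the hits of one contiguous
    alignment. 3 for R=98, w=56, t=41.
    """
    return (read_length - k - 1) // t + 2


@dataclass(frozen=True)
class Params:
    """All tunables of the sketching pipeline.

    Parameters
    ----------
    k : k-mer length (1..31; 2-bit packed into 64 bits).
    s : sketch size — the number of smallest k-mer hashes kept per window.
    w : window size in bases.
    t : window stride in bases (default w - k + 1).
    r : number of consecutive reference windows over which feature hits
        are accumulated into a mapping score.
    threshold : minimum accumulated score for a transcript to become a
        mapping candidate (inclusive).
    max_locations : features stored at more than this many (transcript,
        window) locations are dropped from the database.
    whitelist_fraction : prefix-sum cutoff fraction for cell-barcode
        whitelisting.
    dedup_factor : occurrence factor of the directional UMI collapse
        criterion count(A) >= factor * count(B) - 1.
    cb_len, umi_len : barcode layout of mate 1 (Chromium v2: 16 + 10).
    hamming_only : restrict barcode rescue to substitutions (for
        fixed-length 16-mers this coincides with Levenshtein <= 1).
    """

    k: int = 16
    s: int = 16
    w: int = 56
    t: int | None = None
    r: int = 3
    threshold: int = 28
    max_locations: int = 1000
    whitelist_fraction: float = 0.95
    dedup_factor: int = 2
    cb_len: int = 16
    umi_len: int = 10
    hash_name: str = "splitmix64"
    hamming_only: bool = False

    def __post_init__(self) -> None:
        if self.t is None:
            object.__setattr__(self, "t", default_stride(self.w, self.k))
        if not (1 <= self.k <= 31):
            raise ValueError(f"k must be in 1..31, got {self.k}")
        if self.s < 1:
            raise ValueError("sketch size s must be >= 1")
        if self.w < self.k:
            raise ValueError(f"window size w={self.w} must be >= k={self.k}")
        if not (1 <= self.t <= self.w - self.k + 1):
            raise ValueError(f"stride t={self.t} must be in 1..w-k+1={self.w - self.k + 1}")
        if self.r < 1:
            raise ValueError("range r must be >= 1")
        if self.threshold < 1:
            raise ValueError("threshold must be >= 1")
        if self.max_locations < 1:
            raise ValueError("max_locations must be >= 1")
        if not (0 < self.whitelist_fraction <= 1):
            raise ValueError("whitelist_fraction must be in (0, 1]")
        if self.dedup_factor < 1:
            raise ValueError("dedup_factor must be >= 1")
        if self.hash_name != "splitmix64":
            raise ValueError(f"unknown hash function: {self.hash_name!r}")

    @classmethod
    def for_read_length(cls, read_length: int, *, k: int = 16, **kwargs) -> "Params":
        """Derive w, t and r from a read length, keeping other defaults."""
        w = kwargs.pop("w", None) or default_window_size(read_length, k)
        t = kwargs.pop("t", None) or default_stride(w, k)
        r = kwargs.pop("r", None) or default_range(read_length, k, t)
        return cls(k=k, w=w, t=t, r=r, **kwargs)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "Params":
        return cls(**d)
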