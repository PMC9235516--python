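"""Minimizer sketches over k-mer sequences.

A nucleotide string of length ``n`` is viewed as an ordered sequence of
``L = n - k + 1`` overlapping k-mers.  A hash function assigns each distinct
k-mer a value in [0, 1); the minimizer sketch ``MS(A; w)`` is the set of
k-mers that achieve the minimum hash value in at least one window of ``w``
consecutive positions.  The minimizer Jaccard estimator compares two sketches
built under one shared hash function.

The theory this package quantifies assumes a collision-free real-valued hash;
in practice we use a seeded 64-bit integer mixer scaled to [0, 1) and break
argmin ties by the smaller position.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

_BASES = "ACGT"
_ENCODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(_BASES):
    _ENCODE[ord(_b)] = _i

__all__ = [
    "KmerSequence",
    "HashAssignment",
    "MinimizerSketch",
    "kmerize",
    "hash_kmers",
    "minimizer_sketch",
    "charged_index",
    "true_jaccard",
    "jaccard_estimate",
]


def _encode_string(seq: str) -> np.ndarray:
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    codes = _ENCODE[raw]
    if (codes == 255).any():
        bad = seq[int(np.argmax(codes == 255))]
        raise ValueError(f"non-ACGT character {bad!r} in sequence")
    return codes


def _kmer_codes(base_codes: np.ndarray, k: int) -> np.ndarray:
    """Pack each window of k bases into one uint64 (2 bits per base)."""
    if k > 31:
        raise ValueError("k-mer packing supports k <= 31")
    win = np.lib.stride_tricks.sliding_window_view(base_codes, k).astype(np.uint64)
    powers = (np.uint64(1) << (np.uint64(2) * np.arange(k - 1, -1, -1, dtype=np.uint64)))
    return (win * powers).sum(axis=1, dtype=np.uint64)


def decode_kmer(code: int, k: int) -> str:
    return "".join(_BASES[(int(code) >> (2 * (k - 1 - t))) & 3] for t in range(k))


class KmerSequence:
    """An ordered sequence of L k-mers, stored 2-bit packed.

    Built either from one nucleotide string (consecutive k-mers then overlap
    by k-1 bases) or from an explicit list of k-mers (no overlap implied).
    """

    __slots__ = ("codes", "k", "source", "_dupfree")

    def __init__(self, codes: np.ndarray, k: int, source: Optional[str] = None):
        self.codes = np.ascontiguousarray(codes, dtype=np.uint64)
        self.k = int(k)
        self.source = source
        self._dupfree: Optional[bool] = None

    @classmethod
    def from_string(cls, seq: str, k: int) -> "KmerSequence":
        seq = seq.upper()
        if k < 2:
            raise ValueError("k must be >= 2")
        if len(seq) < k:
            raise ValueError(f"sequence length {len(seq)} < k={k}")
        return cls(_kmer_codes(_encode_string(seq), k), k, source=seq)

    @classmethod
    def from_kmers(cls, kmers: Iterable[str]) -> "KmerSequence":
        kmers = list(kmers)
        if not kmers:
            raise ValueError("empty k-mer list")
        k = len(kmers[0])
        if any(len(m) != k for m in kmers):
            raise ValueError("k-mers must share one length")
        codes = np.array(
            [_kmer_codes(_encode_string(m.upper()), k)[0] for m in kmers],
            dtype=np.uint64,
        )
        return cls(codes, k)

    @classmethod
    def from_codes(cls, codes: Sequence[int], k: int) -> "KmerSequence":
        return cls(np.asarray(codes, dtype=np.uint64), k)

    @property
    def L(self) -> int:
        return int(self.codes.size)

    def __len__(self) -> int:
        return self.L

    @property
    def duplicate_free(self) -> bool:
        if self._dupfree is None:
            self._dupfree = bool(np.unique(self.codes).size == self.codes.size)
        return self._dupfree

    @property
    def kmers(self) -> list[str]:
        return [decode_kmer(c, self.k) for c in self.codes]

    @property
    def spectrum(self) -> set[int]:
        """Sp_k: the set of distinct (packed) k-mers."""
        return set(int(c) for c in self.codes)

    def __repr__(self) -> str:  # pragma: no cover
        return f"KmerSequence(L={self.L}, k={self.k}, duplicate_free={self.duplicate_free})"


def kmerize(seq: str, k: int) -> KmerSequence:
    """Split a nucleotide string into its L = len(seq) - k + 1 ordered k-mers."""
    return KmerSequence.from_string(seq, k)


# -- hashing ---------------------------------------------------------------

_U64 = np.uint64


def _splitmix64(x: np.ndarray) -> np.ndarray:
    x = (x + _U64(0x9E3779B97F4A7C15)).astype(np.uint64)
    x = (x ^ (x >> _U64(30))) * _U64(0xBF58476D1CE4E5B9)
    x = (x ^ (x >> _U64(27))) * _U64(0x94D049BB133111EB)
    return x ^ (x >> _U64(31))


@dataclass(frozen=True)
class HashAssignment:
    """Seeded map from k-mer content to a value in [0, 1).

    Deterministic in (seed, k-mer); identical k-mers in different sequences
    receive identical values.  64-bit resolution makes collisions negligible
    for any realistic k-mer set.
    """

    seed: int
    _mixed: int = field(init=False, repr=False)

    def __post_init__(self):
        m = int(_splitmix64(np.array([self.seed], dtype=np.uint64))[0])
        object.__setattr__(self, "_mixed", m)

    def values_for_codes(self, codes: np.ndarray) -> np.ndarray:
        h = _splitmix64(np.asarray(codes, dtype=np.uint64) ^ _U64(self._mixed))
        return h.astype(np.float64) / np.float64(2.0**64)

    def values(self, ks: KmerSequence) -> np.ndarray:
        return self.values_for_codes(ks.codes)

    def __call__(self, kmer: str) -> float:
        code = _kmer_codes(_encode_string(kmer.upper()), len(kmer))[0]
        return float(self.values_for_codes(np.array([code], dtype=np.uint64))[0])


def hash_kmers(ks: KmerSequence, seed: int) -> np.ndarray:
    """Hash every position of ``ks``; position i depends only on (seed, k-mer i)."""
    return HashAssignment(seed).values(ks)


# -- minimizer selection ---------------------------------------------------


@dataclass
class MinimizerSketch:
    """Positions and k-mers selected as window minima."""

    positions: np.ndarray        # sorted, unique selected positions
    member_codes: np.ndarray     # distinct k-mer codes of the members
    w: int
    L: int
    k: int

    @property
    def members(self) -> set[str]:
        return {decode_kmer(c, self.k) for c in self.member_codes}

    def __len__(self) -> int:
        return int(self.member_codes.size)


def sketch_positions(values: np.ndarray, w: int) -> np.ndarray:
    """Positions that are the argmin of at least one window of w values.

    Ties broken toward the smaller position (argmin returns the first hit).
    """
    L = values.size
    if w < 1:
        raise ValueError("w must be >= 1")
    if L < w:
        raise ValueError(f"need L >= w (got L={L}, w={w})")
    if w == 1:
        return np.arange(L)
    sw = np.lib.stride_tricks.sliding_window_view(values, w)
    pos = sw.argmin(axis=1) + np.arange(L - w + 1)
    return np.unique(pos)


def minimizer_sketch(ks: KmerSequence, hashes: np.ndarray, w: int) -> MinimizerSketch:
    """Build MS(A; w): the union over windows of each window's argmin k-mer."""
    if not ks.duplicate_free:
        warnings.warn(
            "sequence has duplicate k-mers; sketch uses set semantics and the "
            "bias theory's guarantees do not apply",
            stacklevel=2,
        )
    pos = sketch_positions(np.asarray(hashes, dtype=np.float64), w)
    member_codes = np.unique(ks.codes[pos])
    return MinimizerSketch(positions=pos, member_codes=member_codes, w=w, L=ks.L, k=ks.k)


def charged_index(values: np.ndarray, p: int, w: int) -> Optional[int]:
    """The unique window index charged by position p, or None.

    Position p charges index i (a window starting at i+1) when
    i lies in [max(-1, p-w), p-1], a_p is the minimum of positions
    i+1 .. i+w, and either i == max(-1, p-w) or a_i < a_p.  A position
    charges some index iff it is a minimizer, and then the index is unique.
    Comparisons use the (value, position) order so hash ties cannot occur.
    """
    values = np.asarray(values, dtype=np.float64)
    L = values.size
    if not (0 <= p <= L - 1):
        raise ValueError(f"p={p} out of range for L={L}")

    def less(a: int, b: int) -> bool:
        return (values[a], a) < (values[b], b)

    lo = max(-1, p - w)
    hi = min(p - 1, L - w - 1)
    for i in range(lo, hi + 1):
        window = [t for t in range(i + 1, i + w + 1) if t != p]
        if all(less(p, t) for t in window):
            if i == lo or less(i, p):
                return i
    return None


# -- Jaccard quantities ----------------------------------------------------


def true_jaccard(A: KmerSequence, B: KmerSequence) -> float:
    """J(A, B): Jaccard similarity of the two k-mer spectra."""
    if A.k != B.k:
        raise ValueError(f"k mismatch: {A.k} vs {B.k}")
    if not (A.duplicate_free and B.duplicate_free):
        warnings.warn("duplicate k-mers present; Jaccard computed on spectra (set semantics)",
                      stacklevel=2)
    sa, sb = A.spectrum, B.spectrum
    union = len(sa | sb)
    return len(sa & sb) / union if union else 0.0


def sketch_intersection_union(A: KmerSequence, B: KmerSequence, w: int, seed: int
                              ) -> tuple[int, int]:
    """(|MS(A)∩MS(B)|, |MS(A)∪MS(B)|) under one shared hash seed."""
    if A.k != B.k:
        raise ValueError(f"k mismatch: {A.k} vs {B.k}")
    h = HashAssignment(seed)
    mA = minimizer_sketch(A, h.values(A), w).member_codes
    mB = minimizer_sketch(B, h.values(B), w).member_codes
    inter = int(np.intersect1d(mA, mB, assume_unique=True).size)
    union = int(mA.size + mB.size - inter)
    return inter, union


def jaccard_estimate(A: KmerSequence, B: KmerSequence, w: int, seed: int) -> float:
    """The minimizer Jaccard estimator Ĵ = |MS(A)∩MS(B)| / |MS(A)∪MS(B)|."""
    inter, union = sketch_intersection_union(A, B, w, seed)
    return inter / union
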