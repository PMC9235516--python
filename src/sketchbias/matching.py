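"""The k-mer matching between two duplicate-free sequences.

Because each sequence is duplicate-free, the relation "position p of A holds
the same k-mer as position q of B" is a matching: every position appears in
at most one pair.  The layout of this matching along the sequences (not just
its size) is what drives the minimizer Jaccard estimator's bias; the true
Jaccard depends only on the counts I and U.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .sketch import KmerSequence

__all__ = ["KmerMatching", "kmer_matching", "is_padded", "is_sparsely_matched"]


@dataclass
class KmerMatching:
    pairs: np.ndarray   # (I, 2) array of (p, q), sorted by p
    L_A: int
    L_B: int
    # partner lookup: match_A[p] = q if (p, q) matched else -1, and vice versa
    match_A: np.ndarray
    match_B: np.ndarray

    @property
    def I(self) -> int:
        return int(self.pairs.shape[0])

    @property
    def U(self) -> int:
        return self.L_A + self.L_B - self.I

    @property
    def J(self) -> float:
        return self.I / self.U if self.U else 0.0

    def to_frame(self, A: KmerSequence):
        """Matching as a table with columns p, q, kmer."""
        import pandas as pd
        from .sketch import decode_kmer

        return pd.DataFrame(
            {
                "p": self.pairs[:, 0],
                "q": self.pairs[:, 1],
                "kmer": [decode_kmer(A.codes[p], A.k) for p in self.pairs[:, 0]],
            }
        )


def kmer_matching(A: KmerSequence, B: KmerSequence) -> KmerMatching:
    """All (p, q) with A_p == B_q, for duplicate-free A and B of equal k."""
    if A.k != B.k:
        raise ValueError(f"k mismatch: {A.k} vs {B.k}")
    if not A.duplicate_free or not B.duplicate_free:
        raise ValueError("k-mer matching requires duplicate-free sequences")
    common, ia, ib = np.intersect1d(A.codes, B.codes, assume_unique=True,
                                    return_indices=True)
    order = np.argsort(ia)
    pairs = np.column_stack([ia[order], ib[order]]).astype(np.int64)
    match_A = np.full(A.L, -1, dtype=np.int64)
    match_B = np.full(B.L, -1, dtype=np.int64)
    if pairs.size:
        match_A[pairs[:, 0]] = pairs[:, 1]
        match_B[pairs[:, 1]] = pairs[:, 0]
    return KmerMatching(pairs=pairs, L_A=A.L, L_B=B.L, match_A=match_A, match_B=match_B)


def is_padded(A: KmerSequence, B: KmerSequence, matching: KmerMatching, w: int) -> bool:
    """No shared k-mer in the first or last w positions of either sequence.

    This is the hash-independent sufficient form of the padding condition
    ("share no minimizers in the boundary windows"): if no k-mer there is
    shared at all, none can be a shared minimizer under any hash.
    """
    if matching.I == 0:
        return True
    p = matching.pairs[:, 0]
    q = matching.pairs[:, 1]
    ok_A = bool(((p >= w) & (p <= matching.L_A - w - 1)).all())
    ok_B = bool(((q >= w) & (q <= matching.L_B - w - 1)).all())
    return ok_A and ok_B


def is_sparsely_matched(A: KmerSequence, B: KmerSequence, matching: KmerMatching,
                        w: int) -> bool:
    """Padded, and every shared position's 2w-neighborhood holds no other share.

    For each matched (p, q): the k-mers at A positions p-w..p-1, p+1..p+w must
    be absent from Sp_k(B), and symmetrically for B's neighborhood of q.
    Since shares are exactly the matched positions, this is equivalent to no
    two matched positions lying within w of each other on either sequence.
    """
    if not is_padded(A, B, matching, w):
        return False
    if matching.I <= 1:
        return True
    for pos in (np.sort(matching.pairs[:, 0]), np.sort(matching.pairs[:, 1])):
        if (np.diff(pos) <= w).any():
            return False
    return True
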