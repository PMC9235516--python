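"""Ground-truth engines for the estimator's expectation.

Under a collision-free uniform hash, minimizer selection depends only on the
relative order of the hash values, so the exact expectation of any sketch
statistic is the average over all n! equally likely rank assignments to the
n distinct k-mers of the union spectrum.  That enumeration is feasible only
for tiny instances (n <= ~10); at realistic scale, Monte Carlo over hash
seeds ("hash replicates") estimates the same expectations.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np

from .matching import kmer_matching
from .sketch import HashAssignment, KmerSequence, sketch_positions

__all__ = [
    "ExactExpectation",
    "MonteCarloEstimate",
    "exact_expectations",
    "joint_minimizer_probability",
    "monte_carlo",
]

_MAX_UNION = 10
_CHUNK = 120_000


@dataclass
class ExactExpectation:
    """Exact rational expectations over all orderings of the union spectrum."""

    E_I: Fraction
    E_U: Fraction
    E_J: Fraction
    n: int  # number of distinct k-mers enumerated (n! orderings)


@dataclass
class MonteCarloEstimate:
    mean_J_hat: float
    mean_I_hat: float
    mean_U_hat: float
    var_I_hat: float
    var_U_hat: float
    percentile_2_5: float
    percentile_97_5: float
    n_seeds: int
    seeds: np.ndarray = field(repr=False)


def _variable_indices(A: KmerSequence, B: KmerSequence):
    """Map each position of A and B to an index over the union spectrum."""
    union = np.union1d(A.codes, B.codes)
    varA = np.searchsorted(union, A.codes)
    varB = np.searchsorted(union, B.codes)
    return union.size, varA.astype(np.int64), varB.astype(np.int64)


def _membership(vals: np.ndarray, w: int) -> np.ndarray:
    """Boolean (n_perms, L) matrix: is position a window argmin of its row."""
    nperm, L = vals.shape
    sw = np.lib.stride_tricks.sliding_window_view(vals, w, axis=1)
    idx = sw.argmin(axis=2) + np.arange(L - w + 1)[None, :]
    member = np.zeros((nperm, L), dtype=bool)
    rows = np.repeat(np.arange(nperm), L - w + 1)
    member[rows, idx.ravel()] = True
    return member


def _enumerate(A: KmerSequence, B: KmerSequence, w: int, max_union: int):
    if A.k != B.k:
        raise ValueError("k mismatch")
    if not (A.duplicate_free and B.duplicate_free):
        raise ValueError("exact enumeration requires duplicate-free sequences")
    if min(A.L, B.L) < w:
        raise ValueError("need L >= w")
    n, varA, varB = _variable_indices(A, B)
    if n > max_union:
        raise ValueError(
            f"union spectrum has {n} > {max_union} distinct k-mers; "
            "n! enumeration refused - use monte_carlo instead"
        )
    m = kmer_matching(A, B)
    pairs = m.pairs
    nfact = math.factorial(n)
    perms = itertools.permutations(range(n))
    while True:
        block = np.array(list(itertools.islice(perms, _CHUNK)), dtype=np.int8)
        if block.size == 0:
            break
        memA = _membership(block[:, varA], w)
        memB = _membership(block[:, varB], w)
        if pairs.size:
            I_hat = (memA[:, pairs[:, 0]] & memB[:, pairs[:, 1]]).sum(axis=1)
        else:
            I_hat = np.zeros(block.shape[0], dtype=np.int64)
        U_hat = memA.sum(axis=1) + memB.sum(axis=1) - I_hat
        yield nfact, memA, memB, I_hat, U_hat


def exact_expectations(A: KmerSequence, B: KmerSequence, w: int,
                       max_union: int = _MAX_UNION) -> ExactExpectation:
    """Exact E[Î], E[Û], E[Ĵ] by enumerating all orderings of the union."""
    sum_I = 0
    sum_U = 0
    sum_J = Fraction(0)
    nfact = 1
    for nfact, memA, memB, I_hat, U_hat in _enumerate(A, B, w, max_union):
        sum_I += int(I_hat.sum())
        sum_U += int(U_hat.sum())
        key = I_hat.astype(np.int64) * (2 * max(A.L, B.L) + 1) + U_hat
        uniq, counts = np.unique(key, return_counts=True)
        base = 2 * max(A.L, B.L) + 1
        for kval, cnt in zip(uniq.tolist(), counts.tolist()):
            i_val, u_val = divmod(kval, base)
            sum_J += Fraction(i_val, u_val) * cnt
    n = _variable_indices(A, B)[0]
    return ExactExpectation(
        E_I=Fraction(sum_I, nfact),
        E_U=Fraction(sum_U, nfact),
        E_J=sum_J / nfact,
        n=n,
    )


def joint_minimizer_probability(A: KmerSequence, B: KmerSequence, w: int,
                                p: int, q: int,
                                max_union: int = _MAX_UNION) -> Fraction:
    """Pr[A_p in MS(A;w) and B_q in MS(B;w)] as an exact rational.

    (p, q) must be a matched pair, i.e. A_p == B_q.  For an isolated shared
    k-mer the value depends only on the relative order of the 2(w-1)+...
    neighborhood values, so a minimal embedding gives the same answer as a
    padded one.
    """
    if int(A.codes[p]) != int(B.codes[q]):
        raise ValueError(f"positions (p={p}, q={q}) are not a matched pair")
    count = 0
    nfact = 1
    for nfact, memA, memB, _, _ in _enumerate(A, B, w, max_union):
        count += int((memA[:, p] & memB[:, q]).sum())
    return Fraction(count, nfact)


def monte_carlo(A: KmerSequence, B: KmerSequence, w: int, n_seeds: int,
                master_seed: int) -> MonteCarloEstimate:
    """Estimator statistics over hash replicates.

    Replicate seeds are derived from the master seed via a counter-based
    seed sequence and recorded in the output, so the same master seed gives
    bit-identical results.
    """
    if n_seeds < 2:
        raise ValueError("need at least 2 hash replicates")
    if A.k != B.k:
        raise ValueError("k mismatch")
    seeds = np.random.SeedSequence(master_seed).generate_state(n_seeds, dtype=np.uint64)
    I_vals = np.empty(n_seeds, dtype=np.float64)
    U_vals = np.empty(n_seeds, dtype=np.float64)
    J_vals = np.empty(n_seeds, dtype=np.float64)
    for t, s in enumerate(seeds):
        h = HashAssignment(int(s))
        mA = np.unique(A.codes[sketch_positions(h.values(A), w)])
        mB = np.unique(B.codes[sketch_positions(h.values(B), w)])
        inter = np.intersect1d(mA, mB, assume_unique=True).size
        union = mA.size + mB.size - inter
        I_vals[t] = inter
        U_vals[t] = union
        J_vals[t] = inter / union
    lo, hi = np.percentile(J_vals, [2.5, 97.5])
    return MonteCarloEstimate(
        mean_J_hat=float(J_vals.mean()),
        mean_I_hat=float(I_vals.mean()),
        mean_U_hat=float(U_vals.mean()),
        var_I_hat=float(I_vals.var(ddof=1)),
        var_U_hat=float(U_vals.var(ddof=1)),
        percentile_2_5=float(lo),
        percentile_97_5=float(hi),
        n_seeds=n_seeds,
        seeds=seeds,
    )
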