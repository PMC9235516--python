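"""Synthetic sequence-pair factories.

Four models:

* ``unrelated_pair`` -- two independent duplicate-free sequences of
  L = floor(2j*4^k / (j+1)) k-mers each, the length at which the expected
  Jaccard of two uniform L-subsets of the 4^k k-mer universe equals j.
* ``related_pair`` -- sweep a base sequence, mutating each nucleotide with
  probability r1 to an alternative that keeps the result duplicate-free.
* ``deterministic_gap_pair`` -- identical sequences except for single-base
  mutations every g nucleotides; with g > w + 2k every mutation knocks out an
  isolated run of k shared k-mers, so I = L - (ell+1)*k exactly.
* ``sparsely_matched_pair`` -- a padded pair sharing exactly n_shared k-mers,
  each more than w positions from any other share on both sequences.

Duplicate-freeness is a hard postcondition everywhere.  Dense regimes (L a
large fraction of 4^k) draw the sequence as a prefix of a random Eulerian
circuit of the order-(k-1) de Bruijn graph: every k-mer is an edge of that
graph, a circuit uses each edge exactly once, so any prefix is duplicate-free
by construction.  Sparse regimes use plain rejection sampling.
"""

from __future__ import annotations

import warnings

import numpy as np

from .matching import is_padded, is_sparsely_matched, kmer_matching
from .sketch import KmerSequence, decode_kmer

__all__ = [
    "random_duplicate_free",
    "unrelated_pair",
    "unrelated_pair_length",
    "related_pair",
    "deterministic_gap_pair",
    "sparsely_matched_pair",
]

_BASES = "ACGT"
_MAX_EULER_K = 12  # 4^12 = 16.7M edges; beyond this rejection always wins


def _random_string(n: int, rng: np.random.Generator) -> str:
    return "".join(_BASES[c] for c in rng.integers(0, 4, size=n))


def _euler_prefix(L: int, k: int, rng: np.random.Generator) -> KmerSequence:
    """First L edges of a random Eulerian circuit of the de Bruijn graph."""
    n_nodes = 4 ** (k - 1)
    # per-node randomized order over the 4 outgoing symbols
    sym_order = np.argsort(rng.random((n_nodes, 4)), axis=1).astype(np.int8)
    next_edge = np.zeros(n_nodes, dtype=np.int8)
    start = int(rng.integers(n_nodes))
    stack = [start]
    circuit = []
    while stack:
        v = stack[-1]
        if next_edge[v] < 4:
            c = int(sym_order[v, next_edge[v]])
            next_edge[v] += 1
            stack.append((v * 4 + c) % n_nodes)
        else:
            circuit.append(stack.pop())
    circuit.reverse()  # Eulerian circuit as node sequence
    # edge between consecutive nodes u -> v is the k-mer u*4 + (v mod 4)
    nodes = circuit[: L + 1]
    codes = np.array([nodes[t] * 4 + (nodes[t + 1] % 4) for t in range(L)],
                     dtype=np.uint64)
    first = decode_kmer(nodes[0], k - 1) if k > 1 else ""
    source = first + "".join(_BASES[n % 4] for n in nodes[1: L + 1])
    ks = KmerSequence(codes, k, source=source)
    return ks


def random_duplicate_free(L: int, k: int, rng: np.random.Generator,
                          max_tries: int = 50) -> KmerSequence:
    """A nucleotide string whose L k-mers are pairwise distinct."""
    N = 4 ** k
    if L > N:
        raise ValueError(f"cannot fit {L} distinct k-mers in a 4^{k} universe")
    if L < 1:
        raise ValueError("L must be >= 1")
    # expected duplicate count for a uniform string is ~ L^2 / (2*4^k)
    if L * L <= N and k <= 31:
        for _ in range(max_tries):
            ks = KmerSequence.from_string(_random_string(L + k - 1, rng), k)
            if ks.duplicate_free:
                return ks
    if k - 1 > _MAX_EULER_K:
        raise RuntimeError(
            f"failed to draw a duplicate-free sequence (L={L}, k={k}) within "
            f"{max_tries} tries and k too large for the Eulerian constructor"
        )
    return _euler_prefix(L, k, rng)


def unrelated_pair_length(j: float, k: int) -> int:
    """L = floor(2j*4^k / (j+1)): the length whose expected Jaccard is j."""
    if not 0 < j <= 1:
        raise ValueError("target Jaccard j must lie in (0, 1]")
    return int(2 * j * 4 ** k / (j + 1))


def unrelated_pair(j: float, k: int, rng: np.random.Generator,
                   w: int | None = None) -> tuple[KmerSequence, KmerSequence]:
    """Two independent duplicate-free sequences at target Jaccard j."""
    L = unrelated_pair_length(j, k)
    if w is not None and L < 7 * (w + 1):
        warnings.warn(f"L={L} < 7(w+1): below the bias theory's length regime",
                      stacklevel=2)
    return random_duplicate_free(L, k, rng), random_duplicate_free(L, k, rng)


def related_pair(base: KmerSequence, r1: float, rng: np.random.Generator
                 ) -> tuple[KmerSequence, KmerSequence]:
    """Per-position mutation of ``base`` at rate r1, kept duplicate-free.

    Sweeps the nucleotide string left to right; at each position, with
    probability r1, substitutes a nucleotide chosen among the alternatives
    that do not create a duplicate k-mer in the partially mutated string.
    Positions where every alternative would create a duplicate are left
    unmutated (counted in the returned sequence's generation, rare for the
    k used in practice).
    """
    if base.source is None:
        raise ValueError("related_pair needs a sequence built from one string")
    if not base.duplicate_free:
        raise ValueError("base must be duplicate-free")
    if not 0 <= r1 <= 1:
        raise ValueError("r1 must lie in [0, 1]")
    k = base.k
    s = list(base.source)
    n = len(s)
    L = base.L

    def window_kmers(chars, t):
        out = []
        for st in range(max(0, t - k + 1), min(t, L - 1) + 1):
            out.append("".join(chars[st: st + k]))
        return out

    spectrum = set(base.kmers)
    mutate = rng.random(n) < r1
    for t in np.flatnonzero(mutate):
        t = int(t)
        old = set(window_kmers(s, t))
        spectrum -= old
        alts = [b for b in _BASES if b != s[t]]
        rng.shuffle(alts)
        orig = s[t]
        for b in alts:
            s[t] = b
            new = window_kmers(s, t)
            if len(set(new)) == len(new) and spectrum.isdisjoint(new):
                spectrum |= set(new)
                break
        else:  # every alternative would duplicate a k-mer: leave unmutated
            s[t] = orig
            spectrum |= old
    B = KmerSequence.from_string("".join(s), k)
    assert B.duplicate_free
    return base, B


def deterministic_gap_pair(ell: int, g: int, k: int, rng: np.random.Generator,
                           w: int | None = None, max_tries: int = 200,
                           strict: bool = True
                           ) -> tuple[KmerSequence, KmerSequence]:
    """The deterministic-gap layout: mutations at nucleotides k-1+i*g, i=0..ell.

    Both sequences have L = ell*g + k k-mers.  With g > w + 2k (checked when w
    is given) each mutation destroys an isolated run of k shared k-mers, so
    the matching has I = L - (ell+1)*k pairs; ``strict`` resamples until the
    realized matching equals that count (spurious collisions are rare for the
    k of interest).
    """
    if ell < 1:
        raise ValueError("ell must be >= 1")
    if g <= 2 * k or (w is not None and g <= w + 2 * k):
        raise ValueError("need g > w + 2k")
    L = ell * g + k
    expected_I = L - (ell + 1) * k
    last_err = ""
    for _ in range(max_tries):
        A = random_duplicate_free(L, k, rng)
        s = list(A.source)
        for i in range(ell + 1):
            t = k - 1 + i * g
            s[t] = _BASES[(_BASES.index(s[t]) + int(rng.integers(1, 4))) % 4]
        B = KmerSequence.from_string("".join(s), k)
        if not B.duplicate_free:
            last_err = "mutated copy had duplicate k-mers"
            continue
        if strict and kmer_matching(A, B).I != expected_I:
            last_err = "spurious k-mer sharing altered the matching"
            continue
        return A, B
    raise RuntimeError(
        f"deterministic_gap_pair failed after {max_tries} tries "
        f"(ell={ell}, g={g}, k={k}): {last_err}"
    )


def _spaced_positions(n: int, lo: int, hi: int, gap: int,
                      rng: np.random.Generator) -> np.ndarray:
    """n sorted positions in [lo, hi] with consecutive differences >= gap."""
    span = hi - lo - (n - 1) * gap
    if n > 0 and span < 0:
        raise ValueError("infeasible packing")
    extra = np.sort(rng.integers(0, span + 1, size=n))
    return lo + extra + gap * np.arange(n)


def sparsely_matched_pair(L: int, n_shared: int, k: int, w: int,
                          rng: np.random.Generator, max_tries: int = 200
                          ) -> tuple[KmerSequence, KmerSequence]:
    """A padded pair sharing exactly n_shared isolated k-mers.

    Shared k-mers are copied from A into fresh random filler at positions
    more than w apart and at least w from both ends, then the realized
    matching and the padded/sparse predicates are verified (spurious sharing
    between filler and A triggers a resample; use k >= 12 so that is rare).
    """
    if n_shared < 0:
        raise ValueError("n_shared must be >= 0")
    gap = max(w + 1, k + 1)
    if n_shared and w + (n_shared - 1) * gap > L - w - 1:
        raise ValueError("infeasible packing: increase L or reduce n_shared")
    if L * L > 4 ** k // 4:
        warnings.warn("4^k is small relative to L^2: expect many resamples",
                      stacklevel=2)
    for _ in range(max_tries):
        A = random_duplicate_free(L, k, rng)
        p_pos = _spaced_positions(n_shared, w, L - w - 1, gap, rng)
        q_pos = _spaced_positions(n_shared, w, L - w - 1, gap, rng)
        src = p_pos.copy()
        rng.shuffle(src)  # which A share lands at which B slot
        chars = list(_random_string(L + k - 1, rng))
        for q, p in zip(q_pos, src):
            chars[q: q + k] = A.source[p: p + k]
        B = KmerSequence.from_string("".join(chars), k)
        if not B.duplicate_free:
            continue
        m = kmer_matching(A, B)
        planted = set(zip(src.tolist(), q_pos.tolist()))
        if set(map(tuple, m.pairs.tolist())) != planted:
            continue
        if not is_sparsely_matched(A, B, m, w):
            continue
        return A, B
    raise RuntimeError(
        f"sparsely_matched_pair failed after {max_tries} tries "
        f"(L={L}, n_shared={n_shared}, k={k}, w={w})"
    )
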