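"""Analytical bias of the minimizer Jaccard estimator.

The expected sketch intersection E[Î] decomposes over *charging events*:
a minimizer charges exactly one window index, so ``Î`` is a sum of indicator
products over matched position pairs (p, q) and their legal charged indices
(i, j).  Conditioned on the shared anchor hash value x, each joint event
requires some positions to hash below x and some above; with matched pairs
counted once, the event probability is ``x^alpha * (1-x)^beta`` and its
contribution to E[Î] is the Beta integral

    ∫₀¹ x^alpha (1-x)^beta dx = alpha! beta! / (alpha+beta+1)!

Summing over all consistent configurations yields C(A, B; w), which brackets
E[Î] within [C, C+2].  With the expected sketch union approximated by
d·L - C for d = 4/(w+1), the bias estimate is

    B(A, B; w) = C / (d·L - C) - J(A, B),

accurate up to an additive error eps <= 15 w² / L^(1/3).

Closed forms are provided for two structured layouts: sparsely-matched pairs
(every shared k-mer isolated by more than w positions) and the deterministic
gap layout (identical sequences mutated every g bases), whose bias involves
harmonic numbers.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from fractions import Fraction
from typing import Optional

import numpy as np

from .matching import KmerMatching, kmer_matching
from .sketch import KmerSequence

try:  # numba accelerates the configuration enumeration; pure python fallback
    from numba import njit as _njit
except ImportError:  # pragma: no cover
    _njit = None

__all__ = [
    "ChargePattern",
    "BiasReport",
    "charge_pattern",
    "joint_integral",
    "joint_integral_exact",
    "expected_intersection",
    "configuration_counts",
    "bias_estimate",
    "epsilon_bound",
    "sparse_ratio_bound",
    "sparse_bias_bound",
    "harmonic_number",
    "gap_layout_h",
    "gap_layout_bias",
    "mash_divergence",
    "jaccard_from_divergence",
]


# -- charge patterns -------------------------------------------------------


@dataclass(frozen=True)
class ChargePattern:
    """Sign pattern of the event {position p charges index i}.

    Conditioned on a_p = x, every position in ``below`` must hash under x and
    every position in ``above`` over x.  The anchor belongs to neither set.
    """

    anchor: int
    below: frozenset
    above: frozenset

    @property
    def alpha(self) -> int:
        return len(self.below)

    @property
    def beta(self) -> int:
        return len(self.above)


def charge_pattern(i: int, p: int, w: int, L: int) -> list[ChargePattern]:
    """Patterns whose disjunction is {p charges i}; here always a single one.

    Index i must lie in [max(-1, p-w), min(p-1, L-w-1)].  The window
    positions i+1 .. i+w other than p go above; position i goes below unless
    i sits at the boundary max(-1, p-w), where the charging definition
    imposes no constraint on a_i.
    """
    lo = max(-1, p - w)
    hi = min(p - 1, L - w - 1)
    if not (lo <= i <= hi):
        raise ValueError(f"index i={i} outside legal charge range [{lo}, {hi}] for p={p}")
    above = frozenset(t for t in range(i + 1, i + w + 1) if t != p)
    below = frozenset([i]) if i > lo else frozenset()
    return [ChargePattern(anchor=p, below=below, above=above)]


def joint_integral_exact(alpha: int, beta: int) -> Fraction:
    """∫₀¹ x^alpha (1-x)^beta dx as an exact rational."""
    if alpha < 0 or beta < 0:
        raise ValueError("alpha and beta must be non-negative")
    return Fraction(math.factorial(alpha) * math.factorial(beta),
                    math.factorial(alpha + beta + 1))


def joint_integral(alpha: int, beta: int) -> float:
    return float(joint_integral_exact(alpha, beta))


# -- C(A, B; w): configuration enumeration ---------------------------------


def _beta_table(w: int) -> np.ndarray:
    tab = np.empty((3, 2 * (w - 1) + 1), dtype=np.float64)
    for a in range(3):
        for b in range(2 * (w - 1) + 1):
            tab[a, b] = joint_integral(a, b)
    return tab


def _c_kernel(pp, qq, match_A, match_B, w, LA, LB, beta_table):
    total = 0.0
    for t in range(pp.size):
        p = pp[t]
        q = qq[t]
        ilo = max(-1, p - w)
        ihi = min(p - 1, LA - w - 1)
        jlo = max(-1, q - w)
        jhi = min(q - 1, LB - w - 1)
        for i in range(ilo, ihi + 1):
            a_below = i >= 0 and i > ilo
            for j in range(jlo, jhi + 1):
                b_below = j >= 0 and j > jlo
                alpha = 0
                consistent = True
                if a_below and b_below and match_A[i] == j:
                    alpha = 1
                else:
                    if a_below:
                        m = match_A[i]
                        if m >= 0 and j + 1 <= m <= j + w and m != q:
                            consistent = False
                        alpha += 1
                    if b_below:
                        m = match_B[j]
                        if m >= 0 and i + 1 <= m <= i + w and m != p:
                            consistent = False
                        alpha += 1
                if not consistent:
                    continue
                merged = 0
                for s in range(i + 1, i + w + 1):
                    if s == p:
                        continue
                    m = match_A[s]
                    if m >= 0 and j + 1 <= m <= j + w and m != q and m != j:
                        merged += 1
                beta = 2 * (w - 1) - merged
                total += beta_table[alpha, beta]
    return total


if _njit is not None:
    _c_kernel_jit = _njit(cache=True)(_c_kernel)
else:  # pragma: no cover
    _c_kernel_jit = None


def configuration_counts(A: KmerSequence, B: KmerSequence, w: int,
                         matching: Optional[KmerMatching] = None) -> dict:
    """Multiplicity of each consistent (alpha, beta) configuration.

    Reference implementation of the same enumeration as the fast kernel;
    the number of distinct keys is at most 6(w-1).
    """
    m = matching if matching is not None else kmer_matching(A, B)
    counts: dict = {}
    for p, q in m.pairs:
        p, q = int(p), int(q)
        ilo, ihi = max(-1, p - w), min(p - 1, A.L - w - 1)
        jlo, jhi = max(-1, q - w), min(q - 1, B.L - w - 1)
        for i in range(ilo, ihi + 1):
            (pat_a,) = charge_pattern(i, p, w, A.L)
            for j in range(jlo, jhi + 1):
                (pat_b,) = charge_pattern(j, q, w, B.L)
                # merge through the matching: matched positions share a value
                below_vars = set()
                above_vars = set()
                consistent = True
                for s in pat_a.below:
                    mm = m.match_A[s]
                    below_vars.add(("m", s, int(mm)) if mm >= 0 else ("a", s))
                for s in pat_b.below:
                    mm = m.match_B[s]
                    below_vars.add(("m", int(mm), s) if mm >= 0 else ("b", s))
                for s in pat_a.above:
                    mm = m.match_A[s]
                    above_vars.add(("m", s, int(mm)) if mm >= 0 else ("a", s))
                for s in pat_b.above:
                    mm = m.match_B[s]
                    above_vars.add(("m", int(mm), s) if mm >= 0 else ("b", s))
                if below_vars & above_vars:
                    consistent = False
                if consistent:
                    key = (len(below_vars), len(above_vars))
                    counts[key] = counts.get(key, 0) + 1
    return counts


def expected_intersection(A: KmerSequence, B: KmerSequence, w: int,
                          matching: Optional[KmerMatching] = None,
                          engine: str = "auto") -> float:
    """C(A, B; w): the configuration-count approximation to E[Î].

    Satisfies C <= E[Î] <= C + 2 and C <= 2L/(w+1).  Cost is
    O(|matching| * w^2 * w); with the compiled kernel this handles
    L ~ 10^4-10^5 and w in the tens to hundreds.
    """
    if w < 2:
        raise ValueError("w must be >= 2")
    if min(A.L, B.L) < w + 1:
        raise ValueError("need L >= w + 1")
    m = matching if matching is not None else kmer_matching(A, B)
    if engine == "python" or (engine == "auto" and _c_kernel_jit is None):
        counts = configuration_counts(A, B, w, m)
        return float(sum(n * joint_integral_exact(a, b) for (a, b), n in counts.items()))
    kern = _c_kernel_jit if _c_kernel_jit is not None else _c_kernel
    return float(
        kern(
            np.ascontiguousarray(m.pairs[:, 0], dtype=np.int64),
            np.ascontiguousarray(m.pairs[:, 1], dtype=np.int64),
            m.match_A, m.match_B, w, A.L, B.L, _beta_table(w),
        )
    )


# -- the bias estimate -----------------------------------------------------


@dataclass
class BiasReport:
    """Bundled analytical quantities for one sequence pair and window size."""

    J: float          # true Jaccard
    C: float          # expected-intersection approximation
    B: float          # bias estimate: C/(dL - C) - J
    U_approx: float   # 4L/(w+1) - C
    epsilon: float    # additive error bound on B
    w: int
    L: int
    k: int

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame([self.__dict__])


def epsilon_bound(w: int, L: int, coeff: float = 15.0) -> float:
    """Additive error bound coeff * w^2 / L^(1/3) on the bias estimate.

    Vacuous (>1) at many practical scales, e.g. w=20 with non-astronomical L;
    the empirically observed error is far smaller.
    """
    if w < 2:
        raise ValueError("w must be >= 2")
    return coeff * w * w / L ** (1.0 / 3.0)


def bias_estimate(A: KmerSequence, B: KmerSequence, w: int,
                  matching: Optional[KmerMatching] = None,
                  engine: str = "auto") -> BiasReport:
    """B(A, B; w) = C/(4L/(w+1) - C) - J, with the supporting quantities."""
    if A.L != B.L:
        raise ValueError("bias estimate assumes equal-length sequences")
    L = A.L
    if L < 7 * (w + 1):
        warnings.warn(
            f"L={L} < 7(w+1)={7 * (w + 1)}: below the regime where the error "
            "bound on B is guaranteed", stacklevel=2,
        )
    m = matching if matching is not None else kmer_matching(A, B)
    C = expected_intersection(A, B, w, m, engine=engine)
    cap = 2.0 * L / (w + 1)
    if C > cap * (1 + 1e-9):
        raise RuntimeError(f"C={C} exceeds 2L/(w+1)={cap}: internal error")
    U_approx = 4.0 * L / (w + 1) - C
    if U_approx <= 0:
        raise RuntimeError("approximate union non-positive")
    J = m.J
    return BiasReport(J=J, C=C, B=C / U_approx - J, U_approx=U_approx,
                      epsilon=epsilon_bound(w, L), w=w, L=L, k=A.k)


# -- closed forms for structured layouts -----------------------------------


def sparse_ratio_bound(w: int) -> Fraction:
    """Reported ceiling on E[Ĵ]/J for sparsely-matched pairs: (5w²-3w-2)/(8w²-2).

    Evaluates to 2/5 at w=2, ≈0.606 at w=20, with limit 5/8 as w grows.
    """
    if w < 2:
        raise ValueError("w must be >= 2")
    return Fraction(5 * w * w - 3 * w - 2, 8 * w * w - 2)


def sparse_bias_bound(J: float, w: int) -> float:
    """Upper bound -J(3w²-3w)/(8w²-2) on the bias of sparsely-matched pairs.

    Tight in the low share-density limit; generated sparse pairs sit strictly
    below it.
    """
    if not 0 <= J <= 1:
        raise ValueError("J must lie in [0, 1]")
    if w < 2:
        raise ValueError("w must be >= 2")
    return -J * (3 * w * w - 3 * w) / (8 * w * w - 2)


def harmonic_number(n: int) -> Fraction:
    """H_n = 1 + 1/2 + ... + 1/n as an exact rational."""
    if n < 0:
        raise ValueError("n must be >= 0")
    return sum((Fraction(1, j) for j in range(1, n + 1)), Fraction(0))


def gap_layout_h(w: int) -> float:
    """Per-mutation charge term h(w) = (w+1)(1 - 2(H_{2w} - H_w)) / 2.

    Negative for w >= 2 (since H_{2w} - H_w > 1/2), which is what makes the
    gap-layout bias negative.
    """
    if w < 2:
        raise ValueError("w must be >= 2")
    return float((w + 1) * (1 - 2 * (harmonic_number(2 * w) - harmonic_number(w))) / 2)


def gap_layout_bias(ell: int, g: int, k: int, w: int) -> float:
    """Closed-form bias for the deterministic-gap layout.

    Two otherwise identical duplicate-free sequences of L = ell*g + k k-mers
    differ by single-base mutations at nucleotide positions k-1+i*g for
    i = 0..ell.  Requires 2 <= w < k and g > w + 2k so the mutated stretches
    are isolated.  Returns

        B = 2*ell*L*h(w) / ((ell*(g+k) + 2k - ell*h(w)) * (ell*(g+k) + 2k))

    which is negative.
    """
    if not 2 <= w < k:
        raise ValueError("need 2 <= w < k")
    if g <= w + 2 * k:
        raise ValueError("need g > w + 2k")
    if ell < 1:
        raise ValueError("need ell >= 1")
    L = ell * g + k
    h = gap_layout_h(w)
    denom_core = ell * (g + k) + 2 * k
    return 2.0 * ell * L * h / ((denom_core - ell * h) * denom_core)


# -- divergence (ANI) conversions ------------------------------------------


def mash_divergence(j_hat: float, k: int, mode: str = "binomial") -> float:
    """Per-base divergence inferred from a Jaccard value.

    ``poisson`` is the classical Mash formula -(1/k) ln(2J/(1+J)); ``binomial``
    inverts the exact containment relation J = t/(2-t) with t = (1-d)^k,
    giving d = 1 - (2J/(1+J))^(1/k).  The two agree to first order as d -> 0;
    the Poisson form overestimates at higher divergence.  J=0 carries no
    signal and returns the maximal divergence 1.0.
    """
    if not 0 <= j_hat <= 1:
        raise ValueError("jaccard must lie in [0, 1]")
    if j_hat == 0:
        return 1.0
    t = 2.0 * j_hat / (1.0 + j_hat)
    if mode == "poisson":
        return -math.log(t) / k
    if mode == "binomial":
        return 1.0 - t ** (1.0 / k)
    raise ValueError(f"unknown mode {mode!r}")


def jaccard_from_divergence(d: float, k: int) -> float:
    """Forward map: expected Jaccard t/(2-t) with t = (1-d)^k."""
    if not 0 <= d <= 1:
        raise ValueError("divergence must lie in [0, 1]")
    t = (1.0 - d) ** k
    return t / (2.0 - t)
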