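import numpy as np
import pytest

from sketchbias import KmerSequence


@pytest.fixture
def rng():
    return np.random.default_rng(20_240_901)


def tiny_pair(rng, n_max=8, w_max=3):
    """Random small pair over a shared universe of <= n_max distinct k-mers.

    Suitable for exact permutation enumeration.  Returns (A, B, w).
    """
    n = int(rng.integers(5, n_max + 1))
    w = int(rng.integers(2, w_max + 1))
    L_A = int(rng.integers(w + 1, n + 1))
    L_B = int(rng.integers(w + 1, n + 1))
    A = KmerSequence.from_codes(rng.permutation(n)[:L_A], 4)
    B = KmerSequence.from_codes(rng.permutation(n)[:L_B], 4)
    return A, B, w


# Worked tiny layouts: a shared k-mer x flanked by unshared neighbors.
# With w=2, x at the middle of three is a minimizer iff it is not the largest
# of its window pair on at least one side.
@pytest.fixture
def shared_middle_distinct():
    """A = [u1, x, u2], B = [v1, x, v2]: five distinct hash values."""
    A = KmerSequence.from_kmers(["AA", "CC", "GG"])
    B = KmerSequence.from_kmers(["TT", "CC", "AT"])
    return A, B


@pytest.fixture
def shared_middle_tied_tail():
    """A = [u1, x, u2], B = [v1, x, u2]: the right neighbor is itself shared."""
    A = KmerSequence.from_kmers(["AA", "CC", "GG"])
    B = KmerSequence.from_kmers(["TT", "CC", "GG"])
    return A, B
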