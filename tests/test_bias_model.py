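from fractions import Fraction

import numpy as np
import pytest
from scipy.integrate import quad

from sketchbias import (
    KmerSequence,
    bias_estimate,
    charge_pattern,
    configuration_counts,
    epsilon_bound,
    expected_intersection,
    gap_layout_bias,
    gap_layout_h,
    harmonic_number,
    jaccard_from_divergence,
    joint_integral,
    joint_integral_exact,
    joint_minimizer_probability,
    kmer_matching,
    mash_divergence,
    sparse_bias_bound,
    sparse_ratio_bound,
    sparsely_matched_pair,
)
from sketchbias.oracle import exact_expectations


class TestJointIntegral:
    @pytest.mark.parametrize("a,b,expect", [
        (0, 0, Fraction(1)),
        (1, 1, Fraction(1, 6)),
        (2, 2, Fraction(1, 30)),
        (0, 2, Fraction(1, 3)),
        (1, 2, Fraction(1, 12)),
    ])
    def test_closed_form(self, a, b, expect):
        assert joint_integral_exact(a, b) == expect

    def test_against_quadrature(self):
        for a in range(3):
            for b in range(8):
                num, _ = quad(lambda x: x**a * (1 - x) ** b, 0, 1)
                assert joint_integral(a, b) == pytest.approx(num, abs=1e-10)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            joint_integral_exact(-1, 0)


class TestChargePattern:
    def test_boundary_index_has_no_below_clause(self):
        (pat,) = charge_pattern(i=-1, p=1, w=3, L=10)
        assert pat.below == frozenset()
        assert pat.above == frozenset({0, 2}) and pat.anchor == 1

    def test_interior_index_constrains_i_below(self):
        (pat,) = charge_pattern(i=4, p=5, w=3, L=10)
        assert pat.below == frozenset({4})
        assert pat.above == frozenset({6, 7})

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            charge_pattern(i=5, p=5, w=3, L=10)

    def test_pattern_probabilities_sum_to_minimizer_probability(self):
        # summing the Beta integrals over all legal i gives 2/(w+1) for an
        # interior position, the classical minimizer density
        for w in (2, 3, 5, 8):
            L, p = 4 * w, 2 * w
            total = Fraction(0)
            for i in range(max(-1, p - w), min(p - 1, L - w - 1) + 1):
                (pat,) = charge_pattern(i, p, w, L)
                total += joint_integral_exact(pat.alpha, pat.beta)
            assert total == Fraction(2, w + 1)


class TestExpectedIntersection:
    def test_empty_matching_gives_zero(self, rng):
        A = KmerSequence.from_codes(np.arange(12), 4)
        B = KmerSequence.from_codes(np.arange(12) + 50, 4)
        assert expected_intersection(A, B, 3) == 0.0

    def test_worked_shared_middle_layouts(self, shared_middle_distinct,
                                          shared_middle_tied_tail):
        # per-shared-k-mer joint minimizer probability 8/15 (distinct flanks)
        # and 7/12 (one flank itself shared); C matches the exact E[I-hat]
        A, B = shared_middle_distinct
        assert expected_intersection(A, B, 2) == pytest.approx(8 / 15)
        A, B = shared_middle_tied_tail
        C = expected_intersection(A, B, 2)
        E_I = exact_expectations(A, B, 2).E_I
        assert C == pytest.approx(float(E_I))  # 7/12 + 1/2 for the two pairs
        assert E_I == Fraction(7, 12) + Fraction(1, 2)

    def test_layout_changes_C_but_not_J(self):
        # equal I and U (hence equal J) but different layouts: isolated vs
        # adjacent shares give different expected sketch intersections
        def pair(pos_a, pos_b):
            ca = np.arange(1000, 1020)
            cb = np.arange(2000, 2020)
            for t, (p, q) in enumerate(zip(pos_a, pos_b)):
                ca[p] = cb[q] = 3000 + t
            return (KmerSequence.from_codes(ca, 4), KmerSequence.from_codes(cb, 4))

        A1, B1 = pair([5, 12], [8, 15])
        A2, B2 = pair([5, 6], [8, 9])
        m1, m2 = kmer_matching(A1, B1), kmer_matching(A2, B2)
        assert (m1.I, m1.U) == (m2.I, m2.U)  # J identical by construction
        c_isolated = expected_intersection(A1, B1, 3, m1)
        c_adjacent = expected_intersection(A2, B2, 3, m2)
        assert c_isolated != pytest.approx(c_adjacent)

    def test_per_share_probability_is_layout_sensitive(
            self, shared_middle_distinct, shared_middle_tied_tail):
        A1, B1 = shared_middle_distinct
        A2, B2 = shared_middle_tied_tail
        t1 = joint_minimizer_probability(A1, B1, 2, 1, 1)
        t2 = joint_minimizer_probability(A2, B2, 2, 1, 1)
        assert t1 != t2

    def test_python_and_compiled_engines_agree(self, rng):
        for _ in range(10):
            codes = rng.permutation(40)
            A = KmerSequence.from_codes(codes[:15], 4)
            B = KmerSequence.from_codes(rng.permutation(codes[:30])[:15], 4)
            for w in (2, 4):
                assert expected_intersection(A, B, w, engine="python") == \
                    pytest.approx(expected_intersection(A, B, w, engine="numba"))

    def test_distinct_configurations_bounded(self, rng):
        # at most 6(w-1) distinct (alpha, beta) configurations arise
        for w in (2, 3, 5):
            codes = rng.permutation(60)
            A = KmerSequence.from_codes(codes[:25], 4)
            B = KmerSequence.from_codes(rng.permutation(codes[:40])[:25], 4)
            counts = configuration_counts(A, B, w)
            assert len(counts) <= 6 * (w - 1)
            assert all(a <= 2 and b <= 2 * (w - 1) for a, b in counts)

    def test_intersection_cap(self, rng):
        # C never exceeds 2L/(w+1) (shared-minimizer count cap)
        for _ in range(20):
            n = int(rng.integers(10, 30))
            L = int(rng.integers(6, n + 1))
            w = int(rng.integers(2, 5))
            if L < w + 1:
                continue
            codes = rng.permutation(n)
            A = KmerSequence.from_codes(codes[:L], 4)
            B = KmerSequence.from_codes(rng.permutation(n)[:L], 4)
            assert expected_intersection(A, B, w) <= 2 * L / (w + 1) + 1e-9


class TestBiasEstimate:
    def test_zero_jaccard_zero_bias(self, rng):
        A = KmerSequence.from_codes(np.arange(40), 4)
        B = KmerSequence.from_codes(np.arange(40) + 100, 4)
        rep = bias_estimate(A, B, 3)
        assert rep.J == 0.0 and rep.B == 0.0 and rep.C == 0.0

    def test_negative_for_padded_positive_jaccard(self, rng):
        for w in (2, 4):
            A, B = sparsely_matched_pair(300, 4, 13, w, rng)
            rep = bias_estimate(A, B, w)
            assert rep.J > 0 and rep.B < 0

    def test_symmetry(self, rng):
        A, B = sparsely_matched_pair(200, 3, 13, 3, rng)
        ra, rb = bias_estimate(A, B, 3), bias_estimate(B, A, 3)
        assert ra.C == pytest.approx(rb.C) and ra.B == pytest.approx(rb.B)

    def test_short_sequences_warn(self, rng):
        A, B = sparsely_matched_pair(60, 1, 13, 2, rng)
        with pytest.warns(UserWarning, match="7"):
            bias_estimate(A, B, 8)


class TestEpsilonBound:
    def test_values_and_monotonicity(self):
        assert epsilon_bound(2, 10**12) == pytest.approx(60 / 10**4)
        assert epsilon_bound(20, 10**4) > 1  # vacuous at practical scales
        assert epsilon_bound(5, 1000) < epsilon_bound(6, 1000)
        assert epsilon_bound(5, 2000) < epsilon_bound(5, 1000)
        assert epsilon_bound(2, 1000, coeff=100) == pytest.approx(100 * 4 / 10)


class TestSparseClosedForms:
    def test_ratio_values(self):
        assert sparse_ratio_bound(2) == Fraction(12, 30)
        assert sparse_ratio_bound(20) == Fraction(1938, 3198)
        assert float(sparse_ratio_bound(20)) == pytest.approx(0.606, abs=5e-4)
        # large-w limit is 5/8
        assert float(sparse_ratio_bound(10**6)) == pytest.approx(5 / 8, abs=1e-5)

    def test_bias_bound_arithmetic(self):
        assert sparse_bias_bound(0.0, 4) == 0.0
        assert sparse_bias_bound(1.0, 2) == pytest.approx(-6 / 30)

    def test_generated_sparse_pairs_satisfy_bound(self, rng):
        for w in (2, 5, 10, 20):
            for _ in range(5):
                L = max(420, 25 * (w + 1))
                A, B = sparsely_matched_pair(L, 5, 13, w, rng)
                m = kmer_matching(A, B)
                rep = bias_estimate(A, B, w, matching=m)
                assert rep.B <= sparse_bias_bound(rep.J, w) + 1e-12


class TestGapLayoutClosedForm:
    def test_harmonic_arithmetic(self):
        assert harmonic_number(4) - harmonic_number(2) == Fraction(7, 12)
        assert harmonic_number(0) == 0

    def test_h_negative(self):
        for w in (2, 5, 10, 50):
            assert gap_layout_h(w) < 0

    def test_agrees_with_configuration_formula(self, rng):
        # closed form vs C-based estimate on constructed layouts
        import warnings

        from sketchbias import deterministic_gap_pair

        for ell, g, k, w in [(3, 20, 5, 3), (5, 40, 8, 4), (10, 61, 10, 6)]:
            A, B = deterministic_gap_pair(ell, g, k, rng, w=w)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # short-L warning expected
                rep = bias_estimate(A, B, w)
            assert gap_layout_bias(ell, g, k, w) == pytest.approx(rep.B, rel=0.10)

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            gap_layout_bias(3, 20, 5, 5)  # w must be < k
        with pytest.raises(ValueError):
            gap_layout_bias(3, 12, 5, 3)  # g must exceed w + 2k
        with pytest.raises(ValueError):
            gap_layout_bias(0, 20, 5, 3)


class TestDivergence:
    def test_identical_sequences(self):
        assert mash_divergence(1.0, 16, "poisson") == 0.0
        assert mash_divergence(1.0, 16, "binomial") == 0.0

    def test_zero_jaccard_sentinel(self):
        assert mash_divergence(0.0, 16) == 1.0

    def test_binomial_inverts_forward_map(self):
        for k in (8, 16, 21):
            for d in np.linspace(0.001, 0.5, 40):
                j = jaccard_from_divergence(d, k)
                assert abs(mash_divergence(j, k, "binomial") - d) < 1e-12

    def test_modes_agree_to_first_order(self):
        k = 16
        for d in (1e-4, 1e-5, 1e-6):
            j = jaccard_from_divergence(d, k)
            ratio = mash_divergence(j, k, "poisson") / mash_divergence(j, k, "binomial")
            assert ratio == pytest.approx(1.0, abs=50 * d)

    def test_poisson_overestimates_at_high_divergence(self):
        j = jaccard_from_divergence(0.15, 16)
        assert mash_divergence(j, 16, "poisson") > mash_divergence(j, 16, "binomial")
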