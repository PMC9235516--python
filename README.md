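# sketchbias

Minimizer sketches, the minimizer Jaccard estimator, and an analytical
account of its bias.

## The problem

Sketching lets sequence-comparison tools work on a small subset of k-mers
instead of whole genomes.  The *minimizer sketch* `MS(A; w)` keeps, for every
window of `w` consecutive k-mers, the k-mer with the smallest hash value; the
*minimizer Jaccard estimator*

    Ĵ(A, B; w) = |MS(A;w) ∩ MS(B;w)| / |MS(A;w) ∪ MS(B;w)|

is used by mapping tools to approximate the true Jaccard similarity
`J(A, B) = |Sp_k(A) ∩ Sp_k(B)| / |Sp_k(A) ∪ Sp_k(B)|` of the k-mer spectra.
Unlike the classical minhash estimator, Ĵ is **biased and inconsistent**:
`E[Ĵ] − J` does not vanish as sequences grow, because `E[Ĵ]` depends on
*where* the shared k-mers sit along the sequences while `J` depends only on
how many there are.  This package is for people who use (or build) sketch
based comparison tools and want to quantify that bias.

## What it computes

For duplicate-free sequences `A`, `B` of `L` k-mers each, every minimizer
charges a unique window, so `E[Î]` decomposes over matched position pairs
`(p, q)` and charged indices `(i, j)`.  Conditioned on the shared anchor hash
value `x`, each joint charging event needs `α` positions below and `β` above
`x` (matched pairs counted once) and contributes the Beta integral
`∫₀¹ x^α (1−x)^β dx = α!β!/(α+β+1)!`.  The sum over consistent
configurations, `C(A, B; w)`, brackets `E[Î]` within `[C, C+2]`, and

    B(A, B; w) = C / (4L/(w+1) − C) − J(A, B)

approximates the bias up to an additive `ε ≤ 15 w²/∛L`.  The package provides:

- `sketch` / `matching` — k-merization, seeded hashing, minimizer sketches,
  charged windows, the k-mer matching and its padded / sparsely-matched
  predicates;
- `bias` — the `C` enumeration (numba-accelerated), the bias report `B`,
  closed-form bounds for sparsely-matched pairs, the harmonic-number closed
  form for deterministic-gap layouts, and Poisson/Binomial Jaccard-to-
  divergence conversions;
- `oracle` — exact expectations by enumerating all orderings of the union
  spectrum (tiny instances), and Monte-Carlo estimation over hash replicates;
- `generate` — duplicate-free sequence-pair generators (unrelated pairs at a
  target Jaccard, per-position mutation pairs, deterministic-gap layouts,
  sparsely-matched constructions);
- `sweep` — grid drivers pairing empirical bias with the analytical estimate,
  and a power-law fit of error versus length.

## Worked example

`python examples/analytical_bias.py` generates an unrelated duplicate-free
pair at target Jaccard 0.9 (k=8, w=20, L=62086 k-mers) and prints:

```
true Jaccard J           = 0.8998
expected intersection C  = 3639.1  (of ~5913 max)
analytical bias B        = -0.4553
predicted   E[J^] ~ J+B  = 0.4445
observed    J-bar (50 replicates) = 0.4448
|J-bar - J - B| = 0.00026  (the formula tracks the observed bias to ~1e-3)
```

A pair whose spectra overlap 90% yields sketch estimates averaging 0.44 —
the estimator halves the similarity — and the analytical `B` predicts the
collapse to three decimals.  `examples/gap_layout_closed_form.py` does the
same for the deterministic-gap layout, where the closed form in harmonic
numbers matches the configuration enumeration to machine precision, and
`examples/divergence_conversion.py` shows why divergence estimates should
invert the exact Binomial relation rather than the Poisson approximation.

A thin CLI mirrors the library (`sketchbias sketch|jaccard|bias|simulate|
oracle|mc|divergence|sweep`); run `sketchbias --help`.

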