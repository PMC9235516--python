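# Methods

## Model and assumptions

All theory operates on two duplicate-free sequences of `L` k-mers under an
idealized hash: each distinct k-mer receives an independent Uniform[0,1)
value, so collisions have probability zero and minimizer selection depends
only on the relative order of hash values.  The implementation realizes the
hash as a seeded splitmix-style 64-bit mixer scaled to [0,1); argmin ties
(possible only through 64-bit collisions) are broken toward the smaller
position, giving a strict total order.  Reverse complements are not
canonicalized: the model is strand-fixed, and windowed variants such as
syncmers or modulo sketches are out of scope.

Sequences with duplicate k-mers are accepted by the sketching and Jaccard
operations with set semantics plus a warning; the matching and bias
machinery requires duplicate-free input because the position-to-position
matching (and everything built on it) is otherwise ill-defined.

## Charging and the configuration enumeration

Position `p` charges index `i` when `i ∈ [max(−1, p−w), p−1]`, `a_p` is the
minimum over window positions `i+1 .. i+w`, and either `i` is the lower end
of that range or `a_i < a_p`.  The window in the middle condition is always
the full `w` positions starting at `i+1`: since charged indices satisfy
`i ≤ L−w−1`, the window never crosses the right edge, which resolves an
ambiguity in how the definition's upper index can be read.  This reading is
validated by brute force: on random instances a position charges exactly one
index iff it is a minimizer.

`C(A, B; w)` iterates over matched pairs only (the indicator kills all other
terms), over all legal charged indices including the boundary index −1 and
edge windows, so the computation remains valid for non-padded inputs.  Sign
patterns from the two sides are merged through the matching: a matched pair
of constrained positions is one variable (counted once when the signs agree,
zeroing the term when they conflict); a constrained position can never hold
the anchor k-mer because the sequences are duplicate-free.  Beta integrals
are tabulated exactly (`α ≤ 2`, `β ≤ 2(w−1)`), so the only floating-point
step is the final summation.  The hot triple loop costs
`O(|matching| · w³)` and is compiled with numba; a pure-Python reference
path (`configuration_counts`) produces the same sums and doubles as the
cross-check and as the source of the distinct-configuration audit.

The bias estimate is `B = C/(4L/(w+1) − C) − J` with additive error bound
`ε = coeff · w²/∛L`.  The constant is exposed (`coeff`, default 15) because
the bound is quoted with different constants in different places; at
practical scales it is vacuous either way (for w=20 it exceeds 1 unless L is
astronomical), while the observed error of `B` is two to three orders of
magnitude smaller — the acceptance run measures ~1e-3 on the unrelated-pair
grid against 50 hash replicates.

## Exact oracle and Monte Carlo

Because only hash order matters, exact expectations on a tiny instance are
averages over all `n!` rank assignments to the `n` distinct k-mers of the
union spectrum (refused above `n = 10`).  Sums are accumulated as exact
rationals so worked enumerations (e.g. the 64/120 and 14/24 joint minimizer
probabilities of a shared k-mer with distinct or partially shared flanks at
w=2) are reproduced exactly, not approximately.  The per-share probability
may equivalently be computed on a minimal 3-k-mer embedding or on a padded
one; both agree because the event involves only the window neighborhoods.

Monte-Carlo estimation re-runs the estimator under hash replicates whose
seeds derive from a master seed through a counter-based seed sequence; the
seed list is recorded in the output, making every estimate bit-reproducible.

## Closed forms

For padded sparsely-matched pairs each shared k-mer contributes
independently, and the bias obeys `B ≤ −J(3w²−3w)/(8w²−2)`; the property
suite asserts this bound on generated pairs across w ∈ {2, 5, 10, 20}.  The
companion ratio ceiling on `E[Ĵ]/J` is reported by `sparse_ratio_bound` as
`(5w²−3w−2)/(8w²−2)` (40% at w=2, ≈61% at w=20, limit 5/8); it is exposed
as a reporting convention and deliberately not asserted against simulated
pairs, which are checked against the bias bound above instead.

For the deterministic-gap layout the closed form is

    B = 2ℓL·h(w) / ((ℓ(g+k) + 2k − ℓh(w)) · (ℓ(g+k) + 2k)),   L = ℓg + k

with `h(w) = (w+1)(1 − 2(H_{2w} − H_w))/2`.  The division by 2 (rather than
a square) was fixed by requiring agreement with the configuration
enumeration and with simulation: `h` is then negative (H_{2w} − H_w > 1/2),
making `B` negative as the padded-pair sign result demands, and the closed
form matches the `C`-based estimate to machine precision on constructed
layouts.  At k=15, w=10 the relative loss `100(J − E[Ĵ])/J` is ≈9.5% for
g=43 (L=9991) and ≈3.7% for g=100 (L=10015); the layout lengths are the
nearest integers of the form ℓg+k.

Divergence conversions: the Poisson form is `−ln(2J/(1+J))/k`; the Binomial
form inverts `J = t/(2−t)`, `t = (1−d)^k`, exactly (round-trip error below
1e-12 on a grid), and a Jaccard of zero returns the sentinel divergence 1.0.

## Generators

* **unrelated pair** — `L = ⌊2j·4^k/(j+1)⌋` makes the expected Jaccard of
  two uniform L-subsets of the k-mer universe equal `j`.  Dense regimes
  (L comparable to 4^k, needed for high `j` at k=8) draw the sequence as a
  prefix of a randomized Eulerian circuit of the order-(k−1) de Bruijn
  graph — every k-mer is an edge, so any circuit prefix is duplicate-free by
  construction; sparse regimes use rejection sampling.  Realized `J`
  concentrates within ~0.005 of the target at k=8.
* **related pair** — sweeps the base string left to right, mutating each
  base with probability `r1` to an alternative that keeps the partially
  mutated string duplicate-free; when all three alternatives would create a
  duplicate the position is left unmutated.  With a random base this
  calibrates near the reference points (e.g. `r1 = 0.01`, `L = 10⁴`,
  `k = 16` lands near `J ≈ 0.74`); real genomes have repeat structure a
  random base lacks, so these calibrations are treated as loose diagnostics,
  not gates.
* **deterministic gap** — mutates bases `k−1+ig` of a random duplicate-free
  string, resampling until the mutated copy is duplicate-free and the
  realized matching equals the designed one (`I = L − (ℓ+1)k`); spurious
  collisions are rare for k ≥ 15 at these lengths.
* **sparsely matched** — copies `n_shared` k-mers of A into fresh random
  filler at positions spaced more than `w` apart and away from both ends,
  then verifies the realized matching is exactly the planted set and the
  padded/sparse predicates hold.  Requires k large enough (≥ 12 in tests)
  that filler-versus-A spurious sharing, expected ≈ L²/4^k per draw, stays
  rare.

"Padded" is implemented as the hash-independent sufficient condition — no
*shared k-mer* in the first or last `w` positions — rather than the
hash-dependent "no shared minimizer", so generators can guarantee it before
any hash is drawn.

## What the synthetic data does and does not show

The generators realize the exact study conditions of the analysis (known
matchings, duplicate-free guarantees, controlled layouts), which is what
makes exact bracketing tests possible.  They do not emulate repeat content,
GC skew, indels, or strandedness of real genomes; the mutation model is
substitution-only.  Passing tests therefore validate the estimator theory
and its implementation, not the magnitude of bias on any particular genome
pair — although the bias mechanism itself is layout-driven and carries over.

## Problem sizes and numerical choices

Test and acceptance runs use the study-condition sizes directly: the
unrelated grid at k=7/8 (L up to ~62k k-mers, 50 hash replicates), the gap
layouts at L ≈ 10⁴ with 200 replicates, exact enumeration up to 8 distinct
k-mers in property suites (100+ random instances per bracket).  The compiled
C kernel makes the largest grid instance a few seconds of work.  Degenerate
inputs: `L < w` is rejected for sketching; `w = 1` selects every position
(no sketching); `C ≥ 4L/(w+1)` or `C > 2L/(w+1)` raise internal errors since
they would contradict the counting caps; bias reports below `L = 7(w+1)`
carry a warning because the error bound is not guaranteed there.
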