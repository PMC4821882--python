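# Methods

## Scope and model

`degenlib` designs partially degenerate IUPAC sequences for a randomized
RBS window so that the encoded library's predicted translation initiation
rates (TIRs) match a target distribution. The input is an explicit
sequence → TIR table produced by an external predictor; this package never
predicts TIRs itself and treats them as opaque positive numbers in the
predictor's arbitrary units. No internal rescaling is applied — target
distributions carry the dataset's range instead.

## Candidate space

A degenerate sequence of length L over the 15 IUPAC codes encodes the
Cartesian product of per-position base sets; its degeneracy is the product
of the set sizes (∈ {1,2,3,4} per position), so achievable library sizes
are exactly the 3-smooth integers 2^a·3^b. Sizes are matched **exactly**
(degeneracy == m, not ≤ m). The number of candidates is computed in
closed form: for each factorization of m into factors {2,3,4} with counts
(k2,k3,k4),

    L! / (k2! k3! k4! (L−d)!) · 6^k2 · 4^k3 · 1^k4 · 4^(L−d),   d = k2+k3+k4,

summed over factorizations (6 two-fold, 4 three-fold, 1 four-fold code).
Enumeration is lexicographic over the canonical symbol order
A<C<G<T<R<Y<S<W<K<M<B<D<H<V<N, implemented as a pruned depth-first
generator (a prefix is extended only while the residual size divides m and
fits in the remaining positions). Degenerate codes may appear at any
window position; position-restricted designs are out of scope.

## Scoring

The empirical CDF of an m-member multiset uses the strictly-smaller-than
convention F(x) = H_n/n. All targets (uniform, uniform sub-range,
truncated Gaussian) are continuous, so

    d_KS = max_i max( F_t(x_(i)) − (i−1)/m ,  i/m − F_t(x_(i)) )

over the sorted members is the exact supremum; ties contribute through
step multiplicity. The Gaussian target is truncated to [lo, hi] and
renormalized, Φ-based; its μ and σ are required parameters (no default
width is assumed). Downstream comparisons of d_KS use exact float
ordering — every candidate is scored by the same code path, so no epsilon
is needed or wanted.

Uniform targets default to the **full dataset range** [tir_min, tir_max],
not each candidate's own range; this is what penalizes low-skew
candidates. Sub-range bounds may be given absolutely or as fractions of
the dataset range; bounds outside the range are clamped with a warning
(or rejected with `clamp=False`).

## Search

The search is exhaustive and the ranking therefore globally optimal.
Candidates are evaluated grouped by *structure* — the assignment of code
degeneracies to positions — so that one structure's members are scored by
a single gather / sort / CDF pass over a (candidates × m) array. Each
structure keeps only its top-k; chunks of structures are merged by
(d_KS, canonical sequence key). Since that key is a total order, the
ranked output is identical for any chunk count or worker count, and only
O(top_k) state is retained — a 70.2-million-candidate L=8, m=24 run never
materializes its scores (≈1–2 minutes on one CPU). The optimized member
lookup is tested observationally equivalent to `expand()` + `tirs_for()`.

Missing expansion members are a hard error by default (predictor exports
are complete 4^L tables); `skip_incomplete=True` drops affected candidates
and reports the count, for truncated exports.

Pathway designs score genes **independently** (the model has no
cross-gene coupling); a fixed-RBS gene contributes a factor 1 to the
combined size ∏ m_g. The "two-round" refinement is pure configuration:
round 2 is the same search with per-gene sub-range targets and fixed
genes.

## Screening statistics

Coverage is the expected fraction of distinct variants observed after T
equiprobable picks with replacement: exact 1 − (1 − 1/n)^T, Poisson
approximation 1 − e^(−T/n). The Poisson form is the default because it is
the convention of the screening literature this package interoperates
with (picks for 95% coverage = ⌈n ln 20⌉) and is conservative (never
exceeds the exact value). It is *not* the probability of seeing every
variant. All quantities are closed-form; n ≥ 10^7 costs nothing.

The picking simulator draws per-gene members independently and uniformly,
with replacement (picking clones re-samples the library), from one seeded
`numpy` generator; 252 picks (three 96-well plates) is the default
budget. Expression-space coverage is summarized as the occupied fraction
of an n-gene bin grid (linear or geometric bins, by default over each
library's own range; pass the dataset range to make skewed libraries look
as sparse as they are) plus the distinct-combination count, which links to
the closed form n·coverage(n, T) and is tested against the occupancy
distribution's mean and variance.

## Synthetic TIR tables

The generator emulates only the *shape* of predictor exports: complete
4^L tables, strictly positive rates, and a heavy low-TIR skew. Model:
per-position per-base weights w[p, b] ~ N(0, σ_p) drawn once per seed,
with σ_p = 1.0 inside a contiguous "hot" sub-window (the central
min(4, L) positions, anti-SD-core-like) and 0.15 elsewhere; energy
E(s) = Σ_p w[p, s_p]; rate TIR(s) = rate_max · exp(β (E − E_max)) with
rate_max = 150,000 au (a predictor-like scale). Additivity makes the TIR
multiset of a degenerate candidate structured (non-i.i.d.), which is what
makes the search problem non-trivial; the exponential link produces the
skew. β → 0 gives a flat table; the fraction of variants below a given
fraction of the range is non-decreasing in β, so `calibrate_skew` finds
the smallest β meeting a quantile specification by bisection (β ∈
[10⁻⁴, 64], tolerance 10⁻⁴; targets at or below the flat-table baseline
clamp to the smallest β). No biophysical fidelity is claimed: real
predictor tables have sequence-correlated structure (folding energies,
standby sites, context dependence) that this model does not emulate, so
passing tests demonstrate the correctness of the optimizer and its
statistics, not the quality of any particular predictor.

## Problem sizes used in the tests

Brute-force oracle comparisons enumerate all 15^L degenerate strings at
L ≤ 4 (50 seeded datasets at L ∈ {2,3}); the chunking-determinism check
runs the L=6, m=12 space (583,680 candidates); the full-scale check runs
the calibrated L=8, m=24 space (70,189,056 candidates) once; the
simulator link uses 1,000 seeded 252-pick runs on a 4×4 combination
space. These sizes keep the whole suite under a few minutes while still
exercising every code path at the scale the design problem is posed at.

## Known limitations

- Joint multi-gene objectives are out of scope; genes never interact in
  scoring (matching the design assumption, not cell physiology — e.g.
  mutual burden of two strong RBSs is real but unmodeled).
- Coverage statistics assume equiprobable variants; synthesis bias and
  unequal transformation efficiencies are not modeled.
- The KS objective compares distributions only; it does not penalize
  member TIRs being close to each other beyond what the CDF gap sees.
- Degenerate-sequence expansions are distinct by construction under the
  IUPAC code, so no deduplication across candidates is attempted.
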