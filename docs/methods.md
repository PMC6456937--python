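# Methods

## Normalization

Every factor series is imputed and then replaced by its normal scores
Z_k = Φ⁻¹(R_k/(n+1)), with midranks for ties.  The transform is invariant to
strictly increasing re-expressions of the raw data (so relative abundances,
log abundances, and raw fluorescence units all normalize identically) and
makes the downstream statistics correlation-scale.  The scores are *not*
rescaled to unit variance: their mean square s²_n = (1/n)Σ Φ⁻¹(k/(n+1))² is
below one (0.933 at n = 120, → 1 as n grows), and the null calibration of
the local-similarity p-value accounts for this explicitly.  A constant
series maps to all-zero scores with a logged warning — such a factor cannot
associate with anything and effectively drops out.

Imputation defaults to linear interpolation in time (nearest observed value
at the edges), the least-structured smooth fill for approximately monthly
series; `zero` and `fail` are available where interpolation is wrong for the
data at hand.  One rule is applied to all rows, biological and
environmental alike.  No detrending or seasonal decomposition is done.

## Local similarity

The signed LS statistic is computed by the positive/negative accumulator
dynamic program over alignment offsets |d| ≤ D and normalized by the full
series length n, so scores are comparable to correlation coefficients at
the same sample size.  The pipeline default is D = 0 (synchronous
associations only).  Tie-breaking is fully deterministic: higher score,
positive over negative accumulator, smaller |d| (negative offset before
positive), earliest segment start, shortest segment.  One subtlety: normal
scores contain exactly antisymmetric values, so a maximal segment is often
*tied* by a backward extension across a chunk whose running sum is exactly
zero; a refinement pass therefore locates the earliest-start, shortest
segment attaining the DP maximum under identical left-to-right rounding.
The test suite checks the DP against exhaustive enumeration over all
intervals and offsets, bit-exactly.

### Theoretical p-values

The maximal absolute segment sum equals the range (max − min) of the
partial-sum walk of the products, so √n·LS converges under the null to the
range of a standard Brownian motion on [0, 1], with tail
P(R ≥ x) = 8 Σ_{k≥1} (−1)^{k−1} k (1 − Φ(kx)).  At realistic series lengths
this asymptotic tail is substantially anticonservative (at n = 120 it
overstates the p-value of LS = 0.28 by a factor of ~4), because of the
sub-unit score variance, the discreteness of the walk, and the leptokurtic
product increments.  The default theoretical p-value therefore evaluates a
precomputed finite-sample calibration surface of the exact permutation
null: for 16 series lengths from 15 to 1000, one million random pairings of
the rank-score multisets were simulated offline (`scripts/build_null_table.py`,
seeded), and the log tail of the standardized statistic x = LS·√n/s²_n is
tabulated on a fixed grid and interpolated bilinearly in (1/√n, x).  Beyond
the tabulated grid, and as the n → ∞ limit column, the reflection series
takes over (offset-matched in log space).  This is the same design as the
simulation-calibrated response surfaces behind the Lilliefors and
Dickey–Fuller tests in statsmodels.  The suite validates the surface
against fresh 20,000-permutation estimates at n ∈ {50, 120} across
p ∈ [0.0005, 0.05], and checks empirical type-I error at n = 120.  For
n < 15 the shortest tabulated column is used with a warning — use the
permutation method for very short series.  The table assumes (nearly)
tie-free data; with heavy ties, prefer `p_method="perm"`.

Offsets for D > 0 are combined as p = 1 − F(x)^{2D+1}, treating the 2D+1
alignments as approximately independent.

Inverting the calibrated tail at n = 120 gives 0.30 as the smallest
two-decimal LS score with p ≤ 0.001 (the exact null puts p(0.28) ≈ 0.0022);
analyses in the literature using a one-sided or asymptotic approximation at
this length quote slightly smaller cutoffs.

### Screening filters

Pairs are kept when p ≤ 0.001, q ≤ 0.05 (q-values over the family of all
F(F−1)/2 tested pairs in the run), and the optimal segment spans strictly
more than half the series — the span filter discards associations confined
to a short window.  Filters are applied in that order and per-stage counts
are logged.

## Liquid association

LA(X;Y|Z) is the mean elementwise triple product of normal scores, exactly
symmetric in its arguments (each triple is multiplied in canonical sorted
order, so the symmetry identity holds bitwise, not just to rounding).  The
screening stage is what breaks the symmetry operationally: the pair comes
from LSA, the third factor is the mediator candidate.

The permutation test permutes Z only, preserving the pair's own dependence,
and is two-sided by default: the reference procedure's "fraction of
permuted scores higher than the true score" is sign-ambiguous for negative
LA, and both signs are biologically meaningful (all four mediation types
occur), so |LA| is compared; a `one_sided` option preserves the literal
upper-tail reading.  P-values use the (1 + count)/(N + 1) estimator, so the
smallest achievable p is 1/(N+1).  Internally the xy products and z are
sorted before pairings are drawn — the statistic depends only on the
pairing — which makes the p-value exactly invariant under jointly permuting
the three series.  Each (pair, Z) test draws its permutations from a
substream hashed from the run seed and the factor ids, so adding factors
never reshuffles unrelated tests.

Triplets are kept when p ≤ 0.001 and q ≤ 0.05, with q computed over the
pooled family of all (pair, Z) tests in the run (`scan_mediators` called
standalone uses its own pair's family); an optional |LA| effect cutoff
(e.g. 0.8 for focused subnetworks) is off by default.  Type classification
is the bijection (LS sign, LA sign) → {A: ++, B: −+, C: +−, D: −−}, since
positive LA means the XY product is largest where the centered Z is high.

### Permutation resolution vs. FDR — a usage caveat

Because permutation p-values are floored at 1/(N+1), the q-value of even a
perfect triplet is at least π̂0 · m · /(s·(N+1)) for s true signals among m
pooled tests.  With the defaults N = 1000 and Q ≤ 0.05, sparse discoveries
are therefore impossible once m exceeds ~50·s: e.g. 3 genuine mediators
among ~900 tests bottom out at q ≈ 0.2 no matter how strong the effect.
When scanning many candidates for few expected mediators, raise `n_perm`
so that (N+1) ≳ 20·m/s; the pipeline logs the family size to make this
check easy.  This interaction is inherent to the permutation + FDR design,
not a property of the data.

## Multiple testing

Storey q-values with the single-λ plug-in π̂0 = #{p > λ}/((1−λ)m) at
λ = 0.5, clamped into [1/m, 1]; the spline smoother is deliberately avoided
because permutation p-values live on a discrete lattice.  With π0 = 1 the
computation reduces exactly to Benjamini–Hochberg adjusted p-values, which
is also the independent cross-check used in the tests (statsmodels).

## Synthetic communities

`simulate_null_matrix` draws independent Gaussian series (a lognormal
option mimics relative-abundance skew; rank normalization makes the two
indistinguishable downstream — a tested property).  Planted pairs set
y = ρx + √(1−ρ²)ε.  Planted mediated triplets use a z-gated coupling

    x_i = s_type · β · (1 + g_type(z_i)) · y_i + σ_noise · ε_i

with g(z) = z for the high-Z-enhancing types (A, D) and −z for the
low-Z-enhancing types (B, C), and s_type = ±1 for positive/negative pair
correlation.  The unit baseline gives the pair a marginal correlation of
the type's sign — necessary for it to pass the LS screen and to define the
pair's LS sign, mirroring the asymmetric enhancement of the four mediation
diagrams — while the z-proportional term makes E(XYZ) = s_type·sign(g)·β.
β = 0 collapses to independence; `baseline=0` recovers the pure
multiplicative coupling used for the β-monotonicity property test.
Defaults (β = 1, σ_noise = 0.5, ρ = 0.8, 120 timepoints, ≤ 100 factors)
are desk-scale stand-ins for a decade-long monthly marine survey.
Missingness is injected completely at random at a configurable rate, always
leaving at least two observations per row.

What the generator does *not* emulate: compositional closure, seasonal and
autocorrelated dynamics, detection limits, and uneven sampling.  Passing
tests demonstrate the statistical machinery recovers planted structure
under idealized noise; they do not certify performance on real survey data.

## Numerical and interface choices

- Result tables are TSV with fixed headers, floats at six significant
  digits, rows sorted by (p, −|score|, ids) with lexical tie-breaks, so
  identical runs are byte-identical.
- Network export writes edge/node attribute TSVs plus GraphML; "wavy" is an
  edge attribute (plain SIF cannot encode it) for Cytoscape style mapping;
  hubs are named `LA:X|Y|Z` with the pair ordered lexically.
- Degenerate inputs: constant series → zero scores + warning; all-missing
  series → hard error naming the factor; duplicate factor ids, ragged rows
  and non-numeric cells → hard errors with coordinates.
- The run log records the package version, full configuration and counts at
  every filter stage; the pipeline's single seed drives all substreams.

## Problem sizes used in the test suite

Calibration and recovery checks run at the scale the defaults target:
series length 120, up to 100 factors, 1000–2000 permutations, 200 seeds for
type recovery, 2000 replicates for test calibration, one-million-replicate
offline simulations for the null table.  These sizes make the full suite
complete in a few minutes while keeping Monte-Carlo error well inside the
asserted tolerance bands.
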