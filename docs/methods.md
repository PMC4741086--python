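# Methods

## Sampling model

A community holds *S* taxa with unknown relative abundances *p₁ … p_S*
(Σpᵢ = 1).  A sample of *n* individuals (reads, contig members) is
multinomial in the pᵢ; *Xᵢ* is the count of taxon *i* and
*f_k* = #{i : Xᵢ = k} the frequency counts.  All estimators in this package
are functions of the *f_k* alone (plus *n* = Σ k·f_k and S_obs = Σ f_k);
nothing depends on taxon identities, so frequency counts are the universal
input and are stored sparsely.

Under this model E(f_k) = Σᵢ C(n,k) pᵢᵏ(1−pᵢ)ⁿ⁻ᵏ.  The test suite uses this
expectation formula directly — via exact enumeration of all multinomial
outcomes for tiny communities, and via binomial pmf sums for random known
communities — as the independent oracle for the Cauchy–Schwarz bound, the
simulator, and the unbiasedness of the Simpson sum.

## Singleton correction

The Cauchy–Schwarz inequality
(Σ pᵢ(1−pᵢ)ⁿ⁻¹)(Σ pᵢ³(1−pᵢ)ⁿ⁻³) ≥ (Σ pᵢ²(1−pᵢ)ⁿ⁻²)² translates into
E(f₁) ≥ 2(n−2)[E(f₂)]² / [3(n−1)E(f₃)]; plugging in observed counts gives
the preliminary lower bound f̃₁.  The gap of the bound is, to first order,
(2/(n−1))·[(1−α₂)/α₂ − (1−α₃)/α₃]·E(f₂), where α_r is the true mean
relative abundance of taxa seen r times.  Estimating α₂, α₃ by the modified
Good–Turing formula α̂_r = (r+1)f_{r+1}/[(n−r)f_r + (r+1)f_{r+1}] and taking
the large-n limit of the coefficients yields the estimator actually used:

    f̂₁ = 2f₂²/(3f₃) + 2f₂[f₂/(3f₃) − f₃/(4f₄)].

Design choices:

- **Large-n coefficients.** The bound's exact coefficient
  C(n,1)C(n,3)/C(n,2)² = 2(n−2)/(3(n−1)) is kept in `singleton_lower_bound`
  but the estimator uses the limit 2/3 (and 1/2 in the correction), the form
  whose fixture outputs round to the reference counts.  For n in the
  thousands the difference is far below the rounding granularity.
- **Sparse tails.** f₃ = 0 or f₄ = 0 would zero a denominator; both are
  smoothed to 1 (the same +1 device as bias-corrected Chao1), with a flag
  and a logged warning.  f₂ = 0 returns 0: with no doubletons there is no
  evidence for any true singletons.
- **Clamping.** The correction term can drive the estimate negative when
  f₃²/f₄ is large relative to f₂; counts cannot be negative, so the value is
  clamped at 0 and flagged.  The estimator assumes f₂–f₄ are reliable; a
  clamp is a sign that they are not.
- **No cap at the observed f₁.** On error-free data f̂₁ may legitimately
  exceed f₁; interpreting f₁/f̂₁ is left to the diagnostic (default
  threshold: ratio > 2 ⇒ errors suspected).
- **Shifted generalization.** `estimate_shifted(fc, r)` repeats the
  derivation with every index shifted, giving
  (r+1)/(r+2)·f_{r+1}²/f_{r+2} + (r+1)f_{r+1}[f_{r+1}/((r+2)f_{r+2}) −
  f_{r+2}/((r+3)f_{r+3})]; at r = 1 it reproduces `estimate_singletons`
  bit-for-bit (the arithmetic is ordered identically on purpose).  The
  r ≥ 2 cases are validated against expectation-level oracles only, since no
  reference values exist.
- The estimator is monotone increasing in f₂ wherever the correction term
  is non-negative (f₂/(3f₃) ≥ f₃/(4f₄)); outside that regime the derivative
  (8/3)f₂/f₃ − f₃/(2f₄) can change sign, so no global monotonicity is
  claimed or tested.

The adjusted sample replaces f₁ by round(f̂₁) (half-up; the tables the
method reproduces print integers) and recomputes n.  The unrounded value is
retained for reporting.

## Richness

Chao1: S_obs + [(n−1)/n]·f₁²/(2f₂), falling back to
[(n−1)/n]·f₁(f₁−1)/2 when f₂ = 0.  The adjusted version substitutes f̂₁ and
uses the adjusted n everywhere; its f₂ = 0 branch is
S_obs − f₁ + f̂₁ + f̂₁(f̂₁−1)/[2(f₂+1)] (no (n−1)/n factor — that is the form
the adjusted-data reference values pin down).  A
`small_sample_correction=False` flag drops the (n−1)/n factor from classic
Chao1, which is the convention that reproduces the original-data reference
values; the factor is kept by default.

Variance uses the classic Chao1 form with the singleton slot's value
substituted (r̂ = f̂₁/f₂, A = (n−1)/n):
var = f₂[A²r̂⁴/4 + A²r̂³ + Ar̂²/2].  The 95% CI is log-normal on the excess
over S_obs, so the lower limit cannot fall below the observed richness.
The analytic SE is cross-checked against the bootstrap in the tests
(tolerance 35%, a sampling-noise allowance at B = 200).

## Hill numbers

Empirical ᵠD uses the plug-in proportions k/n summed over the sparse
representation, Σ_k f_k (k/n)^q, never over expanded taxa.  |q−1| < 10⁻⁶
routes to the entropy branch exp(−Σ f_k (k/n) log(k/n)) because the
1/(1−q) exponent is numerically singular there.  Note that the one-sided
difference between the branches at |q−1| = 10⁻⁴ is ~10⁻⁵ relative — that is
the profile's true slope, not error — so the continuity tests compare the
symmetric midpoint of the two one-sided evaluations (agreement ~10⁻¹⁰).

The asymptotic estimator corrects the undetected-taxa bias:

    ᵠD̂ = [ Σ_{k=0}^{n−1} C(q−1,k)(−1)ᵏ Δ̂(k)
          + (f̂₁/n)(1−A)^{−n+1}(A^{q−1} − Σ_{r=0}^{n−1} C(q−1,r)(A−1)^r) ]^{1/(1−q)}

with Δ̂(0) = 1, Δ̂(k) = Σ_j [C(n−k−1, j−1)/C(n, j)] f_j, and
A = 2f₂/[(n−1)f̂₁+2f₂] (with the stated fallbacks when f₂ or f̂₁ is 0).
Numerical choices:

- (−1)ᵏC(q−1,k) is generated by the ratio recurrence b_k = b_{k−1}(k−q)/k,
  which is sign-exact and underflow-free; the full n-term sums are
  evaluated vectorized (n ≈ 5·10³ is trivial, and the terms have a single
  sign change at ⌈q⌉, so no guarded accumulation is needed in float64).
- (1−A)^{−n+1} is computed as exp(−(n−1)·log1p(−A)); raw powering overflows
  for A ~ 10⁻⁴, n ~ 5·10³.
- Δ̂(k) goes through log-gamma.  Δ̂(0) is set to 1 exactly (its sum form
  Σ f_j (j/n) is identically 1).
- q = 0, |q−1| < 10⁻⁶ and q = 2 use their analytic reductions (adjusted
  Chao1; the exponential-entropy estimator
  exp(Σ_j f_j (j/n)(H_{n−1} − H_{j−1}) + tail); the inverse unbiased Simpson
  sum [Σ f_j j(j−1)/(n(n−1))]⁻¹).  The general series is kept callable for
  verification; it matches the reductions to ~10⁻¹² (q = 0) and ~10⁻⁸
  (q = 2, the log-gamma noise floor).

## Coverage and rarefaction/extrapolation

Coverage at the observed size: Ĉ = 1 − (f₁/n)[(n−1)f₁/((n−1)f₁+2f₂)].
Rarefied coverage uses the hypergeometric form
1 − Σ_k f_k (k/n) C(n−k,m)/C(n−1,m); extrapolated coverage decays
geometrically, 1 − (f₁/n)[(n−1)f₁/((n−1)f₁+2f₂)]^{m−n+1}.  The binomial
ratios are telescoping products of (n−m−i+1)/(n−i+1) evaluated directly —
more accurate than differencing large log-gamma values, which left ~10⁻⁸
residuals at the curve endpoints.

Size-based curves (q ∈ {0, 1, 2}): richness interpolation is the exact
hypergeometric expectation (verified against exhaustive enumeration of all
C(n,m) subsamples for n ≤ 12); richness extrapolation approaches
S_obs + f̂₀ with the Chao1 undetected term f̂₀.  Shannon interpolation
exponentiates the entropy of the expected rarefied counts
E[f_k(m)] = Σ_j f_j C(j,k)C(n−j,m−k)/C(n,m); Shannon extrapolation blends
the empirical and asymptotic entropies with weights n/(n+m*) and m*/(n+m*),
the simplest form satisfying the two constraints the framework fixes —
continuity at m* = 0 and convergence to the asymptote as m* → ∞.  Simpson
has the closed form [1/m + ((m−1)/m)·Σ f_j j(j−1)/(n(n−1))]⁻¹ at every m,
which equals the empirical value at m = n identically.

Coverage-based curves invert the monotone Ĉ(m): integer bisection below
Ĉ(n), the closed-form geometric solution above it, ties resolved to the
smallest m reaching the target.  Default size grids use 40 knots from 1 to
2n (always including n); richness extrapolation should not be trusted much
beyond 2–3n, while the q = 1, 2 curves may be extended toward their
asymptotes.  When an adjusted sample is supplied, every formula operates on
the adjusted counts and adjusted n.

## Bootstrap

The bootstrap community assigns each detected taxon with count X the
probability (X/n)(1 − λ(1−X/n)ⁿ), with λ = (1−Ĉ)/Σ(Xᵢ/n)(1−Xᵢ/n)ⁿ — the
constraint is linear in λ, so it is solved exactly rather than by search —
and spreads the remaining 1−Ĉ equally over f̂₀ = ⌈Chao1 undetected term⌉
unseen taxa.  B multinomial resamples of size n are drawn (default B = 200,
the replication used for the reference bands); statistics are recomputed
per replicate without re-estimating the singleton count, so the bands are
conditional on the adjustment.  CIs: log-normal for q = 0 richness,
symmetric normal otherwise, percentile behind a flag.  A fixed seed gives
bit-identical output.

## Simulator

`make_model` provides uniform, geometric, lognormal, Zipf–Mandelbrot,
broken-stick and custom abundance families (default S = 2,000, the
community size the correction was characterized at); heterogeneity is
summarized by the CV of the pᵢ.  `draw_sample` draws n multinomial reads
and, with probability ε per read (error scenarios use ε = 0.1), relabels a
read as a never-seen taxon — so every error is exactly one spurious
singleton, and the truth record preserves the error-free counts.
Multinomial and error draws consume a single seeded stream in fixed order.

What the generator does *not* emulate: position/quality-dependent error
rates, chimeras, errors that merge into existing taxa, and abundance-biased
misclassification.  Passing tests therefore show that the estimator
corrects classification-level, singleton-generating noise under multinomial
sampling — not that it fixes every real error mode.

The evaluation harness uses 100 replicates per (model, n) cell over
n = 2,000 … 10,000, a desk-scale replication chosen so the whole suite runs
in seconds while Monte-Carlo error on cell means stays ~1%.  One regime
note: for a perfectly even community (CV = 0) the error-free singleton
count collapses across this n-range faster than spurious singletons
accumulate, so observed f₁ need not rise monotonically; the
"spurious counts always grow with n" pattern is exercised on heterogeneous
models (CV ≈ 1–2.6), and the even community is used where it is the cleanest
case — the decline of error-free f₁ and the ε = 0 tracking of the truth.

## Known limitations

- The singleton correction inherits the reliability of f₂–f₄; on very
  sparse tails the +1 smoothing and clamping keep it defined but the result
  should be read together with its flags.
- Adjusted Chao1 remains a lower bound; entire-community richness ranking
  is not meaningful, which is exactly why the coverage-standardized
  comparison exists.
- The q = 1 extrapolation blend is an operational choice pinned only at its
  endpoints; between m = n and the asymptote other schedules are defensible.
- Bootstrap bands ignore the uncertainty of the singleton adjustment
  itself (they are conditional on f̂₁).
- The doubleton-and-beyond generalization (`estimate_shifted`, r ≥ 2) has
  no external reference values and is validated against inequality and
  reduction properties only.
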