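# Methods

## Scope and model

`dynlr` computes the null distribution of the total log₁₀ likelihood ratio
of exact STR profile matches between unrelated individuals, and inverts a
Poisson false-positive budget into match-specific reporting thresholds.
Matching is exact genotype equality on the overlapping loci set; wildcard /
near-match searching, mixture or probabilistic-genotyping LRs, and kinship
LRs are out of scope (relatives are simulated, but always *scored* with the
identity LR, which is the operationally relevant question: does a relative
clear a threshold built for unrelated false positives?).

### Allele frequencies

Input tables are long-format CSV (`locus,allele,frequency,n_typed`). Allele
labels are opaque strings so microvariants ("9.3") survive round-trips.
Each locus carries the number of typed individuals N; the minimum allele
frequency p_min = 5/(2N) guards against unobserved rare variants. The
correction floors every frequency at p_min and renormalises. Because
renormalising can push a borderline frequency back below p_min, the
implementation iterates to the fixed point: floored alleles sit exactly at
p_min, all others share one scale factor. This keeps two properties every
downstream computation assumes — frequencies sum to one, and none is below
p_min — and makes the correction idempotent. The correction is applied to
the base table only, not to simulated subpopulation draws (those are
sampling fluctuations, not sampling-bias corrections).

### Single-locus probabilities

Genotype and conditional match probabilities follow the Balding–Nichols
model (NRC II Recommendation 4.10 form), with θ configurable and 0.01 by
default; probabilities are computed in linear space and logs taken once.
The equal-genotype LR is the reciprocal of the conditional match
probability, so log₁₀LR ≥ 0 for every genotype, and the distribution of
log₁₀LR over matching pairs is supported on a nonnegative grid.

### Discretisation and convolution

The per-locus mass P(g|g,H₀)·P(g) is binned at n = round(log₁₀LRE(g)/Δ)
with Δ = 0.001 and array length 2¹⁶ = 65,536 (defaults, both
configurable). Rounding is half-away-from-zero with a 10⁻¹² pre-snap so
analytically exact bin centres land deterministically across platforms.
Genotypes sharing a bin are summed ("clumping"). Multi-locus PMFs are the
convolution of single-locus PMFs, computed with `scipy.fft` real
transforms; the contract is defined by `convolve_direct`, a trimmed-support
`np.convolve` (plain multiply–add) implementation kept as the independent
oracle, and the two agree to better than 10⁻¹⁰ per bin on all tested loci
subsets. Aliasing is prevented by checking the summed support of the
inputs against the array length rather than a fixed bin budget, so
nonstandard grids stay safe. FFT round-off below −10⁻¹² is clamped to
zero; anything more negative raises rather than being silently absorbed.

The tail sum of a loci set's PMF at a threshold bin is the expected
per-comparison false-positive rate α; the inverse returns Δ·k* for the
*smallest* bin k* whose tail is ≤ α. When several adjacent empty bins share
the same tail value, any of them yields the identical expected FPR; the
smallest is returned, which keeps the round-trip guarantee
`alpha_from_threshold(threshold_from_alpha(α)) ≤ α` and monotonicity in α
exact. If α already exceeds the PMF's total mass the threshold is 0 (the
loci set is so discriminating that no filtering is needed); if even the
largest support atom's tail exceeds α the returned threshold lies just
above the support, i.e. no match on that loci set can be reported — the
correct behaviour for very short loci sets in very large databases.
Multi-locus PMFs and thresholds are memoised per loci set (one convolution
per distinct overlapping set per search).

### Poisson risk accounting

A stain-to-database search performs T = N_profiles comparisons; a full
database self-comparison T = N(N−1)/2. The false-positive count is modelled
as Poisson(μ = αT). The laboratory may specify μ directly or an upper
bound U at confidence β; the inversion μ = F⁻¹(U; β) is solved by
bracketed root-finding on the Poisson CDF, which is evaluated through the
regularised incomplete gamma function and is stable far beyond μ = 10⁴.
Two-sided 95% bands use the equal-tailed convention: L is the largest
integer with P(X < L) ≤ 0.025, U the smallest with P(X ≤ U) ≥ 0.975. Batch
searches expose both comparison-count conventions (per stain search or per
whole batch); the calibration and relatives analyses count the whole
batch.

## Synthetic data

The generator emulates the study conditions the framework assumes, which
is precisely what makes calibration checkable:

* **Population structure.** One Dirichlet draw per locus with
  concentration αᵢ = pᵢ(1−θ)/θ — the stationary Balding–Nichols
  parameterisation, so E[qᵢ] = pᵢ and Var[qᵢ] = θpᵢ(1−pᵢ) exactly — gives
  the subpopulation frequencies; database and stain donors are drawn in
  HWE *within* that shared subpopulation. Sampling directly from the base
  table would overstate diversity and understate coincidental match rates
  relative to the θ-corrected LR model.
* **Degradation** is uniformly random locus dropout to a target count
  (default range 3–9), deliberately ignoring amplicon-size structure so
  that unusual loci subsets are exercised too.
* **Relatives** are built locus-by-locus from IBD states: parent–child
  shares exactly one allele per locus; full siblings draw IBD 2/1/0 with
  probability ¼/½/¼; non-IBD alleles come from the subpopulation pool.
  Relatives derive from the full donor profile before stain truncation.
* **Reproducibility.** Every generator is a pure function of (seed,
  config, table); study batches draw child seeds from one `SeedSequence`.

What the generator does **not** model: mutation between relatives,
amplicon-size-correlated dropout, typing error, hidden relatedness inside
the "unrelated" database, and real allele-frequency shapes (ladders are
flat-Dirichlet synthetic, 4–14 alleles per locus). Passing tests therefore
demonstrate internal consistency of model + inversion + simulation under
the model's own assumptions, not operational performance on casework data;
with user-supplied population tables the same machinery runs unchanged.

## Validation analyses and chosen scales

Scales are chosen to finish on one CPU in minutes while leaving sampling
error well inside the asserted tolerances.

* **Calibration.** 50 batches per target μ ∈ {1, 5, 10}; each batch draws a
  fresh shared subpopulation, a 5000-profile database and 1000 four-locus
  stains (donors not in the database, so every surviving match is a false
  positive), with α = μ/(1000·5000). Asserted: batch-mean within 3
  standard errors (√(μ/50)) of μ, and 95%-band coverage within binomial
  tolerance. Fresh subpopulations per batch are essential: conditioning on
  a single draw, counts are Poisson around α(q)T rather than μ, and the
  band calibration claim would be ill-posed.
* **Monte-Carlo convergence.** The conditional distribution of log₁₀LR_M
  given a full match factorises over loci, so the sampler conditions per
  locus: genotype pairs are drawn with the exact Pólya-urn sequential form
  of Balding–Nichols (allele m+1 copies a uniformly chosen previous allele
  with probability mθ/(1+(m−1)θ), else is a fresh base-frequency draw) and
  unequal pairs rejected. The FFT PMF is renormalised by its total mass
  for comparison. Agreement is scored by the Wasserstein-1 distance
  normalised by the FFT distribution's standard deviation; at 10⁵ trials
  on a four-locus set it is ≈ 0.006, asserted ≤ 0.01.
* **ROC.** 200 stains per locus count 3–7 (database members truncated to
  random loci subsets) searched against a 20,000-profile structured
  database. The classification populations are the planted true matches
  and the adventitious full matches; each method is swept over its control
  parameter (minimum locus count; static log₁₀LR in [0, 40] steps of 0.1;
  α log-uniform over [10⁻¹², 10⁻²], a pair passing at level α iff the tail
  probability of its loci set's PMF at its log₁₀LR is ≤ α). Curves are
  evaluated at the union of the sweep grid and observed scores, so the
  trapezoid AUC is exact for the sample, including half-credit for ties.
  Locus counting is consistently the weakest (AUC ≈ 0.88 on the synthetic
  fixture); static and dynamic LR filtering rank nearly identically
  (AUC ≈ 0.96, within 0.01 of each other) — the dynamic method's advantage
  is workload control under database growth, not per-pair discrimination.
* **Discreteness diagnostics.** Gap analysis reports zero-mass intervals
  wider than a configurable width (default 0.04 log₁₀LR) inside the
  support; the Gaussian-baseline comparison fits a Normal with the PMF's
  conditional mean and variance and reports discrete vs Gaussian tail mass
  at mean + kσ (k = 1..4) plus skewness. Multi-locus PMFs on the synthetic
  fixture are right-skewed (mean six-locus skewness ≈ 0.57), and the
  discrete tail exceeds the Gaussian tail at +3σ — the regime where
  operational thresholds sit, which is why a continuous approximation
  underestimates false-positive risk.
* **Relatives.** Stain donors receive one simulated parent/child and one
  full sibling; stains truncated to 3–6 loci are scanned against an
  unrelated database under the μ = 1 dynamic threshold, and relatives are
  compared directly. Raw relative matches fall steeply with locus count,
  parent/child survivors are essentially eliminated, and the *fraction* of
  sibling matches that clear the threshold rises with locus count — a
  six-locus sibling match carries genuine statistical weight.

## Numerical and design notes

* The Poisson upper-bound inversion brackets μ in [0, U + 20√(U+1) + 20]
  and solves to 10⁻¹² absolute tolerance; U = 0 uses the closed form
  −ln β.
* `upper_bound` returns the smallest integer whose CDF reaches the level;
  at μ = 20, β = 0.95 this is 28 (F(27; 20) = 0.94752).
* Degenerate inputs fail loudly: loci with fewer than two alleles,
  non-positive N, empty loci sets, zero-variance PMFs in the Gaussian
  comparison, α ≤ 0 in threshold inversion. μ = 0 in calibration is the
  one deliberate soft case: it means an unbounded threshold, and the
  observed count is exactly zero.
* Known limitations: comparisons are assumed independent in the Poisson
  step (relatedness within real databases violates this and inflates
  adventitious matches); the matcher is a flat per-stain scan, adequate
  for simulation studies but not indexed for >10⁷-profile operations;
  profiles must carry two alleles per locus (no single-allele expansion).
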