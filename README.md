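# dynlr — dynamic likelihood-ratio thresholds for DNA database searching

Operational forensic DNA databases decide which candidate matches reach a
human reviewer with static rules: a minimum number of shared STR loci, or a
fixed likelihood-ratio cutoff. Both rules ignore two things that drive the
real false-positive burden — the *genetic rarity* of the specific loci and
alleles that matched, and the *number of pairwise comparisons* a search
performs. A six-locus match of common alleles can be weaker evidence than a
four-locus match of rare ones, and a cutoff that is safe in a database of
100,000 profiles drowns the reviewer in adventitious matches at 10 million.

`dynlr` implements the alternative: the laboratory states its acceptable
false-positive workload, and the threshold adapts per match. It is aimed at
forensic statisticians and database custodians experimenting with
risk-based match filtering, and at simulation studies of search policy.

## The model

For a locus ℓ with allele frequencies *pᵢ* and coancestry coefficient θ
(Balding–Nichols population-substructure correction, default θ = 0.01), the
probability that a second unrelated person carries an observed genotype *g*
is the NRC II 4.10 match probability

    P(gᵢᵢ | gᵢᵢ, H₀) = (3θ + (1−θ)pᵢ)(2θ + (1−θ)pᵢ) / ((1+θ)(1+2θ))
    P(gᵢⱼ | gᵢⱼ, H₀) = 2(θ + (1−θ)pᵢ)(θ + (1−θ)pⱼ) / ((1+θ)(1+2θ))

and the equal-genotype likelihood ratio is LRE(g) = 1 / P(g | g, H₀). A
full match on a loci set M scores log₁₀LR_M = Σ_ℓ log₁₀ LRE(gℓ).

The chance that two unrelated people fully match at ℓ with genotype *g* is
P(g|g,H₀)·P(g). Placing that mass at the genotype's log₁₀LR on a uniform
grid (bin width Δ = 0.001, 2¹⁶ bins) gives a per-locus *sub*-probability
mass function; the PMF of log₁₀LR_M for any loci set M is the convolution
of its single-locus PMFs, computed exactly (up to discretisation) by FFT.

Risk control inverts this distribution. The laboratory specifies either the
expected number of false positives μ per search, or an upper bound U at
confidence β (linked by the Poisson CDF, μ = F⁻¹(U; β)). With T pairwise
comparisons in the search, the per-comparison rate is α = μ/T, and the
dynamic threshold for a match on loci set M is the smallest log₁₀LR whose
tail mass under the M-PMF is ≤ α. Thresholds therefore rise with database
size and fall for rare loci combinations, keeping the reviewer workload at
the stated budget regardless of either.

## Worked example

Generate a synthetic 10-locus reference population and ask for the dynamic
threshold of a four-locus match under a budget of one expected false
positive per search:

```
$ python -c "from dynlr.popsim import synthetic_frequency_table;
synthetic_frequency_table(10, seed=7).to_csv('freqs.csv')"

$ dynlr threshold --freqs freqs.csv --loci L03,L05,L08,L10 --db-size 500000 --mu 1
loci: L03,L05,L08,L10
T=500000 mu=1 alpha=2e-06
log10LR threshold = 4.790

$ dynlr threshold --freqs freqs.csv --loci L03,L05,L08,L10 --db-size 5000000 --mu 1
loci: L03,L05,L08,L10
T=5000000 mu=1 alpha=2e-07
log10LR threshold = 5.387
```

A candidate pair sharing these four loci is reported for review only if its
summed log₁₀LR clears the threshold; expanding the database tenfold raises
the bar from 4.79 to 5.39 so that the expected number of coincidental
survivors stays at one. The risk translation is available directly:

```
$ dynlr risk --mu 10 --beta 0.95
mu=10.0 beta=0.95 -> U=15
P(at least one FP) = 0.999955
```

i.e. with μ = 10 the count of false positives stays at or below 15 in 95%
of searches. `dynlr simulate` writes a full in-silico study (structured
subpopulation, degraded stains, relatives) and `dynlr search` runs the
matcher with `dynamic-lr`, `static-lr` or `locus-count` filtering;
`dynlr calibrate`, `roc`, `mc-check` and `relatives` run the validation
analyses and emit CSV reports.

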