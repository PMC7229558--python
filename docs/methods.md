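# Methods

## Model and scores

For sample `i` and SNP `k`, `G_ik` counts minor alleles (0/1/2) and
`Y_i ∈ {0,1}` is case-control status, `n = n1 + n0`.  Both score systems
test the global null that no SNP in the region is associated with the
phenotype.

**Additive prospective score.**  `Ũ_P = Gᵀ(Y − Ȳ1)` with
`Ṽ_P = Ȳ(1−Ȳ) Σᵢ (G₍ᵢ₎ − Ḡ)(G₍ᵢ₎ − Ḡ)ᵀ` — the score of logistic
regression of `Y` on the allele counts, evaluated at the null.  The
principal chi-squared statistic on `(Ũ_P, Ṽ_P)` is algebraically identical
to the score test of logistic regression on the top principal components
of the centered genotype matrix; the test suite verifies this through an
independent SVD route.

**Empirical-Bayes codominant score.**  Each SNP is expanded to
`m(g) = (I[g=1], I[g=2])`.  With pooled minor-allele frequency `f̂`, HWE
expectation `e = (2f̂(1−f̂), f̂²)`, pooled indicator mean `m̄`, deviation
`τ = e − m̄`, and indicator variances `s²` (denominator `n`, consistent
with the `s²/n` scaling inside the weight), the per-SNP diagonal weight is
`W = (s²/n)/(s²/n + τ²)` and

    U_B,k = Σ_cases [ (m − e) W + (m − m̄)(I − W) ].

The two centerings are the retrospective (HWE-constrained) and prospective
scores; `W` interpolates between them according to how compatible the
pooled sample is with HWE.  Degenerate columns (`s² = 0`) resolve the 0/0
weight to 1 when `τ = 0` and 0 otherwise — the continuous limits of the
ratio.  Monomorphic input SNPs are retained; their zero-variance
coordinates are removed downstream by the eigenvalue floor rather than by
silent column renumbering.

## The covariance of the empirical-Bayes score

`U_B` obeys the exact decomposition `U_B = U_prosp − n1 (W ∘ τ̂)`, where
`U_prosp` is the mean-centered codominant case sum.  Under the null the
prospective part is exactly uncorrelated with the pooled deviation `τ̂`
(the covariance cancels for any case fraction), so

    V_B = V_P + n1² Cov(ψ(τ̂)),     ψ(τ) = w(τ) τ = (s²/n) τ / (s²/n + τ²).

`ψ` is the bounded, non-linear shrinkage map: its per-component magnitude
never exceeds `s/(2√n)`, which is what keeps the empirical-Bayes test
valid under HWE deviation.  Because the weight is *random* (it does not
concentrate under an HWE-true null), a plug-in that treats `W` as fixed
misstates this term in either direction; instead `Cov(ψ)` is evaluated by
integrating `ψ` over the asymptotic Gaussian law of `τ̂`: mean zero and
covariance `Σ_τ = (1/n) Cov(t_i)` from the influence function
`t_i = (de/df)(g_i/2 − f̂) − (x_i − m̄)` with `de/df = (2 − 4f̂, 2f̂)`.
The integral uses 4000 Gaussian draws with a fixed internal seed, so the
estimator is a deterministic function of the data.  At `W = 0` the ψ-term
vanishes and `V_B = V_P` exactly.

Referencing the integral at the HWE-null (mean-zero) law makes the
estimator sharp when the population is in HWE: against a 5000-replicate
Monte-Carlo oracle on the NAT2 panel (1000/1000, `F_st = 0`) the entrywise
deviations sit at chance level (≈0.2% of the 36×36 entries beyond 3
Monte-Carlo s.e.; a perfect estimator is expected to show ≈0.3%).  Under
genuine inbreeding (`F_st > 0`) the ψ-term is overstated, so PChiB becomes
mildly conservative rather than inflated (the replicated null studies show
PChiB rejection slightly below nominal, never above the band).  A
permutation-based covariance (`eb_covariance(method="permutation")`) is
available as an alternative estimator.

## Eigen-truncation, SSUP, Min2

Eigenvalues below `1e-8 × λ_max` are treated as null space (duplicated or
monomorphic columns must not inflate the apparent variability); the
component count `s` is the smallest number of top eigenvalues whose share
of the retained total reaches the threshold (default 0.85).  With the full
retained rank the statistic is Hotelling's `T² = U V⁺ Uᵀ`.

SSUP's null law `Σ λ_k χ²₁` is evaluated by the moment-matching
(skewness-corrected noncentral chi-squared) approximation by default; an
exact characteristic-function inversion (Imhof's integral, with the
oscillatory tail integrated under sin/cos quadrature weights) is available
via `method="imhof"`.  The two agree to ~1e-3 in p over the mixtures
arising here; the moment-matching form is used in the replicated studies
for speed.

Min2 takes the smaller of the PChiP and PChiB asymptotic p-values and
calibrates it by label permutation with the add-one estimator
`(1 + #{perm ≤ obs})/(B + 1)` (smallest achievable value `1/(B+1)`; ties
count as ≤).  All pooled quantities — allele frequencies, weights, both
covariances, eigenvectors, and the component counts — are label-invariant
by construction, so each permutation only recomputes the two projected
case sums; this makes the permutation exact, not an approximation, and
keeps a 500-replicate × 200-permutation study cell at a few seconds.

## The simulator

Controls draw ordered haplotype pairs from
`φ(H,H′) = (1 − F_st) f_H f_H′ + δ_HH′ F_st f_H`, implemented as the exact
mixture "with probability `F_st` duplicate a single draw, else two
independent draws".  Cases reweight the same `φ` (with the configured
`F_st`, so both arms share one base law) by
`r_het^[het at causal] r_hom^[minor-hom at causal]` and renormalize over
ordered pairs.  Genetic modes map a per-mode odds ratio θ to
`(r_het, r_hom)`: additive `(θ, θ²)` (multiplicative per allele), dominant
`(θ, θ)`, recessive `(1, θ)`.  Phase is discarded and loci are reported as
minor-allele counts, with the minor allele fixed by the panel
(lexicographically smaller symbol on a 0.5 tie).

The packaged NAT2 panel (18 SNPs, 16 haplotypes) has printed frequencies
summing to 0.998; they are renormalized at load and the raw values remain
accessible.  The panel encodes realistic LD: the simulator reproduces HWE
genotype proportions at `F_st = 0`, the inbreeding identity
`P(het) = 2f(1−f)(1−F_st)` at `F_st > 0`, and the panel-implied pairwise
count covariances (all verified in the test suite).  What it does not
emulate: genotyping error or missingness, covariates or population
stratification beyond the single `F_st` parameter, and rare variants (all
panel MAFs exceed 0.05 except SNP 8 at 0.114) — so passing tests speak to
the statistical behavior of the methods under clean LD structure, not to
robustness against data-quality artifacts.

## Study defaults and reproduced conditions

The replicated study uses one fixed set of design conditions: 1000
cases / 1000 controls, 500 replicates per cell, 200 permutations for Min2,
α = 0.05, `F_st ∈ {0, 0.5·log 2}`, odds ratios 1.2 / 1.3 / 1.5 for
additive / dominant / recessive effects, every SNP designated causal in
turn, and three SNP-subset scenarios (all SNPs, drop-causal, explicit
subset).  The inbred setting uses `F_st = 0.5·log 2 ≈ 0.3466` — a mild
but clearly non-null deviation from HWE of the kind seen in real
association panels.  The mapping from panel columns to named tag SNPs is
not part of the packaged panel, so the tag-SNP scenario is supported only
through an explicit user-supplied subset.  GOLD enters the causal
column of the *full* data under its true genetic coding — it is an oracle
benchmark, which is why dropping the causal SNP from the multilocus tests
leaves it unchanged.

Seeding: every replicate draws from `SeedSequence([master, causal, rep])`,
so tables are bit-reproducible and any cell can be regenerated
independently.

The absorbed degrees of freedom reported for null data ((2, 5) for PChiP,
PChiB on the NAT2 panel) sit right at the 85% boundary for PChiB: the
cumulative eigenvalue share of the top five components is ≈0.851–0.854, so
a single dataset's count flips between 5 and 6 by sampling noise.
`report_absorbed_df` therefore accepts an `n_reps` argument that averages
the covariances over independent null replicates before applying the
selection rule; the acceptance script uses 30 replicates, which yields a
stable count, while the default (1) reports what a single analysed dataset
would absorb.

## Missing data and file formats

The simulation study has no missingness; for real inputs the loaders apply
a stated rule — drop samples with any missing genotype (default) or impute
the rounded per-SNP mean count — before validation fixes entries in
{0, 1, 2}.  Dosage tables are TSV with a `phenotype` column followed by
one column per SNP; VCF input (GT fields, via cyvcf2) rejects
multi-allelic sites and flips ALT dosages to minor-allele counts using the
pooled sample frequency.

## Known limitations

* Covariate adjustment is out of scope; the scores condition on nothing
  beyond the intercept.
* The component-count rule is the fixed 85% threshold; no data-driven
  selection of the threshold is attempted.
* SSUP p-values below ~1e-12 from the moment-matching approximation should
  be treated as orders of magnitude, not precise values.
* The ψ-integral covariance is exact under HWE and deliberately
  conservative under inbreeding; users testing populations with strong,
  known substructure may prefer the permutation covariance.
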