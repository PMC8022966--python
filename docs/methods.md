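# Methods

## Model

`bdtsel` implements decision-theoretic parental selection on top of a
multi-trait GBLUP model. With one adjusted record per line the design
matrices of the random genetic effects reduce to the identity, so the model
is, per trait *t*:

y_t = 1 μ_t + g_t + ε_t, with vec(g) ~ MVN(0, Σg ⊗ G) (trait-major) and
ε ~ MVN(0, R ⊗ I), R diagonal. A diagonal R (zero residual covariance
between traits) is the standard simplification for single-environment
breeding data and keeps every residual full conditional univariate.
Multi-record or multi-environment designs, pedigree (A-matrix)
relationships and non-Gaussian traits are out of scope.

## Gibbs sampler

All full conditionals are conjugate:

* **Intercepts** μ_t | rest ~ N(mean(y_t − g_t), σe²_t/n) under a flat prior.
* **Genetic values** are updated in the eigenbasis of G = U diag(d) Uᵀ
  (one eigendecomposition cached per fit). In that basis the rows of
  g̃ = Uᵀg are independent with per-row covariance d_i Σg, so each trait
  column is sampled from univariate normal conditionals given the other
  trait columns — O(nT) work per sweep plus one T×T solve per trait.
  Eigenvalues are floored at 1e−8·λmax so the prior stays proper for
  singular relationship matrices.
* **Genetic covariance** Σg | rest ~ InvWishart(ν₀ + n, S₀ + g̃ᵀD⁻¹g̃).
* **Residual variances** σe²_t | rest ~ Scale-inv-χ²(ν₀ + n,
  (ν₀s₀² + SSE_t)/(ν₀ + n)).

Priors default to a weakly informative 50/50 split of the observed
phenotypic variance: Σg ~ InvWishart(df = T+2, scale = diag(0.5·var(y))),
σe²_t ~ Scale-inv-χ²(df = 4, scale = 0.5·var(y_t)). Both are overridable
through `MCMCConfig`; the data-derived scales are floored at 1e−8 so
degenerate (constant) traits cannot produce an improper prior. Variance
components can instead be clamped (`fix_sigma_g`, `fix_r_diag`), which
turns the sampler into Bayesian GBLUP with known variances — the
configuration used to validate it against the exact mixed-model-equation
solution (`gblup_fixed_variance`, a direct dense solve intended for small
n). Chains are bitwise reproducible given a seed; a draw with non-finite
or exploding variances aborts with the sweep index.

The default schedule in the worked examples is 1000–2000 burn-in sweeps
with 500–1000 stored draws; the classical recipe for production analyses
of real panels (tens of thousands of sweeps, thinning at lag 5) is
available by configuration, the shorter schedule being plenty for the
few-hundred-line panels the synthetic generator produces.

## Parental distribution and losses

The breeder's target is the truncated parental distribution
TMVN(μ₁, P, y_c), P = Σg + R: the lines one *would* select by truncation
at y_c. Every posterior draw k yields its own parental distribution
(μ^(k), P^(k)) and its own candidate predictive MVN(μ^(k) + g_o^(k), P^(k));
quantities derived from them (orthant probability z, truncated mean μS)
are recomputed per draw.

* The **orthant probability** z = Pr(Y > y_c) uses the deterministic
  rectangle-probability routine (absolute accuracy ≈ 1e−7 at T ≤ 4); z is
  floored at 1e−300 with a warning suggesting the threshold be relaxed.
* The **truncated mean** μS is computed by the exact first-moment identity
  for orthant-truncated normals, E[Y] = μ₁ + P f / z with
  f_j = φ(y_c,j) · Pr(Y₋j ≥ y_c,₋j | Y_j = y_c,j) — deterministic, so the
  KL loss carries no sampling noise. A Monte-Carlo estimator
  (`truncated_mvn_moments`) doubles as an independent cross-check.
* **Truncated-MVN sampling** uses plain rejection while the acceptance
  probability (z) exceeds 1%, otherwise a coordinate-wise Gibbs sampler
  with a 50-sweep burn-in; tail coordinates are drawn by inverse-survival
  transform, which stays exact far into the tail.
* The **KL closed form** −log z + ½(μS−μ₂)ᵀP⁻¹(μS−μ₂) − ½SᵀP⁻¹S is the
  exact divergence KL(TMVN ‖ MVN(μ₂, P)): because both densities share P,
  the terms quadratic in y cancel in the expectation of the log-ratio and
  only the truncated *mean* enters. No covariance correction is needed.
* The **energy score** uses exponent β = 1 with the Euclidean norm — the
  standard strictly proper scoring-rule default — estimated as a
  V-statistic (all ordered pairs) so identical samples score exactly zero.
* **MALF** defaults to τ = 0.9 on every trait: shortfall below the
  threshold costs nine times as much as the same excess above it. τ is
  per-trait configurable.

Traits improved downward are handled by negating values and thresholds
(and conjugating covariances, D P D) so every loss is evaluated on the
increasing-improvement scale; the transform is an involution and the
losses are invariant to applying it consistently.

## PEL integration and selection

For KL the inner integral over offspring phenotypes is analytic, so the
PEL is a plain average of closed-form values over (a stride of) the chain.
For the energy score and MALF each retained posterior draw contributes
one parental sample (default 500 draws) and per-candidate predictive
samples (default 500). Candidate samples reuse **common random numbers**
across lines within a draw: identical candidates receive identical PEL,
and between-line comparisons are variance-reduced. The default chain
stride of 10 bounds the cost of the sampling-based losses; the KL ranking
is insensitive to the stride because each term is exact.

Raw PELs are min–max standardized to [0, 1], ranked ascending, and the
best floor(intensity·n) lines flagged (default intensity 10%, the common
choice in genomic-selection programs — 76 lines of a 766-line panel, 32 of
a 320-line panel). Ties are broken by line identifier so selection is
reproducible. Pairwise overlap between the losses' selected sets is
reported as 100·|A∩B|/|A| with equal-size sets.

A note on an edge of the KL criterion established while validating: the
KL loss ranks candidates by the distance of their predictive mean from μS,
so it coincides with truncation selection (pick the largest GEBV) exactly
when the threshold is strong enough that μS lies above every candidate
mean; with a lax threshold, candidates *overshooting* μS are penalized.
This is inherent to the divergence — the truncated distribution is the
target, not a lower bound.

## Synthetic data

The generator draws markers per column as Binomial(2, q) dosages with
allele frequency q uniform on a configurable range (monomorphic columns
resampled), builds G = WWᵀ/p from population-SD-standardized columns, and
simulates g from the matrix normal (row covariance G, column covariance
Σg) plus independent Gaussian residuals — exactly the structure the model
assumes, which is the point: parameter-recovery and oracle tests are
well-posed. What it does **not** emulate: linkage disequilibrium and
population structure in the markers, genotype-by-environment effects,
non-zero residual correlations, selection history, or missing records.
Passing tests therefore demonstrate correctness of the machinery, not
robustness to real-data violations of the model.

Fixture presets: `tiny` (n=12, T=2, for fast plumbing tests),
`dataset1_like` (n=200, T=4; one strong genetic correlation of 0.8, three
decreasing traits and one increasing, heritabilities 0.4–0.6, trait means
and scales in the range of phenology/height/yield panels) and
`dataset2_like` (n=160, T=4; all-positive weak correlations, all traits
increasing, means in the range of yield/kernel-weight/micronutrient
panels). Marker counts (p = 500) and line counts are sized so the full
pipeline, including MCMC, runs in seconds while keeping GEBV accuracy
non-trivial (mean correlation with true genetic values ≈ 0.7–0.8).

## Numerical choices

* Quantile thresholds use linear interpolation of order statistics
  (numpy's default, "type 7"); the convention matters because y_c shifts
  the selection and is therefore explicit and test-pinned.
* Marker standardization uses the population (divide-by-n) SD; with the
  cross-product/p construction the GRM diagonal then averages ≈ 1.
* Mills ratios are evaluated through `erfcx`, stable to α ≈ 8 and beyond.
* PSD repairs add the smallest power-of-ten jitter that restores a
  non-negative spectrum and are logged; genuinely indefinite inputs raise.
* Missing phenotypes are rejected, not imputed; genotype rows are aligned
  to phenotypes by identifier, never by position.

## Known limitations

* The inverse-Wishart prior on Σg is informative for very small panels;
  variance recovery tests use n = 200 where its influence is modest but
  visible (credible intervals occasionally miss a diagonal).
* The energy-score and MALF PELs carry Monte-Carlo noise of order
  1/√(draws·chain/stride); near-tied lines at the selection boundary can
  swap under different seeds. KL is noise-free given the chain.
* Orthant probabilities beyond T ≈ 10 would need a different integration
  strategy; the intended use is a handful of traits.
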