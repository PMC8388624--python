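# Methods

## Model and sampling scheme

The package fits the two-trait linear animal model
`y_t = X b_t + Z a_t + e_t` (t = MS, MT) with `a ~ N(0, G0 ⊗ K)` and
`e ~ N(0, R0 ⊗ I_n)`; both traits are recorded on every cow, and the
ordinal scores are analysed as continuous responses. K is either the
pedigree numerator matrix A or the single-step matrix H; only K⁻¹ ever
enters the computation.

One Gibbs cycle:

1. **Locations.** The joint full conditional of θ = (b, a) for both traits
   is Gaussian with precision
   `C = R0⁻¹ ⊗ W'W + G0⁻¹ ⊗ Kpad` (W = [X Z], Kpad = K⁻¹ padded with
   zeros on the fixed block). Let Q solve the generalized eigenproblem
   `G0⁻¹ Q = R0⁻¹ Q Λ` normalized so `Q' R0⁻¹ Q = I`. In the transformed
   basis the system splits into one SPD m×m system `W'W + λ_t Kpad` per
   transformed trait. A draw is produced by sampling-by-perturbation:
   solve `M_t θ̃_t = b̃_t + W'z₁ + √λ_t L_K z₂` with `z ~ N(0, I)` and
   `L_K L_K' = Kpad`, which yields exactly `N(M_t⁻¹ b̃_t, M_t⁻¹)`; the
   draw is then mapped back with θ = (Q ⊗ I) θ̃. The Monte-Carlo identity
   of this update with the dense `N(C⁻¹b, C⁻¹)` is verified in the test
   suite, and end-to-end correctness is cross-checked against an
   independent scalar conjugate Gibbs sampler and a closed-form ANOVA
   (expected-mean-squares) estimator on a balanced half-sib design.
2. **G0** from inverse-Wishart(ν₀ + q, S₀ + a'K⁻¹a) over the q kernel
   animals.
3. **R0** from inverse-Wishart(ν₀ + n, S₀ + e'e).

Priors default to S₀ = 0.01·I, ν₀ = (number of traits) + 1 — proper but
minimally informative; at the problem sizes used they contribute < 0.1%
of the posterior scale. Starting values: G0 = R0 = half the phenotypic
covariance of y; b = a = 0. Phenotypic components are derived per sample
as P0 = G0 + R0. Chains are deterministic given the seed. A numerically
non-positive-definite inverse-Wishart scale is jittered once
(1e-10·trace) and the draw retried; failure aborts with a diagnostic.

Default chain protocol: 100,000 iterations, 20,000 burn-in, every 5th
post-burn-in draw recorded (16,000 kept samples).

### Numerical choices

* The m×m systems share one sparsity pattern across all iterations and
  both traits, so a fill-reducing symmetric ordering (SuperLU minimum
  degree) and the symbolic LDL′ analysis run once; only the numeric
  factorization (an up-looking, elimination-tree LDL′, numba-compiled)
  and two triangular solves run per iteration. No pivoting is needed
  because every system is SPD.
* For K = A the factor `L_A L_A' = A⁻¹` is analytic:
  `L_A = (I − P)' D^{-1/2}` from the Henderson decomposition. For K = H
  the factor is a Cholesky of H⁻¹ (dense below 4000 animals, otherwise a
  verified no-pivot SuperLU factorization with dense fallback).
* Fixed effects use reference coding (first level dropped) plus an
  intercept; covariates are centred. A rank check on X'X rejects designs
  confounded beyond reference coding.
* Unphenotyped founder parents with a single offspring (the simulated
  dams) are pruned before analysis, with the offspring's missing-parent
  Mendelian variance adjusted — an exact marginalization (the principal
  submatrix of A is unchanged; tested), halving the system.

## Relationship kernels

* **A / A⁻¹** — memoized tabular recursion for A and pairwise
  relationships (used for A22); Henderson's sparse rules with inbreeding
  for A⁻¹ (inbreeding from the recursive kinship, exact for the ≤2
  ancestor generations this package targets). A⁻¹ is tested against
  dense inversion of tabular A to 1e-8 on random pedigrees.
* **G** — VanRaden method 1, `G = MM'/(2Σp(1−p))` with dosages centred by
  observed frequencies after a MAF > 0.001 filter. With observed-frequency
  centring the expected mean off-diagonal among unrelated animals is
  −mean(diag)/(n−1), not zero; the tests assert that form.
* **H⁻¹** — `A⁻¹ + [0,0; 0, Gw⁻¹ − A22⁻¹]` with `Gw = 0.95·G + 0.05·A22`
  (blending configurable; default guards invertibility). No τ/ω scaling
  of the correction. An empty genotyped set returns A⁻¹ exactly.

## Posterior summaries

* **HPD**: shortest interval over the sorted chain containing
  ⌈0.95·n⌉ samples.
* **MCE**: batch means with ⌊√n⌋ batches.
* **Geweke z**: first 10% vs last 50%, segment variances from spectral
  densities at frequency zero estimated by an AIC-selected autoregressive
  fit (falling back to the sample variance for white-noise segments).
  The conventional |z| > 1.96 flag is reported; the raw z is always
  printed.
* Reported rounding follows evaluation practice: derived parameters to
  2 d.p. with MCE in parentheses, covariance components to 5 d.p.

## Synthetic populations

The generator emulates the structure of national milk-recording extracts:

* **Pedigree** — founder sires with half-sib daughter groups; family
  sizes constant, Poisson, or drawn from the recorded size-class
  distribution (empirical bins; 16,720 groups, heavy right tail). Dams
  are unrelated, non-genotyped founders with one daughter each: the
  recorded data give no dam-side structure, so none is invented.
* **HYS cells** — cell sizes from a configurable distribution (the
  recorded 85,172-subclass table available as the empirical option);
  cows are assigned to cells at random, and calving dates fall inside
  the cell's season (winter cells use Oct–Dec so a cell never straddles
  two calendar-year HYS keys).
* **Genotypes** — founder alleles per SNP at frequencies uniform on the
  configured MAF range, descendants by Mendelian gene dropping,
  independent SNPs (no linkage map, no QTL: breeding values are drawn
  from the pedigree, so genomic relationships agree with the additive
  covariance only in expectation — a deliberate limitation; see below).
  Only a configured fraction of sires is retained as genotyped,
  mirroring sire-only genotyping.
* **Phenotypes** — breeding values exactly from
  `a_i = ½a_s + ½a_d + m_i`, `m_i ~ N(0, D_i G0)`; residuals N(0, R0);
  HYS effects i.i.d. normal with configurable SD, eight lactation-stage
  effects, linear regressions on centred age at calving (days) and
  percent HF. Default truth: the pedigree-analysis posterior means
  (genetic 0.02588/0.00055/0.00462; residual = phenotypic − genetic).
  In ordinal mode latent values are standardized and cut at equally
  spaced thresholds calibrated by moment matching so score means/SDs
  reproduce the recorded totals (MS 3.05/0.73, MT 1.97/0.37); the
  latent-continuous mode is the clean model world used for recovery
  experiments.

Default sizes (300 sires × 15 daughters, 45 herds, 2,000 SNPs, 20% of
sires genotyped) are a desk-scale rendition of the recorded analysis
(13,280 cows, 43,772 SNPs, 319 genotyped sires): small enough to run in
minutes, large enough that half-sib information identifies heritabilities
of 0.08–0.12.

## What passing tests do and do not show

The synthetic world satisfies the model assumptions exactly (multivariate
normal latents, homogeneous HYS variance, complete genotypes, no
selection, single records). Passing recovery tests therefore demonstrate
the correctness of the estimation machinery, not robustness to the
violations real recording data carry (subjective ordinal scoring,
selection, heterogeneous herds, imputation error). Because genotypes are
simulated independently of the breeding values, the single-step run on
synthetic data measures only the degeneracy and algebra of H⁻¹, not a
genomic-information gain; consistent with the reference analysis, the
two modes give very similar estimates.

The recovery experiment (300×15, truth h² = 0.120/0.080, tolerance
±0.03) deliberately keeps the prescribed desk scale: the realized-h²
sampling SD of that design is ≈ 0.025–0.03 per trait, so recovered
values sit within, but sometimes near, the tolerance — that is a
property of the design, not of the sampler.

## Known limitations

* Linear treatment of ordinal scores (matching the reference analysis);
  no threshold-model likelihood.
* Single-trait or two-trait only; no maternal effects, repeated records,
  or multi-chain R-hat.
* `location_update` supports the blocked draw only; the canonical
  decomposition makes it cheap at every supported scale, so a
  single-site fallback would have no use case.
* Genotype QC beyond the MAF filter (call rate, imputation) is out of
  scope; dosages must be complete.
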