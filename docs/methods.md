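# Methods

## Phenotype model

The six CSF analytes are modeled as linear combinations of five orthogonal
component scores plus marker-specific noise. After a rank-based inverse
normal transformation (INT) the analytes are treated as standard normal
within study, so the analysis operates on the correlation matrix throughout.

**INT.** Within each study, observed values are replaced by
`Φ⁻¹((rank − 3/8)/(n + 1/4))` with average ranks for ties (Blom offsets).
The offset choice is conventional; any of the standard offsets gives
rank-identical scores, so downstream results are qualitatively unchanged.
Missing cells stay missing. Groups with fewer than two observations are an
error rather than a silent pass-through.

**Component count.** Cross-validation holds out *cells* of the biomarker
matrix, not rows: a matrix-completion model can predict a deleted cell from
the rest of its row, whereas deleting a whole row leaves nothing to predict
from. Observed cells are partitioned into folds (default 10; exact
leave-one-cell-out available via `n_folds=None`), each fold is masked in
turn, the matrix is re-imputed at rank k, and the mean squared prediction
error on the original standardized scale is accumulated. k = 0 (column
means) up to `k_max` are candidates; the argmin wins.

**Imputation.** Regularized iterative PCA: standardize by observed
moments, fill missing cells, and alternate (i) a truncated SVD of the
completed, recentred matrix with retained singular values shrunk by
`σ ← (σ² − r·σ̄²)/σ` — where `σ̄²` is the mean discarded squared singular
value and `r` the regularization weight (default 1, i.e. full shrinkage;
0 recovers plain EM-PCA) — and (ii) a refill of the missing cells only.
The refill solves the per-row fixed point
`(I − W)ₘₘ(xₘ − μₘ) = Wₘₒ(xₒ − μₒ)` exactly (W the rank-k smoother,
rows batched by missingness pattern), which converges in a handful of outer
iterations even when the spectrum is nearly degenerate; the plain
cell-update iteration can need thousands of iterations there. Tolerance
10⁻⁶ on the largest imputed-cell change, 1000 iterations maximum,
non-convergence raises with the last delta. Observed cells pass through
bit-identically.

**Rotation and scores.** Principal axes of the correlation matrix are
varimax-rotated with Kaiser row normalization using the classical iterative
pairwise planar rotations. (A gradient-projection rotation was tried first
and stalls on a saddle point when two components are exactly balanced —
e.g. two perfectly correlated marker blocks; the pairwise angle update
resolves that case and agrees with the gradient solution elsewhere, which a
test verifies against `statsmodels.rotate_factors`.) Loadings are structure
coefficients; variance explained is the column sum of squared loadings over
the marker count. Component order and sign are fixed by anchor markers
(tau, Aβ, NfL, YKL-40, Ng for PC1..PC5), ties broken by variance explained.
Scores use the regression method (weights `R⁻¹Λ`; Bartlett weights behind a
flag) and are rescaled to unit SD on the estimation sample; applying a
fitted model to new data never refits anything.

**Group comparison.** The pipeline is fitted per group, components matched
by maximal Tucker congruence with sign alignment, and loading differences
below 0.04 in absolute value flagged "indifferent". One caveat a user should
know: varimax compresses cross-loading contrasts, so a difference planted in
the *generating* factor loadings reappears in the *fitted* loadings at
roughly half its size. Tests that check recovery of a target fitted-loading
difference therefore calibrate the generating contrast against the
population varimax solution rather than assuming the two coincide.

## Association models

Per SNP and per study, OLS with the PC score as outcome and imputed dosage
(0–2 effect alleles) as predictor. The main model adds sex and five ancestry
components (plus an array/study indicator where the metadata calls for it);
stratified models subset by sex and drop the sex term; the interaction model
adds dosage×sex (female = 1) and reports the product coefficient — the
female-minus-male effect difference, which equals the difference of
stratified slopes exactly in the covariate-free case. Dosages enter the
regression as dosages; hard calls (rounded) are used only for the HWE
chi-square. X-chromosome male dosages are coded {0, 2}. Rank-deficient or
within-stratum-monomorphic designs are dropped with a logged reason; the
report layer prints NA.

QC keeps a variant iff MAF ≥ 0.01 in **every** study, imputation R²
strictly > 0.30, and HWE p ≥ 5×10⁻⁶ (chi-square on combined cases and
controls; at these thresholds and sample sizes the exact test adds nothing).
Genomic inflation is `median(χ²)/0.4549`. Fixed-effect meta-analysis uses
inverse-variance weights after allele harmonization (sign flip + frequency
complement for swapped alleles; strand-ambiguous A/T and C/G variants with
frequency in (0.4, 0.6) are dropped as undecidable). DerSimonian–Laird
random effects (the standard default when no method is named) is provided
for sensitivity only — the primary combination is fixed-effect.

Gene tests use the SNP-wise mean model: with per-SNP statistics `zᵢ²`, the
sum `Σzᵢ²` is referred to a `Σλᵢχ²₁` null, λ the eigenvalues of the local
LD correlation matrix — estimated from the analysis cohort's own dosages,
which is self-contained and asymptotically equivalent to reference-panel
LD for in-sample statistics. The tail probability comes from Imhof's
characteristic-function inversion (tolerance 10⁻⁹); if the integral is
unreliable (extreme tails, p < 10⁻¹⁰) a moment-matched gamma takes over.
Non-PSD LD matrices are projected by eigenvalue clipping with a warning.
The gene-wise Bonferroni threshold is α/n_genes as a formula; for 19,511
genes this is 2.56×10⁻⁶.

## Latent AD and mediation

Diagnosis (control / MCI / AD) is the categorization of a latent disease
scale at two thresholds. With a single three-category indicator, the item
factor analysis of that indicator *is* an ordinal probit, so the model is
fitted by maximum likelihood: latent response `y* = x'β + ε`, `ε ~ N(0,1)`,
categories cut at τ₁ < τ₂ (parametrized as τ₁ and a log-difference so
monotonicity is unconstrained). The fit uses BFGS with analytic gradients —
products of linear and probit coefficients need bootstrap inference, and the
bootstrap needs thousands of warm-started refits, so the likelihood is
implemented in-package; `statsmodels.OrderedModel` serves as the independent
cross-check in the test suite. Standard errors, when requested, come from
the observed information (finite differences of the analytic gradient).

Coefficients are re-standardized to the latent-AD SD scale by dividing by
`√(Var(x'β̂) + 1)`; thresholds likewise. This makes a coefficient the effect
in SD of latent AD, the scale on which mediation products live, and it is
exact under the model: a predictor with true standardized effect ρ is
recovered as ρ (verified by simulation at ρ ∈ {0, 0.2, 0.41}).

The mediation model for one SNP: a-paths are OLS slopes of each PC on
dosage (plus covariates); b-paths and the direct path come from one joint
ordinal probit of diagnosis on all five PCs, the dosage, and covariates.
Mediation through PC j is `aⱼ·βⱼ/D` with `D` the standardization
denominator; the decomposition `total = Σ mediation + direct` holds to
machine precision by construction. The proportion mediated `joint/total` is
reported only when joint and total share a sign (a zero joint with nonzero
direct reports 0; a zero total reports undefined), and is printed to two
decimals. The full-information estimator this package replaces weighs the
polychoric moments differently (WLSMV); with one ordinal indicator the
estimand coincides, and maximum likelihood plus bootstrap is simpler to
make reproducible.

**Inference.** Nonparametric bootstrap over individuals (default B = 1000,
seeded), warm-starting each probit at the full-sample solution; SEs are
bootstrap SDs, p-values and CIs use the normal approximation. Products of
coefficients are skewed at realistic effect sizes, which is why the delta
method is not used. Calibration note: for a path whose true product is
exactly zero the CI covers essentially always (both factors concentrate at
0), so coverage should be — and in the tests is — assessed on paths with
nonzero truth, where it sits near nominal.

**Moderated mediation** duplicates every SNP path with a dosage×sex product
term: male estimates are the base coefficients, female estimates base plus
interaction. If any SNP-path interaction is nominally significant
(p < 0.05) the sex-specific decompositions are selected for reporting,
otherwise the main-model results are presented; both are always carried.
With the product terms removed the model reduces exactly to the main
mediation fit.

## Synthetic cohorts

The generator emulates the two-study setting the analysis assumes: HWE
genotypes at configurable MAFs (hemizygous X coding), five standard-normal
component scores, biomarkers = loadings·scores + noise with the published
all-sample loading structure as default and uniquenesses 1 − communality
(floored at 0.02 where rounded published loadings imply communality > 1),
per-study assay intercepts and a monotone exponential marginal distortion
(`exp(x/2)`) so the INT stage has real work to do, MCAR missingness
(default 10%, capped at two missing analytes per participant to respect the
4-of-6 inclusion rule), ancestry components, per-study age distributions,
and an ordinal diagnosis from the latent-index model with thresholds
(−1.47, 0.40).

Two deliberate design choices:

* **Diagnosis precedes the sex shifts.** The latent disease index is built
  from the component scores *before* the female–male mean shifts are added
  (planted SNP effects are included, so mediation pathways exist). If the
  shifts fed the diagnosis, adjusting the sex-contrast regression for
  diagnosis — as the analysis specifies — would condition on a collider and
  the planted shift would no longer be the estimand (about −0.34 recovered
  for a planted −0.40 under the default PC3→AD coefficient). With the
  generator's ordering, the planted shift is exactly the adjusted contrast.
* **Unit-variance outcomes.** When SNP effects are planted, component noise
  is rescaled so the phenotype keeps unit variance (for a −0.50 SD allele at
  MAF 0.30 the residual variance is 1 − 2pqβ² = 0.895); per-allele effects
  then stay on the SD scale of the observed phenotype. Toggle:
  `unit_variance`.

Defaults are the study conditions: n = 973 (genotyped subset; 1158 for
biomarker-only analyses), two studies, female fraction 557/1158, sex shifts
(0, 0, −0.40, 0, +0.21), PC→AD coefficients (0.41, −0.34, 0.40, 0, 0),
imputation quality ~ U(0.3, 1) so QC has work to do.

What the generator does **not** emulate: linkage disequilibrium beyond
optional block-correlated genotypes (gene-level tests build their own LD
blocks), population structure, assay batch effects beyond an additive study
intercept, informative missingness, and selection into genotyping. Passing
tests therefore demonstrate correctness of the estimators under the stated
model, not robustness to the messiness of real cohort data.

## Problem sizes in the test suite

Simulation-based checks are sized to keep the default suite fast while
leaving the Monte-Carlo error well inside each assertion's tolerance: e.g.
the null-GWAS λ check uses 50,000 SNPs because the sampling SD of a
median-based λ at 5,000 SNPs (≈0.032, measured) exceeds the width of the
[0.95, 1.05] band, while at 50,000 it is ≈0.010; bootstrap-coverage checks
pool seven active paths over 50 replicates at n = 973 with B = 150; GWAS
effect-recovery averages 100 replicates. The acceptance script mirrors the
study sizes directly (n = 973, 1158, 601) and completes in seconds.

## Known limitations

* Ordinal probit + bootstrap replaces the WLSMV weighting of the original
  estimator; point estimands coincide for this model class but small-sample
  behavior can differ.
* The gene test implements the SNP-wise mean model only (no top-SNP or
  multi-model combination).
* In-sample LD is a single-cohort approximation; with very small cohorts the
  eigenvalue weights are noisy.
* `proportion mediated` is intrinsically unstable when the total effect is
  near zero; the undefined-on-sign-disagreement rule handles the qualitative
  cases but values above 1 still occur when direct and joint effects
  partially cancel.
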