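# Methods

This note records the statistical models the package implements, the
design of the synthetic cohorts used to exercise them, and the numerical
choices and limitations a user should know about.

## Study design being emulated

The pipeline targets a two-cohort genomic-selection design common in
livestock work: a *discovery* cohort (default n = 685) genotyped and
phenotyped to supply GWAS priors, and an independent
*reference/validation* cohort (default n = 651) on which breeding-value
prediction is evaluated. Both cohorts carry two-scale quantitative
growth traits with moderate heritability (default h² = 0.45) affected
by sex and age. Because the motivating pig data are not public, the
package ships a simulator with known ground truth; every downstream
claim the tests make is therefore a claim about this synthetic design,
checked against exact oracles where one exists.

## Synthetic cohorts (simdata)

**Genotypes.** Each SNP gets a base-population allele frequency drawn
uniformly from `maf_range` (default 0.05–0.5), shared by both cohorts,
so cross-cohort allele-frequency correlation is high and panel
intersection is realistic. Haplotypes come from a first-order Gaussian
copula: per chromosome a latent AR(1) series with lag-one correlation
`ld_rho` is thresholded at the normal quantile of each frequency.
Dosages are sums of two independent haplotypes, so sites are in
Hardy–Weinberg proportions by construction and dosages are exactly
{0, 1, 2} (a missingness rate exists solely to exercise QC).

`ld_rho` defaults to 0.98. The choice is a calibration of the emulation,
made as follows: the accuracy of single-kernel genomic prediction is
governed by the number of effective independent chromosome segments Me
relative to n·h². With 5000 markers and latent correlation ρ, the
correlation length is ≈ 1/(1−ρ) markers; ρ = 0.98 gives a few hundred
effective segments across 18 chromosomes — the magnitude implied by
livestock chip data, where commercial populations show strong LD at
50K-chip marker spacing — and puts single-kernel cross-validated
accuracy at h² = 0.45 in the 0.3–0.5 range typical of real pig cohorts.
Weak-LD settings (ρ ≈ 0.5) make Me ≫ n·h² and depress accuracy to ~0.1,
which no livestock study shows; ρ is exposed for users who want that
regime. The heritability-recovery behaviour of REML is insensitive to
this choice (verified in the tests at both ρ = 0 and ρ = 0.98).

**Traits.** A trait has `n_qtls` causal SNPs (default 500) placed
uniformly among the panel, with i.i.d. normal effects. The genetic score
is rescaled so its sample variance equals h²·`trait_sd`², and residuals
are drawn with variance (1−h²)·`trait_sd`², so realized heritability
matches the target in expectation and is recorded exactly per replicate.
Defaults put the trait near mean 40, SD 5 (a loin-muscle-area-like
scale, cm²); a helper converts caliper height × width to area via the
standard 0.7 factor. Sex (balanced 0/1, default effect 1.5) and age
(uniform over 160–220 days, default slope 0.05/day) enter as fixed
effects. The two cohorts share `prop_shared_qtl` of their QTLs
(default 1.0 — full sharing; the cross-population genetic correlation of
real breeds is unknown, so this is a knob, not a claim).

**What the simulator does not emulate:** pedigree/family structure,
selection, genotyping error, allele-frequency divergence between
breeds, imputation error, or sequence-scale marker density. Passing
tests therefore show the *methods* behave correctly under a clean
livestock-like architecture; they do not certify performance on any
particular real population.

## Quality control (genio)

Filters run in a fixed order — individuals by call rate (> 0.90), then
SNPs by call rate (> 0.90), minor allele frequency (> 0.01),
Hardy–Weinberg exact-test p (> 1e-6), then sex-chromosome and
monomorphic removal — with allele frequencies recomputed after
individual removal so SNP statistics reflect the retained cohort. The
HWE test is the exact conditional test (sum of probabilities of all
heterozygote counts, given allele counts, no more probable than the
observed one), computed by the numerically safe mid-out recurrence; a
chi-square approximation is deliberately not used. Dosages count copies
of the second listed allele (.bim A2); SNP identity everywhere is
`chrom:pos:alleleA/alleleB` with alphabetically ordered alleles, making
panel intersection allele-aware but allele-order insensitive.

## Relationship matrices (kinship)

The GRM standardizes each SNP by its sample frequency:
G = (1/m) Σᵢ wᵢwᵢᵀ with w = (x − 2p)/√(2p(1−p)); missing dosages are
mean-imputed before centering; zero-variance SNPs are skipped with m
reduced. A VanRaden ratio form is available behind a flag. Feature and
remainder GRMs recompute frequencies per subset by default; passing
shared full-panel frequencies makes the exact partition identity
(m_f·G_f + m_r·G_r)/(m_f + m_r) = G hold to machine precision, which the
tests use as the module's oracle for the scaling convention.

## Variance components (varcomp)

AI-REML with an EM fallback. Each iteration evaluates a small candidate
set — the average-information step solved over the *active* components
(those not pinned at the variance floor with a negative score), a
half-step, a boundary move flooring the components the AI step pushed
negative, and the EM step — and takes whichever has the highest
restricted likelihood. The EM candidate guarantees accepted iterations
never decrease the likelihood; the active-set step makes boundary optima
(a variance estimated at zero) converge in a handful of iterations
instead of crawling. Convergence is |Δ log-likelihood| < 1e-8, at most
200 iterations; non-convergence is flagged on the result, not raised.
Variances are floored at 1e-8·var(y) to keep the AI matrix invertible,
and estimates ending on the floor set a boundary flag. Standard errors
come from the inverse AI matrix; the h² standard error uses the delta
method. Single-kernel models are iterated in the kernel's eigenbasis
(one O(n³) decomposition, then O(n·p²) per iteration), which is what
makes per-fold re-estimation in cross-validation cheap. A genetic kernel
equal to the identity raises an identifiability error (it is confounded
with the residual), and a constant response raises rather than returning
a degenerate fit.

Phenotype correction fits the animal model y = Xb + u + e with the
genomic kernel (fixed effects: intercept, sex, centered age, and the
top genomic PCs — PC scores are GRM eigenvectors scaled by √eigenvalue
with a deterministic sign convention), then returns y − X·b̂ at the GLS
estimate of b. The genetic and residual parts are retained on purpose:
they carry the signal prediction needs. Corrected values satisfy the GLS
normal-equation identity XᵀV⁻¹(y − Xb̂) = 0, which the tests check; plain
zero covariance with X holds only for OLS residualization and is not
asserted.

## Association scan (assoc)

The mixed-linear-model scan estimates (σ²_g, σ²_e) once under the null
model (intercept only), then fixes them: V = Gσ̂²_g + Iσ̂²_e is
Cholesky-factorized a single time and reused for every SNP's GLS effect
estimate (intercept projected out) and Wald χ²(1) p-value. The candidate
SNP remains in the GRM — no leave-one-chromosome-out — so proximal
contamination is accepted; at the panel sizes used here its effect is a
slight conservatism. Monomorphic SNPs are flagged untestable, never
dropped. The genomic inflation factor is median χ²/0.4549; under
permuted-phenotype nulls the scan's type-I error at α = 0.05 is inside
[0.035, 0.065] and λ_gc ≈ 1.

## Preselection (select)

Discovery SNPs are binned at strict p < {0.05, 0.005, 0.0005, 0.00005},
giving nested sets, and each set is intersected with the target panel by
canonical key. Sites matching on position but not on the (unordered)
allele pair do not match; strand flips and multiallelic sites are out of
scope, appropriate for two panels derived from one reference. Empty
selections warn rather than fail; the empty-feature refusal happens at
the prediction stage, where it is actionable.

## Prediction and evaluation (predict)

GBLUP: μ̂ by GLS on the reference block, then
û = σ²_u·G[:,ref]·V_ref⁻¹·(y_ref − μ̂) for every individual, so validation
individuals get predictions without their phenotypes ever being read —
the predictor's interface accepts reference phenotypes only. GEBV agree
with marker-effect ridge regression (SNP-BLUP) to 1e-6 when the GRM is
built from the same standardized markers.

GFBLUP: two-kernel REML on the reference block gives (σ̂²_f, σ̂²_r, σ̂²_e);
the kernels collapse to G_new = λG_f + (1−λ)G_r with λ = σ̂²_f/(σ̂²_f+σ̂²_r),
and a single-kernel BLUP with genetic variance σ̂²_f + σ̂²_r produces the
GEBV. Since λ·(σ̂²_f+σ̂²_r) = σ̂²_f, the collapsed kernel reproduces
σ̂²_f·G_f + σ̂²_r·G_r exactly — the collapse is an identity for point
prediction, not an approximation; an explicit two-kernel solver is kept
behind a flag as a numerical cross-check.

Cross-validation: 5 folds × 5 repeats (sizes differing by ≤ 1; 651
individuals give {131, 130, 130, 130, 130}), fresh random partition per
repeat, variance components re-estimated inside every training split
(the conservative, leakage-free choice), feature sets fixed from the
external discovery scan and never re-selected per fold. Accuracy is the
Pearson correlation between held-out corrected phenotypes and GEBV —
raw, not divided by √h², so its ceiling is ≈ √h². Splits with
zero-variance validation phenotypes are flagged and excluded from the
mean with a warning, never silently averaged. Identical seeds give
identical partitions, so models compared at the same seed share folds.

## Problem sizes and runtime

Default analyses run at the emulated study design — discovery 685,
target 651, 5000 markers, 500 QTLs — where a full GBLUP 5×5 CV takes a
few seconds (eigenbasis REML) and a GFBLUP CV about half a minute
(dense two-kernel AI-REML per fold). The acceptance script performs one
complete end-to-end run at this design; the test suite additionally runs
ten-replicate recovery and directional checks at the same scale.

## Known limitations

- The copula LD model has no recombination-map or demographic
  interpretation; `ld_rho` is an effective-LD dial calibrated to
  livestock accuracy scales, not an estimate of any population's LD.
- h² estimates on PC-corrected phenotypes can drift a few points from
  the realized value at strong LD (structure partially absorbed by PCs);
  the recovery guarantees in the tests apply to the direct fixed-effects
  model.
- No multi-trait models, dominance/epistasis, single-step (H-matrix)
  blending, LD pruning of features, or imputation; QC assumes biallelic
  autosomal-style input.
- The two cohorts share a marker map; real cross-panel intersection
  with differing chips/imputation attrition is emulated only through the
  allele-aware key matching, not through panel differences.
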