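# Methods

## The log-linear model and its assumptions

The haplotypic read count of a gene is modeled as
Yᵢʰ = Lᵢ θ₀,ᵢ exp(β Xᵢʰ) × noise: library size acts as an exposure,
baseline abundance θ₀,ᵢ varies between individuals, and the variant's
effect is a multiplicative allelic fold change exp(β) on the haplotype
carrying the alternative allele.  Three approximations make the
inference linear and fast:

1. **Weak effects.** log((e^{βX¹} + e^{βX²})/2) ≈ β(X¹+X²)/2, so the log
   total count is linear in the average dosage.  The approximation error
   is second order in β and affects only heterozygotes; at aFC = 2 it
   biases the total-count slope by a few percent, which is diluted far
   below the combined estimate's tolerance because the allelic component
   (which is exact in β) dominates the meta-analysis weight whenever
   allele-specific coverage is good.
2. **Count-scaled errors.** Log-count errors have variance inversely
   proportional to the count (Var(Y) ∝ E(Y) on the natural scale).  The
   allelic log-ratio therefore has variance σ²(1/Y⁽¹⁾ + 1/Y⁽²⁾) ≡ σ²/w,
   giving the WLS weights w.
3. **Approximate independence.** The allelic ratio cancels the
   individual-level baseline (and any covariate acting on both
   haplotypes), and is approximately independent of the total count, so
   the two regressions can be solved separately and combined as
   independent studies.

## mixQTL: single-variant scan

- Total-count component: OLS of log(Yᵗᵒᵗᵃˡ/2L) on (X¹+X²)/2 with
  intercept; two-sided p from t(n−2).
- Allelic component: WLS of log(Y⁽¹⁾/Y⁽²⁾) on X¹−X² through the origin
  (the baseline cancels, so no intercept is identified); σ² is estimated
  from the weighted residuals of all valid samples with n−1 degrees of
  freedom.  Homozygous samples have fitted value zero but still inform σ².
- Combination: fixed-effect inverse-variance meta-analysis; the combined
  p-value uses the Normal, standard for inverse-variance pooling.  When a
  component is undefined (monomorphic variant, too few allele-specific
  samples) the other is reported alone and the `method` flag records it.

The t-distributions for the components and the Normal for the
combination are our choices; at the sample sizes where the allelic
component activates (≥ 15 samples) the distinction is numerically minor.

### Count filters and weight capping (defaults)

| parameter | default | meaning |
|---|---|---|
| `asc_sample_min_reads` | 15 | sample enters the allelic regression only with **more than** 15 reads on both haplotypes |
| `asc_outlier_max` | 1000 | counts above this on either haplotype are treated as alignment artifacts; sample dropped for that gene |
| `trc_zero_impute` | 1 | zero total counts replaced by 1 before the log |
| weight cap K | min(10, n/10) | largest w at most K× the smallest, limiting leverage of ultra-deep samples; floored at 1 for cohorts under 10 samples |
| `gene_*` filters | 15 samples ≥ 50 asc reads/hap; 500 samples ≥ 100 total | optional gene-level inclusion rule for cohort analyses |
| `min_asc_samples_for_meta` | 15 | minimum valid samples for the allelic component to enter the combined test |

Covariates are removed from the total-count response only, in two
stages: a joint OLS on all covariates, keep those with two-sided
coefficient p < 0.05, then re-fit on the kept set and take residuals.
The joint (not marginal) stage-1 fit is our reading of the procedure;
the allelic response is never adjusted because individual-level effects
cancel in the ratio.

## Two-step preparation for multi-SNP models

Multi-SNP solvers expect one homoskedastic linear model.  Step 1
estimates each block's residual variance by REML, treating the genetic
effect as a random effect: y ~ N(offset, σ_g² K + σ_e² D) with
K = XXᵀ/p (columns centered when an intercept is present) and
D = diag(1/w).  Rows are pre-whitened by √w, the restricted kernel is
eigendecomposed once, and the likelihood is maximized over
δ = σ_e²/σ_g² on log δ ∈ [−10, 10] with a 64-point grid pre-scan
followed by bounded Brent refinement (the grid guards against local
optima; estimates at the search boundary are flagged).  Step 2 centers
the total-count block (response and design columns) and multiplies it by
1/σ̂̃₀, multiplies each allelic row by √wᵢ/σ̂, and stacks the blocks.
Both codings carry the same β, so one coefficient vector solves the
augmented system and single-variant OLS on it reproduces the
meta-analytic z-score (tested to within 10%).

The √w (rather than w) scaling of the allelic rows is the
variance-standardizing transformation for errors N(0, σ²/w): after
multiplication the error is N(0, σ²) exactly.

## mixFine: sum-of-single-effects fine-mapping

A minimal IBSS solver: L = 10 single-effect components, each an exact
Bayesian single-variant regression with a N(0, V_l) effect prior and a
uniform prior over variants.  Per update, the prior variance V_l is
re-estimated by maximizing the single-effect marginal likelihood over
log V (bounded search, initialized at 0.2), with V_l = 0 kept whenever
the null is at least as good; the residual variance is re-estimated as
the expected residual sum of squares over n.  Iteration stops when the
variational objective (ELBO) changes by less than 1e−3 (default cap 100
iterations; non-convergence is reported, not raised).

Credible sets take the smallest prefix of variants, sorted by inclusion
weight (ties broken by index), whose cumulative weight reaches the
requested coverage (default 0.95), and are discarded when the minimum
pairwise |correlation| of member genotype columns falls below 0.5
(purity; sets above 100 members are assessed on their 100 top-weight
members).

**PIPs are aggregated only over effects that produce a purity-passing
credible set.**  Effects with nonzero prior variance but diffuse weights
are fitting noise; including them leaks spurious inclusion mass in the
0.1–0.3 range onto non-causal variants and visibly distorts PIP
calibration in simulation, so they are pruned — the analogue of
credible-set-based pruning in established single-effects software.  The
solver itself is deterministic; an external sum-of-single-effects
implementation can be substituted through the `solver` hook of
`ibss_fit` for cross-checking.

## mixPred: penalized prediction

Elastic net (mixing parameter 0.5 by default, the convention of
transcriptome prediction pipelines) on the augmented rows.  The penalty
path (100 values, logarithmic, down to 1e−3 of the maximal penalty) is
scored by internal 5-fold cross-validation with folds drawn over cohort
samples — a sample's total-count and allelic rows stay together — and
the validation loss is computed **on total-count rows only**, because
the deployable prediction target is log(Yᵗᵒᵗᵃˡ/2L); allelic rows still
inform every fit.  Coefficients from the augmented fit are already on
the per-allele β scale; the intercept is recovered from the training
means.  The evaluation harness follows the inverted cross-validation
convention for learning curves: train on one fold, test on the remaining
k−1, so larger k probes smaller training sets; each split is repeated
twice by default.

## Simulator

Three steps per gene:

1. **Gene body.** Site count ~ Poisson(10), positions uniform on a
   2,000 bp gene body, per-site allele frequency ~ U(0.05, 0.3), alleles
   drawn independently per haplotype so a site is heterozygous with
   probability 2f(1−f).
2. **Counts.** Library size ~ NB(mean 94×10⁶, size 15; coefficient of
   variation ≈ 0.26, matching large RNA-seq cohorts); baseline abundance
   θ₀,ᵢ = 2θ·Beta(c/2, c/2) with concentration c = 20, giving mean θ and
   a between-individual log-s.d. of ≈ 0.23; haplotypic counts
   Yʰ ~ NB with mean L θ₀ e^{βXʰ} and **variance-to-mean ratio
   φ = 2** (`nb_phi`).  Parameterizing over-dispersion by the
   variance-to-mean ratio keeps Var(Y) ∝ E(Y), which is exactly the
   error-scaling assumption of the model; a fixed NB size parameter
   would instead impose constant multiplicative noise that grows without
   bound relative to Poisson at cohort-scale counts and invalidates the
   count-derived weights.
3. **Readout.** A read of 76 bp placed uniformly on the gene body is
   allele-specific iff it overlaps a heterozygous site; the per-sample
   coverage probability α is computed exactly from the merged per-site
   start windows and the allele-specific counts drawn as
   Binomial(Yʰ, α), the marginal of placing each read independently.
   Total count is Y¹ + Y².

Effects are specified either as an aFC per causal variant or as a target
heritability h².  For h², the drawn effects are rescaled so that
var(Σβⱼxⱼ) / (var(Σβⱼxⱼ) + var(log θ₀) + φ/E[Yᵗᵒᵗᵃˡ]) = h², i.e. the
denominator counts all non-genetic variance on the log scale including
the count noise; in simulation the realized genetic fraction of
log-abundance variance then tracks the target (tested to ±0.1).

Candidate cis-variants are drawn independently by default (no LD);
a phased haplotype panel can be supplied to inherit real LD structure.
The simulator does **not** model reference-mapping bias, paired-end
fragments, indels, genotyping error, or shared reads between
overlapping genes — so calibration and power results on simulated data
speak to the statistical model, not to alignment artifacts that real
pipelines must handle upstream (the outlier filter and weight cap exist
precisely for those).

## Numerical choices and degenerate inputs

- Monomorphic variants, all-homozygous allelic designs and empty blocks
  return NA results rather than raising; the scan records per-variant
  `method` flags.
- Zero-variance design columns in the single-effect regression receive a
  Bayes factor of 1 (posterior = prior).
- Missing genotypes drop the affected sample for that variant in the
  scan; the augmented builders use samples with complete genotypes.
- The weight cap is applied after the validity mask, on the masked set.
- Credible-set ties are broken by variant index; duplicate sets across
  effects are reported once.

## Problem sizes

The bundled evaluation defaults are chosen so each suite completes in
minutes on one core: 200 replicates for calibration/power and effect
recovery (n = 500), 100 signal + 100 null replicates with 200 variants
for fine-mapping, 50 replicates × 2 splits for prediction, and 50
synthetic datasets at n = 1000 for variance-component recovery.  The
full simulation grid (sample sizes 100–500, six expression levels,
eight aFC values) is available behind the `--full` flag of
`mixqtl evaluate`.

## Known limitations

- With 200 replicates, the 95% binomial band around a 5% type I error is
  roughly [0.024, 0.085]; any single calibration run has a non-trivial
  chance of grazing the band edges even for a perfectly calibrated test.
- The weak-effect linearization biases the total-count slope upward for
  large effects (visible alone at aFC ≳ 2); the combined estimate
  inherits a diluted version of this only when allele-specific coverage
  is poor.
- The allelic weights are count-derived; if real over-dispersion is
  strongly multiplicative (large constant CV per haplotype), the WLS
  weights lose efficiency, though σ² estimation keeps the test
  calibrated.
- The IBSS solver implements the core algorithm only: no
  summary-statistic mode, refinement passes, or estimated residual-prior
  couplings beyond those described above.
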