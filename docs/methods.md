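# Methods

## The disease model behind the simulator

`grs.synth` generates case/control cohorts under a liability-threshold
model. Each individual's latent liability is L = g + e, where e ~ N(0,1)
and the genetic value g = Σ_j b_j x_j sums per-SNP effects (liability
units) over two groups of causal variants:

- a **major-effect block** of n_block SNPs placed in an MHC-like region
  (chromosome 6, 29.7–33.3 Mb). Block dosages are drawn through a Gaussian
  copula with exchangeable latent correlation r, thresholded per SNP at the
  Hardy-Weinberg genotype-probability quantiles, so pairwise dosage
  correlations land close to (slightly below) r. Defaults: 5 SNPs, r = 0.6,
  effects (0.5, 0.25, 0.2, 0.15, 0.1), allele frequencies U(0.15, 0.5).
- a **polygenic tail** of n_polygenic independent SNPs with effects
  ~ N(0, sd²); default 15 SNPs with sd = 0.15.

All remaining SNPs are independent binomial(2, f) noise with
f ~ U(0.05, 0.95). With the defaults the genetic variance is ≈ 0.5–0.6, so
the variance explained Var(g)/(Var(g)+1) is ≈ 0.33–0.38 and the achievable
AUC at 1% prevalence ≈ 0.88–0.91 — the strongly-predictive regime of a
major-histocompatibility-driven autoimmune disease, chosen from the
analytic variance formula (block: Σb²v + r·v·((Σb)²−Σb²) with v = 2f(1−f))
rather than by tuning against outcomes.

**Disease threshold.** Instead of standardizing L and using a normal
quantile, the threshold T solves `mean_i Φ(g_i − T) = K` over the simulated
super-population pool. Because e is exactly standard normal, the marginal
disease probability is then K by construction — the realized pool disease
count is a sum of independent Bernoullis with mean exactly n·K — which
makes prevalence checks exact tests of the sampler rather than of a
normality approximation. Effect sizes remain on the liability scale
(Var(e) = 1), and the achievable variance explained is
Var(g)/(Var(g)+1).

**Ascertainment.** Cases and controls are drawn *with replacement* from the
case/control strata of a finite pool (default 25× the cohort size), so
rare-disease settings do not require enormous pre-ascertainment
populations; the cost is some duplication of case genotypes at low K. The
study case fraction defaults to 0.4, typical of case/control GWAS panels.
A configurable fraction of "controls" (default 1%) are actually cryptic
cases — undiagnosed true cases mislabeled as controls, as expected when
population-based controls are not screened — which slightly depresses every
measured AUC. Per-cohort allele-frequency perturbations are applied on the
logit scale (sd configurable, default 0) to emulate multi-ethnic cohort
mixing. Dosages are masked missing completely at random (default 0.1%).

What the generator does **not** emulate: realistic recombination/LD maps
(the block is exchangeable, real MHC LD is structured), related
individuals, genotyping batch effects correlated with case status,
X-chromosome SNPs, and imputation dosages. Passing tests on these cohorts
therefore demonstrate correctness of the statistical machinery under the
stated model, not robustness to array artefacts or population structure.

## The solver

The weights minimize Σ_i max(0, 1 − y_i(β₀ + x_iᵀβ))² + λΣ_j|β_j| on raw
{0,1,2} dosages (additive coding, unstandardized; missing values mean-imputed
from the training fold). The optimizer is cyclic coordinate descent:

- each coordinate is set to the **exact minimizer** of its one-dimensional
  piecewise-quadratic restriction (active-set iteration on the margin set,
  then soft-thresholding), with a Lipschitz-majorized gradient step as a
  descent safeguard;
- the intercept is reset to its exact one-dimensional minimizer each sweep;
- sweeps over the non-zero set are interleaved with a full sweep every 10
  iterations; convergence requires a full sweep whose largest relative
  weight change is below `tol`;
- kernels are numba-compiled against the variant-major (transposed) matrix.

Defaults: tol 1e-6, max 10⁴ sweeps. The cross-validation layer uses
tol 1e-4 and max 2000 sweeps — model selection by AUC is insensitive at
that level and paths over 10³–10⁵ SNPs stay fast. The penalty grid is
geometric with 25 points from λ_max (the smallest penalty with an all-zero
optimum, computed from the subgradient condition at the intercept-only
optimum) down to 0.01·λ_max, warm-starting each fit from the previous
solution. An L2 (elastic-net) term is deliberately not offered.

Numerical tie-breaks: weights below 1e-12 of the largest are snapped to
zero; among *exactly* duplicated columns the whole weight is consolidated
onto the first index (cyclic order) after convergence — the L1 optimum is
otherwise indifferent to how weight splits across identical columns.
Solutions are verified in the tests against an independent generic convex
optimizer (L-BFGS-B on the smooth split-variable reformulation) and by KKT
certificates.

## Cross-validation and the consensus model

Folds are stratified by case/control status (preserves the case fraction in
every fold; the choice matters at small n). Imputation means are computed
on each training fold only and reused for the held-out fold. AUC is
aggregated as the mean over fold×replicate models, not by pooling scores.
Ties in mean AUC break toward the smaller model. "Approximately the target
number of SNPs" is operationalized as exact truncation to the target_size
largest |mean weight| SNPs; stability (percent of fold-models selecting a
SNP) is reported untruncated. The diagnostic AUC-versus-size curve is
smoothed with lowess (span 0.75, configurable). The consensus averages all
k·r fold-models at the single selected penalty.

## Evaluation under prevalence

Case/control panels over-represent cases, so PPV at a target prevalence K
is estimated by down-sampling cases (all controls kept;
n_cases = ⌊n_controls·K/(1−K)⌋, so the realized prevalence matches K up to
integer rounding) and measuring precision empirically, repeated 50 times
with **threshold averaging**: all replicate curves are evaluated on one
common grid of cutoffs (default 101 evenly spaced score quantiles of the
full cohort) and averaged at fixed cutoffs. Sensitivity and specificity are
prevalence-invariant; PPV/NPV follow the standard Bayes formulas, checked
in the tests against direct confusion-table counts. The misdiagnosis odds
(1−PPV)/PPV counts non-cases implicated per true case. Classification
thresholds are expressed as *population fractions* (score quantiles), not
sensitivity levels, because the true case count is unknown at deployment;
ties at the quantile boundary all go positive, so with distinct scores
exactly ⌈q·n⌉ samples are flagged. The NPV of the nobody-positive threshold
equals one minus the realized prevalence exactly.

The coarse baseline `stratum_risk_score` assigns each risk stratum (e.g.
carrier classes of a major locus) its training-set log-odds of disease with
a +0.5 continuity correction — the natural comparator for haplotype-level
risk typing against the SNP-level score.

## Calibration

Raw scores are mapped to probabilities via isotonic regression of case
status on score rank in a reference cohort (the empirical case rate as a
monotone function of rank). Calibration is then assessed in 5% quantile
bins of the predictions — observed case proportion per bin with 95%
Agresti–Coull intervals — and corrected by a LOESS smooth (span 0.75,
degree 1, fitted to the bin means) post-processed with isotonic regression
so the correction map is monotone, interpolated linearly between bin knots
and clipped to [0,1]. Empty bins created by heavily tied predictions are
merged into their neighbors with a warning. The split-half protocol fits
the map on one random stratified half and reports the binned absolute
calibration error of the untouched half, before and after correction, both
at the data's own case fraction (~40%) and after down-sampling cases to
10% — calibration is prevalence-specific, so a map fitted at one prevalence
must be refitted for another.

## Quality control

Defaults: remove samples with missingness > 1%; then SNPs with missingness
> 1%, MAF < 1%, or Hardy-Weinberg exact-test P < 5×10⁻⁶ in controls. All
comparisons are strict, so boundary values survive. The HWE test is the
two-sided exact test (plain, not mid-p), summing the probabilities of
heterozygote counts no more probable than observed conditional on allele
counts; monomorphic sites return P = 1. Because removing SNPs changes
per-sample missingness denominators (and vice versa), the filter sequence
iterates to a fixed point, which makes `apply_qc` exactly idempotent; the
report accumulates removal counts over passes. HWE is skipped with a
recorded warning when no controls are present. The MHC selector keeps (or
excludes) chr6:29,700,000–33,300,000, both bounds inclusive. Relatedness
filtering and principal-component adjustment are out of scope: simulated
samples are unrelated by construction.

## File formats and conventions

PLINK 1 bed/bim/fam with the standard two-bit, variant-major encoding
(00 = hom A1, 01 = missing, 10 = het, 11 = hom A2; final byte per variant
zero-padded); dosages count the **A1 allele** (the first bim allele), and
the model table records the effect allele explicitly so scoring can flip
(2 − d) when a target cohort counts the other allele. Strand-ambiguous A/T
and C/G SNPs that only match via complement are dropped with a warning
rather than guessed. The model table stores each SNP's training mean dosage
so missing genotypes score deterministically. fam phenotypes use 1=control,
2=case, anything else unknown; sex is ignored.

## Problem sizes used in the checks

The acceptance script and the heaviest tests use a 2000-sample × 5000-SNP
cohort (20 causal SNPs) with 5×5 cross-validation over a 15-point penalty
grid down to 0.05·λ_max — with 20 causal variants the AUC-optimal model
holds tens to a couple of hundred SNPs, far above the grid floor, so the
shallower grid loses nothing while keeping the run to a few minutes on one
CPU. Prevalence-invariance checks use 12,000-sample cohorts scored with the
true genetic liability (the Monte-Carlo-cheapest score with known ceiling);
solver-versus-oracle equivalence uses ≥50 random instances with n ≤ 60,
p ≤ 20 at several penalties.

## Known limitations

- The exchangeable-copula block understates real MHC haplotype structure;
  selection stability on real data will be lower than on these cohorts.
- Sampling with replacement during ascertainment duplicates case genotypes
  at low prevalence, slightly reducing effective sample size.
- The solver consolidates only *exactly* duplicated columns; near-perfect
  LD still splits weight arbitrarily (as any L1 method does).
- Calibration maps are prevalence-specific by design; applying a map fitted
  at 40% case fraction to a 1%-prevalence population without re-weighting
  will misestimate absolute risk.
- p ≫ 10⁵ out-of-core fitting and imputation dosages are not supported.
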