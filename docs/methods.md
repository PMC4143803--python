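# Methods

`rplskit` tests whether the rare and common variants inside a gene are
jointly associated with a trait, in an unrelated-individuals design.  This
note records the statistical models, the defaults and why they were
chosen, the numerical machinery, and what the simulation studies do and do
not demonstrate.

## Data model

Genotypes are minor-allele dosages `x_ij ∈ {0,1,2}` for sample `i` and SNV
`j`.  ALT-coded VCF dosages are folded (`x → 2−x` wherever the coded-allele
frequency among observed genotypes exceeds 0.5), monomorphic variants are
dropped, and missing genotypes are mean-imputed per variant.  MAF is
computed from observed entries only, before imputation; multiallelic
records are skipped rather than split.  Positions are 1-based internally;
BED intervals are converted at the boundary.  A variant may belong to
several overlapping genes.

Traits are either quantitative (`gaussian` family: SBP, DBP in mm Hg, or
the PC1 composite) or binary (`binomial`: hypertension status).  HTN is 1
iff SBP ≥ 140 mm Hg, DBP ≥ 90 mm Hg (inclusive), or the sample is on
antihypertensive medication.  PC1 is the leading principal component of
*standardized* SBP and DBP — for a 2×2 correlation matrix the loading is
`(1, sign r)/√2`, so PC1 is the equally weighted composite of the two
z-scores, sign-fixed so that higher PC1 means higher blood pressure.
Standardizing first makes the composite invariant to the different
measurement scales of the two pressures; the raw-covariance alternative
would let SBP (larger variance) dominate.

## The rPLS test

For one gene with dosage matrix `X` (n×p) and covariates `Z` (age, sex):

1. **Screening.**  An elastic net with mixing weight `en_alpha = 0.5` is
   fit to the standardized dosage columns with the covariates unpenalized
   (for the gaussian family the covariates are profiled out exactly by
   residualization; for the logistic family they carry zero penalty
   weight).  The penalty is chosen by 10-fold cross-validation with folds
   taken from a seeded permutation; the **1-SE rule** picks the largest
   penalty whose mean CV error is within one standard error of the
   minimum.  Variants with nonzero coefficients form the selected set
   (size `k`).
2. **Supervariant.**  The selected columns are centered and collapsed into
   `t = X_s w` with the first partial-least-squares loading
   `w = X_s'y / ‖X_s'y‖` (the working response is the centered trait; for
   a binary trait, the centered 0/1 indicator).  Only the first component
   is used.
3. **Inference.**  `g(μ) = β₀ + tβ* + Zγ` is fit (identity link/OLS for
   gaussian, logit for binomial) and H₀: β* = 0 is tested two-sided.  The
   gaussian Wald test uses the exact t reference; the logistic test the
   usual normal reference, with perfect separation mapped to p = 1 plus a
   flag.  Genes with `k = 0`, or where the working response is orthogonal
   to every selected column, return p = 1 with an empty ranking so
   genome-wide summaries stay well defined.

The magnitudes `|w_j|` rank the selected SNVs (ties broken by genomic
position).  Because `w` is proportional to the covariances between the
*centered, unscaled* dosages and the trait, the ranking readout is most
meaningful when it is read conditionally on the screen having selected a
set — which is how the benchmark reports it.

**Why the 1-SE rule.**  The screen and the test use the same data, so the
procedure is anticonservative by construction.  Under a global null with
10-SNV genes at n = 150, choosing the CV-minimizing penalty yields an
empirical size of ≈ 0.045 at α = 0.001 — selection happens in almost every
gene and the subsequent test then rejects.  The 1-SE rule (the default
coefficient-extraction convention of the reference penalized-regression
software) leaves the selection empty for ≈ 99.8% of null genes and brings
the size to ≈ 0.0014, i.e. mildly elevated but within ~3× nominal.  The
CV-min rule remains available (`lambda_rule="min"`).

The gaussian elastic-net path is computed by Gram-matrix coordinate
descent (numba-compiled), warm-started down a 100-point geometric grid
from the all-zero penalty; it reproduces scikit-learn's coordinate descent
to its own tolerance and is ~50× faster at per-gene sizes, which is what
makes the 10⁵-test calibration study feasible.

## Comparison tests

* **SUM** collapses the gene to the per-sample minor-allele count
  `s_i = Σ_j x_ij` and tests its slope with 1 df (exact t test for
  gaussian traits).  It is powerful when effects share a direction and
  collapses to near-zero power when balanced positive and negative
  effects cancel in `s`.
* **SKAT** computes `Q = (y−μ̂₀)' X W² X' (y−μ̂₀)` with Beta(1,25)-density
  MAF weights (flat weights by flag) and the covariates-only null fit
  `μ̂₀`.  Under the null `Q` is a positively weighted mixture of 1-df
  chi-squares with weights the eigenvalues of the projected weighted
  kernel.
* **SKAT-O** evaluates `Q_ρ = (1−ρ)Q_SKAT + ρQ_burden` over the grid
  `ρ ∈ {0, 0.01, 0.04, 0.09, 0.16, 0.25, 0.5, 1}`, takes the minimum of
  the per-ρ p-values, and converts it back to a p-value by integrating the
  grid-minimization null over the shared 1-df burden component (see
  Numerics).  The optimal ρ is reported.

All variants in a gene enter every test (a `--maf-max` filter exists but
defaults to off).

### Small-sample exact gaussian SKAT

The classical SKAT p-value plugs the estimated residual variance in as if
known; at n = 150 this inflates the α = 0.01 size to ≈ 0.012.  For
gaussian traits the residual vector is exactly multivariate normal under
the null, so the event `Q/σ̂² ≥ q` is equivalent to a sign condition on a
single quadratic form with eigenvalues `{μ_j − c}` (kernel directions) and
`−c` with multiplicity ν−m (remaining residual df), `c = r'Kr/r'r`.  One
CF inversion evaluates this exactly; it is the default
(`exact_gaussian=True`).  For a single variant it reduces to the exact
F/t test, while the plug-in version (`exact_gaussian=False`) reduces to
the 1-df chi-square score test.  Binomial traits use the standard
asymptotic score machinery; SKAT-O uses the plug-in convention throughout
because its min-p null is inherently asymptotic.

## Numerics

**Mixture-of-chi-squares tails.**  `P(Σ λ_j χ²₁ > q)` is computed by
characteristic-function inversion of Imhof's integral with a composite
16-point Gauss–Legendre rule: the truncation point comes from scanning the
integrand envelope until its tail bound drops below π·acc (acc = 1e-9),
and the panel grid is the union of a linear grid resolving the oscillation
(≈ 2 periods per panel) and a geometric grid resolving the envelope decay.
Eigenvalue multiplicities are handled symbolically, so the exact gaussian
SKAT null (one distinct eigenvalue with multiplicity ≈ n) costs the same
as a small mixture.  Mixtures of ≤ 4 positive terms decay too slowly for a
truncated oscillatory integral; they are computed exactly by conditioning
one chi-square out at a time (χ²₁ = Z²), with the square-root endpoint
kink absorbed by a Gauss–Jacobi rule (m = 2 uses the odd-analytic
structure of `erf` and is exact to ~1e-12).  A two-resolution check guards
every inversion; on failure the Liu moment-matching approximation is used
and flagged in the result row.

**SKAT-O min-p null.**  Per-ρ critical values at the observed min-p are
exact CF-based quantiles (log-secant refinement of the Liu start).  The
one-dimensional integral over the burden component substitutes `x = s²`
(removing the χ²₁ density singularity) and evaluates the
moment-corrected remainder CDF for all abscissae in one vectorized CF
sweep.  Against a 5×10⁵-draw direct Monte-Carlo of the gaussian min-p null
the integration agrees to ~1e-3 in the detection regime (p ≲ 0.1); at
mid-range p the moment-matched remainder approximation leaves an absolute
error of order 0.01, a known property of this construction, which is
designed for small p.  The reported SKAT-O p-value is clipped to the
theoretically valid bracket `[min-p, |grid|·min-p]`.

**Wald references.**  Gaussian 1-df Wald tests use the t distribution
(the normal approximation alone would shift the α = 0.01 size to ≈ 0.011
at n = 150); logistic tests use the IRLS normal reference.

## Synthetic data

The generator emulates a replicate-based evaluation design: genotypes drawn
once and fixed, phenotypes re-simulated per replicate from a known model,
so that per-gene power is a fraction of replicates.

* **MAF spectrum** `maf ~ min(Beta(0.2, 5), 0.5)` — severely rare-skewed
  (median ≈ 0.008, > 50% of variants below 0.05).  Dosages are
  Binomial(2, maf) under Hardy–Weinberg equilibrium, independent across
  variants; optional within-gene LD via a latent AR(1) gaussian copula.
  By default monomorphic draws are redrawn so every simulated variant is
  polymorphic at the sampled size; spectrum-fidelity checks disable this.
  A `causal_maf` override pins individual causal variants at a stated
  frequency.
* **Traits.**  `y = β₀ + Σ β_j x_j + 0.01·age + 0.25·sex + ε`,
  `ε ~ N(0, 1)`; age ~ Uniform(20, 80) and sex ~ Bernoulli(0.5) are drawn
  once and fixed with the genotypes.  The covariate slopes put the age
  contribution at ≈ 0.17 residual SD across the cohort and the sex
  contribution at 0.25 SD — visible to the adjustment but not dominant.
  Binary traits threshold the same liability at a configured prevalence
  (default 0.30), with the threshold solved so the *expected* case
  fraction matches the prevalence.  A blood-pressure helper produces
  correlated SBP/DBP on the mm Hg scale (120/80 ± 15/10, residual
  correlation ≈ 0.6, 10% medicated) from which HTN and PC1 derive.
* **Cohort size** defaults to n = 150 samples and 200 phenotype
  replicates, the scale of the unrelated-individuals design the package
  targets.
* **Default benchmark scenario**: 30 causal genes and 100 noncausal genes
  of 50–500 SNVs; causal genes carry 2–8 causal SNVs with |β| = 0.5,
  alternating sign in half of the genes (the regime where burden tests
  fail); one "driver" gene holds a single β = 1.0, maf = 0.1 causal SNV
  among 49 noise SNVs to exercise the loading-ranking readout.

All randomness flows from one scenario seed through named substreams
(genotypes / covariates / phenotypes), so every artifact is bit
reproducible.

What the generator does **not** emulate: linkage disequilibrium with
untyped causal variants, population structure and relatedness, genotyping
error, non-gaussian trait residuals, and gene–environment interaction.
Calibration and power results under this generator therefore demonstrate
the statistical machinery, not robustness to those real-data features.

## Simulation studies and their sizes

* **Null calibration** (`null_size_study`): n = 150, 200 fixed 10-SNV null
  genes, a fresh trait per gene-test (so outcomes are independent
  Bernoulli draws and binomial bounds apply): 10⁵ tests for SKAT and SUM,
  2.5×10⁴ for rPLS (~25 expected nominal hits at α = 0.001, ample for the
  ≤ 0.01 bound on its screening-inflated size).
* **Permutation oracles** (`permutation_agreement_study`): one n = 50,
  p = 8 gene with common-ish variants (maf ~ Beta(1, 4)) and moderate
  aligned effects, 10⁵ permutations; each analytic p-value is compared
  with the permutation p-value of *the same statistic*.  The rPLS oracle
  conditions on the fitted supervariant: refitting the loading per
  permutation is a different, adaptive statistic, whose inflation is
  exactly what the calibration study measures.
* **Matched-size power** (`matched_power_study`): one 20-SNV gene with 8
  causal SNVs (maf 0.1, |β| = 0.5), mixed-sign vs aligned; 100 signal
  replicates, thresholds from 1000 null replicates on the same genotypes
  at empirical size ≤ 0.05 (order-statistic threshold, so the heavily
  discrete rPLS null — most p-values exactly 1 — is compared at an even
  *smaller* size than SUM, making the ordering assertion conservative).
* **Ranking recovery** (`ranking_recovery_study`): one gene with a single
  β = 1.0, maf = 0.1 causal SNV among 20 spectrum-drawn noise SNVs,
  n = 150, 100 replicates.  The headline rate is the fraction of
  replicates *with a nonempty selection* in which the causal SNV tops the
  |loading| ranking (~100%); the unconditional rate (~0.7) is limited by
  the 1-SE screen's deliberate conservatism and is reported alongside.

## Known limitations

* The rPLS p-value is not selection-corrected; it is the same-data
  screening-plus-testing procedure, and its residual size inflation is
  measured, not removed.  Data splitting or selective inference are out of
  scope.
* Binomial-family screening (logistic elastic net with unpenalized
  covariates) is one to two orders of magnitude slower than the gaussian
  path; large binary-trait benchmarks should budget accordingly.
* SKAT-O's analytic p-value is least accurate (absolute error ~0.01) in
  the mid-range p regime; interpretation there should lean on SKAT and the
  burden test individually.
* The VCF reader loads genotypes densely into memory; chromosome-scale
  cohorts should be chunked by gene map before loading.
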