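# Methods

## Shape model

Landmark sets are 65 ordered 2D points per subject; point order encodes
anatomical correspondence and is never permuted. Generalized Procrustes
analysis centres each configuration, scales it to unit centroid size
(default; a `scale=False` / `--keep-size` switch keeps size in the
shape), and iteratively rotates each shape to the current mean with the
rotation-only (det +1) orthogonal Procrustes solution, re-estimating and
re-normalising the mean until it moves by less than `tol` (default
1e-10). Centroid size is recorded per subject before normalisation, so
size is set aside, not discarded. Rationale for the scale-normalised
default: radiograph magnification varies between exposures, so raw size
mixes acquisition geometry with anatomy; the analysis concerns shape.

PCA uses the 1/(n−1) sample covariance via SVD of the centred data
matrix. Modes are ordered by descending eigenvalue; the sign of each
eigenvector is fixed by making its largest-magnitude coordinate
positive, which makes output deterministic across BLAS
implementations. The retained count is the smallest m whose cumulative
variance fraction reaches the threshold (default 0.95). A threshold
outside (0, 1] is rejected; a training set with (numerically) zero
total variance raises "zero total variance" rather than returning an
empty model.

Tangent-space projection after GPA is **not** applied. At the
deformation scales this package targets (mode SDs of order 1e-2 on
unit-size shapes) the curvature correction is second order
(≈ 1e-4 relative), far below sampling noise; the unit-sphere curvature
is visible only as trailing eigenvalues ~1e-8, several orders below the
smallest generating mode.

The Kolmogorov–Smirnov normality check tests each mode's scores against
a normal with moments estimated from those same scores. Estimating the
parameters makes the test conservative (the Lilliefors effect):
its false-positive rate is below the nominal level, which is acceptable
for its role as a diagnostic. It warns; it never filters.

## Genotypes

PED/MAP text files are the interchange format. The minor allele is
determined dataset-wide from observed allele counts (ties broken toward
the lexicographically smaller label) and calls are stored as minor-allele
counts with missing as a separate state. MAF is not recomputed after
subsetting to a sex stratum, matching the convention of reporting a
single MAF per SNP. Missing genotypes are handled complete-case per
test: a subject is dropped only for the SNPs where its call is missing;
no imputation of calls is performed.

Hard-calling from probability triples uses the most probable genotype
when its probability is ≥ 0.9 (configurable), otherwise missing. The
MAF filter drops SNPs with MAF ≤ 0.05 — strictly greater is kept, so a
SNP at exactly 5% is removed.

Two-SNP LD uses EM haplotype-frequency estimation from unphased
genotypes: initialised at linkage equilibrium, the only ambiguous cell
(double heterozygotes) is fractionally assigned each iteration, and the
loop stops when the observed-data log-likelihood changes by less than
1e-10 (max 100 iterations). D′ uses the sign-appropriate Dmax; r² is
D²/(pA·qA·pB·qB). Proxy search returns SNPs with r² > 0.85 **or**
|D′| > 0.85, sorted by r².

## Univariate association

`fit_linear` is ordinary least squares of one mode score on
[intercept, coded genotype, covariates] (statsmodels), reporting the
genotype slope, SE, t (n−k df) and two-sided p. Rank-deficient designs
and constant genotypes raise a named "not estimable" error rather than
returning NaNs — an all-heterozygote SNP under dominant coding is the
canonical case.

max(T) permutations recompute |t| for every test in the family under
each permutation. Pointwise and familywise empirical p-values use
(r+1)/(N+1), which cannot be zero and matches the rank-based convention
of standard association tools. The default family is the 12 modes
within one SNP, each SNP receiving an independent permutation stream
derived from the plan seed — permutations are shared across the modes
of a SNP, which is what makes the max(T) familywise correction valid.
An `all_snps_and_modes` family is available, sharing one permutation
stream across every test; with missing genotypes this family restricts
to subjects complete for all SNPs, since a shared permutation is
otherwise undefined.

With covariates the default scheme is Freedman–Lane: residuals of the
scores on the covariates are permuted, the covariate fit is added back,
and the full model is re-fitted. A `raw_label_swap` scheme (plain
phenotype shuffling) is provided for compatibility with simpler tools;
without covariates the two coincide. The permutation engine works in a
partialled-out parameterisation in which each permuted statistic is an
inner product of a permuted basis vector with fixed residual columns,
so a permutation costs one small matrix product; without covariates
this reduces to shuffling the centred genotype vector directly.

The dominance diagnostic computes mean scores per genotype class and
raises a flag when |mean₂ − mean₁| < 0.25·|mean₁ − mean₀| (classes =
minor-allele counts), i.e. when heterozygotes resemble minor-allele
homozygotes, prompting a dominant-model re-fit. The 0.25 ratio is
configurable; at the default it reliably separates dominant from
additive patterns once the per-class mean SEs are a few times smaller
than the allelic effect.

Analytic power for the additive slope test uses the noncentral F
distribution with λ = n·β²·2·MAF·(1−MAF)/σ², where σ is the residual
score SD. At β = 0 this returns exactly the type-I rate.

## Multivariate association

One coded genotype against all retained modes. Since the genotype side
is univariate, the first canonical correlation satisfies r₁² = R² of
regressing the (covariate-residualised) genotype on the
(covariate-residualised) modes; Wilks' Λ = 1 − r₁² and
F = ((1−Λ)/Λ)·((n−c−1−p)/p) on (p, n−c−1−p) df is exact. Covariates
enter by Frisch–Waugh residualisation with the error df reduced by c;
this is the assumed mechanism for covariate-adjusted multivariate
p-values, since the classical implementation of this test has no
covariate support of its own.

Loadings are structure correlations — the correlation of each mode with
the canonical phenotype variate. On training-set PCA scores, whose
columns are empirically uncorrelated, these coincide up to sign with
the normalised canonical weights and their squares sum to 1 (published
loading tables square-sum to ≈1 up to rounding, consistent with either
definition on uncorrelated phenotypes). Signed values are kept
internally; absolute values are reported.

Top-k selection takes the k largest |loading|, ties toward the lower
mode index, and returns mode indices in ascending order. The reduced
model is then re-tested on the same data. This selection-then-retest
step is reproduced as published; under the null it is anti-conservative
(the test suite measures the inflation rather than hiding it), so
reduced-model p-values should be read as descriptive of where the
association lives, not as independently calibrated.

The screen is additive-only by default — the multivariate engine
rejects dominant coding with a clear message, because mixing codings
silently would make the screen's Bonferroni accounting ambiguous — and
accepts it via `allow_any_coding=True`, flagged in the result.

## Synthetic cohorts

The generator defines the study conditions the package is tested under:

* **Template**: a fixed 65-point femur-like closed outline (medial
  shaft, lesser trochanter, femoral head arc, saddle, greater
  trochanter, lateral shaft), resampled to equal arc length, centred,
  unit centroid size. Pure function of its arguments.
* **Modes**: 12 displacement fields — head size, neck width, shaft
  width, neck-shaft angle, trochanter height, then smooth
  normal-direction bending fields — Gram–Schmidt-orthonormalised
  against each other **and** against the four similarity-transform
  directions at the template (translations, rotation, scaling), so the
  injected variance is not absorbed by Procrustes alignment.
* **Score SDs**: sd_k = 0.012·0.78^((k−1)/2), k = 1..12, with
  per-coordinate landmark jitter SD 4.8e-4. These two constants were
  chosen jointly, once, so that (a) the 95% variance cutoff retains
  exactly the 12 generating modes (the noise floor contributes ~5% of
  total variance, putting the 11-mode cumulative fraction just below
  0.95 and the 12-mode fraction just above), and (b) a per-allele
  effect of −0.0029 score units on mode 5 at MAF 0.48 — the magnitude
  scale of reported hip-shape effects — yields >80% analytic power at
  n = 929. No per-mode SDs for real femur SSMs are published; these are
  calibrated to the printed effect sizes and power claims, not taken
  from data.
* **Genotypes**: Binomial(2, MAF) per SNP — Hardy–Weinberg by
  construction; null-SNP MAFs evenly spaced over 0.12–0.48. Effects add
  β·code(g) to the targeted mode's score.
* **Pose jitter**: rotation ±10°, scale 0.9–1.1, translation ±10% of
  centroid size per subject — large enough that skipping Procrustes
  visibly corrupts the PCA, small enough to keep point correspondence
  meaningful.
* **Demography**: 929 subjects, 570:359 female:male, age 64.1 ± 15.0 y,
  BMI 27.4 ± 7.9 kg/m²; height is not part of the emulated summary
  statistics and is drawn per sex (women 162.7 ± 6.2 cm, men
  176.2 ± 6.9 cm, ordinary European adult values). Sex is a label used
  for stratification only; there is no sex-specific template.
* **Seeding**: one master seed; genotypes get one sub-stream per SNP
  and subjects one sub-stream each (spawned deterministically), so the
  first n subjects are bit-identical when the cohort grows. Identical
  specs give byte-identical on-disk cohorts.

What the generator does **not** emulate: correlated landmark
annotation error (jitter is i.i.d. per coordinate), LD between the
simulated SNPs (each is drawn independently; LD routines are tested
against a separate haplotype simulator), genotype missingness,
covariate–shape confounding (available but off by default), and any
nonlinear shape variation. Passing tests therefore demonstrate
correctness of the statistical machinery under the stated model, not
robustness to annotation artefacts or population structure in real
radiograph cohorts.

## Problem sizes used by the checks

The statistical suite runs at the cohort scale it emulates (929
subjects, 12 modes, 41 SNPs). Null calibration of EMP1/EMP2 uses 250
replicate cohorts at 2,000 permutations each (the acceptance script
uses 150), pooling the pointwise rate over all tests and the familywise
rate over per-SNP families; effect recovery uses 200 seeds (script:
100); power comparisons use 5,000 Monte-Carlo simulations per grid
point; subspace recovery uses n = 2,000. Exhaustive-enumeration checks
of the permutation engine use n = 7 (7! = 5,040 relabelings) against
100,000 sampled permutations.

## Known limitations

* The multivariate reduced-model re-test inherits the published
  procedure's selection bias (measured, not corrected).
* The EM LD estimator assumes random mating within the sample and is
  undefined for monomorphic SNPs (it raises).
* GPA assumes landmark correspondence is correct; there is no outlier
  down-weighting.
* The `all_snps_and_modes` permutation family requires complete
  genotypes across the family.
* No binary PED (BED/BIM/FAM) support; inputs are text formats.
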