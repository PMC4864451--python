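# shapeqt

Statistical-shape-model (SSM) quantitative-trait association for 2D
landmark outlines.

Radiographic bone shape — here, the outline of the proximal femur on a
pelvic radiograph, annotated with 65 corresponding landmarks — is a
heritable, clinically relevant phenotype: femoral head size and neck
width are linked to hip osteoarthritis risk. This package implements
the full analysis chain for testing candidate SNPs against such shape
phenotypes:

1. **Shape modelling.** Generalized Procrustes analysis (GPA)
   superimposes the landmark sets (removing translation, rotation and
   scale), and PCA of the aligned coordinates yields a point-distribution
   model: each subject's shape is `x ≈ x̄ + Σₖ bₖ φₖ`, where the
   orthonormal modes `φₖ` are retained up to 95% cumulative variance.
   The per-subject mode scores `bₖ` are the quantitative traits.
2. **Univariate association.** Each retained mode is regressed on the
   coded genotype (additive 0/1/2 or dominant 0/1 minor-allele copies)
   with optional covariates (age, BMI, height). Empirical significance
   comes from max(T) permutations: pointwise (EMP1) and familywise
   (EMP2) p-values with the `(r+1)/(N+1)` convention, the familywise
   correction using the per-permutation maximum |t| over the family of
   modes. Bonferroni thresholds and an analytic power calculation
   (noncentral F with `λ = n β² · 2·MAF·(1−MAF) / σ²`) round this out.
3. **Multivariate association.** A canonical-correlation test of one
   SNP against all retained modes jointly: with a single genotype
   variable, `r₁² = R²` of regressing the genotype on the modes,
   Wilks' Λ = 1 − r₁², and `F = ((1−Λ)/Λ)·((n−c−1−p)/p)` is exact on
   `(p, n−c−1−p)` df. Per-mode loadings (correlations with the
   canonical variate) identify the top-k contributing modes, which are
   then re-tested as a reduced model.
4. **Synthetic cohorts.** Because landmark/genotype cohorts of this
   kind are rarely shareable, a first-class generator produces cohorts
   with known structure — a femur-like 65-point template, 12
   orthonormal displacement modes with decreasing SDs, Hardy–Weinberg
   genotypes (MAF 0.12–0.48), per-allele effects of a few thousandths
   of a score unit, and per-subject pose jitter — so every stage is
   testable end to end.

## Worked example

```python
import numpy as np
from shapeqt import (CohortSpec, GeneticEffectSpec, simulate_cohort,
                     gpa_align, build_ssm, mode_scores, fit_linear,
                     cca_snp_test, top_k_modes, code_genotype)

effect = GeneticEffectSpec("rs_demo", maf=0.48, model="additive",
                           target_mode=5, beta=-0.0029)
cohort = simulate_cohort(CohortSpec(n_subjects=929, seed=1, null_snps=40,
                                    effects=(effect,)))
aligned, _ = gpa_align(cohort.landmarks)
model = build_ssm(aligned, variance_threshold=0.95)
print(f"retained modes: {model.retained}")
scores = mode_scores(model, aligned)
g = code_genotype(cohort.genotypes.column("rs_demo"), "additive")
uni = fit_linear(scores["mode5"].to_numpy(), g)
print(f"mode 5: beta={uni.beta:.6f} se={uni.se:.6f} p={uni.p:.2e}")
mv = cca_snp_test(g, scores, snp_id="rs_demo")
print(f"CCA: r1={mv.canonical_correlation:.3f} p={mv.p_value:.2e}")
print(f"top-3 modes by |loading|: {top_k_modes(mv, 3)}")
```

prints

```
retained modes: 12
mode 5: beta=-0.003319 se=0.000341 p=2.13e-21
CCA: r1=0.342 p=6.71e-19
top-3 modes by |loading|: [3, 4, 5]
```

Twelve modes cover 95% of the aligned shape variance; the regression
recovers the simulated per-allele effect on mode 5 (−0.0029, estimate
−0.0033 ± 0.0003); the joint CCA test is strongly significant and its
top-3 loading set contains the causal mode (the other two slots are
noise, since only one mode carries signal here).

A command-line interface mirrors the library
(`shapeqt simulate | build-ssm | assoc-uni | assoc-mv | run`); `shapeqt
run --config study.yaml` executes a full stratified study (per-sex
shape models, per-SNP stratum assignment, covariate sets, permutation
plan) and writes association tables, loadings, KS normality reports,
mode-extreme outline SVGs and a reproducibility manifest.

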