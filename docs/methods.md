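# Methods

This note records the statistical model behind `morphostat`, the choices
made where the design was genuinely open, and what the synthetic-data
generator does and does not emulate.

## Data model

A morphology study is a samples × parameters table with strain labels and
a breeding lineage: every strain belongs to a genetic background, sits at
a breeding step (`original`, `GE01`, `GE21`, `GE31`, `GE41`), and — unless
original — has exactly one parent in the same background. One strain is
the global reference (K7 in the default layout). Replicate counts are
unbalanced by design: 37 for the reference, 6 for its derivatives, 5
elsewhere (136 samples over 20 strains). Parameter values may be missing
per sample; statistics drop missing pairs per parameter and never impute.

## GLM normalization and Wald Z-values

Each parameter is modeled as `g(E[y]) = β₀ + β_strain` with the reference
strain as intercept:

| family   | link     | dispersion handling                      |
|----------|----------|------------------------------------------|
| gaussian | identity | closed-form OLS, σ² = SSR/(n−p)           |
| gamma    | log      | IRLS, Pearson-χ² scale                    |
| beta     | logit    | joint ML of mean and log-precision        |
| binomial | logit    | variance weights = cell counts when known, else quasi-binomial (Pearson scale) |

Wald statistics use the observed-information covariance at the fit.
Strain-level Z is the contrast Wald statistic `(η̂_s − η̂_b)/SE`; for the
gaussian two-group case this reduces exactly to the pooled two-sample Z.
Replicate-level Z standardizes each observation against the fitted
baseline-strain mean using the family's plug-in single-observation SD,
`Z_i = (y_i − μ̂_b)/ŝd_Y(μ̂_b)`, on the response scale. The response scale
is used because the raw-value link transform is undefined for binomial
proportions of exactly 0 or 1; for gaussian/identity the two scales
coincide. The plug-in (not leave-one-out) group variance is used and
recorded in the Z-matrix sidecar. Two baselines are supported: the global
reference strain, and each strain's parent (original strains are centered
on their own mean, so the reference replicates remain usable for the
second-step PCA).

Zero-variance parameters are estimable but carry no dispersion; they are
flagged, excluded from PCA inputs, and listed in the Z-matrix metadata.

## Morphospace

PCA is computed on the sample variance–covariance matrix (n−1
denominator) of the explicitly column-centered Z-matrix. Because rows ≪
columns, the implementation runs through the thin SVD of the centered
data, which is algebraically identical to the explicit covariance
eigendecomposition (tested to 1e-10 against that oracle). Loading signs
are fixed by flipping each vector so its largest-magnitude entry is
positive, making results backend-independent. The degenerated space keeps
the smallest k with cumulative explained variance ≥ the threshold
(default 0.90); a 1e-12 tolerance absorbs float roundoff at exact
boundaries (ten equal eigenvalues at 0.90 give k = 9, not 10).

## HMA and its gamma ANOVA

HMA of a replicate is its Euclidean distance from the reference strain's
score centroid over the first k PCs. At threshold 1.0 this equals the
distance computed directly in centered Z-space (rotation invariance, an
acceptance property).

Step tests fit a gamma GLM (log link) of distance against the lineage's
cumulative-step design matrix: intercept = reference strain, one
indicator per non-reference background (the original-strain offset), and
one cumulative indicator per (background, step) covering the edited
strain and all its descendants. Under this coding each step coefficient
is the parent → derivative increment, so no post-hoc contrasts are
needed. Both the coefficient Wald test and a drop-one-column
scaled-deviance LRT are available (the underlying study used both in
different places); the result object records which was used. q-values are
Benjamini–Hochberg across the 16 steps. The gamma family excludes zero;
a distance of exactly 0 can only arise in degenerate synthetic fixtures
and is nudged by (smallest positive distance) × 1e-6 with a loud log
entry.

## Step-effect detection

Per parameter, the same design matrix is fitted with the parameter's own
family, and detection is two-staged: (1) omnibus test of the full model
against intercept-only, BH-FDR across parameters; (2) per-step Wald
tests for surviving parameters, BH-FDR across all (parameter × step)
hypotheses; a pair is detected only if both gates pass. The omnibus
statistic is the exact-likelihood LRT where a true likelihood exists
(gaussian: n·log(SSR₀/SSR₁); beta and count-weighted binomial: 2Δllf) and
the scaled-deviance quasi-LRT (D₀−D₁)/φ̂ for gamma and quasi-binomial,
all referred to χ² with df = number of step/background columns.
Non-converged fits are flagged, logged, and excluded from downstream
Venn counting. The gaussian path is solved as one vectorized
least-squares system across all gaussian parameters — numerically
identical to the per-parameter fit (tested to 1e-10) and what makes
50-seed calibration ensembles affordable.

Direction is the sign of the step's Wald Z; an exactly-zero Z cannot be
directional and is excluded. The direction-aware Venn assigns each
detected parameter to the subset of backgrounds sharing its sign; a sign
reversal contributes the parameter to two disjoint regions ("counted
twice"). Conservation holds by construction: total region counts equal
the number of distinct signs per parameter summed over parameters.

## Two-step successive PCA

Step one: covariance PCA of strain-level mean Z-values (parent-baseline
mode), truncated at 90%. Screening correlates every parameter's Z column
with each kept PC's scores; significance is the exact t-test of zero
Pearson correlation (n−2 df) — the "uncorrelation test" — with BH-FDR per
PC. Step two re-decomposes each correlated set using only the reference
strain's replicates and keeps components covering 60% of the set's
variance (a reported property of the original analysis, adopted as the
default); a parameter is representative if its correlation with any
retained component passes α = 0.01 after Bonferroni correction over the
set size (the conservative per-PC family). A singleton set is trivially
representative and flagged as degenerate. The replicate-only second step
is what separates parameters co-varying through shared cell biology from
parameters that merely respond to the same strain contrasts.

## Brewing components

Tukey HSD (studentized range, scipy) per component on the one-way strain
layout; with two groups it reduces to the pooled t-test (tested to 1e-6).
The component PCA standardizes each component to unit strain-mean SD
before the covariance decomposition, because the 21 components carry
incommensurable units (density index, %, ppm, mg/L) and raw covariance
PCA would be dominated by the largest-unit component; a flag disables the
scaling. Samples are projected with the same centering, scaling and
loadings as the strain means, and per-background trajectory vectors run
from the original strain to its terminal edited strain present in the
table.

## Synthetic-data generator

The generator emulates the statistical structure the pipeline assumes,
with fully known ground truth:

- **Families.** Each parameter has a family, baseline, and dispersion.
  The default census splits 501 parameters as 254 gaussian / 123 gamma /
  93 beta / 31 binomial; the true family of each CalMorph parameter is
  catalogued elsewhere and not public, so the census is a configurable
  stand-in fixed only in its total.
- **Effects** are signed shifts on the link scale, attached to a strain,
  and inherited additively by every descendant — matching the GLM
  linear-predictor semantics, so a planted shift is exactly the
  coefficient the normalization should recover.
- **Correlated blocks** share a per-sample latent gaussian factor with
  loading √ρ, pushed through each family's quantile function (gaussian
  copula). Marginals stay exact; latent correlation ≈ ρ (default 0.3,
  blocks of 6 over the continuous parameters — morphological parameters
  move in groups in real data, and an uncorrelated 501-column table would
  make the morphospace trivially isotropic).
- **Seeding** is hierarchical: the global seed is combined with a CRC-32
  of each parameter (or block) name into an independent SeedSequence
  stream, so adding parameters never perturbs existing columns and equal
  seeds give byte-identical tables.
- Default family baselines/dispersions (gaussian N(0,1); gamma mean 1,
  shape 20; beta mean 0.3, precision 50; binomial p 0.3, 100 cells) give
  coefficients of variation of 15–30%, typical of replicate-level
  morphology summaries.

What it does **not** emulate: image segmentation artifacts, heavy-tailed
outliers, missing-value mechanisms tied to cell counts, parameter-specific
mean–variance relationships beyond the four families, and any real
biological covariance between specific named CalMorph parameters. Passing
tests therefore demonstrate correctness and calibration of the
*statistics* under the assumed families, not robustness to CalMorph's
real error structure.

## Simulation sizes and calibration checks

Calibration and recovery properties are verified on seeded ensembles
sized to hold Monte-Carlo error well below the margins being tested:
null FDR of step detection on 50 seeds × 500 mixed-family parameters at
the study's replicate counts; planted-effect sensitivity (3
observation-SD link shifts on 30 parameters at one step) on 50 seeds of a
200-parameter census; block recovery through the successive PCA on 50
seeds; gamma-ANOVA power on 200 seeds of the 6-vs-5 replicate layout.
Coefficient recovery is checked as Wald coverage: the planted effect lies
within estimate ± 2 SE in ≥ 85% of 50 fits (nominal 95%).

## Known limitations

- Beta-family fits use numerical ML; on pathological inputs they can fail
  to converge and are then excluded (flagged and logged), unlike the
  closed-form gaussian path.
- The quasi-LRT for gamma/quasi-binomial omnibus tests is asymptotic; at
  very small replicate counts its χ² reference is approximate (the FDR
  calibration ensemble covers the study's actual counts).
- Per-replicate Z uses a plug-in variance, so replicate Zs within a
  strain are weakly dependent; PCA treats them as exchangeable rows.
- The Venn analysis trusts the two-stage detector; parameters whose GLM
  did not converge are absent from all regions rather than imputed.
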