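# Methods

## The analysis problem

Pancreatic neuroendocrine tumors are graded G1/G2/G3 from the Ki-67
proliferation index, but grade is unreliable on fine-needle biopsy and only
definitive after resection. The pipeline quantifies how much preoperative
portal-venous CT adds to the preoperative clinical picture for two endpoints:
disease progression (a right-censored time-to-event outcome, also analysed as
a binary classification target) and higher-grade disease (G2/G3 at biopsy).
Its distinctive ingredient is *spatial* Δ-radiomics: instead of subtracting a
temporal baseline (the usual delta-radiomics), each radiomic primitive is
referenced to the same feature computed on the patient's contralateral
non-tumor pancreas in the same acquisition.

## Measurement model

For feature *j* of patient *i* the simulator (and, implicitly, the analysis)
assumes

    lesion_ij   = bio_ij + patient_ij + scanner_c(i),j + eps_ij
    pancreas_ij =          patient_ij + scanner_c(i),j + eps'_ij

with `bio_ij = beta_j * aggressiveness_i + sigma_bio * N(0,1)`, the patient
and scanner components drawn once per patient × feature and **shared by both
ROIs**, and the scanner component carrying a per-center additive shift
(gamma_c) and multiplicative scale (delta_c). Consequences the test suite
verifies:

- the lesion-minus-pancreas difference cancels the patient and scanner terms
  exactly when the independent noise vanishes, and on average improves the
  correlation with the latent biology whenever patient/scanner variance is
  present;
- the per-center shift gamma_c is what ComBat estimates and removes;
- common-mode offsets (contrast timing, body habitus) never reach the
  Δ-features.

ComBat at the center level and the Δ-subtraction at the patient level are
complementary: the former removes between-center location/scale batch
structure, the latter within-patient common-mode signal that no
population-level model can see.

## Synthetic cohort: what it emulates and what it does not

`CohortProfile` defaults pin the cohort's categorical structure exactly:
n = 44, biopsy grades 24/15/4 (the counts cover 43 patients; one patient has
no usable biopsy grade), 25 male, 6 functional tumors, 22 patients with
≥ 1 metastatic organ, progression 16/43 with one patient of unknown
progression status, 8 deaths. Continuous variables are quantile-matched: age
~ normal (median 62, IQR 58–68), imaging size and follow-up ~ lognormal
fitted to their median/IQR. Ki-67 is drawn log-normally *per grade*
(G1/G2/G3 medians 2/8/30%, a clinically plausible choice since the profile
only pins the cohort-level median) and then rescaled by a single
multiplicative constant so the observed-cohort median is exactly 4.0% — a
monotone transform that preserves all rank structure. Five patients have
missing Ki-67; together with the missing grade and the missing progression
status this yields the complete-case pattern the univariable survival table
reports (n = 38 for Ki-67 signatures, 42 for grade signatures, 43
otherwise).

Category assignment uses exact-count sampling without replacement, so the
marginals hold for *every* seed; all draws flow from one
`numpy.random.default_rng(seed)`, making outputs bit-identical given the
profile.

Outcomes come from an exponential proportional-hazards model: event time
~ Exp(h0 · exp(lp)) with uniform censoring on [0, W]. Exponential rather than
Weibull keeps closed-form checks (the CDF test, the HR-recovery test)
analytic. Pipeline defaults: h0 = 0.012/month, lp = 0.7 × aggressiveness
(HR ≈ 2 per SD, the order of magnitude of the per-SD hazard ratios such
panels report), W = 120 months.

Not emulated: anatomically realistic organ shapes, contrast-phase or
respiratory variation, spatially correlated feature noise, informative
censoring, and any real joint distribution between radiomic classes. Passing
tests therefore demonstrate that the *statistical machinery* is correct and
leak-free under a known truth — not that any particular discrimination level
will hold in patients.

The phantom generator is plumbing for the extraction chain: ellipsoidal
lesion/pancreas masks in an HU-valued volume, with texture modeled as a
Gaussian random field smoothed to a stated correlation length, and a
whole-volume scanner offset whose cancellation in Δ-statistics is asserted.

## Feature extraction

Defaults: B-spline image resampling to 1×1×1 mm, linear mask resampling
thresholded at 0.5 (nearest-neighbour is available), resegmentation to
[−150, 240] HU, fixed 25-HU bins anchored at the ROI minimum
(`bin = floor((x − min)/25) + 1`, the fixed-bin-width convention of the
common extraction tools; an absolute anchor is configurable). Texture
matrices use distance-1, 26-connected neighbourhoods; GLCM/GLRLM build 13
unique directions and features are averaged over directions; GLSZM zones and
GLDM dependencies use 26-connectivity. Conventions for degenerate inputs:
NGTDM Busyness is 0 when only one gray level exists (vanishing denominator);
Coarseness is capped at 1e6; GLCM Correlation is 1 for a single level.

Shape: volume is voxel count × voxel volume. Surface area comes from a
marching-cubes mesh of the mask *lightly smoothed* (Gaussian, σ = 0.5 voxel)
before meshing — meshing the raw binary staircase overestimates the area of
digitized round objects by ~10%, while the smoothed isosurface recovers the
analytic sphere area to a few percent. The voxel-face convention (sum of
exposed faces) is exposed for exact small-mask arithmetic and is the fallback
when a closed mesh cannot be built (e.g. a single voxel, for which axis
lengths are 0 and flatness 1 by convention). Axis lengths are
4·√(eigenvalue) of the physical coordinate covariance; the maximum 3D
diameter is the largest pairwise distance between boundary-voxel centers
(convex-hull reduced for large masks).

The default inventory is the ~20 primitives the signature panel and
downstream statistics need plus the full first-order and shape classes; full
parity with any specific extraction tool's 100+ feature list is a non-goal.

## Harmonization

Parametric ComBat with center as batch and **no biological covariates in the
design** — the pipeline instead verifies covariate balance across centers
beforehand (Mann–Whitney for continuous, Fisher's exact for binary
covariates) and flags imbalance at p < 0.05. Lesion and pancreas rows are
pooled into one matrix so both ROIs of a patient receive their center's
correction; a switch to per-ROI fits would be a one-line change but is not
the default.
Estimation is the classical empirical-Bayes scheme: standardize by grand
mean/pooled variance, normal prior on the location effects, inverse-gamma on
the squared scale effects, method-of-moments hyperparameters, iterative
conditional estimation to relative tolerance 1e−6 (max 100 iterations).
Zero-variance features are excluded with a warning and passed through; a
single batch degenerates to the identity. The implementation is checked in
the test suite against the Bioconductor `sva::ComBat` reference on a shared
fixture (agreement ~1e−7).

## Signatures

The panel is evaluated from a declarative YAML registry; each signature is a
product of factors drawn from the harmonized lesion table, the Δ table, or
the encoded clinical table (Ki-67 as a fraction in [0,1], grade literally
1/2/3, functional status literally 0/1 — so A3 is 0 for nonfunctional
patients by construction, which is flagged rather than patched). A4 uses the
natural log in log(Energy + 1) and the harmonized lesion Energy. Missingness propagates: a signature
is NaN iff any multiplicand is NaN (a missing factor beats a zero one), which
is what produces the complete-case n bookkeeping downstream. Shape
collinearity is summarized by PCA on the z-scored lesion shape features
(correlation-matrix eigendecomposition, first three components, loading sign
fixed by making each vector's largest entry positive).

## Survival analysis

Each signature is z-standardized on its complete cases with the sample-SD
(n−1) convention — per-SD hazard ratios depend on this choice, so it is
stated. The single-covariate Cox partial likelihood with Efron tie handling
is maximized directly (bounded scalar optimization, |β| ≤ 25); implementing
the likelihood rather than delegating the fit is what makes the
profile-likelihood 95% CI available by bisection of the likelihood-ratio
surface at χ²₁(0.95)/2. A monotone likelihood (separation) is flagged with
infinite bounds, never an exception. The reported p is Wald (from the
numerical observed information); the LRT p is computed alongside. Concordance
is Harrell's c; its bootstrap CI resamples patients (2000 resamples,
percentile) and the permutation p shuffles the score across patients keeping
(time, event) pairs fixed, with p = (1 + #{|c*| ≥ |c|})/(B + 1) on the
|c| = max(c, 1−c) scale so protective and adverse markers are comparable.
Kaplan–Meier uses the product-limit estimator with Greenwood variance on the
log(−log) scale (bands respect [0,1]); median splits send ties to the low
group for determinism.

## Prediction study

Blocks: M0 = {age, sex, imaging size, biopsy grade, biopsy Ki-67} — the five
preoperative variables; under the higher-grade target grade is replaced by
functional status (keeping five) and A3/A4/A7/B3 are excluded from MA/MB
because their formulas contain grade. Screening gates candidates added to
blocks: Spearman correlation clustering at |ρ| ≥ 0.8 (connected components,
medoid representative, name tie-break), baseline-adjusted logistic LRT with
BH-FDR < 0.10 (a light ridge fallback keeps the LRT computable under
separation or collinearity), and 100-bootstrap stability selection at ≥ 60%.

Nested CV: outer 5-fold stratified (re-stratified with a seed bump if a fold
lacks a class), inner 5-fold GridSearchCV over SelectKBest k ∈ {2,3,5}
(ANOVA F score), with median imputation and z-scaling fitted inside the
training pipeline only. Classifiers: logistic regression, random forest,
gradient boosting at fixed library defaults — only k is tuned. Pooled
out-of-fold probabilities (clipped to [1e−6, 1−1e−6]) yield the AUC with a
2000-resample percentile bootstrap CI, the Brier score, and the TRIPOD
calibration regression of the outcome on logit(p): slope and intercept
jointly by maximum likelihood, plus the slope-fixed-at-1 intercept
(calibration-in-the-large) since the variant is ambiguous in practice — both
are reported. LOCO trains on one center and predicts the other, both
directions, pooling all out-of-fold predictions into a single AUC with a
1000-resample bootstrap CI; preprocessing and k-selection see only the
training center.

All resampling streams (bootstrap, permutation, fold shuffling, stability
resamples) derive from explicit seeds; a pipeline run expands one global seed
into independent per-stage streams via `numpy.random.SeedSequence`, and two
runs with the same configuration produce byte-identical metric files.

## Problem sizes used in the checks

The acceptance-style tests run at deliberately modest sizes chosen to give
comfortable statistical margins: calibration recovery averages 200
simulations of n = 2000; ComBat recovery uses 500 samples per center × 20
features; the Δ-cancellation advantage averages 50 cohort seeds; Cox HR
recovery uses n = 2000; the permuted-label leakage check runs 100 repeats per
block × target with the logistic classifier (leakage is a property of the
resampling plumbing shared by all classifiers; the null AUC band
[0.45, 0.55] is a statement about the mean over repeats, and 100 repeats
keep its Monte-Carlo standard error near 0.01).

## Known limitations

- The radiomic inventory is a curated subset, not a full PyRadiomics clone;
  GLDM dependence size is defined as 1 + number of dependent neighbours.
- Cohen's d in the lesion-vs-pancreas comparison is signed as pancreas mean
  minus lesion mean (lesion-elevated features plot negative) and the default
  test is an *unpaired* Mann–Whitney even though the data are paired; a
  paired Wilcoxon variant exists behind a flag.
- Multivariable Cox is intentionally absent: at ~16 events and 10 signatures
  the events-per-variable budget does not support it.
- Synthetic higher-grade discrimination is dominated by Ki-67 in the
  clinical baseline; synthetic progression
  discrimination at n = 43 is weak and noisy — by design the package reports
  uncertainty rather than optimistic point estimates.
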