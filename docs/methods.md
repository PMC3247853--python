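# Methods

This note documents the statistical model, the synthetic-data generator,
the numerical choices, and the limitations of the `twinvar` pipeline.

## The twin mixed-effects model

Each antibody's transformed intensity is modelled as a Gaussian linear
mixed model over the cohort's aliquots,

    Y_ijkl = mu_p(i,j,k,l) [+ beta_p * w~] + H_i + M + E_ij + W_ik + V_ijk + eps_ijkl,

with indices i (pair), j (twin within pair), k (visit), l (aliquot
replicate) and the plate map p(·). Fixed effects are one mean per plate
(no global intercept); model form 2 adds one slope per plate on the well
index centered to mean zero within plate (centering is for conditioning
only and does not change the fit). All random effects are independent,
mean-zero Gaussians.

The classical biometric decomposition into additive genetic (A), dominant
genetic (D) and common-environment (C) variances is not identifiable from
twin data alone. The model therefore estimates the identifiable
re-parameterisation

    Var(H) = 1/2 Var(A) + 1/4 Var(D) + Var(C),
    Var(M) = 1/2 Var(A) + 3/4 Var(D),

implemented structurally: H is grouped at the pair level for everyone,
while M is grouped at the pair level for MZ pairs and at the individual
level for DZ pairs. This is the unique additive grouping that reproduces
both co-twin covariances — Var(H)+Var(M)+Var(W) within an MZ pair at one
visit, Var(H)+Var(W) within a DZ pair. A, D, C are never estimated
individually; only the familial sum Var(H)+Var(M) is reported. Designs
with a single zygosity leave the H/M split completely flat (the profile
likelihood depends only on the sum) and are refused by `build_grouping`
unless explicitly overridden.

### Estimation

Because no random effect spans twin pairs, the marginal covariance is
block-diagonal with one block per pair. The log-likelihood is evaluated
blockwise; blocks with identical within-block grouping patterns share one
Cholesky factorisation per parameter point, so the cost scales with the
number of distinct block structures rather than the number of pairs.
Fixed effects are profiled out by generalised least squares at each
variance iterate — this profiling attains the joint maximum, so the
criterion is full maximum likelihood (not REML). Unbalanced designs
(missing second visits, singleton aliquots) are handled by the likelihood
over observed entries; there is no imputation.

Optimisation details:

- Parameterisation: standard deviations of the six components, lower
  bound 0, so boundary (zero-variance) estimates are attainable — boundary
  estimates are common in practice and are reported as exact zeros.
- The response is standardised internally (results mapped back), which
  makes proportion estimates exactly equivariant under affine rescaling
  of the data and keeps optimizer tolerances scale-free.
- L-BFGS-B with numerical gradients, ftol 1e-12 / gtol 1e-8, at most 500
  iterations, from 5 deterministic multistarts that allocate the
  empirical residual variance in fixed proportions (equal split;
  residual-heavy; familial-heavy; individual-environment-heavy;
  visit-heavy). The best final likelihood wins; the fit is deterministic
  for given data.
- SDs below 1e-7 (standardised scale) are snapped to exactly 0 unless
  snapping lowers the likelihood by more than 1e-6.
- A residual variance estimated at the boundary while duplicate aliquots
  exist is flagged with a warning on the result object.
- Parameter count for AIC: all plate fixed effects plus all six variance
  parameters (k = #plates + 6, or 2·#plates + 6 with drift), with no
  boundary correction. AIC = 2k − 2 ln L; on exact ties the
  plate-means-only form is selected.

Sampling behaviour worth knowing: the individual-visit and residual
components are separated only by duplicate aliquots, and familial versus
individual-environment only by the MZ/DZ contrast. At the canonical
cohort size (77 pairs) boundary-adjacent ML estimates scatter
substantially — single-antibody proportion estimates can move by ±5-15
points between replicates. This is a property of the likelihood surface,
not the optimizer; tests that check point recovery therefore either use
large simulated cohorts (hundreds of pairs) or average over replicates.

## Pre-processing

Order: PQN → outlier removal → Box-Cox, each feeding the next.

- **PQN.** Reference spectrum = antibody-wise median across study
  aliquots (reference wells excluded from the reference, but normalised
  alongside). Each aliquot is divided by the median of its antibody-wise
  quotients against the reference. Applied once, globally — plate-level
  differences are left to the model's plate means.
- **Outlier screen.** Columns standardised to mean 0, SD 1 (SD with
  n−1); SVD of the standardised matrix; squared Mahalanobis distance of
  each aliquot from the origin in the first two principal scores, using
  the empirical diagonal covariance of the scores (distinct score vectors
  are exactly orthogonal, so the diagonal is the full covariance).
  Distances are compared to the upper-alpha chi-squared quantile with 2
  degrees of freedom (18.42 at alpha = 1e-4; for 2 df the quantile is
  exactly −2 ln alpha). The squared distance is the quantity with the
  chi-squared reference distribution. Removal is single-pass — no
  re-screening after removal.
- **Box-Cox.** t(y; λ) = (y^λ − 1)/λ for λ ≠ 0, ln y at λ = 0. λ is
  chosen per antibody by maximising the profile log-likelihood over
  [−2, 2] with bounded scalar minimisation (tolerance 1e-6).
- **Replicate concordance.** Spearman correlation (average ranks on
  ties) between first- and second-aliquot vectors across duplicated
  samples, per antibody; undefined (constant-vector) correlations are
  reported missing and excluded from the cohort median/IQR. Computed on
  raw intensities before normalisation and on normalised intensities
  after. Quartiles throughout use linear interpolation.

## The synthetic-data generator

The generator emulates the study design: 56 MZ + 21 DZ pairs sampled at
visit 1, 34 MZ pairs re-attending in pairs for visit 2 (222 samples), the
visit-1 samples of 24 MZ pairs split into duplicate aliquots (270
aliquots), randomised over three 96-well plates with 6 reference wells
each (288 occupied wells). Revisiting and duplicated pairs are the first
n of the MZ pairs (deterministic); only well assignment consumes
randomness. Latent values follow the model above; the raw scale is the
inverse Box-Cox image of the latent value times a per-aliquot log-normal
dilution factor shared across antibodies — exactly the corruption PQN
targets. Reference wells carry plate/well/residual effects around a fixed
profile and no biological effects. The generator rejects specs whose
inverse Box-Cox image would be non-positive.

Default study conditions (`reference_panel`):

- Variance proportions per antibody follow the published 66-antibody
  decomposition table, with total variance 1 on the transformed scale and
  the familial share assigned entirely to A (the A/D/C split within
  familiality affects nothing estimable).
- boxcox_lambda = 0: log-normal raw fluorescence, the typical shape of
  bead-array intensities.
- dilution_sd = 0.65 (log scale), calibrated so that simulated duplicate
  concordance before/after normalisation reproduces the cohort medians
  reported for the real data (≈0.26 → ≈0.36): with a median
  non-experimental variance share near 0.37 of a unit total,
  r_before ≈ 0.37/(1 + sd²) gives sd ≈ 0.65.
- Plate means (7.0, 7.3, 6.8) on the log scale — a few-tenths plate
  offset, comparable to the component SDs.

What the generator does **not** emulate: bead counts and
median-fluorescence aggregation (simulation starts at per-aliquot
intensity), detection floors/saturation, heavy-tailed or correlated
assay noise across antibodies (other than shared dilution), age or other
covariate effects, assortative mating, and gene–environment interaction.
Passing tests therefore demonstrate correctness of the estimation
machinery under the model's own assumptions, not robustness to
real-data violations of them.

## Problem sizes used in the checks

Test and script problem sizes are the package's own choices, set to make
each quantity statistically identifiable: covariance identities use 5000
pairs per zygosity (Monte-Carlo error ≈ 2% of the target); parameter
recovery uses 500 MZ + 500 DZ pairs with revisits and duplicates,
averaged over replicates (per-replicate sampling SD of a proportion is
≈ 2.7 points, the mean over 10 replicates ≈ 0.9); AIC operating
characteristics use the canonical 77-pair design with 100 simulated
cohorts per scenario, and a drift scenario whose slope spans two total
SDs across a plate. The acceptance script uses 3 recovery replicates and
50 selection replicates per scenario to keep a single-CPU run to a few
minutes; its numbers are correspondingly noisier than the test-suite
versions.

## Known limitations

- No standard errors or confidence intervals for variance components
  (point ML decomposition only), and no small-sample or boundary
  correction to AIC.
- Narrow-sense heritability is not estimable from this design and is not
  reported; familiality bundles additive, dominant and
  common-environment variance.
- With a single zygosity only the combined familial variance is
  identifiable; the package refuses the H/M split rather than silently
  returning an arbitrary one.
- Under the null of no drift, AIC still selects the drift form in
  roughly 10-15% of cohorts at this design (the classical 2-point
  penalty behaviour); model selection here is a descriptive check for
  residual instrument drift, not a test with controlled size.
- The outlier rule assumes the two leading principal scores are
  approximately bivariate normal; with heavy-tailed intensity
  distributions it flags a few aliquots per cohort even without planted
  contamination.
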