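# twinvar

Variance decomposition of antibody-array protein profiles measured on a
longitudinal twin cohort.

Antibody suspension bead arrays report, for each serum sample and each
antibody, a fluorescence intensity proportional to the amount of captured
target protein. Before such profiles can be used for biomarker discovery
one needs to know how much of their variation is stable biology and how
much is short-term fluctuation or assay noise. A twin design answers this:
comparing monozygotic (MZ) twins, dizygotic (DZ) twins, repeat clinic
visits, and duplicate aliquots of the same serum sample separates the
variance of each antibody's profile into five components.

## The model

For aliquot *l* of the sample taken at visit *k* from twin *j* of pair
*i*, the normalised, Box-Cox-transformed intensity is modelled as

```
Y_ijkl = mu_p(i,j,k,l) + H_i + M + E_ij + W_ik + V_ijk + eps_ijkl
```

where `mu_p` is a fixed mean per assay plate (model form 2 adds a linear,
plate-specific drift over well position 1..96) and the random effects are
independent Gaussians:

| effect | grouped by | meaning |
|--------|------------|---------|
| H | twin pair | familial |
| M | pair (MZ) / individual (DZ) | familial |
| E | individual | stable individual environment |
| W | pair × visit | common-visit (shared sampling day) |
| V | individual × visit | individual-visit (short-term biology) |
| eps | aliquot | experimental residual |

H and M re-parameterise the classical additive/dominant/common-environment
(A/D/C) biometric effects — Var(H) = ½Var(A) + ¼Var(D) + Var(C), Var(M) =
½Var(A) + ¾Var(D) — which are not separately identifiable from twin data.
The grouping of M reproduces the co-twin covariances Var(H) + Var(M) for MZ
and Var(H) for DZ pairs, so *familiality* (the genetic plus
common-environment share of variance) is estimable as
`fam = (Var(H) + Var(M)) / Var(Y)`.

The marginal covariance is block-diagonal over pairs. The likelihood is
maximised over non-negative standard deviations with fixed effects
profiled out by GLS, per antibody; plate-means-only and well-drift model
forms are compared by `AIC = 2k − 2 ln L`.

The surrounding pipeline: probabilistic quotient normalisation (PQN)
removes per-aliquot dilution; aliquots whose squared Mahalanobis distance
in the first two principal-component scores exceeds the chi-squared(2)
critical value (18.42 at the 0.0001 level) are dropped; each antibody is
Gaussianised by a profile-ML Box-Cox transform. Technical reproducibility
is tracked as the per-antibody Spearman correlation between duplicate
aliquots.

## Worked example

Simulate the canonical cohort — 56 MZ + 21 DZ pairs, 34 MZ pairs
re-attending for a second visit (222 samples), 48 samples split into
duplicate aliquots (270 aliquots) on three 96-well plates with 6 reference
wells each — then preprocess and fit one antibody:

```python
import twinvar as tv

design = tv.generate_design(56, 21, 34, 24, seed=7)
raw = tv.simulate_intensities(design, tv.reference_panel(n_antibodies=5), seed=7)
pre = tv.preprocess_pipeline(raw, design, alpha=1e-4)

meta = design.metadata(include_reference=False)
meta = meta[meta["aliquot_id"].isin(pre.table.values.index)]
res = tv.select_model(pre.table.values["HPA002550"], meta)
print(res.summary())
```

```
Twin variance decomposition (ML)
================================================
model form:        1  (plate means)
aliquots:          264
log-likelihood:    -466.4555
parameters (k):    9
AIC:               950.9110
converged:         True
------------------------------------------------
component                 variance  % of total
familial (H+M)             0.91587        38.2
indiv. environment         0.12577         5.2
common visit               0.00362         0.2
individual visit           0.16585         6.9
experimental               1.18909        49.5
------------------------------------------------
mu_plate_1                 9.09343
mu_plate_2                 8.92224
mu_plate_3                 9.21325
```

Here 6 of the 270 aliquots were flagged as multivariate outliers, median
duplicate concordance rose from 0.31 to 0.43 after PQN, and for this
antibody 38% of the variance is familial while roughly half is
experimental — the kind of breakdown that tells you whether an antibody
is a promising, stable biomarker readout or dominated by assay noise.

`tv.reference_breakdowns()` returns the published 66-antibody breakdown
table; `tv.cohort_summary` aggregates per-antibody breakdowns into cohort
medians and IQRs.

## Command line

The same workflow is exposed as a CLI:

```bash
twinvar simulate   --config config.yaml --seed 1 --out run/
twinvar preprocess --in run/ --alpha 0.0001 --out run/
twinvar fit        --in run/ --out run/ --model auto
twinvar summarize  --in run/results.csv --out run/
twinvar run-all    --config config.yaml --seed 1 --out run/
```

A full config example:

```yaml
design:
  n_mz_pairs: 56
  n_dz_pairs: 21
  n_revisit_mz_pairs: 34
  n_duplicated_mz_pairs: 24
  plate_capacity: 96
  n_reference_wells_per_plate: 6
antibodies: reference   # the published 66-antibody panel
# or an explicit list:
# antibodies:
#   - antibody_id: ab1
#     components: {var_A: 0.3, var_E: 0.2, var_W: 0.05, var_V: 0.1, var_eps: 0.35}
#     plate_means: [5.0, 5.2, 4.9]
#     boxcox_lambda: 0.0
#     dilution_sd: 0.65
alpha: 0.0001
model: auto             # auto | 1 | 2
# inputs:               # skip simulation, ingest existing CSVs
#   metadata: path/to/metadata.csv
#   intensities: path/to/intensities_raw.csv
```

Identical config + seed gives byte-identical outputs.

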