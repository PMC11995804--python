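# Methods

`megprog` re-creates, on fully synthetic data, an analysis pipeline for
predicting progression from mild cognitive impairment (MCI) to AD dementia
from resting-state MEG, structural MRI and clinical covariates. This note
documents the models, the numerical conventions, and the choices made where
the design was genuinely open.

## Synthetic cohort generator

The generator is the pipeline's test bed: it produces a two-site cohort
(default 64 progressors / 53 stable MCI; Madrid "CTB" 41/49, Cambridge "CBU"
23/4) whose demographics are drawn from group-specific Gaussians matching the
published summary (age 73.03 ± 6.98 vs 72.47 ± 5.32 years, education
10.24 ± 4.54 vs 8.58 ± 4.50 years, MMSE 25.54 ± 2.82 clipped to [17, 30] vs
27.15 ± 2.41 clipped to [22, 30]; sex Bernoulli with the published
proportions and no effect on signals). Missingness is planted exactly: 15
education values, 5 MMSE values and 13 whole MRI blocks, uniformly at random
from the seeded stream. Everything is a pure function of the `CohortSpec`,
including its seed.

### Signal model

Each subject's sensor signals (default 12 × 10 s epochs at 250 Hz over 102
sensors on a unit-disc layout) are a sum of:

1. **1/f background** — white noise spectrally shaped to a power exponent of
   1.0, unit variance per sensor;
2. **posterior alpha** — 8–12 Hz Butterworth-filtered noise (4th order)
   projected through a broad, spatially smooth posterior field (amplitude
   1.5 relative to the background);
3. **posterior beta source** — 16–38 Hz band-limited noise on a posterior
   field (amplitude 1.2), multiplied by `1 − beta_power_reduction` in
   progressors — the planted spectral-power effect;
4. **delta–theta pair** — two 1–4 Hz sources whose sensor mixing differs
   between groups (`lowfreq_cov_shift`), with each sensor's total
   low-frequency gain rescaled so per-sensor power is matched and only the
   cross-sensor covariance changes;
5. **phase-lagged pair** — a ~9 Hz source and its Hilbert quadrature (fixed
   90° lag) on two mixing patterns; the coupling coefficient shrinks by
   `alpha_plv_shift` in progressors (power matched by construction);
6. **envelope-correlated pair** — two independent ~12 Hz carriers multiplied
   by slow (< 0.5 Hz, softplus-positive) envelopes that share a common
   modulator; the shared-envelope weight shrinks by `env_corr_shift` in
   progressors.

Mixing fields are sums of Gaussian bumps over the layout, fixed per cohort so
planted effects are consistent group-level topographies, with 10% leakage
outside the posterior mask to imitate field spread. Subject-level realism
comes from per-source lognormal amplitude jitter (σ = 0.15) and a global
per-subject gain (σ = 0.2 lognormal), the latter acting as a random intercept
on log-power. The group label enters only through multiplicative effect
factors, so with all effect sizes at zero the signal path is exchangeable —
the basis of every null calibration.

Effect-size defaults (`beta_power_reduction = 0.4`, `lowfreq_cov_shift =
0.4`, `env_corr_shift = 0.2`, `alpha_plv_shift = 0.1`) realize the intended
effect hierarchy — spectral power / covariance and MRI strong, envelope
moderate, phase weak — at the reduced cohort sizes the simulation studies
use. A 40% amplitude reduction corresponds to a −0.3 to −0.44 log10 shift at
source-dominated posterior sensors, a large but realistic effect for a group
difference that is visible in averaged spectra.

MRI: total grey matter ~ N(600 cm³, 50 cm³); the hippocampal ratio
(hippocampal volume / total grey matter) is drawn per group (0.0048 vs
0.0058, SD 0.0008, d ≈ 1.25 — the high end of published hippocampal atrophy
in MCI converters) and the hippocampus is region 0 of the 64 atlas regions.
Progressors additionally lose ~0.4 SD in regions 1–8, a mild distributed
temporo-parietal atrophy; the remaining 55 regions are pure nuisance.

What the generator does **not** emulate: biophysical forward models,
ocular/cardiac artefacts, site-specific hardware differences, non-Gaussian
demographics, follow-up time. Passing tests therefore demonstrate the
statistical machinery's correctness and calibration, not performance on real
recordings.

## Wavelet spectra

Morlet kernels sit on a base-2 log grid `f_k = f_min · 2^(k·Δ)` with
Δ = 0.05 octaves over 1–64 Hz (121 wavelets). The Gaussian envelope is set by
the **half-power convention**: the spectral magnitude falls to 1/√2 at
`f ± f(2^{b/2} − 2^{−b/2})/2` with b = 0.35 octaves, i.e.
σ_f = f(2^{b/2} − 2^{−b/2})/(2√ln 2) and σ_t = 1/(2πσ_f). Because the
spectrum is Gaussian in linear frequency, the two octave-defined edges are
reached at slightly asymmetric gains (≈ 0.61 above, ≈ 0.79 below at 10 Hz);
the symmetric half-width is exact. Kernels are truncated at ±5σ_t, normalized
to unit spectral gain at their centre frequency, and samples within the
truncation half-width of an epoch edge are invalid everywhere downstream. At
the default bandwidth the 1 Hz kernel's half-width (5.45 s) exceeds half of a
10 s epoch, so the lowest one or two wavelets carry no valid samples on 10 s
epochs and are flagged unusable rather than zero-filled.

Metrics, all computed from the same coefficients with observations pooled
over every valid sample of every epoch:

* **PSD** — mean |coefficient|² scaled by 2/NEB with NEB = σ_f√π (the
  noise-equivalent bandwidth of a unit-peak Gaussian), giving one-sided
  density in units²/Hz; epoch averaging precedes log10. White noise of
  variance σ² maps to the flat density 2σ²/fs, and Hz-integration across a
  sinusoid's peak recovers a²/2 (both are test oracles).
* **Covariance** — real part of the averaged outer product; its diagonal is
  the unscaled power.
* **dwPLI** — debiased squared weighted phase-lag index
  `((ΣI)² − ΣI²)/((Σ|I|)² − ΣI²)` with I = Im(X_i X̄_j); the denominator is
  treated as zero (value missing) when the imaginary cross-spectrum is zero
  to within rounding of the coefficient amplitude scale.
* **Envelope correlation** — Pearson correlation of log(|coefficient| + ε),
  ε = 10⁻¹² × median amplitude (numerical guard only); invariant to positive
  per-sensor rescaling because log shifts cancel in the correlation.

## Riemannian statistics

Sensor covariance and envelope-correlation matrices are projected to the top
`rank` principal components of the grand-average matrix (rank 65 by default,
matching the rank left by the upstream interference suppression the sensor
counts imply), then regularized by `reg · trace/dim · I` with reg = 10⁻¹⁵.
Eigenvector signs follow a fixed convention (largest-magnitude component
positive) for cross-platform determinism. dwPLI matrices are zero-filled,
repaired to the nearest SPD matrix by eigenvalue clipping, and projected at
rank 5. The affine-invariant metric `δ(A,B) = ‖log(A^{−1/2} B A^{−1/2})‖_F`
is computed via generalized eigenvalues; the Fréchet mean uses the standard
fixed-point iteration on the tangent-space barycentre (tolerance 10⁻⁸, 50
iterations). Tangent vectors are √2-scaled upper triangles, so Euclidean
distance locally matches the manifold distance (verified to < 5% at δ < 0.1).

The group test is a distance MANOVA: pseudo-F from the Gower decomposition of
the pairwise squared-distance matrix, label-permutation p-values with the
(b+1)/(n_perm+1) convention (default 1000 permutations), Benjamini–Hochberg
FDR across frequencies. The pseudo-F is checked exactly against scikit-bio's
PERMANOVA.

## Cluster inference

Per-frequency inference uses percentile bootstrap CIs and two-sided
permutation p-values of the group mean difference (9999 iterations by
default). Mass-univariate maps use the two-group F (= squared pooled t).
TFCE integrates `extent^E · h^H · dh` with E = 0.5, H = 2 and dh = max/50 —
the standard parameterization — over clusters defined by frequency
neighbourhood (1D) or sensor adjacency at equal frequency plus frequency
neighbourhood at equal sensor (2D). Two implementations exist: a per-height
connected-components reference and an incremental union-find used in
production; they agree to machine precision. Two-tailed testing enhances the
positive and negative parts of the t-map separately and uses the permutation
distribution of max |TFCE| for family-wise corrected p-values. Covariate
adjustment (MMSE, site) is per-point linear residualization before testing.
The step count dh = max/n_steps is an approximation of the TFCE integral;
per-map adaptive dh approximates the same integral for observed and permuted
maps alike.

## Logistic risk models

Four nested models of progression (age + education + MMSE, plus hippocampal
ratio and/or cluster MEG power), all predictors z-scored, at most 5 non-site
predictors (⌊27 × 0.2⌋, the 20%-of-smaller-class rule). The "cluster MEG
power" variable is the mean 16–38 Hz log-power over significant posterior
sensors from the spatio-spectral TFCE test, falling back (flagged) to the
full posterior × band selection when no mask is available. Education and MMSE
gaps are mean-imputed; subjects missing the whole MRI block are excluded from
MRI models (117 → 104 at the defaults) rather than imputed. Fitting is
Newton MLE (tolerance 10⁻⁸), with perfect separation detected and reported
with the most separating predictor; average marginal effects use the overall
dydx convention with delta-method inference; discrimination reports in-sample
AUC with refitted percentile-bootstrap CIs (2000 iterations), shared
bootstrap index streams for paired model comparisons, and
sensitivity/specificity at both the Youden-optimal and 0.5 thresholds (the
operating-point rule is open; both are emitted).

## Stacked classification

Nine modality blocks (site, age, sex, education, MMSE, MEG covariance,
MEG envelope correlation, MEG dwPLI, 64 MRI volumes) feed per-block
L2-regularized least-squares classifiers on ±1 targets, penalty chosen by
efficient generalized cross-validation over 50 log-spaced values in
[10⁻³, 10⁵]. MEG matrices enter at every 4th wavelet (31 frequencies at the
default grid) as rank-65 tangent vectors (covariance, envelope) or
upper-triangle vectors (dwPLI). The second layer is an L2 logistic regression
on the nine cross-fitted scores with leave-one-group-out internal CV, the
groups being the outer folds of the training subjects. Evaluation is 10 ×
10-fold stratified CV (stratification is a choice the small classes force),
with identical splits reused across compared models. Every data-dependent
transform — iterative imputation (joint over scalars + MRI, ridge round
robin, 10 rounds or Δ < 10⁻³), standardization, common-subspace filters,
tangent reference — is fitted on training rows only; a corrupted fold
partition raises a hard `LeakageError`.

## Conditional permutation importance

For each second-layer input, a ridge regression (same 50-value grid) predicts
it from the other inputs on the training rows; on the test rows the column is
replaced by prediction + permuted residuals (permutation over test rows only,
re-drawn per permutation; 500 permutations per split by default) and the
increase in log loss is recorded. The cross-fitted pseudo-t (mean/SD across
the 100 splits) is tested one-sided with the Nadeau–Bengio variance
correction `(1/K + ρ)·var`, ρ = n_test/n_train = 1/(n_folds − 1); no
multiplicity correction across the nine variables. An input that is an exact
linear function of the others has zero residuals and hence zero importance —
the property that distinguishes CPI from marginal permutation importance.

## Simulation studies (reduced sizes)

The calibration and recovery studies run at sizes chosen so hundreds of
replicates complete on one CPU; each preserves the progressor/stable
imbalance and two-site structure:

| study | cohort | data per subject | inference |
|---|---|---|---|
| MANOVA type-1 | 12+10, 12 sensors | 3 × 4 s | 1 frequency, rank 6, 100 perms |
| TFCE FWER | 12+10, 10 sensors | 3 × 4 s | 8 wavelets, 100 perms, 20 steps |
| CPI type-1 | 22+18, covariates only | — | 5 blocks + noise, 1 × 5-fold, 50 perms |
| TFCE recovery | 28+23, 24 sensors | 5 × 4 s | 14 wavelets 8–48 Hz, 150 perms |
| logistic ordering | 24+20, 16 sensors | 4 × 4 s | in-sample AUC of Models 1–4 |
| stacking ranking | 24+20, 16 sensors | 4 × 4 s | 6 wavelets, rank 8, 2 × 5-fold |

Null cohorts set every planted effect to zero, making the group label
exchangeable, so empirical rejection rates estimate the true type-1/FWER.
The stacking ranking is assessed on mean AUCs over replicates; per-replicate
rankings at these sizes are dominated by CV noise and are reported, not
asserted.

## Known limitations

* The wavelet bandwidth convention (half-power) and the TFCE step
  parameterization are declared choices; other toolchains may differ in
  detail while agreeing qualitatively.
* The permutation MANOVA is computed on AIRM distances of rank-reduced
  matrices; its numerical agreement with any particular published
  frequency-profile is not a target — its calibration is.
* In-sample logistic AUCs are optimistic by construction; honest
  generalization estimates belong to the cross-validated stacked model.
* The Nadeau–Bengio correction is conservative for truly independent scores;
  its calibration here reflects the dependence structure of repeated CV.
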