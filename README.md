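# megprog

Statistical machinery for asking whether resting-state MEG carries
prognostic information about progression from mild cognitive impairment
(MCI) to AD dementia, and whether that information adds to what MRI atrophy
markers and cognitive screening already provide — packaged with a synthetic
cohort generator so every stage is testable end to end without access to any
clinical dataset.

The pipeline covers, in order:

1. **Synthetic cohort** — a two-site cohort (64 progressors / 53 stable MCI
   by default) with epoched multichannel sensor signals (1/f background,
   posterior alpha, planted group effects in beta-band power, low-frequency
   covariance, phase coupling and envelope correlation), demographics and
   regional brain volumes drawn from published summary distributions, and an
   exact pattern of missing values.
2. **Wavelet spectra** — Morlet wavelets on a base-2 log grid (121 wavelets,
   1–64 Hz, 0.35-octave bandwidth) yielding four metrics on one
   representation: power spectral density, sensor covariance, debiased
   squared weighted phase-lag index (dwPLI) and power-envelope correlation.
3. **Riemannian statistics** — rank-reduced SPD matrices under the
   affine-invariant metric, tangent-space embedding, and a frequency-wise
   permutation distance MANOVA (pseudo-F) with FDR correction.
4. **Cluster inference** — bootstrap CIs, permutation p-values, and
   threshold-free cluster enhancement (TFCE) with max-statistic family-wise
   error control over frequency and sensor × frequency maps.
5. **Risk models** — four nested logistic models
   (`progression ~ age + education + MMSE [+ hippocampal ratio]
   [+ cluster MEG power]`) with AIC comparison, average marginal effects and
   bootstrap AUC.
6. **Stacked classification** — per-modality regularized linear classifiers
   (tangent-space MEG features, MRI volumes, clinical scalars) cross-fitted
   into a logistic combiner under 10 × 10-fold CV with strict leakage
   guards.
7. **Conditional permutation importance** — residual-permutation importance
   of the nine stacked inputs with the Nadeau–Bengio corrected one-sided
   test.

The models and conventions are documented in [docs/methods.md](docs/methods.md).

## Worked example

Simulate a reduced cohort, extract the posterior 16–38 Hz log-power
variable, and compare the four risk models:

```python
import numpy as np
from megprog import cohort, risk, wavelets

spec = cohort.reduced_spec(n_prog=28, n_stable=23, n_sensors=24,
                           n_epochs=5, epoch_len_s=4.0, seed=7)
coh = cohort.simulate_cohort(spec)
layout = cohort.make_layout(spec.n_sensors, spec.seed)
fam = wavelets.build_wavelet_family(8.0, 48.0, 0.35, 0.2, spec.fs)
log_power = wavelets.cohort_log_power(coh, fam)

meg = risk.cluster_meg_power_variable(np.nan_to_num(log_power), fam.foi,
                                      layout)
table = cohort.cohort_table(coh)
comparison = risk.compare_models(table, cluster_power=meg.values,
                                 n_boot=500, rng=0)
print(comparison[["model", "n", "aic", "auc", "auc_lo", "auc_hi"]]
      .round(3).to_string(index=False))
```

```
  model  n    aic   auc  auc_lo  auc_hi
Model 1 51 69.710 0.720   0.607   0.857
Model 2 45 45.430 0.916   0.828   0.984
Model 3 51 60.188 0.837   0.747   0.946
Model 4 45 38.800 0.936   0.889   1.000
```

Model 1 (age, education, MMSE) discriminates progressors moderately
(AUC 0.72); adding the planted MRI atrophy marker (Model 2) or the planted
MEG beta-power reduction (Model 3) improves both fit (lower AIC) and
discrimination, and the combined Model 4 is best — the additive pattern the
pipeline is designed to detect. (MRI models use the 45 subjects with a
complete MRI block; n differs by design.) Average marginal effects of the
full model show each biomarker's independent contribution:

```python
m4 = risk.ProgressionModel.from_cohort(table, risk.MODEL4, meg.values).fit()
print(m4.ame().round(3).to_string())
```

```
                     ame     se      z      p
age                0.072  0.045  1.624  0.104
education          0.030  0.056  0.534  0.594
mmse              -0.162  0.054 -2.979  0.003
cluster_meg_power -0.163  0.050 -3.273  0.001
hippocampal_ratio -0.209  0.045 -4.703  0.000
```

Higher MMSE, higher posterior beta power and a larger hippocampal ratio each
independently lower the modelled probability of progression (here by 16–21
percentage points per standardized unit), conditional on the other
covariates.

The same stages run from the shell:

```bash
megprog run-all --outdir run --seed 7          # simulate ... cpi
megprog stats cluster --outdir run --n-perm 1000
megprog classify --outdir run
```

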