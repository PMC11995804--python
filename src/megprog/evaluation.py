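"""Calibration and recovery simulation studies.

These studies are the package's empirical acceptance evidence: the
permutation machinery must hold its nominal type-1/family-wise error on null
cohorts (all planted effect sizes at zero, so the group label is exchangeable
by construction), and must recover the planted posterior 16-38 Hz power
reduction when it is present.  They run at deliberately reduced cohort sizes
(documented in docs/methods.md) so that hundreds of replicates complete on a
single CPU; the reduced sizes preserve the progressor/stable imbalance and
the two-site structure of the default cohort.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import cluster as cl
from . import cohort as ch
from . import importance as imp
from . import risk
from . import spd
from . import stacking as st
from . import wavelets as wv


def _seeds(seed, n):
    """Independent child seeds (< 2**31) derived from one master seed."""
    return np.random.SeedSequence(seed).generate_state(n) % (2 ** 31)


# ---------------------------------------------------------------------------
# Null calibration
# ---------------------------------------------------------------------------

def _null_spec(seed, **kw):
    base = dict(beta_power_reduction=0.0, lowfreq_cov_shift=0.0,
                alpha_plv_shift=0.0, env_corr_shift=0.0, seed=int(seed))
    base.update(kw)
    return ch.reduced_spec(**base)


def manova_null_calibration(n_reps: int = 300, seed: int = 0,
                            alpha: float = 0.05, n_perm: int = 100,
                            rank: int = 6) -> float:
    """Rejection rate of the covariance distance MANOVA on null cohorts.

    Reduced size: 12+10 subjects, 12 sensors, 3 x 4 s epochs; covariance at
    one mid-frequency wavelet, rank-6 common subspace.
    """
    rej = 0
    for s in _seeds(seed, n_reps):
        spec = _null_spec(s, n_prog=12, n_stable=10, n_sensors=12,
                          n_epochs=3, epoch_len_s=4.0)
        coh = ch.simulate_cohort(spec, with_missingness=False)
        fam = wv.build_wavelet_family(8.0, 16.0, 0.35, 0.5, spec.fs)
        covs = []
        for subj in coh:
            coeffs, valid = wv.convolve_frequency(
                subj.signals, fam, fam.n_freqs // 2)
            covs.append(wv.covariance_from_coeffs(coeffs, valid))
        ms = spd.common_subspace_project(np.stack(covs), rank)
        labels = np.array([subj.group == "progression" for subj in coh], int)
        _, p = spd.distance_manova_single(ms.matrices, labels, n_perm,
                                          rng=int(s) + 1)
        rej += p <= alpha
    return rej / n_reps


def tfce_null_calibration(n_reps: int = 300, seed: int = 0,
                          alpha: float = 0.05, n_perm: int = 100,
                          n_steps: int = 20) -> float:
    """Family-wise error rate of the spatio-spectral TFCE permutation test on
    null cohorts (any significant point counts as a family-wise error).

    Reduced size: 12+10 subjects, 10 sensors, 3 x 4 s epochs, 8 wavelets.
    """
    fwe = 0
    for s in _seeds(seed, n_reps):
        spec = _null_spec(s, n_prog=12, n_stable=10, n_sensors=10,
                          n_epochs=3, epoch_len_s=4.0)
        coh = ch.simulate_cohort(spec, with_missingness=False)
        lay = ch.make_layout(spec.n_sensors, spec.seed)
        fam = wv.build_wavelet_family(8.0, 40.0, 0.35, 0.35, spec.fs)
        logp = wv.cohort_log_power(coh, fam)
        labels = np.array([subj.group == "progression" for subj in coh], int)
        res = cl.tfce_permutation_test(logp, labels, n_perm=n_perm,
                                       adjacency=lay.adjacency, alpha=alpha,
                                       n_steps=n_steps, rng=int(s) + 1)
        fwe += res.sig_mask.any()
    return fwe / n_reps


def _cpi_null_config(seed):
    return st.StackingConfig(n_repeats=1, n_folds=5,
                             first_layer_grid=np.logspace(-3, 5, 10),
                             second_layer_grid=np.logspace(-3, 5, 10),
                             seed=int(seed))


def cpi_null_calibration(n_reps: int = 300, seed: int = 0,
                         alpha: float = 0.05, n_perm: int = 50) -> float:
    """Rejection rate of the CPI pseudo-t for a provably null variable.

    Covariate-only cohorts (22+18 subjects): the stacked model sees the four
    demographic blocks plus one independent Gaussian noise block whose CPI
    p-value is the null statistic.
    """
    rej = 0
    for s in _seeds(seed, n_reps):
        spec = _null_spec(s, n_prog=22, n_stable=18, n_sensors=4,
                          n_epochs=1, epoch_len_s=1.0)
        coh = ch.simulate_cohort(spec, with_signals=False,
                                 with_missingness=False)
        rng = np.random.default_rng(int(s) + 7)
        n = len(coh)
        blocks = [
            st.ModalityBlock("age", np.array([[x.age] for x in coh]), "scalar"),
            st.ModalityBlock("sex", np.array(
                [[1.0 if x.sex == "M" else 0.0] for x in coh]), "scalar"),
            st.ModalityBlock("education", np.array(
                [[x.education] for x in coh]), "scalar"),
            st.ModalityBlock("mmse", np.array([[x.mmse] for x in coh]),
                             "scalar"),
            st.ModalityBlock("noise", rng.standard_normal((n, 1)), "scalar"),
        ]
        labels = np.array([x.group == "progression" for x in coh], int)
        cfg = _cpi_null_config(s)
        result = st.StackedProgressionClassifier(blocks, labels, cfg).fit()
        deltas = imp.cpi_scores(result, n_perm=n_perm, rng=int(s) + 11,
                                grid=cfg.first_layer_grid, variables=[4])
        _, p = imp.nadeau_bengio_test(deltas[:, 0], cfg.n_folds,
                                      cfg.n_repeats)
        rej += p <= alpha
    return rej / n_reps


# ---------------------------------------------------------------------------
# Recovery
# ---------------------------------------------------------------------------

def tfce_recovery(n_cohorts: int = 50, seed: int = 0, n_perm: int = 150,
                  n_steps: int = 25, band=(14.0, 40.0)):
    """Fraction of planted-effect cohorts in which the spatio-spectral TFCE
    test flags at least one posterior sensor inside the 14-40 Hz band.

    Reduced size: 28+23 subjects, 24 sensors, 5 x 4 s epochs, default planted
    posterior 16-38 Hz power reduction.
    """
    hits, details = 0, []
    for s in _seeds(seed, n_cohorts):
        spec = ch.reduced_spec(n_prog=28, n_stable=23, n_sensors=24,
                               n_epochs=5, epoch_len_s=4.0, seed=int(s))
        coh = ch.simulate_cohort(spec, with_missingness=False)
        lay = ch.make_layout(spec.n_sensors, spec.seed)
        fam = wv.build_wavelet_family(8.0, 48.0, 0.35, 0.2, spec.fs)
        logp = wv.cohort_log_power(coh, fam)
        labels = np.array([subj.group == "progression" for subj in coh], int)
        res = cl.tfce_permutation_test(logp, labels, n_perm=n_perm,
                                       adjacency=lay.adjacency,
                                       n_steps=n_steps, rng=int(s) + 1)
        fmask = (fam.foi >= band[0]) & (fam.foi <= band[1])
        hit = (res.sig_mask & lay.posterior_mask[:, None]
               & fmask[None, :]).any()
        hits += hit
        details.append(bool(hit))
    return hits / n_cohorts, details


def logistic_auc_ordering(n_reps: int = 30, seed: int = 0):
    """Mean in-sample AUC of the four risk models over planted-effect cohort
    replicates (reduced size: 24+20 subjects, 16 sensors).

    Returns ``(mean_auc dict, orderings dict)`` where the orderings report
    Model1 <= Model2 <= Model4 and Model1 <= Model3 <= Model4 on the means.
    """
    aucs = {m.name: [] for m in risk.DEFAULT_MODELS}
    for s in _seeds(seed, n_reps):
        spec = ch.reduced_spec(n_prog=24, n_stable=20, n_sensors=16,
                               n_epochs=4, epoch_len_s=4.0, seed=int(s))
        coh = ch.simulate_cohort(spec)
        lay = ch.make_layout(spec.n_sensors, spec.seed)
        fam = wv.build_wavelet_family(14.0, 40.0, 0.35, 0.25, spec.fs)
        logp = wv.cohort_log_power(coh, fam)
        cpv = risk.cluster_meg_power_variable(logp, fam.foi, lay)
        tab = ch.cohort_table(coh)
        for mspec in risk.DEFAULT_MODELS:
            m = risk.ProgressionModel.from_cohort(tab, mspec, cpv.values)
            r = m.fit()
            from sklearn.metrics import roc_auc_score
            aucs[mspec.name].append(roc_auc_score(m.endog, r.predict()))
    mean_auc = {k: float(np.mean(v)) for k, v in aucs.items()}
    orderings = {
        "m1_le_m2_le_m4": mean_auc["Model 1"] <= mean_auc["Model 2"]
                          <= mean_auc["Model 4"],
        "m1_le_m3_le_m4": mean_auc["Model 1"] <= mean_auc["Model 3"]
                          <= mean_auc["Model 4"],
    }
    return mean_auc, orderings


def _reduced_stacking_cohort(seed):
    spec = ch.reduced_spec(n_prog=24, n_stable=20, n_sensors=16,
                           n_epochs=4, epoch_len_s=4.0, seed=int(seed))
    coh = ch.simulate_cohort(spec)
    fam = wv.build_wavelet_family(4.0, 45.0, 0.35, 0.35, spec.fs)
    tensors = wv.cohort_spectral_tensors(coh, fam)
    tab = ch.cohort_table(coh)
    labels = (tab["group"] == "progression").astype(int).to_numpy()
    return tensors, tab, labels, fam


def stacking_ranking(n_reps: int = 10, seed: int = 0):
    """Mean cross-validated AUC per stacked-model input over planted-effect
    cohort replicates, plus the fraction of replicates in which (a) the full
    stack ranks on top and (b) both MEG covariance and MRI rank above dwPLI.

    Reduced size: 24+20 subjects, 16 sensors, 8 wavelets (stride 2 -> 4
    frequencies), rank-8 tangent spaces, 2 x 5-fold CV.
    """
    cfg_proto = None
    per_model = None
    top_frac = 0
    cov_mri_frac = 0
    for s in _seeds(seed, n_reps):
        tensors, tab, labels, fam = _reduced_stacking_cohort(s)
        cfg = st.StackingConfig(n_repeats=2, n_folds=5, freq_stride=2,
                                rank=8,
                                first_layer_grid=np.logspace(-3, 5, 15),
                                second_layer_grid=np.logspace(-3, 5, 15),
                                seed=int(s))
        cfg_proto = cfg
        blocks = st.build_blocks(tensors, tab, cfg, fam.foi)
        res = st.StackedProgressionClassifier(blocks, labels, cfg).fit()
        means = res.mean_auc()
        if per_model is None:
            per_model = {k: [] for k in means.index}
        for k, v in means.items():
            per_model[k].append(v)
        top_frac += means["stacked"] >= means.drop("stacked").max()
        cov_mri_frac += (means["MEG_cov"] > means["MEG_dwpli"]
                         and means["MRI_vol"] > means["MEG_dwpli"])
    mean_auc = {k: float(np.mean(v)) for k, v in per_model.items()}
    return mean_auc, top_frac / n_reps, cov_mri_frac / n_reps
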