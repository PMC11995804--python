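"""Logistic risk models: printed-table statistics, imputation rules, the
cluster power variable, ML fitting, marginal effects and discrimination."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from megprog import cohort as ch
from megprog import risk
from megprog import wavelets as wv


class TestTableStatistics:
    @pytest.mark.parametrize("table,expected", [
        ([[41, 49], [23, 4]], 11.61),      # site x progression
        ([[32, 32], [20, 33]], 1.30),      # sex x progression
    ])
    def test_yates_chi2(self, table, expected):
        chi2, p = risk.chi2_yates(table)
        assert chi2 == pytest.approx(expected, abs=0.005)
        assert 0 < p < 1

    def test_proportional_table_zero(self):
        chi2, p = risk.chi2_yates([[20, 40], [10, 20]])
        assert chi2 == 0.0 and p == pytest.approx(1.0)

    def test_zero_margin_rejected(self):
        with pytest.raises(risk.RiskModelError):
            risk.chi2_yates([[0, 0], [5, 3]])

    @pytest.mark.parametrize("args,expected", [
        ((25.54, 2.82, 64, 27.15, 2.41, 53), -3.28),   # MMSE by outcome
        ((73.99, 4.87, 90, 68.74, 8.48, 27), 4.07),    # age by site
        ((8.43, 4.47, 90, 13.02, 2.88, 27), -5.02),    # education by site
    ])
    def test_pooled_t_from_summary(self, args, expected):
        t, df, p = risk.pooled_t_from_summary(*args)
        assert t == pytest.approx(expected, abs=0.005)
        assert df == args[2] + args[5] - 2

    def test_equal_means_zero_t(self):
        t, _, p = risk.pooled_t_from_summary(5, 1, 10, 5, 1, 10)
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_invalid_summary_rejected(self):
        with pytest.raises(risk.RiskModelError):
            risk.pooled_t_from_summary(1, 0.0, 10, 2, 1, 10)


class TestImputation:
    def test_identity_without_gaps(self):
        df = pd.DataFrame({"education": [1.0, 2.0], "mmse": [28.0, 29.0]})
        assert risk.mean_impute(df).equals(df)

    def test_grand_mean_fill(self):
        df = pd.DataFrame({"education": [10.0, np.nan, 14.0],
                           "mmse": [np.nan, 26.0, 28.0]})
        out = risk.mean_impute(df)
        assert out.loc[1, "education"] == pytest.approx(12.0)
        assert out.loc[0, "mmse"] == pytest.approx(27.0)

    def test_all_missing_rejected(self):
        with pytest.raises(risk.RiskModelError):
            risk.mean_impute(pd.DataFrame({"education": [np.nan, np.nan]}))

    def test_mri_subset_size(self):
        """Default cohort: 13 missing MRI blocks leave 104 subjects for the
        MRI models."""
        tab = ch.cohort_table(ch.simulate_cohort(ch.CohortSpec(),
                                                 with_signals=False))
        assert tab["hippocampal_ratio"].notna().sum() == 104


class TestModelSpec:
    def test_harrell_cap(self):
        assert risk.harrell_cap(27, 0.2) == 5
        assert risk.PREDICTOR_CAP == 5

    def test_too_many_predictors(self):
        with pytest.raises(risk.RiskModelError):
            risk.ModelSpec("bad", ("age", "education", "mmse",
                                   "hippocampal_ratio", "cluster_meg_power",
                                   "site", "age"))

    def test_duplicates_rejected(self):
        with pytest.raises(risk.RiskModelError):
            risk.ModelSpec("bad", ("age", "age"))

    def test_site_not_counted(self):
        spec = risk.ModelSpec("m", ("age", "education", "mmse",
                                    "hippocampal_ratio", "cluster_meg_power",
                                    "site"))
        assert len(spec.predictors) == 6


class TestClusterPowerVariable:
    def test_global_power_doubling(self, tiny_layout):
        """Doubling signal amplitude quadruples power: the variable moves by
        exactly log10(4)."""
        rng = np.random.default_rng(0)
        logp = rng.standard_normal((3, tiny_layout.n_sensors, 6))
        foi = np.array([10, 14, 17, 22, 30, 44], float)
        v1 = risk.cluster_meg_power_variable(logp, foi, tiny_layout)
        v2 = risk.cluster_meg_power_variable(logp + np.log10(4), foi,
                                             tiny_layout)
        assert np.allclose(v2.values - v1.values, np.log10(4))

    def test_planted_cohort_sign(self, tiny_cohort, tiny_layout, tiny_family):
        logp = wv.cohort_log_power(tiny_cohort, tiny_family)
        v = risk.cluster_meg_power_variable(np.nan_to_num(logp),
                                            tiny_family.foi, tiny_layout)
        prog = np.array([s.group == "progression" for s in tiny_cohort])
        assert v.values[prog].mean() < v.values[~prog].mean()

    def test_empty_mask_fallback_flagged(self, tiny_layout):
        logp = np.zeros((2, tiny_layout.n_sensors, 3))
        foi = np.array([20.0, 25.0, 30.0])
        empty = type("R", (), {"sig_mask": np.zeros(
            (tiny_layout.n_sensors, 3), bool)})()
        v = risk.cluster_meg_power_variable(logp, foi, tiny_layout, empty)
        assert v.used_fallback

    def test_significant_mask_used(self, tiny_layout):
        logp = np.zeros((2, tiny_layout.n_sensors, 3))
        foi = np.array([20.0, 25.0, 30.0])
        sig = np.ones((tiny_layout.n_sensors, 3), bool)
        res = type("R", (), {"sig_mask": sig})()
        v = risk.cluster_meg_power_variable(logp, foi, tiny_layout, res)
        assert not v.used_fallback


def _toy_table(n=400, beta=(0.5, -1.0), seed=0):
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((n, 2))
    eta = x @ np.array(beta)
    y = (rng.uniform(size=n) < 1 / (1 + np.exp(-eta))).astype(float)
    return pd.DataFrame({"progression": y, "age": x[:, 0],
                         "education": x[:, 1]})


class TestLogisticFit:
    def test_intercept_only_aic_closed_form(self):
        df = pd.DataFrame({"progression": [1.0] * 64 + [0.0] * 53,
                           "age": np.r_[np.linspace(60, 80, 64),
                                        np.linspace(60, 80, 53)]})
        # model with a useless predictor removed: use empty predictor tuple
        spec = risk.ModelSpec("null", ())
        res = risk.ProgressionModel(df, spec).fit()
        expected = 2 - 2 * (64 * np.log(64 / 117) + 53 * np.log(53 / 117))
        assert res.aic == pytest.approx(expected, rel=1e-9)

    def test_separation_detected(self):
        df = _toy_table(60)
        df["age"] = df["progression"] * 2 - 1          # predictor == outcome
        spec = risk.ModelSpec("sep", ("age", "education"))
        with pytest.raises(risk.SeparationError) as err:
            risk.ProgressionModel(df, spec).fit()
        assert "age" in str(err.value)

    def test_parameter_recovery(self):
        """Known-coefficient simulation at n=2000: estimates within 3 SE."""
        beta = (0.5, -1.0)
        df = _toy_table(2000, beta, seed=3)
        spec = risk.ModelSpec("rec", ("age", "education"), standardize=False)
        res = risk.ProgressionModel(df, spec).fit()
        for name, b in zip(("age", "education"), beta):
            assert abs(res.params[name] - b) < 3 * res.bse[name]

    def test_aic_noise_predictor_distribution(self):
        """Adding a pure-noise predictor changes AIC by ~ +2 - chi2(1):
        mean ~ +1 over replicates."""
        deltas = []
        for i in range(200):
            df = _toy_table(150, seed=100 + i)
            df["noise"] = np.random.default_rng(500 + i).standard_normal(150)
            a0 = risk.ProgressionModel(df, risk.ModelSpec(
                "m0", ("age", "education"))).fit().aic
            a1 = risk.ProgressionModel(
                df.rename(columns={"noise": "mmse"}),
                risk.ModelSpec("m1", ("age", "education", "mmse"))).fit().aic
            deltas.append(a1 - a0)
        assert np.mean(deltas) == pytest.approx(1.0, abs=0.4)


class TestMarginalEffects:
    def test_finite_difference_oracle(self):
        df = _toy_table(300, seed=5)
        spec = risk.ModelSpec("m", ("age", "education"), standardize=False)
        model = risk.ProgressionModel(df, spec)
        res = model.fit()
        ame = res.ame()
        eps = 1e-6
        for j, name in enumerate(("age", "education"), start=1):
            hi, lo = model.exog.copy(), model.exog.copy()
            hi[:, j] += eps
            lo[:, j] -= eps
            fd = (res.predict(hi) - res.predict(lo)).mean() / (2 * eps)
            assert ame.loc[name, "ame"] == pytest.approx(fd, abs=1e-6)

    def test_logistic_derivative_formula(self):
        """AME_j = mean beta_j p(1-p); with all p near 0.5, AME ~ beta/4."""
        df = _toy_table(500, beta=(0.05, 0.0), seed=7)
        spec = risk.ModelSpec("m", ("age",), standardize=False)
        res = risk.ProgressionModel(df[["progression", "age"]], spec).fit()
        p = res.predict()
        expected = res.params["age"] * (p * (1 - p)).mean()
        assert res.ame().loc["age", "ame"] == pytest.approx(expected,
                                                            rel=1e-6)


class TestDiscrimination:
    def test_auc_equals_mann_whitney(self):
        df = _toy_table(200, seed=9)
        res = risk.ProgressionModel(df, risk.ModelSpec(
            "m", ("age", "education"))).fit()
        d = res.discrimination(n_boot=50, rng=0)
        p = res.predict()
        y = df["progression"].to_numpy()
        u = stats.mannwhitneyu(p[y == 1], p[y == 0]).statistic
        assert d.auc == pytest.approx(u / ((y == 1).sum() * (y == 0).sum()),
                                      rel=1e-12)

    def test_random_scores_cover_half(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame({"progression": rng.integers(0, 2, 200).astype(float),
                           "age": rng.standard_normal(200)})
        res = risk.ProgressionModel(df, risk.ModelSpec("m", ("age",))).fit()
        d = res.discrimination(n_boot=300, rng=2)
        assert d.auc_ci[0] <= 0.5 <= d.auc_ci[1] or abs(d.auc - 0.5) < 0.1

    def test_shared_bootstrap_indices_pair_models(self):
        df = _toy_table(150, seed=11)
        idx = risk.shared_bootstrap_indices(len(df), 40, rng=3)
        m = risk.ProgressionModel(df, risk.ModelSpec("m", ("age",)))
        r = m.fit()
        d1 = r.discrimination(n_boot=40, rng=0, bootstrap_indices=idx)
        d2 = r.discrimination(n_boot=40, rng=0, bootstrap_indices=idx)
        assert np.array_equal(d1.bootstrap_aucs, d2.bootstrap_aucs)


class TestModelComparison:
    def test_compare_models_on_planted_cohort(self):
        spec = ch.reduced_spec(n_prog=24, n_stable=20, n_sensors=16,
                               n_epochs=3, epoch_len_s=4.0, seed=21)
        coh = ch.simulate_cohort(spec)
        lay = ch.make_layout(spec.n_sensors, spec.seed)
        fam = wv.build_wavelet_family(14.0, 40.0, 0.35, 0.35, spec.fs)
        logp = wv.cohort_log_power(coh, fam)
        cpv = risk.cluster_meg_power_variable(np.nan_to_num(logp), fam.foi,
                                              lay)
        tab = ch.cohort_table(coh)
        comp = risk.compare_models(tab, cluster_power=cpv.values, n_boot=60,
                                   rng=1)
        assert list(comp["model"]) == ["Model 1", "Model 2", "Model 3",
                                       "Model 4"]
        assert (comp["aic"] == 2 * (comp["k"] + 1) - 2 * comp["loglik"]).all()
        assert ((comp["auc"] >= 0) & (comp["auc"] <= 1)).all()
        # MRI models fit on the MRI-complete subset
        assert (comp.loc[comp["model"].isin(["Model 2", "Model 4"]), "n"]
                < len(tab)).all()
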