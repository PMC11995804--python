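"""Additive logistic models of AD-progression risk and cohort statistics.

Implements the four nested logistic models

    Model 1: progression ~ age + education + MMSE
    Model 2: ... + hippocampal ratio (hippocampal volume / total grey matter)
    Model 3: ... + cluster MEG power (mean 16-38 Hz log-power over the
             significant posterior sensor set)
    Model 4: ... + cluster MEG power + hippocampal ratio

with AIC comparison, average marginal effects (AME, delta-method inference),
in-sample ROC AUC with refitted-bootstrap confidence intervals, and the
cohort-description statistics (Yates-corrected chi-square, pooled-variance
t from summary statistics).  Predictors are z-scored before fitting; the
number of non-site predictors is capped at 5 (10-20% of the smaller class,
floor(27 * 0.2) at the reference cohort size).  Education and MMSE gaps are
mean-imputed; subjects with a missing MRI block are excluded from MRI models.

Model fitting follows the statsmodels Model/Results idiom:
``ProgressionModel(data, spec).fit() -> ProgressionResults``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.metrics import roc_auc_score, roc_curve


class RiskModelError(ValueError):
    pass


class SeparationError(RiskModelError):
    """Perfect separation: the MLE diverges."""


PREDICTOR_CAP = 5          # floor(27 * 0.2), smaller-class 10-20% rule
ALLOWED_PREDICTORS = ("age", "education", "mmse", "hippocampal_ratio",
                      "cluster_meg_power", "site")


def harrell_cap(n_smaller_class: int = 27, frac: float = 0.2) -> int:
    """Predictor budget: floor of ``frac`` times the smaller class size."""
    return int(np.floor(n_smaller_class * frac))


# ---------------------------------------------------------------------------
# Printed-table statistics
# ---------------------------------------------------------------------------

def chi2_yates(table):
    """Pearson chi-square with Yates continuity correction on a 2x2 table."""
    t = np.asarray(table, float)
    if t.shape != (2, 2) or (t < 0).any() or not np.allclose(t, np.round(t)):
        raise RiskModelError("need a nonnegative integer 2x2 table")
    if (t.sum(0) == 0).any() or (t.sum(1) == 0).any():
        raise RiskModelError("zero margin in contingency table")
    res = stats.chi2_contingency(t, correction=True)
    return float(res.statistic), float(res.pvalue)


def pooled_t_from_summary(mean1, sd1, n1, mean2, sd2, n2):
    """Two-sample pooled-variance t from group summary statistics.

    Returns ``(t, df, p)``; two-sided p.
    """
    if n1 < 2 or n2 < 2:
        raise RiskModelError("need n >= 2 per group")
    if sd1 <= 0 or sd2 <= 0:
        raise RiskModelError("standard deviations must be positive")
    res = stats.ttest_ind_from_stats(mean1, sd1, n1, mean2, sd2, n2,
                                     equal_var=True)
    return float(res.statistic), float(n1 + n2 - 2), float(res.pvalue)


# ---------------------------------------------------------------------------
# Derived variables
# ---------------------------------------------------------------------------

def mean_impute(table: pd.DataFrame,
                columns=("education", "mmse")) -> pd.DataFrame:
    """Fill gaps in the given columns with the grand mean over all subjects.

    The MRI block is never imputed here; MRI-missing subjects are instead
    excluded from models that use the hippocampal ratio.
    """
    out = table.copy()
    for col in columns:
        if col not in out.columns:
            continue
        if out[col].isna().all():
            raise RiskModelError(f"column {col!r} entirely missing")
        out[col] = out[col].fillna(out[col].mean())
    return out


@dataclass
class ClusterPowerVariable:
    values: np.ndarray
    used_fallback: bool
    sensor_mask: np.ndarray
    freq_mask: np.ndarray


def cluster_meg_power_variable(log_psd_stack, foi, layout,
                               cluster_result=None,
                               band=(16.0, 38.0)) -> ClusterPowerVariable:
    """Per-subject mean log10-power over the significant posterior sensors
    and the 16-38 Hz band.

    ``log_psd_stack``: (n_subjects, S, F).  The sensor/frequency selection is
    ``posterior_mask & significant`` from a 2D TFCE result; when no cluster
    result is supplied, or its mask is empty, the fallback selection
    ``posterior_mask x [16, 38] Hz`` is used and flagged.
    """
    x = np.asarray(log_psd_stack, float)
    foi = np.asarray(foi, float)
    fmask = (foi >= band[0]) & (foi <= band[1])
    post = np.asarray(layout.posterior_mask, bool)
    used_fallback = True
    smask = post
    if cluster_result is not None:
        sig = np.asarray(cluster_result.sig_mask, bool)   # (S, F)
        sel = sig & post[:, None] & fmask[None, :]
        if sel.any():
            used_fallback = False
            vals = np.array([xi[sel].mean() for xi in x])
            return ClusterPowerVariable(vals, False, sel.any(1), sel.any(0))
    sel = post[:, None] & fmask[None, :]
    vals = np.array([xi[sel].mean() for xi in x])
    return ClusterPowerVariable(vals, used_fallback, smask, fmask)


# ---------------------------------------------------------------------------
# Model / Results
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelSpec:
    """A named additive logistic model over the allowed predictor set."""

    name: str
    predictors: tuple
    standardize: bool = True

    def __post_init__(self):
        preds = tuple(self.predictors)
        if len(set(preds)) != len(preds):
            raise RiskModelError("duplicate predictors")
        unknown = set(preds) - set(ALLOWED_PREDICTORS)
        if unknown:
            raise RiskModelError(f"unknown predictors: {sorted(unknown)}")
        n_nonsite = len([p for p in preds if p != "site"])
        if n_nonsite > PREDICTOR_CAP:
            raise RiskModelError(
                f"{n_nonsite} non-site predictors exceed the cap of "
                f"{PREDICTOR_CAP}")
        object.__setattr__(self, "predictors", preds)


MODEL1 = ModelSpec("Model 1", ("age", "education", "mmse"))
MODEL2 = ModelSpec("Model 2", ("age", "education", "mmse",
                               "hippocampal_ratio"))
MODEL3 = ModelSpec("Model 3", ("age", "education", "mmse",
                               "cluster_meg_power"))
MODEL4 = ModelSpec("Model 4", ("age", "education", "mmse",
                               "cluster_meg_power", "hippocampal_ratio"))
DEFAULT_MODELS = (MODEL1, MODEL2, MODEL3, MODEL4)


class ProgressionModel:
    """Additive logistic model of progression risk.

    Parameters
    ----------
    data : DataFrame with a binary ``progression`` column (1 = progressor)
        and the spec's predictor columns.  ``site`` may be categorical; it is
        encoded as a 0/1 indicator.  Rows with missing predictors are
        dropped (impute beforehand; MRI models thereby use the MEG+MRI
        subset).
    spec : ModelSpec
    """

    def __init__(self, data: pd.DataFrame, spec: ModelSpec):
        self.spec = spec
        df = data.copy()
        if "site" in spec.predictors and df["site"].dtype == object:
            df["site"] = (df["site"] == "CBU").astype(float)
        cols = ["progression", *spec.predictors]
        df = df[cols].dropna()
        self.data = df
        y = df["progression"].to_numpy(float)
        if set(np.unique(y)) - {0.0, 1.0}:
            raise RiskModelError("outcome must be binary 0/1")
        x = df[list(spec.predictors)].to_numpy(float)
        if spec.standardize:
            self._mu = x.mean(0)
            self._sd = x.std(0, ddof=0)
            if (self._sd == 0).any():
                j = int(np.argmax(self._sd == 0))
                raise RiskModelError(
                    f"constant predictor {spec.predictors[j]!r}")
            x = (x - self._mu) / self._sd
        self.endog = y
        self.exog = sm.add_constant(x, has_constant="add")
        self.exog_names = ["const", *spec.predictors]

    @classmethod
    def from_cohort(cls, table: pd.DataFrame, spec: ModelSpec,
                    cluster_power: np.ndarray | None = None,
                    impute: bool = True) -> "ProgressionModel":
        df = table.copy()
        df["progression"] = (df["group"] == "progression").astype(float)
        if cluster_power is not None:
            df["cluster_meg_power"] = np.asarray(cluster_power, float)
        if impute:
            df = mean_impute(df)
        return cls(df, spec)

    def fit(self, tol: float = 1e-8, maxiter: int = 100) -> "ProgressionResults":
        model = sm.Logit(self.endog, self.exog)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("error",
                                      sm.tools.sm_exceptions.PerfectSeparationWarning)
                res = model.fit(method="newton", tol=tol, maxiter=maxiter,
                                disp=False)
        except (sm.tools.sm_exceptions.PerfectSeparationError,
                sm.tools.sm_exceptions.PerfectSeparationWarning) as err:
            raise SeparationError(self._culprit(str(err))) from err
        except np.linalg.LinAlgError:
            # ill-conditioned Newton step: retry with a gradient method and
            # let the coefficient-magnitude check decide
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = model.fit(method="lbfgs", maxiter=500, disp=False)
        if len(res.params) > 1 and np.abs(res.params[1:]).max() > 50:
            raise SeparationError(self._culprit(""))
        return ProgressionResults(self, res)

    def _culprit(self, detail):
        # name the predictor most aligned with the outcome
        scores = []
        y = self.endog
        for j, name in enumerate(self.exog_names[1:], start=1):
            x = self.exog[:, j]
            scores.append(abs(np.corrcoef(x, y)[0, 1]))
        culprit = self.exog_names[1:][int(np.nanargmax(scores))]
        return (f"perfect separation while fitting {self.spec.name}; "
                f"most separating predictor: {culprit!r}. {detail}")


@dataclass
class DiscriminationResult:
    auc: float
    auc_ci: tuple
    sensitivity: float            # at the Youden-optimal threshold
    specificity: float
    threshold: float
    sensitivity_at_half: float
    specificity_at_half: float
    n_boot: int
    n_degenerate_resampled: int
    bootstrap_aucs: np.ndarray = field(repr=False, default=None)


class ProgressionResults:
    """Results wrapper: coefficients, AIC, AME and discrimination metrics."""

    def __init__(self, model: ProgressionModel, smres):
        self.model = model
        self._res = smres

    @property
    def params(self) -> pd.Series:
        return pd.Series(self._res.params, index=self.model.exog_names)

    @property
    def bse(self) -> pd.Series:
        return pd.Series(self._res.bse, index=self.model.exog_names)

    @property
    def llf(self) -> float:
        return float(self._res.llf)

    @property
    def aic(self) -> float:
        return float(self._res.aic)

    def predict(self, exog=None) -> np.ndarray:
        return self._res.predict(exog if exog is not None else self.model.exog)

    def summary(self):
        return self._res.summary(xname=self.model.exog_names,
                                 title=self.model.spec.name)

    def ame(self) -> pd.DataFrame:
        """Average marginal effects (overall dydx) with delta-method z/p."""
        me = self._res.get_margeff(at="overall", method="dydx")
        return pd.DataFrame({"ame": me.margeff, "se": me.margeff_se,
                             "z": me.margeff / me.margeff_se,
                             "p": me.pvalues},
                            index=self.model.exog_names[1:])

    # -- discrimination ---------------------------------------------------

    def discrimination(self, n_boot: int = 2000, rng=None,
                       bootstrap_indices=None) -> DiscriminationResult:
        """In-sample ROC AUC with percentile bootstrap CI (model refitted on
        each replicate); sensitivity/specificity reported at the Youden
        threshold and at 0.5.  Degenerate single-class replicates are redrawn
        and counted.  ``bootstrap_indices`` allows sharing index streams
        across models for paired AUC differences."""
        y = self.model.endog
        p = self.predict()
        auc = roc_auc_score(y, p)
        fpr, tpr, thr = roc_curve(y, p)
        j = int(np.argmax(tpr - fpr))
        youden_thr = float(thr[j])
        sens, spec = float(tpr[j]), float(1 - fpr[j])
        sens05 = float(((p >= 0.5) & (y == 1)).sum() / (y == 1).sum())
        spec05 = float(((p < 0.5) & (y == 0)).sum() / (y == 0).sum())

        rng = np.random.default_rng(rng)
        n = len(y)
        aucs = np.empty(n_boot)
        n_degen = 0
        for i in range(n_boot):
            idx = (bootstrap_indices[i] if bootstrap_indices is not None
                   else rng.integers(0, n, n))
            while len(np.unique(y[idx])) < 2:     # degenerate: redraw
                n_degen += 1
                idx = rng.integers(0, n, n)
            try:
                # separation in a resample is expected at small n; the refit
                # is only used for its predicted ranks
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    bres = sm.Logit(y[idx], self.model.exog[idx]).fit(
                        disp=False, maxiter=100)
                    pb = bres.predict(self.model.exog[idx])
                aucs[i] = roc_auc_score(y[idx], pb)
            except (np.linalg.LinAlgError, ValueError):
                n_degen += 1
                aucs[i] = np.nan
        aucs_ok = aucs[np.isfinite(aucs)]
        lo, hi = np.quantile(aucs_ok, [0.025, 0.975])
        return DiscriminationResult(float(auc), (float(lo), float(hi)),
                                    sens, spec, youden_thr, sens05, spec05,
                                    n_boot, n_degen, aucs)


def shared_bootstrap_indices(n, n_boot, rng):
    """Fixed bootstrap index streams, reusable across models so AUC
    differences are computed on paired replicates."""
    rng = np.random.default_rng(rng)
    return rng.integers(0, n, size=(n_boot, n))


def compare_models(table: pd.DataFrame, specs=DEFAULT_MODELS,
                   cluster_power=None, n_boot: int = 2000,
                   rng=None) -> pd.DataFrame:
    """Fit a family of model specs on the shared (imputed) cohort table and
    return an AIC/AUC comparison table.  Models that use the hippocampal
    ratio are fitted on the MRI-complete subset."""
    rng = np.random.default_rng(rng)
    seed_disc = int(rng.integers(2 ** 31))
    rows = []
    for spec in specs:
        m = ProgressionModel.from_cohort(table, spec, cluster_power)
        r = m.fit()
        d = r.discrimination(n_boot=n_boot, rng=seed_disc)
        rows.append({"model": spec.name, "n": len(m.endog), "k": len(spec.predictors),
                     "loglik": r.llf, "aic": r.aic, "auc": d.auc,
                     "auc_lo": d.auc_ci[0], "auc_hi": d.auc_ci[1],
                     "sensitivity": d.sensitivity, "specificity": d.specificity})
    return pd.DataFrame(rows)
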