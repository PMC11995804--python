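"""Conditional permutation importance (CPI) of the stacked-model inputs.

Marginal permutation importance over-states the importance of correlated
inputs.  CPI instead destroys only the information in a variable that is
*not* explained by the other variables: the variable is predicted from the
others (ridge regression fitted on training rows), its residuals on the test
rows are permuted and re-added, and the increase in the second-layer log loss
is recorded.  A variable that is an exact linear function of the others has
zero residuals, hence zero CPI.

Across the repeated-CV splits, a cross-fitted pseudo-t is formed as
mean / SD of the per-split CPI scores, and tested one-sided with the
Nadeau-Bengio variance correction ``var * (1/K + n_test/n_train)`` (with
``rho = 1/(n_folds - 1)`` for K-fold), which accounts for the overlap of
CV training sets.  No multiplicity correction is applied across variables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import RidgeCV

from .stacking import DEFAULT_GRID, StackingResult


def _log_loss(y, p, eps=1e-15):
    """Binary cross-entropy (labels in {0, 1}), probabilities clipped."""
    p = np.clip(p, eps, 1 - eps)
    y = np.asarray(y, float)
    return float(-(y * np.log(p) + (1 - y) * np.log(1 - p)).mean())


class ImportanceError(ValueError):
    pass


def conditional_permutation(score_matrix, j, train_rows, test_rows, rng,
                            grid=DEFAULT_GRID, n_perm=1):
    """Perturbed copies of column ``j`` on the test rows.

    Fits an L2 regression of column j on the remaining columns using the
    training rows (penalty over the standard grid), then replaces the test
    rows of column j by prediction + permuted residuals.  Returns an
    ``(n_perm, n_test)`` array of perturbed columns.
    """
    x = np.asarray(score_matrix, float)
    if not 0 <= j < x.shape[1]:
        raise ImportanceError(f"column {j} out of range")
    others = [k for k in range(x.shape[1]) if k != j]
    rng = np.random.default_rng(rng)
    if others:
        reg = RidgeCV(alphas=grid)
        reg.fit(x[np.ix_(train_rows, others)], x[train_rows, j])
        pred = reg.predict(x[np.ix_(test_rows, others)])
    else:
        pred = np.full(len(test_rows), x[train_rows, j].mean())
    resid = x[test_rows, j] - pred
    out = np.empty((n_perm, len(test_rows)))
    for p in range(n_perm):
        out[p] = pred + rng.permutation(resid)
    return out


def cpi_scores(result: StackingResult, n_perm: int = 500, rng=None,
               grid=DEFAULT_GRID, variables=None) -> np.ndarray:
    """Per-split, per-variable log-loss increase.

    ``Delta[s, v] = mean over permutations of loss(perturbed) - loss(original)``
    on the held-out fold of split ``s``, using the split's trained second
    layer.  Requires the split artifacts stored by the stacking fit.
    """
    if not result.splits:
        raise ImportanceError("stacking result carries no split artifacts")
    rng = np.random.default_rng(rng)
    n_vars = result.splits[0].scores_train.shape[1]
    variables = list(range(n_vars)) if variables is None else list(variables)
    out = np.zeros((len(result.splits), len(variables)))
    for si, split in enumerate(result.splits):
        clf = split.second_layer
        x_te = split.scores_test
        x_all = np.vstack([split.scores_train, x_te])
        n_tr = len(split.scores_train)
        tr_rows = np.arange(n_tr)
        te_rows = np.arange(n_tr, n_tr + len(x_te))
        y_te = split_labels(split)
        pos = int(np.where(clf.classes_ == 1)[0][0])
        base = _log_loss(y_te, clf.predict_proba(x_te)[:, pos])
        # linear model: evaluate all permutations in one matrix pass
        coef = clf.coef_.ravel()
        icpt = float(clf.intercept_[0])
        logit_base = x_te @ coef + icpt
        for vi, j in enumerate(variables):
            perturbed = conditional_permutation(x_all, j, tr_rows, te_rows,
                                                rng, grid, n_perm)
            logits = logit_base[None, :] + coef[j] * (perturbed - x_te[:, j])
            if pos == 0:
                logits = -logits
            pmat = 1.0 / (1.0 + np.exp(-logits))
            losses = np.array([_log_loss(y_te, pm) for pm in pmat])
            out[si, vi] = losses.mean() - base
    return out


def split_labels(split):
    """Held-out labels for a split (stored on the artifact)."""
    if getattr(split, "labels_test", None) is None:
        raise ImportanceError("split artifacts carry no test labels")
    return split.labels_test


def nadeau_bengio_test(per_split_scores, n_folds: int, n_repeats: int):
    """Corrected one-sided t-test on per-split scores.

    ``t = mean / sqrt((1/K + rho) * var)`` with ``rho = n_test/n_train =
    1/(n_folds - 1)`` for K-fold CV, ``K = n_folds * n_repeats`` scores,
    df = K - 1, upper-tail p.
    """
    s = np.asarray(per_split_scores, float)
    s = s[np.isfinite(s)]
    k = len(s)
    if k < 2:
        raise ImportanceError("need >= 2 split scores")
    rho = 1.0 / (n_folds - 1)
    mean = s.mean()
    var = s.var(ddof=1)
    if var == 0:
        warnings.warn("zero variance across splits")
        return (np.inf if mean > 0 else -np.inf), (0.0 if mean > 0 else 1.0)
    t = mean / np.sqrt((1.0 / k + rho) * var)
    p = float(stats.t.sf(t, df=k - 1))
    return float(t), p


@dataclass
class CPIResult:
    variables: list
    mean_delta: np.ndarray         # mean log-loss increase across splits
    sd_delta: np.ndarray
    pseudo_t: np.ndarray
    p: np.ndarray                  # one-sided, Nadeau-Bengio corrected
    n_permutations: int
    n_splits: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"variable": self.variables,
                             "mean_delta_logloss": self.mean_delta,
                             "sd": self.sd_delta, "t": self.pseudo_t,
                             "p": self.p})


def conditional_permutation_importance(result: StackingResult,
                                       n_perm: int = 500, rng=None,
                                       grid=DEFAULT_GRID) -> CPIResult:
    """CPI of every second-layer input with the corrected pseudo-t test."""
    deltas = cpi_scores(result, n_perm=n_perm, rng=rng, grid=grid)
    names = result.block_names or [f"var{j}" for j in range(deltas.shape[1])]
    ts, ps = [], []
    for v in range(deltas.shape[1]):
        t, p = nadeau_bengio_test(deltas[:, v], result.n_folds,
                                  result.n_repeats)
        ts.append(t)
        ps.append(p)
    return CPIResult(list(names), deltas.mean(0), deltas.std(0, ddof=1),
                     np.asarray(ts), np.asarray(ps), n_perm, deltas.shape[0])
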