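"""Two-layer stacked classification of AD progression.

First layer: one regularized linear classifier per modality block (site, age,
sex, education, MMSE as scalars; MEG covariance and power-envelope matrices as
rank-reduced tangent-space vectors per strided frequency; dwPLI as
upper-triangle vectors; 64 regional MRI volumes), each an L2-penalized
least-squares classifier on +-1 targets with its penalty chosen on the
training folds by efficient generalized cross-validation over a 50-value
logarithmic grid.  Second layer: an L2-regularized logistic regression on the
9 cross-fitted first-layer scores, with leave-one-group-out internal CV where
the groups are the outer folds of the training subjects.

Evaluation uses repeated stratified K-fold CV (default 10 x 10 = 100 splits),
with identical splits reused across all compared models.  Every subject's
first-layer score comes from a model never trained on it; imputation
(iterative, ridge-based round robin), scaling, the common-subspace filters
and the tangent-space reference are all fitted on training rows only.  A
corrupted fold bookkeeping trips a hard :class:`LeakageError`.

Surface follows the Model/Results idiom:
``StackedProgressionClassifier(blocks, labels, config).fit() -> StackingResult``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.experimental import enable_iterative_imputer  # noqa: F401
from sklearn.impute import IterativeImputer
from sklearn.linear_model import LogisticRegressionCV, RidgeClassifierCV
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import LeaveOneGroupOut, StratifiedKFold
from sklearn.preprocessing import StandardScaler

from .spd import TangentSpace


class StackingError(ValueError):
    pass


class LeakageError(RuntimeError):
    """A subject was (or would be) scored by a model trained on it."""


DEFAULT_GRID = np.logspace(-3, 5, 50)

SCALAR_BLOCKS = ("site", "age", "sex", "education", "mmse")
BLOCK_ORDER = ("site", "age", "sex", "education", "mmse",
               "MEG_cov", "MEG_env", "MEG_dwpli", "MRI_vol")


@dataclass(frozen=True)
class StackingConfig:
    n_repeats: int = 10
    n_folds: int = 10
    first_layer_grid: np.ndarray = field(default_factory=lambda: DEFAULT_GRID)
    second_layer_grid: np.ndarray = field(default_factory=lambda: DEFAULT_GRID)
    freq_stride: int = 4           # every 4th wavelet -> 31 of 121
    rank: int = 65                 # tangent-space rank for cov / env
    reg: float = 1e-15
    seed: int = 0

    @property
    def n_splits(self) -> int:
        return self.n_repeats * self.n_folds


@dataclass
class ModalityBlock:
    """One input modality.

    ``data`` is (n, d) for scalar/raw encodings or (n, F, S, S) for matrix
    metrics; the fold-aware encoding to features happens inside the CV.
    """

    name: str
    data: np.ndarray
    encoding: str                  # scalar | tangent | upper_triangle | raw
    freqs: np.ndarray | None = None

    @property
    def n_subjects(self) -> int:
        return len(self.data)


def strided_frequencies(foi, stride: int = 4):
    """Every ``stride``-th wavelet (121 -> 31 at the default)."""
    foi = np.asarray(foi)
    idx = np.arange(0, len(foi), stride)
    return idx, foi[idx]


def block_param_count(name: str, n_sensors: int = 102, n_freqs: int = 31,
                      rank: int = 65) -> dict:
    """Feature accounting per block: raw input count and first-layer
    parameter count."""
    if name in SCALAR_BLOCKS:
        return {"inputs": 1, "first_layer": 1}
    if name == "MRI_vol":
        return {"inputs": 64, "first_layer": 64}
    inputs = n_sensors * n_sensors * n_freqs
    if name == "MEG_dwpli":
        return {"inputs": inputs,
                "first_layer": n_sensors * (n_sensors - 1) // 2 * n_freqs}
    if name in ("MEG_cov", "MEG_env"):
        return {"inputs": inputs,
                "first_layer": rank * (rank - 1) // 2 * n_freqs}
    raise StackingError(f"unknown block {name!r}")


def build_blocks(tensors: list, cohort_table: pd.DataFrame,
                 config: StackingConfig, foi=None) -> list[ModalityBlock]:
    """Assemble the 9 modality blocks from per-subject spectral tensors and
    the cohort table (rows aligned with ``tensors``)."""
    df = cohort_table.reset_index(drop=True)
    n = len(df)
    if len(tensors) != n:
        raise StackingError("tensors and cohort table must align")
    if foi is None:
        foi = tensors[0].foi
    idx, freqs = strided_frequencies(foi, config.freq_stride)
    blocks = []
    site = (df["site"] == "CBU").astype(float).to_numpy()
    sex = (df["sex"] == "M").astype(float).to_numpy()
    scalars = {"site": site, "age": df["age"].to_numpy(float), "sex": sex,
               "education": df["education"].to_numpy(float),
               "mmse": df["mmse"].to_numpy(float)}
    for name in SCALAR_BLOCKS:
        blocks.append(ModalityBlock(name, scalars[name][:, None], "scalar"))
    for name, attr in (("MEG_cov", "cov"), ("MEG_env", "env_corr"),
                       ("MEG_dwpli", "dwpli")):
        stack = []
        for t in tensors:
            arr = getattr(t, attr)
            if arr is None:
                raise StackingError(f"missing {attr} metric")
            sub = arr[idx]
            chk = sub.copy()
            if name == "MEG_dwpli":      # NaN diagonal is part of the contract
                chk[:, np.arange(sub.shape[1]), np.arange(sub.shape[1])] = 0.0
            if np.isnan(chk).any():
                raise StackingError(
                    f"{attr} not available at all strided frequencies "
                    "(frequency unusable at this epoch length?)")
            stack.append(sub)
        enc = "upper_triangle" if name == "MEG_dwpli" else "tangent"
        blocks.append(ModalityBlock(name, np.stack(stack), enc, freqs))
    vol_cols = [c for c in df.columns if c.startswith("vol_")]
    blocks.append(ModalityBlock("MRI_vol", df[vol_cols].to_numpy(float), "raw"))
    return blocks


# ---------------------------------------------------------------------------
# Encoders (fold-aware where a reference is estimated)
# ---------------------------------------------------------------------------

def _upper_triangle(mats):
    """(n, F, S, S) -> (n, F * S(S-1)/2) upper-triangle vectors (NaN -> 0 for
    the dwPLI diagonal-free matrices)."""
    n, f, s, _ = mats.shape
    iu = np.triu_indices(s, 1)
    out = np.nan_to_num(mats[:, :, iu[0], iu[1]], nan=0.0)
    return out.reshape(n, -1)


class BlockEncoder:
    """fit(train data) / transform(data) feature encoder for one block."""

    def __init__(self, block: ModalityBlock, config: StackingConfig):
        self.block = block
        self.config = config
        self._tangent = None

    def fit(self, train_idx):
        b = self.block
        if b.encoding == "tangent":
            rank = min(self.config.rank, b.data.shape[-1])
            self._tangent = [TangentSpace(rank, self.config.reg)
                             for _ in range(b.data.shape[1])]
            for fi, ts in enumerate(self._tangent):
                ts.fit(b.data[train_idx, fi])
        return self

    def transform(self, idx):
        b = self.block
        if b.encoding in ("scalar", "raw"):
            return np.asarray(b.data[idx], float)
        if b.encoding == "upper_triangle":
            return _upper_triangle(b.data[idx])
        if b.encoding == "tangent":
            feats = [ts.transform(b.data[idx, fi])
                     for fi, ts in enumerate(self._tangent)]
            return np.concatenate(feats, axis=1)
        raise StackingError(f"unknown encoding {b.encoding!r}")


def iterative_impute(table: np.ndarray, train_rows: np.ndarray,
                     max_iter: int = 10, tol: float = 1e-3, rng=0):
    """Round-robin regression imputation fitted on training rows only.

    Each incomplete column is iteratively regressed on the others (ridge-type
    Bayesian regressors); returns the completed table.  Columns entirely
    missing in the training rows fall back to the overall training mean (or
    raise when nothing is observed at all).
    """
    x = np.asarray(table, float).copy()
    train_rows = np.asarray(train_rows)
    xt = x[train_rows]
    for j in range(x.shape[1]):
        col = xt[:, j]
        if np.isnan(col).all():
            if np.isnan(x[:, j]).all():
                raise StackingError(f"column {j} entirely missing")
            warnings.warn(f"column {j} all-missing in training rows; "
                          "falling back to overall mean")
            x[np.isnan(x[:, j]), j] = np.nanmean(x[:, j])
    imp = IterativeImputer(max_iter=max_iter, tol=tol, random_state=rng,
                           sample_posterior=False, keep_empty_features=True)
    imp.fit(x[train_rows])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return imp.transform(x), imp


def assert_no_leakage(train_idx, test_idx, n_subjects):
    """Hard leakage guard on fold bookkeeping."""
    tr, te = set(map(int, train_idx)), set(map(int, test_idx))
    if tr & te:
        raise LeakageError(f"train/test overlap: {sorted(tr & te)[:5]} ...")
    if tr | te != set(range(n_subjects)):
        raise LeakageError("train/test folds do not partition the cohort")


def first_layer_fit(features_train, labels_train, grid=DEFAULT_GRID):
    """Standardize (train-fitted) + ridge classifier on +-1 targets, penalty
    by internal efficient leave-one-out/GCV over the grid.  Returns a
    ``score(features) -> decision values`` closure."""
    x = np.asarray(features_train, float)
    keep = x.std(0) > 0
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} constant feature columns")
    if not keep.any():
        return lambda f: np.zeros(len(f))
    scaler = StandardScaler().fit(x[:, keep])
    clf = RidgeClassifierCV(alphas=grid)
    clf.fit(scaler.transform(x[:, keep]), labels_train)
    return lambda feats: clf.decision_function(
        scaler.transform(np.asarray(feats, float)[:, keep]))


# ---------------------------------------------------------------------------
# Cross-fitting driver
# ---------------------------------------------------------------------------

@dataclass
class SplitArtifacts:
    """Everything the second layer / CPI needs for one outer split."""

    repeat: int
    fold: int
    train_idx: np.ndarray
    test_idx: np.ndarray
    scores_train: np.ndarray      # (n_train, 9) cross-fitted first-layer scores
    scores_test: np.ndarray
    groups_train: np.ndarray      # outer-fold ids of the training subjects
    second_layer: object          # fitted LogisticRegressionCV
    labels_test: np.ndarray = None


@dataclass
class StackingResult:
    """Per-model AUC per CV split, plus split artifacts for importance."""

    model_names: list
    auc: dict                      # name -> (n_splits,) array (NaN = skipped)
    n_repeats: int
    n_folds: int
    n_skipped: int
    splits: list = field(repr=False, default_factory=list)
    block_names: list = field(default_factory=list)

    def mean_auc(self) -> pd.Series:
        return pd.Series({k: np.nanmean(v) for k, v in self.auc.items()})

    def summary(self) -> pd.DataFrame:
        rows = []
        for name in self.model_names:
            v = self.auc[name]
            ok = v[np.isfinite(v)]
            rows.append({"model": name, "mean_auc": ok.mean(),
                         "sd_auc": ok.std(ddof=1),
                         "median_auc": np.median(ok), "n_splits": len(ok)})
        return pd.DataFrame(rows)


def build_impute_table(blocks):
    """Collect the columns with potential missingness (the scalar blocks and
    the MRI volumes) into one table for joint iterative imputation.

    Returns ``(table (n, d), mapping block_name -> column indices)``; blocks
    not listed carry no missing values.
    """
    cols, mapping, j = [], {}, 0
    for b in blocks:
        if b.encoding == "scalar":
            cols.append(np.asarray(b.data, float).reshape(len(b.data), 1))
            mapping[b.name] = np.array([j])
            j += 1
        elif b.name == "MRI_vol":
            arr = np.asarray(b.data, float)
            cols.append(arr)
            mapping[b.name] = np.arange(j, j + arr.shape[1])
            j += arr.shape[1]
    if not cols:
        return None, {}
    return np.concatenate(cols, axis=1), mapping


def cross_fitted_scores(blocks, labels, config: StackingConfig):
    """First-layer cross-fitting.

    Returns a list over repeats of ``(score_matrix (n, n_blocks), fold_ids)``
    where each subject's score was produced by models trained on the other
    folds; fold assignment is stratified by outcome and deterministic for a
    fixed seed.  Missing values in the scalar and MRI blocks are imputed
    jointly per fold (iterative imputer fitted on training rows only), so no
    subject is excluded.
    """
    labels = np.asarray(labels)
    n = len(labels)
    out = []
    imp_table, imp_map = build_impute_table(blocks)
    needs_impute = imp_table is not None and np.isnan(imp_table).any()
    for rep in range(config.n_repeats):
        skf = StratifiedKFold(n_splits=config.n_folds, shuffle=True,
                              random_state=(config.seed * 1009 + rep) % (2 ** 31))
        scores = np.full((n, len(blocks)), np.nan)
        fold_ids = np.full(n, -1)
        for fold, (tr, te) in enumerate(skf.split(np.zeros(n), labels)):
            assert_no_leakage(tr, te, n)
            fold_ids[te] = fold
            imputed = None
            if needs_impute:
                imputed, _ = iterative_impute(imp_table, tr, rng=config.seed)
            for bi, block in enumerate(blocks):
                if imputed is not None and block.name in imp_map:
                    ftr = imputed[np.ix_(tr, imp_map[block.name])]
                    fte = imputed[np.ix_(te, imp_map[block.name])]
                else:
                    enc = BlockEncoder(block, config).fit(tr)
                    ftr = enc.transform(tr)
                    fte = enc.transform(te)
                scorer = first_layer_fit(ftr, labels[tr],
                                         config.first_layer_grid)
                scores[te, bi] = scorer(fte)
        if np.isnan(scores).any() or (fold_ids < 0).any():
            raise LeakageError("incomplete cross-fitting bookkeeping")
        out.append((scores, fold_ids))
    return out


def second_layer_fit_and_eval(scores_per_repeat, labels,
                              config: StackingConfig,
                              block_names=None) -> StackingResult:
    """Second-layer stacking under the same splits, plus marginal AUCs.

    For each outer split the combiner is trained on the cross-fitted scores
    of the training subjects (internal leave-one-group-out CV over their
    outer folds) and evaluated on the held-out fold.  Marginal single-block
    models are evaluated on identical splits.  Single-class test folds are
    skipped and counted.
    """
    labels = np.asarray(labels)
    n = len(labels)
    if block_names is None:
        block_names = list(BLOCK_ORDER[:scores_per_repeat[0][0].shape[1]])
    names = [*block_names, "stacked"]
    n_splits = len(scores_per_repeat) * config.n_folds
    auc = {name: np.full(n_splits, np.nan) for name in names}
    splits = []
    n_skipped = 0
    si = 0
    for rep, (scores, fold_ids) in enumerate(scores_per_repeat):
        for fold in range(config.n_folds):
            te = np.where(fold_ids == fold)[0]
            tr = np.where(fold_ids != fold)[0]
            assert_no_leakage(tr, te, n)
            if len(np.unique(labels[te])) < 2:
                n_skipped += 1
                si += 1
                continue
            inner = list(LeaveOneGroupOut().split(
                scores[tr], labels[tr], groups=fold_ids[tr]))
            clf = LogisticRegressionCV(
                Cs=config.second_layer_grid, cv=inner, penalty="l2",
                scoring="neg_log_loss", max_iter=2000)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                clf.fit(scores[tr], labels[tr])
            p = clf.predict_proba(scores[te])[:, 1]
            auc["stacked"][si] = roc_auc_score(labels[te], p)
            for bi, name in enumerate(block_names):
                auc[name][si] = roc_auc_score(labels[te], scores[te, bi])
            splits.append(SplitArtifacts(rep, fold, tr, te, scores[tr],
                                         scores[te], fold_ids[tr], clf,
                                         labels[te]))
            si += 1
    return StackingResult(names, auc, len(scores_per_repeat), config.n_folds,
                          n_skipped, splits, list(block_names))


class StackedProgressionClassifier:
    """Model object tying the pieces together.

    Parameters
    ----------
    blocks : list of ModalityBlock (see :func:`build_blocks`)
    labels : (n,) binary outcome (1 = progression)
    config : StackingConfig
    """

    def __init__(self, blocks, labels, config: StackingConfig | None = None):
        self.blocks = blocks
        self.labels = np.asarray(labels)
        self.config = config or StackingConfig()

    def fit(self) -> StackingResult:
        scores = cross_fitted_scores(self.blocks, self.labels, self.config)
        return second_layer_fit_and_eval(scores, self.labels, self.config,
                                         [b.name for b in self.blocks])
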