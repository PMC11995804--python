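"""Riemannian machinery for symmetric positive-definite (SPD) matrix sets.

Sensor covariance and power-envelope matrices live on the SPD manifold once
rank deficiency is removed.  This module provides the common-subspace
projection (PCA of the grand-average matrix) used to reduce rank-deficient
102-sensor matrices to a full-rank subspace (rank 65 for covariance and
envelope correlation, rank 5 for dwPLI after a nearest-SPD repair), the
affine-invariant Riemannian metric (AIRM), tangent-space embedding around the
Frechet (geometric) mean, and a non-parametric distance MANOVA: a pseudo-F
computed from the pairwise AIRM distance matrix with label-permutation
inference and BH-FDR correction across frequencies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg as sla
from statsmodels.stats.multitest import multipletests


class SPDError(ValueError):
    pass


def _check_square_sym(m, tol=1e-8, name="matrix"):
    m = np.asarray(m, float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise SPDError(f"{name} must be square")
    if not np.isfinite(m).all():
        raise SPDError(f"{name} has non-finite entries")
    if np.abs(m - m.T).max() > tol * max(1.0, np.abs(m).max()):
        raise SPDError(f"{name} is not symmetric")
    return 0.5 * (m + m.T)


def _fix_eigvec_signs(vecs):
    """Deterministic sign convention: largest-|.| component of each
    eigenvector made positive."""
    idx = np.argmax(np.abs(vecs), axis=0)
    signs = np.sign(vecs[idx, np.arange(vecs.shape[1])])
    signs[signs == 0] = 1.0
    return vecs * signs


@dataclass
class SPDMatrixSet:
    """A set of same-size SPD matrices at one frequency, after common
    subspace projection and trace-scaled regularization."""

    matrices: np.ndarray               # (n, r, r)
    rank: int
    reg: float = 1e-15
    filters: np.ndarray | None = None  # (p, r) projection used

    def __len__(self):
        return len(self.matrices)


def regularize(m: np.ndarray, reg: float = 1e-15) -> np.ndarray:
    """Add ``reg * trace/dim`` on the diagonal (trace-scaled jitter)."""
    d = m.shape[-1]
    tr = np.trace(m, axis1=-2, axis2=-1)
    scale = np.where(tr > 0, tr, 1.0) / d
    return m + (reg * scale)[..., None, None] * np.eye(d)


def common_subspace_project(matrices, rank: int, reg: float = 1e-15) -> SPDMatrixSet:
    """Project each matrix to the top-``rank`` principal subspace of the
    grand-average matrix: ``M -> F.T M F`` with ``F`` the leading eigenvectors
    (signs fixed deterministically), then regularize."""
    mats = np.asarray(matrices, float)
    n, p, _ = mats.shape
    if rank > p:
        raise SPDError(f"rank {rank} exceeds matrix dimension {p}")
    grand = _check_square_sym(mats.mean(0), name="grand-average")
    w, v = np.linalg.eigh(grand)
    order = np.argsort(w)[::-1][:rank]
    filters = _fix_eigvec_signs(v[:, order])
    proj = np.einsum("pr,npq,qs->nrs", filters, mats, filters)
    proj = 0.5 * (proj + np.swapaxes(proj, -1, -2))
    return SPDMatrixSet(regularize(proj, reg), rank, reg, filters)


def nearest_spd(matrix, reg: float = 1e-15) -> np.ndarray:
    """Nearest-PSD repair by eigenvalue clipping (symmetrize, clip negative
    eigenvalues to zero, reconstruct) plus trace-scaled jitter, giving a
    strictly positive-definite output.  The clipped reconstruction is the
    Frobenius-nearest PSD matrix to the symmetrized input."""
    m = np.asarray(matrix, float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise SPDError("input must be square")
    if not np.isfinite(m).all():
        raise SPDError("non-finite entries")
    sym = 0.5 * (m + m.T)
    w, v = np.linalg.eigh(sym)
    w = np.clip(w, 0.0, None)
    out = (v * w) @ v.T
    out = 0.5 * (out + out.T)
    d = m.shape[0]
    tr = np.trace(out)
    jitter = reg * (tr / d if tr > 0 else 1.0)
    return out + max(jitter, np.finfo(float).tiny) * np.eye(d)


def _assert_spd(m, name="matrix"):
    m = _check_square_sym(m, name=name)
    w = np.linalg.eigvalsh(m)
    if w.min() <= 0:
        raise SPDError(f"{name} is not positive definite (min eig {w.min():g})")
    return m


def airm_distance(a, b) -> float:
    """Affine-invariant Riemannian distance
    ``||logm(A^{-1/2} B A^{-1/2})||_F`` (via generalized eigenvalues)."""
    a = _assert_spd(a, "A")
    b = _assert_spd(b, "B")
    w = sla.eigh(b, a, eigvals_only=True)
    return float(np.sqrt((np.log(w) ** 2).sum()))


def pairwise_airm(matrices) -> np.ndarray:
    """Pairwise AIRM distance matrix, using whitened eigendecompositions."""
    mats = np.asarray(matrices, float)
    n = len(mats)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            w = sla.eigh(mats[j], mats[i], eigvals_only=True)
            d[i, j] = d[j, i] = np.sqrt((np.log(w) ** 2).sum())
    return d


# ---------------------------------------------------------------------------
# Frechet mean & tangent space
# ---------------------------------------------------------------------------

def _sym_pow(m, p):
    w, v = np.linalg.eigh(m)
    return (v * w ** p) @ v.T


def _logm_sym(m):
    w, v = np.linalg.eigh(m)
    if w.min() <= 0:
        raise SPDError("matrix log of non-PD matrix")
    return (v * np.log(w)) @ v.T


def _expm_sym(m):
    w, v = np.linalg.eigh(m)
    return (v * np.exp(w)) @ v.T


def frechet_mean(matrices, tol: float = 1e-8, max_iter: int = 50) -> np.ndarray:
    """Geometric (Karcher) mean under the AIRM, by fixed-point iteration on
    the tangent-space barycentre.  Raises if not converged in ``max_iter``."""
    mats = np.asarray(matrices, float)
    g = mats.mean(0)
    err = np.inf
    for _ in range(max_iter):
        g_half = _sym_pow(g, 0.5)
        g_ihalf = _sym_pow(g, -0.5)
        logs = np.stack([_logm_sym(g_ihalf @ m @ g_ihalf) for m in mats])
        s = logs.mean(0)
        err = np.linalg.norm(s)
        g = g_half @ _expm_sym(s) @ g_half
        g = 0.5 * (g + g.T)
        if err < tol:
            return g
    raise SPDError(f"Frechet mean did not converge in {max_iter} iterations "
                   f"(last step norm {err:g})")


def _vec_upper(s):
    """Upper-triangle vectorization with sqrt(2)-scaled off-diagonals, so the
    Euclidean norm of the vector equals the Frobenius norm of the matrix."""
    r = s.shape[-1]
    iu = np.triu_indices(r, 1)
    diag = s[..., np.arange(r), np.arange(r)]
    off = s[..., iu[0], iu[1]] * np.sqrt(2.0)
    return np.concatenate([diag, off], axis=-1)


def tangent_vectors(matrices, base: np.ndarray | None = None,
                    tol: float = 1e-8, max_iter: int = 50):
    """Tangent-space embedding: whiten by the Frechet mean ``G`` and take
    ``logm(G^{-1/2} M G^{-1/2})``, vectorized so Euclidean distances locally
    match AIRM distances.  Returns ``(vectors (n, r(r+1)/2), base)``."""
    mats = np.asarray(matrices, float)
    if base is None:
        base = frechet_mean(mats, tol=tol, max_iter=max_iter)
    w_ihalf = _sym_pow(_check_square_sym(base, name="base"), -0.5)
    logs = np.stack([_logm_sym(w_ihalf @ m @ w_ihalf) for m in mats])
    return _vec_upper(logs), base


class TangentSpace:
    """Fit/transform wrapper (train-only reference) around
    :func:`common_subspace_project` + :func:`tangent_vectors`."""

    def __init__(self, rank: int, reg: float = 1e-15):
        self.rank = rank
        self.reg = reg
        self.filters_ = None
        self.base_ = None

    def fit(self, matrices):
        ms = common_subspace_project(matrices, self.rank, self.reg)
        self.filters_ = ms.filters
        self.base_ = frechet_mean(ms.matrices)
        return self

    def transform(self, matrices):
        mats = np.asarray(matrices, float)
        proj = np.einsum("pr,npq,qs->nrs", self.filters_, mats, self.filters_)
        proj = regularize(0.5 * (proj + np.swapaxes(proj, -1, -2)), self.reg)
        vecs, _ = tangent_vectors(proj, base=self.base_)
        return vecs

    def fit_transform(self, matrices):
        return self.fit(matrices).transform(matrices)


# ---------------------------------------------------------------------------
# Distance MANOVA
# ---------------------------------------------------------------------------

@dataclass
class ManovaResult:
    foi: np.ndarray
    pseudo_f: np.ndarray
    p: np.ndarray
    p_fdr: np.ndarray
    n_permutations: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"freq": self.foi, "pseudo_F": self.pseudo_f,
                             "p": self.p, "p_fdr": self.p_fdr})


def pseudo_f_from_distances(d2: np.ndarray, labels: np.ndarray) -> float:
    """PERMANOVA pseudo-F from a squared-distance matrix (Gower decomposition
    of total/within sums of squares)."""
    n = len(labels)
    groups = np.unique(labels)
    g = len(groups)
    ss_t = d2[np.triu_indices(n, 1)].sum() / n
    ss_w = 0.0
    for gr in groups:
        idx = np.where(labels == gr)[0]
        ss_w += d2[np.ix_(idx, idx)][np.triu_indices(len(idx), 1)].sum() / len(idx)
    ss_b = ss_t - ss_w
    return (ss_b / (g - 1)) / (ss_w / (n - g))


def _permuted_pseudo_f(d2, labels, n_perm, rng):
    """Vectorized pseudo-F over label permutations (two groups)."""
    n = len(labels)
    groups, counts = np.unique(labels, return_counts=True)
    if len(groups) != 2:
        raise SPDError("distance MANOVA implemented for two groups")
    perm = np.stack([rng.permutation(labels == groups[0]) for _ in range(n_perm)])
    u = perm.astype(float)                      # (P, n) indicator of group 0
    v = 1.0 - u
    row = d2.sum(1)
    tot = row.sum() / 2.0
    ss_t = tot / n
    quad_u = np.einsum("pi,ij,pj->p", u, d2, u) / 2.0
    quad_v = np.einsum("pi,ij,pj->p", v, d2, v) / 2.0
    ss_w = quad_u / counts[0] + quad_v / counts[1]
    ss_b = ss_t - ss_w
    return (ss_b / 1.0) / (ss_w / (n - 2))


def distance_manova_single(matrices, labels, n_perm: int = 1000,
                           rng=None) -> tuple[float, float]:
    """Pseudo-F and permutation p for one frequency's SPD set."""
    labels = np.asarray(labels)
    groups, counts = np.unique(labels, return_counts=True)
    if len(groups) != 2 or counts.min() < 2:
        raise SPDError("need two groups with >= 2 subjects each")
    rng = np.random.default_rng(rng)
    d2 = pairwise_airm(matrices) ** 2
    f_obs = pseudo_f_from_distances(d2, labels)
    f_perm = _permuted_pseudo_f(d2, labels, n_perm, rng)
    p = (np.sum(f_perm >= f_obs) + 1) / (n_perm + 1)
    return f_obs, float(p)


def distance_manova(matrix_sets, labels, n_perm: int = 1000, rng=None,
                    foi=None) -> ManovaResult:
    """Frequency-wise distance MANOVA with BH-FDR across frequencies.

    ``matrix_sets``: sequence over frequencies of (n_subjects, r, r) arrays or
    :class:`SPDMatrixSet`.
    """
    rng = np.random.default_rng(rng)
    fs, ps = [], []
    for ms in matrix_sets:
        mats = ms.matrices if isinstance(ms, SPDMatrixSet) else ms
        f, p = distance_manova_single(mats, labels, n_perm, rng)
        fs.append(f)
        ps.append(p)
    p_fdr = multipletests(ps, method="fdr_bh")[1]
    p_fdr = np.maximum(p_fdr, ps)
    if foi is None:
        foi = np.arange(len(fs), dtype=float)
    return ManovaResult(np.asarray(foi), np.asarray(fs), np.asarray(ps),
                        p_fdr, n_perm)


def dwpli_to_spd(dwpli_matrices, rank: int = 5, reg: float = 1e-15) -> SPDMatrixSet:
    """dwPLI matrices are not SPD: fill missing entries (incl. the NaN
    diagonal) with 0, repair with :func:`nearest_spd`, then apply the
    low-rank common-subspace projection."""
    mats = np.nan_to_num(np.asarray(dwpli_matrices, float), nan=0.0)
    repaired = np.stack([nearest_spd(m, reg) for m in mats])
    return common_subspace_project(repaired, rank, reg)
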