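"""Mass-univariate group inference with TFCE permutation correction.

Covers three layers of inference on frequency-resolved (1D) or
sensor-by-frequency (2D) group data:

* percentile-bootstrap confidence intervals and uncorrected permutation
  p-values of the per-frequency mean difference;
* pointwise one-way F statistics (identical to the squared pooled-variance t);
* threshold-free cluster enhancement (TFCE): each point accumulates
  ``extent^E * h^H * dh`` over height steps of the clusters it belongs to,
  with clusters defined by frequency neighbourhood (1D) or by sensor
  adjacency at equal frequency plus frequency neighbourhood at equal sensor
  (2D); family-wise error is controlled by a max-|TFCE| label-permutation
  null (two-tailed, on signed t maps enhanced separately per sign).

Optional covariate adjustment residualizes each point on a covariate design
(with intercept) before testing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import connected_components
from scipy import stats


class ClusterError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Per-frequency bootstrap / permutation / F
# ---------------------------------------------------------------------------

def bootstrap_mean_diff(group_a, group_b, n_boot: int = 9999, ci: float = 0.95,
                        rng=None):
    """Percentile bootstrap of ``mean(A) - mean(B)`` per frequency.

    Returns ``(diff, lo, hi)`` arrays over the last-but-one axis points.
    """
    a = np.atleast_2d(np.asarray(group_a, float))
    b = np.atleast_2d(np.asarray(group_b, float))
    if len(a) < 2 or len(b) < 2:
        raise ClusterError("need >= 2 subjects per group")
    if n_boot < 100:
        warnings.warn("n_boot < 100: bootstrap CI will be unstable")
    rng = np.random.default_rng(rng)
    diff = a.mean(0) - b.mean(0)
    boots = np.empty((n_boot,) + diff.shape)
    chunk = max(1, min(n_boot, int(2e7 / max(1, a.size + b.size))))
    for s in range(0, n_boot, chunk):
        m = min(chunk, n_boot - s)
        ia = rng.integers(0, len(a), size=(m, len(a)))
        ib = rng.integers(0, len(b), size=(m, len(b)))
        boots[s:s + m] = a[ia].mean(1) - b[ib].mean(1)
    alpha = (1 - ci) / 2
    lo, hi = np.quantile(boots, [alpha, 1 - alpha], axis=0)
    return diff, lo, hi


def permutation_p_uncorrected(group_a, group_b, n_perm: int = 9999, rng=None):
    """Two-sided label-permutation p of the mean difference per frequency,
    with the (b+1)/(n_perm+1) convention."""
    a = np.atleast_2d(np.asarray(group_a, float))
    b = np.atleast_2d(np.asarray(group_b, float))
    if len(a) < 2 or len(b) < 2:
        raise ClusterError("need >= 2 subjects per group")
    rng = np.random.default_rng(rng)
    data = np.concatenate([a, b])
    na, n = len(a), len(data)
    obs = np.abs(a.mean(0) - b.mean(0))
    count = np.zeros(obs.shape)
    total = data.sum(0)
    for _ in range(n_perm):
        idx = rng.permutation(n)
        suma = data[idx[:na]].sum(0)
        d = np.abs(suma / na - (total - suma) / (n - na))
        count += d >= obs - 1e-15
    return (count + 1) / (n_perm + 1)


def pointwise_t(group_a, group_b):
    """Pooled-variance two-sample t per point."""
    a = np.atleast_2d(np.asarray(group_a, float))
    b = np.atleast_2d(np.asarray(group_b, float))
    na, nb = len(a), len(b)
    if min(na, nb) < 2:
        raise ClusterError("need >= 2 subjects per group")
    va = a.var(0, ddof=1)
    vb = b.var(0, ddof=1)
    sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    denom = np.sqrt(sp2 * (1 / na + 1 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (a.mean(0) - b.mean(0)) / denom
    bad = ~np.isfinite(t)
    if bad.any():
        warnings.warn("zero within-group variance at some points; "
                      "t capped at 1e6")
        diff = a.mean(0) - b.mean(0)
        t = np.where(bad, np.sign(diff) * 1e6, t)
    return t


@dataclass
class StatMap:
    """F statistics over frequency (1D) or sensor x frequency (2D)."""

    values: np.ndarray
    foi: np.ndarray | None = None
    sensor_ids: list | None = None
    adjacency: np.ndarray | None = None


def pointwise_f(group_a, group_b, foi=None, sensor_ids=None,
                adjacency=None) -> StatMap:
    """One-way two-group F map (equals the squared pooled t everywhere)."""
    t = pointwise_t(group_a, group_b)
    return StatMap(np.minimum(t ** 2, 1e12), foi, sensor_ids, adjacency)


def residualize(data, covariates):
    """Per-point linear residualization on a covariate design (intercept
    added); NaN-free covariates required."""
    y = np.asarray(data, float)
    x = np.column_stack([np.ones(len(y)), np.asarray(covariates, float)])
    if not np.isfinite(x).all():
        raise ClusterError("covariates contain non-finite values")
    beta, *_ = np.linalg.lstsq(x, y.reshape(len(y), -1), rcond=None)
    return y - (x @ beta).reshape(y.shape)


# ---------------------------------------------------------------------------
# TFCE
# ---------------------------------------------------------------------------

def _grid_graph(shape, adjacency=None):
    """Sparse connectivity over flattened map points.

    1D (F,): neighbouring frequencies.  2D (S, F): adjacent sensors at the
    same frequency, plus neighbouring frequencies at the same sensor.
    """
    if len(shape) == 1:
        f = shape[0]
        i = np.arange(f - 1)
        return sparse.coo_matrix((np.ones(f - 1), (i, i + 1)),
                                 shape=(f, f)).tocsr()
    s, f = shape
    if adjacency is None:
        raise ClusterError("sensor adjacency required for 2D TFCE")
    rows, cols = [], []
    ai, aj = np.nonzero(np.triu(np.asarray(adjacency, bool), 1))
    for k in range(f):                       # same frequency, adjacent sensors
        rows.append(ai * f + k)
        cols.append(aj * f + k)
    si = np.arange(s)
    for k in range(f - 1):                   # same sensor, neighbouring freq
        rows.append(si * f + k)
        cols.append(si * f + k + 1)
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    n = s * f
    return sparse.coo_matrix((np.ones(len(rows)), (rows, cols)),
                             shape=(n, n)).tocsr()


def _neighbor_lists(graph):
    """Symmetric adjacency lists from the (upper-triangular) sparse graph."""
    g = (graph + graph.T).tocsr()
    return [g.indices[g.indptr[i]:g.indptr[i + 1]] for i in range(g.shape[0])]


def _tfce_reference(flat, e, h, dh, graph, heights):
    """Per-height connected-components TFCE (reference implementation)."""
    out = np.zeros_like(flat)
    for height in heights:
        active = np.where(flat >= height)[0]
        if len(active) == 0:
            break
        sub = graph[np.ix_(active, active)]
        n_comp, lab = connected_components(sub, directed=False)
        sizes = np.bincount(lab, minlength=n_comp)
        out[active] += sizes[lab] ** e * height ** h * dh
    return out


def _tfce_union_find(flat, e, h, dh, neighbors, heights):
    """Incremental union-find TFCE: process heights descending, adding nodes
    as they activate; numerically identical to the reference."""
    n = len(flat)
    parent = np.arange(n)
    size = np.ones(n, dtype=np.int64)
    added = np.zeros(n, bool)
    out = np.zeros(n)

    def find(i):
        root = i
        while parent[root] != root:
            root = parent[root]
        while parent[i] != root:          # path compression
            parent[i], i = root, parent[i]
        return root

    order = np.argsort(flat)[::-1]
    ptr = 0
    active: list = []
    hh = heights[::-1]                     # descending
    contrib = dh * hh ** h
    for height, c in zip(hh, contrib):
        while ptr < n and flat[order[ptr]] >= height:
            i = order[ptr]
            added[i] = True
            for j in neighbors[i]:
                if added[j]:
                    ri, rj = find(i), find(j)
                    if ri != rj:
                        if size[ri] < size[rj]:
                            ri, rj = rj, ri
                        parent[rj] = ri
                        size[ri] += size[rj]
            active.append(i)
            ptr += 1
        if active:
            idx = np.fromiter((find(i) for i in active), dtype=np.int64,
                              count=len(active))
            out[active] += size[idx] ** e * c
    return out


def tfce_enhance(values, e: float = 0.5, h: float = 2.0, dh: float | None = None,
                 adjacency=None, graph=None, n_steps: int = 50,
                 neighbors=None) -> np.ndarray:
    """TFCE of a nonnegative map.

    ``TFCE(p) = sum_h extent(cluster_h(p))^E * h^H * dh`` over height steps
    ``dh, 2dh, ... <= max``; ``dh`` defaults to ``max/n_steps``.  Monotone in
    the input, zero map -> zero output.
    """
    v = np.asarray(values, float)
    if (v < 0).any() or not np.isfinite(v).all():
        raise ClusterError("TFCE input must be finite and nonnegative")
    vmax = v.max()
    if vmax == 0:
        return np.zeros_like(v)
    if dh is None:
        dh = vmax / n_steps
    if neighbors is None:
        if graph is None:
            graph = _grid_graph(v.shape, adjacency)
        neighbors = _neighbor_lists(graph)
    flat = v.ravel()
    heights = np.arange(dh, vmax + 0.5 * dh, dh)
    return _tfce_union_find(flat, e, h, dh, neighbors, heights).reshape(v.shape)


@dataclass
class ClusterTestResult:
    tfce: np.ndarray            # signed enhanced map
    p_corrected: np.ndarray
    sig_mask: np.ndarray
    n_permutations: int
    e: float
    h: float
    alpha: float
    t_obs: np.ndarray


def _signed_tfce(tmap, e, h, neighbors, n_steps):
    pos = tfce_enhance(np.clip(tmap, 0, None), e, h, None,
                       neighbors=neighbors, n_steps=n_steps)
    neg = tfce_enhance(np.clip(-tmap, 0, None), e, h, None,
                       neighbors=neighbors, n_steps=n_steps)
    return pos - neg


def tfce_permutation_test(data, labels, e: float = 0.5, h: float = 2.0,
                          n_perm: int = 1000, adjacency=None,
                          alpha: float = 0.05, n_steps: int = 50,
                          covariates=None, rng=None) -> ClusterTestResult:
    """Two-tailed TFCE permutation test on group data.

    ``data``: (n_subjects, F) or (n_subjects, S, F); ``labels``: binary group
    labels.  Signed t maps are enhanced separately per sign; the null is the
    permutation distribution of the maximum |TFCE|, giving per-point
    family-wise corrected p-values with the +1 convention.
    """
    x = np.asarray(data, float)
    labels = np.asarray(labels)
    groups = np.unique(labels)
    if len(groups) != 2:
        raise ClusterError("need exactly two groups")
    if n_perm < 100:
        warnings.warn("n_perm < 100: corrected p-values are coarse")
    if covariates is not None:
        x = residualize(x, covariates)
    rng = np.random.default_rng(rng)
    map_shape = x.shape[1:]
    neighbors = _neighbor_lists(_grid_graph(map_shape, adjacency))
    mask_a = labels == groups[0]

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        t_obs = pointwise_t(x[mask_a], x[~mask_a])
    tfce_obs = _signed_tfce(t_obs, e, h, neighbors, n_steps)

    null_max = np.empty(n_perm)
    for i in range(n_perm):
        pm = rng.permutation(mask_a)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            t_p = pointwise_t(x[pm], x[~pm])
        null_max[i] = np.abs(_signed_tfce(t_p, e, h, neighbors, n_steps)).max()

    obs_abs = np.abs(tfce_obs)
    p = (np.sum(null_max[:, None] >= obs_abs.ravel()[None, :], axis=0) + 1) \
        / (n_perm + 1)
    p = p.reshape(map_shape)
    return ClusterTestResult(tfce_obs, p, p <= alpha, n_perm, e, h, alpha, t_obs)
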