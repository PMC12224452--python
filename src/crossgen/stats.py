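"""Group-level permutation inference on decoding accuracy.

Implements the one-sample route used throughout: per-cell one-tailed t
statistics of subject accuracies against the 50% chance level, a
threshold-free cluster enhancement (TFCE) transform over the spatiotemporal
adjacency graph, family-wise correction by the max-statistic sign-flip
permutation scheme, and a 2-D cluster-mass permutation test for temporal
generalization matrices.

TFCE integrates, over thresholds h, ``extent_h(v)^E * h^H * dh`` where
``extent_h(v)`` is the size of the connected suprathreshold component
containing v; E = 0.5 and H = 2 are the method's standard exponents.
Negative t never contributes (one-tailed: only above-chance accuracy is
flagged). Sign-flip permutations negate each subject's deviation from
chance, which is exact under the symmetric one-sample null; when the number
of subjects is so small that 2^n does not exceed the requested permutation
count, all flips are enumerated instead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from numba import njit
from scipy import ndimage
from scipy import stats as sps

__all__ = [
    "TMap",
    "TFCEParams",
    "ClusterResult",
    "one_sample_t",
    "tfce_transform",
    "sign_flip_permutation",
    "cluster_mass_permutation_2d",
]


@dataclass
class TMap:
    """Mass-univariate one-sample t statistics (one-tailed, greater)."""

    values: np.ndarray
    df: int
    popmean: float = 0.5
    n_zero_variance: int = 0
    tail: str = "greater"


@dataclass(frozen=True)
class TFCEParams:
    """TFCE exponents and permutation settings.

    ``dh=None`` selects ``max(t)/100`` with a floor of 0.05 t-units.
    """

    e: float = 0.5
    h: float = 2.0
    dh: float | None = None
    n_permutations: int = 10000
    seed: int = 0

    def __post_init__(self):
        if self.dh is not None and self.dh <= 0:
            raise ValueError("dh must be positive")
        if self.n_permutations < 100:
            raise ValueError("n_permutations must be >= 100")


@dataclass
class ClusterResult:
    """A significant spatiotemporal (or train x test time) cluster.

    ``members`` are flat cell indices into the map the test ran on; extent
    is reported three ways (cells, distinct sources, distinct timepoints)
    since any of them may be the convention a reader expects.
    """

    method: str
    members: np.ndarray
    p: float
    peak_t: float
    mass: float
    n_cells: int
    n_sources: int
    n_times: int
    vertices: np.ndarray = field(default_factory=lambda: np.empty(0, np.int64))
    time_window_ms: tuple[float, float] | None = None

    def __len__(self) -> int:
        return self.n_cells

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "members": self.members.tolist(),
            "p": self.p,
            "peak_t": self.peak_t,
            "mass": self.mass,
            "extent": {
                "cells": self.n_cells,
                "sources": self.n_sources,
                "timepoints": self.n_times,
            },
            "vertices": self.vertices.tolist(),
            "time_window_ms": list(self.time_window_ms)
            if self.time_window_ms is not None
            else None,
        }


# ---------------------------------------------------------------------------
# t statistics


def one_sample_t(per_subject_maps: np.ndarray, popmean: float = 0.5) -> TMap:
    """Per-cell one-sample t against ``popmean`` (sd with n-1 denominator).

    Zero-variance cells get a signed infinity sentinel (0 when the mean
    equals ``popmean``) and are counted in ``n_zero_variance``.
    """
    maps = np.asarray(per_subject_maps, dtype=np.float64)
    n = maps.shape[0]
    if n < 2:
        raise ValueError(f"need >= 2 subjects, got {n}")
    mean = maps.mean(axis=0)
    sd = maps.std(axis=0, ddof=1)
    zero = sd == 0
    n_zero = int(zero.sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (mean - popmean) / (sd / np.sqrt(n))
    if n_zero:
        warnings.warn(
            f"{n_zero} cells have zero across-subject variance; "
            "t set to signed infinity",
            stacklevel=2,
        )
        diff = mean - popmean
        t[zero] = np.where(diff[zero] > 0, np.inf, np.where(diff[zero] < 0, -np.inf, 0.0))
    return TMap(values=t, df=n - 1, popmean=popmean, n_zero_variance=n_zero)


# ---------------------------------------------------------------------------
# TFCE


@njit(cache=True)
def _uf_find(parent, i):
    root = i
    while parent[root] != root:
        root = parent[root]
    while parent[i] != root:
        nxt = parent[i]
        parent[i] = root
        i = nxt
    return root


@njit(cache=True)
def _tfce_kernel(t, eu, ev, e_exp, h_exp, dh, n_steps):
    n = t.shape[0]
    out = np.zeros(n)
    parent = np.empty(n, dtype=np.int64)
    size = np.empty(n, dtype=np.float64)
    for step in range(1, n_steps + 1):
        h = dh * step
        for i in range(n):
            parent[i] = i if t[i] >= h else -1
        for k in range(eu.shape[0]):
            u, v = eu[k], ev[k]
            if parent[u] >= 0 and parent[v] >= 0:
                ru = _uf_find(parent, u)
                rv = _uf_find(parent, v)
                if ru != rv:
                    parent[rv] = ru
        for i in range(n):
            size[i] = 0.0
        for i in range(n):
            if parent[i] >= 0:
                size[_uf_find(parent, i)] += 1.0
        inc = h**h_exp * dh
        for i in range(n):
            if parent[i] >= 0:
                out[i] += size[_uf_find(parent, i)] ** e_exp * inc
    return out


_MAX_TFCE_STEPS = 5000


def _edge_arrays(adjacency: sp.spmatrix) -> tuple[np.ndarray, np.ndarray]:
    coo = sp.triu(adjacency, k=1).tocoo()
    return coo.row.astype(np.int64), coo.col.astype(np.int64)


def _resolve_dh(tmax: float, params: TFCEParams) -> float:
    if params.dh is not None:
        return params.dh
    return max(tmax / 100.0, 0.05)


def tfce_transform(
    tmap: TMap | np.ndarray, adjacency: sp.spmatrix, params: TFCEParams
) -> np.ndarray:
    """TFCE-enhanced map, same shape as the input t map.

    Infinite t values (zero-variance sentinels) are clipped to the largest
    finite value before enhancement.
    """
    t = np.asarray(tmap.values if isinstance(tmap, TMap) else tmap, dtype=np.float64)
    shape = t.shape
    flat = t.ravel().copy()
    finite = np.isfinite(flat)
    if not finite.all():
        cap = flat[finite].max() if finite.any() else 0.0
        flat[np.isposinf(flat)] = cap
        flat[np.isneginf(flat)] = 0.0
    tmax = flat.max(initial=0.0)
    if tmax <= 0:
        return np.zeros(shape)
    dh = _resolve_dh(tmax, params)
    n_steps = int(np.floor(tmax / dh))
    if n_steps < 1:
        warnings.warn("dh exceeds max(t); TFCE map is all zero", stacklevel=2)
        return np.zeros(shape)
    # cap the integration grid: extreme t (e.g. near-degenerate permutations)
    # would otherwise blow the threshold count up without accuracy benefit
    if n_steps > _MAX_TFCE_STEPS:
        dh = tmax / _MAX_TFCE_STEPS
        n_steps = _MAX_TFCE_STEPS
    if adjacency.shape[0] != flat.shape[0]:
        raise ValueError(
            f"adjacency covers {adjacency.shape[0]} cells, map has {flat.shape[0]}"
        )
    eu, ev = _edge_arrays(adjacency)
    out = _tfce_kernel(flat, eu, ev, params.e, params.h, dh, n_steps)
    return out.reshape(shape)


# ---------------------------------------------------------------------------
# sign-flip permutation with max-statistic correction


def _flip_matrix(n_subjects: int, n_permutations: int, seed: int) -> tuple[np.ndarray, bool]:
    if 2**n_subjects < n_permutations:
        warnings.warn(
            f"2^{n_subjects} < {n_permutations} permutations; "
            "enumerating all sign flips exactly",
            stacklevel=3,
        )
        bits = np.arange(2**n_subjects)[:, None] >> np.arange(n_subjects)
        return 1 - 2 * (bits & 1).astype(np.float64), True
    rng = np.random.default_rng(seed)
    return rng.choice([-1.0, 1.0], size=(n_permutations, n_subjects)), False


def _max_stat_p(null_max: np.ndarray, observed: np.ndarray, exhaustive: bool) -> np.ndarray:
    """Corrected p from a max-statistic null distribution.

    Exhaustive enumeration (identity flip included) yields the exact
    ``count / n``; Monte-Carlo draws use the standard ``(1 + count) / (n + 1)``
    smoothing so p is never zero.
    """
    null_sorted = np.sort(null_max)
    n_ge = len(null_sorted) - np.searchsorted(null_sorted, observed, side="left")
    if exhaustive:
        return n_ge / len(null_sorted)
    return (1.0 + n_ge) / (len(null_sorted) + 1.0)


#: Cap on |t| inside permutation schemes. Zero-variance cells (e.g. every
#: subject decoding at exactly 100%) would otherwise be infinite; capping
#: keeps them maximal while leaving the TFCE threshold grid usable. Applied
#: identically to observed and permuted maps, so the comparison stays exact.
_T_CAP = 100.0


def _t_from_deviations(dev: np.ndarray) -> np.ndarray:
    n = dev.shape[0]
    mean = dev.mean(axis=0)
    sd = dev.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    t[np.isnan(t)] = 0.0
    return np.clip(t, -_T_CAP, _T_CAP)


def _components(mask: np.ndarray, adjacency: sp.spmatrix) -> list[np.ndarray]:
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return []
    sub = adjacency[idx][:, idx]
    n_comp, labels = sp.csgraph.connected_components(sub, directed=False)
    return [idx[labels == c] for c in range(n_comp)]


def _cluster_from_cells(
    cells: np.ndarray,
    t_flat: np.ndarray,
    p: float,
    method: str,
    n_times_grid: int | None,
    vertices: np.ndarray | None,
    time_ms: np.ndarray | None,
) -> ClusterResult:
    tvals = t_flat[cells]
    if n_times_grid is not None:
        src_pos = cells // n_times_grid
        t_pos = cells % n_times_grid
        uniq_src = np.unique(src_pos)
        uniq_t = np.unique(t_pos)
        verts = (
            np.asarray(vertices)[uniq_src] if vertices is not None else uniq_src
        )
        window = None
        if time_ms is not None:
            window = (float(time_ms[uniq_t.min()]), float(time_ms[uniq_t.max()]))
        return ClusterResult(
            method=method,
            members=cells,
            p=float(p),
            peak_t=float(tvals.max()),
            mass=float(tvals.sum()),
            n_cells=len(cells),
            n_sources=len(uniq_src),
            n_times=len(uniq_t),
            vertices=np.asarray(verts, dtype=np.int64),
            time_window_ms=window,
        )
    return ClusterResult(
        method=method,
        members=cells,
        p=float(p),
        peak_t=float(tvals.max()),
        mass=float(tvals.sum()),
        n_cells=len(cells),
        n_sources=len(cells),
        n_times=len(cells),
    )


def sign_flip_permutation(
    per_subject_maps: np.ndarray,
    adjacency: sp.spmatrix,
    params: TFCEParams,
    alpha: float = 0.05,
    popmean: float = 0.5,
    vertices: np.ndarray | None = None,
    time_ms: np.ndarray | None = None,
) -> tuple[list[ClusterResult], np.ndarray]:
    """TFCE + sign-flip max-statistic inference.

    ``per_subject_maps`` is (n_subjects, n_sources, n_times) — or
    (n_subjects, n_cells) for an arbitrary graph. Returns the significant
    clusters (connected components of cells with corrected p <= alpha) and
    the corrected p-map. ``p(v) = (1 + #{perm max >= TFCE(v)}) / (n_perm+1)``.
    """
    maps = np.asarray(per_subject_maps, dtype=np.float64)
    n_subjects = maps.shape[0]
    if n_subjects < 2:
        raise ValueError("need >= 2 subjects for sign-flip inference")
    if n_subjects < 5:
        warnings.warn(
            f"only {n_subjects} subjects; sign-flip p-values are coarse",
            stacklevel=2,
        )
    grid_shape = maps.shape[1:]
    n_times_grid = grid_shape[1] if len(grid_shape) == 2 else None
    dev = maps.reshape(n_subjects, -1) - popmean
    t_obs = _t_from_deviations(dev)
    # fix the TFCE step from the observed map so all permutations share it
    tmax = max(t_obs.max(initial=0.0), 1e-9)
    dh = _resolve_dh(tmax, params)
    fixed = TFCEParams(
        e=params.e, h=params.h, dh=dh,
        n_permutations=params.n_permutations, seed=params.seed,
    )
    tfce_obs = tfce_transform(t_obs, adjacency, fixed)
    flips, exhaustive = _flip_matrix(n_subjects, params.n_permutations, params.seed)
    null_max = np.empty(len(flips))
    for i, s in enumerate(flips):
        t_perm = _t_from_deviations(dev * s[:, None])
        null_max[i] = tfce_transform(t_perm, adjacency, fixed).max(initial=0.0)
    p_map = _max_stat_p(null_max, tfce_obs, exhaustive)
    clusters = [
        _cluster_from_cells(
            cells, t_obs, p_map[cells].min(), "tfce", n_times_grid, vertices, time_ms
        )
        for cells in _components(p_map <= alpha, adjacency)
    ]
    clusters.sort(key=lambda c: c.p)
    return clusters, p_map.reshape(grid_shape)


# ---------------------------------------------------------------------------
# 2-D cluster-mass permutation for TGM matrices

_FOUR_CONN = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


def _mass_clusters(t2d: np.ndarray, threshold: float) -> tuple[np.ndarray, int]:
    labels, n = ndimage.label(t2d > threshold, structure=_FOUR_CONN)
    return labels, n


def cluster_mass_permutation_2d(
    per_subject_tgms: np.ndarray,
    threshold_p: float = 0.05,
    n_permutations: int = 1000,
    seed: int = 0,
    popmean: float = 0.5,
    train_time_ms: np.ndarray | None = None,
    test_time_ms: np.ndarray | None = None,
) -> list[ClusterResult]:
    """Cluster-mass sign-flip permutation test on (train x test) matrices.

    Cells are thresholded at the one-tailed t quantile of ``threshold_p``;
    4-connected suprathreshold components are scored by summed t; the null
    is the max cluster mass under subject sign flips. Returns every observed
    suprathreshold cluster with its corrected p (empty list when no cell is
    suprathreshold).
    """
    tgms = np.asarray(per_subject_tgms, dtype=np.float64)
    if tgms.ndim != 3:
        raise ValueError("per_subject_tgms must be (subjects, train, test)")
    n_subjects = tgms.shape[0]
    if n_subjects < 2:
        raise ValueError(f"need >= 2 subjects for cluster inference, got {n_subjects}")
    df = n_subjects - 1
    threshold = sps.t.ppf(1.0 - threshold_p, df)
    shape = tgms.shape[1:]
    dev = tgms.reshape(n_subjects, -1) - popmean
    t_obs = _t_from_deviations(dev).reshape(shape)
    labels, n_clu = _mass_clusters(t_obs, threshold)
    if n_clu == 0:
        return []
    masses = ndimage.sum_labels(t_obs, labels, index=np.arange(1, n_clu + 1))
    flips, exhaustive = _flip_matrix(n_subjects, n_permutations, seed)
    null_max = np.empty(len(flips))
    for i, s in enumerate(flips):
        t_perm = _t_from_deviations(dev * s[:, None]).reshape(shape)
        lab_p, n_p = _mass_clusters(t_perm, threshold)
        if n_p == 0:
            null_max[i] = 0.0
        else:
            null_max[i] = ndimage.sum_labels(
                t_perm, lab_p, index=np.arange(1, n_p + 1)
            ).max()
    results = []
    t_flat = t_obs.ravel()
    p_all = _max_stat_p(null_max, masses, exhaustive)
    for c in range(1, n_clu + 1):
        cells = np.flatnonzero(labels.ravel() == c)
        p = p_all[c - 1]
        clu = _cluster_from_cells(
            cells, t_flat, p, "cluster_mass", shape[1], None, test_time_ms
        )
        # for TGMs, "sources" are train timepoints
        if train_time_ms is not None:
            tr_pos = np.unique(cells // shape[1])
            clu.vertices = np.asarray(tr_pos, dtype=np.int64)
        results.append(clu)
    results.sort(key=lambda c: c.p)
    return results
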