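"""Neural state-space visualization by classical multidimensional scaling.

Condition-mean source patterns from a significant cluster are embedded in
two dimensions with classical (Torgerson) MDS — the double-centered Gram
eigendecomposition of squared Euclidean distances — which is deterministic
and exact for configurations of intrinsic dimension <= 2. Per-timepoint
phrase and noun means trace trajectories through that space; their
Euclidean separation over time is the distance timecourse (also reported in
the full feature space, since a 2-D truncation can distort distances).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .simulate import EpochSet, NOUN, PHRASE
from .stats import ClusterResult

__all__ = ["StateSpaceResult", "classical_mds", "condition_trajectories"]


@dataclass
class StateSpaceResult:
    """2-D condition trajectories and condition-separation timecourses."""

    coords: np.ndarray  # (n_conditions, n_times, 2), centered
    condition_names: tuple[str, ...]
    time_ms: np.ndarray
    distance_2d: np.ndarray  # per-timepoint separation in the embedding
    distance_full: np.ndarray  # same, in the original feature space


def classical_mds(items: np.ndarray, out_dim: int = 2) -> np.ndarray:
    """Classical (Torgerson) MDS of item coordinates to ``out_dim``.

    Returns centered coordinates; deterministic up to reflection, which is
    canonicalized by making the largest-|value| entry of each output
    dimension positive. If fewer than ``out_dim`` eigenvalues are positive
    the remaining dimensions are zero-padded with a warning.
    """
    items = np.asarray(items, dtype=float)
    if items.ndim != 2 or items.shape[0] < 3:
        raise ValueError("need >= 3 items of finite coordinates")
    if not np.all(np.isfinite(items)):
        raise ValueError("items contain non-finite values")
    n = items.shape[0]
    d2 = cdist(items, items, metric="sqeuclidean")
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ d2 @ J
    evals, evecs = np.linalg.eigh(B)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    coords = np.zeros((n, out_dim))
    n_pos = int(np.sum(evals[:out_dim] > 1e-12))
    if n_pos < out_dim:
        warnings.warn(
            f"only {n_pos} positive eigenvalues; padding {out_dim - n_pos} "
            "dimensions with zeros",
            stacklevel=2,
        )
    for j in range(n_pos):
        coords[:, j] = evecs[:, j] * np.sqrt(evals[j])
    for j in range(out_dim):
        i_max = np.argmax(np.abs(coords[:, j]))
        if coords[i_max, j] < 0:
            coords[:, j] = -coords[:, j]
    return coords


def condition_trajectories(
    epochs: EpochSet, cluster: ClusterResult
) -> StateSpaceResult:
    """Embed per-timepoint phrase/noun mean patterns from a cluster's
    sources into one shared 2-D space.

    Items for the embedding are the condition-mean feature vectors at every
    timepoint (2 x n_times items), so both trajectories live in a common
    space; the distance timecourse is the per-timepoint separation between
    the phrase and noun means.
    """
    if cluster is None or cluster.n_cells == 0:
        raise ValueError("cluster is empty")
    rows = epochs.vertex_rows(np.unique(cluster.vertices))
    names = ("noun", "phrase")
    means = []
    for label in (NOUN, PHRASE):
        sel = epochs.labels == label
        if not sel.any():
            raise ValueError(f"condition {names[label]!r} has no epochs")
        means.append(epochs.data[sel][:, rows, :].mean(axis=0))  # (k, T)
    stacked = np.stack(means)  # (2, k, T)
    n_t = stacked.shape[2]
    items = stacked.transpose(0, 2, 1).reshape(2 * n_t, -1)
    coords = classical_mds(items, out_dim=2).reshape(2, n_t, 2)
    distance_2d = np.linalg.norm(coords[1] - coords[0], axis=1)
    distance_full = np.linalg.norm(stacked[1] - stacked[0], axis=0)
    return StateSpaceResult(
        coords=coords,
        condition_names=names,
        time_ms=epochs.time_ms.copy(),
        distance_2d=distance_2d,
        distance_full=distance_full,
    )
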