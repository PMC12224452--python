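"""Temporal generalization across paradigms.

A classifier trained on a fixed source set at one training-paradigm
timepoint is tested at every timepoint of the other paradigm, giving a
(train time x test time) accuracy matrix per subject. Training uses all
epochs of the training paradigm — evaluation is on the other paradigm, so
no cross-validation is needed — and z-scoring parameters are learned from
the training data only. The source set and training window are usually
those of a significant spatiotemporal cluster from the within-paradigm
searchlight analysis (:func:`restrict_to_cluster`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._ffnn import ClassifierSpec
from .decoding import fit_classifier
from .simulate import EpochSet
from .stats import ClusterResult

__all__ = ["TGMMatrix", "tgm", "restrict_to_cluster", "NoClusterError"]


class NoClusterError(RuntimeError):
    """Raised when temporal generalization is requested for an empty
    cluster: there is no significant cluster to restrict to."""


@dataclass
class TGMMatrix:
    """Per-subject temporal generalization matrix.

    ``values[i, j]`` is prediction accuracy when training at train time i
    and testing at test time j.
    """

    subject_id: str
    train_paradigm: str
    test_paradigm: str
    values: np.ndarray
    train_time_ms: np.ndarray
    test_time_ms: np.ndarray
    source_set: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.min() < 0 or self.values.max() > 1:
            raise ValueError("TGM accuracies must lie in [0, 1]")
        if self.values.shape != (len(self.train_time_ms), len(self.test_time_ms)):
            raise ValueError("TGM shape does not match time axes")
        if len(self.source_set) == 0:
            raise ValueError("source_set must be non-empty")


def restrict_to_cluster(
    epochs: EpochSet, cluster: ClusterResult
) -> tuple[np.ndarray, tuple[float, float]]:
    """Source set and training window of a significant cluster.

    Returns the cluster's vertex ids (ascending) and the [min, max] of its
    member timepoints in ms.
    """
    if cluster is None or cluster.n_cells == 0:
        raise NoClusterError(
            "no significant cluster: temporal generalization has nothing to "
            "train on"
        )
    vertices = np.unique(cluster.vertices)
    if cluster.time_window_ms is None:
        raise ValueError("cluster carries no time window")
    epochs.vertex_rows(vertices)  # validates membership
    return vertices, cluster.time_window_ms


def tgm(
    train: EpochSet,
    test: EpochSet,
    source_set: np.ndarray,
    train_window_ms: tuple[float, float],
    spec: ClassifierSpec,
) -> TGMMatrix:
    """Train per-timepoint classifiers in ``train_window_ms`` (inclusive)
    on ``train`` and test each at every timepoint of ``test``."""
    source_set = np.asarray(sorted(int(v) for v in source_set), dtype=np.int64)
    tr_rows = train.vertex_rows(source_set)
    te_rows = test.vertex_rows(source_set)
    a, b = train_window_ms
    tr_times = np.flatnonzero((train.time_ms >= a) & (train.time_ms <= b))
    if tr_times.size == 0:
        raise ValueError(f"training window {train_window_ms} contains no timepoints")
    n_te_times = len(test.time_ms)
    values = np.empty((len(tr_times), n_te_times))
    te_feats = test.data[:, te_rows, :]  # (n_test, k, T_test)
    for i, ti in enumerate(tr_times):
        X = train.data[:, tr_rows, ti]
        mu = X.mean(axis=0)
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        model = fit_classifier(
            (X - mu) / sd,
            train.labels,
            ClassifierSpec(
                hidden_units=spec.hidden_units,
                activation=spec.activation,
                alpha=spec.alpha,
                max_iterations=spec.max_iterations,
                seed=spec.seed + 100003 * int(ti),
            ),
        )
        # all test timepoints in one prediction call
        Xte = (te_feats - mu[None, :, None]) / sd[None, :, None]
        flat = Xte.transpose(0, 2, 1).reshape(-1, len(source_set))
        pred = model.predict(flat).reshape(test.n_epochs, n_te_times)
        values[i] = (pred == test.labels[:, None]).mean(axis=0)
    return TGMMatrix(
        subject_id=train.subject_id,
        train_paradigm=train.paradigm,
        test_paradigm=test.paradigm,
        values=values,
        train_time_ms=train.time_ms[tr_times],
        test_time_ms=test.time_ms.copy(),
        source_set=source_set,
    )
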