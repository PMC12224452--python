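"""Searchlight decoding of phrase vs. noun epochs.

At every (masked source, timepoint) a small feed-forward classifier (one
hidden layer, two units) is trained on the searchlight's member sources'
values at that timepoint and scored by stratified cross-validation,
producing a per-subject accuracy map against the 50% chance level.

Features are z-scored within training folds (training-fold means and SDs
applied to the test fold), which makes the maps invariant to per-source
affine rescaling of the data. By default accuracies are cross-validated;
``evaluation_mode="train"`` instead scores the training set itself, which
reproduces the literal protocol of testing training accuracies against
chance but is upward-biased under the null.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from sklearn.model_selection import StratifiedKFold

from ._ffnn import ClassifierSpec, FFNN, fit_ffnn_batch, predict_ffnn_batch
from .geometry import Neighborhoods
from .simulate import EpochSet

__all__ = [
    "ClassifierSpec",
    "AccuracyMap",
    "fit_classifier",
    "searchlight_decode",
    "decode_residuals",
    "permute_epoch_labels",
]


@dataclass
class AccuracyMap:
    """Per-subject decoding accuracy over masked sources x timepoints."""

    subject_id: str
    values: np.ndarray  # (n_sources, n_times) in [0, 1]
    vertices: np.ndarray
    time_ms: np.ndarray
    chance_level: float = 0.5
    evaluation_mode: str = "cv"
    provenance: str = "epochs"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("accuracy values must be (sources, times)")
        if self.values.min() < 0 or self.values.max() > 1:
            raise ValueError("accuracies must lie in [0, 1]")
        if self.values.shape != (len(self.vertices), len(self.time_ms)):
            raise ValueError("accuracy shape does not match vertices/times")


def fit_classifier(features: np.ndarray, labels: np.ndarray, spec: ClassifierSpec) -> FFNN:
    """Train a single feed-forward classifier; deterministic given
    (data, spec.seed). Raises on single-class input."""
    return FFNN(spec).fit(features, labels)


def permute_epoch_labels(epochs: EpochSet, seed: int) -> EpochSet:
    """Copy of an epoch set with labels randomly permuted (null decoding)."""
    rng = np.random.default_rng(seed)
    return replace(epochs, labels=rng.permutation(epochs.labels))


def _check_folds(labels: np.ndarray, cv_folds: int) -> None:
    _, counts = np.unique(labels, return_counts=True)
    if cv_folds > counts.min():
        raise ValueError(
            f"cv_folds={cv_folds} exceeds the smallest class count "
            f"({counts.min()} epochs)"
        )


def _gather_features(
    data: np.ndarray, member_rows: np.ndarray, time_idx: np.ndarray
) -> np.ndarray:
    """Stack searchlight features for every (source, time) cell.

    Returns (n_cells, n_epochs, k) with cells ordered source-major
    (cell = s * n_times + t).
    """
    n_src, k = member_rows.shape
    n_t = len(time_idx)
    n_ep = data.shape[0]
    out = np.empty((n_src * n_t, n_ep, k), dtype=np.float32)
    for ti, t in enumerate(time_idx):
        # (n_ep, n_src, k) -> per-source cells at this timepoint
        feats = data[:, member_rows, t]
        out[ti::n_t] = feats.transpose(1, 0, 2)
    return out


def searchlight_decode(
    epochs: EpochSet,
    neighborhoods: Neighborhoods,
    spec: ClassifierSpec,
    cv_folds: int = 5,
    evaluation_mode: str = "cv",
    time_idx: np.ndarray | None = None,
) -> AccuracyMap:
    """Searchlight classification accuracy at every (source, timepoint).

    ``time_idx`` optionally restricts decoding to a subset of timepoints
    (e.g. a decimated grid) without changing the stored epoch data.
    """
    if evaluation_mode not in ("cv", "train"):
        raise ValueError(f"unknown evaluation_mode {evaluation_mode!r}")
    member_rows = np.stack(
        [epochs.vertex_rows(m) for m in neighborhoods.members]
    )
    if time_idx is None:
        time_idx = np.arange(len(epochs.time_ms))
    time_idx = np.asarray(time_idx, dtype=np.int64)
    n_src = len(neighborhoods)
    n_t = len(time_idx)
    labels = epochs.labels
    X_all = _gather_features(epochs.data, member_rows, time_idx)

    if evaluation_mode == "train":
        mu = X_all.mean(axis=1, keepdims=True)
        sd = X_all.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        Xz = (X_all - mu) / sd
        params = fit_ffnn_batch(Xz, labels, spec, seed=spec.seed)
        pred = predict_ffnn_batch(params, Xz, spec.activation)
        acc = (pred == labels[None, :]).mean(axis=1)
        return AccuracyMap(
            subject_id=epochs.subject_id,
            values=acc.reshape(n_src, n_t),
            vertices=neighborhoods.centers.copy(),
            time_ms=epochs.time_ms[time_idx],
            evaluation_mode="train",
            provenance=epochs.provenance,
        )

    _check_folds(labels, cv_folds)
    skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=spec.seed)
    fold_acc = np.zeros((cv_folds, n_src * n_t))
    for fold, (tr, te) in enumerate(skf.split(np.zeros(len(labels)), labels)):
        Xtr = X_all[:, tr]
        Xte = X_all[:, te]
        mu = Xtr.mean(axis=1, keepdims=True)
        sd = Xtr.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        params = fit_ffnn_batch(
            (Xtr - mu) / sd, labels[tr], spec, seed=spec.seed + 7919 * fold
        )
        pred = predict_ffnn_batch(params, (Xte - mu) / sd, spec.activation)
        fold_acc[fold] = (pred == labels[te][None, :]).mean(axis=1)
    acc = fold_acc.mean(axis=0)
    return AccuracyMap(
        subject_id=epochs.subject_id,
        values=acc.reshape(n_src, n_t),
        vertices=neighborhoods.centers.copy(),
        time_ms=epochs.time_ms[time_idx],
        evaluation_mode="cv",
        provenance=epochs.provenance,
    )


def decode_residuals(
    residual_epochs: EpochSet,
    neighborhoods: Neighborhoods,
    spec: ClassifierSpec,
    cv_folds: int = 5,
    time_idx: np.ndarray | None = None,
) -> AccuracyMap:
    """Searchlight decoding of residualized epochs (provenance-tagged alias
    of :func:`searchlight_decode`)."""
    out = searchlight_decode(
        residual_epochs, neighborhoods, spec, cv_folds=cv_folds, time_idx=time_idx
    )
    out.provenance = "residual"
    return out
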