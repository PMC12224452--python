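"""Small feed-forward network used for all decoding analyses.

One hidden layer (two units by default), logistic activations, sigmoid
output trained on mean binary cross-entropy with an L2 penalty. Two trainers
share the architecture:

* :class:`FFNN` — a single network fit with L-BFGS (deterministic given a
  seed); used wherever one classifier is fit at a time (temporal
  generalization, embeddings, toy problems).
* :func:`fit_ffnn_batch` — many independent networks trained simultaneously
  with full-batch Adam for a fixed number of steps, vectorized over the
  batch axis; used by the searchlight sweep where ~10^5 fits per subject
  would otherwise dominate runtime.

Class convention throughout: 0 = noun, 1 = phrase. A predicted probability
of exactly 0.5 resolves to the noun class.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

__all__ = ["ClassifierSpec", "FFNN", "fit_ffnn_batch", "predict_ffnn_batch"]


@dataclass(frozen=True)
class ClassifierSpec:
    """Architecture and training configuration of the decoder.

    ``hidden_units=2`` with a single hidden layer is the study architecture.
    ``batch_iterations`` / ``batch_learning_rate`` apply only to the batched
    searchlight trainer.
    """

    hidden_units: int = 2
    activation: str = "logistic"
    alpha: float = 1e-4
    max_iterations: int = 500
    batch_iterations: int = 200
    batch_learning_rate: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.hidden_units < 1:
            raise ValueError("hidden_units must be >= 1")
        if self.activation not in ("logistic", "tanh"):
            raise ValueError(f"unknown activation {self.activation!r}")


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _act(z: np.ndarray, kind: str) -> np.ndarray:
    return _sigmoid(z) if kind == "logistic" else np.tanh(z)


def _act_grad(a: np.ndarray, kind: str) -> np.ndarray:
    return a * (1.0 - a) if kind == "logistic" else 1.0 - a * a


def _init_params(rng: np.random.Generator, k: int, h: int) -> np.ndarray:
    # Glorot-style uniform init, flattened (W1, b1, w2, b2)
    s1 = np.sqrt(6.0 / (k + h))
    s2 = np.sqrt(6.0 / (h + 1))
    return np.concatenate(
        [
            rng.uniform(-s1, s1, size=k * h),
            np.zeros(h),
            rng.uniform(-s2, s2, size=h),
            np.zeros(1),
        ]
    )


class FFNN:
    """Single feed-forward classifier trained with L-BFGS."""

    def __init__(self, spec: ClassifierSpec):
        self.spec = spec
        self._params: np.ndarray | None = None
        self._n_features: int | None = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "FFNN":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2:
            raise ValueError("features must be 2-D (items x dims)")
        if not np.all(np.isfinite(X)):
            raise ValueError("features contain non-finite values")
        classes, counts = np.unique(y, return_counts=True)
        if len(classes) < 2:
            raise ValueError(
                "training data contains a single class; need both noun (0) "
                "and phrase (1) items"
            )
        if counts.min() < 2:
            raise ValueError("need at least 2 items per class")
        n, k = X.shape
        h = self.spec.hidden_units
        kind = self.spec.activation
        alpha = self.spec.alpha

        def loss_grad(theta: np.ndarray):
            W1 = theta[: k * h].reshape(k, h)
            b1 = theta[k * h : k * h + h]
            w2 = theta[k * h + h : k * h + 2 * h]
            b2 = theta[-1]
            A1 = _act(X @ W1 + b1, kind)
            p = _sigmoid(A1 @ w2 + b2)
            eps = 1e-12
            loss = -np.mean(y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps))
            loss += 0.5 * alpha * (np.sum(W1 * W1) + np.sum(w2 * w2)) / n
            dz2 = (p - y) / n
            gw2 = A1.T @ dz2 + alpha * w2 / n
            gb2 = dz2.sum()
            dA1 = np.outer(dz2, w2)
            dz1 = dA1 * _act_grad(A1, kind)
            gW1 = X.T @ dz1 + alpha * W1 / n
            gb1 = dz1.sum(axis=0)
            grad = np.concatenate([gW1.ravel(), gb1, gw2, [gb2]])
            return loss, grad

        theta0 = _init_params(np.random.default_rng(self.spec.seed), k, h)
        res = minimize(
            loss_grad,
            theta0,
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": self.spec.max_iterations},
        )
        self._params = res.x
        self._n_features = k
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        if self._params is None:
            raise RuntimeError("classifier is not fitted")
        X = np.asarray(X, dtype=float)
        k, h = self._n_features, self.spec.hidden_units
        theta = self._params
        W1 = theta[: k * h].reshape(k, h)
        b1 = theta[k * h : k * h + h]
        w2 = theta[k * h + h : k * h + 2 * h]
        b2 = theta[-1]
        A1 = _act(X @ W1 + b1, self.spec.activation)
        return _sigmoid(A1 @ w2 + b2)

    def predict(self, X: np.ndarray) -> np.ndarray:
        # p == 0.5 exactly resolves to the noun class (label 0)
        return (self.predict_proba(X) > 0.5).astype(np.int64)


# ---------------------------------------------------------------------------
# batched trainer


def fit_ffnn_batch(
    X: np.ndarray, y: np.ndarray, spec: ClassifierSpec, seed: int
) -> dict[str, np.ndarray]:
    """Train C independent networks on ``X`` of shape (C, n, k), labels ``y``
    of shape (n,) shared across the batch. Full-batch Adam, fixed step count,
    deterministic given ``seed``. Returns the parameter arrays.
    """
    X = np.ascontiguousarray(X, dtype=np.float32)
    C, n, k = X.shape
    h = spec.hidden_units
    kind = spec.activation
    rng = np.random.default_rng(seed)
    s1 = np.sqrt(6.0 / (k + h))
    s2 = np.sqrt(6.0 / (h + 1))
    params = {
        "W1": rng.uniform(-s1, s1, size=(C, k, h)).astype(np.float32),
        "b1": np.zeros((C, 1, h), dtype=np.float32),
        "w2": rng.uniform(-s2, s2, size=(C, h, 1)).astype(np.float32),
        "b2": np.zeros((C, 1, 1), dtype=np.float32),
    }
    yb = np.asarray(y, dtype=np.float32).reshape(1, n, 1)
    alpha = np.float32(spec.alpha)
    lr = spec.batch_learning_rate
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    m = {key: np.zeros_like(v) for key, v in params.items()}
    v = {key: np.zeros_like(val) for key, val in params.items()}
    Xt = np.ascontiguousarray(X.transpose(0, 2, 1))
    for step in range(1, spec.batch_iterations + 1):
        A1 = _act(X @ params["W1"] + params["b1"], kind)  # (C, n, h)
        P = _sigmoid(A1 @ params["w2"] + params["b2"])  # (C, n, 1)
        dz2 = (P - yb) / np.float32(n)
        grads = {
            "w2": A1.transpose(0, 2, 1) @ dz2 + alpha * params["w2"] / n,
            "b2": dz2.sum(axis=1, keepdims=True),
        }
        dz1 = (dz2 @ params["w2"].transpose(0, 2, 1)) * _act_grad(A1, kind)
        grads["W1"] = Xt @ dz1 + alpha * params["W1"] / n
        grads["b1"] = dz1.sum(axis=1, keepdims=True)
        bc1 = 1.0 - beta1**step
        bc2 = 1.0 - beta2**step
        for key in params:
            g = grads[key]
            m[key] = beta1 * m[key] + (1 - beta1) * g
            v[key] = beta2 * v[key] + (1 - beta2) * g * g
            params[key] -= np.float32(lr) * (m[key] / bc1) / (
                np.sqrt(v[key] / bc2) + eps
            )
    return params


def predict_ffnn_batch(
    params: dict[str, np.ndarray], X: np.ndarray, activation: str = "logistic"
) -> np.ndarray:
    """Predicted labels, shape (C, m), for ``X`` of shape (C, m, k)."""
    X = np.ascontiguousarray(X, dtype=np.float32)
    A1 = _act(X @ params["W1"] + params["b1"], activation)
    P = _sigmoid(A1 @ params["w2"] + params["b2"])
    return (P[..., 0] > 0.5).astype(np.int64)
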