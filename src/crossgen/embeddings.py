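"""Embedding-side analyses of phrase vs. noun representations.

Operates on per-layer embedding vectors delivered by a provider (the
package ships only the synthetic generator; wiring a real transformer in is
an optional extension). Three operations mirror the neural analyses:
residualize the word-position confound out of the embeddings, measure the
per-layer cosine distance between class mean vectors, and train the small
feed-forward classifier in one context and test it in the other.
"""

from __future__ import annotations

import numpy as np

from ._ffnn import ClassifierSpec
from .decoding import fit_classifier
from .simulate import EmbeddingSet, NOUN, PHRASE

__all__ = [
    "EmbeddingSet",
    "position_residualize",
    "layer_cosine_distance",
    "cross_context_classify",
]


def position_residualize(emb: EmbeddingSet) -> EmbeddingSet:
    """Regress the binary word-position indicator out of every embedding
    dimension (per layer, with intercept) and keep the residuals.

    Afterwards the first-token and later-token group means coincide in every
    dimension, removing the confound that single nouns are sentence-initial
    while phrase-final nouns are not.
    """
    pos = (emb.meta["word_position"].to_numpy() == "first").astype(float)
    if len(np.unique(pos)) < 2:
        raise ValueError(
            "only one word-position value present; nothing to residualize"
        )
    n = len(pos)
    X = np.column_stack([np.ones(n), pos])
    values = emb.values.copy()
    for layer in range(emb.n_layers):
        beta, *_ = np.linalg.lstsq(X, values[layer], rcond=None)
        values[layer] = values[layer] - X @ beta
    return EmbeddingSet(values=values, meta=emb.meta.copy())


def layer_cosine_distance(emb: EmbeddingSet, context: str) -> np.ndarray:
    """Per-layer cosine distance (1 - cosine similarity) between the phrase
    and noun mean vectors within one context."""
    in_ctx = emb.meta["context"].to_numpy() == context
    labels = emb.meta["label"].to_numpy()
    sel_p = in_ctx & (labels == PHRASE)
    sel_n = in_ctx & (labels == NOUN)
    if not sel_p.any() or not sel_n.any():
        raise ValueError(f"context {context!r} lacks one of the classes")
    out = np.empty(emb.n_layers)
    for layer in range(emb.n_layers):
        mp = emb.values[layer, sel_p].mean(axis=0)
        mn = emb.values[layer, sel_n].mean(axis=0)
        norm = np.linalg.norm(mp) * np.linalg.norm(mn)
        if norm == 0:
            raise ValueError(f"zero-norm class mean at layer {layer}")
        out[layer] = 1.0 - float(mp @ mn) / norm
    return out


def cross_context_classify(
    emb: EmbeddingSet,
    train_context: str,
    layer: int = -1,
    spec: ClassifierSpec = ClassifierSpec(),
) -> tuple[float, float]:
    """Fit the classifier on one context's items at ``layer`` (default: the
    last layer) and report (training-set accuracy, other-context accuracy).

    Features are standardized with training-context statistics. Apply
    :func:`position_residualize` first so the word-position confound cannot
    carry the classification.
    """
    if not (-emb.n_layers <= layer < emb.n_layers):
        raise ValueError(f"layer {layer} out of range for {emb.n_layers} layers")
    contexts = emb.meta["context"].to_numpy()
    known = set(contexts)
    if train_context not in known:
        raise ValueError(f"unknown context {train_context!r}; have {sorted(known)}")
    test_context = next(c for c in sorted(known) if c != train_context)
    labels = emb.meta["label"].to_numpy()
    tr = contexts == train_context
    te = contexts == test_context
    X = emb.values[layer]
    mu = X[tr].mean(axis=0)
    sd = X[tr].std(axis=0)
    sd[sd == 0] = 1.0
    model = fit_classifier((X[tr] - mu) / sd, labels[tr], spec)
    train_acc = float((model.predict((X[tr] - mu) / sd) == labels[tr]).mean())
    test_acc = float((model.predict((X[te] - mu) / sd) == labels[te]).mean())
    return train_acc, test_acc
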