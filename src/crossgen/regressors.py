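"""Word-level confound regressors and mass-univariate residualization.

Seven properties of naturalistic stimuli that correlate with — and could
mimic — a composition effect are quantified per target word:

* ``peak_rms``, ``peak_f0`` — maximum RMS intensity / fundamental frequency
  over the word's 10-ms prosody frames;
* ``word_rate`` — word duration in ms divided by its letter count;
* ``log_frequency`` — log unigram count (natural log by default);
* ``surprisal`` — negative log probability of the word given its preceding
  sentence context (bits by default), from a pluggable language-model
  provider;
* ``valence``, ``arousal`` — per-sentence rater means broadcast to member
  words.

The table is z-scored (columns to mean 0, SD 1) and regressed out of the
naturalistic source estimates by ordinary least squares per (source,
timepoint) across epochs, with an intercept; the dependent variable is
z-scored per cell. Residuals are exactly orthogonal to every regressor,
so re-decoding them tests whether a decodable class difference survives
the confounds.
"""

from __future__ import annotations

import warnings
from dataclasses import replace

import numpy as np
import pandas as pd

from .simulate import EpochSet, REGRESSOR_NAMES

__all__ = [
    "REGRESSOR_NAMES",
    "peak_prosody",
    "word_rate",
    "log_frequency",
    "surprisal",
    "lm_surprisal",
    "UniformVocabularyProvider",
    "propagate_sentence_emotion",
    "isc",
    "zscore_columns",
    "collinearity_report",
    "residualize_epochs",
    "build_regressor_table",
]


# ---------------------------------------------------------------------------
# individual regressors


def peak_prosody(frames: pd.DataFrame, word_table: pd.DataFrame) -> pd.DataFrame:
    """Peak RMS intensity and peak f0 within each word's interval.

    A frame belongs to a word when its start lies in
    ``[onset, onset + duration)``.
    """
    t = frames["frame_onset_ms"].to_numpy()
    rows = []
    for _, w in word_table.iterrows():
        sel = (t >= w["onset_ms"]) & (t < w["onset_ms"] + w["duration_ms"])
        if not sel.any():
            raise ValueError(
                f"word {w['word_id']} ({w.get('token', '?')}) has no prosody "
                "frame inside its interval"
            )
        rows.append(
            {
                "word_id": w["word_id"],
                "peak_rms": frames.loc[sel, "rms"].max(),
                "peak_f0": frames.loc[sel, "f0"].max(),
            }
        )
    return pd.DataFrame(rows)


def word_rate(duration_ms, n_letters):
    """Presentation rate: word duration in ms per letter."""
    duration_ms = np.asarray(duration_ms, dtype=float)
    n_letters = np.asarray(n_letters)
    if np.any(n_letters < 1):
        raise ValueError("n_letters must be >= 1")
    if np.any(duration_ms <= 0):
        raise ValueError("duration_ms must be positive")
    out = duration_ms / n_letters
    return out.item() if out.ndim == 0 else out


def log_frequency(count, base: float | None = None):
    """Log-transformed unigram count (natural log unless ``base`` given)."""
    count = np.asarray(count, dtype=float)
    if np.any(count < 1):
        raise ValueError("unigram count must be >= 1 (no zero-count smoothing)")
    out = np.log(count)
    if base is not None:
        out = out / np.log(base)
    return out.item() if out.ndim == 0 else out


def surprisal(probability, base: float = 2.0):
    """Negative log probability; base 2 gives bits."""
    probability = np.asarray(probability, dtype=float)
    if np.any(probability <= 0) or np.any(probability > 1):
        raise ValueError("probability must lie in (0, 1]")
    out = -np.log(probability) / np.log(base)
    return out.item() if out.ndim == 0 else out


class UniformVocabularyProvider:
    """Language-model provider assigning 1/vocab_size to every word."""

    def __init__(self, vocab_size: int):
        if vocab_size < 1:
            raise ValueError("vocab_size must be >= 1")
        self.vocab_size = vocab_size

    def __call__(self, context: list[str], word: str) -> float:
        return 1.0 / self.vocab_size


def lm_surprisal(word_table: pd.DataFrame, provider, base: float = 2.0) -> np.ndarray:
    """Per-word surprisal from ``provider(context_tokens, word) -> P``.

    Context is the preceding tokens of the same sentence; it resets at
    sentence boundaries (the first word of each sentence sees an empty
    context).
    """
    out = np.empty(len(word_table))
    context: list[str] = []
    last_sentence = None
    for i, (_, w) in enumerate(word_table.iterrows()):
        if w["sentence_index"] != last_sentence:
            context = []
            last_sentence = w["sentence_index"]
        p = provider(list(context), w["token"])
        try:
            out[i] = surprisal(p, base=base)
        except ValueError as err:
            raise ValueError(
                f"provider returned invalid probability {p!r} for word index "
                f"{i} ({w['token']!r}): {err}"
            ) from None
        context.append(w["token"])
    return out


def propagate_sentence_emotion(
    valence_ratings: np.ndarray,
    arousal_ratings: np.ndarray,
    word_table: pd.DataFrame,
) -> pd.DataFrame:
    """Broadcast per-sentence rater-mean valence/arousal to member words."""
    val = np.asarray(valence_ratings, dtype=float)
    aro = np.asarray(arousal_ratings, dtype=float)
    val_mean = val.mean(axis=0)
    aro_mean = aro.mean(axis=0)
    sidx = word_table["sentence_index"].to_numpy()
    if sidx.max() >= len(val_mean) or sidx.max() >= len(aro_mean):
        raise ValueError(
            f"sentence index {sidx.max()} missing from the ratings matrix"
        )
    return pd.DataFrame(
        {
            "word_id": word_table["word_id"],
            "valence": val_mean[sidx],
            "arousal": aro_mean[sidx],
        }
    )


def isc(ratings: np.ndarray, strict: bool = False) -> tuple[np.ndarray, float]:
    """Inter-subject correlation of a raters x sentences matrix.

    Each rater's ratings are correlated with the across-rater mean; ISC is
    the mean of those Pearson r values. Zero-variance raters are excluded
    with a warning (or rejected under ``strict=True``).
    """
    ratings = np.asarray(ratings, dtype=float)
    if ratings.ndim != 2 or ratings.shape[0] < 2:
        raise ValueError("ratings must be (>=2 raters, sentences)")
    if ratings.shape[1] < 3:
        raise ValueError("need >= 3 sentences")
    sd = ratings.std(axis=1)
    if np.any(sd == 0):
        bad = np.flatnonzero(sd == 0)
        if strict:
            raise ValueError(f"raters {bad.tolist()} have zero variance")
        warnings.warn(
            f"excluding zero-variance raters {bad.tolist()} from ISC",
            stacklevel=2,
        )
        ratings = ratings[sd > 0]
    grand = ratings.mean(axis=0)
    r = np.array([np.corrcoef(row, grand)[0, 1] for row in ratings])
    return r, float(r.mean())


# ---------------------------------------------------------------------------
# table-level operations


def _regressor_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c in REGRESSOR_NAMES]


def zscore_columns(table: pd.DataFrame, columns: list[str] | None = None) -> pd.DataFrame:
    """Z-score regressor columns (mean 0, SD 1, n-1 denominator).

    Idempotent; zero-SD columns are rejected by name. Non-regressor columns
    (``word_id``, ``sentence_index``...) pass through unchanged.
    """
    out = table.copy()
    cols = columns if columns is not None else _regressor_columns(table)
    for c in cols:
        x = out[c].to_numpy(dtype=float)
        sd = x.std(ddof=1)
        if sd == 0:
            raise ValueError(f"column {c!r} has zero variance; cannot z-score")
        out[c] = (x - x.mean()) / sd
    out.attrs["zscored"] = True
    return out


def collinearity_report(
    table: pd.DataFrame, threshold: float = 0.7
) -> tuple[pd.DataFrame, float, list[tuple[str, str, float]]]:
    """Pairwise Pearson correlations among regressors.

    Returns (correlation matrix, max off-diagonal |r|, flagged pairs with
    |r| above ``threshold``).
    """
    cols = _regressor_columns(table)
    corr = table[cols].corr(method="pearson")
    flagged = []
    max_abs = 0.0
    for i, a in enumerate(cols):
        for b in cols[i + 1 :]:
            r = float(corr.loc[a, b])
            max_abs = max(max_abs, abs(r))
            if abs(r) > threshold:
                flagged.append((a, b, r))
    return corr, max_abs, flagged


def _check_zscored(table: pd.DataFrame, cols: list[str]) -> None:
    for c in cols:
        x = table[c].to_numpy(dtype=float)
        if abs(x.mean()) > 1e-8 or abs(x.std(ddof=1) - 1.0) > 1e-6:
            raise ValueError(
                f"regressor column {c!r} is not z-scored; call zscore_columns first"
            )


def residualize_epochs(epochs: EpochSet, table: pd.DataFrame) -> EpochSet:
    """OLS residuals of the z-scored source estimates on the regressors.

    Per (source, timepoint): z-score the epoch values across epochs, regress
    on the seven z-scored regressors plus an intercept, keep the residuals.
    Rows must align with the epochs via ``word_id``.
    """
    cols = _regressor_columns(table)
    if not cols:
        raise ValueError("table contains no regressor columns")
    _check_zscored(table, cols)
    if epochs.word_ids is None:
        raise ValueError("epochs carry no word_ids; cannot align the table")
    if len(table) != epochs.n_epochs or not np.array_equal(
        table["word_id"].to_numpy(), epochs.word_ids
    ):
        raise ValueError("table word_id rows are not aligned with epoch word_ids")
    n = epochs.n_epochs
    if n <= len(cols) + 1:
        raise ValueError(
            f"need more epochs ({n}) than regressors + intercept ({len(cols) + 1})"
        )
    X = np.column_stack([np.ones(n)] + [table[c].to_numpy(dtype=float) for c in cols])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify columns beyond the independent set via pivoted QR
        from scipy.linalg import qr

        _, _, piv = qr(X, pivoting=True, mode="economic")
        dependent = [cols[i - 1] for i in sorted(piv[rank:]) if i > 0]
        raise ValueError(
            f"rank-deficient regressor design; dependent columns: {dependent}"
        )
    Y = epochs.data.reshape(n, -1)
    if epochs.provenance == "residual":
        # already-residualized input: plain OLS (re-z-scoring would rescale
        # the residuals per cell and break idempotence)
        Z = Y
    else:
        mu = Y.mean(axis=0)
        sd = Y.std(axis=0, ddof=1)
        sd_safe = np.where(sd == 0, 1.0, sd)
        Z = (Y - mu) / sd_safe
    beta, *_ = np.linalg.lstsq(X, Z, rcond=None)
    resid = Z - X @ beta
    return replace(
        epochs,
        data=resid.reshape(epochs.data.shape),
        provenance="residual",
    )


def build_regressor_table(
    word_table: pd.DataFrame,
    frames: pd.DataFrame,
    valence_ratings: np.ndarray,
    arousal_ratings: np.ndarray,
    provider,
    surprisal_base: float = 2.0,
    frequency_base: float | None = None,
) -> pd.DataFrame:
    """Assemble the full seven-column regressor table from stimulus inputs."""
    prosody = peak_prosody(frames, word_table)
    emotion = propagate_sentence_emotion(valence_ratings, arousal_ratings, word_table)
    table = word_table[["word_id", "sentence_index"]].copy()
    table = table.merge(prosody, on="word_id").merge(emotion, on="word_id")
    table["word_rate"] = word_rate(
        word_table["duration_ms"].to_numpy(), word_table["n_letters"].to_numpy()
    )
    table["log_frequency"] = log_frequency(
        word_table["unigram_count"].to_numpy(), base=frequency_base
    )
    table["surprisal"] = lm_surprisal(word_table, provider, base=surprisal_base)
    return table[["word_id", "sentence_index", *REGRESSOR_NAMES]]
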