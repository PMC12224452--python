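"""Confound regressors: construction formulas, ISC, z-scoring, residualization."""

import numpy as np
import pandas as pd
import pytest

from crossgen.regressors import (
    REGRESSOR_NAMES,
    UniformVocabularyProvider,
    build_regressor_table,
    collinearity_report,
    isc,
    lm_surprisal,
    log_frequency,
    peak_prosody,
    propagate_sentence_emotion,
    residualize_epochs,
    surprisal,
    word_rate,
    zscore_columns,
)
from crossgen.simulate import (
    ConfoundSpec,
    SimConfig,
    resolve_geometry,
    simulate_naturalistic_with_confounds,
    simulate_prosody_frames,
    simulate_ratings,
    simulate_word_table,
)


class TestScalarFormulas:
    @pytest.mark.parametrize(
        "duration,letters,expected", [(500, 5, 100.0), (300, 3, 100.0), (150, 10, 15.0)]
    )
    def test_word_rate(self, duration, letters, expected):
        assert word_rate(duration, letters) == expected

    def test_word_rate_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            word_rate(500, 0)
        with pytest.raises(ValueError):
            word_rate(0, 5)

    def test_log_frequency(self):
        assert log_frequency(1) == 0.0
        assert log_frequency(np.e**2) == pytest.approx(2.0)
        counts = np.array([10, 100, 1000])
        assert np.all(np.diff(log_frequency(counts)) > 0)
        with pytest.raises(ValueError):
            log_frequency(0)

    @pytest.mark.parametrize("p,expected", [(1.0, 0.0), (0.5, 1.0), (0.25, 2.0)])
    def test_surprisal_bits(self, p, expected):
        assert surprisal(p) == pytest.approx(expected)

    def test_surprisal_domain(self):
        for bad in (0.0, -0.1, 1.5):
            with pytest.raises(ValueError):
                surprisal(bad)


class TestPeakProsody:
    def test_peak_is_max_of_covered_frames(self):
        frames = pd.DataFrame(
            {"frame_onset_ms": [0, 10, 20], "rms": [10, 20, 15], "f0": [1, 2, 3]}
        )
        words = pd.DataFrame(
            {"word_id": [0], "onset_ms": [0], "duration_ms": [30], "token": ["x"]}
        )
        out = peak_prosody(frames, words)
        assert out.loc[0, "peak_rms"] == 20 and out.loc[0, "peak_f0"] == 3

    def test_constant_frames_give_constant_peaks(self):
        words = simulate_word_table(5, 2, seed=0)
        span = (words["onset_ms"] + words["duration_ms"]).max()
        t = np.arange(0, span + 10, 10)
        frames = pd.DataFrame({"frame_onset_ms": t, "rms": 7.0, "f0": 200.0})
        out = peak_prosody(frames, words)
        assert (out["peak_rms"] == 7.0).all() and (out["peak_f0"] == 200.0).all()

    def test_recovers_generator_ground_truth_exactly(self):
        words = simulate_word_table(15, 3, seed=8)
        frames, truth = simulate_prosody_frames(words, seed=8)
        out = peak_prosody(frames, words).merge(truth, on="word_id")
        assert np.array_equal(out["peak_rms"], out["true_peak_rms"])
        assert np.array_equal(out["peak_f0"], out["true_peak_f0"])

    def test_uncovered_word_rejected(self):
        frames = pd.DataFrame({"frame_onset_ms": [0], "rms": [1.0], "f0": [1.0]})
        words = pd.DataFrame(
            {"word_id": [3], "onset_ms": [500], "duration_ms": [100], "token": ["y"]}
        )
        with pytest.raises(ValueError, match="word 3"):
            peak_prosody(frames, words)


class TestLMSurprisal:
    def test_uniform_vocabulary_gives_constant_bits(self):
        words = simulate_word_table(10, 2, seed=1)
        out = lm_surprisal(words, UniformVocabularyProvider(1024))
        assert np.allclose(out, 10.0)

    def test_deterministic_provider_gives_zero(self):
        words = simulate_word_table(6, 2, seed=1)
        out = lm_surprisal(words, lambda ctx, w: 1.0)
        assert np.array_equal(out, np.zeros(6))

    def test_context_resets_at_sentence_boundaries(self):
        words = simulate_word_table(9, 3, seed=2)
        seen = []
        def provider(ctx, w):
            seen.append(list(ctx))
            return 0.5
        lm_surprisal(words, provider)
        starts = words.groupby("sentence_index").head(1).index.tolist()
        for i in starts:
            assert seen[i] == []
        # non-initial words see their predecessors
        assert all(len(seen[i]) > 0 for i in range(9) if i not in starts)

    def test_invalid_probability_names_word(self):
        words = simulate_word_table(4, 1, seed=3)
        with pytest.raises(ValueError, match="word index 2"):
            lm_surprisal(words, lambda ctx, w: 2.0 if len(ctx) == 2 else 0.5)


class TestEmotionAndISC:
    def test_same_sentence_same_values(self):
        words = pd.DataFrame({"word_id": [0, 1, 2], "sentence_index": [0, 0, 1]})
        val = np.array([[1.0, 4.0], [3.0, 2.0]])
        aro = np.array([[5.0, 1.0], [7.0, 3.0]])
        out = propagate_sentence_emotion(val, aro, words)
        assert out.loc[0, "valence"] == out.loc[1, "valence"] == 2.0
        assert out.loc[2, "arousal"] == 2.0

    def test_missing_sentence_rejected(self):
        words = pd.DataFrame({"word_id": [0], "sentence_index": [5]})
        with pytest.raises(ValueError, match="missing"):
            propagate_sentence_emotion(np.ones((2, 3)), np.ones((2, 3)), words)

    def test_identical_raters_isc_one(self):
        ratings = np.tile(np.array([1.0, 3.0, 2.0, 5.0]), (4, 1))
        r, mean_isc = isc(ratings)
        assert np.allclose(r, 1.0) and mean_isc == 1.0

    def test_rater_equal_to_mean_has_r_one(self, rng):
        others = rng.normal(size=(3, 20))
        mean_of_others = others.mean(axis=0)
        # rater 0 set to the overall mean of the final matrix: solve by
        # construction — rater 0 = mean of all 4 implies rater0 = mean(others)
        ratings = np.vstack([mean_of_others, others])
        r, _ = isc(ratings)
        assert r[0] == pytest.approx(1.0)

    def test_closed_form_attenuation(self):
        """ISC with signal_sd = noise_sd approaches sqrt((1 + 1/R) / 2)."""
        R = 30
        ratings = simulate_ratings(R, 10000, signal_sd=1.0, noise_sd=1.0, seed=6)
        _, mean_isc = isc(ratings)
        expected = np.sqrt((1.0 + 1.0 / R) / 2.0)
        assert abs(mean_isc - expected) < 0.05

    def test_no_shared_signal_isc_is_self_correlation_floor(self):
        """Without shared signal each rater still correlates ~1/sqrt(R) with
        the grand mean (which contains the rater); the ISC floor shrinks to
        zero only as raters grow."""
        R = 10
        ratings = simulate_ratings(R, 5000, signal_sd=0.0, noise_sd=1.0, seed=7)
        _, mean_isc = isc(ratings)
        assert abs(mean_isc - 1.0 / np.sqrt(R)) < 0.05
        R = 100
        _, floor = isc(simulate_ratings(R, 5000, 0.0, 1.0, seed=8))
        assert abs(floor) < 0.15

    def test_zero_variance_rater_excluded(self):
        ratings = np.vstack([np.ones(5), [1.0, 2, 3, 4, 5], [2.0, 1, 4, 3, 5]])
        with pytest.warns(UserWarning, match="zero-variance"):
            r, _ = isc(ratings)
        assert len(r) == 2
        with pytest.raises(ValueError):
            isc(ratings, strict=True)


def _table(rng, n=50):
    data = {name: rng.standard_normal(n) for name in REGRESSOR_NAMES}
    return pd.DataFrame({"word_id": np.arange(n), "sentence_index": 0, **data})


class TestZScoreAndCollinearity:
    def test_zscore_simple_column(self):
        t = pd.DataFrame({"word_id": [0, 1, 2], "surprisal": [1.0, 2.0, 3.0]})
        z = zscore_columns(t)
        assert np.allclose(z["surprisal"], [-1.0, 0.0, 1.0])

    def test_zscore_idempotent_and_normalized(self, rng):
        t = _table(rng)
        z1 = zscore_columns(t)
        z2 = zscore_columns(z1)
        for c in REGRESSOR_NAMES:
            assert abs(z1[c].mean()) < 1e-9
            assert abs(z1[c].std(ddof=1) - 1.0) < 1e-9
            assert np.allclose(z1[c], z2[c])

    def test_zero_variance_column_named(self, rng):
        t = _table(rng)
        t["arousal"] = 3.0
        with pytest.raises(ValueError, match="arousal"):
            zscore_columns(t)

    def test_duplicated_column_flagged(self, rng):
        t = _table(rng)
        t["arousal"] = t["valence"]
        corr, max_abs, flagged = collinearity_report(t)
        assert max_abs == pytest.approx(1.0)
        assert ("valence", "arousal", pytest.approx(1.0)) in [
            (a, b, pytest.approx(r)) for a, b, r in flagged
        ]
        assert np.allclose(np.diag(corr.to_numpy()), 1.0)
        assert np.allclose(corr.to_numpy(), corr.to_numpy().T)

    def test_independent_columns_unflagged(self, rng):
        t = _table(rng, n=2000)
        corr, max_abs, flagged = collinearity_report(t)
        assert max_abs < 0.1 and flagged == []


@pytest.fixture(scope="module")
def nat_setup():
    cfg = SimConfig(
        n_epochs_per_class=30, mesh_level=0, mask_regions=("LATL", "LMTG", "LIFG",
                                                           "LvmPFC", "LAG", "LSMG"),
        master_seed=31,
        confounds=(
            ConfoundSpec(
                regressor_name="surprisal", class_shift=1.5,
                loading_vertices=(0, 1, 2), loading_window=(500, 700),
                loading_gain=5.0, pattern_seed=2,
            ),
        ),
    )
    mesh, mask = resolve_geometry(cfg)
    epochs, table = simulate_naturalistic_with_confounds(cfg, "sub00", mesh, mask)
    return epochs, table


class TestResidualize:
    def test_exact_linear_data_leaves_zero_residuals(self, nat_setup, rng):
        from dataclasses import replace

        epochs, table = nat_setup
        z = zscore_columns(table)
        # construct data exactly linear in two regressors
        x = z["surprisal"].to_numpy()[:, None, None]
        y = z["valence"].to_numpy()[:, None, None]
        linear = replace(epochs, data=np.broadcast_to(
            2.0 * x - 1.0 * y + 0.5, epochs.data.shape
        ).copy())
        resid = residualize_epochs(linear, z)
        assert np.abs(resid.data).max() < 1e-9

    def test_residuals_orthogonal_to_regressors(self, nat_setup):
        epochs, table = nat_setup
        z = zscore_columns(table)
        resid = residualize_epochs(epochs, z)
        flat = resid.data.reshape(epochs.n_epochs, -1)
        for c in REGRESSOR_NAMES:
            dots = z[c].to_numpy() @ flat
            assert np.abs(dots).max() < 1e-6

    def test_idempotent(self, nat_setup):
        epochs, table = nat_setup
        z = zscore_columns(table)
        r1 = residualize_epochs(epochs, z)
        r2 = residualize_epochs(r1, z)
        assert np.abs(r1.data - r2.data).max() < 1e-8

    def test_misaligned_word_ids_rejected(self, nat_setup):
        epochs, table = nat_setup
        z = zscore_columns(table).iloc[::-1].reset_index(drop=True)
        with pytest.raises(ValueError, match="not aligned"):
            residualize_epochs(epochs, z)

    def test_unscored_table_rejected(self, nat_setup):
        epochs, table = nat_setup
        with pytest.raises(ValueError, match="z-scored"):
            residualize_epochs(epochs, table)

    def test_rank_deficient_design_names_columns(self, nat_setup):
        epochs, table = nat_setup
        t = table.copy()
        t["arousal"] = t["valence"] * 2.0
        z = zscore_columns(t)
        with pytest.raises(ValueError, match="rank-deficient"):
            residualize_epochs(epochs, z)

    def test_confound_only_signal_removed_genuine_preserved(self, nat_setup):
        """The class-correlated confound's late loading disappears from the
        residuals: class mean difference in the loading window collapses."""
        epochs, table = nat_setup
        z = zscore_columns(table)
        resid = residualize_epochs(epochs, z)
        labels = epochs.labels
        win = (epochs.time_ms >= 500) & (epochs.time_ms < 700)

        def class_gap(ep):
            d = ep.data[:, :3][:, :, win]
            # normalize away the per-cell scale introduced by z-scoring
            scale = ep.data.std()
            return abs(
                d[labels == 1].mean() - d[labels == 0].mean()
            ) / scale

        assert class_gap(resid) < 0.25 * class_gap(epochs)


def test_build_regressor_table_end_to_end():
    words = simulate_word_table(24, 6, seed=12)
    frames, _ = simulate_prosody_frames(words, seed=12)
    val = simulate_ratings(5, 6, 1.0, 0.3, seed=1)
    aro = simulate_ratings(5, 6, 1.0, 0.3, seed=2)
    table = build_regressor_table(
        words, frames, val, aro, UniformVocabularyProvider(256)
    )
    assert list(table.columns) == ["word_id", "sentence_index", *REGRESSOR_NAMES]
    assert np.allclose(table["surprisal"], 8.0)  # log2(256)
    assert np.isfinite(table[list(REGRESSOR_NAMES)].to_numpy()).all()
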