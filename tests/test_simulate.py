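"""Synthetic data generator: determinism, shapes, and generative contracts."""

import numpy as np
import pytest
from scipy import stats as sps

from crossgen.geometry import ConfigurationError
from crossgen.simulate import (
    ConfoundSpec,
    EffectSpec,
    SimConfig,
    epoch_times_ms,
    resolve_geometry,
    simulate_epochs,
    simulate_naturalistic_with_confounds,
    simulate_prosody_frames,
    simulate_ratings,
    simulate_embeddings,
    simulate_word_table,
    PHRASE,
)


@pytest.fixture(scope="module")
def geo1():
    cfg = SimConfig(mesh_level=1)
    return resolve_geometry(cfg)


def test_epoch_grid_is_175_samples_at_5ms():
    t = epoch_times_ms()
    assert len(t) == 175
    assert t[0] == 0 and t[-1] == 870
    assert np.all(np.diff(t) == 5)


def test_epochs_shape_and_determinism(geo1):
    mesh, mask = geo1
    cfg = SimConfig(n_epochs_per_class=10, mesh_level=1, master_seed=42)
    a = simulate_epochs(cfg, "two_word", "sub00", mesh, mask)
    b = simulate_epochs(cfg, "two_word", "sub00", mesh, mask)
    assert a.data.shape == (20, len(mask), 175)
    assert np.array_equal(a.data, b.data)
    # different subject or paradigm changes the draw
    c = simulate_epochs(cfg, "two_word", "sub01", mesh, mask)
    d = simulate_epochs(cfg, "naturalistic", "sub00", mesh, mask)
    assert not np.array_equal(a.data, c.data)
    assert not np.array_equal(a.data, d.data)


def test_null_simulation_rejects_at_nominal_rate(geo1):
    """With no effect, per-cell two-sample t-tests reject ~5% of the time."""
    mesh, mask = geo1
    cfg = SimConfig(n_epochs_per_class=100, mesh_level=1, master_seed=7)
    ep = simulate_epochs(cfg, "two_word", "sub00", mesh, mask)
    noun = ep.data[ep.labels == 0]
    phrase = ep.data[ep.labels == 1]
    _, p = sps.ttest_ind(phrase, noun, axis=0)
    rate = (p < 0.05).mean()
    assert 0.02 < rate < 0.09


def test_effect_mean_difference_matches_generative_formula(geo1):
    """Class mean difference at an effect vertex equals amplitude x pattern
    weight, to within sampling error."""
    mesh, mask = geo1
    verts = tuple(int(v) for v in mask.vertices[:5])
    eff = EffectSpec(vertices=verts, time_window=(200, 340), amplitude=5.0,
                     pattern_seed=3)
    cfg = SimConfig(
        n_epochs_per_class=400, mesh_level=1, master_seed=11,
        effects={"two_word": [eff]},
    )
    ep = simulate_epochs(cfg, "two_word", "sub00", mesh, mask)
    w = eff.pattern()
    v_star = int(np.argmax(np.abs(w)))  # strongest-loading vertex
    rows = ep.vertex_rows(np.array(verts))
    col = np.flatnonzero((ep.time_ms >= 200) & (ep.time_ms < 340))[3]
    diff = (
        ep.data[ep.labels == 1, rows[v_star], col].mean()
        - ep.data[ep.labels == 0, rows[v_star], col].mean()
    )
    expected = 5.0 * w[v_star]
    assert abs(diff - expected) < 0.1 * abs(expected)


def test_effect_outside_mask_rejected(geo1):
    mesh, mask = geo1
    cfg = SimConfig(
        mesh_level=1,
        mask_regions=("LATL",),
        effects={"two_word": [EffectSpec(vertices=(9999,), time_window=(0, 100),
                                         amplitude=1.0)]},
    )
    with pytest.raises(ConfigurationError, match="outside the mask"):
        simulate_epochs(cfg, "two_word", "sub00")


class TestNaturalisticConfounds:
    def test_inert_confounds_leave_data_untouched(self, geo1):
        mesh, mask = geo1
        base = SimConfig(n_epochs_per_class=8, mesh_level=1, master_seed=5)
        with_conf = SimConfig(
            n_epochs_per_class=8, mesh_level=1, master_seed=5,
            confounds=(ConfoundSpec(regressor_name="surprisal", class_shift=0.0,
                                    loading_gain=0.0),),
        )
        plain = simulate_epochs(base, "naturalistic", "sub00", mesh, mask)
        ep, table = simulate_naturalistic_with_confounds(with_conf, "sub00", mesh, mask)
        assert np.array_equal(plain.data, ep.data)
        assert len(table) == ep.n_epochs
        assert np.array_equal(table["word_id"].to_numpy(), ep.word_ids)

    def test_class_shift_moves_regressor_mean(self, geo1):
        mesh, mask = geo1
        cfg = SimConfig(
            n_epochs_per_class=2000, mesh_level=1, master_seed=5,
            confounds=(ConfoundSpec(regressor_name="valence", class_shift=1.5),),
        )
        ep, table = simulate_naturalistic_with_confounds(cfg, "sub00", mesh, mask)
        shift = (
            table.loc[ep.labels == PHRASE, "valence"].mean()
            - table.loc[ep.labels == 0, "valence"].mean()
        )
        assert abs(shift - 1.5) < 0.15
        # unshifted regressors stay centered
        assert abs(table["peak_rms"].mean()) < 0.1

    def test_loading_adds_signal_in_window(self, geo1):
        mesh, mask = geo1
        spec = ConfoundSpec(
            regressor_name="arousal",
            loading_vertices=tuple(int(v) for v in mask.vertices[:4]),
            loading_window=(500, 700),
            loading_gain=3.0,
            pattern_seed=9,
        )
        cfg = SimConfig(n_epochs_per_class=100, mesh_level=1, master_seed=5,
                        confounds=(spec,))
        ep, table = simulate_naturalistic_with_confounds(cfg, "sub00", mesh, mask)
        base = simulate_epochs(cfg, "naturalistic", "sub00", mesh, mask)
        delta = ep.data - base.data
        in_win = (ep.time_ms >= 500) & (ep.time_ms < 700)
        assert np.abs(delta[:, :4][:, :, in_win]).max() > 0
        assert np.abs(delta[:, :, ~in_win]).max() == 0
        # added component is proportional to the z-scored regressor
        z = table["arousal"].to_numpy()
        z = (z - z.mean()) / z.std(ddof=1)
        w = spec.pattern()
        col = np.flatnonzero(in_win)[0]
        assert np.allclose(delta[:, 0, col], 3.0 * z * w[0], atol=1e-10)


class TestWordTable:
    def test_single_word(self):
        t = simulate_word_table(1, 1, seed=0)
        assert len(t) == 1 and t.loc[0, "onset_ms"] == 0

    def test_intervals_ordered_and_disjoint(self):
        t = simulate_word_table(50, 5, seed=1)
        ends = t["onset_ms"] + t["duration_ms"]
        assert (t["onset_ms"].to_numpy()[1:] >= ends.to_numpy()[:-1]).all()
        assert t["duration_ms"].between(150, 600).all()
        assert t["n_letters"].between(2, 10).all()
        assert t["sentence_index"].nunique() == 5

    def test_same_seed_identical(self):
        a = simulate_word_table(20, 4, seed=9)
        b = simulate_word_table(20, 4, seed=9)
        assert a.equals(b)

    def test_bad_counts_rejected(self):
        with pytest.raises(ValueError):
            simulate_word_table(3, 5, seed=0)


class TestProsodyFrames:
    def test_frame_count_covers_span(self):
        words = simulate_word_table(12, 3, seed=2)
        frames, truth = simulate_prosody_frames(words, frame_ms=10, seed=2)
        span = (words["onset_ms"] + words["duration_ms"]).max()
        assert len(frames) == int(np.ceil(span / 10))
        assert len(truth) == 12

    def test_truth_is_max_frame_inside_word(self):
        words = simulate_word_table(8, 2, seed=3)
        frames, truth = simulate_prosody_frames(words, seed=3)
        t = frames["frame_onset_ms"].to_numpy()
        for _, w in words.iterrows():
            sel = (t >= w["onset_ms"]) & (t < w["onset_ms"] + w["duration_ms"])
            row = truth.loc[truth["word_id"] == w["word_id"]].iloc[0]
            assert row["true_peak_rms"] == frames.loc[sel, "rms"].max()

    def test_nonpositive_frame_step_rejected(self):
        words = simulate_word_table(3, 1, seed=0)
        with pytest.raises(ValueError):
            simulate_prosody_frames(words, frame_ms=0)


def test_ratings_structure():
    r = simulate_ratings(5, 30, signal_sd=1.0, noise_sd=0.0, seed=4)
    assert r.shape == (5, 30)
    # zero noise: all raters identical
    assert np.allclose(r, r[0][None, :])
    r2 = simulate_ratings(5, 30, signal_sd=1.0, noise_sd=0.5, seed=4)
    assert not np.allclose(r2, r2[0][None, :])


def test_embeddings_metadata_and_separation():
    emb = simulate_embeddings(
        20, dim=8, class_separation=6.0, context_shift=2.0, seed=5, noise_sd=0.5
    )
    assert emb.values.shape == (3, 80, 8)
    meta = emb.meta
    two = meta["context"] == "two_word"
    assert (meta.loc[two & (meta["label"] == 0), "word_position"] == "first").all()
    assert (meta.loc[two & (meta["label"] == 1), "word_position"] == "later").all()
    assert (meta.loc[~two, "word_position"] == "later").all()
    # class means separated along the class axis
    v = emb.values[-1]
    gap = v[meta["label"] == 1, 0].mean() - v[meta["label"] == 0, 0].mean()
    assert abs(gap - 6.0) < 1.0
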