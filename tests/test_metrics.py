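"""Metric stack: Fréchet closed forms, IS bounds, embedder and protocol behavior."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from trajgan import (
    ConfigError,
    GaussianSummary,
    InputError,
    fid,
    fit_gaussian,
    frechet_distance,
    fvd,
    inception_score,
)
from trajgan.metrics import (
    CriticClipEmbedder,
    CriticFrameEmbedder,
    EvaluationConfig,
    FeatureFileEmbedder,
    RandomProjectionEmbedder,
    RandomSoftmaxHead,
    evaluation_protocol,
    save_feature_file,
)
from trajgan.plugin import Plugin, PluginConfig
from trajgan.synthetic_video import SceneSpec, generate_moving_shapes, generate_tunnel


class TestFitGaussian:
    def test_identical_rows_give_zero_covariance(self):
        g = fit_gaussian(np.tile([1.0, 2.0, 3.0], (5, 1)))
        np.testing.assert_allclose(g.covariance, 0.0, atol=1e-12)

    def test_two_point_hand_case_uses_n_minus_one(self):
        g = fit_gaussian(np.array([[0.0], [2.0]]))
        assert g.mean[0] == pytest.approx(1.0)
        assert g.covariance[0, 0] == pytest.approx(2.0)

    def test_single_row_rejected(self):
        with pytest.raises(InputError):
            fit_gaussian(np.ones((1, 3)))


class TestFrechetDistance:
    def test_identical_summaries_give_zero(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(50, 4))
        g = fit_gaussian(x)
        assert frechet_distance(g, g) <= 1e-8

    def test_one_dimensional_unit_variance_shift(self):
        a = GaussianSummary(np.zeros(1), np.ones((1, 1)))
        b = GaussianSummary(np.ones(1), np.ones((1, 1)))
        assert frechet_distance(a, b) == pytest.approx(1.0, abs=1e-8)

    def test_two_dimensional_diagonal_case(self):
        a = GaussianSummary(np.zeros(2), np.diag([1.0, 4.0]))
        b = GaussianSummary(np.array([1.0, 2.0]), np.diag([4.0, 1.0]))
        assert frechet_distance(a, b) == pytest.approx(7.0, abs=1e-8)

    def test_commuting_closed_form_matches_general_path(self):
        rng = np.random.default_rng(1)
        va, vb = rng.uniform(0.1, 3.0, 5), rng.uniform(0.1, 3.0, 5)
        mu_a, mu_b = rng.normal(size=5), rng.normal(size=5)
        a = GaussianSummary(mu_a, np.diag(va))
        b = GaussianSummary(mu_b, np.diag(vb))
        expected = np.sum((mu_a - mu_b) ** 2) + np.sum((np.sqrt(va) - np.sqrt(vb)) ** 2)
        assert frechet_distance(a, b) == pytest.approx(expected, abs=1e-8)

    def test_symmetry_and_nonnegativity(self):
        rng = np.random.default_rng(2)
        ga = fit_gaussian(rng.normal(size=(40, 6)))
        gb = fit_gaussian(rng.normal(size=(40, 6)) * 2 + 1)
        d_ab, d_ba = frechet_distance(ga, gb), frechet_distance(gb, ga)
        assert d_ab >= 0
        assert d_ab == pytest.approx(d_ba, abs=1e-8)

    def test_agrees_with_scipy_matrix_square_root(self):
        from scipy.linalg import sqrtm

        rng = np.random.default_rng(3)
        ga = fit_gaussian(rng.normal(size=(100, 5)))
        gb = fit_gaussian(rng.normal(size=(90, 5)) * 1.4 + 0.3)
        cross = sqrtm(ga.covariance @ gb.covariance).real
        expected = float(np.sum((ga.mean - gb.mean) ** 2)
                         + np.trace(ga.covariance + gb.covariance - 2 * cross))
        assert frechet_distance(ga, gb) == pytest.approx(expected, rel=1e-9)

    def test_orthogonal_rotation_invariance(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=(60, 8))
        y = rng.normal(size=(70, 8)) * 1.5
        q, _ = np.linalg.qr(rng.normal(size=(8, 8)))
        base = frechet_distance(fit_gaussian(x), fit_gaussian(y))
        rotated = frechet_distance(fit_gaussian(x @ q), fit_gaussian(y @ q))
        assert rotated == pytest.approx(base, abs=1e-6)

    def test_dimension_mismatch_rejected(self):
        a = GaussianSummary(np.zeros(2), np.eye(2))
        b = GaussianSummary(np.zeros(3), np.eye(3))
        with pytest.raises(InputError):
            frechet_distance(a, b)


class TestInceptionScore:
    def test_uniform_rows_give_exactly_one(self):
        mean, std = inception_score(np.full((20, 4), 0.25), n_splits=4)
        assert mean == pytest.approx(1.0, abs=1e-12)
        assert std == pytest.approx(0.0, abs=1e-12)

    def test_balanced_one_hot_rows_give_k(self):
        probs = np.eye(4)[np.tile(np.arange(4), 5)]
        mean, _ = inception_score(probs, n_splits=1)
        assert mean == pytest.approx(4.0, abs=1e-10)

    def test_two_class_hand_case(self):
        mean, _ = inception_score(np.array([[0.9, 0.1], [0.1, 0.9]]), n_splits=1)
        # KL of each row against the (0.5, 0.5) marginal, exponentiated
        expected = np.exp(0.9 * np.log(1.8) + 0.1 * np.log(0.2))
        assert mean == pytest.approx(expected, abs=1e-10)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(2, 40), st.integers(2, 6), st.integers(0, 2**31 - 1))
    def test_score_always_between_one_and_k(self, n, k, seed):
        rng = np.random.default_rng(seed)
        p = rng.dirichlet(np.ones(k), size=n)
        mean, _ = inception_score(p, n_splits=1)
        assert 1.0 - 1e-9 <= mean <= k + 1e-9

    def test_invalid_rows_rejected(self):
        with pytest.raises(InputError):
            inception_score(np.array([[0.5, 0.4]]), n_splits=1)
        with pytest.raises(InputError):
            inception_score(np.full((4, 2), 0.5), n_splits=9)


class TestFidFvd:
    @pytest.fixture(scope="class")
    def clip_sets(self):
        spec = SceneSpec(kind="tunnel", resolution=16, n_frames=8)
        spec_shapes = SceneSpec(kind="moving_shapes", resolution=16, n_frames=8)
        return {
            "tunnel_a": generate_tunnel(spec, 24, seed=0),
            "tunnel_b": generate_tunnel(spec, 24, seed=99),
            "shapes": generate_moving_shapes(spec_shapes, 24, seed=1),
        }

    def test_set_against_itself_is_zero(self, clip_sets):
        emb = RandomProjectionEmbedder((16, 16, 3), dim=16, seed=0, mode="frame")
        frames = np.concatenate([c.frames for c in clip_sets["tunnel_a"]])
        assert fid(frames, frames, emb) <= 1e-6

    def test_order_invariance(self, clip_sets):
        emb = RandomProjectionEmbedder((16, 16, 3), dim=16, seed=0, mode="frame")
        a = np.concatenate([c.frames for c in clip_sets["tunnel_a"]])
        b = np.concatenate([c.frames for c in clip_sets["shapes"]])
        base = fid(a, b, emb)
        shuf = fid(a[::-1], b[np.random.default_rng(0).permutation(len(b))], emb)
        assert shuf == pytest.approx(base, rel=1e-9)

    def test_same_generator_closer_than_different_generator(self, clip_sets):
        emb = RandomProjectionEmbedder((16, 16, 3), dim=16, seed=0, mode="frame")
        a = np.concatenate([c.frames for c in clip_sets["tunnel_a"]])
        b = np.concatenate([c.frames for c in clip_sets["tunnel_b"]])
        c = np.concatenate([c.frames for c in clip_sets["shapes"]])
        assert fid(a, b, emb) < fid(a, c, emb)

    def test_fvd_consumes_clips_and_detects_scene_change(self, clip_sets):
        emb = RandomProjectionEmbedder((16, 16, 3), dim=16, seed=0, mode="clip")
        same = fvd(clip_sets["tunnel_a"], clip_sets["tunnel_b"], emb)
        diff = fvd(clip_sets["tunnel_a"], clip_sets["shapes"], emb)
        assert same < diff
        assert fvd(clip_sets["tunnel_a"], clip_sets["tunnel_a"], emb) <= 1e-6

    def test_mode_mismatch_is_config_error(self, clip_sets):
        frame_emb = RandomProjectionEmbedder((16, 16, 3), dim=8, seed=0, mode="frame")
        with pytest.raises(ConfigError):
            fvd(clip_sets["tunnel_a"], clip_sets["tunnel_b"], frame_emb)

    def test_critic_embedders_expose_feature_widths(self, tiny_backbone):
        _, critic, _, cfg = tiny_backbone
        assert CriticFrameEmbedder(critic).dim == cfg.feature_dim
        assert CriticClipEmbedder(critic).dim == 2 * cfg.feature_dim

    def test_feature_file_roundtrip(self, tmp_path):
        feats = np.random.default_rng(0).normal(size=(10, 4))
        save_feature_file(tmp_path / "f.txt", feats, name="external", mode="frame")
        emb = FeatureFileEmbedder(tmp_path / "f.txt")
        out = emb(list(range(10)))
        np.testing.assert_allclose(out, feats, rtol=1e-12)
        with pytest.raises(InputError):
            emb(list(range(7)))


class TestEvaluationProtocol:
    def test_report_schema_and_determinism(self, tiny_backbone):
        gen, critic, _, cfg = tiny_backbone
        plugin = Plugin(PluginConfig(z_dim=15, layer_widths=[15, 15, 15, cfg.latent_dim],
                                     out_dim=cfg.latent_dim), seed=0)
        clips = generate_tunnel(SceneSpec(kind="tunnel", resolution=16, n_frames=16), 12, seed=0)
        eval_cfg = EvaluationConfig(n_clips=12, clip_len=16, n_splits=3, seed=0)
        rep1 = evaluation_protocol(gen, plugin, critic, clips, eval_cfg)
        rep2 = evaluation_protocol(gen, plugin, critic, clips, eval_cfg)
        assert rep1 == rep2
        for key in ("FVD", "FID_mean", "FID_std", "IS_fake_mean", "IS_fake_std",
                    "IS_real_mean", "IS_real_std"):
            assert key in rep1 and np.isfinite(rep1[key])

    def test_real_versus_real_is_near_zero(self):
        clips = generate_tunnel(SceneSpec(kind="tunnel", resolution=16, n_frames=8), 20, seed=3)
        emb_f = RandomProjectionEmbedder((16, 16, 3), dim=12, seed=0, mode="frame")
        emb_c = RandomProjectionEmbedder((16, 16, 3), dim=12, seed=0, mode="clip")
        frames = np.concatenate([c.frames for c in clips])
        assert fid(frames, frames, emb_f) <= 1e-6
        assert fvd(clips, clips, emb_c) <= 1e-6


def test_random_softmax_head_outputs_valid_probabilities():
    head = RandomSoftmaxHead((8, 8, 3), n_classes=5, seed=0)
    frames = np.random.default_rng(0).uniform(-1, 1, size=(10, 8, 8, 3))
    p = head(frames)
    assert p.shape == (10, 5)
    np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-12)
    assert (p >= 0).all()


def test_write_report_csv_round_trips_rows(tmp_path):
    import csv

    from trajgan.metrics import write_report_csv

    rep = {"FVD": 1.5, "FID_mean": 2.0, "FID_std": 0.1,
           "IS_fake_mean": 1.1, "IS_fake_std": 0.01,
           "IS_real_mean": 1.2, "IS_real_std": 0.02}
    path = write_report_csv({"tunnel/ours": rep}, tmp_path / "table.csv")
    rows = list(csv.DictReader(open(path)))
    assert len(rows) == 1
    assert rows[0]["label"] == "tunnel/ours"
    assert float(rows[0]["FVD"]) == 1.5
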