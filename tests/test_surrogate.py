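"""Deformation surrogate: features, training, prediction, accuracy metric."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mammoplan import phantom as ph, surrogate
from mammoplan.geometry import GeometryError, TriMesh
from mammoplan.phantom import Corpus, CorpusRecord, PhantomConfig
from mammoplan.poses import STANDARD_POSES, PoseCase

POSE_PAIR = (STANDARD_POSES["PRONE"], STANDARD_POSES["SS"])


@pytest.fixture(scope="module")
def skin_mesh(default_phantom):
    return ph.rest_geometry(default_phantom, max_edge=10.0).skin_mesh()


class TestMakeFeatures:
    def test_deterministic(self, skin_mesh):
        a = surrogate.make_features(skin_mesh, POSE_PAIR, 32)
        b = surrogate.make_features(skin_mesh, POSE_PAIR, 32)
        assert np.array_equal(a.landmarks, b.landmarks)
        assert np.array_equal(a.landmark_indices, b.landmark_indices)

    def test_translation_equivariance(self, skin_mesh):
        t = np.array([5.0, -3.0, 2.0])
        moved = skin_mesh.with_vertices(skin_mesh.vertices + t)
        a = surrogate.make_features(skin_mesh, POSE_PAIR, 32)
        b = surrogate.make_features(moved, POSE_PAIR, 32)
        assert np.array_equal(a.landmark_indices, b.landmark_indices)
        assert np.allclose(b.landmarks, a.landmarks + t, atol=1e-12)

    def test_k_too_small_rejected(self, skin_mesh):
        with pytest.raises(ValueError):
            surrogate.make_features(skin_mesh, POSE_PAIR, 4)

    def test_mesh_smaller_than_k_rejected(self):
        tiny = TriMesh(np.eye(3), np.array([[0, 1, 2]]))
        with pytest.raises(GeometryError):
            surrogate.make_features(tiny, POSE_PAIR, 8)

    def test_fps_covering_radius_beats_random_sampling(self, skin_mesh):
        from scipy.spatial import cKDTree

        v = skin_mesh.vertices
        idx = surrogate.farthest_point_landmarks(v, 64)
        cover_fps = cKDTree(v[idx]).query(v)[0].max()
        rng = np.random.default_rng(123)
        cover_rand = np.median(
            [
                cKDTree(v[rng.choice(len(v), 64, replace=False)]).query(v)[0].max()
                for _ in range(10)
            ]
        )
        assert cover_fps < 2.0 * cover_rand

    def test_flatten_length(self, skin_mesh):
        fv = surrogate.make_features(skin_mesh, POSE_PAIR, 32)
        assert fv.flatten().shape == (3 * 32 + 6,)


def synthetic_corpus(n, transform, noise_sd=0.0, seed=0):
    """Corpus whose target skin is an explicit map of the source skin."""
    rng = np.random.default_rng(seed)
    records = []
    for i in range(n):
        s = rng.uniform(0.85, 1.15)
        cfg = PhantomConfig(
            breast_semi_axes=(50.0 * s, 50.0 * s, 55.0 * s),
            tumor_semi_axes=(9.0, 9.0, 9.0),
            tumor_offset=(5.0, 5.0, 22.0 * s),
        )
        p = ph.make_phantom(cfg, seed=i)
        skin = ph.rest_geometry(p, max_edge=12.0).skin_mesh()
        vidx = np.unique(skin.faces)
        remap = -np.ones(len(skin.vertices), dtype=np.int64)
        remap[vidx] = np.arange(len(vidx))
        skin = TriMesh(skin.vertices[vidx], remap[skin.faces], "skin")
        target = transform(skin.vertices)
        if noise_sd:
            target = target + rng.normal(0, noise_sd, target.shape)
        c_src = p.tumor_center
        records.append(
            CorpusRecord(
                subject_id=i,
                config=cfg,
                skin_mesh_source=skin,
                skin_vertices_target=target,
                tumor_centroid_source=c_src,
                tumor_centroid_target=transform(c_src[None])[0],
            )
        )
    return Corpus(tuple(records), *POSE_PAIR, seed)


class TestTrain:
    def test_zero_dislocation_corpus_learns_zero(self):
        corpus = synthetic_corpus(25, lambda v: v.copy())
        model, info = surrogate.train(corpus, k=24, epochs=300, seed=0)
        assert info["validation_rmse"] < 0.1

    def test_linear_map_within_2x_of_least_squares_oracle(self):
        A = np.diag([1.05, 0.95, 0.9])
        b = np.array([1.0, -2.0, 4.0])
        corpus = synthetic_corpus(40, lambda v: v @ A.T + b, noise_sd=0.1, seed=1)
        model, info = surrogate.train(corpus, k=24, epochs=500, seed=1)

        X, Y, _ = surrogate.corpus_design(corpus, 24)
        vi, ti = info["validation_indices"], info["train_indices"]
        Xd = np.column_stack([X, np.ones(len(X))])
        coef, *_ = np.linalg.lstsq(Xd[ti], Y[ti], rcond=None)
        ols_rmse = float(np.sqrt(np.mean((Xd[vi] @ coef - Y[vi]) ** 2)))
        assert info["validation_rmse"] <= max(2.0 * ols_rmse, 0.2)

    def test_same_seed_identical_weights(self):
        corpus = synthetic_corpus(22, lambda v: v + [0, 0, -5.0])
        m1, _ = surrogate.train(corpus, k=16, epochs=50, seed=3)
        m2, _ = surrogate.train(corpus, k=16, epochs=50, seed=3)
        for a, b in zip(m1.coefs, m2.coefs):
            assert np.array_equal(a, b)

    def test_small_corpus_rejected(self):
        corpus = synthetic_corpus(10, lambda v: v.copy())
        with pytest.raises(ValueError):
            surrogate.train(corpus, k=16)

    def test_holdout_below_20_percent_rejected(self):
        corpus = synthetic_corpus(25, lambda v: v.copy())
        with pytest.raises(ValueError):
            surrogate.train(corpus, k=16, holdout_fraction=0.1)


class TestPredict:
    @pytest.fixture(scope="class")
    def trained(self):
        corpus = synthetic_corpus(25, lambda v: v + [0, 0, -8.0])
        model, _ = surrogate.train(corpus, k=16, epochs=100, seed=0)
        feats = surrogate.corpus_design(corpus, 16)[2][0]
        return model, feats

    def test_repeated_calls_identical(self, trained):
        model, feats = trained
        a = surrogate.predict(model, feats)
        b = surrogate.predict(model, feats)
        assert np.array_equal(a.landmarks_target, b.landmarks_target)

    def test_output_dimensionality(self, trained):
        model, feats = trained
        out = model.predict_raw(feats.flatten())
        assert out.shape == (1, 3 * (model.k + 1))

    def test_k_mismatch_rejected(self, trained, skin_mesh):
        model, _ = trained
        wrong = surrogate.make_features(skin_mesh, POSE_PAIR, 32)
        with pytest.raises(ValueError):
            surrogate.predict(model, wrong)

    def test_source_centroid_offsets_prediction(self, trained):
        model, feats = trained
        pred = surrogate.predict(model, feats, tumor_centroid_source=[1.0, 2.0, 3.0])
        assert np.allclose(
            pred.tumor_centroid_target, [1, 2, 3] + pred.tumor_dislocation
        )

    def test_save_load_round_trip(self, trained, tmp_path):
        model, feats = trained
        model.save(tmp_path / "model.npz")
        back = surrogate.SurrogateModel.load(tmp_path / "model.npz")
        assert np.array_equal(
            back.predict_raw(feats.flatten()), model.predict_raw(feats.flatten())
        )


class TestAccuracyWithin:
    def test_exact_match_is_one(self):
        pts = np.random.default_rng(0).normal(size=(30, 3))
        assert surrogate.accuracy_within(pts, pts, 5.0) == 1.0

    def test_all_beyond_delta_is_zero(self):
        pts = np.zeros((10, 3))
        assert surrogate.accuracy_within(pts + 10.0, pts, 5.0) == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            surrogate.accuracy_within(np.empty((0, 3)), np.empty((0, 3)))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            surrogate.accuracy_within(np.zeros((3, 3)), np.zeros((4, 3)))

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_monotone_in_delta(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.normal(0, 5, (40, 3))
        t = rng.normal(0, 5, (40, 3))
        deltas = [0.5, 1.0, 3.0, 7.0, 15.0]
        accs = [surrogate.accuracy_within(p, t, d) for d in deltas]
        assert all(a <= b + 1e-12 for a, b in zip(accs, accs[1:]))
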