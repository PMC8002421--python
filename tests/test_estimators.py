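import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation
from sklearn.base import clone

from endoview.benchmark import generate_trial, quaternion_spread
from endoview.estimators import (HornRegistration,
                                 InlierMaximizingRegistration,
                                 QuaternionFilterRegistration,
                                 enumerate_triples, quaternion_filter)
from endoview.exceptions import InsufficientPointsError
from endoview.metrics import rotation_vector_angle
from endoview.transforms import (SimilarityTransform, canonicalize_quaternion,
                                 rotvec_to_quaternion)


def _noise_free(seed=5, n=10):
    trial = generate_trial(seed, n_points=n, noise_factor=0.0)
    return trial.ideal_cloud, trial.noisy_cloud, trial.gt_transform


class TestInlierMaximizing:
    def test_all_inliers_and_exact_transform_without_noise(self):
        p, q, gt = _noise_free()
        est = InlierMaximizingRegistration().fit(p, q)
        assert est.inlier_count_ == 10
        assert np.allclose(est.transform_.R, gt.R, atol=1e-8)
        assert est.scale_ == pytest.approx(gt.s, rel=1e-8)

    def test_gross_outlier_is_excluded(self):
        p, q, gt = _noise_free(seed=8)
        scale = np.abs(q).max()
        q = q.copy()
        q[4] += 10.0 * scale          # displaced by 10x the scene scale
        est = InlierMaximizingRegistration().fit(p, q)
        assert est.inlier_count_ == 9
        assert not est.inlier_mask_[4]
        assert np.allclose(est.transform_.R, gt.R, atol=1e-8)
        assert np.allclose(est.translation_, gt.t, atol=1e-8)

    def test_two_points_raise(self):
        with pytest.raises(InsufficientPointsError):
            InlierMaximizingRegistration().fit(np.zeros((2, 3)),
                                               np.zeros((2, 3)))

    def test_invariant_to_correspondence_order(self):
        rng = np.random.default_rng(9)
        trial = generate_trial(33)
        perm = rng.permutation(10)
        a = InlierMaximizingRegistration().fit(trial.ideal_cloud,
                                               trial.noisy_cloud)
        b = InlierMaximizingRegistration().fit(trial.ideal_cloud[perm],
                                               trial.noisy_cloud[perm])
        assert a.inlier_count_ == b.inlier_count_
        assert np.allclose(a.transform_.R, b.transform_.R, atol=1e-9)
        assert a.scale_ == pytest.approx(b.scale_, rel=1e-12)


class TestPixelResidualRegime:
    def test_reprojection_inliers_with_intrinsics(self, scene):
        """With intrinsics supplied, inliers are counted by 2D reprojection
        error in the second camera's image."""
        corr = scene.correspondences
        q_cam2 = scene.pose2.to_camera(corr.p)   # exact camera-2 coordinates
        est = InlierMaximizingRegistration(
            intrinsics=scene.intrinsics).fit(corr.p, q_cam2)
        assert est.inlier_count_ == len(corr.p)
        # threshold is in pixels: 1% of the image diagonal
        K = scene.intrinsics
        assert est.threshold_ == pytest.approx(
            0.01 * np.hypot(K.width, K.height))


class TestQuaternionFilter:
    def test_identical_candidates_all_kept(self):
        q = rotvec_to_quaternion([0.3, 0.1, -0.2])
        res = quaternion_filter(np.tile(q, (12, 1)), d=2.0)
        assert res.kept_mask.all()
        assert np.allclose(res.representative, q, atol=1e-12)

    @pytest.mark.parametrize("seed", range(20))
    def test_kept_set_shrinks_as_d_grows(self, seed):
        """Larger d tightens the window: kept(d=4) is a subset of kept(d=2)."""
        rng = np.random.default_rng(seed)
        base = Rotation.random(30, random_state=np.random.RandomState(seed))
        cands = canonicalize_quaternion(np.roll(base.as_quat(), 1, axis=1))
        k2 = quaternion_filter(cands, d=2.0).kept_mask
        k4 = quaternion_filter(cands, d=4.0).kept_mask
        assert not np.any(k4 & ~k2)

    def test_planted_outlier_rejected_and_mean_improved(self):
        rng = np.random.default_rng(4)
        target = rotvec_to_quaternion([0.5, -0.3, 0.8])
        cluster = canonicalize_quaternion(
            target + rng.normal(scale=0.01, size=(119, 4)))
        outlier = rotvec_to_quaternion([-2.0, 2.0, -1.0])
        cands = np.vstack([cluster, outlier])
        res = quaternion_filter(cands, d=2.0)
        assert not res.kept_mask[-1]

        def qangle(a, b):
            return 2 * np.degrees(np.arccos(np.clip(abs(a @ b), 0, 1)))
        unfiltered = canonicalize_quaternion(cands.mean(axis=0))
        assert qangle(res.representative, target) < qangle(unfiltered, target)

    def test_degenerate_window_falls_back_to_nearest_candidate(self):
        # two antipodal-ish candidates: the component-wise median is not
        # attained; the filter must still keep something
        cands = np.array([[1.0, 0, 0, 0],
                          [0.5, 0.5, 0.5, 0.5]])
        res = quaternion_filter(cands, d=100.0)
        assert res.kept_mask.sum() >= 1


class TestQuaternionFilterRegistration:
    def test_zero_noise_recovers_ground_truth(self):
        p, q, gt = _noise_free(seed=2)
        est = QuaternionFilterRegistration(d=2.0).fit(p, q)
        assert rotation_vector_angle(gt.rotvec, est.transform_.rotvec) < 1e-6
        assert est.scale_ == pytest.approx(gt.s, rel=1e-8)
        assert np.allclose(est.translation_, gt.t, atol=1e-7)

    def test_candidate_count_is_n_choose_3(self):
        p, q, _ = _noise_free(seed=3, n=10)
        est = QuaternionFilterRegistration(d=2.0).fit(p, q)
        assert est.n_candidates_ == math.comb(10, 3) == 120

    def test_matches_full_horn_at_zero_noise(self):
        p, q, _ = _noise_free(seed=6)
        a2 = QuaternionFilterRegistration(d=2.0).fit(p, q)
        h = HornRegistration().fit(p, q)
        assert np.allclose(a2.transform_.R, h.transform_.R, atol=1e-8)
        assert a2.scale_ == pytest.approx(h.scale_, abs=1e-8)


class TestSklearnProtocol:
    @pytest.mark.parametrize("est", [
        HornRegistration(), InlierMaximizingRegistration(threshold=0.5),
        QuaternionFilterRegistration(d=4.0)])
    def test_clone_and_params_round_trip(self, est):
        c = clone(est)
        assert c.get_params() == est.get_params()

    def test_transform_predict_and_score(self):
        p, q, gt = _noise_free(seed=1)
        est = HornRegistration().fit(p, q)
        assert np.allclose(est.transform(p), q, atol=1e-8)
        assert np.allclose(est.predict(p), est.transform(p))
        assert np.allclose(est.inverse_transform(q), p, atol=1e-8)
        assert est.score(p, q) == pytest.approx(0.0, abs=1e-12)


class TestQuaternionSpread:
    def test_zero_noise_spread_vanishes_and_noise_increases_it(self):
        quiet = quaternion_spread(generate_trial(14, noise_factor=0.0))
        noisy = quaternion_spread(generate_trial(14, noise_factor=0.1))
        assert quiet["n_candidates"] == 120
        assert max(quiet["std"]) < 1e-8
        assert min(noisy["std"]) > 0
        assert max(noisy["std"]) > max(quiet["std"])


def test_triple_enumeration_is_exhaustive_then_sampled():
    assert len(enumerate_triples(10)) == 120
    sampled = enumerate_triples(50, max_triples=100,
                                rng=np.random.default_rng(0))
    assert len(sampled) == 100
    assert len({tuple(t) for t in sampled}) == 100
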