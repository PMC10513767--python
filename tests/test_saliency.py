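"""CAM-family saliency methods against analytic cases and brute-force oracles."""

from __future__ import annotations

import numpy as np
import pytest

from dermxai.errors import InputError, NumericError
from dermxai.model_adapter import finite_difference_gradients
from dermxai.saliency import (
    TECHNIQUES,
    compute_map,
    eigen_cam,
    grad_cam,
    grad_cam_pp,
    minmax_normalize,
    score_cam,
    score_cam_weights,
    segment_superpixels,
    upsample,
)


def normalized(raw, shape):
    return minmax_normalize(upsample(raw, shape))[0]


class TestGradCam:
    def test_zero_gradients_give_zero_map(self, stub_model_factory):
        acts = np.random.default_rng(0).uniform(size=(4, 4, 1))
        m = stub_model_factory(acts=acts, grads=np.zeros((4, 4, 1)))
        smap = grad_cam(m, np.zeros(m.input_shape), 0, "feat")
        assert np.allclose(smap.values, 0.0)

    def test_uniform_positive_gradient_reproduces_activation(self, stub_model_factory):
        acts = np.abs(np.random.default_rng(1).normal(size=(4, 4, 1))) + 0.1
        m = stub_model_factory(acts=acts, grads=np.full((4, 4, 1), 0.7))
        smap = grad_cam(m, np.zeros(m.input_shape), 0, "feat")
        assert np.allclose(smap.values, normalized(acts[:, :, 0], (4, 4)), atol=1e-12)

    def test_matches_finite_difference_oracle(self, small_model, test_image):
        smap = grad_cam(small_model, test_image, 1, "conv1")
        acts = small_model.activations(test_image, "conv1").maps
        fd = finite_difference_gradients(small_model, test_image, "conv1", 1)
        raw = np.maximum((acts * fd.mean(axis=(0, 1))).sum(axis=2), 0.0)
        assert np.abs(smap.values - normalized(raw, test_image.shape[:2])).max() < 1e-4

    def test_nan_gradients_raise(self, stub_model_factory):
        m = stub_model_factory(acts=np.ones((3, 3, 1)), grads=np.full((3, 3, 1), np.nan))
        with pytest.raises(NumericError):
            grad_cam(m, np.zeros(m.input_shape), 0, "feat")


class TestGradCamPP:
    def test_zero_gradients_give_zero_map(self, stub_model_factory):
        m = stub_model_factory(acts=np.ones((4, 4, 2)), grads=np.zeros((4, 4, 2)))
        smap = grad_cam_pp(m, np.zeros(m.input_shape), 0, "feat")
        assert np.allclose(smap.values, 0.0)

    def test_uniform_gradient_single_channel_equals_grad_cam(self, stub_model_factory):
        acts = np.abs(np.random.default_rng(2).normal(size=(5, 5, 1)))
        m = stub_model_factory(acts=acts, grads=np.full((5, 5, 1), 0.3))
        a = grad_cam(m, np.zeros(m.input_shape), 0, "feat").values
        b = grad_cam_pp(m, np.zeros(m.input_shape), 0, "feat").values
        assert np.abs(a - b).max() < 1e-6

    def test_matches_straight_line_oracle(self, small_model, test_image):
        """Duplicate evaluation of the weight formula on fd gradients."""
        smap = grad_cam_pp(small_model, test_image, 0, "conv1")
        acts = small_model.activations(test_image, "conv1").maps
        g = finite_difference_gradients(small_model, test_image, "conv1", 0)
        h, w, k = acts.shape
        weights = np.zeros(k)
        for c in range(k):
            sum_ag3 = float((acts[:, :, c] * g[:, :, c] ** 3).sum())
            for i in range(h):
                for j in range(w):
                    denom = 2.0 * g[i, j, c] ** 2 + sum_ag3
                    if abs(denom) > 1e-12:
                        alpha = g[i, j, c] ** 2 / denom
                    else:
                        alpha = 0.0
                    weights[c] += alpha * max(g[i, j, c], 0.0)
        raw = np.maximum((acts * weights).sum(axis=2), 0.0)
        assert np.abs(smap.values - normalized(raw, test_image.shape[:2])).max() < 1e-4


class TestEigenCam:
    def test_single_channel_matches_normalized_activation(self, stub_model_factory):
        acts = np.abs(np.random.default_rng(3).normal(size=(4, 4, 1)))
        m = stub_model_factory(acts=acts)
        smap = eigen_cam(m, np.zeros(m.input_shape), "feat")
        assert np.allclose(smap.values, normalized(acts[:, :, 0], (4, 4)), atol=1e-10)

    def test_rank_one_stack_recovers_shared_pattern(self, stub_model_factory):
        rng = np.random.default_rng(4)
        base = np.abs(rng.normal(size=(5, 5)))
        coeffs = np.array([0.5, 1.5, -0.7])
        acts = base[:, :, None] * coeffs[None, None, :]
        m = stub_model_factory(acts=acts, input_shape=(5, 5, 3))
        smap = eigen_cam(m, np.zeros((5, 5, 3)), "feat")
        assert np.allclose(smap.values, normalized(base, (5, 5)), atol=1e-10)

    def test_matches_ata_eigendecomposition_oracle(self, stub_model_factory):
        acts = np.random.default_rng(5).normal(size=(4, 4, 3))
        m = stub_model_factory(acts=acts, input_shape=(4, 4, 3))
        smap = eigen_cam(m, np.zeros((4, 4, 3)), "feat")
        a = acts.reshape(16, 3)
        evals, evecs = np.linalg.eigh(a.T @ a)
        proj = a @ evecs[:, np.argmax(evals)]
        if proj.sum() < 0:
            proj = -proj
        assert np.abs(smap.values - normalized(proj.reshape(4, 4), (4, 4))).max() < 1e-6

    def test_zero_activations_give_zero_map(self, stub_model_factory):
        m = stub_model_factory(acts=np.zeros((4, 4, 2)))
        smap = eigen_cam(m, np.zeros(m.input_shape), "feat")
        assert np.allclose(smap.values, 0.0)

    def test_invariant_to_positive_scaling(self, stub_model_factory):
        acts = np.random.default_rng(6).normal(size=(4, 4, 3))
        a = eigen_cam(stub_model_factory(acts=acts), np.zeros((4, 4, 3)), "feat").values
        b = eigen_cam(stub_model_factory(acts=7.5 * acts), np.zeros((4, 4, 3)), "feat").values
        assert np.abs(a - b).max() < 1e-10


class TestScoreCam:
    def test_weights_match_brute_force_forward_passes(self, small_model, test_image):
        ws = score_cam_weights(small_model, test_image, 1, "conv2").weights
        acts = small_model.activations(test_image, "conv2").maps
        base = small_model.class_scores(np.zeros_like(test_image))[1]
        for i in range(acts.shape[2]):
            up = upsample(acts[:, :, i], test_image.shape[:2])
            lo, hi = up.min(), up.max()
            mask = np.zeros_like(up) if hi - lo <= 1e-12 else (up - lo) / (hi - lo)
            expected = small_model.class_scores(test_image * mask[:, :, None])[1] - base
            assert abs(ws[i] - expected) < 1e-6

    def test_nonpositive_weights_give_zero_map(self, stub_model_factory):
        # negative score weights make every masked pass score <= baseline
        acts = np.abs(np.random.default_rng(7).normal(size=(4, 4, 2)))
        m = stub_model_factory(acts=acts, score_weights=-np.ones((4, 4, 3)))
        smap = score_cam(m, np.random.default_rng(8).uniform(size=(4, 4, 3)), 0, "feat")
        assert np.allclose(smap.values, 0.0)

    def test_channel_order_invariance(self, stub_model_factory):
        rng = np.random.default_rng(9)
        acts = np.abs(rng.normal(size=(4, 4, 3)))
        img = rng.uniform(size=(4, 4, 3))
        sw = rng.normal(size=(4, 4, 3))
        a = score_cam(stub_model_factory(acts=acts, score_weights=sw), img, 0, "feat").values
        b = score_cam(
            stub_model_factory(acts=acts[:, :, ::-1].copy(), score_weights=sw), img, 0, "feat"
        ).values
        assert np.abs(a - b).max() < 1e-10

    def test_baseline_shape_mismatch_raises(self, small_model, test_image):
        with pytest.raises(InputError):
            score_cam(small_model, test_image, 0, baseline=np.zeros((3, 3, 3)))


class TestSegmentation:
    def test_constant_image_gives_compact_segments(self):
        seg = segment_superpixels(np.full((24, 24, 3), 0.5), 4)
        assert seg.n_segments == 4
        assert set(np.unique(seg.labels)) == {0, 1, 2, 3}

    def test_two_tone_boundary_follows_color_edge(self):
        img = np.zeros((24, 48, 3))
        img[:, 24:] = 0.8
        seg = segment_superpixels(img, 2)
        assert seg.n_segments == 2
        left, right = seg.labels[:, :24], seg.labels[:, 24:]
        left_mode = np.bincount(left.ravel()).argmax()
        right_mode = np.bincount(right.ravel()).argmax()
        assert left_mode != right_mode
        assert (left == left_mode).mean() >= 0.95
        assert (right == right_mode).mean() >= 0.95

    def test_deterministic_for_same_seed(self):
        img = np.random.default_rng(11).uniform(size=(24, 24, 3))
        a = segment_superpixels(img, 8, seed=1).labels
        b = segment_superpixels(img, 8, seed=1).labels
        assert np.array_equal(a, b)

    def test_too_many_segments_raises(self):
        with pytest.raises(InputError):
            segment_superpixels(np.zeros((4, 4, 3)), 100)


class TestSharedInvariants:
    def test_all_methods_share_shape_and_range(self, small_model, test_image):
        for technique in TECHNIQUES:
            smap = compute_map(
                technique, small_model, test_image, class_index=1,
                n_segments=6, n_samples=20, seed=0,
            )
            assert smap.values.shape == test_image.shape[:2]
            assert smap.values.min() >= 0.0 and smap.values.max() <= 1.0

    def test_unknown_technique_raises_with_valid_names(self, small_model, test_image):
        with pytest.raises(InputError, match="grad_cam"):
            compute_map("gradcam", small_model, test_image, 0)
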