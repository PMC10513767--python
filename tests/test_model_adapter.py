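"""Fixture-CNN adapter: forward pass, hand-rolled backprop, contract errors."""

from __future__ import annotations

import numpy as np
import pytest

from dermxai.errors import InputError
from dermxai.model_adapter import ConvLayer, FixtureModel, finite_difference_gradients


def _constant_image(shape, value=0.5):
    return np.full(shape, value)


def make_mean_channel_model(input_shape=(6, 6, 3)):
    """Class-0 logit = spatial mean of channel 0; class 1 has zero weights."""
    k = np.zeros((2, 3, 3, 3))
    k[0, 1, 1, 0] = 1.0  # channel 0 copies the red plane
    k[1, 1, 1, 1] = 1.0
    convs = [ConvLayer(weights=k, bias=np.zeros(2), activation="linear")]
    head = np.array([[1.0, 0.0], [0.0, 0.0]])
    return FixtureModel(
        input_shape=input_shape, convs=convs, head_weights=head, head_bias=np.zeros(2)
    )


class TestClassScores:
    def test_zero_head_weights_give_zero_scores(self):
        m = FixtureModel.from_seed(0, input_shape=(8, 8, 3), channels=(3,))
        m.head_weights[:] = 0.0
        m.head_bias[:] = 0.0
        scores = m.class_scores(_constant_image((8, 8, 3)))
        assert np.allclose(scores, 0.0)

    def test_mean_channel_head_matches_analytic_value(self):
        # identity kernel on the red plane, linear activation, unit head:
        # logit 0 must equal the constant red value exactly
        m = make_mean_channel_model()
        img = np.zeros((6, 6, 3))
        img[:, :, 0] = 0.37
        assert m.class_scores(img)[0] == pytest.approx(0.37, abs=1e-12)

    def test_wrong_spatial_size_raises(self):
        m = FixtureModel.from_seed(0, input_shape=(8, 8, 3), channels=(3,))
        with pytest.raises(InputError):
            m.class_scores(np.zeros((9, 8, 3)))


class TestActivations:
    def test_constant_image_gives_constant_interior(self):
        m = make_mean_channel_model()
        acts = m.activations(_constant_image((6, 6, 3), 0.4), "conv1").maps
        interior = acts[1:-1, 1:-1, 0]
        assert np.allclose(interior, interior.flat[0])

    def test_hand_computed_convolution(self):
        # 'same'-padded 3x3 correlation computed with explicit python loops
        rng = np.random.default_rng(1)
        img = rng.uniform(0, 1, size=(5, 5, 3))
        kernel = rng.normal(size=(1, 3, 3, 3))
        m = FixtureModel(
            input_shape=(5, 5, 3),
            convs=[ConvLayer(weights=kernel, bias=np.array([0.2]), activation="linear")],
            head_weights=np.ones((1, 1)),
            head_bias=np.zeros(1),
        )
        got = m.activations(img, "conv1").maps[:, :, 0]
        expected = np.zeros((5, 5))
        for i in range(5):
            for j in range(5):
                acc = 0.2
                for di in range(3):
                    for dj in range(3):
                        ii, jj = i + di - 1, j + dj - 1
                        if 0 <= ii < 5 and 0 <= jj < 5:
                            acc += float(img[ii, jj] @ kernel[0, di, dj])
                expected[i, j] = acc
        assert np.allclose(got, expected, atol=1e-12)

    def test_determinism_bit_identical(self):
        m = FixtureModel.from_seed(2, input_shape=(8, 8, 3), channels=(3, 2))
        img = np.random.default_rng(0).uniform(size=(8, 8, 3))
        a1 = m.activations(img, "conv2").maps
        a2 = m.activations(img, "conv2").maps
        assert np.array_equal(a1, a2)

    def test_unknown_layer_raises(self):
        m = FixtureModel.from_seed(0, input_shape=(8, 8, 3), channels=(3,))
        with pytest.raises(InputError, match="unknown layer"):
            m.activations(np.zeros((8, 8, 3)), "conv9")


class TestScoreGradients:
    def test_zero_head_class_has_zero_gradients(self):
        m = make_mean_channel_model()
        img = np.random.default_rng(3).uniform(size=(6, 6, 3))
        g = m.score_gradients(img, "conv1", 1).grads
        assert np.allclose(g, 0.0)

    def test_mean_channel_gradient_is_one_over_z(self):
        m = make_mean_channel_model()
        img = np.random.default_rng(3).uniform(size=(6, 6, 3))
        g = m.score_gradients(img, "conv1", 0).grads
        assert np.allclose(g[:, :, 0], 1.0 / 36.0)
        assert np.allclose(g[:, :, 1], 0.0)

    def test_invalid_class_index_raises(self):
        m = make_mean_channel_model()
        with pytest.raises(InputError):
            m.score_gradients(np.zeros((6, 6, 3)), "conv1", 5)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    @pytest.mark.parametrize("activation", ["softplus", "linear"])
    @pytest.mark.parametrize("strides", [(1, 1), (2, 2), (2, 1)])
    def test_matches_finite_differences(self, seed, activation, strides):
        m = FixtureModel.from_seed(
            seed, input_shape=(11, 13, 3), channels=(3, 4), strides=strides,
            activation=activation,
        )
        img = np.random.default_rng(seed + 100).uniform(size=(11, 13, 3))
        for layer in m.layer_names:
            for ci in range(m.n_classes):
                g = m.score_gradients(img, layer, ci).grads
                fd = finite_difference_gradients(m, img, layer, ci, step=1e-3)
                scale = max(np.abs(fd).max(), 1e-12)
                assert np.abs(g - fd).max() / scale < 1e-4

    def test_relu_matches_finite_differences_away_from_kinks(self):
        # central differences are only valid when no pre-activation sits
        # within the step of a ReLU kink; shift the biases to guarantee it
        m = FixtureModel.from_seed(
            1, input_shape=(11, 13, 3), channels=(3, 4), activation="relu"
        )
        m.convs[1].bias = m.convs[1].bias + 2.0
        img = np.random.default_rng(101).uniform(size=(11, 13, 3))
        zs, _, _ = m._forward(img)
        assert np.abs(zs[1]).min() > 1e-2  # kink margin for the oracle
        g = m.score_gradients(img, "conv1", 0).grads
        fd = finite_difference_gradients(m, img, "conv1", 0, step=1e-3)
        assert np.abs(g - fd).max() / np.abs(fd).max() < 1e-4


class TestAdapterContract:
    def test_operations_do_not_mutate_weights(self):
        m = FixtureModel.from_seed(4, input_shape=(8, 8, 3), channels=(2, 2))
        img = np.random.default_rng(0).uniform(size=(8, 8, 3))
        before = [c.weights.copy() for c in m.convs] + [m.head_weights.copy()]
        m.class_scores(img)
        m.activations(img, "conv1")
        m.score_gradients(img, "conv1", 1)
        after = [c.weights for c in m.convs] + [m.head_weights]
        for b, a in zip(before, after):
            assert np.array_equal(b, a)

    def test_json_round_trip_preserves_forward_pass(self):
        m = FixtureModel.from_seed(7, input_shape=(8, 8, 3), channels=(2, 3), strides=(2, 1))
        img = np.random.default_rng(9).uniform(size=(8, 8, 3))
        m2 = FixtureModel.from_json(m.to_json())
        assert np.allclose(m.class_scores(img), m2.class_scores(img), atol=1e-14)
        assert m2.layer_names == m.layer_names

    def test_activation_and_gradient_shapes_agree(self):
        m = FixtureModel.from_seed(0, input_shape=(10, 10, 3), channels=(3, 2), strides=(2, 1))
        img = np.random.default_rng(0).uniform(size=(10, 10, 3))
        for layer in m.layer_names:
            a = m.activations(img, layer).maps
            g = m.score_gradients(img, layer, 0).grads
            assert a.shape == g.shape
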