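from __future__ import annotations

import numpy as np
import pytest

from dermxai.model_adapter import ActivationStack, FixtureModel, GradientStack
from dermxai.synthesis import LesionSpec, make_lesion


class StubModel:
    """Adapter with hand-set activations/gradients and a linear score head.

    ``score_weights`` (H, W, 3) defines class_scores(image) = [<W, image>, 0]
    so Score-CAM/LIME forward passes on perturbed images are well defined;
    ``acts`` and ``grads`` are returned verbatim for the single layer "feat".
    """

    def __init__(self, acts, grads=None, score_weights=None, input_shape=None):
        self.acts = np.asarray(acts, dtype=float)
        self.grads = None if grads is None else np.asarray(grads, dtype=float)
        self.input_shape = input_shape or (self.acts.shape[0], self.acts.shape[1], 3)
        self.score_weights = (
            np.zeros(self.input_shape) if score_weights is None else np.asarray(score_weights)
        )
        self.n_classes = 2
        self.layer_names = ["feat"]

    def class_scores(self, image):
        return np.array([float((self.score_weights * image).sum()), 0.0])

    def activations(self, image, layer):
        return ActivationStack(maps=self.acts, layer=layer)

    def score_gradients(self, image, layer, class_index):
        return GradientStack(grads=self.grads, class_index=class_index)


@pytest.fixture
def stub_model_factory():
    return StubModel


@pytest.fixture(scope="session")
def small_model():
    """Smooth-activation fixture CNN used by the saliency oracle tests."""
    return FixtureModel.from_seed(
        3, input_shape=(12, 12, 3), channels=(2, 3), strides=(1, 2), activation="softplus"
    )


@pytest.fixture(scope="session")
def test_image():
    return np.random.default_rng(5).uniform(0.0, 1.0, size=(12, 12, 3))


@pytest.fixture(scope="session")
def plain_lesion():
    """Symmetric one-color lesion (grades 0/0/0)."""
    return make_lesion(LesionSpec(seed=5, n_colors=1))


@pytest.fixture(scope="session")
def blob_lesion():
    """Symmetric lesion with a centered second pigment color."""
    return make_lesion(LesionSpec(seed=5, n_colors=2, central_blobs=True))
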