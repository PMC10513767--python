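"""Classifier adapter contract and a small fully inspectable fixture CNN.

The saliency methods in :mod:`dermxai.saliency` only need three things from a
classifier: class scores (logits) for an image, the activation maps of a named
convolutional layer, and the gradient of a chosen class score with respect to
those activations.  Any model exposing the :class:`ModelAdapter` protocol can
be explained; production networks are plugged in by wrapping them in an
adapter with the same three methods.

The package ships :class:`FixtureModel`, a tiny convolutional network
(a few 3x3 kernels per layer, elementwise nonlinearity, global average
pooling, linear head) written directly in numpy with hand-derived backprop.
Every weight is settable, the forward pass is a pure function of
(weights, image), and gradients can be cross-checked against central finite
differences, which makes it suitable as an oracle in tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Protocol, Sequence, runtime_checkable

import numpy as np
from scipy.signal import convolve2d, correlate2d

from .errors import InputError

__all__ = [
    "ActivationStack",
    "GradientStack",
    "ModelAdapter",
    "ConvLayer",
    "FixtureModel",
    "finite_difference_gradients",
]


@dataclass(frozen=True)
class ActivationStack:
    """Feature maps ``A^k`` of one convolutional layer: array (h, w, K)."""

    maps: np.ndarray
    layer: str

    def __post_init__(self) -> None:
        maps = np.asarray(self.maps, dtype=float)
        if maps.ndim != 3 or min(maps.shape) < 1:
            raise InputError(f"activation stack must be (h, w, K), got {maps.shape}")
        if not np.isfinite(maps).all():
            raise InputError("activation stack contains non-finite values")
        object.__setattr__(self, "maps", maps)

    @property
    def n_channels(self) -> int:
        return self.maps.shape[2]


@dataclass(frozen=True)
class GradientStack:
    """Gradients of one class score w.r.t. a layer's activations: (h, w, K)."""

    grads: np.ndarray
    class_index: int

    def __post_init__(self) -> None:
        grads = np.asarray(self.grads, dtype=float)
        if grads.ndim != 3:
            raise InputError(f"gradient stack must be (h, w, K), got {grads.shape}")
        object.__setattr__(self, "grads", grads)


@runtime_checkable
class ModelAdapter(Protocol):
    """Contract a classifier must satisfy to be explained.

    Attributes
    ----------
    input_shape : tuple (H, W, 3)
        Expected image shape, float values in [0, 1], channel-last.
    n_classes : int
    layer_names : sequence of str
        Ordered names of layers whose activations can be requested; the last
        entry is the conventional "final convolutional layer".
    """

    input_shape: tuple[int, int, int]
    n_classes: int
    layer_names: Sequence[str]

    def class_scores(self, image: np.ndarray) -> np.ndarray: ...

    def activations(self, image: np.ndarray, layer: str) -> ActivationStack: ...

    def score_gradients(
        self, image: np.ndarray, layer: str, class_index: int
    ) -> GradientStack: ...


def _check_image(image: np.ndarray, input_shape: tuple[int, int, int]) -> np.ndarray:
    image = np.asarray(image, dtype=float)
    if image.shape != tuple(input_shape):
        raise InputError(f"image shape {image.shape} != expected {tuple(input_shape)}")
    if not np.isfinite(image).all():
        raise InputError("image contains non-finite values")
    return image


def _activate(z: np.ndarray, kind: str) -> np.ndarray:
    if kind == "linear":
        return z
    if kind == "relu":
        return np.maximum(z, 0.0)
    if kind == "softplus":
        return np.logaddexp(0.0, z)
    raise InputError(f"unknown activation {kind!r}")


def _activate_grad(z: np.ndarray, kind: str) -> np.ndarray:
    if kind == "linear":
        return np.ones_like(z)
    if kind == "relu":
        return (z > 0.0).astype(float)
    if kind == "softplus":
        return 1.0 / (1.0 + np.exp(-z))
    raise InputError(f"unknown activation {kind!r}")


@dataclass
class ConvLayer:
    """One convolutional layer: 'same'-padded odd kernel, optional stride.

    weights: (K_out, kh, kw, K_in); bias: (K_out,).
    """

    weights: np.ndarray
    bias: np.ndarray
    stride: int = 1
    activation: str = "relu"
    name: str = "conv"

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.bias = np.asarray(self.bias, dtype=float)
        if self.weights.ndim != 4:
            raise InputError("conv weights must be (K_out, kh, kw, K_in)")
        if self.weights.shape[1] % 2 == 0 or self.weights.shape[2] % 2 == 0:
            raise InputError("kernel height/width must be odd for 'same' padding")
        if self.bias.shape != (self.weights.shape[0],):
            raise InputError("bias length must equal K_out")
        if self.stride < 1:
            raise InputError("stride must be >= 1")

    @property
    def k_out(self) -> int:
        return self.weights.shape[0]

    def forward(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Return (pre-activation z, post-activation a), both (h', w', K_out)."""
        h, w, _ = x.shape
        z_full = np.empty((h, w, self.k_out))
        for k in range(self.k_out):
            acc = np.zeros((h, w))
            for c in range(x.shape[2]):
                acc += correlate2d(x[:, :, c], self.weights[k, :, :, c], mode="same")
            z_full[:, :, k] = acc + self.bias[k]
        z = z_full[:: self.stride, :: self.stride, :]
        return z, _activate(z, self.activation)

    def backward_input(self, x_shape: tuple[int, int, int], g_z: np.ndarray) -> np.ndarray:
        """Adjoint of :meth:`forward` pre-activation w.r.t. the layer input.

        g_z is the gradient at the (strided) pre-activation; returns the
        gradient at the layer input, shape x_shape.
        """
        h, w, c_in = x_shape
        g_full = np.zeros((h, w, self.k_out))
        g_full[:: self.stride, :: self.stride, :] = g_z
        g_x = np.zeros((h, w, c_in))
        for c in range(c_in):
            acc = np.zeros((h, w))
            for k in range(self.k_out):
                # convolve2d is the exact adjoint of correlate2d for 'same'
                # padding with odd kernels
                acc += convolve2d(g_full[:, :, k], self.weights[k, :, :, c], mode="same")
            g_x[:, :, c] = acc
        return g_x


@dataclass
class FixtureModel:
    """Small convolutional classifier with hand-settable weights.

    Forward pass: image -> conv layers (each: same-padded conv, stride,
    elementwise nonlinearity) -> global average pooling over space ->
    linear head -> logits.  ``class_scores`` returns the logits.

    The named "activations" of layer i are the post-nonlinearity maps of
    conv layer i, matching the feature maps a CAM method consumes.
    """

    input_shape: tuple[int, int, int]
    convs: list[ConvLayer]
    head_weights: np.ndarray  # (n_classes, K_last)
    head_bias: np.ndarray  # (n_classes,)
    layer_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.head_weights = np.asarray(self.head_weights, dtype=float)
        self.head_bias = np.asarray(self.head_bias, dtype=float)
        if not self.convs:
            raise InputError("at least one conv layer is required")
        if self.head_weights.ndim != 2:
            raise InputError("head weights must be (n_classes, K_last)")
        if self.head_weights.shape[1] != self.convs[-1].k_out:
            raise InputError("head width must equal last conv channel count")
        if self.head_bias.shape != (self.head_weights.shape[0],):
            raise InputError("head bias length must equal n_classes")
        if not self.layer_names:
            self.layer_names = [f"conv{i + 1}" for i in range(len(self.convs))]
        if len(self.layer_names) != len(self.convs):
            raise InputError("one layer name per conv layer")
        for name, conv in zip(self.layer_names, self.convs):
            conv.name = name

    @property
    def n_classes(self) -> int:
        return self.head_weights.shape[0]

    # -- forward -----------------------------------------------------------

    def _forward(self, image: np.ndarray) -> tuple[list[np.ndarray], list[np.ndarray], np.ndarray]:
        """Run the full network; returns (pre-activations, activations, logits)."""
        x = _check_image(image, self.input_shape)
        zs: list[np.ndarray] = []
        acts: list[np.ndarray] = []
        for conv in self.convs:
            z, a = conv.forward(x)
            zs.append(z)
            acts.append(a)
            x = a
        pooled = acts[-1].mean(axis=(0, 1))  # (K_last,)
        logits = self.head_weights @ pooled + self.head_bias
        return zs, acts, logits

    def class_scores(self, image: np.ndarray) -> np.ndarray:
        return self._forward(image)[2]

    def _layer_index(self, layer: str) -> int:
        try:
            return self.layer_names.index(layer)
        except ValueError:
            raise InputError(
                f"unknown layer {layer!r}; valid layers: {list(self.layer_names)}"
            ) from None

    def activations(self, image: np.ndarray, layer: str) -> ActivationStack:
        idx = self._layer_index(layer)
        _, acts, _ = self._forward(image)
        return ActivationStack(maps=acts[idx], layer=layer)

    # -- backward ----------------------------------------------------------

    def score_gradients(self, image: np.ndarray, layer: str, class_index: int) -> GradientStack:
        """d logit[class_index] / d activations[layer], by hand-rolled backprop.

        The gradient is taken with respect to the *post-nonlinearity*
        activation maps of the named layer, i.e. exactly the tensor
        :meth:`activations` returns.
        """
        if not (0 <= int(class_index) < self.n_classes):
            raise InputError(
                f"class_index {class_index} out of range [0, {self.n_classes})"
            )
        idx = self._layer_index(layer)
        zs, acts, _ = self._forward(image)

        # head + global average pooling: d logit_c / d A_last = w_ck / Z
        h_last, w_last, _ = acts[-1].shape
        g = np.broadcast_to(
            self.head_weights[class_index] / (h_last * w_last),
            acts[-1].shape,
        ).copy()

        # walk down through conv layers until the requested one
        for i in range(len(self.convs) - 1, idx, -1):
            conv = self.convs[i]
            g_z = g * _activate_grad(zs[i], conv.activation)
            g = conv.backward_input(acts[i - 1].shape, g_z)
        return GradientStack(grads=g, class_index=int(class_index))

    # -- construction / serialization --------------------------------------

    @classmethod
    def from_seed(
        cls,
        seed: int,
        input_shape: tuple[int, int, int] = (32, 32, 3),
        channels: Sequence[int] = (4, 4),
        strides: Sequence[int] | None = None,
        n_classes: int = 2,
        activation: str = "relu",
        scale: float = 0.6,
    ) -> "FixtureModel":
        """Reproducible random fixture; weights ~ N(0, scale^2 / fan_in)."""
        rng = np.random.default_rng(seed)
        strides = list(strides) if strides is not None else [1] * len(channels)
        convs = []
        c_in = input_shape[2]
        for k_out, stride in zip(channels, strides):
            w = rng.normal(0.0, scale / np.sqrt(9 * c_in), size=(k_out, 3, 3, c_in))
            b = rng.normal(0.0, 0.05, size=k_out)
            convs.append(ConvLayer(weights=w, bias=b, stride=stride, activation=activation))
            c_in = k_out
        head_w = rng.normal(0.0, 1.0, size=(n_classes, c_in))
        head_b = rng.normal(0.0, 0.1, size=n_classes)
        return cls(
            input_shape=tuple(input_shape),
            convs=convs,
            head_weights=head_w,
            head_bias=head_b,
        )

    def to_json(self) -> str:
        payload = {
            "input_shape": list(self.input_shape),
            "layer_names": list(self.layer_names),
            "convs": [
                {
                    "weights": conv.weights.tolist(),
                    "bias": conv.bias.tolist(),
                    "stride": conv.stride,
                    "activation": conv.activation,
                }
                for conv in self.convs
            ],
            "head_weights": self.head_weights.tolist(),
            "head_bias": self.head_bias.tolist(),
        }
        return json.dumps(payload)

    @classmethod
    def from_json(cls, text: str) -> "FixtureModel":
        payload = json.loads(text)
        convs = [
            ConvLayer(
                weights=np.array(c["weights"]),
                bias=np.array(c["bias"]),
                stride=int(c["stride"]),
                activation=c["activation"],
            )
            for c in payload["convs"]
        ]
        return cls(
            input_shape=tuple(payload["input_shape"]),
            convs=convs,
            head_weights=np.array(payload["head_weights"]),
            head_bias=np.array(payload["head_bias"]),
            layer_names=list(payload["layer_names"]),
        )


def finite_difference_gradients(
    model: ModelAdapter,
    image: np.ndarray,
    layer: str,
    class_index: int,
    step: float = 1e-3,
) -> np.ndarray:
    """Central-difference gradient of logit[class_index] w.r.t. layer activations.

    Independent oracle for :meth:`FixtureModel.score_gradients`: perturbs each
    activation entry of the named layer by +/- step and re-runs only the part
    of the network above it.  Only implemented for :class:`FixtureModel`.
    """
    if not isinstance(model, FixtureModel):
        raise InputError("finite differences require the fixture model")
    idx = model._layer_index(layer)
    _, acts, _ = model._forward(image)
    base = acts[idx]

    def head_from(a: np.ndarray) -> float:
        x = a
        for conv in model.convs[idx + 1 :]:
            _, x = conv.forward(x)
        pooled = x.mean(axis=(0, 1))
        return float(model.head_weights[class_index] @ pooled + model.head_bias[class_index])

    grads = np.zeros_like(base)
    it = np.nditer(base, flags=["multi_index"])
    while not it.finished:
        ij = it.multi_index
        plus = base.copy()
        minus = base.copy()
        plus[ij] += step
        minus[ij] -= step
        grads[ij] = (head_from(plus) - head_from(minus)) / (2 * step)
        it.iternext()
    return grads
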