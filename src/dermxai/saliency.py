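"""Five visual explanation techniques for convolutional classifiers.

Implements the CAM family (Grad-CAM, Grad-CAM++, Eigen-CAM, Score-CAM) and
LIME as pure functions from (model, image, class) to a :class:`SaliencyMap`.
All methods share the same conventions: activations come from a named layer
of a :class:`~dermxai.model_adapter.ModelAdapter`; the coarse map is
bilinearly upsampled to the input resolution and min-max normalized to
[0, 1] (a constant raw map normalizes to all zeros).

Method summaries
----------------
Grad-CAM      weights each activation channel by the spatial mean of the
              class-score gradient, then ReLUs the weighted sum.
Grad-CAM++    weights channels by a combination of second- and third-order
              gradient powers restricted to positive partial derivatives,
              giving per-location channel weights.
Eigen-CAM     projects the activation matrix on its first right singular
              vector; class-agnostic, no gradients, no ReLU.
Score-CAM     gradient-free: each channel's upsampled, normalized map masks
              the input, and the channel weight is the induced change of the
              class score relative to a baseline image.
LIME          perturbs superpixels, fits a locally weighted ridge surrogate,
              and reads channel importance off the surrogate coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.segmentation import slic
from skimage.transform import resize
from sklearn.linear_model import Ridge

from .errors import EstimationError, InputError, NumericError
from .model_adapter import ModelAdapter

__all__ = [
    "SaliencyMap",
    "ChannelWeights",
    "SuperpixelSegmentation",
    "SurrogateExplanation",
    "TECHNIQUES",
    "minmax_normalize",
    "upsample",
    "grad_cam",
    "grad_cam_pp",
    "eigen_cam",
    "score_cam",
    "segment_superpixels",
    "lime_explain",
    "lime_to_map",
    "compute_map",
]

#: Canonical technique identifiers, in the order used throughout the package.
TECHNIQUES = ("grad_cam", "grad_cam_pp", "eigen_cam", "score_cam", "lime")


@dataclass(frozen=True)
class SaliencyMap:
    """Per-pixel relevance field at input resolution, values in [0, 1]."""

    values: np.ndarray
    method: str
    class_index: int | None
    raw_min: float
    raw_max: float

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise InputError(f"saliency map must be 2-D, got shape {v.shape}")
        if not np.isfinite(v).all():
            raise NumericError("saliency map contains non-finite values")
        if v.min() < -1e-12 or v.max() > 1 + 1e-12:
            raise InputError("saliency map values must lie in [0, 1]")
        object.__setattr__(self, "values", np.clip(v, 0.0, 1.0))


@dataclass(frozen=True)
class ChannelWeights:
    """Per-channel weights alpha_k used to combine activation maps."""

    weights: np.ndarray
    method: str


@dataclass(frozen=True)
class SuperpixelSegmentation:
    """Integer label image partitioning an image into superpixels."""

    labels: np.ndarray
    n_segments: int


@dataclass(frozen=True)
class SurrogateExplanation:
    """Fitted LIME surrogate: one weight per superpixel plus an intercept."""

    weights: np.ndarray
    intercept: float
    kernel_width: float
    n_samples: int


# ---------------------------------------------------------------------------
# shared numerics


def minmax_normalize(values: np.ndarray) -> tuple[np.ndarray, float, float]:
    """Min-max rescale to [0, 1]; a constant array maps to all zeros."""
    values = np.asarray(values, dtype=float)
    lo, hi = float(values.min()), float(values.max())
    if hi - lo <= 1e-12:
        return np.zeros_like(values), lo, hi
    return (values - lo) / (hi - lo), lo, hi


def upsample(values: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Bilinear upsampling to the target spatial shape."""
    if values.shape == tuple(shape):
        return np.asarray(values, dtype=float)
    return resize(
        np.asarray(values, dtype=float),
        shape,
        order=1,
        mode="edge",
        anti_aliasing=False,
        preserve_range=True,
    )


def _finish_map(
    raw: np.ndarray, shape: tuple[int, int], method: str, class_index: int | None
) -> SaliencyMap:
    up = upsample(raw, shape)
    normed, lo, hi = minmax_normalize(up)
    return SaliencyMap(values=normed, method=method, class_index=class_index, raw_min=lo, raw_max=hi)


def _grads_and_acts(model: ModelAdapter, image, class_index: int, layer: str):
    acts = model.activations(image, layer).maps
    grads = model.score_gradients(image, layer, class_index).grads
    if not np.isfinite(grads).all():
        raise NumericError("gradients contain non-finite values")
    if grads.shape != acts.shape:
        raise InputError("gradient and activation stacks must share a shape")
    return acts, grads


def _default_layer(model: ModelAdapter, layer: str | None) -> str:
    return layer if layer is not None else model.layer_names[-1]


# ---------------------------------------------------------------------------
# CAM family


def grad_cam(
    model: ModelAdapter,
    image: np.ndarray,
    class_index: int,
    layer: str | None = None,
) -> SaliencyMap:
    """Gradient-weighted class activation map.

    Channel weights are the spatial means of the class-score gradient,
    alpha_k = (1/Z) sum_ij d y_c / d A^k_ij; the map is
    ReLU(sum_k alpha_k A^k), upsampled and min-max normalized.
    """
    layer = _default_layer(model, layer)
    acts, grads = _grads_and_acts(model, image, class_index, layer)
    alphas = grads.mean(axis=(0, 1))  # (K,)
    raw = np.maximum((acts * alphas).sum(axis=2), 0.0)
    return _finish_map(raw, image.shape[:2], "grad_cam", class_index)


def grad_cam_weights(model, image, class_index, layer=None) -> ChannelWeights:
    """The alpha_k of Grad-CAM, exposed for inspection and testing."""
    layer = _default_layer(model, layer)
    _, grads = _grads_and_acts(model, image, class_index, layer)
    return ChannelWeights(weights=grads.mean(axis=(0, 1)), method="grad_cam")


def grad_cam_pp(
    model: ModelAdapter,
    image: np.ndarray,
    class_index: int,
    layer: str | None = None,
) -> SaliencyMap:
    """Grad-CAM++: positive partial derivatives with per-location weights.

    Uses the standard closed form: with g = d y_c / d A^k,
    a^k_ij = g_ij^2 / (2 g_ij^2 + sum_ab A^k_ab g_ab^3) (0 where the
    denominator vanishes), channel weight w_k = sum_ij a^k_ij ReLU(g_ij),
    map = ReLU(sum_k w_k A^k).
    """
    layer = _default_layer(model, layer)
    acts, grads = _grads_and_acts(model, image, class_index, layer)
    g2 = grads**2
    g3 = grads**3
    denom = 2.0 * g2 + (acts * g3).sum(axis=(0, 1), keepdims=True)
    alpha = np.where(np.abs(denom) > 1e-12, g2 / np.where(denom == 0, 1.0, denom), 0.0)
    w = (alpha * np.maximum(grads, 0.0)).sum(axis=(0, 1))  # (K,)
    raw = np.maximum((acts * w).sum(axis=2), 0.0)
    return _finish_map(raw, image.shape[:2], "grad_cam_pp", class_index)


def eigen_cam(
    model: ModelAdapter,
    image: np.ndarray,
    layer: str | None = None,
) -> SaliencyMap:
    """Eigen-CAM: projection of the activations on the first right singular
    vector.

    The (h, w, K) stack is reshaped to a Z x K matrix A (Z = h*w), factorized
    A = U S V^T, and the map is A V_1 reshaped back to (h, w).  The sign of
    V_1 is chosen so the map sums to a nonnegative value; no ReLU is applied.
    Class-agnostic.
    """
    layer = _default_layer(model, layer)
    acts = model.activations(image, layer).maps
    h, w, k = acts.shape
    a = acts.reshape(h * w, k)
    if np.allclose(a, 0.0):
        raw = np.zeros((h, w))
    else:
        _, _, vt = np.linalg.svd(a, full_matrices=False)
        proj = a @ vt[0]
        if proj.sum() < 0:
            proj = -proj
        raw = proj.reshape(h, w)
    return _finish_map(raw, image.shape[:2], "eigen_cam", None)


def score_cam(
    model: ModelAdapter,
    image: np.ndarray,
    class_index: int,
    layer: str | None = None,
    baseline: np.ndarray | None = None,
) -> SaliencyMap:
    """Score-CAM: gradient-free channel weights from masked forward passes.

    Each channel map is upsampled to the input size and min-max normalized
    to a mask H^k (a constant channel yields H^k = 0); the channel weight is
    the class score of the masked input minus the class score of the
    baseline, alpha_k = f_c(X * H^k) - f_c(X_b).  The map is
    ReLU(sum_k alpha_k A^k).  Uses exactly K + 1 forward passes beyond the
    activation extraction; the default baseline is the all-zero image.
    """
    layer = _default_layer(model, layer)
    image = np.asarray(image, dtype=float)
    if baseline is None:
        baseline = np.zeros_like(image)
    baseline = np.asarray(baseline, dtype=float)
    if baseline.shape != image.shape:
        raise InputError("baseline must have the same shape as the image")
    acts = model.activations(image, layer).maps
    k = acts.shape[2]
    f_base = float(model.class_scores(baseline)[class_index])
    alphas = np.empty(k)
    for i in range(k):
        mask, _, _ = minmax_normalize(upsample(acts[:, :, i], image.shape[:2]))
        masked = image * mask[:, :, None]
        alphas[i] = float(model.class_scores(masked)[class_index]) - f_base
    raw = np.maximum((acts * alphas).sum(axis=2), 0.0)
    return _finish_map(raw, image.shape[:2], "score_cam", class_index)


def score_cam_weights(
    model, image, class_index, layer=None, baseline=None
) -> ChannelWeights:
    """The masked-forward-pass weights of Score-CAM, exposed for testing."""
    layer = _default_layer(model, layer)
    image = np.asarray(image, dtype=float)
    if baseline is None:
        baseline = np.zeros_like(image)
    acts = model.activations(image, layer).maps
    f_base = float(model.class_scores(baseline)[class_index])
    weights = np.array(
        [
            float(
                model.class_scores(
                    image * minmax_normalize(upsample(acts[:, :, i], image.shape[:2]))[0][:, :, None]
                )[class_index]
            )
            - f_base
            for i in range(acts.shape[2])
        ]
    )
    return ChannelWeights(weights=weights, method="score_cam")


# ---------------------------------------------------------------------------
# LIME


def segment_superpixels(
    image: np.ndarray, n_segments: int, seed: int = 0
) -> SuperpixelSegmentation:
    """Partition an image into contiguous, color-homogeneous superpixels.

    Thin wrapper over SLIC; deterministic for fixed inputs (the seed is kept
    in the signature for interface stability).
    """
    image = np.asarray(image, dtype=float)
    n_pixels = image.shape[0] * image.shape[1]
    if n_segments < 2:
        raise InputError("n_segments must be >= 2")
    if n_segments > n_pixels:
        raise InputError(f"n_segments {n_segments} exceeds pixel count {n_pixels}")
    labels = slic(
        image,
        n_segments=n_segments,
        start_label=0,
        channel_axis=-1,
        enforce_connectivity=True,
    )
    # relabel densely so label values are 0..n-1
    uniq, dense = np.unique(labels, return_inverse=True)
    labels = dense.reshape(labels.shape)
    return SuperpixelSegmentation(labels=labels, n_segments=len(uniq))


def _cosine_distance_to_ones(z: np.ndarray) -> np.ndarray:
    """Cosine distance of each binary row to the all-ones vector."""
    s = z.sum(axis=1)
    n = z.shape[1]
    with np.errstate(invalid="ignore"):
        sim = s / (np.sqrt(n) * np.sqrt(np.maximum(s, 1e-300)))
    sim = np.where(s == 0, 0.0, sim)
    return 1.0 - sim


def lime_explain(
    model: ModelAdapter,
    image: np.ndarray,
    class_index: int,
    segmentation: SuperpixelSegmentation,
    n_samples: int = 1000,
    sigma: float = 0.25,
    seed: int = 0,
    mask: np.ndarray | None = None,
    ridge_alpha: float = 1e-3,
    samples: np.ndarray | None = None,
) -> SurrogateExplanation:
    """Fit a locally weighted linear surrogate to the classifier.

    Binary perturbation vectors z' switch superpixels on/off; switched-off
    segments are painted with the mean color of the lesion surround (the
    region outside ``mask``; the whole-image mean when no mask is given).
    Samples are weighted by the exponential kernel pi(z) = exp(-D(x,z)^2 /
    sigma^2) with D the cosine distance between binary vectors, and a
    ridge-regularized weighted least squares is solved for the per-segment
    weights.

    ``samples`` lets a caller supply the binary design explicitly (e.g. the
    full 2^S enumeration in tests); otherwise ``n_samples`` rows are drawn
    Bernoulli(1/2), the first row forced to all-ones.
    """
    image = np.asarray(image, dtype=float)
    labels = segmentation.labels
    n_seg = segmentation.n_segments

    if samples is not None:
        z = np.asarray(samples, dtype=float)
        if z.ndim != 2 or z.shape[1] != n_seg:
            raise InputError("samples must be (n, n_segments) binary")
    else:
        if n_samples < n_seg + 1:
            raise InputError("n_samples must be at least n_segments + 1")
        rng = np.random.default_rng(seed)
        z = rng.integers(0, 2, size=(n_samples, n_seg)).astype(float)
        z[0] = 1.0
    if np.unique(z, axis=0).shape[0] <= 1:
        raise EstimationError("degenerate perturbation design: all samples identical")

    if mask is not None:
        surround = np.asarray(mask) == 0
        if surround.any():
            replacement = image[surround].mean(axis=0)
        else:
            replacement = image.mean(axis=(0, 1))
    else:
        replacement = image.mean(axis=(0, 1))

    scores = np.empty(z.shape[0])
    for i, row in enumerate(z):
        off = ~row.astype(bool)[labels]  # (H, W) pixels to gray out
        perturbed = image.copy()
        perturbed[off] = replacement
        scores[i] = float(model.class_scores(perturbed)[class_index])

    d = _cosine_distance_to_ones(z)
    pi = np.exp(-(d**2) / sigma**2)
    reg = Ridge(alpha=ridge_alpha, fit_intercept=True)
    reg.fit(z, scores, sample_weight=pi)
    return SurrogateExplanation(
        weights=np.asarray(reg.coef_, dtype=float),
        intercept=float(reg.intercept_),
        kernel_width=float(sigma),
        n_samples=int(z.shape[0]),
    )


def lime_to_map(
    explanation: SurrogateExplanation,
    segmentation: SuperpixelSegmentation,
    top_k: int | None = None,
) -> SaliencyMap:
    """Render surrogate weights as a signed saliency map.

    Weights are rescaled affinely, w -> 0.5 + w / (2 max|w|), so 0.5 means
    no influence, values above 0.5 positive influence (warm) and below 0.5
    negative influence (cold).  Only the ``top_k`` segments by |w| are
    retained (all by default); dropped segments render at 0.5.
    """
    if top_k is not None and top_k < 1:
        raise InputError("top_k must be >= 1")
    w = np.asarray(explanation.weights, dtype=float)
    n_seg = segmentation.n_segments
    if w.shape != (n_seg,):
        raise InputError("weight vector length must equal n_segments")
    max_abs = np.abs(w).max()
    if max_abs <= 1e-12:
        values = np.full(segmentation.labels.shape, 0.5)
        return SaliencyMap(values=values, method="lime", class_index=None, raw_min=0.0, raw_max=0.0)
    keep = np.argsort(np.abs(w))[::-1][: (top_k if top_k is not None else n_seg)]
    per_segment = np.full(n_seg, 0.5)
    per_segment[keep] = 0.5 + w[keep] / (2.0 * max_abs)
    values = per_segment[segmentation.labels]
    return SaliencyMap(
        values=values,
        method="lime",
        class_index=None,
        raw_min=float(w.min()),
        raw_max=float(w.max()),
    )


# ---------------------------------------------------------------------------
# dispatch


def compute_map(
    technique: str,
    model: ModelAdapter,
    image: np.ndarray,
    class_index: int,
    layer: str | None = None,
    mask: np.ndarray | None = None,
    n_segments: int = 24,
    n_samples: int = 300,
    sigma: float = 0.25,
    seed: int = 0,
) -> SaliencyMap:
    """Compute a saliency map by technique name (one of :data:`TECHNIQUES`)."""
    if technique == "grad_cam":
        return grad_cam(model, image, class_index, layer)
    if technique == "grad_cam_pp":
        return grad_cam_pp(model, image, class_index, layer)
    if technique == "eigen_cam":
        return eigen_cam(model, image, layer)
    if technique == "score_cam":
        return score_cam(model, image, class_index, layer)
    if technique == "lime":
        seg = segment_superpixels(image, n_segments=n_segments, seed=seed)
        expl = lime_explain(
            model,
            image,
            class_index,
            seg,
            n_samples=n_samples,
            sigma=sigma,
            seed=seed,
            mask=mask,
        )
        return lime_to_map(expl, seg)
    raise InputError(f"unknown technique {technique!r}; valid: {list(TECHNIQUES)}")
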