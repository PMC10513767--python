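"""Algorithmic surrogate for the semi-quantitative ABC grading of lesions.

Clinicians screening pigmented lesions grade three features on a 0-2 ordinal
scale: Asymmetry (quadrant dissimilarity in shape and color), Border
irregularity (fraction of the outline that is locally rough or shows a color
abnormality), and Color heterogeneity (number of distinct pigment colors).
Diameter and evolution are not graded (no scale bar, single time point).

This module reproduces that rubric with explicit, frozen constants:

* the lesion is split into 4 quadrants along its principal axes;
* two quadrants are "similar" when their mirrored shapes overlap well
  (IoU >= TAU_SHAPE) and their mean colors are close (Lab distance <=
  TAU_COLOR); the asymmetry grade counts the largest mutually-similar group
  (4 -> 0, 2-3 -> 1, <=1 -> 2);
* the contour is split into arc segments; a segment is irregular when its
  radial profile deviates from a low-harmonic (smooth) outline by more than
  TAU_BORDER, or its local color roughness exceeds TAU_COLOR_GRAD; the
  irregular fraction f maps to the border grade (f = 0 -> 0, f <= 0.5 -> 1,
  f > 0.5 -> 2), and a lesion whose contour lies >50% on the image frame is
  graded NA;
* lesion pixels are clustered in Lab space, clusters closer than
  MERGE_DELTA_E are merged and clusters under 5% of the lesion are dropped;
  the surviving color count maps to the color grade (1 -> 0, 2 -> 1,
  >=3 -> 2) and all non-dominant clusters form the color-abnormality map.

Grades are ``0 | 1 | 2`` ints; NA is represented as ``None``.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from skimage.color import rgb2lab
from skimage.measure import find_contours
from sklearn.cluster import KMeans

from .errors import InputError

__all__ = [
    "QuadrantPartition",
    "partition_quadrants",
    "grade_asymmetry",
    "grade_border",
    "grade_color",
    "grade_lesion",
    "CRITERIA",
]

CRITERIA = ("asymmetry", "border", "color")

# Frozen rubric constants (calibrated once on the generator's level-0 /
# level-2 extremes; see docs/methods.md).
TAU_SHAPE = 0.75  # mirrored-quadrant IoU at or above which shapes are similar
TAU_COLOR = 10.0  # Lab (CIE76 Delta-E-like) distance for similar mean color
TAU_BORDER = 0.045  # RMS radial residual / mean radius above which an arc is irregular
TAU_COLOR_GRAD = 25.0  # Lab spread along an arc's inner band (above pigment-graze noise)
MERGE_DELTA_E = 14.0  # Lab distance under which color clusters are merged
MIN_CLUSTER_FRACTION = 0.05  # clusters smaller than this fraction are dropped
N_ARC_SEGMENTS = 36
SMOOTH_HARMONICS = 9  # harmonics kept in the smooth reference outline


@dataclass(frozen=True)
class QuadrantPartition:
    """Four quadrant masks split along the lesion's principal axes."""

    centroid: tuple[float, float]
    axes: np.ndarray  # (2, 2), rows are orthonormal axis vectors (row, col)
    quadrant_masks: tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]


def _mask_coords(mask: np.ndarray) -> np.ndarray:
    mask = np.asarray(mask).astype(bool)
    coords = np.argwhere(mask)
    if coords.shape[0] == 0:
        raise InputError("mask is empty")
    return coords


def partition_quadrants(mask: np.ndarray) -> QuadrantPartition:
    """Split a lesion mask into 4 quadrants around its centroid.

    The splitting axes are the principal axes of the mask (eigenvectors of
    the pixel-coordinate covariance), which makes downstream grades invariant
    to image rotation.  Quadrants are numbered in fixed angular order:
    (+,+), (-,+), (-,-), (+,-) in (axis-1, axis-2) coordinates.
    """
    mask = np.asarray(mask).astype(bool)
    coords = _mask_coords(mask)
    if coords.shape[0] < 4:
        raise InputError("mask too small to partition into quadrants")
    centroid = coords.mean(axis=0)
    centered = coords - centroid
    cov = centered.T @ centered / coords.shape[0]
    evals, evecs = np.linalg.eigh(cov)
    if evals[-1] <= 1e-9:
        raise InputError("degenerate mask: zero spatial variance")
    # principal axis first; fix signs for determinism.  A nearly isotropic
    # mask has no meaningful orientation — use image-aligned axes there
    # (arbitrary eigenvectors would cut through pixel centers unevenly)
    if evals[-1] / max(evals[0], 1e-12) < 1.02:
        axes = np.eye(2)
    else:
        axes = evecs[:, ::-1].T.copy()
    for i in range(2):
        j = int(np.argmax(np.abs(axes[i])))
        if axes[i, j] < 0:
            axes[i] = -axes[i]
    # right-handed frame
    if axes[0, 0] * axes[1, 1] - axes[0, 1] * axes[1, 0] < 0:
        axes[1] = -axes[1]

    u = centered @ axes[0]
    v = centered @ axes[1]
    # angular quadrant rule: each boundary half-axis belongs to exactly one
    # quadrant, so on-axis pixels are shared out evenly
    ang = np.arctan2(v, u) % (2 * np.pi)
    quadrant = np.floor(ang / (np.pi / 2)).astype(int) % 4
    quads = []
    for qi in range(4):
        sel = quadrant == qi
        q = np.zeros_like(mask)
        q[coords[sel, 0], coords[sel, 1]] = True
        quads.append(q)
    return QuadrantPartition(
        centroid=(float(centroid[0]), float(centroid[1])),
        axes=axes,
        quadrant_masks=tuple(quads),
    )


# ---------------------------------------------------------------------------
# asymmetry


def _canonical_quadrant_grid(
    coords: np.ndarray, centroid: np.ndarray, axes: np.ndarray, extent: float
) -> np.ndarray:
    """Rasterize a quadrant into a canonical |u|,|v| grid for mirror overlap.

    Grid cells are ~2 px so that a contiguous pixel set rasterizes densely
    (finer grids alias and depress the overlap of identical shapes).
    """
    n = max(12, int(np.ceil(extent / 2.0)))
    centered = coords - centroid
    u = np.abs(centered @ axes[0])
    v = np.abs(centered @ axes[1])
    grid = np.zeros((n, n), dtype=bool)
    iu = np.clip((u / extent * n).astype(int), 0, n - 1)
    iv = np.clip((v / extent * n).astype(int), 0, n - 1)
    grid[iu, iv] = True
    return grid


def _quadrant_descriptors(image: np.ndarray, mask: np.ndarray, part: QuadrantPartition):
    lab = rgb2lab(np.asarray(image, dtype=float))
    centroid = np.asarray(part.centroid)
    coords_all = _mask_coords(mask)
    extent = float(np.abs((coords_all - centroid) @ part.axes.T).max()) + 1.0
    grids, colors = [], []
    for q in part.quadrant_masks:
        coords = np.argwhere(q)
        if coords.shape[0] == 0:
            n = max(12, int(np.ceil(extent / 2.0)))
            grids.append(np.zeros((n, n), dtype=bool))
            colors.append(np.full(3, np.nan))
            continue
        grids.append(_canonical_quadrant_grid(coords, centroid, part.axes, extent))
        # median, not mean: a localized pigment blob in one quadrant should
        # not register as whole-quadrant color dissimilarity
        colors.append(np.median(lab[q], axis=0))
    return grids, colors


def _mirror_iou(g1: np.ndarray, g2: np.ndarray) -> float:
    """Overlap of two canonicalized quadrants, either orientation.

    Canonical grids of congruent quadrants are transposes of one another
    when the congruence is a 90-degree rotation rather than a reflection,
    so both orientations are tried.
    """
    best = 0.0
    for g2v in (g2, g2.T):
        inter = np.logical_and(g1, g2v).sum()
        union = np.logical_or(g1, g2v).sum()
        best = max(best, float(inter) / float(union) if union else 1.0)
    return best


def _largest_similar_group(similar: np.ndarray) -> int:
    """Size of the largest clique in the 4-node pairwise similarity graph."""
    best = 1
    for size in (4, 3, 2):
        for group in combinations(range(4), size):
            if all(similar[a, b] for a, b in combinations(group, 2)):
                return size
    return best


def grade_asymmetry(
    image: np.ndarray,
    mask: np.ndarray,
    tau_shape: float = TAU_SHAPE,
    tau_color: float = TAU_COLOR,
) -> int:
    """Asymmetry grade: 4 similar quadrants -> 0, 2-3 -> 1, <=1 -> 2."""
    part = partition_quadrants(mask)
    grids, colors = _quadrant_descriptors(image, mask, part)
    similar = np.zeros((4, 4), dtype=bool)
    for i, j in combinations(range(4), 2):
        iou = _mirror_iou(grids[i], grids[j])
        de = float(np.linalg.norm(colors[i] - colors[j]))
        similar[i, j] = similar[j, i] = (iou >= tau_shape) and (de <= tau_color)
    size = _largest_similar_group(similar)
    if size >= 4:
        return 0
    if size >= 2:
        return 1
    return 2


# ---------------------------------------------------------------------------
# border


def _longest_contour(mask: np.ndarray) -> np.ndarray:
    padded = np.pad(np.asarray(mask, dtype=float), 1)
    contours = find_contours(padded, 0.5)
    if not contours:
        raise InputError("mask has no contour")
    contour = max(contours, key=len) - 1.0  # undo padding offset
    return contour


def _frame_fraction(contour: np.ndarray, shape: tuple[int, int]) -> float:
    h, w = shape
    on_frame = (
        (contour[:, 0] <= 0.0)
        | (contour[:, 0] >= h - 1.0)
        | (contour[:, 1] <= 0.0)
        | (contour[:, 1] >= w - 1.0)
    )
    return float(on_frame.mean())


def _radial_profile(contour: np.ndarray, centroid: np.ndarray, n: int = 360):
    rel = contour - centroid
    theta = np.arctan2(rel[:, 0], rel[:, 1])
    r = np.hypot(rel[:, 0], rel[:, 1])
    order = np.argsort(theta)
    theta, r = theta[order], r[order]
    grid = np.linspace(-np.pi, np.pi, n, endpoint=False)
    theta_ext = np.concatenate([theta - 2 * np.pi, theta, theta + 2 * np.pi])
    r_ext = np.concatenate([r, r, r])
    return grid, np.interp(grid, theta_ext, r_ext)


def _smooth_outline(grid: np.ndarray, r: np.ndarray, harmonics: int = SMOOTH_HARMONICS):
    cols = [np.ones_like(grid)]
    for m in range(1, harmonics + 1):
        cols.append(np.cos(m * grid))
        cols.append(np.sin(m * grid))
    design = np.stack(cols, axis=1)
    coef, *_ = np.linalg.lstsq(design, r, rcond=None)
    return design @ coef


def border_irregular_fraction(
    image: np.ndarray,
    mask: np.ndarray,
    n_segments: int = N_ARC_SEGMENTS,
    tau_k: float = TAU_BORDER,
    tau_g: float = TAU_COLOR_GRAD,
) -> float:
    """Fraction of contour arc segments judged irregular.

    A segment is irregular when the RMS deviation of its radial profile from
    a smooth (<= SMOOTH_HARMONICS harmonics) reference outline exceeds
    ``tau_k`` (in units of the mean radius), or when the Lab color spread in
    the inner band along the segment exceeds ``tau_g``.
    """
    mask = np.asarray(mask).astype(bool)
    contour = _longest_contour(mask)
    centroid = np.argwhere(mask).mean(axis=0)
    grid, r = _radial_profile(contour, centroid)
    r_smooth = _smooth_outline(grid, r)
    residual = (r - r_smooth) / max(float(r.mean()), 1e-9)

    lab = rgb2lab(np.asarray(image, dtype=float))
    h, w = mask.shape
    n = len(grid)
    seg_len = n // n_segments
    irregular = 0
    for s in range(n_segments):
        sl = slice(s * seg_len, (s + 1) * seg_len)
        rough = np.sqrt(np.mean(residual[sl] ** 2)) > tau_k
        # color roughness just inside the contour along this arc
        rows = centroid[0] + 0.85 * r_smooth[sl] * np.sin(grid[sl])
        cols = centroid[1] + 0.85 * r_smooth[sl] * np.cos(grid[sl])
        ri = np.clip(np.round(rows).astype(int), 0, h - 1)
        ci = np.clip(np.round(cols).astype(int), 0, w - 1)
        inside = mask[ri, ci]
        colorful = False
        if inside.sum() >= 4:
            seg_lab = lab[ri[inside], ci[inside]]
            colorful = float(np.linalg.norm(seg_lab.std(axis=0))) > tau_g
        irregular += int(rough or colorful)
    return irregular / n_segments


def grade_border(
    image: np.ndarray,
    mask: np.ndarray,
    n_segments: int = N_ARC_SEGMENTS,
    tau_k: float = TAU_BORDER,
    tau_g: float = TAU_COLOR_GRAD,
) -> int | None:
    """Border grade: 0 / 1 / 2 by irregular arc fraction; None (NA) when
    more than half of the contour lies on the image frame."""
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise InputError("mask is empty")
    contour = _longest_contour(mask)
    if _frame_fraction(contour, mask.shape) > 0.5:
        return None
    f = border_irregular_fraction(image, mask, n_segments, tau_k, tau_g)
    if f == 0.0:
        return 0
    if f <= 0.5:
        return 1
    return 2


# ---------------------------------------------------------------------------
# color


def _merge_centers(centers: np.ndarray, counts: np.ndarray, delta_e: float):
    """Agglomerate cluster centers closer than delta_e (count-weighted)."""
    centers = centers.copy()
    counts = counts.astype(float).copy()
    alive = list(range(len(centers)))
    merged = {i: [i] for i in alive}
    while True:
        best = None
        for a, b in combinations(alive, 2):
            d = np.linalg.norm(centers[a] - centers[b])
            if d < delta_e and (best is None or d < best[0]):
                best = (d, a, b)
        if best is None:
            break
        _, a, b = best
        total = counts[a] + counts[b]
        centers[a] = (centers[a] * counts[a] + centers[b] * counts[b]) / total
        counts[a] = total
        merged[a].extend(merged.pop(b))
        alive.remove(b)
    return alive, centers, counts, merged


def grade_color(
    image: np.ndarray,
    mask: np.ndarray,
    max_colors: int = 5,
    merge_delta_e: float = MERGE_DELTA_E,
    min_fraction: float = MIN_CLUSTER_FRACTION,
    seed: int = 0,
) -> tuple[int, np.ndarray]:
    """Color-heterogeneity grade plus the derived color-abnormality map.

    Lesion pixels are k-means clustered in Lab space (k = ``max_colors``),
    centers closer than ``merge_delta_e`` are merged, and merged clusters
    covering less than ``min_fraction`` of the lesion are dropped.  The
    surviving count c maps to the grade (1 -> 0, 2 -> 1, >=3 -> 2); the
    abnormality map collects the pixels of every non-dominant surviving
    cluster (empty at grade 0).
    """
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise InputError("mask is empty")
    lab = rgb2lab(np.asarray(image, dtype=float))
    px = lab[mask]
    k = int(min(max_colors, px.shape[0]))
    km = KMeans(n_clusters=k, n_init=4, random_state=seed)
    labels = km.fit_predict(px)
    counts = np.bincount(labels, minlength=k)
    alive, centers, merged_counts, members = _merge_centers(km.cluster_centers_, counts, merge_delta_e)

    # merged cluster id per pixel
    owner = np.empty(k, dtype=int)
    for a in alive:
        for m in members[a]:
            owner[m] = a
    merged_labels = owner[labels]

    kept = [a for a in alive if merged_counts[a] / px.shape[0] >= min_fraction]
    if not kept:
        kept = [max(alive, key=lambda a: merged_counts[a])]
    # reassign pixels of dropped clusters to the nearest kept center
    kept_centers = centers[kept]
    drop_sel = ~np.isin(merged_labels, kept)
    if drop_sel.any():
        d = np.linalg.norm(px[drop_sel, None, :] - kept_centers[None, :, :], axis=2)
        merged_labels[drop_sel] = np.asarray(kept)[d.argmin(axis=1)]

    kept_counts = {a: int((merged_labels == a).sum()) for a in kept}
    dominant = max(kept, key=lambda a: kept_counts[a])
    c = len(kept)
    grade = 0 if c == 1 else (1 if c == 2 else 2)

    abnormality = np.zeros_like(mask)
    if c > 1:
        abn_px = merged_labels != dominant
        coords = np.argwhere(mask)
        sel = coords[abn_px]
        abnormality[sel[:, 0], sel[:, 1]] = True
    return grade, abnormality


def grade_lesion(image: np.ndarray, mask: np.ndarray, seed: int = 0) -> dict:
    """All three clinical grades for one lesion.

    Returns {'asymmetry': g, 'border': g|None, 'color': g,
    'abnormality_map': binary array}.
    """
    a = grade_asymmetry(image, mask)
    b = grade_border(image, mask)
    c, abn = grade_color(image, mask, seed=seed)
    return {"asymmetry": a, "border": b, "color": c, "abnormality_map": abn}
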