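"""Synthetic dermoscopy-like lesion generator with known ABC ground truth.

The reader study that motivates this package graded real dermoscopy images;
those are out of reach for automated testing, so this module generates
pigmented-lesion look-alikes whose asymmetry, border irregularity, and color
heterogeneity are *controlled by construction*:

* the lesion outline is a star-convex curve
  r(theta) = r0 * e(theta) * (1 + b(theta)) * (1 + delta(theta)):
  e is a global elliptical elongation, b a per-quadrant bump signature
  (lobe / flat / notch, optionally with a lightness shift) carrying the
  asymmetry level, and delta a fixed-amplitude high-harmonic wiggle applied
  over exactly ``irregular_arc_fraction`` of the arc, carrying the border
  level;
* pigment is painted from a fixed brown/black/red/blue-gray palette, one
  blob per color beyond the base, carrying the color level; the union of
  non-base blobs is the ground-truth color-abnormality map;
* a ``border_na`` lesion is oversized and centered on the image edge so
  most of its outline falls outside the photographed field (border NA).

Ground-truth grades follow the rubric directly: asymmetry level = A grade;
arc fraction 0 -> B 0, (0, 0.5] -> B 1, > 0.5 -> B 2 (NA when off-canvas);
1/2/>=3 colors -> C 0/1/2.

The module also builds *synthetic saliency maps* with prescribed quadrant
intensities, border-band warm/cold fractions, and warm overlap with the
abnormality map — fixtures with exactly known map grades, used to test the
map-grading rubric.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
from skimage.draw import disk as draw_disk
from skimage.draw import polygon as draw_polygon

from .clinical import partition_quadrants
from .errors import InputError
from .map_grading import border_band
from .saliency import SaliencyMap

__all__ = [
    "PALETTE",
    "LesionSpec",
    "SyntheticLesion",
    "SyntheticMapSpec",
    "make_lesion",
    "make_synthetic_map",
    "make_cohort",
]

#: Pigment palette (RGB in [0,1]): base brown, then extra colors in the
#: order blobs are added.
PALETTE = {
    "brown": np.array([0.45, 0.30, 0.20]),
    "black": np.array([0.16, 0.11, 0.10]),
    "red": np.array([0.66, 0.24, 0.22]),
    "bluegray": np.array([0.46, 0.50, 0.58]),
}
_EXTRA_COLORS = ("black", "red", "bluegray")

BACKGROUND = np.array([0.92, 0.80, 0.72])  # light skin tone
NOISE_SIGMA = 0.02  # additive Gaussian texture noise
WIGGLE_AMPLITUDE = 0.13  # radial wiggle amplitude, relative to r(theta)
WIGGLE_HARMONIC = 14  # wiggle frequency (cycles per revolution)
RADIUS_FRACTION = 0.22  # r0 as a fraction of min(canvas)
ELONGATION = 0.28  # global 2nd-harmonic elongation pinning the principal axes

# Asymmetry is carried by quadrant-localized *bump signatures* on the radial
# profile: a mid-quadrant outward lobe, a flat arc, an inward notch, or a
# lobe with a lightness shift.  Low-order radial scalings (harmonic 1 and 2)
# would be absorbed by the measured centroid / principal axes, so quadrant
# dissimilarity must live in the localized profile shape instead.
# Each signature is (bump kind, bump amplitude, lightness shift).
_QUADRANT_SIGNATURES = {
    0: (("lobe", 0.42, 0.0),) * 4,
    1: (("lobe", 0.42, 0.0),) * 3 + (("flat", 0.0, 0.0),),
    2: (
        ("lobe", 0.42, 0.0),
        ("flat", 0.0, 0.0),
        ("notch", 0.38, 0.30),
        ("lobe", 0.42, 0.30),
    ),
}
# border-level -> irregular arc fraction (midpoints of the rubric intervals)
_ARC_FRACTION = {0: 0.0, 1: 0.25, 2: 0.75}


@dataclass(frozen=True)
class LesionSpec:
    """Generator parameters for one lesion; grades derive from the fields."""

    seed: int
    canvas: tuple[int, int] = (128, 128)
    asymmetry_level: int = 0
    border_level: int = 0
    n_colors: int = 1
    border_na: bool = False
    irregular_arc_fraction: float | None = None
    central_blobs: bool = False

    def __post_init__(self) -> None:
        if self.asymmetry_level not in (0, 1, 2):
            raise InputError("asymmetry_level must be 0, 1 or 2")
        if self.border_level not in (0, 1, 2):
            raise InputError("border_level must be 0, 1 or 2")
        if not 1 <= self.n_colors <= 4:
            raise InputError("n_colors must be in 1..4")
        if self.irregular_arc_fraction is not None and not (
            0.0 <= self.irregular_arc_fraction <= 1.0
        ):
            raise InputError("irregular_arc_fraction must be in [0, 1]")

    @property
    def arc_fraction(self) -> float:
        if self.irregular_arc_fraction is not None:
            return float(self.irregular_arc_fraction)
        return _ARC_FRACTION[self.border_level]

    @property
    def truth_grades(self) -> dict:
        """(A, B, C) ground truth implied by the generator fields; B is None when NA."""
        f = self.arc_fraction
        if self.border_na:
            b: int | None = None
        elif f == 0.0:
            b = 0
        elif f <= 0.5:
            b = 1
        else:
            b = 2
        c = 0 if self.n_colors == 1 else (1 if self.n_colors == 2 else 2)
        return {"asymmetry": self.asymmetry_level, "border": b, "color": c}


@dataclass(frozen=True)
class SyntheticLesion:
    """Rendered lesion: image, mask, abnormality map, and its spec."""

    image: np.ndarray
    mask: np.ndarray
    color_abnormality_map: np.ndarray
    spec: LesionSpec

    @property
    def truth_grades(self) -> dict:
        return self.spec.truth_grades


def _signature_bumps(theta: np.ndarray, signatures, phi0: float) -> np.ndarray:
    """Per-quadrant radial bump profile (relative to r0).

    ``t`` is the position within the quadrant arc; a lobe adds
    ``+a sin(pi t)`` (mirror-symmetric about mid-quadrant, zero at the
    boundaries, so the outline stays smooth and canonical quadrant mirroring
    is well defined), a notch subtracts it, a flat arc adds nothing.
    """
    pos = ((theta - phi0) % (2 * np.pi)) / (np.pi / 2)
    quadrant = np.floor(pos).astype(int) % 4
    t = pos - np.floor(pos)
    # bumps occupy only the central 70% of the quadrant arc so that the
    # modest swing of the *measured* quadrant boundaries (the graders use
    # the mask's own principal axes) cannot clip them
    s = np.clip((t - 0.15) / 0.7, 0.0, 1.0)
    profile = np.where((t >= 0.15) & (t <= 0.85), np.sin(np.pi * s), 0.0)
    bump = np.zeros_like(theta)
    for q, (kind, amp, _shade) in enumerate(signatures):
        sel = quadrant == q
        if kind == "flat" or amp == 0.0:
            continue
        sign = -1.0 if kind == "notch" else 1.0
        bump[sel] = sign * amp * profile[sel]
    return bump


def _wiggle(theta: np.ndarray, arc_fraction: float, theta0: float, phase: float) -> np.ndarray:
    """High-harmonic radial perturbation over a contiguous arc."""
    if arc_fraction <= 0.0:
        return np.zeros_like(theta)
    span = 2 * np.pi * arc_fraction
    pos = (theta - theta0) % (2 * np.pi)
    window = np.zeros_like(theta)
    inside = pos <= span
    ramp = min(np.pi * 8 / 180, span / 4)  # raised-cosine edges
    t = pos[inside]
    w = np.ones(t.shape)
    w[t < ramp] = 0.5 * (1 - np.cos(np.pi * t[t < ramp] / ramp))
    tail = span - t
    w[tail < ramp] = np.minimum(w[tail < ramp], 0.5 * (1 - np.cos(np.pi * tail[tail < ramp] / ramp)))
    window[inside] = w
    return WIGGLE_AMPLITUDE * np.sin(WIGGLE_HARMONIC * theta + phase) * window


def make_lesion(spec: LesionSpec) -> SyntheticLesion:
    """Render one lesion deterministically from its spec."""
    h, w = spec.canvas
    r0 = RADIUS_FRACTION * min(h, w)
    if r0 < 10:
        raise InputError(f"canvas {spec.canvas} too small for base radius {r0:.1f}")
    rng = np.random.default_rng(spec.seed)

    phi0 = rng.uniform(0, 2 * np.pi)
    theta0 = rng.uniform(0, 2 * np.pi)
    phase = rng.uniform(0, 2 * np.pi)
    signatures = _QUADRANT_SIGNATURES[spec.asymmetry_level]

    theta = np.linspace(0, 2 * np.pi, 720, endpoint=False)
    elong = 1.0 + ELONGATION * np.cos(2 * (theta - phi0))
    if spec.border_na:
        # an oversized smooth lesion centered on the image edge: the visible
        # piece touches three frame sides, so well over half of its outline
        # lies on the frame / outside the photographed field.  Shape
        # modifiers are suppressed — an off-canvas border cannot be
        # evaluated, which is exactly what the NA grade encodes.
        elong_v = 1.0 + ELONGATION * np.cos(2 * (theta - np.pi / 2))
        r = r0 * 3.2 * elong_v
        center = np.array([h / 2, 0.0])
    else:
        bumps = 1.0 + _signature_bumps(theta, signatures, phi0)
        r = r0 * elong * bumps * (1.0 + _wiggle(theta, spec.arc_fraction, theta0, phase))
        center = np.array([h / 2, w / 2]) + rng.uniform(-0.03 * r0, 0.03 * r0, size=2)

    rows = center[0] + r * np.sin(theta)
    cols = center[1] + r * np.cos(theta)
    mask = np.zeros((h, w), dtype=bool)
    rr, cc = draw_polygon(rows, cols, shape=(h, w))
    mask[rr, cc] = True
    if not mask.any():
        raise InputError("lesion fell entirely outside the canvas")

    # background: light skin with a mild vignette
    yy, xx = np.mgrid[0:h, 0:w]
    d2 = ((yy - h / 2) / (h / 2)) ** 2 + ((xx - w / 2) / (w / 2)) ** 2
    image = BACKGROUND[None, None, :] * (1.0 - 0.08 * d2)[:, :, None]

    # base pigment with per-quadrant shading
    shade = np.asarray([s[2] for s in signatures], dtype=float)
    ang = np.arctan2(yy - center[0], xx - center[1])
    quadrant = np.floor(((ang - phi0) % (2 * np.pi)) / (np.pi / 2)).astype(int) % 4
    base = PALETTE["brown"][None, None, :] * (1.0 + shade[quadrant])[:, :, None]
    image = np.where(mask[:, :, None], base, image)

    # extra pigment blobs -> color-abnormality map
    abnormality = np.zeros((h, w), dtype=bool)
    if spec.n_colors > 1:
        centroid = np.argwhere(mask).mean(axis=0)
        if spec.central_blobs:
            radii = [0.45 * r0, 0.30 * r0, 0.18 * r0]
            centers = [centroid] * 3
        else:
            radii = [0.30 * r0] * 3
            centers = []
            from scipy.ndimage import binary_erosion

            # keep blobs clear of the contour so pigment abnormalities do
            # not spill into the border band (border truth is geometric)
            safe = np.zeros_like(mask)
            for inset in (0.45, 0.35, 0.25, 0.10):
                safe = binary_erosion(mask, iterations=max(1, int(inset * r0)))
                if safe.sum() >= 16:
                    break
            pool = np.argwhere(safe if safe.any() else mask)
            for i in range(3):
                best = None
                for _ in range(20):
                    cand = pool[rng.integers(len(pool))].astype(float)
                    dmin = min(
                        (np.linalg.norm(cand - c) for c in centers), default=np.inf
                    )
                    if best is None or dmin > best[0]:
                        best = (dmin, cand)
                    if dmin > 0.55 * r0:
                        break
                centers.append(best[1])
        for i in range(spec.n_colors - 1):
            blob = np.zeros((h, w), dtype=bool)
            rr, cc = draw_disk(tuple(centers[i]), radii[i], shape=(h, w))
            blob[rr, cc] = True
            blob &= mask
            image[blob] = PALETTE[_EXTRA_COLORS[i]]
            abnormality |= blob
        if spec.central_blobs and spec.n_colors > 2:
            # inner blobs overwrite outer ones; abnormality stays the union
            pass

    image = np.clip(image + rng.normal(0.0, NOISE_SIGMA, size=image.shape), 0.0, 1.0)
    return SyntheticLesion(
        image=image, mask=mask, color_abnormality_map=abnormality, spec=spec
    )


# ---------------------------------------------------------------------------
# synthetic saliency-map fixtures


@dataclass(frozen=True)
class SyntheticMapSpec:
    """Prescription for a saliency-map fixture with known map grades."""

    quadrant_intensities: tuple[float, float, float, float] = (0.35, 0.35, 0.35, 0.35)
    border_warm_fraction: float = 0.0
    border_cold_fraction: float = 0.0
    abnormality_warm_overlap: float = 1.0

    WARM_VALUE: float = field(default=0.85, repr=False)
    COLD_VALUE: float = field(default=0.40, repr=False)
    LOW_VALUE: float = field(default=0.05, repr=False)
    ABN_REST_VALUE: float = field(default=0.10, repr=False)

    def __post_init__(self) -> None:
        for q in self.quadrant_intensities:
            if not 0.0 <= q <= 1.0:
                raise InputError("quadrant intensities must be in [0, 1]")
        if self.border_warm_fraction + self.border_cold_fraction > 1.0 + 1e-9:
            raise InputError("warm + cold border fractions must be <= 1")
        for f in (
            self.border_warm_fraction,
            self.border_cold_fraction,
            self.abnormality_warm_overlap,
        ):
            if not 0.0 <= f <= 1.0:
                raise InputError("fractions must be in [0, 1]")

    def intended_grades(self, lesion: SyntheticLesion) -> dict:
        """Map grades this fixture is constructed to receive.

        Mirrors the grading rubric on the prescription itself: quadrant
        intensities equal (within 0.02) count as similar; border warm/cold
        fractions follow the warm>50% / any-warm-or-cold>50% rule; the
        abnormality overlap follows the 75%/25% warm-agreement bands.
        """
        q = np.asarray(self.quadrant_intensities)
        similar = np.abs(q[:, None] - q[None, :]) <= 0.02
        from .clinical import _largest_similar_group

        size = _largest_similar_group(similar)
        a = 0 if size >= 4 else (1 if size >= 2 else 2)

        if lesion.spec.truth_grades["border"] is None:
            b: int | None = None
        elif self.border_warm_fraction > 0.5:
            b = 2
        elif self.border_warm_fraction > 0.0 or self.border_cold_fraction > 0.5:
            b = 1
        else:
            b = 0

        if not lesion.color_abnormality_map.any():
            c = 0
        elif self.abnormality_warm_overlap > 0.75:
            c = 0
        elif self.abnormality_warm_overlap >= 0.25:
            c = 1
        else:
            c = 2
        return {"asymmetry": a, "border": b, "color": c}


def _angular_order(coords: np.ndarray, centroid: np.ndarray) -> np.ndarray:
    ang = np.arctan2(coords[:, 0] - centroid[0], coords[:, 1] - centroid[1])
    return np.argsort(ang, kind="stable")


def make_synthetic_map(spec: SyntheticMapSpec, lesion: SyntheticLesion) -> SaliencyMap:
    """Build a saliency-map fixture realizing the prescription on a lesion.

    Quadrant interiors carry the prescribed intensities; the border band and
    the abnormality region are assigned warm/cold/low values *stratified by
    quadrant* (same fractions within each quadrant, pixels picked in
    deterministic angular order) so that the band and overlap statistics hit
    the prescribed fractions without disturbing quadrant symmetry.
    """
    mask = lesion.mask
    part = partition_quadrants(mask)
    ring = border_band(mask)
    if not ring.band.any():
        raise InputError("border band is empty")
    abn = lesion.color_abnormality_map
    centroid = np.asarray(part.centroid)

    values = np.zeros(mask.shape, dtype=float)
    interior = mask & ~ring.band & ~abn
    for qi, q in enumerate(part.quadrant_masks):
        values[q & interior] = spec.quadrant_intensities[qi]

    band_in_quad = [ring.band & q for q in part.quadrant_masks]
    unassigned_band = ring.band.copy()
    for q_band in band_in_quad:
        unassigned_band &= ~q_band
    # band pixels outside the mask (dilated part) fall in no quadrant; treat
    # them as a fifth stratum so global fractions still hold
    strata = band_in_quad + [unassigned_band]
    for stratum in strata:
        coords = np.argwhere(stratum)
        if coords.shape[0] == 0:
            continue
        order = _angular_order(coords, centroid)
        n = coords.shape[0]
        n_warm = int(round(spec.border_warm_fraction * n))
        n_cold = int(round(spec.border_cold_fraction * n))
        n_cold = min(n_cold, n - n_warm)
        vals = np.full(n, spec.LOW_VALUE)
        vals[:n_warm] = spec.WARM_VALUE
        vals[n_warm : n_warm + n_cold] = spec.COLD_VALUE
        sel = coords[order]
        values[sel[:, 0], sel[:, 1]] = vals

    if abn.any():
        for q in part.quadrant_masks:
            coords = np.argwhere(abn & q & ~ring.band)
            if coords.shape[0] == 0:
                continue
            order = _angular_order(coords, centroid)
            n = coords.shape[0]
            n_warm = int(round(spec.abnormality_warm_overlap * n))
            vals = np.full(n, spec.ABN_REST_VALUE)
            vals[:n_warm] = spec.WARM_VALUE
            sel = coords[order]
            values[sel[:, 0], sel[:, 1]] = vals

    return SaliencyMap(
        values=np.clip(values, 0.0, 1.0),
        method="synthetic",
        class_index=None,
        raw_min=float(values.min()),
        raw_max=float(values.max()),
    )


# ---------------------------------------------------------------------------
# cohorts


def make_cohort(
    n: int,
    seed: int,
    grade_distribution: dict | str | None = None,
    canvas: tuple[int, int] = (128, 128),
    na_fraction: float = 0.05,
) -> list[SyntheticLesion]:
    """Generate a reproducible cohort of lesions.

    With ``grade_distribution=None`` the 27 (A, B, C) grade cells are swept
    cyclically (all combinations covered once n >= 27); ``"uniform"`` or an
    explicit ``{(a, b, c): probability}`` dict samples cells at random.
    ``na_fraction`` of lesions are rendered off-canvas (border NA).
    """
    if n < 1:
        raise InputError("cohort size must be >= 1")
    rng = np.random.default_rng(seed)
    cells = list(product((0, 1, 2), (0, 1, 2), (1, 2, 3)))  # (A, B, n_colors)
    if grade_distribution is None:
        chosen = [cells[i % len(cells)] for i in range(n)]
    else:
        if grade_distribution == "uniform":
            probs = np.full(len(cells), 1.0 / len(cells))
        else:
            probs = np.array(
                [grade_distribution.get((a, b, c - 1), 0.0) for a, b, c in cells]
            )
            if probs.sum() <= 0:
                raise InputError("grade_distribution has no mass on valid cells")
            probs = probs / probs.sum()
        idx = rng.choice(len(cells), size=n, p=probs)
        chosen = [cells[i] for i in idx]

    lesions = []
    for i, (a, b, c) in enumerate(chosen):
        spec = LesionSpec(
            seed=int(rng.integers(0, 2**31 - 1)),
            canvas=canvas,
            asymmetry_level=a,
            border_level=b,
            n_colors=c,
            border_na=bool(rng.random() < na_fraction),
        )
        lesions.append(make_lesion(spec))
    return lesions


# ---------------------------------------------------------------------------
# rubric fixture suite


def rubric_fixture_suite(base_seed: int = 5) -> list[tuple[SyntheticLesion, SyntheticMapSpec]]:
    """Fifty map fixtures at rubric-interior settings, with known grades.

    Every prescribed quantity sits at least 5% away from a rubric decision
    boundary: equal quadrant intensities are exactly equal and unequal ones
    differ by >= 0.1 (the similarity tolerance is 0.06); border fractions
    avoid the 0.5 cut by >= 0.05; warm overlaps avoid the 0.25/0.75 cuts by
    >= 0.05.  Asymmetry/border fixtures use a plain one-color lesion (empty
    abnormality map), color fixtures a lesion with a centered pigment blob.
    """
    plain = make_lesion(LesionSpec(seed=base_seed, n_colors=1))
    blob = make_lesion(LesionSpec(seed=base_seed, n_colors=2, central_blobs=True))

    quadrant_patterns = [
        (0.35, 0.35, 0.35, 0.35),
        (0.25, 0.25, 0.25, 0.25),
        (0.45, 0.45, 0.45, 0.45),
        (0.15, 0.15, 0.15, 0.15),
        (0.50, 0.50, 0.50, 0.50),
        (0.35, 0.35, 0.35, 0.15),
        (0.45, 0.45, 0.45, 0.25),
        (0.20, 0.20, 0.20, 0.40),
        (0.30, 0.30, 0.30, 0.50),
        (0.15, 0.15, 0.35, 0.35),
        (0.25, 0.25, 0.45, 0.45),
        (0.40, 0.40, 0.20, 0.55),
        (0.10, 0.25, 0.40, 0.55),
        (0.15, 0.30, 0.45, 0.58),
        (0.12, 0.24, 0.36, 0.48),
        (0.10, 0.22, 0.34, 0.46),
        (0.14, 0.28, 0.42, 0.56),
        (0.11, 0.23, 0.35, 0.47),
    ]
    border_settings = [
        (0.0, 0.0), (0.0, 0.10), (0.0, 0.30), (0.0, 0.44),
        (0.10, 0.0), (0.20, 0.0), (0.30, 0.0), (0.44, 0.0),
        (0.10, 0.30), (0.20, 0.20), (0.30, 0.10), (0.44, 0.20),
        (0.56, 0.0), (0.70, 0.0), (0.85, 0.0), (0.60, 0.20),
        (0.0, 0.56), (0.0, 0.70), (0.0, 0.85), (0.10, 0.60),
    ]
    overlaps = [0.0, 0.10, 0.19, 0.31, 0.45, 0.55, 0.70, 0.81, 0.90, 0.95, 1.0, 0.60]

    suite: list[tuple[SyntheticLesion, SyntheticMapSpec]] = []
    for qp in quadrant_patterns:
        suite.append((plain, SyntheticMapSpec(quadrant_intensities=qp)))
    for wf, cf in border_settings:
        suite.append((plain, SyntheticMapSpec(border_warm_fraction=wf, border_cold_fraction=cf)))
    for ov in overlaps:
        suite.append((blob, SyntheticMapSpec(abnormality_warm_overlap=ov)))
    return suite
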