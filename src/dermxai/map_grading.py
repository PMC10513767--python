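"""Grading of saliency maps against the ABC rubric.

The reader-study rubric grades a rendered heatmap by its warm (orange/red)
and cold (blue/purple) regions.  Rendering is a fixed, invertible mapping
from the normalized map value through a blue-to-red colormap, so the rubric
is operationalized directly on the normalized values: a pixel is *warm* when
its value is at least THETA_WARM and *cold* when it falls in
[THETA_COLD_LO, THETA_WARM).  Grades therefore never depend on the rendered
colors themselves, only on the map.

Three grades are produced per map:

asymmetry   quadrant similarity of (mean value, warm fraction) descriptors,
            counted exactly like clinical asymmetry;
border      warm/cold pixel fractions over a morphological ring around the
            lesion contour (f_warm > 50% -> 2; any warm or > 50% cold -> 1;
            else 0; clinical NA propagates);
color       overlap of the warm region with the lesion's color-abnormality
            map (> 75% warm overlap -> 0; 25-75% warm or > 75% cold -> 1;
            else 2; an empty abnormality map grades 0).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from skimage.morphology import dilation, disk, erosion

from .clinical import _largest_similar_group, partition_quadrants
from .errors import InputError
from .saliency import SaliencyMap

__all__ = [
    "WarmColdBands",
    "BorderBand",
    "border_band",
    "grade_map_asymmetry",
    "grade_map_border",
    "grade_color_match",
    "grade_map",
]

THETA_WARM = 0.6
THETA_COLD_LO = 0.2
TAU_MEAN = 0.06  # quadrant mean-value difference at or below which similar
TAU_WARM_FRAC = 0.20  # quadrant warm-fraction difference for similarity


@dataclass(frozen=True)
class WarmColdBands:
    """Thresholds splitting normalized map values into warm/cold/none."""

    theta_warm: float = THETA_WARM
    theta_cold_lo: float = THETA_COLD_LO

    def __post_init__(self) -> None:
        if not (0.0 <= self.theta_cold_lo < self.theta_warm <= 1.0):
            raise InputError("need 0 <= theta_cold_lo < theta_warm <= 1")

    def warm(self, values: np.ndarray) -> np.ndarray:
        return values >= self.theta_warm

    def cold(self, values: np.ndarray) -> np.ndarray:
        return (values >= self.theta_cold_lo) & (values < self.theta_warm)


@dataclass(frozen=True)
class BorderBand:
    """Morphological ring around the lesion contour."""

    band: np.ndarray
    width_px: int


def border_band(mask: np.ndarray, width_px: int | None = None) -> BorderBand:
    """Ring containing the mask contour; width = max(3 px, 5% of the
    equivalent lesion radius) unless given."""
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise InputError("mask is empty")
    if width_px is None:
        r_eq = np.sqrt(mask.sum() / np.pi)
        width_px = max(3, int(round(0.05 * r_eq)))
    half = max(1, int(round(width_px / 2)))
    band = dilation(mask, disk(half)) & ~erosion(mask, disk(half))
    if not band.any():
        raise InputError("border band is empty")
    return BorderBand(band=band, width_px=int(width_px))


def _map_values(smap: SaliencyMap | np.ndarray) -> np.ndarray:
    values = smap.values if isinstance(smap, SaliencyMap) else np.asarray(smap, dtype=float)
    if values.ndim != 2:
        raise InputError("map must be 2-D")
    return values


def grade_map_asymmetry(
    smap: SaliencyMap | np.ndarray,
    mask: np.ndarray,
    bands: WarmColdBands = WarmColdBands(),
    tau_mean: float = TAU_MEAN,
    tau_warm: float = TAU_WARM_FRAC,
) -> int:
    """Asymmetry of the map over the lesion quadrants (0/1/2)."""
    values = _map_values(smap)
    mask = np.asarray(mask).astype(bool)
    if values.shape != mask.shape:
        raise InputError("map and mask must share a shape")
    part = partition_quadrants(mask)
    desc = []
    warm = bands.warm(values)
    for q in part.quadrant_masks:
        if not q.any():
            desc.append((np.nan, np.nan))
            continue
        desc.append((float(values[q].mean()), float(warm[q].mean())))
    similar = np.zeros((4, 4), dtype=bool)
    for i, j in combinations(range(4), 2):
        ok = (
            np.isfinite(desc[i][0])
            and np.isfinite(desc[j][0])
            and abs(desc[i][0] - desc[j][0]) <= tau_mean
            and abs(desc[i][1] - desc[j][1]) <= tau_warm
        )
        similar[i, j] = similar[j, i] = ok
    size = _largest_similar_group(similar)
    if size >= 4:
        return 0
    if size >= 2:
        return 1
    return 2


def grade_map_border(
    smap: SaliencyMap | np.ndarray,
    mask: np.ndarray,
    clinical_border: int | None,
    bands: WarmColdBands = WarmColdBands(),
    band: BorderBand | None = None,
) -> int | None:
    """Border-highlight grade over the contour ring; NA propagates."""
    if clinical_border is None:
        return None
    values = _map_values(smap)
    mask = np.asarray(mask).astype(bool)
    if values.shape != mask.shape:
        raise InputError("map and mask must share a shape")
    ring = band if band is not None else border_band(mask)
    px = values[ring.band]
    f_warm = float(bands.warm(px).mean())
    f_cold = float(bands.cold(px).mean())
    if f_warm > 0.5:
        return 2
    if f_warm > 0.0 or f_cold > 0.5:
        return 1
    return 0


def grade_color_match(
    smap: SaliencyMap | np.ndarray,
    color_abnormality_map: np.ndarray,
    bands: WarmColdBands = WarmColdBands(),
) -> int:
    """Agreement between the warm region and the color-abnormality map.

    o_warm = fraction of abnormality pixels that are warm; o_cold analogous
    for the cold band.  o_warm > 0.75 -> 0; o_warm in [0.25, 0.75] or
    o_cold > 0.75 -> 1; otherwise 2.  An empty abnormality map (clinical
    color grade 0) grades 0: there is nothing to mismatch.
    """
    values = _map_values(smap)
    abn = np.asarray(color_abnormality_map).astype(bool)
    if values.shape != abn.shape:
        raise InputError("map and abnormality map must share a shape")
    if not abn.any():
        return 0
    px = values[abn]
    o_warm = float(bands.warm(px).mean())
    o_cold = float(bands.cold(px).mean())
    if o_warm > 0.75:
        return 0
    if o_warm >= 0.25 or o_cold > 0.75:
        return 1
    return 2


def grade_map(
    smap: SaliencyMap | np.ndarray,
    mask: np.ndarray,
    clinical_border: int | None,
    color_abnormality_map: np.ndarray,
    bands: WarmColdBands = WarmColdBands(),
) -> dict:
    """All three map grades for one (map, lesion) pair."""
    return {
        "asymmetry": grade_map_asymmetry(smap, mask, bands),
        "border": grade_map_border(smap, mask, clinical_border, bands),
        "color": grade_color_match(smap, color_abnormality_map, bands),
    }
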