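"""Disk formats: 16-bit PNG saliency maps with JSON sidecars, lesion PNGs,
cohort manifests, and the blue-to-red rendering used for visual inspection."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from matplotlib import colormaps
from PIL import Image

from .errors import InputError
from .saliency import SaliencyMap
from .synthesis import LesionSpec, SyntheticLesion

__all__ = [
    "save_map",
    "load_map",
    "render_map",
    "save_lesion",
    "load_lesion",
    "save_cohort",
    "load_cohort",
]


def save_map(smap: SaliencyMap, path: str | Path, seed: int | None = None) -> None:
    """Write a map as 16-bit grayscale PNG plus a JSON sidecar."""
    path = Path(path)
    arr = np.round(smap.values * 65535.0).astype(np.uint16)
    Image.fromarray(arr).save(path)
    sidecar = {
        "method": smap.method,
        "class_index": smap.class_index,
        "raw_min": smap.raw_min,
        "raw_max": smap.raw_max,
        "seed": seed,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def load_map(path: str | Path) -> SaliencyMap:
    path = Path(path)
    try:
        arr = np.asarray(Image.open(path), dtype=float) / 65535.0
    except Exception as exc:  # corrupt or unreadable file
        raise IOError(f"cannot read map PNG {path}: {exc}") from exc
    meta = json.loads(path.with_suffix(".json").read_text())
    return SaliencyMap(
        values=arr,
        method=meta["method"],
        class_index=meta["class_index"],
        raw_min=meta["raw_min"],
        raw_max=meta["raw_max"],
    )


def render_map(smap: SaliencyMap | np.ndarray) -> np.ndarray:
    """Blue-to-red heatmap rendering (RGB floats); for human inspection only
    — grading always runs on the normalized values, never on the colors."""
    values = smap.values if isinstance(smap, SaliencyMap) else np.asarray(smap, dtype=float)
    return colormaps["jet"](values)[..., :3]


def _save_png(arr: np.ndarray, path: Path) -> None:
    if arr.dtype == bool:
        Image.fromarray(arr.astype(np.uint8) * 255).save(path)
    else:
        Image.fromarray(np.round(np.clip(arr, 0, 1) * 255).astype(np.uint8)).save(path)


def _load_png(path: Path) -> np.ndarray:
    try:
        return np.asarray(Image.open(path), dtype=float) / 255.0
    except Exception as exc:
        raise IOError(f"cannot read PNG {path}: {exc}") from exc


def save_lesion(lesion: SyntheticLesion, stem: str | Path) -> None:
    stem = Path(stem)
    _save_png(lesion.image, stem.with_suffix(".image.png"))
    _save_png(lesion.mask, stem.with_suffix(".mask.png"))
    _save_png(lesion.color_abnormality_map, stem.with_suffix(".abnormality.png"))


def load_lesion(stem: str | Path, spec: LesionSpec) -> SyntheticLesion:
    stem = Path(stem)
    return SyntheticLesion(
        image=_load_png(stem.with_suffix(".image.png")),
        mask=_load_png(stem.with_suffix(".mask.png")) > 0.5,
        color_abnormality_map=_load_png(stem.with_suffix(".abnormality.png")) > 0.5,
        spec=spec,
    )


def _spec_to_dict(spec: LesionSpec) -> dict:
    return {
        "seed": spec.seed,
        "canvas": list(spec.canvas),
        "asymmetry_level": spec.asymmetry_level,
        "border_level": spec.border_level,
        "n_colors": spec.n_colors,
        "border_na": spec.border_na,
        "irregular_arc_fraction": spec.irregular_arc_fraction,
        "central_blobs": spec.central_blobs,
    }


def _spec_from_dict(d: dict) -> LesionSpec:
    return LesionSpec(
        seed=d["seed"],
        canvas=tuple(d["canvas"]),
        asymmetry_level=d["asymmetry_level"],
        border_level=d["border_level"],
        n_colors=d["n_colors"],
        border_na=d["border_na"],
        irregular_arc_fraction=d["irregular_arc_fraction"],
        central_blobs=d.get("central_blobs", False),
    )


def save_cohort(lesions: list[SyntheticLesion], directory: str | Path) -> Path:
    """Write PNG triples plus one JSON manifest; returns the manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = []
    for i, lesion in enumerate(lesions):
        lesion_id = f"L{i:05d}"
        save_lesion(lesion, directory / lesion_id)
        manifest.append(
            {
                "lesion_id": lesion_id,
                "spec": _spec_to_dict(lesion.spec),
                "truth_grades": {
                    k: ("NA" if v is None else v)
                    for k, v in lesion.truth_grades.items()
                },
            }
        )
    path = directory / "manifest.json"
    path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return path


def load_cohort(directory: str | Path) -> tuple[list[str], list[SyntheticLesion]]:
    directory = Path(directory)
    manifest_path = directory / "manifest.json"
    if not manifest_path.exists():
        raise InputError(f"no cohort manifest in {directory}")
    manifest = json.loads(manifest_path.read_text())
    ids, lesions = [], []
    for entry in manifest:
        ids.append(entry["lesion_id"])
        lesions.append(
            load_lesion(directory / entry["lesion_id"], _spec_from_dict(entry["spec"]))
        )
    return ids, lesions
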