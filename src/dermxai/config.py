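"""Run configuration: one serializable record drives every pipeline stage."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, replace
from pathlib import Path

import yaml

from .errors import InputError
from .saliency import TECHNIQUES

__all__ = ["RunConfig"]


@dataclass(frozen=True)
class RunConfig:
    """Everything a full synthesis-to-report run depends on.

    The melanoma class of the fixture classifier is index 1; saliency maps
    explain that class, mirroring a study design that explains
    melanoma-positive predictions only.
    """

    seed: int = 0
    n_lesions: int = 20
    canvas: tuple[int, int] = (128, 128)
    techniques: tuple[str, ...] = TECHNIQUES
    layer: str | None = None  # None = last conv layer
    model_seed: int = 7
    melanoma_class: int = 1
    n_graders: int = 2
    na_fraction: float = 0.05
    lime_segments: int = 24
    lime_samples: int = 200
    lime_sigma: float = 0.25
    outdir: str = "results/run"
    render: bool = False

    def __post_init__(self) -> None:
        unknown = set(self.techniques) - set(TECHNIQUES)
        if unknown:
            raise InputError(
                f"unknown techniques {sorted(unknown)}; valid: {list(TECHNIQUES)}"
            )
        if self.n_lesions < 1:
            raise InputError("n_lesions must be >= 1")

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["canvas"] = list(self.canvas)
        d["techniques"] = list(self.techniques)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "canvas" in d:
            d["canvas"] = tuple(d["canvas"])
        if "techniques" in d:
            d["techniques"] = tuple(d["techniques"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def write_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:12]

    def with_options(self, **kwargs) -> "RunConfig":
        return replace(self, **kwargs)
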