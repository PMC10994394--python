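"""Pipeline configuration: validated parameters, YAML round-trip."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .harris import HarrisParams
from .preprocess import GaussianParams


@dataclass(frozen=True)
class PipelineConfig:
    """All tunables of the measurement pipeline.

    se_size  : side of the flat square structuring element (odd).
    gaussian : smoothing kernel parameters (sigma px, odd size).
    levels   : gray-level count L.
    harris   : corner detector parameters.
    tip_end  : 'auto' | 'left' | 'right' tip-side override.
    rounding : decimals reported for the dose.
    """

    se_size: int = 3
    gaussian: GaussianParams = field(default_factory=GaussianParams)
    levels: int = 256
    harris: HarrisParams = field(default_factory=HarrisParams)
    tip_end: str = "auto"
    rounding: int = 2

    def __post_init__(self):
        if self.se_size < 1 or self.se_size % 2 == 0:
            raise ValueError(f"se_size must be odd and >= 1, got {self.se_size}")
        if self.levels < 2:
            raise ValueError(f"levels must be >= 2, got {self.levels}")
        if self.tip_end not in ("auto", "left", "right"):
            raise ValueError(f"tip_end must be auto|left|right, got {self.tip_end!r}")

    def to_dict(self) -> dict:
        return {
            "se_size": self.se_size,
            "levels": self.levels,
            "gaussian": {"sigma": self.gaussian.sigma, "size": self.gaussian.size},
            "harris": {
                "window_sigma": self.harris.window_sigma,
                "sensitivity": self.harris.sensitivity,
                "nms_radius": self.harris.nms_radius,
                "rel_threshold": self.harris.rel_threshold,
            },
            "tip_end": self.tip_end,
            "rounding": self.rounding,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d or {})
        gauss = d.pop("gaussian", {}) or {}
        harr = d.pop("harris", {}) or {}
        return cls(
            se_size=d.get("se_size", 3),
            levels=d.get("levels", 256),
            gaussian=GaussianParams(
                sigma=gauss.get("sigma", 1.0), size=gauss.get("size", 5)
            ),
            harris=HarrisParams(
                window_sigma=harr.get("window_sigma", 1.0),
                sensitivity=harr.get("sensitivity", 0.04),
                nms_radius=harr.get("nms_radius", 5),
                rel_threshold=harr.get("rel_threshold", 0.01),
            ),
            tip_end=d.get("tip_end", "auto"),
            rounding=d.get("rounding", 2),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
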