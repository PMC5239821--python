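"""Pipeline configuration with YAML round-tripping."""

from __future__ import annotations

from dataclasses import dataclass, asdict, fields
from pathlib import Path

import yaml

from .errors import ValidationError

__all__ = ["PipelineConfig"]


@dataclass(frozen=True)
class PipelineConfig:
    """All tunable parameters of the mapping and comparison pipeline.

    ``k_points`` is the number K of arc-length equidistant points per edge
    (K - 1 segments).  ``smoothing_window`` is the window of the
    curvature-penalised moving average used on edge curves and along the
    cutting axis; ``contour_window`` the window of the local orthogonal
    regression used on raw traced edges.  Display parameters follow the
    mapping convention: 10x upsampling and Gaussian smoothing with an FWHM of
    two sampling intervals.  ``variance_fwhm`` (grid cells) smooths the
    per-group variance images before the pseudo-t ratio; 0 disables it.
    """

    k_points: int = 30
    smoothing_window: int = 3
    contour_window: int = 7
    display_upsample: int = 10
    display_fwhm_intervals: float = 2.0
    variance_fwhm: float = 2.0
    alpha: float = 0.05
    tails: str = "two"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_points < 2:
            raise ValidationError("k_points must be >= 2")
        for name in ("smoothing_window", "contour_window"):
            v = getattr(self, name)
            if v < 1 or v % 2 == 0:
                raise ValidationError(f"{name} must be an odd integer >= 1")
        if self.contour_window < 3:
            raise ValidationError("contour_window must be >= 3")
        if self.display_upsample < 1:
            raise ValidationError("display_upsample must be >= 1")
        if not 0.0 < self.alpha < 1.0:
            raise ValidationError("alpha must be in (0, 1)")
        if self.tails not in ("one_activation", "one_deactivation", "two"):
            raise ValidationError("unknown tails setting")
        if self.variance_fwhm < 0 or self.display_fwhm_intervals < 0:
            raise ValidationError("FWHM values must be >= 0")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)

    def replace(self, **kwargs) -> "PipelineConfig":
        data = self.to_dict()
        data.update(kwargs)
        return PipelineConfig.from_dict(data)
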