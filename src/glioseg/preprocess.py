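"""Intensity normalization and edge sharpening applied before segmentation.

Grey levels are rescaled to [0, 1] min-max; the p-map additionally receives
an unsharp-mask sharpening pass to crisp up the diffuse lesion boundary
before clustering.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volumes import ScalarVolume

__all__ = ["PreprocessConfig", "normalize_intensity", "sharpen_edges"]


@dataclass
class PreprocessConfig:
    """Unsharp-mask settings: Gaussian scale (voxels) and dimensionless gain."""

    sharpen_radius: float = 1.0
    sharpen_amount: float = 0.8
    normalize: bool = True

    def __post_init__(self) -> None:
        if self.sharpen_radius <= 0:
            raise ValueError("sharpen_radius must be > 0")
        if self.sharpen_amount < 0:
            raise ValueError("sharpen_amount must be >= 0")


def normalize_intensity(vol: ScalarVolume) -> ScalarVolume:
    """Min-max rescale to [0, 1]; the minimum maps to 0, the maximum to 1."""
    v = vol.values
    lo, hi = float(v.min()), float(v.max())
    if hi <= lo:
        raise ValueError("cannot normalize a constant image (degenerate intensity range)")
    return vol.with_values((v - lo) / (hi - lo))


def sharpen_edges(vol: ScalarVolume, cfg: PreprocessConfig | None = None) -> ScalarVolume:
    """Unsharp masking: v + amount * (v - gaussian_blur(v, radius)), clipped to [0, 1].

    Expects a normalized input; the clip keeps the output in the normalized
    range so downstream clustering sees a consistent scale.
    """
    cfg = cfg or PreprocessConfig()
    v = vol.values
    blurred = ndimage.gaussian_filter(v, sigma=cfg.sharpen_radius)
    sharp = v + cfg.sharpen_amount * (v - blurred)
    return vol.with_values(np.clip(sharp, 0.0, 1.0))
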