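"""Core in-memory containers shared across the pipeline.

A :class:`ScalarVolume` is a 3D intensity grid with physical voxel spacing
and a modality tag; a :class:`BinaryMask` is a boolean region on the same
grid.  Masks that are compared against each other must share both shape and
``frame_of_reference`` — the pipeline assumes all modalities have been
co-registered externally.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

__all__ = ["Modality", "ScalarVolume", "BinaryMask"]


class Modality(str, enum.Enum):
    """MRI contrast of a volume: T2-weighted, T2-FLAIR, or the DTI isotropic p-map."""

    T2 = "t2"
    FLAIR = "flair"
    PMAP = "pmap"


@dataclass
class ScalarVolume:
    """A 3D intensity grid with voxel spacing (mm) and a modality tag."""

    values: np.ndarray
    voxel_spacing: tuple[float, float, float]
    modality: Modality | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError(f"expected a 3D volume, got shape {self.values.shape}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("volume contains non-finite values")
        self.voxel_spacing = tuple(float(s) for s in self.voxel_spacing)
        if len(self.voxel_spacing) != 3 or any(s <= 0 for s in self.voxel_spacing):
            raise ValueError(f"voxel spacing must be 3 positive floats, got {self.voxel_spacing}")
        if self.modality is not None:
            self.modality = Modality(self.modality)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def with_values(self, values: np.ndarray) -> "ScalarVolume":
        """Same grid and modality, new intensities."""
        return ScalarVolume(values, self.voxel_spacing, self.modality)


@dataclass
class BinaryMask:
    """A boolean region on a ScalarVolume grid.

    ``frame_of_reference`` identifies the common space of co-registered
    volumes; area/overlap metrics refuse to compare masks from different
    frames.
    """

    values: np.ndarray
    voxel_spacing: tuple[float, float, float]
    frame_of_reference: str = "default"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values).astype(bool)
        if self.values.ndim != 3:
            raise ValueError(f"expected a 3D mask, got shape {self.values.shape}")
        self.voxel_spacing = tuple(float(s) for s in self.voxel_spacing)
        if len(self.voxel_spacing) != 3 or any(s <= 0 for s in self.voxel_spacing):
            raise ValueError(f"voxel spacing must be 3 positive floats, got {self.voxel_spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def count(self) -> int:
        return int(self.values.sum())

    def check_comparable(self, other: "BinaryMask") -> None:
        if self.shape != other.shape:
            raise ValueError(f"mask shapes differ: {self.shape} vs {other.shape}")
        if self.frame_of_reference != other.frame_of_reference:
            raise ValueError(
                "masks live in different frames of reference: "
                f"{self.frame_of_reference!r} vs {other.frame_of_reference!r}"
            )
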