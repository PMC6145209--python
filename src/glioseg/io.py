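"""NIfTI readers/writers and frame-of-reference bookkeeping.

All modalities of one patient must be co-registered externally; on load the
header affine (rounded to 1e-3) and grid shape are hashed into the mask
``frame_of_reference`` string so that accidentally comparing volumes from
different spaces fails loudly.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import nibabel as nib
import numpy as np

from .volumes import BinaryMask, Modality, ScalarVolume

__all__ = [
    "frame_id",
    "read_volume",
    "read_mask",
    "write_volume",
    "write_mask",
    "check_coregistered",
]


def frame_id(affine: np.ndarray, shape: tuple[int, ...]) -> str:
    key = np.round(np.asarray(affine, dtype=np.float64), 3).tobytes() + repr(tuple(shape)).encode()
    return hashlib.sha1(key).hexdigest()[:12]


def _load(path: str | Path) -> tuple[np.ndarray, tuple[float, float, float], np.ndarray]:
    img = nib.load(str(path))
    zooms = img.header.get_zooms()[:3]
    if len(zooms) < 3 or any(z <= 0 for z in zooms):
        raise ValueError(f"{path}: voxel spacing missing or non-positive in header")
    data = np.asanyarray(img.dataobj, dtype=np.float64)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    return data, tuple(float(z) for z in zooms), img.affine


def read_volume(path: str | Path, modality: Modality | str | None = None) -> ScalarVolume:
    """Read a NIfTI-1/2 volume (plain or gzipped); modality comes from the caller's config."""
    data, spacing, _ = _load(path)
    return ScalarVolume(data, spacing, Modality(modality) if modality else None)


def read_mask(path: str | Path) -> BinaryMask:
    data, spacing, affine = _load(path)
    return BinaryMask(data > 0.5, spacing, frame_of_reference=frame_id(affine, data.shape))


def _affine(spacing: tuple[float, float, float]) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    return aff


def write_volume(vol: ScalarVolume, path: str | Path, affine: np.ndarray | None = None) -> None:
    img = nib.Nifti1Image(vol.values.astype(np.float32), affine if affine is not None else _affine(vol.voxel_spacing))
    img.header.set_zooms(vol.voxel_spacing)
    nib.save(img, str(path))


def write_mask(mask: BinaryMask, path: str | Path, affine: np.ndarray | None = None) -> None:
    """Masks are stored as uint8 {0, 1} on the input grid."""
    img = nib.Nifti1Image(
        mask.values.astype(np.uint8), affine if affine is not None else _affine(mask.voxel_spacing)
    )
    img.header.set_zooms(mask.voxel_spacing)
    nib.save(img, str(path))


def check_coregistered(paths: list[str | Path], atol: float = 1e-3) -> str:
    """All volumes must share grid shape and affine (within atol); returns the frame id.

    Registration itself is out of scope — inputs failing this check need
    external resampling before the pipeline will touch them.
    """
    shapes, affines = [], []
    for p in paths:
        img = nib.load(str(p))
        shapes.append(img.shape[:3])
        affines.append(img.affine)
    ref_shape, ref_aff = shapes[0], affines[0]
    for p, s, a in zip(paths, shapes, affines):
        if s != ref_shape or not np.allclose(a, ref_aff, atol=atol):
            raise ValueError(
                f"{p} is not co-registered with {paths[0]} (shape {s} vs {ref_shape}); "
                "register and resample the inputs externally first"
            )
    return frame_id(ref_aff, ref_shape)
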