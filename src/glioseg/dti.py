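"""Diffusion tensor estimation and the isotropic p-map.

Water diffusion in each voxel is modelled by a symmetric 3x3 tensor D
(mm^2/s).  With a diffusion weighting b and unit gradient direction g, the
measured signal follows the mono-exponential model

    S(b, g) = S0 * exp(-b * g^T D g)

so the six unique tensor components are recovered per voxel by ordinary
least squares on the log-attenuations (log-linear fit, no weighting, no
positivity constraint).  From the tensor eigenvalues l1 >= l2 >= l3 the
mean diffusivity is D = (l1 + l2 + l3) / 3 and the isotropic component is

    p = sqrt(3) * D

which is elevated in vasogenic edema and tumour-infiltrated white matter.
Note the sqrt(3) is a multiplicative factor on the mean diffusivity, not a
square root of 3*D.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .volumes import BinaryMask, Modality, ScalarVolume

__all__ = [
    "DiffusionAcquisition",
    "TensorField",
    "fit_tensor",
    "eigen_metrics",
    "compute_p_map",
]

logger = logging.getLogger(__name__)

SQRT3 = float(np.sqrt(3.0))


@dataclass
class DiffusionAcquisition:
    """A DWI series: 4D stack of volumes plus b-values and gradient directions.

    ``dwi_volumes`` has shape (x, y, z, n); ``bvals`` is length n in s/mm^2;
    ``bvecs`` is (n, 3) with unit-norm rows for every non-zero b.  The
    reference scheme is two b-values (0 and 1000 s/mm^2) with 12 gradient
    directions.
    """

    dwi_volumes: np.ndarray
    bvals: np.ndarray
    bvecs: np.ndarray
    voxel_spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.dwi_volumes = np.asarray(self.dwi_volumes, dtype=np.float64)
        self.bvals = np.asarray(self.bvals, dtype=np.float64).ravel()
        self.bvecs = np.asarray(self.bvecs, dtype=np.float64)
        if self.dwi_volumes.ndim != 4:
            raise ValueError(f"expected 4D DWI stack, got shape {self.dwi_volumes.shape}")
        n = self.dwi_volumes.shape[3]
        if self.bvals.shape[0] != n:
            raise ValueError(f"{self.bvals.shape[0]} b-values for {n} volumes")
        if self.bvecs.shape != (n, 3):
            raise ValueError(f"expected bvecs of shape ({n}, 3), got {self.bvecs.shape}")
        if not np.any(self.bvals == 0):
            raise ValueError("acquisition must contain at least one b=0 measurement")
        nonzero = self.bvals > 0
        norms = np.linalg.norm(self.bvecs[nonzero], axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-6):
            raise ValueError("non-zero-b gradient directions must have unit norm (tol 1e-6)")
        if np.any(self.dwi_volumes < 0):
            raise ValueError("DWI intensities must be non-negative")
        self.voxel_spacing = tuple(float(s) for s in self.voxel_spacing)

    @property
    def n_measurements(self) -> int:
        return self.dwi_volumes.shape[3]


@dataclass
class TensorField:
    """Per-voxel diffusion tensors with derived eigen-metrics.

    ``tensor_components`` stores (Dxx, Dyy, Dzz, Dxy, Dxz, Dyz) per voxel in
    mm^2/s; ``eigenvalues`` are sorted descending; ``valid_mask`` marks voxels
    where a fit was performed.  Eigen-metrics may be absent (None) until
    :func:`eigen_metrics` is applied.
    """

    tensor_components: np.ndarray
    valid_mask: np.ndarray
    voxel_spacing: tuple[float, float, float]
    eigenvalues: np.ndarray | None = None
    mean_diffusivity: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.tensor_components = np.asarray(self.tensor_components, dtype=np.float64)
        if self.tensor_components.ndim != 4 or self.tensor_components.shape[3] != 6:
            raise ValueError(
                f"tensor_components must have shape (x, y, z, 6), got {self.tensor_components.shape}"
            )
        self.valid_mask = np.asarray(self.valid_mask).astype(bool)
        if self.valid_mask.shape != self.tensor_components.shape[:3]:
            raise ValueError("valid_mask shape does not match the tensor grid")
        self.voxel_spacing = tuple(float(s) for s in self.voxel_spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.tensor_components.shape[:3]

    def as_matrices(self) -> np.ndarray:
        """Full symmetric 3x3 matrices, shape (x, y, z, 3, 3)."""
        dxx, dyy, dzz, dxy, dxz, dyz = np.moveaxis(self.tensor_components, -1, 0)
        m = np.empty(self.shape + (3, 3), dtype=np.float64)
        m[..., 0, 0] = dxx
        m[..., 1, 1] = dyy
        m[..., 2, 2] = dzz
        m[..., 0, 1] = m[..., 1, 0] = dxy
        m[..., 0, 2] = m[..., 2, 0] = dxz
        m[..., 1, 2] = m[..., 2, 1] = dyz
        return m


def design_matrix(bvals: np.ndarray, bvecs: np.ndarray) -> np.ndarray:
    """Rows b * (gx^2, gy^2, gz^2, 2 gx gy, 2 gx gz, 2 gy gz) so that B @ d = b g^T D g."""
    g = np.asarray(bvecs, dtype=np.float64)
    b = np.asarray(bvals, dtype=np.float64)[:, None]
    gx, gy, gz = g[:, 0], g[:, 1], g[:, 2]
    return b * np.column_stack(
        [gx * gx, gy * gy, gz * gz, 2 * gx * gy, 2 * gx * gz, 2 * gy * gz]
    )


def fit_tensor(acq: DiffusionAcquisition, brain_mask: BinaryMask) -> TensorField:
    """Log-linear least-squares tensor fit inside ``brain_mask``.

    Per voxel, solves ln(S_i / S0) = -b_i g_i^T D g_i over the six unique
    tensor components; S0 is the mean of the b=0 measurements.  Voxels with
    any non-positive measurement are excluded from the valid mask rather
    than floored, to avoid log-domain artifacts.
    """
    if acq.dwi_volumes.shape[:3] != brain_mask.shape:
        raise ValueError(
            f"DWI grid {acq.dwi_volumes.shape[:3]} does not match brain mask {brain_mask.shape}"
        )
    if acq.n_measurements < 7:
        raise ValueError(
            f"tensor fit needs >= 7 measurements (1 b0 + 6 directions), got {acq.n_measurements}"
        )
    dwi_rows = acq.bvals > 0
    B = design_matrix(acq.bvals[dwi_rows], acq.bvecs[dwi_rows])
    if np.linalg.matrix_rank(B) < 6:
        raise ValueError("gradient scheme is rank-deficient: fewer than 6 independent directions")

    mask = brain_mask.values
    signals = acq.dwi_volumes[mask]  # (nvox, nmeas)
    positive = np.all(signals > 0, axis=1)
    n_dropped = int((~positive).sum())
    if n_dropped:
        logger.info("excluding %d voxels with non-positive signal from tensor fit", n_dropped)

    s0 = signals[positive][:, ~dwi_rows].mean(axis=1)
    log_att = -np.log(signals[positive][:, dwi_rows] / s0[:, None])  # = b g^T D g
    d, *_ = np.linalg.lstsq(B, log_att.T, rcond=None)  # (6, nvox)

    components = np.zeros(mask.shape + (6,), dtype=np.float64)
    valid = np.zeros(mask.shape, dtype=bool)
    idx = np.flatnonzero(mask.ravel())[positive]
    components.reshape(-1, 6)[idx] = d.T
    valid.ravel()[idx] = True
    return TensorField(components, valid, acq.voxel_spacing)


def eigen_metrics(tensors: TensorField) -> TensorField:
    """Populate sorted eigenvalues and mean diffusivity on a tensor field.

    Eigenvalues are sorted descending per voxel.  Negative eigenvalues
    (possible under noise with an unconstrained fit) are retained, not
    clipped; their count is reported through logging so the diagnostics
    stay honest.
    """
    if not np.all(np.isfinite(tensors.tensor_components)):
        bad = np.argwhere(~np.isfinite(tensors.tensor_components).all(axis=-1))[0]
        raise ValueError(f"non-finite tensor components at voxel {tuple(int(i) for i in bad)}")
    mats = tensors.as_matrices()
    evals = np.linalg.eigvalsh(mats)[..., ::-1]  # eigvalsh sorts ascending
    md = evals.mean(axis=-1)
    n_negative = int((evals[tensors.valid_mask] < 0).sum())
    if n_negative:
        logger.warning("%d negative eigenvalues in valid voxels (retained, not clipped)", n_negative)
    return TensorField(
        tensors.tensor_components,
        tensors.valid_mask,
        tensors.voxel_spacing,
        eigenvalues=evals,
        mean_diffusivity=md,
    )


def compute_p_map(tensors: TensorField) -> ScalarVolume:
    """Isotropic diffusion component p = sqrt(3) * mean diffusivity.

    Outside the valid mask p is set to 0.  The output carries the PMAP
    modality tag and mm^2/s-scaled units.
    """
    if tensors.mean_diffusivity is None:
        tensors = eigen_metrics(tensors)
    p = SQRT3 * tensors.mean_diffusivity
    p = np.where(tensors.valid_mask, p, 0.0)
    return ScalarVolume(p, tensors.voxel_spacing, Modality.PMAP)
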