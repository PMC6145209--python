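"""Co-registered multimodal digital phantoms with ground-truth lesion masks.

Each phantom emulates a postoperative glioblastoma head: an ellipsoidal
brain (white matter core, cortical grey-matter shell) wrapped in skull and
scalp shells, two CSF ventricles, and a lesion made of a necrotic/cystic
core surrounded by a hyper-signal edema rim.  The per-tissue intensity
tables respect each modality's four-class brightness ordering: on T2 the
lesion core is brightest and CSF/edema intermediate; on FLAIR CSF is
suppressed to near zero; on the p-map CSF and the cystic core are both
bright.  The edema rim extent is drawn per modality, so the discordance
between the three ground-truth masks is controlled by construction — the
phantoms' central property, mirroring the clinical observation that the
three modalities delineate different regions.

Default grid 128x128x20 at 0.9x0.9x5 mm (FLAIR-like resolution) so lesion
areas land in the clinically observed cm^2 range.  A DWI simulator
forward-models the mono-exponential tensor signal with Rician noise, for
testing the tensor fit; the phantom's diffusion tensor field is built so
that sqrt(3)*MD is proportional to the p-map intensity table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .dti import SQRT3, DiffusionAcquisition, TensorField
from .volumes import BinaryMask, Modality, ScalarVolume

__all__ = [
    "PhantomSpec",
    "PhantomBundle",
    "INTENSITY_TABLES",
    "generate_phantom",
    "simulate_dwi",
    "default_dwi_scheme",
    "default_benchmark_suite",
]

# Per-modality, per-tissue grey levels on a [0, 1] scale.  At zero noise the
# values fall into exactly four brightness groups per modality, matching the
# four FCM tissue classes.
INTENSITY_TABLES: dict[Modality, dict[str, float]] = {
    Modality.T2: {
        "background": 0.0, "skull": 0.06, "scalp": 0.37, "wm": 0.34, "gm": 0.40,
        "csf": 0.66, "edema": 0.62, "core": 0.95,
    },
    Modality.FLAIR: {
        "background": 0.0, "skull": 0.05, "scalp": 0.38, "wm": 0.36, "gm": 0.42,
        "csf": 0.06, "edema": 0.65, "core": 0.95,
    },
    Modality.PMAP: {
        "background": 0.0, "skull": 0.02, "scalp": 0.35, "wm": 0.32, "gm": 0.38,
        "csf": 0.92, "edema": 0.62, "core": 0.95,
    },
}

# sqrt(3) * MD proportional to the p-map table; this scale puts CSF MD near
# the physiological 3e-3 mm^2/s ballpark.
MD_SCALE = 1.8e-3  # mm^2/s per unit p-map intensity

# Eigenvalue shape (mean 1) giving white matter its anisotropy.
WM_EIG_SHAPE = (1.8, 0.7, 0.5)


@dataclass
class PhantomSpec:
    """Geometry, intensity tables and noise model of one phantom.

    All geometric quantities are in voxel units on ``grid_shape``; the edema
    rim radii are per modality so the three ground-truth abnormal masks
    differ by construction.
    """

    grid_shape: tuple[int, int, int] = (128, 128, 20)
    voxel_spacing: tuple[float, float, float] = (0.9, 0.9, 5.0)
    brain_center: tuple[float, float, float] = (64.0, 64.0, 10.0)
    brain_radii: tuple[float, float, float] = (54.0, 44.0, 9.0)
    skull_thickness: float = 3.0
    scalp_thickness: float = 3.0
    gm_thickness: float = 4.0
    ventricle_centers: tuple[tuple[float, float, float], ...] = (
        (56.0, 64.0, 10.0),
        (72.0, 64.0, 10.0),
    )
    ventricle_radii: tuple[float, float, float] = (4.0, 9.0, 2.0)
    lesion_center: tuple[float, float, float] = (36.0, 52.0, 10.0)
    core_radii: tuple[float, float, float] = (5.0, 5.0, 1.6)
    rim_radii: dict[Modality, tuple[float, float, float]] = field(
        default_factory=lambda: {
            Modality.T2: (11.0, 11.0, 3.2),
            Modality.FLAIR: (12.5, 12.5, 3.5),
            Modality.PMAP: (9.0, 9.0, 2.9),
        }
    )
    intensity_tables: dict[Modality, dict[str, float]] = field(
        default_factory=lambda: {m: dict(t) for m, t in INTENSITY_TABLES.items()}
    )
    noise_model: str = "rician"
    noise_sigma: float = 0.04
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_model not in ("gaussian", "rician"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


@dataclass
class PhantomBundle:
    """All volumes of one phantom on a shared grid.

    ``truth_masks`` holds the per-modality hyper-signal abnormal region
    (core + that modality's edema rim); ``suggested_seeds`` gives a voxel
    inside each modality's rim, suitable as the region-growing seed.
    """

    spec: PhantomSpec
    t2: ScalarVolume
    flair: ScalarVolume
    pmap: ScalarVolume
    brain_mask: BinaryMask
    truth_masks: dict[Modality, BinaryMask]
    tensor_field: TensorField
    suggested_seeds: dict[Modality, tuple[int, int, int]]

    @property
    def volumes(self) -> dict[Modality, ScalarVolume]:
        return {Modality.T2: self.t2, Modality.FLAIR: self.flair, Modality.PMAP: self.pmap}


def _ellipsoid(shape, center, radii) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, n) for n in shape)]
    acc = np.zeros(shape, dtype=np.float64)
    for g, c, r in zip(grids, center, radii):
        acc = acc + ((g - c) / r) ** 2
    return acc <= 1.0


def generate_phantom(spec: PhantomSpec) -> PhantomBundle:
    """Render a PhantomSpec into co-registered volumes and truth masks.

    Deterministic given ``spec.rng_seed``; noise is drawn independently per
    modality from child streams of that seed.  Raises if any modality's rim
    extends beyond the brain ellipsoid into the skull.
    """
    shape = spec.grid_shape
    bc, br = spec.brain_center, spec.brain_radii
    outer_skull = tuple(r + spec.skull_thickness for r in br)
    outer_scalp = tuple(r + spec.skull_thickness + spec.scalp_thickness for r in br)

    brain = _ellipsoid(shape, bc, br)
    skull = _ellipsoid(shape, bc, outer_skull) & ~brain
    scalp = _ellipsoid(shape, bc, outer_scalp) & ~brain & ~skull
    inner = _ellipsoid(
        shape, bc, (br[0] - spec.gm_thickness, br[1] - spec.gm_thickness, max(br[2] - 1.0, 1.0))
    )
    ventricles = np.zeros(shape, dtype=bool)
    for vc in spec.ventricle_centers:
        ventricles |= _ellipsoid(shape, vc, spec.ventricle_radii)
    ventricles &= brain

    core = _ellipsoid(shape, spec.lesion_center, spec.core_radii)
    rims = {m: _ellipsoid(shape, spec.lesion_center, r) for m, r in spec.rim_radii.items()}
    for m, rim in rims.items():
        if np.any(rim & ~brain):
            raise ValueError(f"lesion rim on {m.value} extends beyond the brain into the skull")

    # Base tissue map without the lesion; lesion painted last per modality.
    base = np.full(shape, "background", dtype=object)
    base[scalp] = "scalp"
    base[skull] = "skull"
    base[brain] = "gm"
    base[brain & inner] = "wm"
    base[ventricles] = "csf"

    ss = np.random.SeedSequence(spec.rng_seed)
    children = ss.spawn(3)
    volumes: dict[Modality, ScalarVolume] = {}
    for child, modality in zip(children, (Modality.T2, Modality.FLAIR, Modality.PMAP)):
        labels = base.copy()
        labels[rims[modality]] = "edema"
        labels[core] = "core"
        table = spec.intensity_tables[modality]
        values = np.vectorize(table.__getitem__, otypes=[np.float64])(labels)
        if spec.noise_sigma > 0:
            rng = np.random.default_rng(child)
            if spec.noise_model == "gaussian":
                values = values + rng.normal(0.0, spec.noise_sigma, size=shape)
            else:
                n1 = rng.normal(0.0, spec.noise_sigma, size=shape)
                n2 = rng.normal(0.0, spec.noise_sigma, size=shape)
                values = np.sqrt((values + n1) ** 2 + n2**2)
        volumes[modality] = ScalarVolume(values, spec.voxel_spacing, modality)

    truth_masks = {
        m: BinaryMask(rims[m] | core, spec.voxel_spacing) for m in rims
    }
    seeds = {}
    for m in rims:
        rx = 0.5 * (spec.core_radii[0] + spec.rim_radii[m][0])
        seed = (
            int(round(spec.lesion_center[0] + rx)),
            int(round(spec.lesion_center[1])),
            int(round(spec.lesion_center[2])),
        )
        if not truth_masks[m].values[seed] or core[seed]:
            raise ValueError(f"internal geometry error: suggested seed {seed} not inside the rim")
        seeds[m] = seed

    tensor_field = _build_tensor_field(spec, base, rims[Modality.PMAP], core)
    return PhantomBundle(
        spec=spec,
        t2=volumes[Modality.T2],
        flair=volumes[Modality.FLAIR],
        pmap=volumes[Modality.PMAP],
        brain_mask=BinaryMask(brain, spec.voxel_spacing),
        truth_masks=truth_masks,
        tensor_field=tensor_field,
        suggested_seeds=seeds,
    )


def _build_tensor_field(
    spec: PhantomSpec, base: np.ndarray, rim: np.ndarray, core: np.ndarray
) -> TensorField:
    """Tensors whose sqrt(3)*MD is proportional to the p-map intensity table.

    All tissues are isotropic except white matter, which gets a prolate
    tensor with the same mean diffusivity.
    """
    labels = base.copy()
    labels[rim] = "edema"
    labels[core] = "core"
    table = spec.intensity_tables[Modality.PMAP]
    md = np.vectorize(table.__getitem__, otypes=[np.float64])(labels) * MD_SCALE
    comps = np.zeros(spec.grid_shape + (6,), dtype=np.float64)
    comps[..., 0] = comps[..., 1] = comps[..., 2] = md
    wm = labels == "wm"
    comps[wm, 0] = md[wm] * WM_EIG_SHAPE[0]
    comps[wm, 1] = md[wm] * WM_EIG_SHAPE[1]
    comps[wm, 2] = md[wm] * WM_EIG_SHAPE[2]
    valid = labels != "background"
    return TensorField(comps, valid, spec.voxel_spacing)


def default_dwi_scheme(b: float = 1000.0) -> tuple[np.ndarray, np.ndarray]:
    """One b=0 measurement plus 12 icosahedral directions at b s/mm^2."""
    phi = (1.0 + math.sqrt(5.0)) / 2.0
    raw = [
        (0, 1, phi), (0, -1, phi), (0, 1, -phi), (0, -1, -phi),
        (1, phi, 0), (-1, phi, 0), (1, -phi, 0), (-1, -phi, 0),
        (phi, 0, 1), (-phi, 0, 1), (phi, 0, -1), (-phi, 0, -1),
    ]
    dirs = np.array(raw, dtype=np.float64)
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    bvals = np.concatenate([[0.0], np.full(12, b)])
    bvecs = np.vstack([[0.0, 0.0, 0.0], dirs])
    return bvals, bvecs


def simulate_dwi(
    tensors: TensorField,
    bvals: np.ndarray,
    bvecs: np.ndarray,
    s0: float = 1000.0,
    snr: float = math.inf,
    rng_seed: int = 0,
) -> DiffusionAcquisition:
    """Forward mono-exponential DWI signal S = s0 exp(-b g^T D g) with Rician noise.

    ``snr`` is s0 / sigma of the per-channel Gaussian noise; infinite SNR
    gives the noiseless signal.
    """
    if s0 <= 0:
        raise ValueError("s0 must be positive")
    bvals = np.asarray(bvals, dtype=np.float64).ravel()
    bvecs = np.asarray(bvecs, dtype=np.float64)
    from .dti import design_matrix

    B = design_matrix(bvals, bvecs)  # (n, 6)
    exponent = np.tensordot(tensors.tensor_components, B, axes=([-1], [1]))  # (x,y,z,n)
    signal = s0 * np.exp(-exponent)
    if np.isfinite(snr):
        if snr <= 0:
            raise ValueError("snr must be positive (or infinite for noiseless)")
        sigma = s0 / snr
        rng = np.random.default_rng(rng_seed)
        n1 = rng.normal(0.0, sigma, size=signal.shape)
        n2 = rng.normal(0.0, sigma, size=signal.shape)
        signal = np.sqrt((signal + n1) ** 2 + n2**2)
    return DiffusionAcquisition(signal, bvals, bvecs, tensors.voxel_spacing)


# Category mix of the default benchmark: mostly p-map-smallest, a few
# p-map-largest and in-between, echoing the observed cohort proportions.
_SUITE_CATEGORIES = ["smallest"] * 13 + ["largest"] * 4 + ["between"] * 3

# xy rim scale per (category, modality); z scale is softened halfway to 1.
_CATEGORY_SCALES = {
    "smallest": {Modality.T2: 1.00, Modality.FLAIR: 1.12, Modality.PMAP: 0.82},
    "largest": {Modality.T2: 0.95, Modality.FLAIR: 1.00, Modality.PMAP: 1.15},
    "between": {Modality.T2: 0.90, Modality.FLAIR: 1.10, Modality.PMAP: 1.00},
}


def default_benchmark_suite(n_phantoms: int = 20, rng_seed: int = 0) -> list[PhantomSpec]:
    """Reproducible suite of varied phantoms used by the acceptance benchmark.

    Lesion size, position and noise level (sigma in [0.02, 0.06]) vary per
    phantom; the rim-scale patterns cover all three size orderings of the
    p-map area relative to T2/FLAIR.  Lesions are rejection-sampled to stay
    inside the brain and clear of the ventricles.
    """
    if n_phantoms < 1:
        raise ValueError("n_phantoms must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence([rng_seed % 2**31, 77]))
    template = PhantomSpec()
    specs = []
    for i in range(n_phantoms):
        category = _SUITE_CATEGORIES[i % len(_SUITE_CATEGORIES)]
        scales = _CATEGORY_SCALES[category]
        for _attempt in range(100):
            rbase_xy = rng.uniform(8.5, 12.0)
            rbase_z = rng.uniform(2.6, 3.4)
            rim_radii = {}
            for m, s in scales.items():
                sz = 1.0 + (s - 1.0) / 2.0
                rim_radii[m] = (rbase_xy * s, rbase_xy * s, rbase_z * sz)
            core_scale = rng.uniform(0.40, 0.50)
            rmin = min(r[0] for r in rim_radii.values())
            rzmin = min(r[2] for r in rim_radii.values())
            core_radii = (core_scale * rmin, core_scale * rmin, max(core_scale * rzmin, 1.1))
            theta = rng.uniform(-0.7, 0.7) + (0.0 if rng.uniform() < 0.5 else math.pi)
            d = rng.uniform(26.0, 33.0)
            center = (
                template.brain_center[0] + d * math.cos(theta),
                template.brain_center[1] + d * math.sin(theta),
                template.brain_center[2],
            )
            spec = replace(
                template,
                lesion_center=center,
                core_radii=core_radii,
                rim_radii=rim_radii,
                noise_sigma=float(rng.uniform(0.02, 0.06)),
                rng_seed=int((rng_seed * 1009 + 31 * i) % 2**31),
            )
            if _lesion_placement_ok(spec):
                specs.append(spec)
                break
        else:
            raise RuntimeError("could not place a lesion satisfying the geometry constraints")
    return specs


def _lesion_placement_ok(spec: PhantomSpec, clearance: int = 2) -> bool:
    """Largest rim fits inside the brain and stays clear of the ventricles."""
    shape = spec.grid_shape
    rmax = tuple(max(r[ax] for r in spec.rim_radii.values()) for ax in range(3))
    rim = _ellipsoid(shape, spec.lesion_center, rmax)
    brain = _ellipsoid(shape, spec.brain_center, spec.brain_radii)
    if np.any(rim & ~brain):
        return False
    ventricles = np.zeros(shape, dtype=bool)
    for vc in spec.ventricle_centers:
        ventricles |= _ellipsoid(shape, vc, spec.ventricle_radii)
    grown = ndimage.binary_dilation(rim, iterations=clearance)
    return not np.any(grown & ventricles)
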