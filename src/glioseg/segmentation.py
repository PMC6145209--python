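"""Fuzzy C-means tissue clustering and seeded region growing.

The semi-automatic delineation used throughout the pipeline is a two-stage
procedure:

1. **FCM clustering** partitions the image intensities into four fuzzy
   clusters.  Ranked by centroid brightness, the clusters map onto
   modality-specific tissue roles — e.g. on T2 the brightest cluster holds
   necrosis/hemorrhage/cysts, the intermediate one CSF plus edema, then
   normal white/grey matter and scalp, then skull/background.  The union of
   the "hyper" and "edema" roles forms the abnormal candidate set.

2. **Region growing** from a user-supplied seed refines the connected
   candidate component: a breadth-first frontier accepts a neighbour when
   its intensity is within ``tolerance`` of the running region mean, which
   is updated incrementally as voxels are accepted.  Fully enclosed holes
   (typically the necrotic core inside the edema rim) are filled afterwards.

Both stages are deterministic given the seed/rng inputs.
"""

from __future__ import annotations

import logging
from collections import deque
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volumes import BinaryMask, Modality, ScalarVolume

__all__ = [
    "FCMResult",
    "TissueClassMap",
    "SegmentationResult",
    "TISSUE_ROLES",
    "ABNORMAL_ROLES",
    "fcm_cluster",
    "assign_tissue_classes",
    "region_grow",
    "extract_abnormal_mask",
]

logger = logging.getLogger(__name__)

# Cluster rank (0 = brightest centroid) -> tissue role, per modality.
TISSUE_ROLES: dict[Modality, tuple[str, ...]] = {
    # hyper = necrosis / tumour hemorrhage / cysts
    Modality.T2: ("hyper", "csf_edema", "normal", "background"),   # background incl. skull
    Modality.FLAIR: ("hyper", "edema", "normal", "background"),    # background incl. CSF, skull
    Modality.PMAP: ("hyper", "edema", "normal", "background"),     # hyper incl. CSF
}

# Roles contributing to the hyper-signal abnormal candidate set.
ABNORMAL_ROLES = frozenset({"hyper", "edema", "csf_edema"})


@dataclass
class FCMResult:
    """Converged fuzzy C-means state.

    ``memberships`` has shape grid + (C,), rows summing to 1 inside the
    clustering mask and 0 outside; ``objective_history`` records the fuzzy
    objective at each iteration (non-increasing).
    """

    memberships: np.ndarray
    centroids: np.ndarray
    mask: np.ndarray
    n_iterations: int
    objective: float
    objective_history: np.ndarray
    fuzziness: float


@dataclass
class TissueClassMap:
    """Per-voxel brightness-rank labels (0 = brightest cluster) plus role semantics.

    ``labels`` is -1 outside the clustering mask; ``class_semantics`` maps
    each rank to its modality-specific tissue role.
    """

    labels: np.ndarray
    class_semantics: dict[int, str]
    modality: Modality
    centroids_by_rank: np.ndarray

    def role_mask(self, roles: frozenset[str] | set[str]) -> np.ndarray:
        ranks = [rank for rank, role in self.class_semantics.items() if role in roles]
        return np.isin(self.labels, ranks)


@dataclass
class SegmentationResult:
    """Everything produced for one modality: FCM state, class map, abnormal mask."""

    fcm: FCMResult
    classes: TissueClassMap
    abnormal_mask: BinaryMask
    seed_point: tuple[int, int, int]


def _fcm_objective(x: np.ndarray, u: np.ndarray, c: np.ndarray, m: float) -> float:
    d2 = (x[:, None] - c[None, :]) ** 2
    return float(np.sum(u**m * d2))


def _fcm_memberships(x: np.ndarray, c: np.ndarray, m: float) -> np.ndarray:
    """Standard FCM membership update u_ik = 1 / sum_j (|x_k-c_i| / |x_k-c_j|)^(2/(m-1))."""
    d = np.abs(x[:, None] - c[None, :])
    with np.errstate(divide="ignore", over="ignore", invalid="ignore"):
        inv = d ** (-2.0 / (m - 1.0))
        u = inv / inv.sum(axis=1, keepdims=True)
    # voxels landing (numerically) on a centroid: hard-assign to the nearest
    bad = ~np.all(np.isfinite(u), axis=1)
    if np.any(bad):
        u[bad] = 0.0
        u[bad, np.argmin(d[bad], axis=1)] = 1.0
    return u


def fcm_cluster(
    vol: ScalarVolume,
    brain_mask: BinaryMask | np.ndarray | None = None,
    n_clusters: int = 4,
    fuzziness: float = 2.0,
    tol: float = 1e-5,
    max_iter: int = 300,
    rng_seed: int = 0,
) -> FCMResult:
    """Fuzzy C-means clustering of in-mask intensities.

    Centroids are initialized at evenly spaced grey levels across the
    in-mask intensity range (deterministic); rng_seed only drives the jitter
    applied when a restart is forced by coincident centroids (up to 3
    restarts).  Iteration
    stops when the maximum centroid change falls below ``tol`` or after
    ``max_iter`` sweeps.
    """
    if brain_mask is None:
        mask = np.ones(vol.shape, dtype=bool)
    elif isinstance(brain_mask, BinaryMask):
        mask = brain_mask.values
    else:
        mask = np.asarray(brain_mask).astype(bool)
    if mask.shape != vol.shape:
        raise ValueError("clustering mask shape does not match volume")
    if not mask.any():
        raise ValueError("empty clustering mask")
    if fuzziness <= 1.0:
        raise ValueError("fuzziness must be > 1")
    x = vol.values[mask]
    if np.unique(x).size < n_clusters:
        raise ValueError(
            f"need >= {n_clusters} distinct intensities inside the mask, got {np.unique(x).size}"
        )

    rng = np.random.default_rng(rng_seed)
    # Evenly spaced grey levels across the observed range.  Quantile-based
    # initialization degenerates on head images: the air background holds
    # most voxels, so several centroids start (and stay) inside it.
    fractions = (2 * np.arange(n_clusters) + 1) / (2 * n_clusters)
    base_init = x.min() + fractions * (x.max() - x.min())

    for attempt in range(4):
        c = base_init.copy()
        if attempt > 0:  # jittered restart after coincident centroids
            c = c + rng.normal(0.0, 0.05 * (x.max() - x.min() + 1e-12), size=n_clusters)
        history = []
        u = _fcm_memberships(x, c, fuzziness)
        for it in range(1, max_iter + 1):
            um = u**fuzziness
            c_new = um.T @ x / um.sum(axis=0)
            u = _fcm_memberships(x, c_new, fuzziness)
            history.append(_fcm_objective(x, u, c_new, fuzziness))
            delta = np.max(np.abs(c_new - c))
            c = c_new
            if delta < tol:
                break
        coincident = np.min(np.diff(np.sort(c))) < 1e-12 if n_clusters > 1 else False
        if not coincident:
            memberships = np.zeros(vol.shape + (n_clusters,), dtype=np.float64)
            memberships[mask] = u
            return FCMResult(
                memberships=memberships,
                centroids=c,
                mask=mask,
                n_iterations=it,
                objective=history[-1],
                objective_history=np.asarray(history),
                fuzziness=fuzziness,
            )
        logger.warning("coincident centroids on attempt %d; restarting with jitter", attempt + 1)
    raise RuntimeError("FCM failed: coincident centroids after 3 jittered restarts")


def assign_tissue_classes(fcm: FCMResult, modality: Modality | str) -> TissueClassMap:
    """Map FCM clusters onto four modality-specific tissue roles.

    Clusters are ranked by centroid descending (ties broken by cluster
    index, logged); each in-mask voxel takes the role of its
    maximum-membership cluster, ties resolved toward the lower cluster
    index.  Voxels outside the clustering mask get label -1.
    """
    modality = Modality(modality)
    roles = TISSUE_ROLES[modality]
    c = fcm.centroids
    if len(c) != len(roles):
        raise ValueError(f"expected exactly {len(roles)} clusters, got {len(c)}")
    if np.min(np.abs(np.diff(np.sort(c)))) < 1e-12:
        logger.warning("centroid tie within 1e-12; ranks broken deterministically by cluster index")
    # stable argsort on -c: equal centroids keep ascending cluster index
    order = np.argsort(-c, kind="stable")  # order[rank] = cluster index
    rank_of_cluster = np.empty_like(order)
    rank_of_cluster[order] = np.arange(len(c))

    hard = np.argmax(fcm.memberships, axis=-1)  # ties -> lower cluster index
    labels = rank_of_cluster[hard]
    labels[~fcm.mask] = -1
    semantics = {rank: role for rank, role in enumerate(roles)}
    return TissueClassMap(
        labels=labels,
        class_semantics=semantics,
        modality=modality,
        centroids_by_rank=c[order],
    )


def _neighbor_offsets(ndim_connectivity: int) -> list[tuple[int, int, int]]:
    if ndim_connectivity not in (6, 18, 26):
        raise ValueError("connectivity must be 6, 18 or 26")
    conn_rank = {6: 1, 18: 2, 26: 3}[ndim_connectivity]
    struct = ndimage.generate_binary_structure(3, conn_rank)
    offs = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                if (dx, dy, dz) != (0, 0, 0) and struct[dx + 1, dy + 1, dz + 1]:
                    offs.append((dx, dy, dz))
    return offs


def region_grow(
    vol: ScalarVolume,
    seed: tuple[int, int, int],
    tolerance: float,
    connectivity: int = 26,
    domain: BinaryMask | np.ndarray | None = None,
) -> BinaryMask:
    """Seeded region growing with an incrementally updated region mean.

    Breadth-first growth: a frontier neighbour n of an accepted voxel is
    accepted when |v(n) - mean(region)| <= tolerance, and the region mean is
    updated after each acceptance.  Each voxel is examined once (FIFO order,
    neighbours in a fixed lexicographic order); a voxel rejected against the
    mean at examination time is not revisited.  Growth stops when no
    acceptable frontier remains.  ``domain`` optionally restricts growth to
    a mask (e.g. the abnormal candidate set).
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be > 0")
    v = vol.values
    seed = tuple(int(s) for s in seed)
    if len(seed) != 3 or any(not (0 <= s < n) for s, n in zip(seed, v.shape)):
        raise ValueError(f"seed {seed} outside volume of shape {v.shape}")
    if domain is None:
        dom = np.ones(v.shape, dtype=bool)
    else:
        dom = domain.values if isinstance(domain, BinaryMask) else np.asarray(domain).astype(bool)
    if not dom[seed]:
        raise ValueError(f"seed {seed} lies outside the growth domain/brain mask")

    offsets = _neighbor_offsets(connectivity)
    accepted = np.zeros(v.shape, dtype=bool)
    visited = np.zeros(v.shape, dtype=bool)
    accepted[seed] = visited[seed] = True
    total = float(v[seed])
    count = 1
    queue: deque[tuple[int, int, int]] = deque([seed])
    nx, ny, nz = v.shape
    while queue:
        x, y, z = queue.popleft()
        for dx, dy, dz in offsets:
            px, py, pz = x + dx, y + dy, z + dz
            if not (0 <= px < nx and 0 <= py < ny and 0 <= pz < nz):
                continue
            if visited[px, py, pz] or not dom[px, py, pz]:
                continue
            visited[px, py, pz] = True
            if abs(v[px, py, pz] - total / count) <= tolerance:
                accepted[px, py, pz] = True
                total += float(v[px, py, pz])
                count += 1
                queue.append((px, py, pz))
    return BinaryMask(accepted, vol.voxel_spacing)


def extract_abnormal_mask(
    seg_classes: TissueClassMap,
    vol: ScalarVolume,
    seed: tuple[int, int, int],
    tolerance: float = 0.1,
    connectivity: int = 26,
    close_iterations: int = 1,
    fill_holes: bool = True,
    max_hole_size: int | None = None,
    frame_of_reference: str = "default",
) -> BinaryMask:
    """Hyper-signal abnormal region: fuzzy candidate set refined by region growing.

    The candidate set is the union of voxels whose tissue role is "hyper" or
    "edema"; the connected component containing the seed is refined by
    region growing restricted to that component.  The grown region is then
    smoothed by a morphological closing confined to the candidate component
    (recovering single voxels the noise pushed out of the homogeneity band
    without ever leaking outside the fuzzy-knowledge region), and fully
    enclosed holes — typically the necrotic/cystic core inside the edema
    rim when the seed sits in the rim — are filled.  ``max_hole_size``
    bounds the filled hole volume in voxels; None fills all enclosed holes.
    """
    candidate = seg_classes.role_mask(ABNORMAL_ROLES)
    seed = tuple(int(s) for s in seed)
    if not candidate[seed]:
        role = (
            seg_classes.class_semantics.get(int(seg_classes.labels[seed]), "outside mask")
            if seg_classes.labels[seed] >= 0
            else "outside mask"
        )
        raise ValueError(
            f"seed {seed} lies in a normal-tissue class ({role}); choose a seed inside "
            "the hyper-signal abnormality"
        )
    conn_rank = {6: 1, 18: 2, 26: 3}[connectivity]
    struct = ndimage.generate_binary_structure(3, conn_rank)
    comp_labels, _ = ndimage.label(candidate, structure=struct)
    component = comp_labels == comp_labels[seed]

    grown = region_grow(vol, seed, tolerance, connectivity=connectivity, domain=component)
    out = grown.values
    if close_iterations > 0:
        closed = ndimage.binary_closing(out, structure=struct, iterations=close_iterations)
        out = (closed & component) | out
    if fill_holes:
        if max_hole_size is None:
            out = ndimage.binary_fill_holes(out)
        else:
            filled = ndimage.binary_fill_holes(out)
            holes, nh = ndimage.label(filled & ~out)
            for lab in range(1, nh + 1):
                hole = holes == lab
                if hole.sum() <= max_hole_size:
                    out = out | hole
    return BinaryMask(out, vol.voxel_spacing, frame_of_reference)
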