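"""Area and agreement metrics between abnormal masks.

The discordance index DI = (|A u B| - |A n B|) / |A u B| is the complement
of the Jaccard overlap: 0 means the two regions coincide, 1 means they are
completely apart.  It relates to the Dice score through
dice = 2 (1 - DI) / (2 - DI).  Areas reproduce the 2D per-patient
convention: pixel count on a slice times in-plane pixel area, in cm^2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .volumes import BinaryMask

__all__ = [
    "AgreementReport",
    "mask_area_cm2",
    "mask_area_per_slice_cm2",
    "mask_volume_cm3",
    "discordance_index",
    "dice",
    "sensitivity_specificity",
    "agreement_report",
]


@dataclass
class AgreementReport:
    """Pairwise mask comparison: areas, Dice, DI, and (optional) sensitivity/specificity."""

    pair: str
    area_a_cm2: float
    area_b_cm2: float
    dice: float
    di: float
    sensitivity: float | None = None
    specificity: float | None = None


def mask_area_per_slice_cm2(mask: BinaryMask) -> np.ndarray:
    """Area of the mask on every axial (z) slice, in cm^2."""
    sx, sy, _ = mask.voxel_spacing
    pixel_area_cm2 = (sx * sy) / 100.0  # mm^2 -> cm^2
    return mask.values.sum(axis=(0, 1)) * pixel_area_cm2


def mask_area_cm2(mask: BinaryMask, slice_index: int | None = None) -> float:
    """2D area in cm^2 on one axial slice.

    When ``slice_index`` is omitted the slice of maximal lesion extent is
    used — the per-patient single-area convention.  Empty masks have area 0.
    """
    per_slice = mask_area_per_slice_cm2(mask)
    if slice_index is None:
        return float(per_slice.max()) if per_slice.size else 0.0
    return float(per_slice[slice_index])


def mask_volume_cm3(mask: BinaryMask) -> float:
    """Total mask volume in cm^3 (all slices)."""
    sx, sy, sz = mask.voxel_spacing
    return float(mask.count() * sx * sy * sz / 1000.0)


def _counts(a: BinaryMask, b: BinaryMask) -> tuple[int, int, int]:
    a.check_comparable(b)
    inter = int((a.values & b.values).sum())
    union = int((a.values | b.values).sum())
    return inter, union, a.count() + b.count()


def discordance_index(a: BinaryMask, b: BinaryMask) -> float:
    """DI = (|A u B| - |A n B|) / |A u B|; 0 identical, 1 disjoint."""
    inter, union, _ = _counts(a, b)
    if union == 0:
        raise ValueError("discordance index undefined: both masks are empty")
    return (union - inter) / union


def dice(a: BinaryMask, b: BinaryMask) -> float:
    """Dice score 2|A n B| / (|A| + |B|)."""
    inter, _, size_sum = _counts(a, b)
    if size_sum == 0:
        raise ValueError("dice undefined: both masks are empty")
    return 2.0 * inter / size_sum


def sensitivity_specificity(
    pred: BinaryMask, truth: BinaryMask, domain: BinaryMask
) -> tuple[float, float]:
    """Sensitivity TP/(TP+FN) and specificity TN/(TN+FP).

    True negatives are counted inside ``domain`` (the brain mask) only, so
    specificity is not inflated by the air background surrounding the head.
    """
    pred.check_comparable(truth)
    pred.check_comparable(domain)
    if truth.count() == 0:
        raise ValueError("sensitivity undefined: empty truth mask")
    p, t, d = pred.values, truth.values, domain.values
    tp = int((p & t).sum())
    fn = int((~p & t).sum())
    fp = int((p & ~t & d).sum())
    tn = int((~p & ~t & d).sum())
    sens = tp / (tp + fn)
    spec = tn / (tn + fp) if (tn + fp) else 1.0
    return sens, spec


def agreement_report(
    pair: str,
    a: BinaryMask,
    b: BinaryMask,
    domain: BinaryMask | None = None,
) -> AgreementReport:
    """Bundle areas, Dice and DI (plus sensitivity/specificity of a vs b if a domain is given)."""
    sens = spec = None
    if domain is not None:
        sens, spec = sensitivity_specificity(a, b, domain)
    return AgreementReport(
        pair=pair,
        area_a_cm2=mask_area_cm2(a),
        area_b_cm2=mask_area_cm2(b),
        dice=dice(a, b),
        di=discordance_index(a, b),
        sensitivity=sens,
        specificity=spec,
    )
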