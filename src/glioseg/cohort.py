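"""Patient-level comparison of abnormal-region areas and discordance indices.

Each patient carries three 2D areas (cm^2) — A_T2, A_F (FLAIR) and A_P
(p-map) — and the three pairwise discordance indices DI_TP, DI_FP, DI_TF.
Patients are grouped by the size ordering of the p-map area relative to the
structural modalities, with an "approximately equal" category when all
pairwise differences stay under 5%.  A 25-patient reference table ships as
a packaged fixture and drives the cohort summary statistics.
"""

from __future__ import annotations

import enum
import hashlib
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "SizeCategory",
    "PatientRecord",
    "CohortSummary",
    "percent_difference",
    "categorize_patient",
    "summarize_cohort",
    "load_table3",
    "records_to_frame",
]

_TABLE3_SHA256 = "c5f8e3e3b67bf74780806cd603a55520be6bbbcaefa2d7ad7e9765102f3b2792"

DI_COLUMNS = ("di_tp", "di_fp", "di_tf")


class SizeCategory(str, enum.Enum):
    P_SMALLEST = "P_SMALLEST"   # A_P < A_T2 and A_P < A_F
    P_LARGEST = "P_LARGEST"     # A_P > A_T2 and A_P > A_F
    P_BETWEEN = "P_BETWEEN"     # strictly between the structural areas
    EQUAL = "EQUAL"             # all pairwise differences < tolerance


@dataclass
class PatientRecord:
    patient_id: int
    area_t2: float
    area_flair: float
    area_pmap: float
    di_tp: float
    di_fp: float
    di_tf: float

    def __post_init__(self) -> None:
        for name in ("area_t2", "area_flair", "area_pmap"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in DI_COLUMNS:
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")


@dataclass
class CohortSummary:
    """Per-pair DI statistics plus size-category counts and mean difference percentages."""

    n_patients: int
    di_stats: pd.DataFrame          # index: di column; columns: mean, sd, min, max
    category_counts: dict[SizeCategory, int]
    category_mean_diff_pct: dict[SizeCategory, dict[str, float]]
    sd_flagged_undefined: bool = False  # single-patient cohort: SD reported as 0


def percent_difference(a: float, b: float) -> float:
    """Symmetric difference percentage 100 |a - b| / max(a, b), bounded by 100."""
    m = max(a, b)
    if m <= 0:
        raise ValueError("percent difference needs max(a, b) > 0")
    return 100.0 * abs(a - b) / m


def categorize_patient(rec: PatientRecord, equal_tol: float = 0.05) -> SizeCategory:
    """Size ordering of the p-map abnormality relative to T2 and FLAIR.

    ``equal_tol`` is a fraction: when all three pairwise difference
    percentages fall below 100*equal_tol the areas count as approximately
    equal, taking precedence over the orderings.
    """
    t, f, p = rec.area_t2, rec.area_flair, rec.area_pmap
    pairs = [(t, f), (t, p), (f, p)]
    if all(percent_difference(a, b) < 100.0 * equal_tol for a, b in pairs):
        return SizeCategory.EQUAL
    if p < t and p < f:
        return SizeCategory.P_SMALLEST
    if p > t and p > f:
        return SizeCategory.P_LARGEST
    return SizeCategory.P_BETWEEN


def _category_diffs(rec: PatientRecord, cat: SizeCategory) -> dict[str, float]:
    """The difference percentages summarized within each category (p vs each structural area)."""
    return {
        "p_vs_t2": percent_difference(rec.area_pmap, rec.area_t2),
        "p_vs_flair": percent_difference(rec.area_pmap, rec.area_flair),
        "t2_vs_flair": percent_difference(rec.area_t2, rec.area_flair),
    }


def summarize_cohort(records: list[PatientRecord], equal_tol: float = 0.05) -> CohortSummary:
    """Mean, sample SD (n-1), min and max per DI column; category counts and mean diffs."""
    if not records:
        raise ValueError("empty cohort")
    df = records_to_frame(records)
    single = len(records) == 1
    stats = {}
    for col in DI_COLUMNS:
        v = df[col].to_numpy()
        stats[col] = {
            "mean": float(v.mean()),
            "sd": 0.0 if single else float(v.std(ddof=1)),
            "min": float(v.min()),
            "max": float(v.max()),
        }
    di_stats = pd.DataFrame(stats).T[["mean", "sd", "min", "max"]]

    counts: dict[SizeCategory, int] = {c: 0 for c in SizeCategory}
    diffs: dict[SizeCategory, list[dict[str, float]]] = {c: [] for c in SizeCategory}
    for rec in records:
        cat = categorize_patient(rec, equal_tol)
        counts[cat] += 1
        diffs[cat].append(_category_diffs(rec, cat))
    mean_diffs = {
        cat: {
            k: float(np.mean([d[k] for d in ds])) for k in ("p_vs_t2", "p_vs_flair", "t2_vs_flair")
        }
        for cat, ds in diffs.items()
        if ds
    }
    return CohortSummary(
        n_patients=len(records),
        di_stats=di_stats,
        category_counts=counts,
        category_mean_diff_pct=mean_diffs,
        sd_flagged_undefined=single,
    )


def records_to_frame(records: list[PatientRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "patient_id": r.patient_id,
                "area_t2": r.area_t2,
                "area_flair": r.area_flair,
                "area_pmap": r.area_pmap,
                "di_tp": r.di_tp,
                "di_fp": r.di_fp,
                "di_tf": r.di_tf,
            }
            for r in records
        ]
    ).set_index("patient_id")


def load_table3() -> list[PatientRecord]:
    """Load the packaged 25-patient reference table (checksum-verified)."""
    ref = resources.files("glioseg").joinpath("data/table3.csv")
    raw = ref.read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != _TABLE3_SHA256:
        raise RuntimeError(
            f"packaged cohort table is corrupted (sha256 {digest}, expected {_TABLE3_SHA256})"
        )
    df = pd.read_csv(ref)
    return [
        PatientRecord(
            patient_id=int(row.patient_id),
            area_t2=float(row.area_t2),
            area_flair=float(row.area_flair),
            area_pmap=float(row.area_pmap),
            di_tp=float(row.di_tp),
            di_fp=float(row.di_fp),
            di_tf=float(row.di_tf),
        )
        for row in df.itertuples()
    ]
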