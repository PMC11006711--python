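"""Nutrition labels from screening-scale scores.

Two questionnaire scales are involved: NRS2002 (Nutrition Risk Screening
2002, integer, threshold 3 flags risk) and the PG-SGA Short Form
(Patient-Generated Subjective Global Assessment, higher = worse).  The
three-class nutrition label is derived from PG-SGA SF with cut points at
2.0 and 5.0: normal (< 2), malnourished (2 to < 5), severe (>= 5).  A score
equal to a cut point enters the worse class, matching triage semantics.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "NutritionClass",
    "ScaleRecord",
    "LabelingError",
    "DEFAULT_THRESHOLDS",
    "assign_class",
    "dichotomize",
    "pearson_r",
    "threshold_profile",
    "read_cohort_csv",
    "COHORT_COLUMNS",
]

DEFAULT_THRESHOLDS = (2.0, 5.0)

VALID_GROUPS = frozenset({"cancer_inpatient", "other_inpatient", "normal_control"})

COHORT_COLUMNS = ["subject_id", "group", "nrs2002", "pgsga_sf", "image_path", "landmark_path"]


class LabelingError(ValueError):
    pass


class NutritionClass(IntEnum):
    NORMAL = 0
    MALNOURISHED = 1
    SEVERE = 2


@dataclass(frozen=True)
class ScaleRecord:
    subject_id: str
    nrs2002: int
    pgsga_sf: float
    group: str = "other_inpatient"

    def __post_init__(self):
        if self.nrs2002 < 0 or self.pgsga_sf < 0:
            raise LabelingError("scale scores must be non-negative")
        if self.group not in VALID_GROUPS:
            raise LabelingError(f"unknown group {self.group!r}")

    @property
    def nutrition_class(self) -> NutritionClass:
        return assign_class(self.pgsga_sf)


def assign_class(
    pgsga_sf: float,
    thresholds: tuple[float, float] = DEFAULT_THRESHOLDS,
) -> NutritionClass:
    """Three-class nutrition label from a PG-SGA SF score."""
    if pgsga_sf < 0:
        raise LabelingError("PG-SGA SF score must be non-negative")
    lo, hi = thresholds
    if pgsga_sf < lo:
        return NutritionClass.NORMAL
    if pgsga_sf < hi:
        return NutritionClass.MALNOURISHED
    return NutritionClass.SEVERE


def dichotomize(label: NutritionClass | int) -> int:
    """Binary collapse for sensitivity/specificity: any malnutrition = 1."""
    return int(int(label) >= NutritionClass.MALNOURISHED)


def pearson_r(x, y) -> tuple[float, float]:
    """Sample Pearson correlation with two-sided p (t transform, n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise LabelingError("pearson_r needs two equal-length vectors, n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise LabelingError("zero variance in input")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def threshold_profile(records, nrs_value: int) -> dict:
    """Distribution of PG-SGA SF among subjects at a given NRS2002 score.

    Returns mean, median, quartiles, min, max and the 95% t-interval of the
    mean — the summary used to map NRS2002 thresholds onto the PG-SGA SF
    scale.
    """
    vals = np.array(
        [r.pgsga_sf for r in records if r.nrs2002 == nrs_value], dtype=float
    )
    if vals.size == 0:
        raise LabelingError(f"no records with NRS2002 == {nrs_value}")
    mean = float(vals.mean())
    if vals.size > 1 and vals.std(ddof=1) > 0:
        lo, hi = stats.t.interval(
            0.95, df=vals.size - 1, loc=mean, scale=stats.sem(vals)
        )
    else:
        lo = hi = mean
    return {
        "nrs2002": nrs_value,
        "n": int(vals.size),
        "mean": mean,
        "median": float(np.median(vals)),
        "q1": float(np.percentile(vals, 25)),
        "q3": float(np.percentile(vals, 75)),
        "min": float(vals.min()),
        "max": float(vals.max()),
        "ci95": (float(lo), float(hi)),
    }


def read_cohort_csv(path) -> list[ScaleRecord]:
    """Strict reader for the cohort table (UTF-8 CSV, fixed schema)."""
    df = pd.read_csv(path, dtype={"subject_id": str})
    missing = set(COHORT_COLUMNS) - set(df.columns)
    if missing:
        raise LabelingError(f"cohort CSV missing columns: {sorted(missing)}")
    return [
        ScaleRecord(
            subject_id=row.subject_id,
            nrs2002=int(row.nrs2002),
            pgsga_sf=float(row.pgsga_sf),
            group=row.group,
        )
        for row in df.itertuples()
    ]
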