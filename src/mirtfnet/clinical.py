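"""Closed-form clinical and bench formulas.

* IHC histoscore: per microscope field, nuclear positive ratio (0-1) times
  staining intensity (0-3); the total score sums exactly four fields
  (range 0-12).  Samples at or above the cutoff (default 1.07) are
  classified as high expression.
* qPCR relative expression by 2^-ddCt with dCt = Ct(target) - Ct(reference
  gene, e.g. beta-actin for mRNA or U6 for miRNA).
* Xenograft tumor volume = length x width^2 / 2, with length the biggest
  and width the smallest diameter in mm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .errors import InputError

HISTOSCORE_CUTOFF = 1.07
INTENSITY_LEVELS = (0, 1, 2, 3)


@dataclass(frozen=True)
class IHCField:
    """One scored microscope field: positive nuclei fraction and intensity."""

    positive_ratio: float
    intensity: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.positive_ratio <= 1.0:
            raise InputError(f"positive_ratio must be in [0, 1], got {self.positive_ratio}")
        if self.intensity not in INTENSITY_LEVELS:
            raise InputError(f"intensity must be one of {INTENSITY_LEVELS}, got {self.intensity}")


@dataclass(frozen=True)
class QPCRMeasurement:
    """Paired cycle thresholds for a target and its reference gene."""

    ct_target: float
    ct_reference: float

    def __post_init__(self) -> None:
        for name in ("ct_target", "ct_reference"):
            v = getattr(self, name)
            if not math.isfinite(v) or v <= 0:
                raise InputError(f"{name} must be a positive finite cycle count, got {v}")

    @property
    def delta_ct(self) -> float:
        return self.ct_target - self.ct_reference


@dataclass(frozen=True)
class TumorMeasurement:
    """Caliper measurement: length = biggest, width = smallest diameter (mm)."""

    length: float
    width: float

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise InputError(f"width must be positive, got {self.width}")
        if self.length < self.width:
            raise InputError(
                f"length ({self.length}) must be >= width ({self.width}): length is "
                "the biggest diameter"
            )


def field_histoscore(field: IHCField) -> float:
    """Positive ratio x intensity for one field; in [0, 3]."""
    return field.positive_ratio * field.intensity


def total_histoscore(fields) -> float:
    """Sum of exactly four field scores; in [0, 12]."""
    fields = list(fields)
    if len(fields) != 4:
        raise InputError(f"total histoscore requires exactly 4 fields, got {len(fields)}")
    return sum(field_histoscore(f) for f in fields)


def classify_expression(score: float, cutoff: float = HISTOSCORE_CUTOFF) -> str:
    """'high' iff score >= cutoff (inclusive boundary), else 'low'."""
    if score < 0:
        raise InputError(f"score must be non-negative, got {score}")
    return "high" if score >= cutoff else "low"


def relative_expression(
    sample: QPCRMeasurement, calibrator: QPCRMeasurement | None = None
) -> float:
    """2^-ddCt relative expression (2^-dCt when no calibrator is given)."""
    ddct = sample.delta_ct
    if calibrator is not None:
        ddct -= calibrator.delta_ct
    return 2.0 ** (-ddct)


def tumor_volume(m: TumorMeasurement) -> float:
    """Tumor volume in mm^3: length x width^2 / 2."""
    return m.length * m.width**2 / 2.0


def score_ihc_table(table: pd.DataFrame, cutoff: float = HISTOSCORE_CUTOFF) -> pd.DataFrame:
    """Batch-score spots given columns ratio_1..4 and intensity_1..4.

    Returns the input plus ``total_score`` and ``expression`` columns.
    """
    needed = [f"{kind}_{i}" for i in range(1, 5) for kind in ("ratio", "intensity")]
    missing = [c for c in needed if c not in table.columns]
    if missing:
        raise InputError(f"IHC table lacks columns: {missing}")
    totals, classes = [], []
    for row in table.itertuples(index=False):
        fields = [
            IHCField(getattr(row, f"ratio_{i}"), int(getattr(row, f"intensity_{i}")))
            for i in range(1, 5)
        ]
        total = total_histoscore(fields)
        totals.append(total)
        classes.append(classify_expression(total, cutoff))
    out = table.copy()
    out["total_score"] = totals
    out["expression"] = classes
    return out
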