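"""SIRI computation and the categorical codings used throughout.

SIRI (systemic inflammatory response index) is computed from a
pre-treatment complete blood count as

    SIRI = (absolute neutrophils x absolute monocytes) / absolute lymphocytes

with all three counts in 10^9 cells/L.  Because SIRI is a ratio, it is
invariant to a common rescaling of neutrophils and lymphocytes, and scales
linearly in the monocyte count; no unit conversion is attempted here.

Also provided: the standard WHO BMI strata and the dichotomization of the
ordinal financial-toxicity (FT) item (0-3) into FT-Low (0-1) / FT-High (2-3).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DomainError

__all__ = [
    "CBCRecord",
    "compute_siri",
    "categorize_bmi",
    "categorize_ft",
    "ensure_siri",
    "BMI_CATEGORIES",
    "FT_LOW",
    "FT_HIGH",
]

BMI_CATEGORIES = ("underweight", "normal", "overweight", "obese")
FT_LOW = "FT-Low"
FT_HIGH = "FT-High"


@dataclass(frozen=True)
class CBCRecord:
    """Absolute differential counts from one complete blood count (10^9/L)."""

    neutrophils: float
    monocytes: float
    lymphocytes: float

    def __post_init__(self) -> None:
        for field in ("neutrophils", "monocytes", "lymphocytes"):
            value = getattr(self, field)
            if value is None or not np.isfinite(value) or value <= 0:
                raise DomainError(f"CBC field {field!r} must be finite and > 0, got {value!r}")


def compute_siri(cbc: CBCRecord | None = None, *, neutrophils: float | None = None,
                 monocytes: float | None = None, lymphocytes: float | None = None
                 ) -> tuple[float, float]:
    """Return ``(SIRI, log2(SIRI))`` for one CBC.

    Accepts either a :class:`CBCRecord` or the three counts as keywords.
    The base-2 logarithm is returned alongside because downstream
    regression models work on the log2 scale.
    """
    if cbc is None:
        cbc = CBCRecord(neutrophils, monocytes, lymphocytes)
    siri = cbc.neutrophils * cbc.monocytes / cbc.lymphocytes
    return siri, float(np.log2(siri))


def categorize_bmi(bmi):
    """Map BMI (kg/m^2) to {underweight, normal, overweight, obese}.

    Boundaries follow the half-open WHO strata: <18.5 underweight,
    [18.5, 25) normal, [25, 30) overweight, >=30 obese — boundary values
    fall in the higher category.
    Accepts a scalar or an array-like; vectorized input returns an
    object array of labels.
    """
    arr = np.asarray(bmi, dtype=float)
    if arr.size == 0:
        raise DomainError("categorize_bmi: empty input")
    if not np.all(np.isfinite(arr)) or np.any(arr <= 0):
        raise DomainError("categorize_bmi: BMI must be finite and > 0")
    idx = np.digitize(arr, [18.5, 25.0, 30.0], right=False)
    labels = np.asarray(BMI_CATEGORIES, dtype=object)[idx]
    if np.isscalar(bmi) or arr.ndim == 0:
        return str(labels if arr.ndim == 0 else labels[0])
    return labels


def categorize_ft(level):
    """Dichotomize the ordinal FT item: 0-1 -> FT-Low, 2-3 -> FT-High."""
    arr = np.asarray(level)
    if arr.size == 0:
        raise DomainError("categorize_ft: empty input")
    flat = arr.astype(float)
    if not np.all(np.isin(flat, [0.0, 1.0, 2.0, 3.0])):
        raise DomainError("categorize_ft: FT level must be one of {0, 1, 2, 3}")
    labels = np.where(flat <= 1, FT_LOW, FT_HIGH).astype(object)
    if np.isscalar(level) or arr.ndim == 0:
        return str(labels if arr.ndim == 0 else labels[0])
    return labels


def ensure_siri(cohort: pd.DataFrame) -> pd.DataFrame:
    """Return a cohort with a ``siri`` column, computing it from CBC columns
    (``neutrophils``, ``monocytes``, ``lymphocytes``) when absent.

    External-validation workflows usually arrive with SIRI precomputed;
    this helper makes either schema acceptable.
    """
    if "siri" in cohort.columns:
        out = cohort
    else:
        needed = {"neutrophils", "monocytes", "lymphocytes"}
        missing = needed - set(cohort.columns)
        if missing:
            raise DomainError(
                "cohort has neither a 'siri' column nor CBC columns; missing: "
                + ", ".join(sorted(missing))
            )
        out = cohort.copy()
        for col in sorted(needed):
            vals = out[col].to_numpy(dtype=float)
            if not np.all(np.isfinite(vals)) or np.any(vals <= 0):
                raise DomainError(f"CBC column {col!r} must be finite and > 0")
        out["siri"] = out["neutrophils"] * out["monocytes"] / out["lymphocytes"]
    if np.any(out["siri"].to_numpy(dtype=float) <= 0):
        raise DomainError("siri must be > 0")
    return out
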