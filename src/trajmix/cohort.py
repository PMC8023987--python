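"""Cohort data model and I/O.

Long-format visit records (one row per clinic visit) plus one baseline row per
patient, stored as plain CSV.  Time is decimal years since diagnosis; no
calendar dates are handled.  Outcomes are the physician's global assessment
(PGA, 0-10) and the cutaneous modified disease activity score (DAS, 0-5),
the latter optionally carried as its four skin components (Gottron's papules,
heliotrope rash, vasculitis, erythema).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: canonical column order for the two CSV files
VISIT_COLUMNS = [
    "patient_id", "t", "pga", "das",
    "gottron", "heliotrope", "vasculitis", "erythema",
]
BASELINE_COLUMNS = [
    "patient_id", "sex", "ethnicity", "diagnosis", "centre",
    "age_at_diagnosis", "time_to_first_visit",
    "pga0", "cmas0", "das0",
    "arthritis", "abnormal_respiration", "calcinosis",
    "lipodystrophy", "ulceration",
]

DAS_COMPONENTS = ["gottron", "heliotrope", "vasculitis", "erythema"]
#: component maxima; sum to the documented 0-5 range of the skin score
DEFAULT_COMPONENT_MAXIMA = {
    "gottron": 1.0, "heliotrope": 1.0, "vasculitis": 1.0, "erythema": 2.0,
}

BINARY_FEATURES = [
    "arthritis", "abnormal_respiration", "calcinosis",
    "lipodystrophy", "ulceration",
]

PGA_RANGE = (0.0, 10.0)
DAS_RANGE = (0.0, 5.0)
CMAS_RANGE = (0.0, 52.0)


class CohortValidationError(ValueError):
    """Raised when a cohort file violates the documented schema."""


@dataclass
class VisitRecord:
    """One clinic visit: outcome scores at time ``t`` (years since diagnosis)."""

    patient_id: str
    t: float
    pga: float | None = None
    das: float | None = None
    das_components: dict[str, float | None] | None = None


@dataclass
class BaselineRecord:
    """Per-patient baseline demographics, first-visit scores and clinical features."""

    patient_id: str
    sex: str
    ethnicity: str
    diagnosis: str
    centre: str
    age_at_diagnosis: float
    time_to_first_visit: float
    pga0: float | None = None
    cmas0: float | None = None
    das0: float | None = None
    arthritis: float | None = None
    abnormal_respiration: float | None = None
    calcinosis: float | None = None
    lipodystrophy: float | None = None
    ulceration: float | None = None


@dataclass
class Cohort:
    """A validated cohort: baseline table (one row per patient) + visit table."""

    baseline: pd.DataFrame
    visits: pd.DataFrame

    def __post_init__(self) -> None:
        validate_cohort(self.baseline, self.visits)

    @property
    def n_patients(self) -> int:
        return len(self.baseline)

    @property
    def n_visits(self) -> int:
        return len(self.visits)

    def patient_ids(self) -> list[str]:
        return list(self.baseline["patient_id"])


def _check_range(df: pd.DataFrame, col: str, lo: float, hi: float, what: str) -> None:
    vals = df[col]
    bad = vals.notna() & ((vals < lo) | (vals > hi))
    if bad.any():
        row = int(np.nonzero(bad.to_numpy())[0][0])
        raise CohortValidationError(
            f"{what} value {vals.iloc[row]!r} out of range [{lo}, {hi}] at row {row}"
        )


def validate_cohort(baseline: pd.DataFrame, visits: pd.DataFrame) -> None:
    """Validate schema, ranges and referential integrity; raise on violation."""
    for col in BASELINE_COLUMNS:
        if col not in baseline.columns:
            raise CohortValidationError(f"baseline table missing column {col!r}")
    for col in VISIT_COLUMNS:
        if col not in visits.columns:
            raise CohortValidationError(f"visit table missing column {col!r}")
    extra = set(visits.columns) - set(VISIT_COLUMNS)
    if extra:
        raise CohortValidationError(f"unknown visit columns: {sorted(extra)}")

    if baseline["patient_id"].duplicated().any():
        dup = baseline.loc[baseline["patient_id"].duplicated(), "patient_id"].iloc[0]
        raise CohortValidationError(f"duplicate baseline patient_id {dup!r}")

    if (visits["t"] < 0).any():
        row = int(np.nonzero((visits["t"] < 0).to_numpy())[0][0])
        raise CohortValidationError(f"negative visit time at row {row}")
    _check_range(visits, "pga", *PGA_RANGE, what="pga")
    _check_range(visits, "das", *DAS_RANGE, what="das")
    _check_range(baseline, "pga0", *PGA_RANGE, what="pga0")
    _check_range(baseline, "cmas0", *CMAS_RANGE, what="cmas0")
    _check_range(baseline, "das0", *DAS_RANGE, what="das0")
    for col in BINARY_FEATURES:
        vals = baseline[col]
        bad = vals.notna() & ~vals.isin([0, 1])
        if bad.any():
            row = int(np.nonzero(bad.to_numpy())[0][0])
            raise CohortValidationError(
                f"binary feature {col!r} has non-binary value at row {row}"
            )

    known = set(baseline["patient_id"])
    orphan = set(visits["patient_id"]) - known
    if orphan:
        raise CohortValidationError(
            f"visits reference unknown patient ids: {sorted(orphan)}"
        )
    # duplicate (patient, t) pairs are rejected, not averaged: silent
    # aggregation would hide data errors upstream
    dup = visits.duplicated(subset=["patient_id", "t"])
    if dup.any():
        pid, t = visits.loc[dup, ["patient_id", "t"]].iloc[0]
        raise CohortValidationError(f"duplicate visit ({pid!r}, t={t})")
    missing_visits = known - set(visits["patient_id"])
    if missing_visits:
        raise CohortValidationError(
            f"patients with zero visits: {sorted(missing_visits)}"
        )


_NA_VALUES = ["", "NA"]


def read_cohort(baseline_path, visits_path) -> Cohort:
    """Read and validate a cohort from the two documented CSV files.

    Missing values (empty field or ``NA``) are preserved as missing, never
    imputed here.
    """
    baseline = pd.read_csv(
        baseline_path, na_values=_NA_VALUES, keep_default_na=False,
        dtype={"patient_id": str},
    )
    visits = pd.read_csv(
        visits_path, na_values=_NA_VALUES, keep_default_na=False,
        dtype={"patient_id": str},
    )
    return Cohort(baseline=baseline, visits=visits)


def write_cohort(cohort: Cohort, baseline_path, visits_path) -> None:
    """Write the two CSV files; missing values are written as empty fields."""
    cohort.baseline.to_csv(baseline_path, index=False, na_rep="")
    cohort.visits.to_csv(visits_path, index=False, na_rep="")


def truncate_followup(cohort: Cohort, horizon_years: float) -> Cohort:
    """Drop visits after ``horizon_years`` since diagnosis (closed boundary).

    Visits with t exactly at the horizon are retained.  Patients left with no
    visits are dropped from the baseline table as well.
    """
    if not horizon_years > 0:
        raise ValueError("horizon_years must be positive")
    visits = cohort.visits[cohort.visits["t"] <= horizon_years].reset_index(drop=True)
    keep = cohort.baseline["patient_id"].isin(visits["patient_id"])
    baseline = cohort.baseline[keep].reset_index(drop=True)
    return Cohort(baseline=baseline, visits=visits)


def compose_modified_das(
    components: dict[str, float | None],
    maxima: dict[str, float] | None = None,
) -> tuple[float, bool]:
    """Combine the four skin components into the modified DAS.

    A missing component contributes 0 (treated as absent; this is known to
    underestimate the true score, hence the returned flag).  The total is
    capped at 5.

    Returns
    -------
    (score, any_missing_flag)
    """
    maxima = maxima or DEFAULT_COMPONENT_MAXIMA
    total = 0.0
    any_missing = False
    for name in DAS_COMPONENTS:
        v = components.get(name)
        if v is None or (isinstance(v, float) and np.isnan(v)):
            any_missing = True
            continue
        if v < 0:
            raise CohortValidationError(f"negative DAS component {name}={v}")
        total += min(float(v), maxima[name])
    return min(total, DAS_RANGE[1]), any_missing


# ---------------------------------------------------------------------------
# outcome transforms

TRANSFORMS = ("identity", "sqrt")


def transform_outcome(y, transform: str):
    """Map an outcome to the modelling scale (identity or square root)."""
    y = np.asarray(y, dtype=float)
    if transform == "identity":
        return y
    if transform == "sqrt":
        if np.any(y[np.isfinite(y)] < 0):
            raise ValueError("negative input to sqrt transform")
        return np.sqrt(y)
    raise ValueError(f"unknown transform {transform!r}")


def inverse_transform(y_star, transform: str):
    """Inverse of :func:`transform_outcome`."""
    y_star = np.asarray(y_star, dtype=float)
    if transform == "identity":
        return y_star
    if transform == "sqrt":
        return np.square(y_star)
    raise ValueError(f"unknown transform {transform!r}")
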