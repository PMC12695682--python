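"""Cohort table I/O, timecourse classification, and cohort summaries.

The cohort table mirrors the clinical characteristics collected for each
sural-nerve-biopsy patient: demographics, clinical and neuropathological
diagnosis, disease timecourse at biosample collection, the signed interval
between biosample collection and biopsy (positive = sample drawn before the
biopsy), a flag for concomitant CNS disease relevant to serum NfL, and a
vasculitis assignment (definite/probable vs. other diagnoses).
"""

from __future__ import annotations

import csv
import importlib.resources
from dataclasses import dataclass, fields
from pathlib import Path
from statistics import median
from typing import Iterable

__all__ = [
    "CohortRecord",
    "CohortSummary",
    "SEXES",
    "TIMECOURSES",
    "CNS_FLAGS",
    "VASCULITIS_FLAGS",
    "MAX_DELTA_DAYS",
    "read_cohort_table",
    "write_cohort_table",
    "classify_timecourse",
    "summarize_cohort",
    "packaged_cohort_path",
]

SEXES = ("m", "f")
TIMECOURSES = ("acute", "subacute", "chronic")
CNS_FLAGS = ("yes", "no", "unclear")
VASCULITIS_FLAGS = ("definite_or_probable", "other")

#: Inclusion window: biosamples drawn within 30 days of the biopsy.
MAX_DELTA_DAYS = 30

# Timecourse category boundaries, in days since onset/exacerbation.
ACUTE_MAX_DAYS = 7  # exclusive: <1 week is acute
SUBACUTE_MAX_DAYS = 56  # inclusive: 1-8 weeks is subacute, >8 weeks chronic


class CohortSchemaError(ValueError):
    """Missing or malformed column in a cohort table."""


@dataclass(frozen=True)
class CohortRecord:
    """One biopsy patient.

    Attributes
    ----------
    study_id : str
        Pseudonymized patient identifier.
    age : int
        Age in years at biopsy.
    sex : str
        ``"m"`` or ``"f"``.
    clinical_dx, path_dx : str
        Clinical and neuropathological diagnosis, free text.
    timecourse : str
        Disease timecourse at biosample collection:
        ``"acute"`` (<1 week after onset/exacerbation), ``"subacute"``
        (1-8 weeks), or ``"chronic"`` (>8 weeks).
    delta_days_to_biopsy : int
        Signed days between biosample collection and biopsy; positive
        means the sample was collected before the biopsy.
    cns_disease : str
        ``"yes"`` / ``"no"`` / ``"unclear"`` relevance of concomitant CNS
        disease for serum NfL at the time of biopsy.
    vasculitis : str
        ``"definite_or_probable"`` or ``"other"``.
    """

    study_id: str
    age: int
    sex: str
    clinical_dx: str
    path_dx: str
    timecourse: str
    delta_days_to_biopsy: int
    cns_disease: str
    vasculitis: str

    def __post_init__(self) -> None:
        if self.age < 0:
            raise ValueError(f"{self.study_id}: age must be >= 0, got {self.age}")
        if self.sex not in SEXES:
            raise ValueError(f"{self.study_id}: sex must be one of {SEXES}, got {self.sex!r}")
        if self.timecourse not in TIMECOURSES:
            raise ValueError(
                f"{self.study_id}: timecourse must be one of {TIMECOURSES}, got {self.timecourse!r}"
            )
        if self.cns_disease not in CNS_FLAGS:
            raise ValueError(
                f"{self.study_id}: cns_disease must be one of {CNS_FLAGS}, got {self.cns_disease!r}"
            )
        if self.vasculitis not in VASCULITIS_FLAGS:
            raise ValueError(
                f"{self.study_id}: vasculitis must be one of {VASCULITIS_FLAGS}, "
                f"got {self.vasculitis!r}"
            )
        if abs(self.delta_days_to_biopsy) > MAX_DELTA_DAYS:
            raise ValueError(
                f"{self.study_id}: |delta_days_to_biopsy| must be <= {MAX_DELTA_DAYS}, "
                f"got {self.delta_days_to_biopsy}"
            )


@dataclass(frozen=True)
class CohortSummary:
    """Headline cohort counts and the median biosample-to-biopsy interval."""

    n_total: int
    n_male: int
    n_female: int
    n_cns_yes: int
    n_vasculitis: int
    n_vasculitis_acute_or_subacute: int
    n_other_dx: int
    median_delta_days: float


_COLUMNS = [f.name for f in fields(CohortRecord)]
_INT_COLUMNS = {"age", "delta_days_to_biopsy"}


def packaged_cohort_path() -> Path:
    """Path to the packaged 35-patient cohort fixture."""
    return Path(importlib.resources.files("nervequant.data") / "reference_cohort.csv")


def read_cohort_table(path: str | Path) -> list[CohortRecord]:
    """Read a cohort CSV into validated :class:`CohortRecord` objects.

    The file must be comma-separated UTF-8 with a header row containing at
    least the columns ``study_id, age, sex, clinical_dx, path_dx, timecourse,
    delta_days_to_biopsy, cns_disease, vasculitis``. Enumeration violations
    and non-integer numeric fields raise ``ValueError`` naming the offending
    row.
    """
    path = Path(path)
    records: list[CohortRecord] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(row for row in fh if not row.startswith("#"))
        if reader.fieldnames is None:
            raise CohortSchemaError(f"{path}: empty file, header row required")
        missing = [c for c in _COLUMNS if c not in reader.fieldnames]
        if missing:
            raise CohortSchemaError(f"{path}: missing required column(s) {missing}")
        for i, row in enumerate(reader, start=2):
            kwargs: dict = {}
            for col in _COLUMNS:
                raw = (row[col] or "").strip()
                if col in _INT_COLUMNS:
                    try:
                        kwargs[col] = int(raw)
                    except ValueError:
                        raise ValueError(
                            f"{path} row {i}, column {col!r}: expected integer, got {raw!r}"
                        ) from None
                else:
                    kwargs[col] = raw
            try:
                records.append(CohortRecord(**kwargs))
            except ValueError as exc:
                raise ValueError(f"{path} row {i}: {exc}") from None
    return records


def write_cohort_table(records: Iterable[CohortRecord], path: str | Path) -> None:
    """Write records as a cohort CSV (round-trips with :func:`read_cohort_table`)."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(_COLUMNS)
        for rec in records:
            writer.writerow([getattr(rec, col) for col in _COLUMNS])


def classify_timecourse(days_since_onset: float) -> str:
    """Classify days since disease onset/exacerbation into a timecourse category.

    <7 days is ``acute``, 7-56 days inclusive is ``subacute``, and more than
    56 days (8 weeks) is ``chronic``.
    """
    if days_since_onset < 0:
        raise ValueError(f"days_since_onset must be >= 0, got {days_since_onset}")
    if days_since_onset < ACUTE_MAX_DAYS:
        return "acute"
    if days_since_onset <= SUBACUTE_MAX_DAYS:
        return "subacute"
    return "chronic"


def summarize_cohort(records: list[CohortRecord]) -> CohortSummary:
    """Compute headline cohort counts by exact enumeration.

    The median biosample-to-biopsy interval is taken over the *signed*
    day values (even-n median = midpoint of the central pair).
    """
    if not records:
        raise ValueError("cannot summarize an empty cohort")
    n_vasc = sum(r.vasculitis == "definite_or_probable" for r in records)
    return CohortSummary(
        n_total=len(records),
        n_male=sum(r.sex == "m" for r in records),
        n_female=sum(r.sex == "f" for r in records),
        n_cns_yes=sum(r.cns_disease == "yes" for r in records),
        n_vasculitis=n_vasc,
        n_vasculitis_acute_or_subacute=sum(
            r.vasculitis == "definite_or_probable" and r.timecourse in ("acute", "subacute")
            for r in records
        ),
        n_other_dx=len(records) - n_vasc,
        median_delta_days=median(r.delta_days_to_biopsy for r in records),
    )
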