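"""Patient-level cohort records, CSV I/O, outcome derivation and descriptive summaries.

The unit of analysis is one person with aphasia (PWA) who completed a course of
telepractice speech-language treatment.  Functional communication is scored
pre/post on the NOMS 7-point Likert scales (verbal expression and auditory
comprehension; 1 = minimal ability, 7 = independence) and quality of
communication life on the ASHA-QCL mean score (1-5).  Improvement is the
dichotomy ``final > initial`` per dimension; ties count as no improvement.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from enum import Enum
from pathlib import Path
from typing import Sequence

import pandas as pd

__all__ = [
    "AphasiaType",
    "Dimension",
    "PatientRecord",
    "ImprovementOutcome",
    "GroupStats",
    "CohortSummary",
    "CohortSchemaError",
    "CohortValidationError",
    "read_cohort",
    "write_cohort",
    "derive_improvement",
    "summarize_cohort",
]


class AphasiaType(str, Enum):
    """Clinical aphasia classification used for the nesting structure."""

    ANOMIC = "anomic"
    BROCA = "broca"
    CONDUCTION = "conduction"
    GLOBAL = "global"


class Dimension(str, Enum):
    """NOMS functional-communication dimension."""

    VERBAL = "verbal"
    COMPREHENSION = "comprehension"


class CohortSchemaError(ValueError):
    """A required column is missing from a cohort file."""


class CohortValidationError(ValueError):
    """A cohort row violates a range or enumeration constraint."""


MAX_SESSIONS = 12

#: CSV column order; also the canonical field order of :class:`PatientRecord`.
COHORT_COLUMNS = (
    "patient_id",
    "age",
    "education",
    "african_american",
    "months_post_onset",
    "aphasia_type",
    "sessions_attended",
    "noms_verbal_initial",
    "noms_verbal_final",
    "noms_comp_initial",
    "noms_comp_final",
    "qcl_initial",
    "qcl_final",
)


@dataclass(frozen=True)
class PatientRecord:
    """One PWA: demographics, aphasia type, attendance and pre/post scores.

    ``african_american`` is a 0/1 indicator (the study cohort is two-category:
    African American vs White).  NOMS scores are integer Likert levels in
    [1, 7]; QCL scores are ASHA-QCL mean item scores in [1, 5].
    """

    patient_id: str
    age: float
    education: float
    african_american: int
    months_post_onset: float
    aphasia_type: AphasiaType
    sessions_attended: int
    noms_verbal_initial: int
    noms_verbal_final: int
    noms_comp_initial: int
    noms_comp_final: int
    qcl_initial: float
    qcl_final: float

    def __post_init__(self) -> None:
        if not self.age > 0:
            raise CohortValidationError(f"age must be positive, got {self.age}")
        if self.education < 0:
            raise CohortValidationError(
                f"education must be non-negative, got {self.education}"
            )
        if self.african_american not in (0, 1):
            raise CohortValidationError(
                f"african_american must be 0 or 1, got {self.african_american}"
            )
        if not self.months_post_onset > 0:
            raise CohortValidationError(
                f"months_post_onset must be positive, got {self.months_post_onset}"
            )
        if not isinstance(self.aphasia_type, AphasiaType):
            try:
                object.__setattr__(self, "aphasia_type", AphasiaType(self.aphasia_type))
            except ValueError:
                raise CohortValidationError(
                    f"unknown aphasia type {self.aphasia_type!r}"
                ) from None
        if not 0 <= self.sessions_attended <= MAX_SESSIONS:
            raise CohortValidationError(
                f"sessions_attended must be in [0, {MAX_SESSIONS}], "
                f"got {self.sessions_attended}"
            )
        for name in (
            "noms_verbal_initial",
            "noms_verbal_final",
            "noms_comp_initial",
            "noms_comp_final",
        ):
            value = getattr(self, name)
            if not (isinstance(value, int) and 1 <= value <= 7):
                raise CohortValidationError(
                    f"{name} must be an integer Likert level in [1, 7], got {value!r}"
                )
        for name in ("qcl_initial", "qcl_final"):
            value = getattr(self, name)
            if not 1.0 <= value <= 5.0:
                raise CohortValidationError(
                    f"{name} must lie in [1, 5], got {value!r}"
                )

    def noms_pair(self, dimension: Dimension) -> tuple[int, int]:
        """(initial, final) NOMS scores for the given dimension."""
        dimension = Dimension(dimension)
        if dimension is Dimension.VERBAL:
            return self.noms_verbal_initial, self.noms_verbal_final
        return self.noms_comp_initial, self.noms_comp_final


@dataclass(frozen=True)
class ImprovementOutcome:
    """Dichotomized outcome: 1 iff the final NOMS score strictly exceeds the initial."""

    patient_id: str
    dimension: Dimension
    improved: int


_INT_COLUMNS = {
    "african_american",
    "sessions_attended",
    "noms_verbal_initial",
    "noms_verbal_final",
    "noms_comp_initial",
    "noms_comp_final",
}


def read_cohort(path: str | Path) -> list[PatientRecord]:
    """Read a cohort CSV (UTF-8, comma-separated, snake_case header).

    Raises :class:`CohortSchemaError` naming the first missing column, or
    :class:`CohortValidationError` carrying the offending row index.
    """
    frame = pd.read_csv(path, dtype={"patient_id": str}, encoding="utf-8")
    for column in COHORT_COLUMNS:
        if column not in frame.columns:
            raise CohortSchemaError(f"missing required column {column!r}")
    records = []
    for index, row in frame.iterrows():
        kwargs = {}
        for column in COHORT_COLUMNS:
            value = row[column]
            if column == "patient_id":
                kwargs[column] = str(value)
            elif column == "aphasia_type":
                kwargs[column] = value
            elif column in _INT_COLUMNS:
                if pd.isna(value) or float(value) != int(value):
                    raise CohortValidationError(
                        f"row {index}: column {column!r} must be an integer, got {value!r}"
                    )
                kwargs[column] = int(value)
            else:
                if pd.isna(value):
                    raise CohortValidationError(
                        f"row {index}: column {column!r} is missing"
                    )
                kwargs[column] = float(value)
        try:
            records.append(PatientRecord(**kwargs))
        except CohortValidationError as exc:
            raise CohortValidationError(f"row {index}: {exc}") from None
    return records


def write_cohort(records: Sequence[PatientRecord], path: str | Path) -> None:
    """Write records as CSV such that :func:`read_cohort` round-trips exactly."""
    rows = []
    for record in records:
        row = {c: getattr(record, c) for c in COHORT_COLUMNS}
        row["aphasia_type"] = record.aphasia_type.value
        rows.append(row)
    frame = pd.DataFrame(rows, columns=list(COHORT_COLUMNS))
    frame.to_csv(path, index=False, encoding="utf-8")


def derive_improvement(
    records: Sequence[PatientRecord], dimension: Dimension
) -> list[ImprovementOutcome]:
    """Dichotomize pre/post NOMS scores: improved = 1 iff final > initial."""
    dimension = Dimension(dimension)
    outcomes = []
    for record in records:
        initial, final = record.noms_pair(dimension)
        outcomes.append(
            ImprovementOutcome(record.patient_id, dimension, int(final > initial))
        )
    return outcomes


@dataclass(frozen=True)
class GroupStats:
    """Counts, means and sample sds for one aphasia type (or the full sample).

    ``sd`` entries are ``None`` for groups of size 1 (no n-1 estimate exists).
    """

    n: int
    african_american: int
    white: int
    verbal_improvers: int
    comp_improvers: int
    mean: dict[str, float]
    sd: dict[str, float | None]


_SUMMARY_VARS = (
    "age",
    "months_post_onset",
    "education",
    "noms_verbal_initial",
    "noms_verbal_final",
    "noms_comp_initial",
    "noms_comp_final",
)


@dataclass(frozen=True)
class CohortSummary:
    """Descriptive summary: full sample plus one block per aphasia type."""

    full: GroupStats
    by_type: dict[AphasiaType, GroupStats]

    def __post_init__(self) -> None:
        if sum(g.n for g in self.by_type.values()) != self.full.n:
            raise CohortValidationError("per-type counts do not sum to the full count")
        for group in (self.full, *self.by_type.values()):
            if group.verbal_improvers > group.n or group.comp_improvers > group.n:
                raise CohortValidationError("improver count exceeds group size")

    def to_dict(self) -> dict:
        return {
            "full": asdict(self.full),
            "by_type": {t.value: asdict(g) for t, g in self.by_type.items()},
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def _group_stats(records: Sequence[PatientRecord]) -> GroupStats:
    n = len(records)
    mean: dict[str, float] = {}
    sd: dict[str, float | None] = {}
    for var in _SUMMARY_VARS:
        values = [float(getattr(r, var)) for r in records]
        m = sum(values) / n
        mean[var] = m
        if n < 2:
            sd[var] = None
        else:
            sd[var] = math.sqrt(sum((v - m) ** 2 for v in values) / (n - 1))
    return GroupStats(
        n=n,
        african_american=sum(r.african_american for r in records),
        white=sum(1 - r.african_american for r in records),
        verbal_improvers=sum(
            o.improved for o in derive_improvement(records, Dimension.VERBAL)
        ),
        comp_improvers=sum(
            o.improved for o in derive_improvement(records, Dimension.COMPREHENSION)
        ),
        mean=mean,
        sd=sd,
    )


def summarize_cohort(records: Sequence[PatientRecord]) -> CohortSummary:
    """Compute descriptive statistics (arithmetic mean, sample n-1 sd) overall
    and per aphasia type.  Empty cohorts are an error; types with no patients
    are omitted from ``by_type``."""
    if not records:
        raise CohortValidationError("cannot summarize an empty cohort")
    by_type = {}
    for aphasia_type in AphasiaType:
        members = [r for r in records if r.aphasia_type is aphasia_type]
        if members:
            by_type[aphasia_type] = _group_stats(members)
    return CohortSummary(full=_group_stats(records), by_type=by_type)
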