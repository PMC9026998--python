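"""Domain types, validation, and CSV/JSON input/output for fusion-testing cohorts.

A cohort is a collection of :class:`CaseRecord` objects, one per molecularly
tested tumor.  Each record carries the working (pre-molecular) and final
(post-molecular) diagnosis, the fusion result, anatomic site, tumor grade, and
the four report-timeline milestones that drive test-order-intent
classification.  Timelines are stored as integer day offsets normalized so
that the surgical pathology order is day 0; calendar dates in input files are
converted on ingestion.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import json
import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Any, Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

__all__ = [
    "PrimarySite",
    "WorkingDx",
    "FinalDx",
    "MarkerStatus",
    "Grade",
    "FusionCall",
    "CaseRecord",
    "AnalysisConfig",
    "RowError",
    "SchemaError",
    "CohortValidationError",
    "CASE_CSV_COLUMNS",
    "read_cases",
    "write_cases",
    "read_config",
    "write_report",
]


class PrimarySite(str, Enum):
    """Anatomic primary-site groups used for frequency tabulation."""

    HEAD_AND_NECK = "head_and_neck"
    BRAIN = "brain"
    BREAST = "breast"
    THYMUS = "thymus"
    LUNG = "lung"
    OTHER = "other"


class WorkingDx(str, Enum):
    """Diagnosis submitted when ordering molecular testing."""

    MEC = "MEC"
    ASC = "ASC"
    OTHER = "OTHER"
    UNKNOWN = "UNKNOWN"


class FinalDx(str, Enum):
    """Adjudicated diagnosis after integrating the molecular result."""

    MEC = "MEC"
    ASC = "ASC"
    OTHER = "OTHER"


class MarkerStatus(str, Enum):
    POSITIVE = "positive"
    NEGATIVE = "negative"
    NOT_TESTED = "not_tested"


class Grade(str, Enum):
    LOW = "low"
    INTERMEDIATE = "intermediate"
    HIGH = "high"


@dataclass(frozen=True)
class FusionCall:
    """A structured gene-fusion call (5' partner first, e.g. CRTC1ex1-MAML2ex2)."""

    gene_5p: str
    exon_5p: int
    gene_3p: str
    exon_3p: int

    def __post_init__(self) -> None:
        if not self.gene_5p or not self.gene_3p:
            raise ValueError("fusion gene symbols must be non-empty")
        if self.exon_5p < 1 or self.exon_3p < 1:
            raise ValueError("fusion exons must be >= 1")

    def label(self) -> str:
        return f"{self.gene_5p}(ex{self.exon_5p})-{self.gene_3p}(ex{self.exon_3p})"


@dataclass
class CaseRecord:
    """One molecularly tested tumor.

    Timeline fields are integer day offsets with ``t_surg_order`` normalized
    to 0.  Invariants enforced by :meth:`validate`:

    * ``t_surg_order <= t_surg_signout`` and ``t_mol_order <= t_mol_signout``;
    * ``marker_status == positive`` exactly when a fusion call is attached;
    * a final diagnosis of ASC excludes a positive marker (the rearrangement
      rules out adenosquamous carcinoma).
    """

    case_id: str
    primary_site: PrimarySite
    working_dx: WorkingDx
    final_dx: FinalDx
    marker_status: MarkerStatus
    subsite: str = ""
    fusion: Optional[FusionCall] = None
    grade: Optional[Grade] = None
    t_surg_order: int = 0
    t_surg_signout: int = 0
    t_mol_order: int = 0
    t_mol_signout: int = 0

    def validation_errors(self) -> list[tuple[str, str]]:
        """Return a list of ``(field, message)`` invariant violations."""
        errs: list[tuple[str, str]] = []
        if self.t_surg_order > self.t_surg_signout:
            errs.append(("t_surg_signout", "surgical sign-out precedes surgical order"))
        if self.t_mol_order > self.t_mol_signout:
            errs.append(("t_mol_signout", "molecular sign-out precedes molecular order"))
        if (self.marker_status is MarkerStatus.POSITIVE) != (self.fusion is not None):
            errs.append(
                ("marker_status", "marker_status=positive must coincide with a fusion call")
            )
        if self.final_dx is FinalDx.ASC and self.marker_status is MarkerStatus.POSITIVE:
            errs.append(
                ("final_dx", "final diagnosis ASC is incompatible with a positive marker")
            )
        return errs

    def validate(self) -> "CaseRecord":
        errs = self.validation_errors()
        if errs:
            raise ValueError("; ".join(f"{f}: {m}" for f, m in errs))
        return self


class AnalysisConfig(BaseModel):
    """Analysis-wide knobs (thresholds, fee schedule, survey scale, CI level)."""

    model_config = ConfigDict(extra="forbid")

    therapeutic_threshold_days: int = Field(default=30, ge=0)
    unit_cost: float = Field(default=597.91, gt=0)
    likert_max: int = Field(default=100, ge=1)
    ci_level: float = Field(default=0.95, gt=0, lt=1)
    seed: int = 0


# ---------------------------------------------------------------------------
# CSV ingestion


@dataclass(frozen=True)
class RowError:
    """A rejected input row: 0-based data row index, field name, message."""

    row: int
    field: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"row {self.row}, field {self.field!r}: {self.message}"


class SchemaError(ValueError):
    """The input file header does not match the documented schema."""


class CohortValidationError(ValueError):
    """One or more rows failed validation; carries the row-indexed errors."""

    def __init__(self, errors: Sequence[RowError]):
        self.errors = list(errors)
        preview = "; ".join(str(e) for e in self.errors[:5])
        more = "" if len(self.errors) <= 5 else f" (+{len(self.errors) - 5} more)"
        super().__init__(f"{len(self.errors)} invalid row(s): {preview}{more}")


CASE_CSV_COLUMNS = [
    "case_id",
    "primary_site",
    "subsite",
    "working_dx",
    "final_dx",
    "marker_status",
    "fusion_5p_gene",
    "fusion_5p_exon",
    "fusion_3p_gene",
    "fusion_3p_exon",
    "grade",
    "t_surg_order",
    "t_surg_signout",
    "t_mol_order",
    "t_mol_signout",
]

_TIME_COLUMNS = ["t_surg_order", "t_surg_signout", "t_mol_order", "t_mol_signout"]


def _parse_enum(enum_cls: type[Enum], raw: str, field_name: str):
    """Case-insensitive enum lookup by value name."""
    token = raw.strip().lower().replace("-", "_").replace(" ", "_")
    for member in enum_cls:
        if member.value.lower() == token:
            return member
    allowed = ", ".join(m.value for m in enum_cls)
    raise ValueError(f"invalid {field_name} {raw!r} (allowed: {allowed})")


def _parse_day(raw: str) -> int | _dt.date:
    """A timeline cell: either an integer day offset or an ISO-8601 date."""
    token = raw.strip()
    try:
        return int(token)
    except ValueError:
        pass
    try:
        return _dt.date.fromisoformat(token)
    except ValueError as exc:
        raise ValueError(f"not an integer day offset or ISO date: {raw!r}") from exc


def _row_to_case(row: pd.Series, idx: int, errors: list[RowError]) -> Optional[CaseRecord]:
    n_before = len(errors)

    def grab(field_name, parser):
        try:
            return parser(row[field_name])
        except ValueError as exc:
            errors.append(RowError(idx, field_name, str(exc)))
            return None

    site = grab("primary_site", lambda v: _parse_enum(PrimarySite, v, "primary_site"))
    working = grab("working_dx", lambda v: _parse_enum(WorkingDx, v, "working_dx"))
    final = grab("final_dx", lambda v: _parse_enum(FinalDx, v, "final_dx"))
    marker = grab("marker_status", lambda v: _parse_enum(MarkerStatus, v, "marker_status"))
    grade = None
    if str(row["grade"]).strip():
        grade = grab("grade", lambda v: _parse_enum(Grade, v, "grade"))

    fusion = None
    fusion_cells = [str(row[c]).strip() for c in
                    ("fusion_5p_gene", "fusion_5p_exon", "fusion_3p_gene", "fusion_3p_exon")]
    if any(fusion_cells):
        try:
            fusion = FusionCall(
                gene_5p=fusion_cells[0],
                exon_5p=int(fusion_cells[1]),
                gene_3p=fusion_cells[2],
                exon_3p=int(fusion_cells[3]),
            )
        except (ValueError, TypeError) as exc:
            errors.append(RowError(idx, "fusion_5p_gene", f"invalid fusion call: {exc}"))

    times: dict[str, int | _dt.date | None] = {c: grab(c, _parse_day) for c in _TIME_COLUMNS}
    if any(v is None for v in times.values()):
        pass
    elif any(isinstance(v, _dt.date) for v in times.values()):
        if not all(isinstance(v, _dt.date) for v in times.values()):
            errors.append(
                RowError(idx, "t_surg_order", "timeline mixes calendar dates and offsets")
            )
        else:
            origin = times["t_surg_order"]
            times = {c: (v - origin).days for c, v in times.items()}  # type: ignore[operator]

    if len(errors) > n_before:
        return None

    case = CaseRecord(
        case_id=str(row["case_id"]).strip(),
        primary_site=site,
        subsite=str(row["subsite"]).strip(),
        working_dx=working,
        final_dx=final,
        marker_status=marker,
        fusion=fusion,
        grade=grade,
        t_surg_order=int(times["t_surg_order"]),
        t_surg_signout=int(times["t_surg_signout"]),
        t_mol_order=int(times["t_mol_order"]),
        t_mol_signout=int(times["t_mol_signout"]),
    )
    for field_name, message in case.validation_errors():
        errors.append(RowError(idx, field_name, message))
    if len(errors) > n_before:
        return None
    return case


def read_cases(
    path: str | Path, *, collect_errors: bool = False
) -> list[CaseRecord] | tuple[list[CaseRecord], list[RowError]]:
    """Read a case-level cohort CSV.

    Parameters
    ----------
    path
        CSV file with the exact header ``CASE_CSV_COLUMNS``.
    collect_errors
        When False (default), any invalid row raises
        :class:`CohortValidationError`.  When True, returns
        ``(cases, row_errors)`` with invalid rows dropped.

    Raises
    ------
    SchemaError
        If a mandatory column is missing.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in CASE_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {', '.join(missing)}")

    cases: list[CaseRecord] = []
    errors: list[RowError] = []
    for idx, row in df.iterrows():
        case = _row_to_case(row, int(idx), errors)
        if case is not None:
            cases.append(case)
    if errors and not collect_errors:
        raise CohortValidationError(errors)
    if collect_errors:
        return cases, errors
    return cases


def write_cases(cases: Iterable[CaseRecord], path: str | Path) -> None:
    """Write cases back to the documented CSV schema (round-trip safe)."""
    rows = []
    for c in cases:
        rows.append(
            {
                "case_id": c.case_id,
                "primary_site": c.primary_site.value,
                "subsite": c.subsite,
                "working_dx": c.working_dx.value,
                "final_dx": c.final_dx.value,
                "marker_status": c.marker_status.value,
                "fusion_5p_gene": c.fusion.gene_5p if c.fusion else "",
                "fusion_5p_exon": c.fusion.exon_5p if c.fusion else "",
                "fusion_3p_gene": c.fusion.gene_3p if c.fusion else "",
                "fusion_3p_exon": c.fusion.exon_3p if c.fusion else "",
                "grade": c.grade.value if c.grade else "",
                "t_surg_order": c.t_surg_order,
                "t_surg_signout": c.t_surg_signout,
                "t_mol_order": c.t_mol_order,
                "t_mol_signout": c.t_mol_signout,
            }
        )
    pd.DataFrame(rows, columns=CASE_CSV_COLUMNS).to_csv(path, index=False)


def read_config(path: str | Path) -> AnalysisConfig:
    """Read an :class:`AnalysisConfig` from JSON; unknown keys are rejected."""
    with open(path) as fh:
        return AnalysisConfig.model_validate(json.load(fh))


# ---------------------------------------------------------------------------
# Report serialization


def _jsonable(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, Enum):
        return obj.value
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, pd.DataFrame):
        return _jsonable(obj.to_dict(orient="records"))
    if isinstance(obj, float) and not math.isfinite(obj):
        raise ValueError(f"non-finite number in report: {obj!r}")
    return obj


def write_report(results: Any, path: str | Path) -> None:
    """Serialize a nested report structure to JSON.

    Dataclasses, enums, numpy scalars/arrays and DataFrames are converted to
    plain JSON types.  Non-finite numbers are a serialization error rather
    than silently becoming ``NaN`` tokens, so the file always round-trips.
    """
    payload = _jsonable(results)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, allow_nan=False)
        fh.write("\n")
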