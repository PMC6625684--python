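"""Labeled TBI cohorts: CSV schema, validation, exclusion flow, round-trip I/O.

A cohort is a table of admission presentations, each with an operative label
(craniotomy or craniectomy within 24 hours of arrival) or an exclusion
reason.  The CSV schema, in column order::

    record_id, gcs_total, intubated, pupils, midline_shift_mm,
    temporal_pathology, edh_width_mm, operative, exclusion_reason,
    age_years, transport_minutes, mechanism

The first eight columns are required, the last four optional.  Booleans are
serialized as 0/1, missing values as empty cells, pupil categories as the
literal tokens ``normal | unilateral_enlarged | bilateral_abnormal``, and
both CT measurements are in millimeters.  ``operative`` may be empty only
when ``exclusion_reason`` is not ``none`` (an excluded record has no
resolved label).
"""
from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import pandas as pd

from .errors import SchemaError, ValidationError
from .scale import CTFindings, PatientPresentation, PupilExam

__all__ = [
    "ExclusionReason",
    "LabeledRecord",
    "LabeledCohort",
    "REQUIRED_COLUMNS",
    "OPTIONAL_COLUMNS",
    "read_cohort",
    "read_presentation_frame",
    "write_cohort",
    "apply_exclusions",
]

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = (
    "record_id",
    "gcs_total",
    "intubated",
    "pupils",
    "midline_shift_mm",
    "temporal_pathology",
    "edh_width_mm",
    "operative",
)
OPTIONAL_COLUMNS = ("exclusion_reason", "age_years", "transport_minutes", "mechanism")
ALL_COLUMNS = REQUIRED_COLUMNS + OPTIONAL_COLUMNS


class ExclusionReason(str, enum.Enum):
    """Why a record is left out of the assessed cohort.

    ``SURGERY_NOT_CONSIDERED`` also covers patients deemed medically unfit
    for surgery; ``NONE`` marks an assessable record.
    """

    NONE = "none"
    CARE_WITHDRAWN = "care_withdrawn"
    POSTERIOR_FOSSA_HEMORRHAGE = "posterior_fossa_hemorrhage"
    SURGERY_NOT_CONSIDERED = "surgery_not_considered"


@dataclass(frozen=True)
class LabeledRecord:
    """One patient: presentation, operative label, and exclusion status."""

    record_id: str
    presentation: PatientPresentation
    operative: bool | None
    exclusion_reason: ExclusionReason = ExclusionReason.NONE
    age_years: float | None = None
    transport_minutes: float | None = None
    mechanism: str | None = None

    def __post_init__(self) -> None:
        if self.operative is None and self.exclusion_reason is ExclusionReason.NONE:
            raise ValidationError(
                f"record {self.record_id!r}: operative label may be missing only "
                "for excluded records"
            )
        for name in ("age_years", "transport_minutes"):
            v = getattr(self, name)
            if v is not None and not float(v) >= 0:
                raise ValidationError(f"record {self.record_id!r}: {name} must be >= 0, got {v!r}")


@dataclass
class LabeledCohort:
    """An ordered collection of labeled records with unique ids."""

    records: list[LabeledRecord] = field(default_factory=list)
    provenance: str = ""
    #: rows dropped by lenient parsing (0 for programmatically built cohorts)
    n_dropped: int = 0

    def __post_init__(self) -> None:
        ids = [r.record_id for r in self.records]
        if len(set(ids)) != len(ids):
            seen: set[str] = set()
            dup = next(i for i in ids if i in seen or seen.add(i))
            raise ValidationError(f"duplicate record_id {dup!r} in cohort")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[LabeledRecord]:
        return iter(self.records)

    def to_frame(self) -> pd.DataFrame:
        """The cohort as a DataFrame in schema column order.

        ``operative`` is an object column holding True/False/None so missing
        labels survive the round trip.
        """
        rows = []
        for r in self.records:
            rows.append(
                {
                    "record_id": r.record_id,
                    "gcs_total": r.presentation.gcs_total,
                    "intubated": r.presentation.intubated,
                    "pupils": r.presentation.pupils.value,
                    "midline_shift_mm": r.presentation.ct.midline_shift_mm,
                    "temporal_pathology": r.presentation.ct.temporal_pathology,
                    "edh_width_mm": r.presentation.ct.edh_width_mm,
                    "operative": r.operative,
                    "exclusion_reason": r.exclusion_reason.value,
                    "age_years": r.age_years,
                    "transport_minutes": r.transport_minutes,
                    "mechanism": r.mechanism,
                }
            )
        return pd.DataFrame(rows, columns=list(ALL_COLUMNS))


_TRUE_TOKENS = {"1", "true"}
_FALSE_TOKENS = {"0", "false"}


def _parse_bool(token: str, row: int, col: str) -> bool:
    t = token.strip().lower()
    if t in _TRUE_TOKENS:
        return True
    if t in _FALSE_TOKENS:
        return False
    raise SchemaError(f"row {row}, column {col!r}: expected 0/1, got {token!r}")


def _parse_float(token: str, row: int, col: str) -> float:
    try:
        v = float(token)
    except ValueError:
        raise SchemaError(f"row {row}, column {col!r}: unparseable number {token!r}") from None
    if not math.isfinite(v):
        raise SchemaError(f"row {row}, column {col!r}: non-finite number {token!r}")
    return v


def _parse_int(token: str, row: int, col: str) -> int:
    v = _parse_float(token, row, col)
    if not v.is_integer():
        raise SchemaError(f"row {row}, column {col!r}: expected an integer, got {token!r}")
    return int(v)


def _row_to_record(row: pd.Series, rownum: int) -> LabeledRecord:
    try:
        presentation = PatientPresentation(
            gcs_total=_parse_int(row["gcs_total"], rownum, "gcs_total"),
            intubated=_parse_bool(row["intubated"], rownum, "intubated"),
            pupils=row["pupils"].strip(),
            ct=CTFindings(
                midline_shift_mm=_parse_float(row["midline_shift_mm"], rownum, "midline_shift_mm"),
                temporal_pathology=_parse_bool(row["temporal_pathology"], rownum, "temporal_pathology"),
                edh_width_mm=_parse_float(row["edh_width_mm"], rownum, "edh_width_mm"),
            ),
        )
    except SchemaError:
        raise
    except ValidationError as exc:
        raise SchemaError(f"row {rownum}: {exc}") from None

    op_token = str(row["operative"]).strip()
    operative = None if op_token == "" else _parse_bool(op_token, rownum, "operative")

    reason_token = str(row.get("exclusion_reason", "") or "").strip()
    try:
        reason = ExclusionReason(reason_token) if reason_token else ExclusionReason.NONE
    except ValueError:
        raise SchemaError(
            f"row {rownum}, column 'exclusion_reason': unknown reason {reason_token!r}"
        ) from None

    def _opt_float(col: str) -> float | None:
        token = str(row.get(col, "") or "").strip()
        return None if token == "" else _parse_float(token, rownum, col)

    mech = str(row.get("mechanism", "") or "").strip() or None
    try:
        return LabeledRecord(
            record_id=str(row["record_id"]).strip(),
            presentation=presentation,
            operative=operative,
            exclusion_reason=reason,
            age_years=_opt_float("age_years"),
            transport_minutes=_opt_float("transport_minutes"),
            mechanism=mech,
        )
    except ValidationError as exc:
        raise SchemaError(f"row {rownum}: {exc}") from None


def read_cohort(path: "str | Path", strict: bool = True, provenance: str | None = None) -> LabeledCohort:
    """Read and validate a labeled cohort from the documented CSV schema.

    In strict mode (default) the first invalid row aborts with its row number
    and field; in lenient mode invalid rows are dropped, the drop count is
    logged and surfaced as ``cohort.n_dropped``.  Row numbers are 1-based
    data rows (the header is row 0).
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")

    records: list[LabeledRecord] = []
    dropped = 0
    for i, (_, row) in enumerate(df.iterrows(), start=1):
        try:
            records.append(_row_to_record(row, i))
        except SchemaError as exc:
            if strict:
                raise SchemaError(f"{path}: {exc}") from None
            dropped += 1
            logger.warning("%s: dropping invalid row: %s", path, exc)
    if dropped:
        logger.warning("%s: dropped %d invalid row(s)", path, dropped)
    return LabeledCohort(
        records=records,
        provenance=provenance if provenance is not None else str(path),
        n_dropped=dropped,
    )


def read_presentation_frame(path: "str | Path") -> pd.DataFrame:
    """Read only the clinical columns needed for scoring (labels optional).

    Used by the ``score`` command so unlabeled files can be scored; values
    are validated by the scorer itself.
    """
    path = Path(path)
    df = pd.read_csv(path, keep_default_na=False, na_values=[""])
    needed = ("record_id", "gcs_total", "pupils", "midline_shift_mm",
              "temporal_pathology", "edh_width_mm")
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    if len(df):
        for col in ("intubated", "temporal_pathology"):
            if col in df.columns:
                df[col] = [
                    _parse_bool(str(v), i, col)
                    for i, v in enumerate(df[col], start=1)
                ]
    return df


def _fmt_bool(v: bool | None) -> str:
    return "" if v is None else str(int(v))


def _fmt_opt(v) -> str:
    return "" if v is None or (not isinstance(v, str) and pd.isna(v)) else str(v)


def write_cohort(cohort: LabeledCohort, path: "str | Path") -> None:
    """Write a cohort to CSV such that :func:`read_cohort` round-trips it."""
    df = cohort.to_frame()
    out = pd.DataFrame(
        {
            "record_id": df["record_id"],
            "gcs_total": df["gcs_total"].astype(int),
            "intubated": df["intubated"].map(_fmt_bool),
            "pupils": df["pupils"],
            "midline_shift_mm": df["midline_shift_mm"].map(repr),
            "temporal_pathology": df["temporal_pathology"].map(_fmt_bool),
            "edh_width_mm": df["edh_width_mm"].map(repr),
            "operative": df["operative"].map(_fmt_bool),
            "exclusion_reason": df["exclusion_reason"],
            "age_years": df["age_years"].map(_fmt_opt),
            "transport_minutes": df["transport_minutes"].map(_fmt_opt),
            "mechanism": df["mechanism"].map(_fmt_opt),
        },
        columns=list(ALL_COLUMNS),
    )
    out.to_csv(path, index=False, encoding="utf-8")


def apply_exclusions(cohort: LabeledCohort) -> tuple[LabeledCohort, dict[str, int]]:
    """Split off excluded records, returning the assessed cohort and a tally.

    The tally maps every non-``none`` reason to its count (zeros included);
    ``len(assessed) + sum(tally.values()) == len(cohort)`` always holds, and
    the operation is idempotent.
    """
    tally = {r.value: 0 for r in ExclusionReason if r is not ExclusionReason.NONE}
    kept: list[LabeledRecord] = []
    for rec in cohort.records:
        if rec.exclusion_reason is ExclusionReason.NONE:
            kept.append(rec)
        else:
            tally[rec.exclusion_reason.value] += 1
    assessed = LabeledCohort(records=kept, provenance=cohort.provenance, n_dropped=cohort.n_dropped)
    return assessed, tally


def records_from_frame(df: pd.DataFrame, provenance: str = "") -> LabeledCohort:
    """Build a cohort from an already-typed DataFrame (inverse of ``to_frame``)."""
    records = []
    for _, row in df.iterrows():
        op = row["operative"]
        records.append(
            LabeledRecord(
                record_id=str(row["record_id"]),
                presentation=PatientPresentation(
                    gcs_total=int(row["gcs_total"]),
                    intubated=bool(row["intubated"]),
                    pupils=PupilExam(row["pupils"]),
                    ct=CTFindings(
                        midline_shift_mm=float(row["midline_shift_mm"]),
                        temporal_pathology=bool(row["temporal_pathology"]),
                        edh_width_mm=float(row["edh_width_mm"]),
                    ),
                ),
                operative=None if op is None or (isinstance(op, float) and pd.isna(op)) else bool(op),
                exclusion_reason=ExclusionReason(row.get("exclusion_reason", "none")),
                age_years=None if pd.isna(row.get("age_years")) else float(row["age_years"]),
                transport_minutes=None if pd.isna(row.get("transport_minutes")) else float(row["transport_minutes"]),
                mechanism=None if not row.get("mechanism") or pd.isna(row.get("mechanism")) else str(row["mechanism"]),
            )
        )
    return LabeledCohort(records=records, provenance=provenance)
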