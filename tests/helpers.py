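"""Shared builders for test cohorts."""
from __future__ import annotations

from sitiscale import (
    CTFindings,
    ExclusionReason,
    LabeledCohort,
    LabeledRecord,
    PatientPresentation,
    PupilExam,
)


def make_record(
    rid: str,
    gcs: int = 15,
    pupils: str = "normal",
    shift: float = 0.0,
    temporal: bool = False,
    edh: float = 0.0,
    operative: bool | None = False,
    intubated: bool = False,
    exclusion: str = "none",
    **kwargs,
) -> LabeledRecord:
    return LabeledRecord(
        record_id=rid,
        presentation=PatientPresentation(
            gcs_total=gcs,
            intubated=intubated,
            pupils=PupilExam(pupils),
            ct=CTFindings(midline_shift_mm=shift, temporal_pathology=temporal, edh_width_mm=edh),
        ),
        operative=operative,
        exclusion_reason=ExclusionReason(exclusion),
        **kwargs,
    )


# component kwargs achieving each exact total 0..11
_TOTAL_RECIPES = {
    0: dict(gcs=13),
    1: dict(gcs=13, temporal=True),
    2: dict(gcs=8),
    3: dict(gcs=8, temporal=True),
    4: dict(gcs=8, pupils="unilateral_enlarged"),
    5: dict(gcs=8, pupils="unilateral_enlarged", temporal=True),
    6: dict(gcs=8, pupils="unilateral_enlarged", shift=7.5),
    7: dict(gcs=8, pupils="unilateral_enlarged", shift=7.5, temporal=True),
    8: dict(gcs=8, pupils="unilateral_enlarged", shift=12.0),
    9: dict(gcs=8, pupils="unilateral_enlarged", shift=12.0, temporal=True),
    10: dict(gcs=8, pupils="unilateral_enlarged", shift=12.0, edh=12.0),
    11: dict(gcs=8, pupils="unilateral_enlarged", shift=12.0, temporal=True, edh=12.0),
}


def record_with_total(rid: str, total: int, operative: bool) -> LabeledRecord:
    """A labeled record whose SITI total is exactly ``total``."""
    return make_record(rid, operative=operative, **_TOTAL_RECIPES[total])


def cohort_from_scores(scores_and_labels: list[tuple[int, bool]]) -> LabeledCohort:
    """Cohort with one record per (siti_total, operative) pair."""
    return LabeledCohort(
        records=[
            record_with_total(f"C{i:04d}", total, op)
            for i, (total, op) in enumerate(scores_and_labels)
        ]
    )
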