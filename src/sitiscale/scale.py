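"""Point rules of the Surgical Intervention for Traumatic Injury (SITI) scale.

The SITI scale is an additive clinical decision score (0-11 points) that
communicates the potential need for surgical decompression (craniotomy or
craniectomy) after closed traumatic brain injury.  It combines five admission
findings:

==============================  ======================  ======
Component                       Finding                 Points
==============================  ======================  ======
Glasgow Coma Scale (total)      >12                     0
                                9-12                    1
                                <9                      2
Pupil examination               unilateral enlarged     2
                                otherwise               0
Midline shift (head CT)         <5 mm                   0
                                5-10 mm                 2
                                >10 mm                  4
Temporal (middle fossa) blood   present                 1
Epidural hematoma width         >=10 mm                 2
==============================  ======================  ======

A total of 3 or more is conventionally read as "surgery should be
considered".  Bilateral enlarged and/or unreactive pupils deliberately score
0: they signal an injury pattern in which decompression may no longer be the
question.  Midline shift is the displacement of the septum pellucidum
measured at the foramen of Monro.  The GCS total of an intubated patient is
computed with the verbal component graded 1T (counted as 1); intubation
itself never changes the points.

Band edges: the 2-point midline-shift band is closed, ``[5.0, 10.0]`` mm, so
the three bands partition the nonnegative line; the epidural cutoff is
inclusive (>=10 mm) by default, with ``edh_strict_gt=True`` switching to a
strict >10 mm rule for sensitivity analyses.
"""
from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = [
    "MIN_SCORE",
    "MAX_SCORE",
    "DEFAULT_THRESHOLD",
    "PupilExam",
    "CTFindings",
    "PatientPresentation",
    "SITIResult",
    "gcs_points",
    "pupil_points",
    "shift_points",
    "temporal_points",
    "edh_points",
    "compute_siti",
    "score_frame",
    "enumerate_all_scores",
]

MIN_SCORE = 0
MAX_SCORE = 11
DEFAULT_THRESHOLD = 3

#: Midline shift at or above this value (mm) is rejected as implausible.
MAX_PLAUSIBLE_SHIFT_MM = 50.0


class PupilExam(str, enum.Enum):
    """Admission pupil examination, collapsed to the categories the scale uses.

    A unilateral *unreactive but not enlarged* pupil is not a scale category
    and is recorded as ``NORMAL`` (0 points).
    """

    NORMAL = "normal"
    UNILATERAL_ENLARGED = "unilateral_enlarged"
    BILATERAL_ABNORMAL = "bilateral_abnormal"


def _coerce_pupils(value: "PupilExam | str") -> PupilExam:
    if isinstance(value, PupilExam):
        return value
    try:
        return PupilExam(value)
    except ValueError:
        tokens = ", ".join(m.value for m in PupilExam)
        raise ValidationError(
            f"pupils must be one of {{{tokens}}}, got {value!r}"
        ) from None


def _check_int(value, name: str) -> int:
    if isinstance(value, bool) or not float(value).is_integer():
        raise ValidationError(f"{name} must be an integer, got {value!r}")
    return int(value)


@dataclass(frozen=True)
class CTFindings:
    """Head-CT measurements feeding the scale, all lengths in millimeters.

    ``edh_width_mm`` is 0 when no epidural hematoma is present.
    """

    midline_shift_mm: float
    temporal_pathology: bool
    edh_width_mm: float = 0.0

    def __post_init__(self) -> None:
        if not self.midline_shift_mm >= 0:
            raise ValidationError(
                f"midline_shift_mm must be >= 0, got {self.midline_shift_mm!r}"
            )
        if self.midline_shift_mm >= MAX_PLAUSIBLE_SHIFT_MM:
            raise ValidationError(
                f"midline_shift_mm={self.midline_shift_mm!r} is implausible "
                f"(>= {MAX_PLAUSIBLE_SHIFT_MM} mm)"
            )
        if not self.edh_width_mm >= 0:
            raise ValidationError(
                f"edh_width_mm must be >= 0, got {self.edh_width_mm!r}"
            )


@dataclass(frozen=True)
class PatientPresentation:
    """One patient's admission findings: GCS, pupils, and head CT."""

    gcs_total: int
    pupils: PupilExam
    ct: CTFindings
    intubated: bool = False

    def __post_init__(self) -> None:
        g = _check_int(self.gcs_total, "gcs_total")
        if not 3 <= g <= 15:
            raise ValidationError(f"gcs_total must be in [3, 15], got {g}")
        object.__setattr__(self, "gcs_total", g)
        object.__setattr__(self, "pupils", _coerce_pupils(self.pupils))


@dataclass(frozen=True)
class SITIResult:
    """Per-component points, the additive total, and threshold positivity."""

    gcs_points: int
    pupil_points: int
    shift_points: int
    temporal_points: int
    edh_points: int
    total: int
    positive: bool


def gcs_points(gcs_total: int) -> int:
    """Points for the total Glasgow Coma Scale score: >12 -> 0, 9-12 -> 1, <9 -> 2."""
    g = _check_int(gcs_total, "gcs_total")
    if not 3 <= g <= 15:
        raise ValidationError(f"gcs_total must be in [3, 15], got {g}")
    if g > 12:
        return 0
    if g >= 9:
        return 1
    return 2


def pupil_points(pupils: "PupilExam | str") -> int:
    """2 points for a unilateral enlarged pupil; normal and bilateral abnormal score 0."""
    return 2 if _coerce_pupils(pupils) is PupilExam.UNILATERAL_ENLARGED else 0


def shift_points(midline_shift_mm: float) -> int:
    """Points for midline shift: <5 mm -> 0, [5, 10] mm -> 2, >10 mm -> 4."""
    s = float(midline_shift_mm)
    if not s >= 0:
        raise ValidationError(f"midline_shift_mm must be >= 0, got {midline_shift_mm!r}")
    if s >= MAX_PLAUSIBLE_SHIFT_MM:
        raise ValidationError(
            f"midline_shift_mm={midline_shift_mm!r} is implausible "
            f"(>= {MAX_PLAUSIBLE_SHIFT_MM} mm)"
        )
    if s < 5.0:
        return 0
    if s <= 10.0:
        return 2
    return 4


def temporal_points(temporal_pathology: bool) -> int:
    """1 point for hemorrhage or edema localized to the middle cranial fossa."""
    return 1 if temporal_pathology else 0


def edh_points(edh_width_mm: float, edh_strict_gt: bool = False) -> int:
    """2 points for an epidural hematoma at least 10 mm wide.

    With ``edh_strict_gt=True`` the cutoff becomes strictly >10 mm, the
    variant printed on the scale card.
    """
    w = float(edh_width_mm)
    if not w >= 0:
        raise ValidationError(f"edh_width_mm must be >= 0, got {edh_width_mm!r}")
    if edh_strict_gt:
        return 2 if w > 10.0 else 0
    return 2 if w >= 10.0 else 0


def compute_siti(
    p: PatientPresentation,
    threshold: int = DEFAULT_THRESHOLD,
    edh_strict_gt: bool = False,
) -> SITIResult:
    """Score a single presentation and classify it against ``threshold``.

    Returns the five component point values, their sum (the SITI total,
    0-11), and ``positive = total >= threshold``.
    """
    t = _check_int(threshold, "threshold")
    if not 0 <= t <= 12:
        raise ValidationError(f"threshold must be in [0, 12], got {t}")
    g = gcs_points(p.gcs_total)
    u = pupil_points(p.pupils)
    s = shift_points(p.ct.midline_shift_mm)
    tb = temporal_points(p.ct.temporal_pathology)
    e = edh_points(p.ct.edh_width_mm, edh_strict_gt=edh_strict_gt)
    total = g + u + s + tb + e
    return SITIResult(
        gcs_points=g,
        pupil_points=u,
        shift_points=s,
        temporal_points=tb,
        edh_points=e,
        total=total,
        positive=total >= t,
    )


#: Columns a scoreable table must carry.
CLINICAL_COLUMNS = (
    "gcs_total",
    "pupils",
    "midline_shift_mm",
    "temporal_pathology",
    "edh_width_mm",
)

POINT_COLUMNS = (
    "gcs_points",
    "pupil_points",
    "shift_points",
    "temporal_points",
    "edh_points",
)


def score_frame(df: pd.DataFrame, edh_strict_gt: bool = False) -> pd.DataFrame:
    """Vectorized scoring of a table of presentations.

    ``df`` must carry the five clinical columns (``gcs_total``, ``pupils``,
    ``midline_shift_mm``, ``temporal_pathology``, ``edh_width_mm``).  Returns
    a new frame, aligned on ``df.index``, with the five point columns and
    ``siti_total``.  Any invalid value raises :class:`ValidationError` naming
    the offending column and value.
    """
    missing = [c for c in CLINICAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"missing required columns: {missing}")
    n = len(df)
    out = pd.DataFrame(index=df.index)
    if n == 0:
        for col in (*POINT_COLUMNS, "siti_total"):
            out[col] = pd.Series([], dtype=int)
        return out

    gcs = np.asarray(df["gcs_total"], dtype=float)
    if np.any(~np.isfinite(gcs)) or np.any(gcs != np.round(gcs)):
        bad = df["gcs_total"].iloc[int(np.flatnonzero(~np.isfinite(gcs) | (gcs != np.round(gcs)))[0])]
        raise ValidationError(f"gcs_total must be an integer, got {bad!r}")
    gcs = gcs.astype(int)
    if np.any((gcs < 3) | (gcs > 15)):
        bad = gcs[(gcs < 3) | (gcs > 15)][0]
        raise ValidationError(f"gcs_total must be in [3, 15], got {bad}")

    pup_pts = df["pupils"].map(
        lambda v: 2 if _coerce_pupils(v) is PupilExam.UNILATERAL_ENLARGED else 0
    ).to_numpy()

    shift = np.asarray(df["midline_shift_mm"], dtype=float)
    if np.any(~np.isfinite(shift) | (shift < 0) | (shift >= MAX_PLAUSIBLE_SHIFT_MM)):
        bad = shift[~np.isfinite(shift) | (shift < 0) | (shift >= MAX_PLAUSIBLE_SHIFT_MM)][0]
        raise ValidationError(
            f"midline_shift_mm must be in [0, {MAX_PLAUSIBLE_SHIFT_MM}), got {bad!r}"
        )

    edh = np.asarray(df["edh_width_mm"], dtype=float)
    if np.any(~np.isfinite(edh) | (edh < 0)):
        bad = edh[~np.isfinite(edh) | (edh < 0)][0]
        raise ValidationError(f"edh_width_mm must be >= 0, got {bad!r}")

    temporal = np.asarray(df["temporal_pathology"], dtype=bool)

    out["gcs_points"] = np.where(gcs > 12, 0, np.where(gcs >= 9, 1, 2))
    out["pupil_points"] = pup_pts
    out["shift_points"] = np.where(shift < 5.0, 0, np.where(shift <= 10.0, 2, 4))
    out["temporal_points"] = temporal.astype(int)
    edh_cut = (edh > 10.0) if edh_strict_gt else (edh >= 10.0)
    out["edh_points"] = np.where(edh_cut, 2, 0)
    out["siti_total"] = out[list(POINT_COLUMNS)].sum(axis=1)
    return out


# Representative raw values for each category level, used to drive the
# single-presentation scorer over the whole discrete grid.
_GCS_BINS = ((">12", 13), ("9-12", 10), ("<9", 6))
_SHIFT_BANDS = (("<5", 2.0), ("5-10", 7.5), (">10", 12.0))
_EDH_LEVELS = (("absent", 0.0), (">=10mm", 12.0))
_TEMPORAL_LEVELS = (("no", False), ("yes", True))


def enumerate_all_scores() -> pd.DataFrame:
    """Exhaustively score the full discrete component grid.

    One row per combination of GCS bin (3) x pupil category (3) x
    midline-shift band (3) x temporal pathology (2) x epidural cutoff (2) =
    108 rows, each scored through :func:`compute_siti` on a representative
    presentation.  Serves as a built-in oracle: the totals span exactly 0-11.
    """
    rows = []
    for gcs_label, gcs_value in _GCS_BINS:
        for pup in PupilExam:
            for shift_label, shift_value in _SHIFT_BANDS:
                for temp_label, temp_value in _TEMPORAL_LEVELS:
                    for edh_label, edh_value in _EDH_LEVELS:
                        p = PatientPresentation(
                            gcs_total=gcs_value,
                            pupils=pup,
                            ct=CTFindings(
                                midline_shift_mm=shift_value,
                                temporal_pathology=temp_value,
                                edh_width_mm=edh_value,
                            ),
                        )
                        r = compute_siti(p)
                        rows.append(
                            {
                                "gcs_bin": gcs_label,
                                "pupils": pup.value,
                                "shift_band": shift_label,
                                "temporal": temp_label,
                                "edh": edh_label,
                                "gcs_points": r.gcs_points,
                                "pupil_points": r.pupil_points,
                                "shift_points": r.shift_points,
                                "temporal_points": r.temporal_points,
                                "edh_points": r.edh_points,
                                "total": r.total,
                            }
                        )
    return pd.DataFrame(rows)
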