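"""Seeded synthetic TBI cohorts emulating the evaluation study's marginals.

The real evaluation cohort (a phase III TBI trial database) is not public,
so this module generates labeled cohorts whose group sizes and per-group
component marginals match the published univariate table: 707 nonoperative
and 164 operative patients out of 871 assessed, with group-specific rates
of unilateral enlarged pupil, midline-shift bands, temporal pathology, and
epidural hematoma.  Components are sampled independently within each group
because only marginals are published; see the methods note for what that
does and does not emulate.

GCS-bin probabilities are not published directly; they are derived from the
published group mean GCS (7.6 nonoperative, 8.1 operative) assuming uniform
draws within the entry-range bins 4-8 and 9-12.  Continuous magnitudes are
uniform within their band: shift 0-5 / 5-10 / 10-15 mm, EDH width 10-20 mm
(all generated hematomas wide enough to score, ``edh_wide_fraction=1``) or
3-10 mm otherwise.

A separate deterministic fixture reconstructs the published threshold-3
confusion matrix exactly, record for record, without sampling.
"""
from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np

from .cohort import ExclusionReason, LabeledCohort, LabeledRecord
from .errors import ValidationError
from .scale import CTFindings, PatientPresentation, PupilExam

__all__ = [
    "GroupDistribution",
    "CohortSpec",
    "generate_cohort",
    "fixture_table3_cohort",
    "spec_to_config",
    "spec_from_config",
]

MECHANISMS = (
    "mvc_atv_scooter",
    "fall",
    "assault",
    "bicycle",
    "other_unknown",
    "pedestrian_struck",
)


@dataclass(frozen=True)
class GroupDistribution:
    """Component marginals for one label group (operative or nonoperative)."""

    p_gcs_9_12: float  # P(GCS in 9-12); complement is the 4-8 bin
    p_unilateral_pupil: float
    shift_band_probs: tuple[float, float, float]  # <5, 5-10, >10 mm
    p_temporal: float
    p_edh: float
    edh_wide_fraction: float = 1.0  # fraction of EDHs >= 10 mm wide
    p_intubated: float = 0.24
    age_mean: float = 40.0
    transport_mean: float = 50.0
    mechanism_probs: tuple[float, ...] = (0.56, 0.154, 0.062, 0.053, 0.041, 0.13)

    def validate(self, name: str) -> None:
        for attr in (
            "p_gcs_9_12",
            "p_unilateral_pupil",
            "p_temporal",
            "p_edh",
            "edh_wide_fraction",
            "p_intubated",
        ):
            v = getattr(self, attr)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name}.{attr} must be in [0, 1], got {v!r}")
        for attr in ("shift_band_probs", "mechanism_probs"):
            probs = getattr(self, attr)
            if any(p < 0 for p in probs) or abs(sum(probs) - 1.0) > 1e-12:
                raise ValidationError(
                    f"{name}.{attr} must be nonnegative and sum to 1, got {probs!r}"
                )


# Published marginals of the nonoperative (n=707) and operative (n=164)
# groups; GCS-bin probabilities derived from the group mean GCS assuming
# uniform draws within the 4-8 and 9-12 bins (see module docstring).
NONOPERATIVE_DEFAULTS = GroupDistribution(
    p_gcs_9_12=1.6 / 4.5,  # mean GCS 7.6
    p_unilateral_pupil=0.132,
    shift_band_probs=(0.973, 0.027, 0.0),
    p_temporal=0.347,
    p_edh=0.079,
    p_intubated=0.239,
    age_mean=37.8,
    transport_mean=55.1,
    mechanism_probs=(0.601, 0.143, 0.054, 0.054, 0.032, 0.116),
)
OPERATIVE_DEFAULTS = GroupDistribution(
    p_gcs_9_12=2.1 / 4.5,  # mean GCS 8.1
    p_unilateral_pupil=0.207,
    shift_band_probs=(0.372, 0.415, 0.213),
    p_temporal=0.872,
    p_edh=0.298,
    p_intubated=0.250,
    age_mean=44.2,
    transport_mean=47.2,
    mechanism_probs=(0.378, 0.201, 0.098, 0.049, 0.079, 0.195),
)

#: Assessed cohort size and operative fraction of the evaluation study.
DEFAULT_N = 871
DEFAULT_OPERATIVE_FRACTION = 164 / 871


@dataclass(frozen=True)
class CohortSpec:
    """Full parameter set governing synthetic-cohort generation."""

    n_total: int = DEFAULT_N
    operative_fraction: float = DEFAULT_OPERATIVE_FRACTION
    nonoperative: GroupDistribution = field(default_factory=lambda: NONOPERATIVE_DEFAULTS)
    operative: GroupDistribution = field(default_factory=lambda: OPERATIVE_DEFAULTS)
    seed: int = 0

    def validate(self) -> None:
        if not (isinstance(self.n_total, (int, np.integer)) and self.n_total >= 0):
            raise ValidationError(f"n_total must be a nonnegative integer, got {self.n_total!r}")
        if not 0.0 <= self.operative_fraction <= 1.0:
            raise ValidationError(
                f"operative_fraction must be in [0, 1], got {self.operative_fraction!r}"
            )
        self.nonoperative.validate("nonoperative")
        self.operative.validate("operative")


def _draw_group(rng: np.random.Generator, dist: GroupDistribution, n: int) -> dict:
    """Vectorized component draws for ``n`` patients of one group."""
    gcs_bin_high = rng.random(n) < dist.p_gcs_9_12
    gcs = np.where(
        gcs_bin_high,
        rng.integers(9, 13, size=n),  # 9-12 inclusive
        rng.integers(4, 9, size=n),  # 4-8 inclusive
    )
    pupil = rng.random(n) < dist.p_unilateral_pupil
    band = rng.choice(3, size=n, p=np.asarray(dist.shift_band_probs))
    u = rng.random(n)
    shift = np.choose(band, [5.0 * u, 5.0 + 5.0 * u, 10.0 + 5.0 * u])
    temporal = rng.random(n) < dist.p_temporal
    edh_present = rng.random(n) < dist.p_edh
    edh_wide = rng.random(n) < dist.edh_wide_fraction
    edh_width = np.where(
        edh_present,
        np.where(edh_wide, 10.0 + 10.0 * rng.random(n), 3.0 + 7.0 * rng.random(n)),
        0.0,
    )
    intubated = rng.random(n) < dist.p_intubated
    age = np.clip(rng.normal(dist.age_mean, 16.0, size=n), 18.0, 90.0)
    transport = np.clip(rng.normal(dist.transport_mean, 15.0, size=n), 5.0, 240.0)
    mech = rng.choice(len(MECHANISMS), size=n, p=np.asarray(dist.mechanism_probs))
    return {
        "gcs": gcs,
        "pupil": pupil,
        "shift": shift,
        "temporal": temporal,
        "edh_width": edh_width,
        "intubated": intubated,
        "age": age,
        "transport": transport,
        "mech": mech,
    }


def generate_cohort(spec: CohortSpec | None = None) -> LabeledCohort:
    """Draw a labeled cohort from ``spec`` (defaults emulate the study).

    Deterministic given ``spec.seed``: one named generator per cohort, no
    global state.  The operative label is drawn first (Bernoulli with
    ``operative_fraction``), then each record's components are drawn
    independently from its group's distributions.
    """
    spec = spec if spec is not None else CohortSpec()
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = int(spec.n_total)
    operative = rng.random(n) < spec.operative_fraction

    draws = {}
    for is_op, dist in ((False, spec.nonoperative), (True, spec.operative)):
        idx = np.flatnonzero(operative == is_op)
        draws[is_op] = (idx, _draw_group(rng, dist, idx.size))

    width = max(4, len(str(max(n, 1))))
    records: list[LabeledRecord | None] = [None] * n
    for is_op, (idx, d) in draws.items():
        for j, i in enumerate(idx):
            records[i] = LabeledRecord(
                record_id=f"S{i + 1:0{width}d}",
                presentation=PatientPresentation(
                    gcs_total=int(d["gcs"][j]),
                    intubated=bool(d["intubated"][j]),
                    pupils=(
                        PupilExam.UNILATERAL_ENLARGED
                        if d["pupil"][j]
                        else PupilExam.NORMAL
                    ),
                    ct=CTFindings(
                        midline_shift_mm=float(d["shift"][j]),
                        temporal_pathology=bool(d["temporal"][j]),
                        edh_width_mm=float(d["edh_width"][j]),
                    ),
                ),
                operative=bool(is_op),
                age_years=round(float(d["age"][j]), 1),
                transport_minutes=round(float(d["transport"][j]), 1),
                mechanism=MECHANISMS[int(d["mech"][j])],
            )
    return LabeledCohort(
        records=records,  # type: ignore[arg-type]
        provenance=f"synthetic cohort (seed={spec.seed}, n={n})",
    )


def _fixture_presentation(
    gcs: int, temporal: bool, shift: float = 0.0, edh: float = 0.0
) -> PatientPresentation:
    return PatientPresentation(
        gcs_total=gcs,
        pupils=PupilExam.NORMAL,
        ct=CTFindings(midline_shift_mm=shift, temporal_pathology=temporal, edh_width_mm=edh),
    )


def fixture_table3_cohort(include_excluded: bool = False) -> LabeledCohort:
    """Deterministic 871-record cohort reproducing the published 2x2 table.

    Constructed (not sampled) so that at threshold 3 the confusion matrix is
    exactly tp=152, fp=237, fn=12, tn=470: operative patients get 152
    score-3 presentations (GCS 8 + temporal pathology) and 12 score-2
    presentations; nonoperative patients get 237 score-3, 235 score-2 and
    235 score-0 presentations.  With ``include_excluded=True`` the 11
    pre-assessment exclusions (6 care withdrawn, 2 posterior fossa
    hemorrhage, 3 surgery not considered) are appended, giving the 882
    enrolled records.
    """
    score3 = dict(gcs=8, temporal=True)  # 2 + 1 points
    score2 = dict(gcs=8, temporal=False)  # 2 points
    score0 = dict(gcs=13, temporal=False)  # 0 points
    blocks: list[tuple[int, dict, bool]] = [
        (152, score3, True),
        (12, score2, True),
        (237, score3, False),
        (235, score2, False),
        (235, score0, False),
    ]
    records: list[LabeledRecord] = []
    i = 0
    for count, kwargs, operative in blocks:
        for _ in range(count):
            i += 1
            records.append(
                LabeledRecord(
                    record_id=f"F{i:04d}",
                    presentation=_fixture_presentation(**kwargs),
                    operative=operative,
                )
            )
    if include_excluded:
        excl = [
            (6, ExclusionReason.CARE_WITHDRAWN),
            (2, ExclusionReason.POSTERIOR_FOSSA_HEMORRHAGE),
            (3, ExclusionReason.SURGERY_NOT_CONSIDERED),
        ]
        for count, reason in excl:
            for _ in range(count):
                i += 1
                records.append(
                    LabeledRecord(
                        record_id=f"F{i:04d}",
                        presentation=_fixture_presentation(gcs=8, temporal=False),
                        operative=None,
                        exclusion_reason=reason,
                    )
                )
    return LabeledCohort(
        records=records,
        provenance="deterministic fixture reproducing the published threshold-3 table"
        + (" plus the 11 enrollment exclusions" if include_excluded else ""),
    )


# -- flat key=value config serialization -------------------------------------

_GROUP_KEYS = ("nonoperative", "operative")


def spec_to_config(spec: CohortSpec) -> str:
    """Serialize a spec as a flat ``key=value`` config (one line per parameter)."""
    lines = [
        f"n_total={spec.n_total}",
        f"operative_fraction={spec.operative_fraction!r}",
        f"seed={spec.seed}",
    ]
    for group in _GROUP_KEYS:
        dist: GroupDistribution = getattr(spec, group)
        d = asdict(dist)
        shift = d.pop("shift_band_probs")
        mech = d.pop("mechanism_probs")
        for k, v in d.items():
            lines.append(f"{group}.{k}={v!r}")
        for label, v in zip(("p_shift_0_5", "p_shift_5_10", "p_shift_gt10"), shift):
            lines.append(f"{group}.{label}={v!r}")
        for name, v in zip(MECHANISMS, mech):
            lines.append(f"{group}.p_mech_{name}={v!r}")
    return "\n".join(lines) + "\n"


def spec_from_config(path: "str | Path") -> CohortSpec:
    """Parse a flat ``key=value`` config written by :func:`spec_to_config`.

    Unknown keys raise; omitted keys keep their defaults.
    """
    kv: dict[str, str] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ValidationError(f"{path}:{lineno}: expected key=value, got {raw!r}")
        k, v = line.split("=", 1)
        kv[k.strip()] = v.strip()

    def pop_float(key: str, default: float) -> float:
        return float(kv.pop(key)) if key in kv else default

    spec = CohortSpec(
        n_total=int(kv.pop("n_total", DEFAULT_N)),
        operative_fraction=pop_float("operative_fraction", DEFAULT_OPERATIVE_FRACTION),
        seed=int(kv.pop("seed", 0)),
    )
    groups = {}
    for group in _GROUP_KEYS:
        base: GroupDistribution = getattr(spec, group)
        shift = tuple(
            pop_float(f"{group}.{label}", base.shift_band_probs[i])
            for i, label in enumerate(("p_shift_0_5", "p_shift_5_10", "p_shift_gt10"))
        )
        mech = tuple(
            pop_float(f"{group}.p_mech_{name}", base.mechanism_probs[i])
            for i, name in enumerate(MECHANISMS)
        )
        scalars = {
            k: pop_float(f"{group}.{k}", getattr(base, k))
            for k in (
                "p_gcs_9_12",
                "p_unilateral_pupil",
                "p_temporal",
                "p_edh",
                "edh_wide_fraction",
                "p_intubated",
                "age_mean",
                "transport_mean",
            )
        }
        groups[group] = replace(base, shift_band_probs=shift, mechanism_probs=mech, **scalars)
    if kv:
        raise ValidationError(f"{path}: unknown config keys {sorted(kv)}")
    spec = replace(spec, nonoperative=groups["nonoperative"], operative=groups["operative"])
    spec.validate()
    return spec
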