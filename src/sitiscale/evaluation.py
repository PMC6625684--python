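"""Diagnostic evaluation of the scale against the operative label.

Implements the retrospective-evaluation toolbox: the confusion matrix of
score positivity versus surgery within 24 h, sensitivity / specificity /
PPV / NPV, the ROC curve swept over all integer score thresholds with its
trapezoidal AUC (equivalently the Mann-Whitney probability that a random
operative patient outscores a random nonoperative one, ties half-credited),
Welch t / Pearson chi-squared group comparisons, and logistic models of the
odds of surgery on subsets of the five score components.

Rounding of reported metrics is two decimals, half away from zero, applied
only at the reporting layer; raw ratios are always retained.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import LabeledCohort, apply_exclusions
from .errors import (
    ConsistencyError,
    EvaluationError,
    PerfectSeparationError,
    SingleClassError,
    ValidationError,
)
from .estimators import IRLSLogisticRegression
from .scale import DEFAULT_THRESHOLD, MAX_SCORE, score_frame

__all__ = [
    "ConfusionMatrix",
    "DiagnosticMetrics",
    "DiagnosticReport",
    "GroupComparison",
    "LogisticFit",
    "COMPONENTS",
    "round_half_away",
    "confusion_at_threshold",
    "diagnostic_metrics",
    "roc_curve",
    "auc_trapezoid",
    "rank_auc",
    "compare_groups",
    "fit_logistic",
    "reproduce_table3",
    "check_table3_consistency",
    "evaluate_cohort",
]

REPORT_SCHEMA_VERSION = "1.0"

#: Score components usable as logistic predictors, mapped to point columns.
COMPONENTS = {
    "gcs": "gcs_points",
    "pupils": "pupil_points",
    "shift": "shift_points",
    "temporal": "temporal_points",
    "edh": "edh_points",
}


def round_half_away(x: float, ndigits: int = 2) -> float:
    """Round to ``ndigits`` decimals with ties going away from zero."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionMatrix:
    """2x2 table of score positivity (rows) against the operative label."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v >= 0):
                raise ValidationError(f"{name} must be a nonnegative integer, got {v!r}")

    @property
    def n_operative(self) -> int:
        return self.tp + self.fn

    @property
    def n_nonoperative(self) -> int:
        return self.fp + self.tn

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class DiagnosticMetrics:
    """Sensitivity, specificity, PPV, NPV; ``None`` where a denominator is zero."""

    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    npv: float | None

    def rounded(self, ndigits: int = 2) -> dict[str, float | None]:
        return {
            k: (None if v is None else round_half_away(v, ndigits))
            for k, v in self.__dict__.items()
        }


@dataclass(frozen=True)
class GroupComparison:
    """Operative-vs-nonoperative comparison of one variable."""

    variable: str
    kind: str  # "t" or "chi2"
    group_summary: dict
    statistic: float | None
    p_value: float | None
    note: str = ""


@dataclass(frozen=True)
class LogisticFit:
    """A fitted (or separation-flagged) logistic model of the odds of surgery."""

    components: tuple[str, ...]
    converged: bool
    coefficients: dict[str, tuple[float, float]] | None  # name -> (estimate, SE)
    auc_of_fit: float | None
    n_used: int
    note: str = ""


@dataclass
class DiagnosticReport:
    """Everything the evaluation computes for one cohort at one threshold."""

    threshold: int
    cm: ConfusionMatrix
    metrics: DiagnosticMetrics
    roc_points: list[tuple[float, float]]
    auc: float
    n_missing_excluded: int
    exclusion_tally: dict[str, int]
    config: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "schema_version": REPORT_SCHEMA_VERSION,
            "threshold": self.threshold,
            "confusion": {
                "tp": self.cm.tp, "fp": self.cm.fp,
                "fn": self.cm.fn, "tn": self.cm.tn,
            },
            "metrics_raw": dict(self.metrics.__dict__),
            "metrics_rounded": self.metrics.rounded(),
            "roc_points": [[float(f), float(t)] for f, t in self.roc_points],
            "auc": float(self.auc),
            "n_missing_excluded": self.n_missing_excluded,
            "exclusion_tally": dict(self.exclusion_tally),
            "config": dict(self.config),
        }

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent)

    def to_text(self) -> str:
        m = self.metrics
        rounded = self.metrics.rounded()

        def fmt(name: str) -> str:
            raw = getattr(m, name)
            if raw is None:
                return f"{name:>12s}: undefined (zero denominator)"
            return f"{name:>12s}: {rounded[name]:.2f}  (raw {raw:.6f})"

        lines = [
            f"SITI diagnostic report (threshold >= {self.threshold})",
            f"  n assessed: {self.cm.n}   operative: {self.cm.n_operative}   "
            f"nonoperative: {self.cm.n_nonoperative}",
            f"  excluded by reason: {self.exclusion_tally} "
            f"(unlabeled dropped: {self.n_missing_excluded})",
            "  confusion matrix [score>=t vs operative]:",
            f"    TP={self.cm.tp}  FP={self.cm.fp}",
            f"    FN={self.cm.fn}  TN={self.cm.tn}",
            fmt("sensitivity"),
            fmt("specificity"),
            fmt("ppv"),
            fmt("npv"),
            f"{'AUC':>12s}: {self.auc:.4f}",
        ]
        return "\n".join(lines)


def _scores_and_labels(
    cohort: LabeledCohort, edh_strict_gt: bool = False
) -> tuple[np.ndarray, np.ndarray, int, dict[str, int]]:
    """Totals and boolean labels for the assessable records.

    Returns ``(scores, labels, n_unlabeled, exclusion_tally)``; excluded
    records are tallied per reason and unlabeled (missing ``operative``)
    records are counted and dropped listwise.
    """
    assessed, tally = apply_exclusions(cohort)
    labeled = [r for r in assessed.records if r.operative is not None]
    n_unlabeled = len(assessed) - len(labeled)
    if not labeled:
        return np.array([]), np.array([], dtype=bool), n_unlabeled, tally
    df = pd.DataFrame(
        {
            "gcs_total": [r.presentation.gcs_total for r in labeled],
            "pupils": [r.presentation.pupils for r in labeled],
            "midline_shift_mm": [r.presentation.ct.midline_shift_mm for r in labeled],
            "temporal_pathology": [r.presentation.ct.temporal_pathology for r in labeled],
            "edh_width_mm": [r.presentation.ct.edh_width_mm for r in labeled],
        }
    )
    scores = score_frame(df, edh_strict_gt=edh_strict_gt)["siti_total"].to_numpy()
    labels = np.array([r.operative for r in labeled], dtype=bool)
    return scores, labels, n_unlabeled, tally


def confusion_at_threshold(
    cohort: LabeledCohort,
    threshold: int = DEFAULT_THRESHOLD,
    edh_strict_gt: bool = False,
) -> ConfusionMatrix:
    """Confusion matrix of ``score >= threshold`` against the operative label.

    Records with an exclusion reason or an unresolved label are left out
    (use :func:`evaluate_cohort` to see the counts).
    """
    scores, labels, _, _ = _scores_and_labels(cohort, edh_strict_gt)
    if scores.size == 0:
        raise EvaluationError("no assessable labeled records in cohort")
    pos = scores >= int(threshold)
    return ConfusionMatrix(
        tp=int(np.sum(pos & labels)),
        fp=int(np.sum(pos & ~labels)),
        fn=int(np.sum(~pos & labels)),
        tn=int(np.sum(~pos & ~labels)),
    )


def diagnostic_metrics(cm: ConfusionMatrix) -> DiagnosticMetrics:
    """The four ratio identities; a zero denominator yields ``None``."""

    def ratio(num: int, den: int) -> float | None:
        return None if den == 0 else num / den

    return DiagnosticMetrics(
        sensitivity=ratio(cm.tp, cm.tp + cm.fn),
        specificity=ratio(cm.tn, cm.tn + cm.fp),
        ppv=ratio(cm.tp, cm.tp + cm.fp),
        npv=ratio(cm.tn, cm.tn + cm.fn),
    )


def roc_curve(
    cohort: LabeledCohort, edh_strict_gt: bool = False
) -> list[tuple[float, float]]:
    """ROC points ``(FPR(t), TPR(t))`` for integer thresholds t = 12 down to 0.

    Positivity is ``score >= t``, so t=12 yields (0, 0) (no total reaches 12)
    and t=0 yields (1, 1); both rates are nondecreasing along the list.
    """
    scores, labels, _, _ = _scores_and_labels(cohort, edh_strict_gt)
    if scores.size == 0:
        raise EvaluationError("no assessable labeled records in cohort")
    if labels.all() or (~labels).all():
        raise SingleClassError(
            "ROC requires at least one operative and one nonoperative record"
        )
    return _roc_points(scores, labels)


def _roc_points(scores: np.ndarray, labels: np.ndarray) -> list[tuple[float, float]]:
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    points = []
    for t in range(MAX_SCORE + 1, -1, -1):
        pos = scores >= t
        tpr = float(np.sum(pos & labels)) / n_pos
        fpr = float(np.sum(pos & ~labels)) / n_neg
        points.append((fpr, tpr))
    return points


def auc_trapezoid(roc_points: Sequence[tuple[float, float]]) -> float:
    """Trapezoidal area under an ROC point list ordered by increasing FPR.

    Equals the Mann-Whitney statistic P(score_op > score_nonop) +
    0.5 P(equal) on the cohort the points came from.
    """
    pts = list(roc_points)
    if len(pts) < 2:
        raise EvaluationError("need at least two ROC points")
    fpr = np.array([p[0] for p in pts])
    tpr = np.array([p[1] for p in pts])
    if np.any(np.diff(fpr) < 0) or np.any(np.diff(tpr) < 0):
        raise EvaluationError("ROC points must be nondecreasing in both coordinates")
    return float(np.trapezoid(tpr, fpr))


def rank_auc(values: np.ndarray, labels: np.ndarray) -> float:
    """Mann-Whitney AUC of continuous or discrete values via average ranks.

    Ties contribute half credit; identical to the trapezoidal area over the
    threshold-swept ROC of the same values.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n1 = int(labels.sum())
    n0 = labels.size - n1
    if n1 == 0 or n0 == 0:
        raise SingleClassError("AUC requires both classes present")
    ranks = stats.rankdata(values)
    return float((ranks[labels].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


_NUMERIC_VARIABLES = {
    "age_years": lambda r: r.age_years,
    "transport_minutes": lambda r: r.transport_minutes,
    "gcs_total": lambda r: r.presentation.gcs_total,
    "midline_shift_mm": lambda r: r.presentation.ct.midline_shift_mm,
    "edh_width_mm": lambda r: r.presentation.ct.edh_width_mm,
}
_CATEGORICAL_VARIABLES = {
    "intubated": lambda r: r.presentation.intubated,
    "temporal_pathology": lambda r: r.presentation.ct.temporal_pathology,
    "pupils": lambda r: r.presentation.pupils.value,
    "mechanism": lambda r: r.mechanism,
    "edh_present": lambda r: r.presentation.ct.edh_width_mm > 0,
}


def compare_groups(
    cohort: LabeledCohort,
    variable: str,
    kind: str | None = None,
    equal_var: bool = False,
) -> GroupComparison:
    """Compare a variable between operative and nonoperative patients.

    Numeric variables (including ``siti_total``) get a t-test — Welch by
    default, pooled-variance with ``equal_var=True``; categorical variables
    get a Pearson chi-squared test on the contingency table, without
    continuity correction.  A degenerate table (zero margin) is flagged in
    ``note`` with no p-value.
    """
    assessed, _ = apply_exclusions(cohort)
    labeled = [r for r in assessed.records if r.operative is not None]
    if not labeled:
        raise EvaluationError("no labeled records to compare")

    if variable == "siti_total":
        scores, labels, _, _ = _scores_and_labels(cohort)
        values: list = list(scores)
        is_numeric = True
        labs = list(labels)
    elif variable in _NUMERIC_VARIABLES:
        getter = _NUMERIC_VARIABLES[variable]
        pairs = [(getter(r), r.operative) for r in labeled if getter(r) is not None]
        if not pairs:
            raise EvaluationError(f"variable {variable!r} has no observed values")
        values, labs = [list(x) for x in zip(*pairs)]
        is_numeric = True
    elif variable in _CATEGORICAL_VARIABLES:
        getter = _CATEGORICAL_VARIABLES[variable]
        pairs = [(getter(r), r.operative) for r in labeled if getter(r) is not None]
        if not pairs:
            raise EvaluationError(f"variable {variable!r} has no observed values")
        values, labs = [list(x) for x in zip(*pairs)]
        is_numeric = False
    else:
        raise EvaluationError(f"unknown comparison variable {variable!r}")

    if kind is not None:
        is_numeric = kind == "t"

    v = np.asarray(values, dtype=float if is_numeric else object)
    g = np.asarray(labs, dtype=bool)
    if g.all() or (~g).all():
        raise SingleClassError("both groups must be nonempty")

    if is_numeric:
        op, nonop = v[g].astype(float), v[~g].astype(float)
        t_stat, p = stats.ttest_ind(op, nonop, equal_var=equal_var)
        return GroupComparison(
            variable=variable,
            kind="t",
            group_summary={
                "operative_mean": float(np.mean(op)),
                "nonoperative_mean": float(np.mean(nonop)),
                "operative_n": int(op.size),
                "nonoperative_n": int(nonop.size),
            },
            statistic=float(t_stat),
            p_value=float(p),
            note="welch" if not equal_var else "pooled",
        )

    table = pd.crosstab(pd.Series(list(v), name=variable), pd.Series(g, name="operative"))
    counts = table.to_numpy()
    if counts.shape[0] < 2 or counts.shape[1] < 2 or (counts.sum(axis=0) == 0).any() or (
        counts.sum(axis=1) == 0
    ).any():
        return GroupComparison(
            variable=variable,
            kind="chi2",
            group_summary={"table": table.to_dict()},
            statistic=None,
            p_value=None,
            note="degenerate contingency table (zero margin); no test performed",
        )
    chi2, p, _, _ = stats.chi2_contingency(counts, correction=False)
    return GroupComparison(
        variable=variable,
        kind="chi2",
        group_summary={"table": {str(k): dict(sv) for k, sv in table.to_dict().items()}},
        statistic=float(chi2),
        p_value=float(p),
        note="pearson, no continuity correction",
    )


def fit_logistic(
    cohort: LabeledCohort,
    components: Sequence[str] = ("gcs", "pupils", "shift", "temporal", "edh"),
    edh_strict_gt: bool = False,
) -> LogisticFit:
    """Logistic model of the odds of surgery on a subset of score components.

    Predictors are the component point values; an empty subset fits the
    intercept-only model.  IRLS maximum likelihood (tol 1e-8, max 100
    iterations); complete separation is reported as a flagged, coefficient-
    free fit rather than an exception.  ``auc_of_fit`` is the Mann-Whitney
    AUC of the fitted probabilities.
    """
    unknown = [c for c in components if c not in COMPONENTS]
    if unknown:
        raise ValidationError(f"unknown components {unknown}; choose from {sorted(COMPONENTS)}")
    assessed, _ = apply_exclusions(cohort)
    labeled = [r for r in assessed.records if r.operative is not None]
    if not labeled:
        raise EvaluationError("no labeled records to fit")
    df = pd.DataFrame(
        {
            "gcs_total": [r.presentation.gcs_total for r in labeled],
            "pupils": [r.presentation.pupils for r in labeled],
            "midline_shift_mm": [r.presentation.ct.midline_shift_mm for r in labeled],
            "temporal_pathology": [r.presentation.ct.temporal_pathology for r in labeled],
            "edh_width_mm": [r.presentation.ct.edh_width_mm for r in labeled],
        }
    )
    pts = score_frame(df, edh_strict_gt=edh_strict_gt)
    y = np.array([r.operative for r in labeled], dtype=int)
    if y.min() == y.max():
        raise SingleClassError("both outcome classes required for a logistic fit")
    cols = [COMPONENTS[c] for c in components]
    X = pts[cols].to_numpy(dtype=float) if cols else np.empty((len(y), 0))

    model = IRLSLogisticRegression()
    try:
        model.fit(X, y)
    except PerfectSeparationError as exc:
        return LogisticFit(
            components=tuple(components),
            converged=False,
            coefficients=None,
            auc_of_fit=None,
            n_used=len(y),
            note=str(exc),
        )
    names = ["intercept", *components]
    coefficients = {
        name: (float(est), float(se))
        for name, est, se in zip(names, model.params_, model.bse_)
    }
    probs = model.predict_proba(X)[:, 1]
    auc = rank_auc(probs, y.astype(bool)) if cols else None
    return LogisticFit(
        components=tuple(components),
        converged=bool(model.converged_),
        coefficients=coefficients if model.converged_ else None,
        auc_of_fit=auc if model.converged_ else None,
        n_used=len(y),
        note="" if model.converged_ else "IRLS did not converge in 100 iterations",
    )


def check_table3_consistency(cm: ConfusionMatrix, nonoperative_total: int) -> None:
    """Verify the nonoperative column of a reported 2x2 table sums to its total.

    Raises :class:`ConsistencyError` naming the violated identity.  Guards
    against transcription errors in published tables (a printed cell that
    cannot coexist with the printed group total).
    """
    if cm.fp + cm.tn != nonoperative_total:
        raise ConsistencyError(
            f"fp + tn = {cm.fp} + {cm.tn} = {cm.fp + cm.tn} != "
            f"nonoperative_total = {nonoperative_total}"
        )


def reproduce_table3(cm: ConfusionMatrix, nonoperative_total: int) -> dict:
    """Raw and 2-decimal-rounded sens/spec/PPV/NPV for a reported 2x2 table.

    The supplied ``nonoperative_total`` must equal ``fp + tn`` (checked), so
    internally inconsistent published counts are surfaced instead of being
    silently corrected.
    """
    check_table3_consistency(cm, nonoperative_total)
    m = diagnostic_metrics(cm)
    return {
        "confusion": {"tp": cm.tp, "fp": cm.fp, "fn": cm.fn, "tn": cm.tn},
        "metrics_raw": dict(m.__dict__),
        "metrics_rounded": m.rounded(),
    }


def evaluate_cohort(
    cohort: LabeledCohort,
    threshold: int = DEFAULT_THRESHOLD,
    edh_strict_gt: bool = False,
) -> DiagnosticReport:
    """Full diagnostic report: exclusions, confusion matrix, metrics, ROC, AUC."""
    scores, labels, n_unlabeled, tally = _scores_and_labels(cohort, edh_strict_gt)
    if scores.size == 0:
        raise EvaluationError("no assessable labeled records in cohort")
    if labels.all() or (~labels).all():
        raise SingleClassError(
            "evaluation requires at least one operative and one nonoperative record"
        )
    pos = scores >= int(threshold)
    cm = ConfusionMatrix(
        tp=int(np.sum(pos & labels)),
        fp=int(np.sum(pos & ~labels)),
        fn=int(np.sum(~pos & labels)),
        tn=int(np.sum(~pos & ~labels)),
    )
    roc = _roc_points(scores, labels)
    return DiagnosticReport(
        threshold=int(threshold),
        cm=cm,
        metrics=diagnostic_metrics(cm),
        roc_points=roc,
        auc=auc_trapezoid(roc),
        n_missing_excluded=n_unlabeled,
        exclusion_tally=tally,
        config={
            "edh_strict_gt": bool(edh_strict_gt),
            "tie_rule": "half-credit",
            "t_test": "welch",
            "chi_squared": "pearson-no-correction",
            "rounding": "2dp-half-away-from-zero",
        },
    )
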