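# Methods

## The scale and its conventions

The SITI scale is a deterministic additive rule over five admission
findings; there are no fitted parameters. The implementation fixes the
conventions a scale card leaves ambiguous:

- **Midline-shift band edges.** The bands are printed as "<5 mm",
  "5–10 mm", ">10 mm", which pins every edge except 10.0 mm. We take the
  2-point band as the closed interval [5.0, 10.0] so the three bands
  partition the nonnegative line and the strict inequalities "<5" and
  ">10" hold exactly as printed.
- **Epidural cutoff.** The prose rule is inclusive ("width ≥ 10 mm adds
  2 points") while the scale card prints ">10 mm". The inclusive rule is
  the default, the prose being the more specific statement; the card
  variant is available everywhere as `edh_strict_gt=True`.
- **Positivity threshold.** Positive means total ≥ 3. The alternative
  reading (> 3) is arithmetically incompatible with the published 2×2
  counts, and "a score of 3 or more" is the stated decision rule.
- **Bilateral abnormal pupils score 0** and are modeled as an explicit
  category rather than missing data: the evaluation cohort excluded
  bilaterally fixed-and-dilated patients, but the scale must remain total
  on real-world inputs. A unilateral unreactive-but-not-enlarged pupil is
  not a scale category and is recorded as `normal`.
- **Intubation.** An intubated patient's GCS total is computed upstream
  with the verbal component graded 1T (counted as 1); the `intubated`
  flag is metadata only and never alters points.
- **Input validation.** GCS outside [3, 15] and negative or implausible
  (≥ 50 mm) midline shifts are rejected, not clamped, to surface upstream
  data errors. Records with any missing component are undefined for
  scoring; the evaluation excludes them listwise and reports the count —
  there is no imputation.

`enumerate_all_scores()` exhaustively scores the 3×3×3×2×2 = 108 discrete
component patterns through the same single-patient code path, giving a
built-in oracle for the additive range 0–11 and for monotonicity checks.

## Diagnostic evaluation

The confusion matrix classifies `total ≥ threshold` against the operative
label (craniotomy/craniectomy within 24 h). Sensitivity, specificity, PPV
and NPV are the usual ratios, kept raw; reported values are additionally
rounded to two decimals, half away from zero, at the reporting layer only.
A zero denominator flags the metric as undefined rather than producing 0/0.

The ROC curve is swept over all integer thresholds t = 12…0 of the full
graded score (the only construction that yields a curve from an integer
score), with positivity `score ≥ t`, so it runs from (0,0) to (1,1). The
AUC is the trapezoidal area over FPR, which for this construction equals
the Mann–Whitney statistic P(S_op > S_nonop) + ½ P(equal); the test suite
verifies that identity against an O(n²) pairwise oracle on a thousand
random cohorts, to 1e-12. `rank_auc` computes the same statistic from
average ranks for continuous predictors (fitted probabilities).

Group comparisons use Welch's t-test by default (a pooled-variance option
exists) for means and the Pearson chi-squared test without continuity
correction for proportions; both variants are recorded in the report
configuration so fixtures are exact. Degenerate contingency tables (a zero
margin) are flagged with no p-value.

Logistic models of the odds of surgery on component subsets use the
component *point values* as predictors and are fitted by hand-written
iteratively reweighted least squares: convergence when the largest
absolute coefficient update drops below 1e-8, at most 100 sweeps, Wald
standard errors from the inverse Fisher information. Complete separation
(coefficients diverging while the linear predictor perfectly splits the
classes, detected as |η| > 15 with perfect classification at
non-convergence) yields a flagged fit with no coefficients reported.
statsmodels' MLE serves as an independent cross-check in the tests, never
as the implementation.

### A note on published-table consistency

The published 2×2 table prints 327 nonoperative patients at or above
threshold, but 327 + 470 does not equal the nonoperative group total 707,
and the printed PPV 0.39 is only consistent with FP = 707 − 470 = 237. The
package therefore treats (TP, FP, FN, TN) = (152, 237, 12, 470) as the
self-consistent matrix; `reproduce_table3` refuses inconsistent totals via
`check_table3_consistency` instead of silently correcting user data. With
that matrix the raw NPV is 470/482 = 0.97510…, which rounds to 0.98 at two
decimals although the source prints 0.97 — the raw ratio is the value the
package stands behind, and both raw and rounded figures appear in every
report.

## Synthetic cohorts

The generator emulates the evaluation study's assessed cohort: n = 871,
operative fraction 164/871, and per-group component marginals taken from
the published univariate table (nonoperative vs operative): unilateral
enlarged pupil 0.132 / 0.207, midline-shift bands (0.973, 0.027, 0) /
(0.372, 0.415, 0.213), temporal pathology 0.347 / 0.872, epidural
hematoma 0.079 / 0.298, intubation 0.239 / 0.250, plus group means for
age, transport time and the mechanism-of-injury mix.

Two quantities are not published directly and were fixed once, by
derivation, before any end-to-end testing:

- **GCS bin probabilities.** Only the group mean GCS (7.6 / 8.1) is
  published. Assuming uniform draws within the trial entry-range bins 4–8
  (mean 6) and 9–12 (mean 10.5), matching the group mean gives
  P(9–12) = 1.6/4.5 ≈ 0.356 (nonoperative) and 2.1/4.5 ≈ 0.467
  (operative).
- **Epidural width.** The published hematoma row does not state a width
  cutoff, so presence is generated at the published rate and the fraction
  of hematomas ≥ 10 mm wide is a separate parameter, `edh_wide_fraction`,
  defaulting to 1.0 (every generated hematoma scores its 2 points, widths
  uniform on 10–20 mm; sub-cutoff hematomas, when enabled, are uniform on
  3–10 mm).

Continuous magnitudes are uniform within their band (shift 0–5 / 5–10 /
10–15 mm; GCS uniform on the chosen bin). Under these defaults the
closed-form expected mean score is 2.46 in the nonoperative group and
5.10 in the operative group — in agreement with the published group means
2.5 and 5.1, which the calibration did not target directly.

**What the generator does not emulate:** components are drawn
independently within each label group, because only marginals are
published. Real injuries correlate mass-effect findings (shift, temporal
blood, hematoma volume), which concentrates high scores in operative
patients and raises discrimination. Accordingly the synthetic pipeline's
mean AUC over 200 seeds is about 0.86–0.88 — inside the documented
[0.80, 0.95] sanity corridor but not a reproduction of the published
0.8866, which would require individual-level data. Passing corridor tests
show the pipeline is calibrated and internally consistent, not that the
scale performs identically on real cohorts.

The deterministic fixture is different in kind: it *constructs* (never
samples) 871 records whose score/label combination reproduces the
published threshold-3 confusion matrix cell for cell — operative: 152 ×
score 3 (GCS 8 + temporal blood) and 12 × score 2; nonoperative: 237 ×
score 3, 235 × score 2, 235 × score 0 — and optionally appends the 11
enrolment exclusions (6 care withdrawn, 2 posterior fossa hemorrhage, 3
surgery not considered, the last label also covering "medically unfit")
to make the 882-record enrolled cohort.

All randomness flows through one `numpy.random.Generator` per cohort,
seeded from the spec; there is no global state, and identical specs
produce byte-identical cohorts.

## Problem sizes and numerical choices

Stochastic test suites use: 1000 random cohorts of n ≤ 20 for the
AUC/Mann–Whitney identity; 100 replicates of n = 5000 for logistic
coefficient recovery (each coefficient within 3 standard errors in ≥ 95 %
of replicates); 200 seeds of n = 871 for the AUC corridor; n = 50 000 for
marginal recovery within 3·√(p(1−p)/n). These sizes give comfortable
statistical resolution for every check while keeping the full suite fast.

IRLS weights are floored at 1e-10 to keep the working-response update
finite near fitted probabilities of 0 or 1. Hypothesis-based property
tests run derandomized so failures are reproducible.

## Known limitations

- The scale covers closed head injury only: no skull-fracture, penetrating
  injury or posterior-fossa scoring, and the positivity flag suggests a
  clinical response rather than dictating one.
- Confidence intervals for Se/Sp/AUC and calibration analyses are out of
  scope, as is any clinical-outcome modelling beyond the operative label.
- The synthetic generator supports only independent components within
  groups; the spec structure permits future correlation injection but none
  is defaulted.
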