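"""Scikit-learn style estimators: the SITI rule and an IRLS logistic model.

``SITIClassifier`` wraps the fixed scale so it composes with sklearn
pipelines and model selection; nothing is learned, so ``fit`` only validates
the input schema.  ``IRLSLogisticRegression`` is an unpenalized
maximum-likelihood logistic regression fitted by iteratively reweighted
least squares, with Wald standard errors from the inverse Fisher
information — the model used to relate the five score components to the
odds of surgery.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .errors import PerfectSeparationError, ValidationError
from .scale import CLINICAL_COLUMNS, DEFAULT_THRESHOLD, score_frame

__all__ = ["SITIClassifier", "IRLSLogisticRegression"]


class SITIClassifier(ClassifierMixin, BaseEstimator):
    """Rule-based classifier applying the SITI scale to a presentation table.

    Parameters
    ----------
    threshold : int, default 3
        Minimum total score classified as positive (surgery should be
        considered).
    edh_strict_gt : bool, default False
        Use the strict >10 mm epidural-hematoma cutoff instead of >=10 mm.

    Input ``X`` is a DataFrame carrying the five clinical columns
    ``gcs_total``, ``pupils``, ``midline_shift_mm``, ``temporal_pathology``
    and ``edh_width_mm``.  ``decision_function`` returns the integer total
    (0-11); ``transform`` returns the per-component point table.
    """

    def __init__(self, threshold: int = DEFAULT_THRESHOLD, edh_strict_gt: bool = False):
        self.threshold = threshold
        self.edh_strict_gt = edh_strict_gt

    def _validate_X(self, X: pd.DataFrame) -> pd.DataFrame:
        if not isinstance(X, pd.DataFrame):
            raise ValidationError(
                "X must be a pandas DataFrame with the clinical columns "
                f"{list(CLINICAL_COLUMNS)}"
            )
        return X

    def fit(self, X: pd.DataFrame, y=None) -> "SITIClassifier":
        """Validate the schema (the point rules are fixed, nothing is learned)."""
        if not 0 <= int(self.threshold) <= 12:
            raise ValidationError(f"threshold must be in [0, 12], got {self.threshold}")
        X = self._validate_X(X)
        score_frame(X, edh_strict_gt=self.edh_strict_gt)  # surfaces invalid values
        self.classes_ = np.array([0, 1])
        self.n_features_in_ = X.shape[1]
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        """Per-component points plus ``siti_total`` for each row of ``X``."""
        check_is_fitted(self)
        return score_frame(self._validate_X(X), edh_strict_gt=self.edh_strict_gt)

    # alias with the domain name
    score_components = transform

    def decision_function(self, X: pd.DataFrame) -> np.ndarray:
        """The SITI total (0-11) per row."""
        return self.transform(X)["siti_total"].to_numpy()

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """1 where the total reaches the positivity threshold, else 0."""
        return (self.decision_function(X) >= int(self.threshold)).astype(int)


class IRLSLogisticRegression(ClassifierMixin, BaseEstimator):
    """Maximum-likelihood logistic regression via iteratively reweighted least squares.

    Unpenalized, so coefficients and their Wald standard errors are directly
    interpretable as log odds ratios.  Iteration stops when the largest
    absolute coefficient update falls below ``tol`` (default 1e-8) or after
    ``max_iter`` (default 100) sweeps.  Complete separation — coefficients
    diverging while the linear predictor perfectly splits the classes —
    raises :class:`PerfectSeparationError` instead of reporting meaningless
    estimates.

    Attributes (after fit): ``coef_``, ``intercept_``, ``params_`` (intercept
    first when fitted), ``bse_`` (matching ``params_``), ``converged_``,
    ``n_iter_``, ``classes_``.
    """

    def __init__(self, fit_intercept: bool = True, tol: float = 1e-8, max_iter: int = 100):
        self.fit_intercept = fit_intercept
        self.tol = tol
        self.max_iter = max_iter

    def _design(self, X: np.ndarray) -> np.ndarray:
        if self.fit_intercept:
            return np.column_stack([np.ones(X.shape[0]), X])
        return X

    def fit(self, X, y) -> "IRLSLogisticRegression":
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        y = np.asarray(y)
        classes = np.unique(y)
        if classes.size != 2:
            raise ValidationError(f"y must be binary, found classes {classes!r}")
        self.classes_ = classes
        yb = (y == classes[1]).astype(float)

        D = self._design(X)
        n, p = D.shape
        if np.linalg.matrix_rank(D) < p:
            raise ValidationError("design matrix is rank deficient")

        beta = np.zeros(p)
        converged = False
        n_iter = 0
        for n_iter in range(1, self.max_iter + 1):
            eta = D @ beta
            mu = expit(eta)
            w = np.clip(mu * (1.0 - mu), 1e-10, None)
            z = eta + (yb - mu) / w
            Dw = D * w[:, None]
            beta_new = np.linalg.solve(D.T @ Dw, D.T @ (w * z))
            step = np.max(np.abs(beta_new - beta))
            beta = beta_new
            if step < self.tol:
                converged = True
                break

        eta = D @ beta
        mu = expit(eta)
        if not converged:
            # Diverging coefficients that already classify the data perfectly
            # are the signature of complete (or quasi-complete) separation.
            perfectly_split = np.all((mu > 0.5) == (yb > 0.5)) and np.max(np.abs(eta)) > 15
            if perfectly_split:
                raise PerfectSeparationError(
                    "complete separation detected: the linear predictor perfectly "
                    "splits the outcome classes and the MLE does not exist"
                )

        w = np.clip(mu * (1.0 - mu), 1e-10, None)
        cov = np.linalg.inv(D.T @ (D * w[:, None]))
        self.params_ = beta
        self.bse_ = np.sqrt(np.diag(cov))
        self.cov_params_ = cov
        if self.fit_intercept:
            self.intercept_ = beta[:1]
            self.coef_ = beta[None, 1:]
        else:
            self.intercept_ = np.zeros(1)
            self.coef_ = beta[None, :]
        self.converged_ = converged
        self.n_iter_ = n_iter
        self.n_features_in_ = X.shape[1]
        return self

    def decision_function(self, X) -> np.ndarray:
        check_is_fitted(self)
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        return self._design(X) @ self.params_

    def predict_proba(self, X) -> np.ndarray:
        p1 = expit(self.decision_function(X))
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X) -> np.ndarray:
        return self.classes_[(self.decision_function(X) > 0).astype(int)]
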