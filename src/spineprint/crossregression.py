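"""Brain-spine cross-regression and residual fingerprinting.

Because brain and spinal cord are imaged simultaneously, their time axes are
shared, and each target region's series can be modeled as a linear
combination of all predictor regions' series:

    Y = X . beta + eps      (per target region, over time samples)

Both sides are mean-centered over time (no explicit intercept), beta is the
minimum-norm least-squares solution, and the residuals eps — target activity
not linearly explained by the predictor structure — are carried forward to
build new FC profiles.  Fingerprinting those residual profiles shows how
much of a structure's identifiable signature survives once the other
structure's signal is regressed out.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

from .connectivity import RunTimeSeries, compute_fc, vectorize_upper
from .fingerprint import IdentifiabilityResult, fingerprint_analysis

__all__ = [
    "CrossRegressionFit",
    "CrossRegression",
    "fit_cross_regression",
    "residual_fingerprint",
]


@dataclass
class CrossRegressionFit:
    """Result of regressing target regions on predictor regions over time."""

    beta: np.ndarray  # (n_predictors, n_targets)
    residuals: np.ndarray  # (n_targets, T)
    fitted: np.ndarray  # (n_targets, T)
    r_squared: np.ndarray  # (n_targets,)
    direction: str = ""
    target: Optional[RunTimeSeries] = None

    def residual_series(self) -> RunTimeSeries:
        """Residuals re-wrapped as a RunTimeSeries on the target's scheme."""
        if self.target is None:
            raise ValueError("fit carries no target metadata")
        return RunTimeSeries(
            data=self.residuals,
            tr=self.target.tr,
            scheme=self.target.scheme,
            subject_id=self.target.subject_id,
            run_id=self.target.run_id,
        )


class CrossRegression(BaseEstimator, RegressorMixin):
    """Multi-output linear regression of target regions on predictor regions.

    sklearn conventions: ``fit(X, y)`` with X of shape (T, n_predictors) and
    y of shape (T, n_targets) — time samples are the observations.  Both are
    mean-centered internally; coefficients are the minimum-norm
    least-squares solution (optionally ridge-regularized).

    Parameters
    ----------
    ridge : float, default 0.0
        L2 penalty added when T is close to the number of predictors;
        0 keeps the plain pseudoinverse solution.

    Attributes
    ----------
    coef_ : ndarray of shape (n_targets, n_predictors)
    intercept_ : ndarray of shape (n_targets,)
    residuals_ : ndarray of shape (T, n_targets)
    r_squared_ : ndarray of shape (n_targets,)
    """

    def __init__(self, ridge: float = 0.0):
        self.ridge = ridge

    def fit(self, X, y):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        y = np.asarray(y, dtype=float)
        if y.ndim == 1:
            y = y[:, None]
        t, p = X.shape
        if y.shape[0] != t:
            raise ValueError(f"X has {t} time samples but y has {y.shape[0]}")
        if t <= p + 1 and self.ridge == 0.0:
            raise ValueError(
                f"T={t} time points cannot constrain {p} predictors; reduce "
                "predictor dimensionality (e.g. PCA) or set ridge > 0"
            )
        self._x_mean_ = X.mean(axis=0)
        self._y_mean_ = y.mean(axis=0)
        xc = X - self._x_mean_
        yc = y - self._y_mean_
        if self.ridge > 0:
            gram = xc.T @ xc + self.ridge * np.eye(p)
            beta = np.linalg.solve(gram, xc.T @ yc)
        else:
            beta, *_ = np.linalg.lstsq(xc, yc, rcond=None)
        self.coef_ = beta.T
        self.intercept_ = self._y_mean_ - self._x_mean_ @ beta
        fitted = xc @ beta + self._y_mean_
        resid = y - fitted
        self.residuals_ = resid
        ss_tot = np.sum(yc**2, axis=0)
        ss_res = np.sum((resid - resid.mean(axis=0)) ** 2, axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            r2 = np.where(ss_tot > 0, 1.0 - ss_res / ss_tot, 0.0)
        self.r_squared_ = np.clip(r2, 0.0, 1.0)
        return self

    def predict(self, X):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return (X - self._x_mean_) @ self.coef_.T + self._y_mean_


def fit_cross_regression(
    target: RunTimeSeries,
    predictors: RunTimeSeries,
    direction: str = "",
    ridge: float = 0.0,
) -> CrossRegressionFit:
    """Regress each target region's series on all predictor regions' series.

    ``target`` (Y) and ``predictors`` (X) are regions x T with a shared time
    axis.  Residuals have the target's shape (n_targets x T) and are exactly
    orthogonal to the centered predictor series.
    """
    if target.n_timepoints != predictors.n_timepoints:
        raise ValueError(
            f"target has T={target.n_timepoints} but predictors have "
            f"T={predictors.n_timepoints}; the time axis must be shared"
        )
    model = CrossRegression(ridge=ridge).fit(predictors.data.T, target.data.T)
    return CrossRegressionFit(
        beta=model.coef_.T,
        residuals=model.residuals_.T,
        fitted=(target.data - model.residuals_.T),
        r_squared=model.r_squared_,
        direction=direction,
        target=target,
    )


def residual_fingerprint(
    fits_run1: Sequence[CrossRegressionFit],
    fits_run2: Sequence[CrossRegressionFit],
    max_k: int = 5,
) -> IdentifiabilityResult:
    """Fingerprint the residual time series of paired per-subject fits.

    Each fit's residual matrix is turned into an FC profile (Pearson,
    vectorized upper triangle) and the two runs go through the standard
    identifiability pipeline.
    """
    if len(fits_run1) != len(fits_run2):
        raise ValueError("runs must have the same number of subjects")

    def fc_vectors(fits: Sequence[CrossRegressionFit]) -> np.ndarray:
        return np.vstack(
            [vectorize_upper(compute_fc(f.residual_series())).values for f in fits]
        )

    return fingerprint_analysis(
        fc_vectors(fits_run1), fc_vectors(fits_run2), max_k=max_k
    )
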