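"""Activity flow mapping: predicting task activations from rest FC.

FC weights to each target parcel are the multiple-regression
coefficients of its resting time series on all other parcels (plus an
intercept).  A target's task activation for condition i is then
predicted as the weight-sum of all *other* parcels' actual activations:

    yhat_{j,i} = sum_{n != j} beta_{j,n} x_{n,i}

(no intercept in the prediction step).  Prediction quality per region
is the mean absolute error across conditions (activity flow MAE); low
MAE means the region's activity is well explained as a distributed
process.

With T > n_parcels all target regressions share one covariance inverse
(the OLS weights to target j are -Theta_{jn} / Theta_{jj} for precision
matrix Theta), which avoids n_parcels separate least-squares solves.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.linear_model import RidgeCV

from .core import ParcelTimeSeries

__all__ = [
    "MultRegFC",
    "ActflowPrediction",
    "multreg_fc",
    "actflow_predict",
    "actflow_mae",
]

logger = logging.getLogger(__name__)


@dataclass
class MultRegFC:
    """Row j holds the regression weights from every source parcel to target j."""

    weights: np.ndarray     # (n_parcels, n_parcels), zero diagonal
    intercepts: np.ndarray  # (n_parcels,)
    ridge: bool = False     # True when the T <= n_parcels fallback was used

    @property
    def n_parcels(self) -> int:
        return self.weights.shape[0]


@dataclass
class ActflowPrediction:
    predicted: np.ndarray  # (n_parcels, n_conditions)
    actual: np.ndarray     # same shape


def multreg_fc(rest_ts: ParcelTimeSeries, allow_ridge: bool = False) -> MultRegFC:
    """Multiple-regression FC weights from resting-state time series.

    Requires more timepoints than parcels for OLS; with
    ``allow_ridge=True`` an under-determined problem falls back to
    per-target ridge regression with leave-one-out generalized
    cross-validation for the penalty (flagged on the result).
    """
    X = rest_ts.data
    T, P = X.shape
    Xc = X - X.mean(axis=0)
    means = X.mean(axis=0)
    if T > P:
        S = Xc.T @ Xc
        # shared-precision shortcut valid only for a well-conditioned
        # covariance; duplicated/collinear parcels fall back to
        # per-target least squares (still ordinary OLS)
        if np.linalg.cond(S) < 1e10:
            theta = np.linalg.inv(S)
            d = np.diag(theta)
            W = -theta / d[:, None]
            np.fill_diagonal(W, 0.0)
            intercepts = means - W @ means
            return MultRegFC(W, intercepts, ridge=False)
        logger.warning("collinear rest covariance; solving per-target least squares")
        W = np.zeros((P, P))
        intercepts = np.zeros(P)
        for j in range(P):
            sources = np.delete(np.arange(P), j)
            A = np.hstack([np.ones((T, 1)), X[:, sources]])
            beta, *_ = np.linalg.lstsq(A, X[:, j], rcond=None)
            W[j, sources] = beta[1:]
            intercepts[j] = beta[0]
        return MultRegFC(W, intercepts, ridge=False)
    if not allow_ridge:
        raise ValueError(
            f"multiple-regression FC needs more timepoints ({T}) than parcels ({P}); "
            "pass allow_ridge=True for the penalized fallback"
        )
    logger.warning("using ridge fallback for multiple-regression FC (T=%d, P=%d)", T, P)
    W = np.zeros((P, P))
    intercepts = np.zeros(P)
    alphas = np.logspace(-3, 3, 13)
    for j in range(P):
        sources = np.delete(np.arange(P), j)
        model = RidgeCV(alphas=alphas).fit(X[:, sources], X[:, j])
        W[j, sources] = model.coef_
        intercepts[j] = model.intercept_
    return MultRegFC(W, intercepts, ridge=True)


def actflow_predict(actual_activations: np.ndarray, fc: MultRegFC) -> ActflowPrediction:
    """Leave-target-out weighted sum of the other parcels' activations."""
    act = np.asarray(actual_activations, dtype=float)
    if act.ndim == 1:
        act = act[:, None]
    if act.shape[0] != fc.n_parcels:
        raise ValueError("activation matrix rows must match FC parcel count")
    if np.any(np.diag(fc.weights) != 0):
        raise ValueError("FC weight diagonal must be zero (no self-prediction)")
    return ActflowPrediction(fc.weights @ act, act)


def actflow_mae(pred: ActflowPrediction) -> np.ndarray:
    """Per-region mean over conditions of |predicted - actual|."""
    if pred.predicted.shape != pred.actual.shape:
        raise ValueError("predicted and actual shapes differ")
    if pred.predicted.shape[1] < 1:
        raise ValueError("need at least one condition")
    return np.abs(pred.predicted - pred.actual).mean(axis=1)
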