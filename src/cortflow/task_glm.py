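"""Task-evoked activation estimation and FIR removal of the mean evoked response.

Two distinct GLMs live here, used for different purposes downstream:

* a canonical-HRF GLM that yields one activation coefficient (beta) per
  parcel per task condition — the "localized processing" measure; and
* a finite-impulse-response (FIR) regression that removes the *mean*
  evoked response, shape-free, so that residual time series isolate
  background (spontaneous) covariation for task-state FC.

The canonical kernel is the SPM-style double gamma: peak delay 6 s,
undershoot delay 16 s, unit dispersions, peak:undershoot ratio 6,
rescaled to peak 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import linalg, special

from .core import ParcelTimeSeries, TaskDesign

__all__ = [
    "canonical_hrf",
    "build_condition_regressors",
    "fit_activation_glm",
    "group_activation_magnitude",
    "fir_regress",
    "build_fir_design",
    "ActivationResult",
    "ActivationMagnitudeMap",
]

logger = logging.getLogger(__name__)

HRF_PEAK_DELAY_S = 6.0
HRF_UNDERSHOOT_DELAY_S = 16.0
HRF_DISPERSION_S = 1.0
HRF_UNDERSHOOT_RATIO = 6.0
DEFAULT_FIR_POST_OFFSET_LAGS = 25


@dataclass
class ActivationResult:
    """Per-parcel, per-condition activation betas for one subject."""

    betas: np.ndarray  # (n_parcels, n_conditions)
    conditions: list[str]
    subject_id: str = ""


@dataclass
class ActivationMagnitudeMap:
    """Mean across conditions of |group t| per parcel; undefined-t parcels flagged."""

    values: np.ndarray  # (n_parcels,)
    flagged: np.ndarray  # boolean, parcels with undefined t in some condition


def canonical_hrf(tr_s: float, duration_s: float = 32.0) -> np.ndarray:
    """Double-gamma hemodynamic response sampled at ``tr_s``, peak scaled to 1.

    h(t) = g(t; 6, 1) - g(t; 16, 1) / 6 with gamma-density kernels; the
    value at t = 0 is exactly 0 and the mode sits near 5 s.
    """
    if tr_s <= 0:
        raise ValueError("tr_s must be positive")
    n = int(np.ceil(duration_s / tr_s))
    t = np.arange(n) * tr_s

    def gamma_pdf(x, shape, scale):
        with np.errstate(divide="ignore", invalid="ignore"):
            out = np.where(
                x > 0,
                np.exp(
                    (shape - 1) * np.log(np.maximum(x, 1e-300))
                    - x / scale
                    - special.gammaln(shape)
                    - shape * np.log(scale)
                ),
                0.0,
            )
        return out

    h = gamma_pdf(t, HRF_PEAK_DELAY_S / HRF_DISPERSION_S, HRF_DISPERSION_S)
    h = h - gamma_pdf(t, HRF_UNDERSHOOT_DELAY_S / HRF_DISPERSION_S, HRF_DISPERSION_S) / HRF_UNDERSHOOT_RATIO
    peak = np.max(np.abs(h))
    if peak > 0:
        h = h / peak
    return h


def build_condition_regressors(design: TaskDesign, hrf: np.ndarray) -> np.ndarray:
    """(T, n_conditions) matrix: per condition, TR boxcar convolved with ``hrf``.

    Condition columns follow ``design.conditions`` (sorted labels).
    """
    T = design.n_tr
    conditions = design.conditions
    regs = np.zeros((T, len(conditions)))
    for c, label in enumerate(conditions):
        boxcar = np.zeros(T)
        for start, end in design.block_intervals(label):
            boxcar[start:end] = 1.0
        regs[:, c] = np.convolve(boxcar, hrf)[:T]
    return regs


def _check_full_rank(X: np.ndarray, labels: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name likely-offending columns via pivoted QR
        _, _, piv = linalg.qr(X, mode="economic", pivoting=True)
        bad = sorted(labels[i] for i in piv[rank:])
        raise ValueError(f"design matrix is rank deficient; offending columns: {bad}")


def fit_activation_glm(
    ts: ParcelTimeSeries,
    condition_regs: np.ndarray,
    conditions: list[str] | None = None,
    nuisance: np.ndarray | None = None,
    subject_id: str = "",
) -> ActivationResult:
    """OLS betas of each parcel on [intercept | condition regressors | nuisance]."""
    condition_regs = np.asarray(condition_regs, dtype=float)
    if condition_regs.shape[0] != ts.n_timepoints:
        raise ValueError("condition regressors and time series row counts differ")
    n_cond = condition_regs.shape[1]
    if conditions is None:
        conditions = [f"cond{c:02d}" for c in range(n_cond)]
    blocks = [np.ones((ts.n_timepoints, 1)), condition_regs]
    labels = ["intercept"] + list(conditions)
    if nuisance is not None:
        nuisance = np.asarray(nuisance, dtype=float)
        if nuisance.shape[0] != ts.n_timepoints:
            raise ValueError("nuisance regressors and time series row counts differ")
        blocks.append(nuisance)
        labels += [f"nuisance{i:02d}" for i in range(nuisance.shape[1])]
    X = np.hstack(blocks)
    _check_full_rank(X, labels)
    beta, *_ = np.linalg.lstsq(X, ts.data, rcond=None)
    return ActivationResult(beta[1 : 1 + n_cond].T.copy(), list(conditions), subject_id)


def _one_sample_t(x: np.ndarray, axis: int = 0) -> np.ndarray:
    """t = mean / (sd / sqrt(n)); 0/0 -> 0, mean/0 -> +-inf."""
    n = x.shape[axis]
    mean = x.mean(axis=axis)
    sd = x.std(axis=axis, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
        t = np.where((sd == 0) & (mean == 0), 0.0, t)
        t = np.where((sd == 0) & (mean != 0), np.sign(mean) * np.inf, t)
    return t


def group_activation_magnitude(results: list[ActivationResult]) -> ActivationMagnitudeMap:
    """Mean over conditions of |one-sample t across subjects| per parcel."""
    if len(results) < 3:
        raise ValueError("need at least 3 subjects for a group t-statistic")
    conditions = results[0].conditions
    for r in results:
        if r.conditions != conditions:
            raise ValueError("subjects have inconsistent condition labels")
    stack = np.stack([r.betas for r in results])  # (S, P, C)
    t = _one_sample_t(stack, axis=0)  # (P, C)
    flagged = ~np.isfinite(t).all(axis=1)
    if flagged.any():
        logger.warning("group t undefined (zero variance) for %d parcels", int(flagged.sum()))
    values = np.abs(t).mean(axis=1)
    return ActivationMagnitudeMap(values, flagged)


def build_fir_design(design: TaskDesign, post_offset_lags: int = DEFAULT_FIR_POST_OFFSET_LAGS) -> np.ndarray:
    """FIR indicator matrix (T, sum of per-condition lag windows).

    For each condition the lag window runs from block onset through block
    offset plus ``post_offset_lags`` TRs, pooled over that condition's
    blocks (one indicator column per peri-onset lag).  All-zero and
    duplicate columns are dropped with a warning.
    """
    T = design.n_tr
    cols = []
    for label in design.conditions:
        intervals = design.block_intervals(label)
        if not intervals:
            continue
        n_lags = max(end - start for start, end in intervals) + post_offset_lags
        block = np.zeros((T, n_lags))
        for start, _ in intervals:
            for lag in range(n_lags):
                t = start + lag
                if t < T:
                    block[t, lag] = 1.0
        cols.append(block)
    X = np.hstack(cols)
    nonzero = X.any(axis=0)
    if not nonzero.all():
        logger.warning("dropping %d all-zero FIR columns", int((~nonzero).sum()))
        X = X[:, nonzero]
    # duplicate columns arise when adjacent blocks overlap lag windows exactly
    _, unique_idx = np.unique(X, axis=1, return_index=True)
    if unique_idx.size < X.shape[1]:
        logger.warning("dropping %d duplicate FIR columns", X.shape[1] - unique_idx.size)
        X = X[:, np.sort(unique_idx)]
    return X


def fir_regress(
    ts: ParcelTimeSeries,
    design: TaskDesign,
    post_offset_lags: int = DEFAULT_FIR_POST_OFFSET_LAGS,
    extra_regressors: np.ndarray | None = None,
) -> ParcelTimeSeries:
    """Residuals after OLS on [intercept | FIR indicators | extras].

    Removes the mean evoked response per condition without assuming a
    response shape, so the block-locked average of the residuals is ~0
    for every condition.  ``extra_regressors`` (e.g. the nuisance
    columns already regressed from the data) can be carried into the
    model so the residual stays jointly orthogonal to both sets —
    sequential regression alone leaves evoked variance re-introduced by
    the earlier fit.  Rank deficiency is resolved by the least-norm
    solution (residuals are unaffected by which solution is picked).
    """
    if ts.n_timepoints != design.n_tr:
        raise ValueError("time series length does not match design n_tr")
    F = build_fir_design(design, post_offset_lags)
    blocks = [np.ones((ts.n_timepoints, 1)), F]
    if extra_regressors is not None:
        extra = np.asarray(extra_regressors, dtype=float)
        if extra.shape[0] != ts.n_timepoints:
            raise ValueError("extra regressors and time series row counts differ")
        blocks.append(extra)
    X = np.hstack(blocks)
    beta, *_ = np.linalg.lstsq(X, ts.data, rcond=None)
    return ts.with_data(ts.data - X @ beta)
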