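"""Task- and rest-state correlation FC on matched temporal intervals.

Task-state FC is computed on FIR residuals restricted to in-block TRs.
The rest comparison applies the *same* FIR design and the *same* block
intervals to resting data, so task-vs-rest differences cannot be driven
by differences in sampling or regression.  The per-region summary is
weighted degree centrality (mean off-diagonal FC, also called global
brain connectivity, GBC), and the FC-change map is task minus rest —
so task-state FC reductions are negative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core import ParcelTimeSeries, TaskDesign
from .task_glm import fir_regress

__all__ = [
    "IntervalSet",
    "FCMatrix",
    "intervals_from_design",
    "correlation_fc",
    "matched_rest_fc",
    "weighted_degree",
    "fc_change_map",
]

logger = logging.getLogger(__name__)


@dataclass
class IntervalSet:
    """Non-overlapping half-open TR intervals [start, end) within a run."""

    intervals: list[tuple[int, int]]
    n_tr: int

    def __post_init__(self) -> None:
        iv = sorted(self.intervals)
        for (s0, e0), (s1, _) in zip(iv, iv[1:]):
            if s1 < e0:
                raise ValueError("intervals overlap")
        for s, e in iv:
            if s < 0 or e > self.n_tr or e <= s:
                raise ValueError(f"interval [{s}, {e}) outside run of {self.n_tr} TRs")
        if self.total_length() < 2:
            raise ValueError("intervals must cover more than one TR")
        self.intervals = iv

    def total_length(self) -> int:
        return sum(e - s for s, e in self.intervals)

    def indices(self) -> np.ndarray:
        return np.concatenate([np.arange(s, e) for s, e in self.intervals])


@dataclass
class FCMatrix:
    """Symmetric correlation FC with unit diagonal; zero-variance parcels flagged."""

    values: np.ndarray
    zero_variance: np.ndarray  # boolean (n_parcels,)

    @property
    def n_parcels(self) -> int:
        return self.values.shape[0]


def intervals_from_design(design: TaskDesign, n_tr: int) -> IntervalSet:
    """Union of all task-block TR intervals, one per block (not merged)."""
    intervals = design.block_intervals()
    if not intervals:
        raise ValueError("design has no blocks")
    if max(e for _, e in intervals) > n_tr:
        raise ValueError("design blocks extend beyond the run")
    return IntervalSet(intervals, n_tr)


def _safe_corrcoef(samples: np.ndarray) -> FCMatrix:
    """Pearson correlation over rows; zero-variance columns get 0 (flagged)."""
    sd = samples.std(axis=0)
    flags = sd == 0
    if flags.any():
        logger.warning("%d zero-variance parcels; their correlations set to 0", int(flags.sum()))
    centered = samples - samples.mean(axis=0)
    denom = np.where(flags, 1.0, sd * np.sqrt(samples.shape[0]))
    z = centered / denom
    fc = z.T @ z
    fc[flags, :] = 0.0
    fc[:, flags] = 0.0
    np.fill_diagonal(fc, 1.0)
    fc = np.clip(0.5 * (fc + fc.T), -1.0, 1.0)
    return FCMatrix(fc, flags)


def correlation_fc(ts: ParcelTimeSeries, intervals: IntervalSet) -> FCMatrix:
    """Pearson FC over the concatenated in-interval samples."""
    if intervals.n_tr > ts.n_timepoints:
        raise ValueError("interval set refers to a longer run than the time series")
    idx = intervals.indices()
    if idx.size < 3:
        raise ValueError("need at least 3 in-interval timepoints")
    return _safe_corrcoef(ts.data[idx])


def matched_rest_fc(
    rest_ts: ParcelTimeSeries,
    design: TaskDesign,
    extra_regressors: np.ndarray | None = None,
) -> FCMatrix:
    """Rest FC with task-matched regression and sampling.

    The task FIR design is regressed out of the resting run, and the
    correlation is then computed over exactly the task-block intervals,
    mirroring the task-state FC computation sample for sample.
    ``extra_regressors`` are forwarded to the FIR model (truncated to
    the design length), matching whatever the task-side regression used.
    """
    if rest_ts.n_timepoints < design.n_tr:
        raise ValueError(
            f"rest run ({rest_ts.n_timepoints} TRs) shorter than the task design "
            f"requires ({design.n_tr} TRs)"
        )
    rest = rest_ts
    if rest_ts.n_timepoints > design.n_tr:
        rest = rest_ts.with_data(rest_ts.data[: design.n_tr])
    if extra_regressors is not None:
        extra_regressors = np.asarray(extra_regressors, dtype=float)[: design.n_tr]
    residual = fir_regress(rest, design, extra_regressors=extra_regressors)
    return correlation_fc(residual, intervals_from_design(design, design.n_tr))


def weighted_degree(fc: FCMatrix | np.ndarray, positive_only: bool = False) -> np.ndarray:
    """Per-parcel mean of off-diagonal FC (GBC).

    With ``positive_only``, negative entries are zeroed before averaging
    (the denominator stays n_parcels - 1).
    """
    values = fc.values if isinstance(fc, FCMatrix) else np.asarray(fc, dtype=float)
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise ValueError("FC matrix must be square")
    if not np.allclose(values, values.T, atol=1e-10):
        raise ValueError("FC matrix must be symmetric")
    off = values.copy()
    np.fill_diagonal(off, 0.0)
    if positive_only:
        off = np.where(off > 0, off, 0.0)
    return off.sum(axis=1) / (values.shape[0] - 1)


def fc_change_map(
    task_fc: FCMatrix | np.ndarray,
    rest_fc: FCMatrix | np.ndarray,
    positive_only: bool = False,
) -> np.ndarray:
    """Delta GBC per parcel, task minus rest (reductions are negative)."""
    task_wd = weighted_degree(task_fc, positive_only)
    rest_wd = weighted_degree(rest_fc, positive_only)
    if task_wd.shape != rest_wd.shape:
        raise ValueError("task and rest FC matrices have different sizes")
    return task_wd - rest_wd
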