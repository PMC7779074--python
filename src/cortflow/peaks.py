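"""Regression-free block-peak estimates of task activation and FC.

Instead of GLM/FIR modeling, each task block contributes one number per
parcel: the in-block sample of largest absolute value after baselining
the run to its mean inter-block rest level.  Averaging peaks across
blocks gives an activation map; correlating peaks across blocks between
parcels gives a block-to-block FC matrix (beta-series-like, but using
the raw peak rather than a fitted coefficient).  Resting data is pushed
through the identical machinery using the task design's "pseudo-blocks"
so task-vs-rest comparisons are sample-matched.

This module deliberately has no dependency on the GLM/FIR machinery:
no task regression happens anywhere on this path.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .connectivity import FCMatrix, _safe_corrcoef
from .core import ParcelTimeSeries, TaskDesign

__all__ = [
    "BlockPeaks",
    "baseline_to_interblock_rest",
    "extract_block_peaks",
    "peak_activation_map",
    "peak_fc",
    "pseudo_block_rest_peak_fc",
]


@dataclass
class BlockPeaks:
    """Signed in-block extrema: (n_blocks, n_parcels) plus block condition labels."""

    peaks: np.ndarray
    block_condition: list[str]

    @property
    def n_blocks(self) -> int:
        return self.peaks.shape[0]


def baseline_to_interblock_rest(ts: ParcelTimeSeries, design: TaskDesign) -> ParcelTimeSeries:
    """Subtract each parcel's mean over all TRs outside every task block."""
    if ts.n_timepoints != design.n_tr:
        raise ValueError("time series length does not match design n_tr")
    rest_mask = ~design.in_block_mask()
    if not rest_mask.any():
        raise ValueError("design leaves no inter-block rest TRs to baseline against")
    return ts.with_data(ts.data - ts.data[rest_mask].mean(axis=0))


def extract_block_peaks(baselined_ts: ParcelTimeSeries, design: TaskDesign, signed: bool = True) -> BlockPeaks:
    """Per block and parcel, the element of maximal |value| within the block.

    The value is kept with its sign by default (``signed=False`` returns
    magnitudes only); ties go to the earliest TR.
    """
    if baselined_ts.n_timepoints != design.n_tr:
        raise ValueError("time series length does not match design n_tr")
    intervals = design.block_intervals()
    labels = list(design.events["trial_type"])
    peaks = np.empty((len(intervals), baselined_ts.n_parcels))
    for b, (start, end) in enumerate(intervals):
        if end <= start:
            raise ValueError(f"block {b} contains no TRs")
        seg = baselined_ts.data[start:end]
        idx = np.abs(seg).argmax(axis=0)  # argmax takes the first maximum on ties
        vals = seg[idx, np.arange(seg.shape[1])]
        peaks[b] = vals if signed else np.abs(vals)
    return BlockPeaks(peaks, labels)


def peak_activation_map(peaks: BlockPeaks) -> np.ndarray:
    """Per parcel, mean of peak values across all blocks."""
    if peaks.n_blocks < 1:
        raise ValueError("need at least one block")
    return peaks.peaks.mean(axis=0)


def peak_fc(peaks: BlockPeaks) -> FCMatrix:
    """Pearson correlation across blocks between parcel peak vectors."""
    if peaks.n_blocks < 3:
        raise ValueError("need at least 3 blocks to correlate peaks")
    return _safe_corrcoef(peaks.peaks)


def pseudo_block_rest_peak_fc(
    rest_ts: ParcelTimeSeries, design: TaskDesign, signed: bool = True
) -> FCMatrix:
    """Block-peak FC of resting data over the task design's pseudo-blocks."""
    if rest_ts.n_timepoints < design.n_tr:
        raise ValueError("rest run does not cover the task design")
    rest = rest_ts
    if rest_ts.n_timepoints > design.n_tr:
        rest = rest_ts.with_data(rest_ts.data[: design.n_tr])
    baselined = baseline_to_interblock_rest(rest, design)
    return peak_fc(extract_block_peaks(baselined, design, signed=signed))
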