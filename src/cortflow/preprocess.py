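"""Nuisance regression for parcellated BOLD time series.

The nuisance model: 6 motion parameters, their backward-difference
derivatives, and the elementwise squares of those 12 (24 motion
regressors); 5 aCompCor components each from white-matter and ventricle
compartment signals, their derivatives, and the squares of those 20
(40 physiological regressors); 64 regressors in total.  Global signal
regression is deliberately absent: the mean-across-parcels signal is
never constructed as a regressor anywhere in this module.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sp_signal

from .core import ParcelTimeSeries

__all__ = [
    "NuisanceDesign",
    "trim_demean_detrend",
    "build_motion_regressors",
    "acompcor",
    "assemble_nuisance",
    "nuisance_regress",
]

N_MOTION_PARAMS = 6
N_ACOMPCOR_COMPONENTS = 5
DEFAULT_N_DROP_FRAMES = 5


@dataclass
class NuisanceDesign:
    columns: np.ndarray  # (T, n_regressors)
    labels: list[str]

    def __post_init__(self) -> None:
        if self.columns.shape[1] != len(self.labels):
            raise ValueError("label count does not match column count")
        if not np.all(np.isfinite(self.columns)):
            raise ValueError("nuisance design contains non-finite values")

    @property
    def n_regressors(self) -> int:
        return self.columns.shape[1]


def trim_demean_detrend(ts: ParcelTimeSeries, n_drop: int = DEFAULT_N_DROP_FRAMES) -> ParcelTimeSeries:
    """Drop the first ``n_drop`` frames, then remove per-parcel mean and linear trend."""
    if ts.n_timepoints <= n_drop + 2:
        raise ValueError(f"series of {ts.n_timepoints} frames too short to drop {n_drop}")
    data = sp_signal.detrend(ts.data[n_drop:], axis=0, type="linear")
    return ts.with_data(data)


def _backward_diff(x: np.ndarray) -> np.ndarray:
    """Backward difference along time, first row zero."""
    d = np.zeros_like(x)
    d[1:] = np.diff(x, axis=0)
    return d


def build_motion_regressors(motion: np.ndarray) -> np.ndarray:
    """[6 params | 6 derivatives | squares of those 12] -> (T, 24)."""
    motion = np.asarray(motion, dtype=float)
    if motion.ndim != 2 or motion.shape[1] != N_MOTION_PARAMS:
        raise ValueError(f"expected exactly {N_MOTION_PARAMS} motion columns")
    expanded = np.hstack([motion, _backward_diff(motion)])
    return np.hstack([expanded, expanded**2])


def acompcor(compartment_ts: np.ndarray, n_components: int = N_ACOMPCOR_COMPONENTS) -> np.ndarray:
    """Top principal-component time series of a compartment signal matrix.

    Columns are demeaned; components are unit-norm left singular
    vectors ordered by explained variance, with the sign fixed so the
    first nonzero loading of each component is positive.
    """
    X = np.asarray(compartment_ts, dtype=float)
    if X.ndim != 2:
        raise ValueError("compartment matrix must be 2-D")
    if X.shape[1] < n_components:
        raise ValueError(
            f"need at least {n_components} compartment signals, got {X.shape[1]}"
        )
    X = X - X.mean(axis=0)
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    comps = U[:, :n_components].copy()
    for k in range(n_components):
        loadings = Vt[k]
        nz = np.flatnonzero(np.abs(loadings) > 1e-12)
        if nz.size and loadings[nz[0]] < 0:
            comps[:, k] = -comps[:, k]
    return comps


def assemble_nuisance(
    motion24: np.ndarray, wm_components: np.ndarray, vent_components: np.ndarray
) -> NuisanceDesign:
    """Combine motion and physiological blocks into the 64-column design.

    Physiological block: [10 components | 10 derivatives | squares of
    those 20] = 40 columns; total 24 + 40 = 64.
    """
    motion24 = np.asarray(motion24, dtype=float)
    wm = np.asarray(wm_components, dtype=float)
    vent = np.asarray(vent_components, dtype=float)
    if motion24.shape[1] != 24:
        raise ValueError("motion block must have 24 columns")
    if wm.shape[1] != N_ACOMPCOR_COMPONENTS or vent.shape[1] != N_ACOMPCOR_COMPONENTS:
        raise ValueError(f"each compartment must contribute {N_ACOMPCOR_COMPONENTS} components")
    if not (motion24.shape[0] == wm.shape[0] == vent.shape[0]):
        raise ValueError("regressor blocks have mismatched row counts")
    phys = np.hstack([wm, vent])
    phys_expanded = np.hstack([phys, _backward_diff(phys)])
    phys_block = np.hstack([phys_expanded, phys_expanded**2])
    labels = (
        [f"motion{i:02d}" for i in range(6)]
        + [f"motion_deriv{i:02d}" for i in range(6)]
        + [f"motion_sq{i:02d}" for i in range(12)]
        + [f"wm_comp{i}" for i in range(5)]
        + [f"vent_comp{i}" for i in range(5)]
        + [f"phys_deriv{i:02d}" for i in range(10)]
        + [f"phys_sq{i:02d}" for i in range(20)]
    )
    return NuisanceDesign(np.hstack([motion24, phys_block]), labels)


def nuisance_regress(ts: ParcelTimeSeries, design: NuisanceDesign) -> ParcelTimeSeries:
    """OLS residuals of each parcel on [intercept | nuisance columns].

    Rank deficiency is resolved by the least-norm solution; residuals
    are unique either way and orthogonal to every design column.
    """
    if design.columns.shape[0] != ts.n_timepoints:
        raise ValueError("design and time series row counts differ")
    X = np.hstack([np.ones((ts.n_timepoints, 1)), design.columns])
    beta, *_ = np.linalg.lstsq(X, ts.data, rcond=None)
    return ts.with_data(ts.data - X @ beta)
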