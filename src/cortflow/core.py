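"""Shared containers and delimited-text I/O for parcellated fMRI analyses.

All analyses in this package operate on *parcellated* BOLD data: a real
matrix of shape (n_timepoints, n_parcels) together with its sampling
interval (TR, seconds).  Task timing is carried as a BIDS-style events
table (onset, duration, trial_type in seconds) plus the run geometry
needed to rasterize blocks onto the TR grid.

Rounding convention for mapping block times onto TRs: onsets are floored
to the TR grid and offsets are ceiled, so a block always covers every TR
it touches.  Intervals are half-open ``[start, end)`` in TR indices.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ParcelTimeSeries",
    "TaskDesign",
    "read_map_tsv",
    "write_map_tsv",
    "read_matrix_tsv",
    "write_matrix_tsv",
]

_GRID_EPS = 1e-9  # guard against float jitter when snapping seconds to TRs


def _as_2d_float(data: np.ndarray, name: str) -> np.ndarray:
    arr = np.asarray(data, dtype=float)
    if arr.ndim != 2:
        raise ValueError(f"{name} must be 2-D (timepoints x parcels), got ndim={arr.ndim}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


@dataclass
class ParcelTimeSeries:
    """A (n_timepoints, n_parcels) BOLD matrix with its TR in seconds."""

    data: np.ndarray
    tr_s: float
    parcel_ids: list[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.data = _as_2d_float(self.data, "data")
        if self.tr_s <= 0:
            raise ValueError(f"tr_s must be positive, got {self.tr_s}")
        if self.parcel_ids is None:
            self.parcel_ids = [f"parcel{i:04d}" for i in range(self.data.shape[1])]
        elif len(self.parcel_ids) != self.data.shape[1]:
            raise ValueError("parcel_ids length does not match number of parcels")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_parcels(self) -> int:
        return self.data.shape[1]

    def with_data(self, data: np.ndarray) -> "ParcelTimeSeries":
        """Copy carrying the same TR/ids but new sample values."""
        return ParcelTimeSeries(data, self.tr_s, list(self.parcel_ids))

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.data, columns=self.parcel_ids).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, tr_s: float) -> "ParcelTimeSeries":
        df = pd.read_csv(path, sep="\t")
        return cls(df.to_numpy(dtype=float), tr_s, [str(c) for c in df.columns])


@dataclass
class TaskDesign:
    """Block task timing: BIDS-style events plus run geometry.

    ``events`` columns: onset (s), duration (s), trial_type (condition
    label).  ``n_tr`` is the run length the design is defined against.
    """

    events: pd.DataFrame
    tr_s: float
    n_tr: int

    def __post_init__(self) -> None:
        required = {"onset", "duration", "trial_type"}
        if not required.issubset(self.events.columns):
            raise ValueError(f"events table must have columns {sorted(required)}")
        if self.tr_s <= 0:
            raise ValueError("tr_s must be positive")
        ev = self.events.sort_values("onset", kind="stable").reset_index(drop=True)
        if len(ev) == 0:
            raise ValueError("design has no blocks")
        if (ev["duration"] <= 0).any():
            raise ValueError("all block durations must be positive")
        if (ev["onset"] < 0).any():
            raise ValueError("block onsets must be non-negative")
        ends = ev["onset"].to_numpy() + ev["duration"].to_numpy()
        if np.any(ev["onset"].to_numpy()[1:] < ends[:-1] - _GRID_EPS):
            raise ValueError("task blocks overlap in time")
        if self.n_tr <= 0:
            raise ValueError("n_tr must be positive")
        if ends[-1] > self.n_tr * self.tr_s + _GRID_EPS:
            raise ValueError(
                f"design extends to {ends[-1]:.3f}s beyond run of "
                f"{self.n_tr} TRs x {self.tr_s}s"
            )
        self.events = ev

    @property
    def n_blocks(self) -> int:
        return len(self.events)

    @property
    def conditions(self) -> list[str]:
        """Condition labels in the canonical (sorted) order."""
        return sorted(self.events["trial_type"].unique())

    def block_intervals(self, condition: str | None = None) -> list[tuple[int, int]]:
        """Half-open TR intervals [start, end), onset floored, offset ceiled."""
        ev = self.events
        if condition is not None:
            if condition not in set(ev["trial_type"]):
                raise ValueError(f"unknown condition label: {condition!r}")
            ev = ev[ev["trial_type"] == condition]
        out = []
        for onset, dur in zip(ev["onset"], ev["duration"]):
            start = int(np.floor(onset / self.tr_s + _GRID_EPS))
            end = int(np.ceil((onset + dur) / self.tr_s - _GRID_EPS))
            end = min(end, self.n_tr)
            if end > start:
                out.append((start, end))
        return out

    def in_block_mask(self) -> np.ndarray:
        """Boolean (n_tr,) mask, True inside any task block."""
        mask = np.zeros(self.n_tr, dtype=bool)
        for start, end in self.block_intervals():
            mask[start:end] = True
        return mask

    def shifted(self, n_tr_drop: int) -> "TaskDesign":
        """Design re-referenced after dropping the first ``n_tr_drop`` frames.

        Blocks that would start before the new origin are invalid (block
        designs here always begin with a rest period longer than the trim).
        """
        shift_s = n_tr_drop * self.tr_s
        ev = self.events.copy()
        ev["onset"] = ev["onset"] - shift_s
        if (ev["onset"] < -_GRID_EPS).any():
            raise ValueError("cannot trim frames that overlap a task block")
        return TaskDesign(ev, self.tr_s, self.n_tr - n_tr_drop)

    def to_tsv(self, path) -> None:
        self.events[["onset", "duration", "trial_type"]].to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, tr_s: float, n_tr: int) -> "TaskDesign":
        return cls(pd.read_csv(path, sep="\t"), tr_s, n_tr)


# ---------------------------------------------------------------------------
# Map / matrix TSV helpers (two-column maps; square matrices with header)
# ---------------------------------------------------------------------------

def write_map_tsv(path, values: np.ndarray, parcel_ids: list[str] | None = None) -> None:
    values = np.asarray(values, dtype=float).ravel()
    if parcel_ids is None:
        parcel_ids = [f"parcel{i:04d}" for i in range(values.size)]
    pd.DataFrame({"parcel_id": parcel_ids, "value": values}).to_csv(path, sep="\t", index=False)


def read_map_tsv(path) -> np.ndarray:
    return pd.read_csv(path, sep="\t")["value"].to_numpy(dtype=float)


def write_matrix_tsv(path, matrix: np.ndarray, labels: list[str] | None = None) -> None:
    matrix = np.asarray(matrix, dtype=float)
    if labels is None:
        labels = [f"parcel{i:04d}" for i in range(matrix.shape[1])]
    pd.DataFrame(matrix, columns=labels).to_csv(path, sep="\t", index=False)


def read_matrix_tsv(path) -> np.ndarray:
    return pd.read_csv(path, sep="\t").to_numpy(dtype=float)


def dataclass_to_dict(obj) -> dict:
    """JSON-friendly dict of a dataclass, ndarrays converted to lists."""
    out = {}
    for f in dataclasses.fields(obj):
        v = getattr(obj, f.name)
        if isinstance(v, np.ndarray):
            v = v.tolist()
        out[f.name] = v
    return out
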