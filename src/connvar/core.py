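"""Shared containers: vertex time series, metric maps, processing states.

A session's BOLD data is a V x T matrix (vertices by time points) tagged with
the preprocessing state it has reached.  Metrics declare which state they
require and refuse anything else, which keeps e.g. smoothed data out of the
ReHo computation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

# Processing states, in the order the pipeline produces them.  "cleaned" means
# volumes discarded, spikes interpolated, global mean scaled and nuisance
# signals regressed out.  Smoothing and band-passing branch off "cleaned".
STATE_RAW = "raw"
STATE_CLEANED = "cleaned"
STATE_BANDPASSED = "cleaned+bandpassed"
STATE_ZNORMALIZED = "cleaned+bandpassed+znormalized"
STATE_SMOOTHED = "cleaned+smoothed"

_VALID_STATES = (
    STATE_RAW,
    STATE_CLEANED,
    STATE_BANDPASSED,
    STATE_ZNORMALIZED,
    STATE_SMOOTHED,
)


class ProcessingStateError(RuntimeError):
    """Raised when an operation receives data in the wrong processing state."""


def require_state(ts: "SessionTimeSeries", *allowed: str) -> None:
    if ts.state not in allowed:
        raise ProcessingStateError(
            f"operation requires state in {allowed}, got {ts.state!r} "
            f"(subject={ts.subject_id}, session={ts.session_id})"
        )


@dataclass
class SessionTimeSeries:
    """V x T vertex time series for one subject-session.

    ``motion`` (T x 6 rigid-body parameters), ``wm`` and ``csf`` (length-T mean
    nuisance series) travel with the session so the nuisance design can be
    assembled downstream; they are optional for externally supplied data.
    """

    data: np.ndarray                # V x T, float64
    dt: float                       # sampling interval, seconds
    subject_id: str
    session_id: str
    state: str = STATE_RAW
    motion: Optional[np.ndarray] = None   # T x 6 (mm, radians)
    wm: Optional[np.ndarray] = None       # length T
    csf: Optional[np.ndarray] = None      # length T

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("data must be a V x T matrix")
        if self.state not in _VALID_STATES:
            raise ValueError(f"unknown processing state {self.state!r}")
        if self.dt <= 0:
            raise ValueError("sampling interval must be positive")

    @property
    def n_vertices(self) -> int:
        return self.data.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[1]

    def with_data(self, data: np.ndarray, state: Optional[str] = None,
                  **extra) -> "SessionTimeSeries":
        """Copy of this session with new data (and optionally a new state)."""
        kwargs = dict(data=data)
        if state is not None:
            kwargs["state"] = state
        kwargs.update(extra)
        return replace(self, **kwargs)


# Canonical metric names.  DR maps are one per template network.
METRIC_NAMES = ("ALFF", "fALFF", "ReHo1", "ReHo2", "SFC", "DR", "DCw", "ECw")


@dataclass
class MetricMap:
    """Per-vertex scalar field for one metric of one subject-session."""

    values: np.ndarray              # length V
    metric: str
    subject_id: str
    session_id: str
    mask: Optional[np.ndarray] = None   # True where the value is undefined
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64).ravel()
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool).ravel()
            if self.mask.shape != self.values.shape:
                raise ValueError("mask must match values in length")

    @property
    def n_vertices(self) -> int:
        return self.values.size

    def valid_values(self) -> np.ndarray:
        if self.mask is None:
            return self.values
        return self.values[~self.mask]
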