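"""Local-scale metrics: spectral amplitude (ALFF/fALFF) and surface ReHo.

ALFF is the summed Fourier amplitude of a vertex series over the
low-frequency band Omega = [0.01, 0.1] Hz, divided by T/2; fALFF is its
fraction of the amplitude summed over the whole detectable range
Omega_0 = (0, 1/(2*dt)].  Regional homogeneity (ReHo) is Kendall's
coefficient of concordance W of a vertex's band-passed series with its
one-ring (ReHo1) or two-ring (ReHo2) mesh neighbors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Tuple

import numpy as np
from scipy.stats import rankdata

from .core import (
    STATE_BANDPASSED,
    STATE_SMOOTHED,
    MetricMap,
    SessionTimeSeries,
    require_state,
)
from .mesh import SurfaceMesh, neighborhood_indicator

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Fourier decomposition
# ---------------------------------------------------------------------------

@dataclass
class SpectralDecomposition:
    """Cosine/sine coefficients of a real series at Fourier frequencies.

    Index l runs 1..T/2; frequency of index l is l / (T * dt) Hz.  The
    mean-removed series is reconstructed exactly from the coefficients.
    """

    alpha: np.ndarray
    beta: np.ndarray
    freqs_hz: np.ndarray
    dt: float

    @property
    def amplitudes(self) -> np.ndarray:
        return np.sqrt(self.alpha ** 2 + self.beta ** 2)


def spectral_decomposition(series: np.ndarray, dt: float
                           ) -> SpectralDecomposition:
    """Decompose a real series into sinusoids at the Fourier frequencies.

    Odd-length series lose their last sample (logged once per process).
    """
    x = np.asarray(series, dtype=np.float64).ravel()
    if x.size % 2 == 1:
        logger.info("odd series length %d: dropping last sample for the "
                    "spectral decomposition", x.size)
        x = x[:-1]
    T = x.size
    if T < 4:
        raise ValueError("series too short for spectral decomposition")
    spec = np.fft.rfft(x)
    # l = 1..T/2 ; the Nyquist bin has no sine component and half weight
    alpha = 2.0 * spec.real[1:] / T
    beta = -2.0 * spec.imag[1:] / T
    alpha[-1] = spec.real[-1] / T
    beta[-1] = 0.0
    freqs = np.arange(1, T // 2 + 1) / (T * dt)
    return SpectralDecomposition(alpha=alpha, beta=beta, freqs_hz=freqs, dt=dt)


def _amplitude_matrix(data: np.ndarray, dt: float
                      ) -> Tuple[np.ndarray, np.ndarray]:
    """Fourier amplitudes for every vertex at once; returns (amps V x T/2, freqs)."""
    X = np.asarray(data, dtype=np.float64)
    if X.shape[1] % 2 == 1:
        X = X[:, :-1]
    T = X.shape[1]
    spec = np.fft.rfft(X, axis=1)
    alpha = 2.0 * spec.real[:, 1:] / T
    beta = -2.0 * spec.imag[:, 1:] / T
    alpha[:, -1] = spec.real[:, -1] / T
    beta[:, -1] = 0.0
    freqs = np.arange(1, T // 2 + 1) / (T * dt)
    return np.sqrt(alpha ** 2 + beta ** 2), freqs


def amplitude_metrics(ts: SessionTimeSeries,
                      band: Tuple[float, float] = (0.01, 0.1)
                      ) -> Tuple[MetricMap, MetricMap]:
    """ALFF and fALFF maps from a cleaned, surface-smoothed session.

    ALFF(v) = sum of in-band amplitudes / (T/2); fALFF(v) is the in-band sum
    over the full-range sum (all l = 1..T/2, DC excluded), in [0, 1].
    Vertices with zero total amplitude get fALFF masked as undefined.
    """
    require_state(ts, STATE_SMOOTHED)
    f_lo, f_hi = band
    nyq = 1.0 / (2.0 * ts.dt)
    if not (0 < f_lo < f_hi <= nyq + 1e-12):
        raise ValueError(f"band {band} outside (0, {nyq}]")
    amps, freqs = _amplitude_matrix(ts.data, ts.dt)
    half_t = amps.shape[1]
    in_band = (freqs >= f_lo - 1e-12) & (freqs <= f_hi + 1e-12)
    alff = amps[:, in_band].sum(axis=1) / half_t
    total = amps.sum(axis=1) / half_t
    undefined = total == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        falff = np.where(undefined, np.nan, alff / np.where(total > 0, total, 1.0))
    common = dict(subject_id=ts.subject_id, session_id=ts.session_id,
                  meta={"band_hz": list(band), "alff_divisor": "T/2",
                        "state": ts.state})
    return (MetricMap(values=alff, metric="ALFF", **common),
            MetricMap(values=falff, metric="fALFF", mask=undefined, **common))


# ---------------------------------------------------------------------------
# Kendall's W and ReHo
# ---------------------------------------------------------------------------

def _tie_correction(ranks: np.ndarray) -> float:
    """Sum over tie groups of (t^3 - t) for one rank series."""
    _, counts = np.unique(ranks, return_counts=True)
    return float((counts ** 3 - counts).sum())


def kendall_w(series: np.ndarray) -> float:
    """Kendall's coefficient of concordance of K series over T time points.

    Each series is converted to within-series ranks (midranks on ties);
    W = 12 * S / (K^2 (T^3 - T) - K * C) with S the squared deviation of the
    per-time-point rank sums from their mean and C the tie correction.
    """
    X = np.asarray(series, dtype=np.float64)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("need a K x T matrix with K >= 2, T >= 2")
    K, T = X.shape
    ranks = rankdata(X, axis=1)
    R = ranks.sum(axis=0)
    S = float(((R - R.mean()) ** 2).sum())
    C = sum(_tie_correction(ranks[k]) for k in range(K))
    denom = K ** 2 * (T ** 3 - T) - K * C
    if denom <= 0:        # every series fully tied
        return 0.0
    return 12.0 * S / denom


def reho(ts: SessionTimeSeries, mesh: SurfaceMesh, rings: int) -> MetricMap:
    """ReHo map: Kendall's W over each vertex's ring neighborhood.

    Requires band-passed, non-smoothed data.  Vectorized: series are ranked
    once, then per-neighborhood rank sums come from a sparse indicator
    product, which matches the per-vertex kendall_w loop exactly.
    """
    require_state(ts, STATE_BANDPASSED)
    if ts.n_vertices != mesh.vertex_count:
        raise ValueError("session and mesh disagree on vertex count")
    V, T = ts.data.shape
    ranks = rankdata(ts.data, axis=1)
    ties = np.array([_tie_correction(ranks[v]) for v in range(V)])

    N = neighborhood_indicator(mesh, rings)
    K = np.asarray(N.sum(axis=1)).ravel()
    R = N @ ranks                      # V x T per-neighborhood rank sums
    S = ((R - R.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    C = N @ ties
    denom = K ** 2 * (T ** 3 - T) - K * C
    with np.errstate(divide="ignore", invalid="ignore"):
        w = np.where(denom > 0, 12.0 * S / denom, 0.0)
    return MetricMap(values=np.clip(w, 0.0, 1.0),
                     metric=f"ReHo{rings}",
                     subject_id=ts.subject_id, session_id=ts.session_id,
                     meta={"rings": rings, "state": ts.state})
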