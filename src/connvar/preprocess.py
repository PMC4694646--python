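"""Signal-level preprocessing of vertex-wise BOLD time series.

Implements the purely computational cleaning steps: initial-volume discard,
robust despiking, 4D global-mean intensity scaling (target 10,000), nuisance
regression (Friston-24 motion expansion, WM/CSF mean series, linear and
quadratic trends), ideal DFT band-pass filtering, iterative surface smoothing
and per-vertex z-normalization.  Each step advances (or preserves) the
session's processing-state tag so downstream metrics can enforce their input
requirements.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Tuple

import numpy as np

from .core import (
    STATE_BANDPASSED,
    STATE_CLEANED,
    STATE_RAW,
    STATE_SMOOTHED,
    STATE_ZNORMALIZED,
    SessionTimeSeries,
    require_state,
)
from .mesh import SurfaceMesh

logger = logging.getLogger(__name__)

_MAD_SCALE = 1.4826  # makes MAD a consistent sigma estimate for a Gaussian


# ---------------------------------------------------------------------------
# volume discard
# ---------------------------------------------------------------------------

def discard_initial(ts: SessionTimeSeries, n_drop: int) -> SessionTimeSeries:
    """Drop the first ``n_drop`` volumes (the scanner-equilibration period)."""
    if n_drop < 0:
        raise ValueError("n_drop must be non-negative")
    if n_drop >= ts.n_timepoints:
        raise ValueError(
            f"cannot discard {n_drop} of {ts.n_timepoints} volumes")
    if n_drop == 0:
        return ts
    extra = {}
    if ts.motion is not None:
        extra["motion"] = ts.motion[n_drop:]
    if ts.wm is not None:
        extra["wm"] = ts.wm[n_drop:]
    if ts.csf is not None:
        extra["csf"] = ts.csf[n_drop:]
    return ts.with_data(ts.data[:, n_drop:], **extra)


# ---------------------------------------------------------------------------
# despiking
# ---------------------------------------------------------------------------

def despike(ts: SessionTimeSeries, z_thresh: float = 5.0
            ) -> Tuple[SessionTimeSeries, np.ndarray]:
    """Replace temporal spikes by linear interpolation.

    A time point is a spike when its robust z-score
    |x - median| / (1.4826 * MAD) exceeds ``z_thresh``.  Spikes are replaced
    by linear interpolation between the nearest non-spike neighbors; spikes at
    the series edges take the nearest retained value.  Returns the despiked
    session and the V x T boolean spike mask.
    """
    if z_thresh <= 0:
        raise ValueError("z_thresh must be positive")
    X = ts.data
    med = np.median(X, axis=1, keepdims=True)
    mad = np.median(np.abs(X - med), axis=1, keepdims=True)
    scale = _MAD_SCALE * mad
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(scale > 0, np.abs(X - med) / scale, 0.0)
    mask = z > z_thresh

    out = X.copy()
    t = np.arange(ts.n_timepoints)
    for v in np.nonzero(mask.any(axis=1))[0]:
        good = ~mask[v]
        if not good.any():
            logger.warning(
                "vertex %d: every time point flagged as spike; left untouched",
                v)
            mask[v] = False
            continue
        out[v, mask[v]] = np.interp(t[mask[v]], t[good], X[v, good])
    return ts.with_data(out), mask


# ---------------------------------------------------------------------------
# global-mean intensity scaling
# ---------------------------------------------------------------------------

def scale_global_mean(ts: SessionTimeSeries,
                      target: float = 10_000.0) -> SessionTimeSeries:
    """Rescale so the grand mean over all vertices and time points is ``target``."""
    grand = float(ts.data.mean())
    if grand <= 0:
        raise ValueError("global mean must be positive for intensity scaling")
    return ts.with_data(ts.data * (target / grand))


# ---------------------------------------------------------------------------
# motion regressors and frame-wise displacement
# ---------------------------------------------------------------------------

def motion_regressors(motion: np.ndarray, radius_mm: float = 50.0
                      ) -> Tuple[np.ndarray, float]:
    """Friston-24 motion expansion and mean frame-wise displacement.

    ``motion`` is T x 6 (3 translations in mm, 3 rotations in radians).  The
    24 columns are [m_t, m_t^2, m_{t-1}, m_{t-1}^2] for each parameter, with
    the lagged terms zero-padded at t=0.  FD is the Power convention:
    FD_t = sum |Delta translation| + radius * sum |Delta rotation|.
    """
    motion = np.asarray(motion, dtype=np.float64)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ValueError("motion must be a T x 6 matrix")
    if motion.shape[0] < 2:
        raise ValueError("need at least two frames")
    if not np.all(np.isfinite(motion)):
        raise ValueError("motion trace contains non-finite values")

    lagged = np.vstack([np.zeros((1, 6)), motion[:-1]])
    friston24 = np.hstack([motion, motion ** 2, lagged, lagged ** 2])

    d = np.diff(motion, axis=0)
    fd = np.abs(d[:, :3]).sum(axis=1) + radius_mm * np.abs(d[:, 3:]).sum(axis=1)
    return friston24, float(fd.mean())


# ---------------------------------------------------------------------------
# nuisance regression
# ---------------------------------------------------------------------------

@dataclass
class NuisanceDesign:
    """T x p fixed nuisance design: Friston-24, WM, CSF, trends, intercept."""

    matrix: np.ndarray
    names: Tuple[str, ...]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if self.matrix.ndim != 2:
            raise ValueError("design must be 2-D")
        if self.matrix.shape[1] != len(self.names):
            raise ValueError("names must match design columns")


def build_nuisance_design(ts: SessionTimeSeries,
                          radius_mm: float = 50.0) -> NuisanceDesign:
    """Assemble the standard nuisance design from the session's own traces."""
    T = ts.n_timepoints
    cols = []
    names = []
    if ts.motion is not None:
        f24, _ = motion_regressors(ts.motion, radius_mm)
        cols.append(f24)
        names += [f"friston24_{i}" for i in range(24)]
    for label, series in (("wm", ts.wm), ("csf", ts.csf)):
        if series is not None:
            cols.append(np.asarray(series, dtype=np.float64).reshape(-1, 1))
            names.append(label)
    t = np.linspace(-1.0, 1.0, T).reshape(-1, 1)
    cols += [t, t ** 2, np.ones((T, 1))]
    names += ["trend_linear", "trend_quadratic", "intercept"]
    return NuisanceDesign(np.hstack(cols), tuple(names))


def _drop_collinear(X: np.ndarray, names) -> Tuple[np.ndarray, list]:
    """Greedily drop columns until the design has full column rank."""
    keep = list(range(X.shape[1]))
    while len(keep) > 0:
        sub = X[:, keep]
        if np.linalg.matrix_rank(sub) == len(keep):
            break
        # drop the column whose removal restores the most rank; in practice
        # dropping the last collinear one is enough and deterministic
        for k in reversed(range(len(keep))):
            trial = keep[:k] + keep[k + 1:]
            if np.linalg.matrix_rank(X[:, trial]) == len(trial):
                warnings.warn(f"dropping collinear nuisance column "
                              f"{names[keep[k]]!r}")
                keep = trial
                break
    return X[:, keep], [names[i] for i in keep]


def regress_nuisance(ts: SessionTimeSeries,
                     design: NuisanceDesign) -> SessionTimeSeries:
    """Per-vertex OLS residuals against the nuisance design.

    Output state becomes "cleaned".  The residuals are orthogonal to every
    retained design column; applying the operation twice is a no-op.
    """
    X = design.matrix
    if X.shape[0] != ts.n_timepoints:
        raise ValueError("design and time series disagree on T")
    if X.shape[1] >= ts.n_timepoints:
        raise ValueError("more nuisance columns than time points")
    X, _ = _drop_collinear(X, list(design.names))
    beta, *_ = np.linalg.lstsq(X, ts.data.T, rcond=None)
    resid = ts.data.T - X @ beta
    return ts.with_data(resid.T, state=STATE_CLEANED)


# ---------------------------------------------------------------------------
# band-pass filtering
# ---------------------------------------------------------------------------

def bandpass(ts: SessionTimeSeries, f_lo: float, f_hi: float
             ) -> SessionTimeSeries:
    """Ideal discrete-Fourier band-pass filter on each vertex series.

    Fourier coefficients with frequency in [f_lo, f_hi] (Hz, inclusive) are
    retained, all others zeroed.  With f_lo > 0 the DC term (series mean) is
    removed.  Consistent with the Fourier decomposition the amplitude metrics
    use, so a pass-band sinusoid at an exact Fourier frequency is untouched.
    """
    require_state(ts, STATE_CLEANED, STATE_RAW)
    nyq = 1.0 / (2.0 * ts.dt)
    if not (0 <= f_lo < f_hi <= nyq + 1e-12):
        raise ValueError(f"invalid band [{f_lo}, {f_hi}] for Nyquist {nyq}")
    T = ts.n_timepoints
    freqs = np.fft.rfftfreq(T, d=ts.dt)
    keep = (freqs >= f_lo - 1e-12) & (freqs <= f_hi + 1e-12)
    spec = np.fft.rfft(ts.data, axis=1)
    spec[:, ~keep] = 0.0
    out = np.fft.irfft(spec, n=T, axis=1)
    return ts.with_data(out, state=STATE_BANDPASSED)


# ---------------------------------------------------------------------------
# surface smoothing
# ---------------------------------------------------------------------------

def smoothing_schedule(fwhm_mm: float, edge_length_mm: float,
                       max_valence: int = 6) -> Tuple[int, float]:
    """Iteration count and diffusion step for heat-kernel mesh smoothing.

    One step of W = I - eps*L (L the combinatorial graph Laplacian) spreads
    variance by about eps * valence * edge^2, so the step count and size are
    chosen to accumulate sigma^2 = (fwhm / 2.355)^2 while keeping every
    weight non-negative (eps <= 1/(max_valence + 1)).
    """
    if fwhm_mm <= 0:
        return 0, 0.0
    sigma2 = (fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0)))) ** 2
    tau = sigma2 / (6.0 * edge_length_mm ** 2)   # total diffusion "time"
    eps_max = 1.0 / (max_valence + 1.0)
    n_iter = max(1, int(np.ceil(tau / eps_max)))
    return n_iter, tau / n_iter


def smooth_on_mesh(data: np.ndarray, mesh: SurfaceMesh, fwhm_mm: float,
                   edge_length_mm: float = 4.0) -> np.ndarray:
    """Heat-kernel smoothing on the mesh graph: iterated W = I - eps*L.

    Works on a length-V map or a V x T matrix (each time point smoothed
    independently).  W is symmetric and doubly stochastic, so constants and
    the total sum are preserved exactly and a point impulse's maximum decays
    monotonically with the kernel width; fwhm 0 is the identity.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm must be non-negative")
    arr = np.asarray(data, dtype=np.float64)
    valence = mesh.vertex_valences()
    n_iter, eps = smoothing_schedule(fwhm_mm, edge_length_mm,
                                     int(valence.max()) if valence.size else 6)
    if n_iter == 0:
        return arr.copy()
    A = mesh.adjacency_matrix()
    out = arr.copy()
    squeeze = out.ndim == 1
    if squeeze:
        out = out[:, None]
    for _ in range(n_iter):
        out = out - eps * (valence[:, None] * out - A @ out)
    return out.ravel() if squeeze else out


def smooth_session(ts: SessionTimeSeries, mesh: SurfaceMesh, fwhm_mm: float,
                   edge_length_mm: float = 4.0) -> SessionTimeSeries:
    """Spatial smoothing of a cleaned session (for the amplitude metrics)."""
    require_state(ts, STATE_CLEANED)
    out = smooth_on_mesh(ts.data, mesh, fwhm_mm, edge_length_mm)
    return ts.with_data(out, state=STATE_SMOOTHED)


# ---------------------------------------------------------------------------
# z-normalization
# ---------------------------------------------------------------------------

def znormalize(ts: SessionTimeSeries) -> SessionTimeSeries:
    """Per-vertex zero-mean unit-variance scaling (population divisor T).

    Constant vertex series cannot be normalized; they are zeroed and a
    warning is emitted.
    """
    require_state(ts, STATE_BANDPASSED)
    X = ts.data
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)       # ddof=0
    flat = (sd.ravel() == 0)
    if flat.any():
        warnings.warn(f"{int(flat.sum())} constant vertex series zeroed "
                      "during z-normalization")
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(sd > 0, (X - mu) / sd, 0.0)
    return ts.with_data(out, state=STATE_ZNORMALIZED)
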