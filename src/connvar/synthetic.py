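"""Synthetic longitudinal rfMRI cohorts with known variance components.

Emulates a balanced test-retest design (default 30 subjects x 10 sessions,
300 volumes at a 2 s sampling interval, mirroring a month of repeated
scanning) on an icosphere surface.  Each vertex carries a band-limited
network oscillation whose amplitude decomposes as

    A_ij(v) = a0 + b_j(v) + w_ij(v),   b_j(v) ~ N(0, sigma_b(v)^2),
                                       w_ij(v) ~ N(0, sigma_w(v)^2),

so the between-subject and within-subject variance of every amplitude-borne
metric — and hence the true intraclass correlation
ICC(v) = sigma_b^2 / (sigma_b^2 + sigma_w^2) — is known exactly.  On top of
the signal sit shared nuisance components (motion-coupled drift, WM/CSF-like
series), additive white measurement noise and optional spikes; the cleaning
pipeline is expected to remove them.

Covariates follow the study's demographics where stated (age uniform on
20-30, balanced sex); head micro-motion is simulated as a random walk and
meanFD is computed from it, mcBBR is log-normal, and the per-vertex surface
Jacobian is normal around 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .core import STATE_RAW, SessionTimeSeries
from .mesh import SurfaceMesh, build_icosphere
from .preprocess import motion_regressors, smooth_on_mesh


# ---------------------------------------------------------------------------
# network atlas
# ---------------------------------------------------------------------------

@dataclass
class NetworkAtlas:
    """Per-vertex network labels (1..L) plus soft template maps (V x L)."""

    labels: np.ndarray
    template_maps: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        self.template_maps = np.asarray(self.template_maps, dtype=np.float64)
        if self.template_maps.shape[0] != self.labels.size:
            raise ValueError("template_maps rows must match label count")
        if (self.template_maps < 0).any():
            raise ValueError("template maps must be non-negative")

    @property
    def n_labels(self) -> int:
        return self.template_maps.shape[1]


def assign_networks(mesh: SurfaceMesh, n_labels: int, seed: int
                    ) -> NetworkAtlas:
    """Partition the mesh into contiguous label patches.

    Patches are grown by breadth-first expansion from ``n_labels`` randomly
    chosen seed vertices, cycling over labels so patch sizes stay balanced.
    Template maps are lightly smoothed patch indicators.
    """
    if n_labels < 2:
        raise ValueError("need at least two labels")
    V = mesh.vertex_count
    if n_labels > V:
        raise ValueError("more labels than vertices")
    rng = np.random.default_rng(seed)
    seeds = rng.choice(V, size=n_labels, replace=False)

    labels = np.zeros(V, dtype=np.int64)
    frontiers: List[List[int]] = []
    for l, s in enumerate(seeds, start=1):
        labels[s] = l
        frontiers.append([int(s)])
    # round-robin BFS: each label claims the unlabeled neighbors of its
    # current frontier before the next label moves, keeping patches connected
    while any(frontiers):
        for l in range(n_labels):
            new: List[int] = []
            for v in frontiers[l]:
                for nb in sorted(mesh.adjacency[v]):
                    if labels[nb] == 0:
                        labels[nb] = l + 1
                        new.append(nb)
            frontiers[l] = new

    indicators = np.zeros((V, n_labels))
    indicators[np.arange(V), labels - 1] = 1.0
    # two averaging passes blur the indicator into a soft confidence map
    templates = smooth_on_mesh(indicators, mesh, fwhm_mm=2.0 * 2.355,
                               edge_length_mm=2.0)
    return NetworkAtlas(labels=labels, template_maps=templates)


# ---------------------------------------------------------------------------
# configuration and ground truth
# ---------------------------------------------------------------------------

ArrayLike = Union[float, np.ndarray]


@dataclass
class CohortConfig:
    """Study-design and generative parameters for a synthetic cohort.

    ``sigma_b`` / ``sigma_w`` are the between- and within-subject standard
    deviations of the network-oscillation amplitude; either may be a scalar
    or a per-vertex array.  ``noise_sd`` is additive white measurement noise,
    separate from the amplitude components so the amplitude-level ICC stays
    the ground truth for the amplitude-borne metrics.
    """

    n_subjects: int = 30
    n_sessions: int = 10
    t_raw: int = 300
    dt: float = 2.0
    band: Tuple[float, float] = (0.01, 0.1)
    a0: float = 1.0
    sigma_b: ArrayLike = 0.2
    sigma_w: ArrayLike = 0.2
    noise_sd: float = 0.2
    baseline: float = 1000.0
    nuisance_gain: float = 0.5
    motion_step_mm: float = 0.02
    motion_step_rad: float = 4e-4
    spike_rate: float = 0.0
    spike_amplitude: float = 15.0
    covariate_effects: Dict[str, float] = field(default_factory=dict)
    n_discard: int = 5          # volumes the standard pipeline will drop
    freq_grid_len: Optional[int] = None
    seed: int = 0

    @property
    def analysis_window(self) -> int:
        """Length of the even post-discard window the metrics analyse.

        Network sinusoids sit on this window's Fourier grid, so they stay
        leakage-free through volume discard and the spectral decomposition.
        """
        if self.freq_grid_len is not None:
            return self.freq_grid_len
        return 2 * ((self.t_raw - self.n_discard) // 2)

    def validate(self) -> None:
        f_lo, f_hi = self.band
        if not (0 < f_lo < f_hi <= 1.0 / (2.0 * self.dt) + 1e-12):
            raise ValueError(f"invalid band {self.band} for dt={self.dt}")
        if self.n_subjects * self.n_sessions < 2:
            raise ValueError("need at least two observations in the design")
        for name in ("sigma_b", "sigma_w"):
            if np.any(np.asarray(getattr(self, name)) < 0):
                raise ValueError(f"{name} must be non-negative")
        if self.noise_sd < 0 or self.spike_rate < 0:
            raise ValueError("noise_sd and spike_rate must be non-negative")
        if self.t_raw < 8:
            raise ValueError("t_raw too small")


@dataclass
class GroundTruth:
    """Per-vertex true variance components and the subject effects drawn."""

    sigma_b2: np.ndarray            # length V
    sigma_w2: np.ndarray            # length V
    icc: np.ndarray                 # length V
    subject_effects: np.ndarray     # n_subjects x V
    covariate_effects: Dict[str, float]


@dataclass
class Cohort:
    """Everything a downstream stage needs: sessions, covariates, truth."""

    sessions: List[SessionTimeSeries]
    covariates: pd.DataFrame        # one row per (subject, session)
    jacobian: np.ndarray            # n_subjects x V
    truth: GroundTruth
    mesh: SurfaceMesh
    atlas: NetworkAtlas
    config: CohortConfig

    @property
    def subject_ids(self) -> List[str]:
        return sorted({s.subject_id for s in self.sessions})


def _per_vertex(value: ArrayLike, V: int) -> np.ndarray:
    arr = np.asarray(value, dtype=np.float64)
    if arr.ndim == 0:
        return np.full(V, float(arr))
    if arr.shape != (V,):
        raise ValueError(f"per-vertex parameter has shape {arr.shape}, "
                         f"expected ({V},)")
    return arr.copy()


def icc_gradient(mesh: SurfaceMesh, icc_lo: float = 0.1, icc_hi: float = 0.9,
                 total_sd: float = 0.3) -> Tuple[np.ndarray, np.ndarray]:
    """Per-vertex (sigma_b, sigma_w) giving a smooth spatial ICC gradient.

    The true ICC runs linearly from ``icc_lo`` to ``icc_hi`` along the z
    coordinate of the mesh, holding the total amplitude variance fixed at
    ``total_sd**2``.  Spatial smoothness matters: surface smoothing then mixes
    vertices of nearly equal ICC, leaving the per-vertex truth intact.
    """
    z = mesh.coordinates[:, 2]
    frac = (z - z.min()) / (z.max() - z.min())
    icc = icc_lo + (icc_hi - icc_lo) * frac
    var_total = total_sd ** 2
    sigma_b = np.sqrt(icc * var_total)
    sigma_w = np.sqrt((1.0 - icc) * var_total)
    return sigma_b, sigma_w


def _band_frequencies(grid_len: int, dt: float,
                      band: Tuple[float, float]) -> np.ndarray:
    freqs = np.fft.rfftfreq(grid_len, d=dt)
    sel = (freqs >= band[0] - 1e-12) & (freqs <= band[1] + 1e-12) & (freqs > 0)
    return freqs[sel]


def network_oscillation(t_raw: int, dt: float, band: Tuple[float, float],
                        rng: np.random.Generator,
                        grid_len: Optional[int] = None) -> np.ndarray:
    """Unit-RMS sum of in-band sinusoids with random phases.

    Frequencies sit on the Fourier grid of ``grid_len`` samples (default the
    raw length), so a series of that length — any contiguous window of it —
    carries the oscillation without leakage.
    """
    grid_len = grid_len or t_raw
    freqs = _band_frequencies(grid_len, dt, band)
    if freqs.size == 0:
        raise ValueError("no Fourier frequency falls inside the band")
    t = np.arange(t_raw) * dt
    phases = rng.uniform(0, 2 * np.pi, size=freqs.size)
    amp = np.sqrt(2.0 / freqs.size)  # total variance sums to 1
    return (amp * np.sin(2 * np.pi * freqs[:, None] * t[None, :]
                         + phases[:, None])).sum(axis=0)


def _random_walk_motion(T: int, step_mm: float, step_rad: float,
                        rng: np.random.Generator) -> np.ndarray:
    steps = np.hstack([rng.normal(0, step_mm, (T, 3)),
                       rng.normal(0, step_rad, (T, 3))])
    steps[0] = 0.0
    return np.cumsum(steps, axis=0)


def simulate_cohort(mesh: SurfaceMesh, atlas: NetworkAtlas,
                    config: CohortConfig) -> Cohort:
    """Generate a balanced longitudinal cohort on ``mesh``.

    Deterministic given ``config.seed`` (per-subject / per-session random
    streams are spawned from a single SeedSequence, so the full output is
    bit-identical across runs).
    """
    config.validate()
    V = mesh.vertex_count
    L = atlas.n_labels
    sigma_b = _per_vertex(config.sigma_b, V)
    sigma_w = _per_vertex(config.sigma_w, V)

    master = np.random.SeedSequence(config.seed)
    ss_subjects, ss_sessions = master.spawn(2)
    rng_subj = np.random.default_rng(ss_subjects)

    n_s, n_k = config.n_subjects, config.n_sessions
    subject_ids = [f"sub{j + 1:03d}" for j in range(n_s)]

    age = rng_subj.uniform(20.0, 30.0, n_s)
    sex = rng_subj.integers(0, 2, n_s).astype(float)
    subject_u = rng_subj.standard_normal((n_s, V))
    b = subject_u * sigma_b[None, :]
    jacobian = rng_subj.normal(1.0, 0.05, size=(n_s, V))

    eff = {"age": 0.0, "sex": 0.0, "meanFD": 0.0, "mcBBR": 0.0}
    eff.update(config.covariate_effects)

    session_streams = ss_sessions.spawn(n_s * n_k)
    sessions: List[SessionTimeSeries] = []
    rows = []
    for j, sid in enumerate(subject_ids):
        for i in range(n_k):
            rng = np.random.default_rng(session_streams[j * n_k + i])
            T = config.t_raw

            osc = np.vstack([network_oscillation(T, config.dt, config.band,
                                                 rng, config.analysis_window)
                             for _ in range(L)])
            w_ij = rng.normal(0.0, 1.0, V) * sigma_w
            motion = _random_walk_motion(T, config.motion_step_mm,
                                         config.motion_step_rad, rng)
            _, mean_fd = motion_regressors(motion)
            mcbbr = float(rng.lognormal(mean=np.log(0.6), sigma=0.15))

            amp = (config.a0 + b[j] + w_ij
                   + eff["age"] * (age[j] - 25.0)
                   + eff["sex"] * sex[j]
                   + eff["meanFD"] * mean_fd
                   + eff["mcBBR"] * mcbbr)

            data = amp[:, None] * osc[atlas.labels - 1, :]

            # shared nuisance: WM/CSF-like band-limited series and a
            # motion-coupled drift, with per-vertex coupling gains
            wm = network_oscillation(T, config.dt, (0.005, 0.12), rng)
            csf = network_oscillation(T, config.dt, (0.005, 0.12), rng)
            drift = motion[:, 0] - motion[:, 0].mean()
            g = config.nuisance_gain
            data += rng.normal(0, g, V)[:, None] * wm[None, :]
            data += rng.normal(0, g, V)[:, None] * csf[None, :]
            data += rng.normal(0, g, V)[:, None] * drift[None, :]

            if config.noise_sd > 0:
                data += rng.normal(0.0, config.noise_sd, size=(V, T))
            if config.spike_rate > 0:
                spikes = rng.random((V, T)) < config.spike_rate
                signs = rng.choice([-1.0, 1.0], size=(V, T))
                data += spikes * signs * config.spike_amplitude
            data += config.baseline

            sessions.append(SessionTimeSeries(
                data=data, dt=config.dt, subject_id=sid,
                session_id=f"ses{i + 1:02d}", state=STATE_RAW,
                motion=motion, wm=wm, csf=csf))
            rows.append(dict(subject=sid, session=f"ses{i + 1:02d}",
                             age=age[j], sex=sex[j], meanFD=mean_fd,
                             mcBBR=mcbbr))

    sigma_b2 = sigma_b ** 2
    sigma_w2 = sigma_w ** 2
    denom = sigma_b2 + sigma_w2
    with np.errstate(invalid="ignore", divide="ignore"):
        icc = np.where(denom > 0, sigma_b2 / denom, 0.0)
    truth = GroundTruth(sigma_b2=sigma_b2, sigma_w2=sigma_w2, icc=icc,
                        subject_effects=b, covariate_effects=dict(eff))
    return Cohort(sessions=sessions, covariates=pd.DataFrame(rows),
                  jacobian=jacobian, truth=truth, mesh=mesh, atlas=atlas,
                  config=config)


def default_cohort(subdivisions: int = 2, seed: int = 0,
                   **overrides) -> Cohort:
    """Convenience: icosphere mesh, 7-network atlas, default design."""
    mesh = build_icosphere(subdivisions)
    atlas = assign_networks(mesh, n_labels=7, seed=seed + 1)
    config = CohortConfig(seed=seed, **overrides)
    return simulate_cohort(mesh, atlas, config)
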