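"""Meso-scale metrics: seed connectivity, dual regression, network interplay.

Seed-based functional connectivity (SFC) is the Fisher-z transform of the
Pearson correlation between a seed's mean series and every vertex; on
z-normalized series (population variance, divisor T) the correlation reduces
to a scaled dot product, so the whole-cortex map is one matrix product.
Dual regression recovers subject-level network time courses (stage 1, data
regressed on group spatial templates) and subject-level spatial maps
(stage 2, data regressed on those time courses).  The interplay matrix is
the Fisher-z pairwise correlation of the stage-1 time courses.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import (
    STATE_CLEANED,
    STATE_ZNORMALIZED,
    MetricMap,
    SessionTimeSeries,
    require_state,
)

logger = logging.getLogger(__name__)

FISHER_EPS = 1e-7
#: correlations within FISHER_EPS of +/-1 are clipped to this magnitude
Z_MAX = float(np.arctanh(1.0 - FISHER_EPS))


def fisher_z(rho):
    """Variance-stabilizing arctanh transform, clipped near |rho| = 1.

    Values with |rho| >= 1 - 1e-7 map to +/-Z_MAX (about 8.4) so downstream
    models always see finite numbers; |rho| > 1 beyond rounding is an error.
    """
    r = np.asarray(rho, dtype=np.float64)
    if np.any(np.abs(r) > 1.0 + 1e-12):
        raise ValueError("correlation outside [-1, 1]")
    n_clip = int((np.abs(r) >= 1.0 - FISHER_EPS).sum())
    if n_clip:
        logger.info("fisher_z: clipped %d near-unit correlations", n_clip)
    r = np.clip(r, -(1.0 - FISHER_EPS), 1.0 - FISHER_EPS)
    out = np.arctanh(r)
    return float(out) if np.isscalar(rho) or out.ndim == 0 else out


# ---------------------------------------------------------------------------
# seed-based connectivity
# ---------------------------------------------------------------------------

@dataclass
class SeedDefinition:
    """A set of vertex indices; the seed series is their mean, re-normalized."""

    vertices: np.ndarray
    name: str = "seed"

    def __post_init__(self) -> None:
        self.vertices = np.unique(np.asarray(self.vertices, dtype=np.int64))
        if self.vertices.size == 0:
            raise ValueError("seed must contain at least one vertex")
        if self.vertices.min() < 0:
            raise ValueError("negative vertex index in seed")


def seed_from_atlas(atlas, label: int, name: str | None = None
                    ) -> SeedDefinition:
    """Seed = the vertices of one atlas label (a synthetic stand-in for a
    posterior-cingulate default-network parcel)."""
    verts = np.nonzero(atlas.labels == label)[0]
    return SeedDefinition(vertices=verts, name=name or f"network{label}")


def sfc(ts: SessionTimeSeries, seed: SeedDefinition) -> MetricMap:
    """Seed-based Fisher-z connectivity map (matrix form).

    Requires z-normalized input.  The seed's mean series is re-normalized to
    unit population variance; rho(v) = <seed, v> / T then equals the Pearson
    correlation, and the map is Fisher-z of the single matrix product V s'.
    """
    require_state(ts, STATE_ZNORMALIZED)
    if seed.vertices.max() >= ts.n_vertices:
        raise ValueError("seed vertex outside the session")
    T = ts.n_timepoints
    s = ts.data[seed.vertices].mean(axis=0)
    sd = s.std()          # population convention
    if sd == 0:
        raise ValueError("seed series is constant")
    s = (s - s.mean()) / sd
    rho = ts.data @ s / T
    rho = np.clip(rho, -1.0, 1.0)
    return MetricMap(values=fisher_z(rho), metric="SFC",
                     subject_id=ts.subject_id, session_id=ts.session_id,
                     meta={"seed": seed.name,
                           "n_seed_vertices": int(seed.vertices.size)})


# ---------------------------------------------------------------------------
# dual regression
# ---------------------------------------------------------------------------

@dataclass
class DualRegressionResult:
    """Stage-1 time courses (T x L), stage-2 maps (V x L), residual norms."""

    time_courses: np.ndarray
    spatial_maps: np.ndarray
    stage1_residual: float
    stage2_residual: float


def dual_regression(ts: SessionTimeSeries, templates: np.ndarray
                    ) -> DualRegressionResult:
    """Two-stage least squares against group spatial templates.

    Input must be cleaned but *not* normalized; an intercept column is
    appended at both stages so mean offsets do not leak into the estimates.
    Stage 1 solves, for each time point, the spatial pattern as a combination
    of the V x L templates; stage 2 solves each vertex series as a
    combination of the stage-1 time courses.
    """
    require_state(ts, STATE_CLEANED)
    P = np.asarray(templates, dtype=np.float64)
    if P.ndim != 2 or P.shape[0] != ts.n_vertices:
        raise ValueError("templates must be V x L")
    V, T = ts.data.shape
    L = P.shape[1]
    if not (L < T and L < V):
        raise ValueError("need fewer templates than time points and vertices")
    if np.linalg.matrix_rank(P) < L:
        norms = np.linalg.norm(P, axis=0)
        bad = [int(i) for i in np.nonzero(norms == 0)[0]]
        raise ValueError(f"rank-deficient templates (suspect columns {bad})")

    D1 = np.column_stack([P, np.ones(V)])
    coef1, *_ = np.linalg.lstsq(D1, ts.data, rcond=None)   # (L+1) x T
    X1 = coef1[:L].T                                       # T x L
    r1 = float(np.linalg.norm(ts.data - D1 @ coef1))

    D2 = np.column_stack([X1, np.ones(T)])
    coef2, *_ = np.linalg.lstsq(D2, ts.data.T, rcond=None)  # (L+1) x V
    Y2 = coef2[:L].T                                        # V x L
    r2 = float(np.linalg.norm(ts.data.T - D2 @ coef2))
    return DualRegressionResult(time_courses=X1, spatial_maps=Y2,
                                stage1_residual=r1, stage2_residual=r2)


def dr_metric_maps(ts: SessionTimeSeries, templates: np.ndarray
                   ) -> Sequence[MetricMap]:
    """One MetricMap per template network from the stage-2 spatial maps."""
    res = dual_regression(ts, templates)
    maps = []
    for l in range(res.spatial_maps.shape[1]):
        maps.append(MetricMap(values=res.spatial_maps[:, l],
                              metric=f"DR_{l + 1}",
                              subject_id=ts.subject_id,
                              session_id=ts.session_id,
                              meta={"network": l + 1}))
    return maps


# ---------------------------------------------------------------------------
# network interplay
# ---------------------------------------------------------------------------

def interplay_matrix(time_courses: np.ndarray) -> np.ndarray:
    """L x L Fisher-z matrix of pairwise time-course correlations.

    The diagonal is undefined and returned as NaN; constant columns get
    their whole row/column masked with a warning.
    """
    X = np.asarray(time_courses, dtype=np.float64)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("need a T x L matrix with L >= 2")
    L = X.shape[1]
    sd = X.std(axis=0)
    constant = sd == 0
    if constant.any():
        warnings.warn(f"{int(constant.sum())} constant time courses masked "
                      "in the interplay matrix")
    Xs = X[:, ~constant]
    C = np.corrcoef(Xs.T)
    out = np.full((L, L), np.nan)
    idx = np.nonzero(~constant)[0]
    Z = fisher_z(np.clip(C, -1.0, 1.0))
    out[np.ix_(idx, idx)] = Z
    np.fill_diagonal(out, np.nan)
    out = (out + out.T) / 2.0   # enforce exact symmetry
    return out
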