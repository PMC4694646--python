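"""Vertex-level weighted functional connectome and centrality metrics.

The connectome is the Fisher-z transform of the full pairwise Pearson
correlation matrix of band-passed, non-smoothed vertex series.  Graphs are
thresholded to a fixed edge density (default 5% of the V(V-1)/2 pairs,
largest weights kept) so they are comparable across subjects and sessions.
Weighted degree centrality (DCw) is the row sum of retained weights;
eigenvector centrality (ECw) is the principal eigenvector of the adjacency,
computed by power iteration on the largest connected component.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .core import STATE_BANDPASSED, MetricMap, SessionTimeSeries, require_state
from .meso_metrics import fisher_z

logger = logging.getLogger(__name__)


@dataclass
class ConnectomeGraph:
    """Symmetric sparse weighted graph at a fixed edge density."""

    weights: csr_matrix            # V x V, zero diagonal, symmetric
    density: float                 # retained fraction of off-diagonal pairs
    n_edges: int                   # undirected edge count
    subject_id: str = ""
    session_id: str = ""

    @property
    def n_vertices(self) -> int:
        return self.weights.shape[0]


def correlation_graph(ts: SessionTimeSeries) -> np.ndarray:
    """Dense V x V Fisher-z adjacency of pairwise vertex correlations.

    Diagonal is zeroed; constant vertex series get their row/column masked
    to zero with a warning (they carry no correlation information).
    """
    require_state(ts, STATE_BANDPASSED)
    if ts.n_vertices < 3:
        raise ValueError("need at least three vertices")
    X = ts.data
    sd = X.std(axis=1)
    constant = sd == 0
    if constant.any():
        warnings.warn(f"{int(constant.sum())} constant vertex series masked "
                      "in the correlation graph")
    with np.errstate(invalid="ignore", divide="ignore"):
        C = np.corrcoef(np.where(constant[:, None], 0.0, X))
    C = np.clip(np.nan_to_num(C, nan=0.0), -1.0, 1.0)
    A = fisher_z(C)
    A[constant, :] = 0.0
    A[:, constant] = 0.0
    np.fill_diagonal(A, 0.0)
    return (A + A.T) / 2.0


def density_threshold(A: np.ndarray, density: float = 0.05,
                      subject_id: str = "", session_id: str = ""
                      ) -> ConnectomeGraph:
    """Keep the floor(density * V(V-1)/2) largest-weight undirected edges.

    The threshold retains the most-positive Fisher-z weights (the upper
    tail); ties at the cutoff are broken by lexicographic (i, j) order so
    the graph is bit-reproducible.
    """
    if not (0 < density <= 1):
        raise ValueError("density must be in (0, 1]")
    A = np.asarray(A, dtype=np.float64)
    V = A.shape[0]
    if A.shape != (V, V):
        raise ValueError("adjacency must be square")
    n_pairs = V * (V - 1) // 2
    m = int(np.floor(density * n_pairs))
    if m < 1:
        raise ValueError(f"density {density} retains no edge for V={V}")

    iu, ju = np.triu_indices(V, k=1)
    w = A[iu, ju]
    # sort by (-weight, i, j): deterministic tie-break at the cutoff
    order = np.lexsort((ju, iu, -w))[:m]
    ri, rj, rw = iu[order], ju[order], w[order]

    rows = np.concatenate([ri, rj])
    cols = np.concatenate([rj, ri])
    vals = np.concatenate([rw, rw])
    G = csr_matrix((vals, (rows, cols)), shape=(V, V))
    return ConnectomeGraph(weights=G, density=m / n_pairs, n_edges=m,
                           subject_id=subject_id, session_id=session_id)


def degree_centrality(g: ConnectomeGraph) -> MetricMap:
    """Weighted degree: sum of retained edge weights at each vertex."""
    dcw = np.asarray(g.weights.sum(axis=1)).ravel()
    return MetricMap(values=dcw, metric="DCw",
                     subject_id=g.subject_id, session_id=g.session_id,
                     meta={"density": g.density, "n_edges": g.n_edges})


def eigenvector_centrality(g: ConnectomeGraph, tol: float = 1e-10,
                           max_iter: int = 10_000) -> MetricMap:
    """Principal eigenvector of the adjacency by power iteration.

    Computed on the largest connected component (other vertices get 0,
    logged); the result is unit-norm with non-negative entries — guaranteed
    strictly positive on the component by Perron-Frobenius when weights are
    non-negative.  Convergence is checked against the eigen-residual
    ||A x - lambda x|| / lambda.
    """
    V = g.n_vertices
    n_comp, labels = connected_components(g.weights, directed=False)
    sizes = np.bincount(labels, minlength=n_comp)
    main = int(np.argmax(sizes))
    if sizes[main] < V:
        logger.info("eigenvector centrality: restricting to largest "
                    "component (%d of %d vertices)", sizes[main], V)
    idx = np.nonzero(labels == main)[0]
    A = g.weights[np.ix_(idx, idx)].toarray()
    n = idx.size
    if n < 2:
        raise ValueError("largest component has fewer than two vertices")

    x = np.full(n, 1.0 / np.sqrt(n))     # deterministic uniform start
    lam = 0.0
    for _ in range(max_iter):
        y = A @ x
        lam = float(np.linalg.norm(y))
        if lam == 0:
            raise ValueError("zero adjacency on the main component")
        y /= lam
        if np.linalg.norm(A @ y - lam * y) / lam < tol:
            x = y
            break
        x = y
    else:
        resid = float(np.linalg.norm(A @ x - lam * x) / lam)
        raise RuntimeError(f"power iteration did not converge "
                           f"(residual {resid:.2e})")
    if x.sum() < 0:
        x = -x
    x = np.clip(x, 0.0, None)
    x /= np.linalg.norm(x)
    ec = np.zeros(V)
    ec[idx] = x
    return MetricMap(values=ec, metric="ECw",
                     subject_id=g.subject_id, session_id=g.session_id,
                     meta={"density": g.density, "lambda1": lam,
                           "component_size": int(n)})
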