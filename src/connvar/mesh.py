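"""Triangulated surface meshes and vertex neighborhoods.

An icosphere stands in for the cortical surface grid: subdividing an
icosahedron n times gives 10*4**n + 2 vertices, all of valence 6 except the
12 original icosahedral vertices (valence 5).  Five subdivisions match the
10,242 vertices of one fsaverage5 hemisphere.  Regional homogeneity uses the
one-ring (K = 7 at a regular vertex, center included) or two-ring (K = 19)
neighborhood of each vertex.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Set

import numpy as np
import trimesh
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components


@dataclass
class SurfaceMesh:
    """Triangle mesh with symmetric, irreflexive vertex adjacency."""

    coordinates: np.ndarray          # V x 3 (unit sphere for icospheres)
    triangles: np.ndarray            # F x 3 integer vertex indices
    adjacency: List[Set[int]] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=np.float64)
        self.triangles = np.asarray(self.triangles, dtype=np.int64)
        V = self.coordinates.shape[0]
        if self.triangles.size and (self.triangles.min() < 0
                                    or self.triangles.max() >= V):
            raise ValueError("triangle references a vertex outside the mesh")
        if self.adjacency is None:
            self.adjacency = self._adjacency_from_triangles()

    def _adjacency_from_triangles(self) -> List[Set[int]]:
        adj: List[Set[int]] = [set() for _ in range(self.vertex_count)]
        for a, b, c in self.triangles:
            adj[a].update((b, c))
            adj[b].update((a, c))
            adj[c].update((a, b))
        for i, nb in enumerate(adj):
            nb.discard(i)
        return adj

    @property
    def vertex_count(self) -> int:
        return self.coordinates.shape[0]

    def adjacency_matrix(self) -> csr_matrix:
        rows, cols = [], []
        for i, nb in enumerate(self.adjacency):
            for j in nb:
                rows.append(i)
                cols.append(j)
        data = np.ones(len(rows))
        return csr_matrix((data, (rows, cols)),
                          shape=(self.vertex_count, self.vertex_count))

    def is_connected(self) -> bool:
        n, _ = connected_components(self.adjacency_matrix(), directed=False)
        return n == 1

    def vertex_valences(self) -> np.ndarray:
        return np.array([len(nb) for nb in self.adjacency])


def build_icosphere(subdivisions: int) -> SurfaceMesh:
    """Icosahedron subdivided ``subdivisions`` times, on the unit sphere.

    Vertex count is 10*4**n + 2; exactly 12 vertices have valence 5 and the
    rest valence 6.
    """
    if not (0 <= int(subdivisions) <= 6):
        raise ValueError("subdivisions must be between 0 and 6")
    m = trimesh.creation.icosphere(subdivisions=int(subdivisions), radius=1.0)
    return SurfaceMesh(coordinates=np.asarray(m.vertices),
                       triangles=np.asarray(m.faces))


def ring_neighborhood(mesh: SurfaceMesh, vertex: int, rings: int) -> Set[int]:
    """Vertex plus its 1-ring, or additionally its 2-ring, neighbors.

    On a regular (valence-6) vertex rings=1 gives K = 7 members and rings=2
    gives K = 19; the paper's fsaverage5 figures of 7 and 20 depend on that
    surface's slightly irregular adjacency.
    """
    if rings not in (1, 2):
        raise ValueError("rings must be 1 or 2")
    if not (0 <= vertex < mesh.vertex_count):
        raise IndexError(f"vertex {vertex} outside mesh")
    members = {vertex} | mesh.adjacency[vertex]
    if rings == 2:
        second = set()
        for v in list(members):
            second |= mesh.adjacency[v]
        members |= second
    return members


def neighborhood_indicator(mesh: SurfaceMesh, rings: int) -> csr_matrix:
    """Sparse V x V 0/1 matrix whose row v marks ring_neighborhood(v)."""
    rows, cols = [], []
    for v in range(mesh.vertex_count):
        for j in sorted(ring_neighborhood(mesh, v, rings)):
            rows.append(v)
            cols.append(j)
    data = np.ones(len(rows))
    return csr_matrix((data, (rows, cols)),
                      shape=(mesh.vertex_count, mesh.vertex_count))
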