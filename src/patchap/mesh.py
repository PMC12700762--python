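"""Triangulated source-space geometry and graph-smoothing operators.

The source space is a triangle mesh whose vertices are candidate dipole
locations (coordinates in mm).  Spatial structure enters the model only
through the vertex-adjacency graph: the combinatorial Laplacian ``L = D - A``
drives a diffusion smoother ``K = I - alpha*L``, and a source *patch* is the
set of vertices within a given number of graph hops (the *extent*) of a seed
vertex.  Extent 0 is a point source.

All vertex and face indices are 0-based, in memory and on disk.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import dijkstra

__all__ = [
    "TriangleMesh",
    "Patch",
    "build_adjacency",
    "mesh_laplacian",
    "smoothing_operator",
    "patch_members",
    "patch_basis",
    "graph_distances",
]


@dataclass(frozen=True)
class Patch:
    """A candidate source patch: a seed vertex plus its graph neighborhood.

    ``members`` holds every vertex within ``extent`` hops of ``seed``,
    ordered by (hop distance, vertex index) so downstream selection matrices
    and SVDs are reproducible.
    """

    seed: int
    extent: int
    members: np.ndarray

    def __post_init__(self) -> None:
        members = np.asarray(self.members, dtype=np.intp)
        object.__setattr__(self, "members", members)
        if members.size == 0 or members[0] != self.seed:
            raise ValueError("patch members must start with the seed vertex")
        if np.unique(members).size != members.size:
            raise ValueError("patch members must be unique")

    @property
    def size(self) -> int:
        return int(self.members.size)


def build_adjacency(faces: np.ndarray, k: int) -> sp.csr_matrix:
    """Binary vertex adjacency of a triangulation: A[i, j] = 1 iff vertices
    i and j share an edge of some face.  Symmetric, zero diagonal."""
    faces = np.asarray(faces, dtype=np.intp)
    if faces.ndim != 2 or faces.shape[1] != 3:
        raise ValueError("faces must be an (n, 3) integer array")
    if faces.size and (faces.min() < 0 or faces.max() >= k):
        raise ValueError(f"face index out of range [0, {k})")
    if np.any(
        (faces[:, 0] == faces[:, 1])
        | (faces[:, 1] == faces[:, 2])
        | (faces[:, 0] == faces[:, 2])
    ):
        raise ValueError("degenerate face (repeated vertex index)")
    rows = faces[:, [0, 1, 2]].ravel()
    cols = faces[:, [1, 2, 0]].ravel()
    data = np.ones(rows.size)
    adj = sp.coo_matrix((data, (rows, cols)), shape=(k, k))
    adj = adj + adj.T
    adj.data[:] = 1.0  # collapse duplicate edges shared by two faces
    return adj.tocsr()


def mesh_laplacian(adjacency: sp.spmatrix) -> sp.csr_matrix:
    """Combinatorial graph Laplacian L = D - A (rows sum to zero, PSD)."""
    adjacency = sp.csr_matrix(adjacency)
    degree = np.asarray(adjacency.sum(axis=1)).ravel()
    return (sp.diags(degree) - adjacency).tocsr()


def smoothing_operator(laplacian: sp.spmatrix, alpha: float) -> sp.csr_matrix:
    """Diffusion smoother K = I - alpha*L.

    ``alpha`` in (0, 1) is the diffusion step; rows of K always sum to one.
    K is a proper (nonnegative) averaging operator only for
    alpha <= 1/max_degree; larger values are accepted per the model contract
    but act as sharpeners on high-degree graphs.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    laplacian = sp.csr_matrix(laplacian)
    k = laplacian.shape[0]
    return (sp.identity(k, format="csr") - alpha * laplacian).tocsr()


def graph_distances(
    adjacency: sp.spmatrix, seeds, limit: float = np.inf
) -> np.ndarray:
    """Hop distances from each seed to every vertex (inf beyond ``limit``)."""
    return dijkstra(
        sp.csr_matrix(adjacency), directed=False, unweighted=True,
        indices=seeds, limit=limit,
    )


def patch_members(adjacency: sp.spmatrix, seed: int, extent: int) -> Patch:
    """All vertices within ``extent`` hops of ``seed`` (breadth-first),
    ordered by (distance, vertex index)."""
    k = adjacency.shape[0]
    if not 0 <= seed < k:
        raise ValueError(f"seed {seed} out of range [0, {k})")
    if extent < 0 or int(extent) != extent:
        raise ValueError("extent must be a non-negative integer")
    if extent == 0:
        return Patch(seed=int(seed), extent=0, members=np.array([seed]))
    dist = graph_distances(adjacency, int(seed), limit=extent)
    idx = np.flatnonzero(dist <= extent)
    order = np.lexsort((idx, dist[idx]))
    return Patch(seed=int(seed), extent=int(extent), members=idx[order])


def patch_basis(members: np.ndarray, k: int) -> sp.csr_matrix:
    """Selection matrix E (k x d): column j is the standard basis vector of
    member j, so E'E = I and E scatters patch-local signals onto the mesh."""
    members = np.asarray(members, dtype=np.intp)
    if np.unique(members).size != members.size:
        raise ValueError("duplicate patch members")
    if members.size and (members.min() < 0 or members.max() >= k):
        raise ValueError("member index out of range")
    d = members.size
    return sp.csr_matrix(
        (np.ones(d), (members, np.arange(d))), shape=(k, d)
    )


@dataclass(frozen=True)
class TriangleMesh:
    """Triangulated cortical source space.

    vertices : (k, 3) float array, coordinates in mm
    faces    : (f, 3) int array of vertex triples, 0-based
    """

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self) -> None:
        vertices = np.asarray(self.vertices, dtype=float)
        faces = np.asarray(self.faces, dtype=np.intp)
        if vertices.ndim != 2 or vertices.shape[1] != 3:
            raise ValueError("vertices must be (k, 3)")
        if not np.all(np.isfinite(vertices)):
            raise ValueError("non-finite vertex coordinate")
        object.__setattr__(self, "vertices", vertices)
        object.__setattr__(self, "faces", faces)
        # validates index range / degeneracy eagerly
        build_adjacency(faces, vertices.shape[0])

    @property
    def n_vertices(self) -> int:
        return int(self.vertices.shape[0])

    @cached_property
    def adjacency(self) -> sp.csr_matrix:
        return build_adjacency(self.faces, self.n_vertices)

    @cached_property
    def degree(self) -> np.ndarray:
        return np.asarray(self.adjacency.sum(axis=1)).ravel().astype(int)

    @cached_property
    def laplacian(self) -> sp.csr_matrix:
        return mesh_laplacian(self.adjacency)

    def smoothing_operator(self, alpha: float) -> sp.csr_matrix:
        return smoothing_operator(self.laplacian, alpha)

    def patch(self, seed: int, extent: int) -> Patch:
        return patch_members(self.adjacency, seed, extent)

    def patch_area_mm2(self, patch: Patch) -> float:
        """Total area of faces whose vertices all lie inside the patch."""
        mask = np.zeros(self.n_vertices, dtype=bool)
        mask[patch.members] = True
        inside = mask[self.faces].all(axis=1)
        tri = self.vertices[self.faces[inside]]
        cross = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        return float(0.5 * np.linalg.norm(cross, axis=1).sum())
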