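"""Spherical surface meshes.

The substrate for all vertex-level computation is a triangulated sphere of
unit radius, the registration space in which surface-based morphometry
operates.  Hemispheres are kept as separate spheres; a
:class:`CorticalSurface` bundles one or two hemisphere meshes and exposes a
single concatenated vertex space (block-diagonal adjacency, so nothing ever
"smooths across" the inter-hemispheric gap).

Physical units enter through ``scale``: vertex coordinates stay on the unit
sphere while areas and edge lengths are reported in ``scale``-radius units
(a scale of 100 mimics a FreeSurfer-style 100 mm registration sphere, giving
areas in mm²).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import trimesh

from .exceptions import InvalidGeometryError, InvalidMeshError

_UNIT_TOL = 1e-9


def geodesic_distance(a: np.ndarray, b: np.ndarray) -> float | np.ndarray:
    """Great-circle distance (radians) between unit vectors.

    Broadcasts over leading axes; the last axis must be length 3.
    Raises :class:`InvalidGeometryError` if either input leaves the unit
    sphere by more than 1e-9.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    for v in (a, b):
        norms = np.linalg.norm(v, axis=-1)
        if not np.allclose(norms, 1.0, atol=1e-9, rtol=0.0):
            raise InvalidGeometryError(
                f"point not on the unit sphere (|norm-1| up to {np.abs(norms - 1).max():.3g})"
            )
    dots = np.clip(np.sum(a * b, axis=-1), -1.0, 1.0)
    out = np.arccos(dots)
    return float(out) if out.ndim == 0 else out


def pairwise_geodesic(points: np.ndarray) -> np.ndarray:
    """All-pairs great-circle distance matrix for (n, 3) unit vectors."""
    points = np.asarray(points, dtype=float)
    gram = np.clip(points @ points.T, -1.0, 1.0)
    return np.arccos(gram)


def _face_edges(faces: np.ndarray) -> np.ndarray:
    """Undirected edge list (with duplicates) from a face array."""
    return np.concatenate([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])


@dataclass
class SphereMesh:
    """Triangulated unit sphere for one hemisphere.

    Parameters
    ----------
    vertices : (V, 3) float array of unit vectors.
    faces : (F, 3) int array of vertex index triples.
    hemisphere : "left" or "right".
    scale : sphere radius in physical units (mm); areas/edge lengths scale
        as ``scale**2`` / ``scale``.
    """

    vertices: np.ndarray
    faces: np.ndarray
    hemisphere: str = "left"
    scale: float = 1.0
    _adjacency: sp.csr_matrix | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.hemisphere not in ("left", "right"):
            raise InvalidMeshError(f"unknown hemisphere label {self.hemisphere!r}")
        norms = np.linalg.norm(self.vertices, axis=1)
        if not np.allclose(norms, 1.0, atol=_UNIT_TOL, rtol=0.0):
            raise InvalidGeometryError("mesh vertices must have unit norm within 1e-9")
        if self.faces.size:
            if self.faces.min() < 0 or self.faces.max() >= len(self.vertices):
                raise InvalidMeshError("face references a vertex index out of range")
            same = (
                (self.faces[:, 0] == self.faces[:, 1])
                | (self.faces[:, 1] == self.faces[:, 2])
                | (self.faces[:, 0] == self.faces[:, 2])
            )
            if same.any():
                raise InvalidMeshError(
                    f"degenerate face with repeated vertex at rows {np.nonzero(same)[0][:5].tolist()}"
                )

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def adjacency(self) -> sp.csr_matrix:
        """Symmetric 0/1 vertex adjacency derived from shared face edges."""
        if self._adjacency is None:
            edges = _face_edges(self.faces)
            n = self.n_vertices
            m = sp.coo_matrix(
                (np.ones(len(edges)), (edges[:, 0], edges[:, 1])), shape=(n, n)
            ).tocsr()
            m = ((m + m.T) > 0).astype(np.float64)
            m.setdiag(0)
            m.eliminate_zeros()
            self._adjacency = m.tocsr()
        return self._adjacency

    def neighbors(self, vertex: int) -> np.ndarray:
        """Indices of vertices sharing an edge with ``vertex``."""
        a = self.adjacency
        return a.indices[a.indptr[vertex] : a.indptr[vertex + 1]]

    @property
    def face_areas(self) -> np.ndarray:
        """Flat-triangle areas in physical units (scale²·mesh units)."""
        v = self.vertices
        a, b, c = v[self.faces[:, 0]], v[self.faces[:, 1]], v[self.faces[:, 2]]
        cross = np.cross(b - a, c - a)
        return 0.5 * np.linalg.norm(cross, axis=1) * self.scale**2

    @property
    def vertex_areas(self) -> np.ndarray:
        """Per-vertex area: one third of each incident triangle's area."""
        fa = self.face_areas / 3.0
        out = np.zeros(self.n_vertices)
        for k in range(3):
            np.add.at(out, self.faces[:, k], fa)
        return out

    @property
    def total_area(self) -> float:
        return float(self.face_areas.sum())

    def edge_lengths(self) -> np.ndarray:
        """Unique-edge geodesic lengths in physical units."""
        edges = _face_edges(self.faces)
        edges = np.unique(np.sort(edges, axis=1), axis=0)
        return geodesic_distance(self.vertices[edges[:, 0]], self.vertices[edges[:, 1]]) * self.scale

    def mean_edge_length(self) -> float:
        return float(self.edge_lengths().mean())


def vertex_neighbors(mesh: SphereMesh) -> list[np.ndarray]:
    """Neighbor index arrays for every vertex (edge adjacency)."""
    return [mesh.neighbors(i) for i in range(mesh.n_vertices)]


def make_icosphere(level: int, hemisphere: str = "left", scale: float = 1.0) -> SphereMesh:
    """Recursively subdivided icosahedron projected to the unit sphere.

    Level L has 10·4^L + 2 vertices and 20·4^L faces.
    """
    if level < 0:
        raise InvalidMeshError("subdivision level must be non-negative")
    ico = trimesh.creation.icosphere(subdivisions=level, radius=1.0)
    verts = np.asarray(ico.vertices, dtype=float)
    verts /= np.linalg.norm(verts, axis=1, keepdims=True)
    return SphereMesh(verts, np.asarray(ico.faces, dtype=np.int64), hemisphere, scale)


class CorticalSurface:
    """One or two hemisphere meshes presented as a single vertex space.

    Vertex indices are offsets into the concatenation (left first), and the
    combined adjacency is block diagonal so connected components never span
    hemispheres.
    """

    def __init__(self, meshes: list[SphereMesh] | tuple[SphereMesh, ...] | SphereMesh):
        if isinstance(meshes, SphereMesh):
            meshes = [meshes]
        if not meshes:
            raise InvalidMeshError("a surface needs at least one hemisphere mesh")
        labels = [m.hemisphere for m in meshes]
        if len(set(labels)) != len(labels):
            raise InvalidMeshError("duplicate hemisphere label in surface")
        self.meshes = list(meshes)
        self.offsets = np.cumsum([0] + [m.n_vertices for m in self.meshes])

    @classmethod
    def bilateral(cls, level: int, scale: float = 1.0) -> "CorticalSurface":
        return cls([make_icosphere(level, "left", scale), make_icosphere(level, "right", scale)])

    @property
    def n_vertices(self) -> int:
        return int(self.offsets[-1])

    @property
    def hemispheres(self) -> list[str]:
        return [m.hemisphere for m in self.meshes]

    @property
    def vertex_hemisphere(self) -> np.ndarray:
        """Hemisphere label per concatenated vertex."""
        return np.concatenate(
            [np.full(m.n_vertices, m.hemisphere, dtype=object) for m in self.meshes]
        )

    @property
    def vertices(self) -> np.ndarray:
        return np.concatenate([m.vertices for m in self.meshes])

    @property
    def adjacency(self) -> sp.csr_matrix:
        return sp.block_diag([m.adjacency for m in self.meshes], format="csr")

    @property
    def vertex_areas(self) -> np.ndarray:
        return np.concatenate([m.vertex_areas for m in self.meshes])

    def mean_edge_length(self) -> float:
        return float(np.concatenate([m.edge_lengths() for m in self.meshes]).mean())

    def hemi_slice(self, hemisphere: str) -> slice:
        i = self.hemispheres.index(hemisphere)
        return slice(int(self.offsets[i]), int(self.offsets[i + 1]))


SurfaceLike = SphereMesh | CorticalSurface


def as_surface(mesh: SurfaceLike) -> CorticalSurface:
    return mesh if isinstance(mesh, CorticalSurface) else CorticalSurface(mesh)
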