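"""Cortical parcellation atlases.

A :class:`ParcelAtlas` is the bridge between vertex space (where the GLM
runs) and region space (where network mapping runs): each region carries a
spherical centroid — the quantity the spin-permutation null rotates — and,
optionally, the assignment of mesh vertices to regions used to aggregate
vertex statistics into region tables.

``make_atlas`` grows contiguous, roughly equal-sized parcels on an arbitrary
sphere mesh by farthest-point seeding followed by geodesic Voronoi
assignment with a few Lloyd refinement sweeps — a synthetic stand-in for an
anatomical parcellation such as Desikan–Killiany (34 regions per
hemisphere).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.csgraph as csgraph

from .exceptions import InvalidGeometryError, InvalidMeshError, UndefinedRegionError
from .geometry import SphereMesh, SurfaceLike, as_surface


@dataclass
class ParcelAtlas:
    """Region table with spherical centroids and optional vertex assignment.

    ``centroid`` rows are unit vectors on each region's hemisphere sphere.
    ``vertex_assignment`` (optional) maps every concatenated surface vertex
    to a region index (0-based, matching row order here).
    """

    region_ids: np.ndarray
    region_names: list[str]
    hemispheres: np.ndarray  # "left"/"right" per region
    centroids: np.ndarray  # (R, 3) unit vectors
    vertex_assignment: np.ndarray | None = None
    surface: SurfaceLike | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.region_ids = np.asarray(self.region_ids, dtype=np.int64)
        self.hemispheres = np.asarray(self.hemispheres, dtype=object)
        self.centroids = np.asarray(self.centroids, dtype=float)
        if len(np.unique(self.region_ids)) != len(self.region_ids):
            raise UndefinedRegionError("region ids must be unique")
        norms = np.linalg.norm(self.centroids, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9, rtol=0.0):
            raise InvalidGeometryError("atlas centroids must have unit norm within 1e-9")
        if self.vertex_assignment is not None:
            self.vertex_assignment = np.asarray(self.vertex_assignment, dtype=np.int64)
            if self.vertex_assignment.min() < 0 or self.vertex_assignment.max() >= self.n_regions:
                raise UndefinedRegionError("vertex assigned to a non-existent region")

    @property
    def n_regions(self) -> int:
        return len(self.region_ids)

    def hemi_mask(self, hemisphere: str) -> np.ndarray:
        return self.hemispheres == hemisphere


def _geodesic_sources_distances(mesh: SphereMesh, sources: np.ndarray) -> np.ndarray:
    """(n_sources, V) graph-geodesic distances along mesh edges."""
    adj = mesh.adjacency.tocoo()
    w = np.arccos(
        np.clip(np.sum(mesh.vertices[adj.row] * mesh.vertices[adj.col], axis=1), -1, 1)
    )
    g = sp.csr_matrix((w, (adj.row, adj.col)), shape=adj.shape)
    return csgraph.dijkstra(g, directed=False, indices=sources)


def _spherical_mean(points: np.ndarray, fallback: np.ndarray) -> np.ndarray:
    """Normalised Euclidean mean; a region covering a whole sphere has a
    near-zero mean, in which case its seed direction stands in."""
    mean = points.mean(axis=0)
    norm = np.linalg.norm(mean)
    if norm < 1e-9:
        return fallback / np.linalg.norm(fallback)
    return mean / norm


def _farthest_point_seeds(mesh: SphereMesh, k: int, rng: np.random.Generator) -> np.ndarray:
    seeds = [int(rng.integers(mesh.n_vertices))]
    dist = _geodesic_sources_distances(mesh, np.array(seeds))[0]
    for _ in range(k - 1):
        nxt = int(np.argmax(dist))
        seeds.append(nxt)
        dist = np.minimum(dist, _geodesic_sources_distances(mesh, np.array([nxt]))[0])
    return np.asarray(seeds)


def _repair_contiguity(mesh: SphereMesh, labels: np.ndarray) -> np.ndarray:
    """Reassign vertices of any secondary connected fragment to the
    neighboring majority label (graph Voronoi cells are almost always
    connected already; ties can strand single vertices)."""
    adj = mesh.adjacency
    for r in np.unique(labels):
        idx = np.nonzero(labels == r)[0]
        sub = adj[idx][:, idx]
        n_comp, comp = csgraph.connected_components(sub, directed=False)
        if n_comp <= 1:
            continue
        sizes = np.bincount(comp)
        main = np.argmax(sizes)
        for v in idx[comp != main]:
            neigh_labels = labels[mesh.neighbors(v)]
            neigh_labels = neigh_labels[neigh_labels != r]
            if neigh_labels.size:
                labels[v] = np.bincount(neigh_labels).argmax()
    return labels


def make_atlas(
    surface: SurfaceLike,
    n_regions_per_hemisphere: int,
    seed: int | np.random.Generator = 0,
    n_lloyd: int = 3,
) -> ParcelAtlas:
    """Grow a contiguous geodesic parcellation on each hemisphere.

    Farthest-point sampling picks well-spread seed vertices; each vertex is
    assigned to its geodesically nearest seed; ``n_lloyd`` sweeps re-center
    seeds at the vertex nearest each region's spherical mean.
    """
    surface = as_surface(surface)
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    ids, names, hemis, cents, assign = [], [], [], [], []
    region_offset = 0
    for mesh in surface.meshes:
        k = n_regions_per_hemisphere
        if k < 1 or k > mesh.n_vertices:
            raise InvalidMeshError(
                f"cannot place {k} regions on a {mesh.n_vertices}-vertex hemisphere"
            )
        seeds = _farthest_point_seeds(mesh, k, rng)
        for _ in range(max(1, n_lloyd)):
            dist = _geodesic_sources_distances(mesh, seeds)
            if np.isinf(dist).any():
                raise InvalidMeshError("mesh is disconnected; vertices unreachable from seeds")
            labels = np.argmin(dist, axis=0)
            new_seeds = seeds.copy()
            for r in range(k):
                members = np.nonzero(labels == r)[0]
                if members.size == 0:
                    continue
                mean = _spherical_mean(mesh.vertices[members], mesh.vertices[seeds[r]])
                new_seeds[r] = members[np.argmax(mesh.vertices[members] @ mean)]
            if np.array_equal(new_seeds, seeds):
                break
            seeds = new_seeds
        labels = _repair_contiguity(mesh, labels)
        for r in range(k):
            members = np.nonzero(labels == r)[0]
            if members.size == 0:
                raise UndefinedRegionError(f"region {r} ended up with no vertices")
            cents.append(_spherical_mean(mesh.vertices[members], mesh.vertices[seeds[r]]))
            ids.append(region_offset + r)
            names.append(f"{mesh.hemisphere[0]}h_parcel_{r:02d}")
            hemis.append(mesh.hemisphere)
        assign.append(labels + region_offset)
        region_offset += k
    return ParcelAtlas(
        region_ids=np.asarray(ids),
        region_names=names,
        hemispheres=np.asarray(hemis, dtype=object),
        centroids=np.asarray(cents),
        vertex_assignment=np.concatenate(assign),
        surface=surface,
    )


def parcel_means(
    values: np.ndarray,
    atlas: ParcelAtlas,
    vertex_areas: np.ndarray | None = None,
    weighted: bool = True,
) -> np.ndarray:
    """Aggregate a per-vertex map (or subjects × vertices matrix) to regions.

    Area-weighted mean by default (volume is extensive over surface area);
    pass ``weighted=False`` for the plain arithmetic mean.  Output columns
    follow atlas region order.
    """
    if atlas.vertex_assignment is None:
        raise UndefinedRegionError("atlas has no vertex assignment; cannot aggregate")
    values = np.asarray(values, dtype=float)
    one_d = values.ndim == 1
    mat = values[None, :] if one_d else values
    if mat.shape[1] != len(atlas.vertex_assignment):
        raise UndefinedRegionError(
            f"map has {mat.shape[1]} vertices but atlas assigns {len(atlas.vertex_assignment)}"
        )
    if weighted:
        if vertex_areas is None:
            if atlas.surface is None:
                raise UndefinedRegionError("area-weighted mean needs vertex areas or a surface")
            vertex_areas = as_surface(atlas.surface).vertex_areas
        w = np.asarray(vertex_areas, dtype=float)
    else:
        w = np.ones(mat.shape[1])
    denom = np.bincount(atlas.vertex_assignment, weights=w, minlength=atlas.n_regions)
    if (denom == 0).any():
        empty = np.nonzero(denom == 0)[0]
        raise UndefinedRegionError(f"regions with no assigned vertices: {empty.tolist()}")
    weights = sp.csr_matrix(
        (w, (atlas.vertex_assignment, np.arange(mat.shape[1]))),
        shape=(atlas.n_regions, mat.shape[1]),
    )
    out = (weights @ mat.T).T / denom
    return out[0] if one_d else out
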