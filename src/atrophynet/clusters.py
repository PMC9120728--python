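"""Cluster-wise inference on surface statistic maps.

Suprathreshold vertices (uncorrected p below a vertex-wise threshold,
conventionally 0.001) are grouped into edge-connected, same-sign clusters
whose size is the summed vertex area.  Family-wise error is controlled by a
Monte Carlo reference distribution: smooth Gaussian null fields are
simulated on the same mesh with the analysis FWHM, thresholded identically,
and the maximum null cluster size recorded per iteration.  A cluster's
corrected p-value is the add-one-corrected fraction of null maxima at least
as large.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse.csgraph as csgraph
import scipy.stats as st

from .exceptions import ConfigurationError, InvalidParameterError
from .geometry import SurfaceLike, as_surface
from .glm import StatMap
from .smoothing import smooth_surface, smoothed_vertex_sd


@dataclass
class ClusterResult:
    """One edge-connected suprathreshold cluster."""

    cluster_id: int
    vertices: np.ndarray
    size: float  # summed vertex area, surface units
    sign: int  # +1 / -1 effect direction
    peak_vertex: int
    peak_stat: float
    p_cluster: float | None = None

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)


@dataclass
class NullClusterDistribution:
    """Monte Carlo maxima of null cluster sizes, with the settings used."""

    max_sizes: np.ndarray
    fwhm: float
    vertex_p_threshold: float
    seed: int | None
    df: int | None = None  # recorded for audit; the reference field is normal

    def __post_init__(self) -> None:
        self.max_sizes = np.asarray(self.max_sizes, dtype=float)
        if (self.max_sizes < 0).any():
            raise InvalidParameterError("null cluster sizes must be non-negative")

    @property
    def n_iter(self) -> int:
        return len(self.max_sizes)


def _components(mask: np.ndarray, adjacency) -> list[np.ndarray]:
    """Connected components of the suprathreshold vertex subgraph."""
    idx = np.nonzero(mask)[0]
    if idx.size == 0:
        return []
    sub = adjacency[idx][:, idx]
    n_comp, labels = csgraph.connected_components(sub, directed=False)
    return [idx[labels == c] for c in range(n_comp)]


def extract_clusters(
    stats: StatMap,
    surface: SurfaceLike,
    vertex_p_threshold: float = 0.001,
) -> list[ClusterResult]:
    """Edge-connected same-sign clusters of suprathreshold vertices.

    Ordered by descending size (ties by lowest member vertex index); sizes
    are summed vertex areas.
    """
    if not 0 < vertex_p_threshold < 1:
        raise InvalidParameterError(
            f"vertex_p_threshold must be in (0, 1), got {vertex_p_threshold}"
        )
    surf = as_surface(surface)
    areas = surf.vertex_areas
    adjacency = surf.adjacency
    supra = stats.p < vertex_p_threshold
    raw: list[ClusterResult] = []
    for sign in (1, -1):
        for comp in _components(supra & (sign * stats.t > 0), adjacency):
            peak = comp[np.argmax(np.abs(stats.t[comp]))]
            raw.append(
                ClusterResult(
                    cluster_id=-1,
                    vertices=np.sort(comp),
                    size=float(areas[comp].sum()),
                    sign=sign,
                    peak_vertex=int(peak),
                    peak_stat=float(stats.t[peak]),
                )
            )
    raw.sort(key=lambda c: (-c.size, int(c.vertices[0])))
    for i, c in enumerate(raw):
        c.cluster_id = i
    return raw


def simulate_null_clusters(
    surface: SurfaceLike,
    fwhm: float,
    vertex_p_threshold: float,
    n_iter: int,
    seed: int | np.random.Generator | None = None,
    df: int | None = None,
    batch: int = 200,
) -> NullClusterDistribution:
    """Monte Carlo distribution of the maximum null cluster size.

    Each iteration draws an independent standard-normal field on the mesh
    vertices, smooths it with the analysis FWHM, renormalises to unit
    vertex variance, converts to two-sided normal p-values, and records the
    largest cluster size at the vertex threshold (0 when nothing survives).
    """
    if n_iter < 1:
        raise InvalidParameterError("n_iter must be at least 1")
    if not 0 < vertex_p_threshold < 1:
        raise InvalidParameterError("vertex_p_threshold must be in (0, 1)")
    surf = as_surface(surface)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    areas = surf.vertex_areas
    adjacency = surf.adjacency
    sd = smoothed_vertex_sd(surf, fwhm)
    # p < thr  <=>  |z| > z_crit under the standard normal reference
    z_crit = st.norm.isf(vertex_p_threshold / 2.0)
    maxima = np.zeros(n_iter)
    done = 0
    while done < n_iter:
        b = min(batch, n_iter - done)
        z = rng.standard_normal((surf.n_vertices, b))
        z = smooth_surface(z.T, surf, fwhm).T / sd[:, None]
        supra = np.abs(z) > z_crit
        for j in range(b):
            best = 0.0
            for sign in (1, -1):
                for comp in _components(supra[:, j] & (sign * z[:, j] > 0), adjacency):
                    best = max(best, float(areas[comp].sum()))
            maxima[done + j] = best
        done += b
    seed_int = seed if isinstance(seed, (int, np.integer)) else None
    return NullClusterDistribution(maxima, fwhm, vertex_p_threshold, seed_int, df)


def permutation_null_clusters(
    data,
    cohort,
    design,
    surface: SurfaceLike,
    vertex_p_threshold: float,
    n_iter: int,
    seed: int | np.random.Generator | None = None,
    fwhm: float = 0.0,
) -> NullClusterDistribution:
    """Alternative null: permute the effect column across subjects.

    Instead of simulating smooth Gaussian fields, each iteration shuffles
    the effect values (severity scores or group labels) over subjects,
    refits the vertex-wise GLM, and records the maximum cluster size.
    ``data`` should be the same (already smoothed) matrix the analysis
    used; ``fwhm`` is stored as metadata so :func:`cluster_pvalue` can
    verify the match.  Naive effect permutation; nuisance covariates stay
    attached to their subjects.
    """
    from .glm import VertexGLM

    if n_iter < 1:
        raise InvalidParameterError("n_iter must be at least 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    surf = as_surface(surface)
    areas = surf.vertex_areas
    adjacency = surf.adjacency
    model = VertexGLM(data, cohort, design)
    X, Y = model.X.copy(), model.Y
    n, p = X.shape
    df = n - p
    t_crit = st.t.isf(vertex_p_threshold / 2.0, df)
    maxima = np.zeros(n_iter)
    for it in range(n_iter):
        X[:, 1] = X[rng.permutation(n), 1]
        xtx_inv = np.linalg.inv(X.T @ X)
        beta = xtx_inv @ X.T @ Y
        resid = Y - X @ beta
        sigma2 = np.einsum("ij,ij->j", resid, resid) / df
        with np.errstate(divide="ignore", invalid="ignore"):
            t = beta[1] / np.sqrt(np.maximum(sigma2 * xtx_inv[1, 1], 1e-300))
        supra = np.abs(t) > t_crit
        best = 0.0
        for sign in (1, -1):
            for comp in _components(supra & (sign * t > 0), adjacency):
                best = max(best, float(areas[comp].sum()))
        maxima[it] = best
    seed_int = seed if isinstance(seed, (int, np.integer)) else None
    return NullClusterDistribution(maxima, fwhm, vertex_p_threshold, seed_int, df)


def cluster_pvalue(cluster: ClusterResult, null: NullClusterDistribution,
                   fwhm: float | None = None,
                   vertex_p_threshold: float | None = None) -> float:
    """Add-one Monte Carlo p: (1 + #{null maxima >= size}) / (1 + n_iter).

    When the analysis ``fwhm`` / ``vertex_p_threshold`` are supplied they
    are checked against the null's metadata; a mismatch is a configuration
    error rather than a silent wrong answer.
    """
    if null.n_iter < 1:
        raise ConfigurationError("empty null distribution")
    if fwhm is not None and not np.isclose(fwhm, null.fwhm):
        raise ConfigurationError(
            f"null was simulated at fwhm={null.fwhm}, analysis used fwhm={fwhm}"
        )
    if vertex_p_threshold is not None and not np.isclose(
        vertex_p_threshold, null.vertex_p_threshold
    ):
        raise ConfigurationError(
            f"null used vertex threshold {null.vertex_p_threshold}, "
            f"analysis used {vertex_p_threshold}"
        )
    count = int(np.sum(null.max_sizes >= cluster.size))
    return (1 + count) / (1 + null.n_iter)


def correct_clusters(
    clusters: list[ClusterResult],
    null: NullClusterDistribution,
    fwhm: float | None = None,
    vertex_p_threshold: float | None = None,
) -> list[ClusterResult]:
    """Attach cluster-wise Monte Carlo p-values in place and return the list."""
    for c in clusters:
        c.p_cluster = cluster_pvalue(c, null, fwhm, vertex_p_threshold)
    return clusters


def cluster_table(clusters: list[ClusterResult], surface: SurfaceLike | None = None) -> pd.DataFrame:
    """Tidy cluster summary (one row per cluster)."""
    hemi = None
    if surface is not None:
        hemi = as_surface(surface).vertex_hemisphere
    rows = []
    for c in clusters:
        rows.append(
            {
                "cluster_id": c.cluster_id,
                "hemisphere": hemi[c.peak_vertex] if hemi is not None else "",
                "n_vertices": c.n_vertices,
                "size": c.size,
                "sign": c.sign,
                "peak_vertex": c.peak_vertex,
                "peak_t": c.peak_stat,
                "p_cluster": c.p_cluster if c.p_cluster is not None else np.nan,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "cluster_id", "hemisphere", "n_vertices", "size",
            "sign", "peak_vertex", "peak_t", "p_cluster",
        ],
    )
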