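"""Cluster extraction and Monte Carlo cluster-wise correction."""

import numpy as np
import pytest
import scipy.stats as st

from atrophynet import (
    ClusterResult,
    NullClusterDistribution,
    cluster_pvalue,
    extract_clusters,
    simulate_null_clusters,
)
from atrophynet.exceptions import ConfigurationError, InvalidParameterError
from atrophynet.glm import StatMap


def stat_map_from_t(t, df=40):
    t = np.asarray(t, dtype=float)
    p = 2 * st.t.sf(np.abs(t), df)
    r = np.sign(t) * np.sqrt(t**2 / (t**2 + df))
    return StatMap(t.copy(), t, r, p, df, "severity")


def flood_fill_clusters(mask, sign_vals, neighbors):
    """Independent BFS oracle returning frozensets of same-sign clusters."""
    out = []
    seen = set()
    for start in np.nonzero(mask)[0]:
        if start in seen:
            continue
        sign = np.sign(sign_vals[start])
        comp, queue = {start}, [start]
        seen.add(start)
        while queue:
            v = queue.pop()
            for u in neighbors[v]:
                if mask[u] and u not in seen and np.sign(sign_vals[u]) == sign:
                    seen.add(u)
                    comp.add(u)
                    queue.append(u)
        out.append(frozenset(comp))
    return set(out)


def test_no_suprathreshold_vertices_gives_empty_list(surf3):
    stats = stat_map_from_t(np.zeros(surf3.n_vertices))
    assert extract_clusters(stats, surf3, 0.001) == []


def test_three_contiguous_vertices_form_one_cluster(surf3):
    v0 = 10
    adjacency = surf3.adjacency
    nb = adjacency.indices[adjacency.indptr[v0] : adjacency.indptr[v0 + 1]][:2]
    t = np.zeros(surf3.n_vertices)
    t[[v0, *nb]] = -9.0
    clusters = extract_clusters(stat_map_from_t(t), surf3, 0.001)
    assert len(clusters) == 1
    c = clusters[0]
    assert c.sign == -1
    assert sorted(c.vertices) == sorted([v0, *nb])
    assert c.size == pytest.approx(surf3.vertex_areas[[v0, *nb]].sum())


def test_antipodal_patches_give_two_clusters(surf3):
    verts = np.concatenate([m.vertices for m in surf3.meshes])
    t = np.zeros(surf3.n_vertices)
    t[np.arccos(np.clip(verts @ verts[0], -1, 1)) < 0.2] = 8.0
    t[np.arccos(np.clip(verts @ -verts[0], -1, 1)) < 0.2] = 8.0
    clusters = extract_clusters(stat_map_from_t(t), surf3, 0.001)
    assert len(clusters) == 2


def test_extract_clusters_matches_flood_fill_oracle(surf3, rng):
    """50 random thresholded maps agree with an independent BFS."""
    neighbors = [surf3.adjacency.indices[surf3.adjacency.indptr[v] : surf3.adjacency.indptr[v + 1]]
                 for v in range(surf3.n_vertices)]
    for _ in range(50):
        t = rng.standard_normal(surf3.n_vertices) * 3.0
        stats = stat_map_from_t(t)
        thr = float(rng.uniform(0.01, 0.2))
        ours = {frozenset(c.vertices.tolist()) for c in extract_clusters(stats, surf3, thr)}
        oracle = flood_fill_clusters(stats.p < thr, t, neighbors)
        assert ours == oracle


def test_cluster_ordering_is_by_descending_size(surf3, rng):
    t = rng.standard_normal(surf3.n_vertices) * 3.0
    clusters = extract_clusters(stat_map_from_t(t), surf3, 0.2)
    sizes = [c.size for c in clusters]
    assert sizes == sorted(sizes, reverse=True)
    assert [c.cluster_id for c in clusters] == list(range(len(clusters)))


# ------------------------------------------------- Monte Carlo null


def test_degenerate_threshold_gives_all_zero_maxima(surf3):
    null = simulate_null_clusters(surf3, 10.0, 1e-300, 50, seed=0)
    assert (null.max_sizes == 0).all()


def test_null_simulation_deterministic_under_seed(surf3):
    a = simulate_null_clusters(surf3, 10.0, 0.01, 60, seed=99)
    b = simulate_null_clusters(surf3, 10.0, 0.01, 60, seed=99)
    np.testing.assert_array_equal(a.max_sizes, b.max_sizes)


def test_unsmoothed_null_matches_binomial_zero_rate(surf3):
    """With fwhm=0 the chance an iteration has no suprathreshold vertex is
    (1-thr)^V; the observed zero fraction must sit in the binomial band."""
    thr, n_iter = 0.001, 800
    null = simulate_null_clusters(surf3, 0.0, thr, n_iter, seed=7)
    p_zero = (1 - thr) ** surf3.n_vertices
    lo, hi = st.binom.ppf([0.0005, 0.9995], n_iter, p_zero)
    assert lo <= (null.max_sizes == 0).sum() <= hi


def test_cluster_pvalue_counting_convention():
    cluster = ClusterResult(0, np.array([1]), size=10.0, sign=1, peak_vertex=1, peak_stat=5.0)
    null = NullClusterDistribution(np.zeros(9999), fwhm=10.0, vertex_p_threshold=0.001, seed=0)
    assert cluster_pvalue(cluster, null) == pytest.approx(1 / 10000)
    zero = ClusterResult(0, np.array([1]), size=0.0, sign=1, peak_vertex=1, peak_stat=5.0)
    assert cluster_pvalue(zero, null) == 1.0


def test_cluster_pvalue_at_null_median():
    sizes = np.arange(1.0, 1000.0)  # median 500
    null = NullClusterDistribution(sizes, 10.0, 0.001, seed=0)
    cluster = ClusterResult(0, np.array([1]), size=500.0, sign=1, peak_vertex=1, peak_stat=5.0)
    # direct count: 500 of 999 maxima are >= 500
    assert cluster_pvalue(cluster, null) == pytest.approx((1 + 500) / 1000)


def test_cluster_pvalue_rejects_mismatched_metadata():
    cluster = ClusterResult(0, np.array([1]), 10.0, 1, 1, 5.0)
    null = NullClusterDistribution(np.zeros(10), fwhm=10.0, vertex_p_threshold=0.001, seed=0)
    with pytest.raises(ConfigurationError):
        cluster_pvalue(cluster, null, fwhm=15.0)
    with pytest.raises(ConfigurationError):
        cluster_pvalue(cluster, null, vertex_p_threshold=0.01)


def test_invalid_threshold_rejected(surf3):
    with pytest.raises(InvalidParameterError):
        extract_clusters(stat_map_from_t(np.zeros(surf3.n_vertices)), surf3, 1.5)
    with pytest.raises(InvalidParameterError):
        simulate_null_clusters(surf3, 10.0, 0.001, 0, seed=1)


def test_permutation_null_behaves_like_gaussian_null(surf3):
    """Subject-label permutation null: deterministic under seed, and under
    smooth pure-noise data the planted-free severity analysis keeps its
    cluster p-values well above significance most of the time."""
    from atrophynet import (
        DesignSpec,
        SimulationConfig,
        correct_clusters,
        permutation_null_clusters,
        simulate_cohort,
    )
    from atrophynet.glm import VertexGLM

    cfg = SimulationConfig(mesh_level=3, effect_rho=0.0, master_seed=5)
    cohort, vdm, _ = simulate_cohort(cfg, surf3)
    scored, _ = cohort.cases().with_severity()
    design = DesignSpec(effect="severity")
    a = permutation_null_clusters(vdm, scored, design, surf3, 0.001, 40, seed=3,
                                  fwhm=cfg.noise_fwhm)
    b = permutation_null_clusters(vdm, scored, design, surf3, 0.001, 40, seed=3,
                                  fwhm=cfg.noise_fwhm)
    np.testing.assert_array_equal(a.max_sizes, b.max_sizes)
    assert a.n_iter == 40 and (a.max_sizes >= 0).all()

    # strong planted effect dwarfs the permutation null
    cfg2 = SimulationConfig(mesh_level=3, effect_rho=-0.6, master_seed=6)
    cohort2, vdm2, truth = simulate_cohort(cfg2, surf3)
    scored2, _ = cohort2.cases().with_severity()
    null = permutation_null_clusters(vdm2, scored2, design, surf3, 0.001, 99, seed=9,
                                     fwhm=cfg2.noise_fwhm)
    res = VertexGLM(vdm2, scored2, design).fit()
    clusters = correct_clusters(res.extract_clusters(0.001), null,
                                cfg2.noise_fwhm, 0.001)
    disc = set(truth.disc_vertices.tolist())
    assert any(c.p_cluster == pytest.approx(1 / 100) and disc & set(c.vertices.tolist())
               for c in clusters)
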