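"""Weighted-degree centrality, spin permutations, epicenter mapping."""

import numpy as np
import pytest

from atrophynet import (
    AtrophyNetworkModel,
    Connectome,
    ParcelAtlas,
    epicenter_map,
    map_correlation,
    plant_epicenter,
    spin_permutations,
    spin_rotate,
    spin_test,
    weighted_degree,
)
from atrophynet.exceptions import (
    InvalidConnectomeError,
    InvalidParameterError,
    UndefinedCorrelationError,
)
from atrophynet.simulate import SimulationConfig, simulate_connectome, smooth_region_map


def three_region_connectome():
    w = np.zeros((3, 3))
    w[0, 1] = w[1, 0] = 0.5
    w[0, 2] = w[2, 0] = 0.2
    w[1, 2] = w[2, 1] = -0.1
    return Connectome(w)


@pytest.mark.parametrize(
    "mode, expected",
    [
        ("positive", [0.7, 0.5, 0.2]),
        ("signed", [0.7, 0.4, 0.1]),
        ("absolute", [0.7, 0.6, 0.3]),
    ],
)
def test_weighted_degree_three_regions(mode, expected):
    deg = weighted_degree(three_region_connectome(), mode)
    np.testing.assert_allclose(deg.values, expected, atol=1e-12)
    assert deg.mode == mode


def test_weighted_degree_zero_matrix():
    deg = weighted_degree(Connectome(np.zeros((4, 4))), "positive")
    np.testing.assert_array_equal(deg.values, np.zeros(4))


def test_weighted_degree_matches_bruteforce_double_loop(rng):
    """100 random connectomes, all three weight modes."""
    for _ in range(100):
        n = int(rng.integers(4, 20))
        raw = rng.uniform(-1, 1, (n, n))
        w = (raw + raw.T) / 2
        np.fill_diagonal(w, 0.0)
        conn = Connectome(w)
        for mode in ("positive", "signed", "absolute"):
            expected = np.zeros(n)
            for i in range(n):
                for j in range(n):
                    if i == j:
                        continue
                    x = w[i, j]
                    if mode == "positive":
                        expected[i] += max(x, 0.0)
                    elif mode == "absolute":
                        expected[i] += abs(x)
                    else:
                        expected[i] += x
            np.testing.assert_allclose(
                weighted_degree(conn, mode).values, expected, atol=1e-10
            )


def test_asymmetric_connectome_rejected():
    w = np.zeros((3, 3))
    w[0, 1] = 0.5
    with pytest.raises(InvalidConnectomeError):
        Connectome(w)


def test_map_correlation_identities(rng):
    a = rng.standard_normal(30)
    assert map_correlation(a, a) == pytest.approx(1.0)
    assert map_correlation(a, -a) == pytest.approx(-1.0)
    assert map_correlation(a, 2.5 * a + 3.0) == pytest.approx(1.0)


def test_map_correlation_constant_map_is_an_error(rng):
    with pytest.raises(UndefinedCorrelationError):
        map_correlation(np.ones(10), rng.standard_normal(10))


# --------------------------------------------------------------- spins


def test_identity_rotation_gives_identity_permutation(atlas68):
    perms = spin_permutations(atlas68, 1, rotations=np.eye(3)[None])
    np.testing.assert_array_equal(perms[0], np.arange(atlas68.n_regions))


def test_spin_rotation_is_an_isometry(atlas68):
    """Rotated centroids keep all pairwise within-hemisphere distances:
    geodesic to 1e-9 away from the arccos singularities (d ≈ 0 or π,
    where arccos amplifies float error), chord to 1e-12 everywhere."""
    _, rots = spin_permutations(atlas68, 3, seed=5, return_rotations=True)
    for hemi, flip in (("left", False), ("right", True)):
        cents = atlas68.centroids[atlas68.hemi_mask(hemi)]
        before = np.arccos(np.clip(cents @ cents.T, -1, 1))
        chord_before = np.linalg.norm(cents[:, None] - cents[None, :], axis=2)
        ok = (before > 1e-6) & (before < np.pi - 1e-6)
        for rot in rots:
            if flip:
                m = np.diag([-1.0, 1.0, 1.0])
                rot = m @ rot @ m
            rc = cents @ rot.T
            after = np.arccos(np.clip(rc @ rc.T, -1, 1))
            np.testing.assert_allclose(after[ok], before[ok], atol=1e-9)
            chord_after = np.linalg.norm(rc[:, None] - rc[None, :], axis=2)
            np.testing.assert_allclose(chord_after, chord_before, atol=1e-12)


def test_spin_permutation_stays_within_hemisphere(atlas68):
    perms = spin_permutations(atlas68, 20, seed=3)
    hemis = atlas68.hemispheres
    assert (hemis[perms] == hemis[None, :]).all()


def test_spin_rotate_deterministic_under_seed(atlas68):
    np.testing.assert_array_equal(spin_rotate(atlas68, seed=11), spin_rotate(atlas68, seed=11))
    assert not np.array_equal(spin_rotate(atlas68, seed=11), spin_rotate(atlas68, seed=12))


def test_spin_test_counting_convention(atlas68, rng):
    a = smooth_region_map(atlas68, 0.6, rng)
    b = 0.9 * a + 0.1 * smooth_region_map(atlas68, 0.6, rng)  # strongly matched maps
    res = spin_test(a, b, atlas68, n_perm=99, seed=1)
    count = int(np.sum(np.abs(res.null) >= abs(res.observed)))
    assert res.p == pytest.approx((1 + count) / 100)
    assert res.p >= 1 / 100  # add-one floor


def test_spin_test_identity_map(atlas68, rng):
    a = smooth_region_map(atlas68, 0.6, rng)
    res = spin_test(a, a, atlas68, n_perm=200, seed=2)
    assert res.observed == pytest.approx(1.0)
    assert res.p < 0.05


# ----------------------------------------------------------- epicenters


def fixture_connectome(atlas):
    return simulate_connectome(SimulationConfig(), atlas)


def test_perfect_profile_match_tops_the_ranking(atlas68):
    conn = fixture_connectome(atlas68)
    j = 7
    atrophy = conn.weights[j].copy()
    atrophy[j] = atrophy[np.arange(68) != j].mean()
    res = epicenter_map(conn, atrophy, atlas68, n_perm=50, seed=0)
    assert res.r[j] == pytest.approx(1.0)
    assert res.ranks[j] == 0


def test_constant_atrophy_map_is_an_error(atlas68):
    conn = fixture_connectome(atlas68)
    with pytest.raises(UndefinedCorrelationError):
        epicenter_map(conn, np.ones(68), atlas68, n_perm=10, seed=0)


def test_epicenter_equivariant_under_relabeling(atlas68, rng):
    """Consistently permuting regions in connectome, atlas and atrophy
    permutes the result identically."""
    conn = fixture_connectome(atlas68)
    atrophy = plant_epicenter(conn, 12, 0.7, 5, atlas68)
    perm = rng.permutation(68)
    conn_p = Connectome(conn.weights[np.ix_(perm, perm)])
    atlas_p = ParcelAtlas(
        atlas68.region_ids[perm],
        [atlas68.region_names[i] for i in perm],
        atlas68.hemispheres[perm],
        atlas68.centroids[perm],
    )
    res = epicenter_map(conn, atrophy, atlas68, n_perm=80, seed=9)
    res_p = epicenter_map(conn_p, atrophy[perm], atlas_p, n_perm=80, seed=9)
    np.testing.assert_allclose(res_p.r, res.r[perm], atol=1e-10)


def test_spin_p_stabilises_with_permutation_count(atlas68):
    """Fixture-scenario p from 5,000 vs 10,000 spins differs by < 0.02."""
    conn = fixture_connectome(atlas68)
    atrophy = plant_epicenter(conn, 20, 0.5, 3, atlas68)
    from atrophynet import centrality_similarity

    p5 = centrality_similarity(atrophy, conn, atlas68, n_perm=5000, seed=21).p
    p10 = centrality_similarity(atrophy, conn, atlas68, n_perm=10000, seed=22).p
    assert abs(p5 - p10) < 0.02


def test_model_results_shape(atlas68):
    conn = fixture_connectome(atlas68)
    atrophy = plant_epicenter(conn, 30, 0.7, 4, atlas68)
    res = AtrophyNetworkModel(conn, atlas68).fit(atrophy, n_perm=100, seed=8)
    frame = res.epicenters.to_frame()
    assert set(frame.columns) == {"region_id", "region_name", "r", "p_spin", "significant", "rank"}
    assert res.similarity.n_perm == 100
    assert "Atrophy network mapping" in res.summary()
    assert (np.abs(res.epicenters.r) <= 1).all()
    np.testing.assert_array_equal(res.epicenters.significant,
                                  res.epicenters.p_spin < res.epicenters.alpha)


def test_centrality_similarity_antisymmetry(atlas68):
    conn = fixture_connectome(atlas68)
    centrality = weighted_degree(conn, "positive").values
    from atrophynet import centrality_similarity

    res = centrality_similarity(-centrality, conn, atlas68, n_perm=30, seed=1)
    assert res.observed == pytest.approx(-1.0)


def test_invalid_weight_mode_rejected():
    with pytest.raises(InvalidParameterError):
        weighted_degree(three_region_connectome(), "squared")


def test_hungarian_spin_is_one_to_one(atlas68):
    perms = spin_permutations(atlas68, 10, seed=4, method="hungarian")
    hemis = atlas68.hemispheres
    for p in perms:
        assert len(set(p.tolist())) == atlas68.n_regions  # a true permutation
        assert (hemis[p] == hemis).all()


def test_uniform_spin_ignores_geometry(atlas68):
    perms = spin_permutations(atlas68, 10, seed=4, method="uniform")
    hemis = atlas68.hemispheres
    for p in perms:
        assert len(set(p.tolist())) == atlas68.n_regions
        assert (hemis[p] == hemis).all()
    # determinism under seed
    np.testing.assert_array_equal(
        spin_permutations(atlas68, 5, seed=6, method="uniform"),
        spin_permutations(atlas68, 5, seed=6, method="uniform"),
    )


def test_unknown_spin_method_rejected(atlas68):
    with pytest.raises(InvalidParameterError):
        spin_permutations(atlas68, 5, seed=0, method="swirl")
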