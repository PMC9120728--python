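"""Atrophy network mapping against a normative connectome.

Two questions are asked of a region-level atrophy map (e.g., parcel means
of a severity partial-correlation map):

* **Hub susceptibility** — does atrophy preferentially hit regions with
  dense connectivity?  Measured as the Pearson correlation between the
  atrophy map and weighted-degree centrality (the per-region sum of
  connection weights).
* **Disease epicenters** — which regions' normative connectivity profiles
  spatially resemble the atrophy map?  Each region's connectome row
  (self-connection excluded) is correlated with the atrophy map.

Both statistics are tested against a spin-permutation null: the atrophy
map's parcel centroids are rotated rigidly on the sphere (the mirrored
rotation applied to the right hemisphere) and regions reassigned to the
nearest rotated centroid, preserving the map's spatial autocorrelation
while destroying its alignment with the connectome.  p-values use the
add-one convention, two-sided by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import special_ortho_group

from .atlas import ParcelAtlas
from .data import Connectome
from .exceptions import (
    InvalidConnectomeError,
    InvalidParameterError,
    UndefinedCorrelationError,
)

WEIGHT_MODES = ("positive", "signed", "absolute")
_MIRROR_X = np.diag([-1.0, 1.0, 1.0])


@dataclass
class CentralityVector:
    """Per-region weighted-degree centrality and the weight mode used."""

    values: np.ndarray
    mode: str

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class SpinNull:
    """Observed statistic with its spin-permutation null distribution."""

    observed: float
    null: np.ndarray
    p: float
    seed: int | None = None
    tail: str = "two-sided"

    @property
    def n_perm(self) -> int:
        return len(self.null)


@dataclass
class EpicenterResult:
    """Per-region epicenter correlations with spin p-values."""

    r: np.ndarray
    p_spin: np.ndarray
    alpha: float
    region_ids: np.ndarray
    region_names: list[str] = field(default_factory=list)

    @property
    def significant(self) -> np.ndarray:
        return self.p_spin < self.alpha

    @property
    def ranks(self) -> np.ndarray:
        """Rank of each region by descending |r| (0 = strongest profile match)."""
        order = np.argsort(-np.abs(self.r), kind="stable")
        ranks = np.empty(len(self.r), dtype=int)
        ranks[order] = np.arange(len(self.r))
        return ranks

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "region_id": self.region_ids,
                "region_name": self.region_names or [""] * len(self.r),
                "r": self.r,
                "p_spin": self.p_spin,
                "significant": self.significant,
                "rank": self.ranks,
            }
        )


def weighted_degree(conn: Connectome, mode: str = "positive") -> CentralityVector:
    """Sum of each region's off-diagonal connection weights.

    ``positive`` drops negative weights (normative-connectome convention),
    ``signed`` sums raw weights, ``absolute`` sums magnitudes.
    """
    if mode not in WEIGHT_MODES:
        raise InvalidParameterError(f"mode must be one of {WEIGHT_MODES}, got {mode!r}")
    w = conn.weights
    if np.abs(w - w.T).max() > 1e-9:
        raise InvalidConnectomeError("connectome asymmetric beyond 1e-9")
    if mode == "positive":
        w = np.where(w > 0, w, 0.0)
    elif mode == "absolute":
        w = np.abs(w)
    return CentralityVector(w.sum(axis=1), mode)


def map_correlation(map_a: np.ndarray, map_b: np.ndarray) -> float:
    """Pearson correlation across regions; constant maps are an error."""
    a = np.asarray(map_a, dtype=float)
    b = np.asarray(map_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise InvalidParameterError(f"maps must be equal-length vectors, got {a.shape}, {b.shape}")
    if len(a) < 3:
        raise InvalidParameterError("need at least 3 regions for a correlation")
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        raise UndefinedCorrelationError("correlation undefined for a constant map")
    return float(np.dot(a - a.mean(), b - b.mean()) / (len(a) * sa * sb))


def spin_permutations(
    atlas: ParcelAtlas,
    n_perm: int,
    seed: int | np.random.Generator | None = None,
    rotations: np.ndarray | None = None,
    return_rotations: bool = False,
    method: str = "nearest",
) -> np.ndarray | tuple[np.ndarray, np.ndarray]:
    """(n_perm, R) spin permutations of the atlas regions.

    Each row ``perm`` reassigns region i the value of region ``perm[i]``:
    a uniform random rotation is applied to left-hemisphere centroids and
    its x-mirrored conjugate to the right hemisphere, then regions are
    matched to rotated centroids within their hemisphere.

    method : "nearest" (default) takes the nearest rotated centroid,
        with replacement; "hungarian" solves the cost-minimising
        one-to-one matching on geodesic distances; "uniform" ignores
        geometry and draws uniform within-hemisphere relabelings (for
        region sets without spherical coordinates, e.g. subcortical).
    """
    if n_perm < 1:
        raise InvalidParameterError("n_perm must be at least 1")
    if method not in ("nearest", "hungarian", "uniform"):
        raise InvalidParameterError(f"unknown spin method {method!r}")
    if method == "uniform":
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        perms = np.empty((n_perm, atlas.n_regions), dtype=np.int64)
        for hemi in np.unique(atlas.hemispheres):
            idx = np.nonzero(atlas.hemi_mask(hemi))[0]
            for p in range(n_perm):
                perms[p, idx] = rng.permutation(idx)
        return (perms, np.broadcast_to(np.eye(3), (n_perm, 3, 3))) if return_rotations else perms
    if rotations is None:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        rots = special_ortho_group.rvs(3, size=n_perm, random_state=rng)
        rots = rots.reshape(n_perm, 3, 3)
    else:
        rots = np.asarray(rotations, dtype=float).reshape(-1, 3, 3)
        n_perm = len(rots)
    perms = np.empty((n_perm, atlas.n_regions), dtype=np.int64)
    for hemi in np.unique(atlas.hemispheres):
        idx = np.nonzero(atlas.hemi_mask(hemi))[0]
        cents = atlas.centroids[idx]
        if hemi == "right":
            hemi_rots = _MIRROR_X @ rots @ _MIRROR_X
        else:
            hemi_rots = rots
        rotated = np.einsum("pij,rj->pri", hemi_rots, cents)  # (n_perm, nR, 3)
        sims = np.einsum("pri,si->psr", rotated, cents)  # (n_perm, n_orig, n_rot)
        if method == "nearest":
            # nearest rotated centroid to each original: max dot product
            perms[:, idx] = idx[np.argmax(sims, axis=2)]
        else:  # hungarian: minimise total geodesic cost, one-to-one
            from scipy.optimize import linear_sum_assignment

            cost = np.arccos(np.clip(sims, -1.0, 1.0))
            for p in range(n_perm):
                rows, cols = linear_sum_assignment(cost[p])
                perms[p, idx[rows]] = idx[cols]
    return (perms, rots) if return_rotations else perms


def spin_rotate(atlas: ParcelAtlas, seed: int | np.random.Generator | None = None) -> np.ndarray:
    """A single spin permutation of the atlas regions."""
    return spin_permutations(atlas, 1, seed)[0]


def _null_correlations(
    permuted: np.ndarray, target: np.ndarray
) -> np.ndarray:
    """Row-wise Pearson correlation of (n_perm, R) maps against a fixed map.

    Degenerate (constant) permuted rows contribute a null correlation of 0
    — they carry no spatial signal.
    """
    pm = permuted - permuted.mean(axis=1, keepdims=True)
    ps = permuted.std(axis=1)
    tm = target - target.mean()
    ts = target.std()
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (pm @ tm) / (permuted.shape[1] * ps * ts)
    return np.where(ps > 0, r, 0.0)


def _perm_pvalue(observed: float, null: np.ndarray, tail: str) -> float:
    if tail == "two-sided":
        count = int(np.sum(np.abs(null) >= abs(observed)))
    elif tail == "greater":
        count = int(np.sum(null >= observed))
    elif tail == "less":
        count = int(np.sum(null <= observed))
    else:
        raise InvalidParameterError(f"unknown tail {tail!r}")
    return (1 + count) / (1 + len(null))


def spin_test(
    map_a: np.ndarray,
    map_b: np.ndarray,
    atlas: ParcelAtlas,
    n_perm: int = 1000,
    seed: int | np.random.Generator | None = None,
    tail: str = "two-sided",
    method: str = "nearest",
) -> SpinNull:
    """Spatial-permutation test of the correlation between two region maps.

    Only ``map_a`` is rotated; ``map_b`` stays fixed (rotate the atrophy
    map, never the connectome-derived map).
    """
    observed = map_correlation(map_a, map_b)
    perms = spin_permutations(atlas, n_perm, seed, method=method)
    null = _null_correlations(np.asarray(map_a, dtype=float)[perms], np.asarray(map_b, float))
    p = _perm_pvalue(observed, null, tail)
    seed_int = seed if isinstance(seed, (int, np.integer)) else None
    return SpinNull(observed, null, p, seed_int, tail)


def epicenter_map(
    conn: Connectome,
    atrophy: np.ndarray,
    atlas: ParcelAtlas,
    n_perm: int = 1000,
    alpha: float = 0.01,
    seed: int | np.random.Generator | None = None,
    tail: str = "two-sided",
    method: str = "nearest",
) -> EpicenterResult:
    """Correlate every region's connectivity profile with the atrophy map.

    For region j the profile is row j of the connectome with the j-th
    (self) entry removed, correlated against the atrophy map with its j-th
    entry removed.  Spin p-values rotate the atrophy map.
    """
    atrophy = np.asarray(atrophy, dtype=float)
    if len(atrophy) != conn.n_regions or conn.n_regions != atlas.n_regions:
        raise InvalidParameterError(
            f"dimension mismatch: connectome {conn.n_regions}, atlas "
            f"{atlas.n_regions}, atrophy {len(atrophy)}"
        )
    if atrophy.std() == 0:
        raise UndefinedCorrelationError("atrophy map is constant")
    n = conn.n_regions
    perms = spin_permutations(atlas, n_perm, seed, method=method)
    permuted = atrophy[perms]  # (n_perm, R)
    r_obs = np.empty(n)
    p_spin = np.empty(n)
    keep_all = np.arange(n)
    for j in range(n):
        keep = keep_all[keep_all != j]
        profile = conn.weights[j, keep]
        r_obs[j] = map_correlation(profile, atrophy[keep])
        null_j = _null_correlations(permuted[:, keep], profile)
        p_spin[j] = _perm_pvalue(r_obs[j], null_j, tail)
    return EpicenterResult(
        r=r_obs,
        p_spin=p_spin,
        alpha=alpha,
        region_ids=np.asarray(atlas.region_ids),
        region_names=list(atlas.region_names),
    )


def centrality_similarity(
    atrophy: np.ndarray,
    conn: Connectome,
    atlas: ParcelAtlas,
    n_perm: int = 1000,
    seed: int | np.random.Generator | None = None,
    mode: str = "positive",
    tail: str = "two-sided",
) -> SpinNull:
    """Spin-tested correlation between an atrophy map and hub centrality."""
    centrality = weighted_degree(conn, mode)
    return spin_test(atrophy, centrality.values, atlas, n_perm, seed, tail)


class AtrophyNetworkModel:
    """Normative-connectome contextualisation of a region atrophy map.

    Parameters
    ----------
    conn : group-average normative connectome.
    atlas : parcellation with spherical centroids (spin substrate).
    weight_mode : centrality weight handling ("positive" default).
    """

    def __init__(self, conn: Connectome, atlas: ParcelAtlas, weight_mode: str = "positive"):
        if conn.n_regions != atlas.n_regions:
            raise InvalidParameterError(
                f"connectome has {conn.n_regions} regions, atlas {atlas.n_regions}"
            )
        self.conn = conn
        self.atlas = atlas
        self.weight_mode = weight_mode
        self.centrality = weighted_degree(conn, weight_mode)

    def fit(
        self,
        atrophy: np.ndarray,
        n_perm: int = 1000,
        alpha: float = 0.01,
        seed: int | np.random.Generator | None = None,
        spin_method: str = "nearest",
    ) -> "AtrophyNetworkResults":
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        similarity = spin_test(
            atrophy, self.centrality.values, self.atlas, n_perm, rng, method=spin_method
        )
        epicenters = epicenter_map(
            self.conn, atrophy, self.atlas, n_perm, alpha, rng, method=spin_method
        )
        return AtrophyNetworkResults(self, np.asarray(atrophy, float), similarity, epicenters)


class AtrophyNetworkResults:
    """Fitted network mapping: hub similarity plus the epicenter table."""

    def __init__(
        self,
        model: AtrophyNetworkModel,
        atrophy: np.ndarray,
        similarity: SpinNull,
        epicenters: EpicenterResult,
    ):
        self.model = model
        self.atrophy = atrophy
        self.similarity = similarity
        self.epicenters = epicenters

    def summary(self) -> str:
        e = self.epicenters
        n_sig = int(e.significant.sum())
        top = int(np.argmin(e.ranks))
        lines = [
            "Atrophy network mapping results",
            "=" * 47,
            f"regions:                  {len(e.r)}",
            f"weight mode:              {self.model.weight_mode}",
            f"spins:                    {self.similarity.n_perm}",
            f"centrality similarity r:  {self.similarity.observed:+.3f}",
            f"similarity p_spin:        {self.similarity.p:.4f}",
            f"epicenters at alpha={e.alpha:<5g} {n_sig}",
            f"top epicenter:            region {e.region_ids[top]} "
            f"({e.region_names[top] if e.region_names else ''}) r={e.r[top]:+.3f}",
        ]
        return "\n".join(lines)
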