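"""Synthetic study generator.

Emulates the measured inputs of a surface-based morphometry + atrophy
network mapping study at the vertex-measurement level (no images are
simulated): a bilateral icosphere registration surface, a
Desikan–Killiany-like parcellation (34 regions per hemisphere), a cohort of
~50 scored cases and 50 controls with an S-FMDRS-like severity score
(0–54), per-vertex volume maps with linear covariate effects plus spatially
smooth noise and a planted severity effect confined to a geodesic disc, and
a normative connectome with modular, distance-decaying connectivity in
which an atrophy epicenter can be planted.

The planted severity effect is calibrated on the *partial correlation*
scale: the severity coefficient is scaled against the per-vertex noise SD
so that the population partial correlation (after age/sex/eTIV adjustment)
inside the disc equals the configured ρ — making ρ the single interpretable
effect-size knob, directly comparable to the analysis output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as st

from .atlas import ParcelAtlas, make_atlas
from .data import SEVERITY_MAX, CohortTable, Connectome, VertexDataMatrix
from .exceptions import ConfigurationError, InvalidParameterError
from .geometry import CorticalSurface, SurfaceLike, as_surface, make_icosphere
from .smoothing import smooth_surface, smoothed_vertex_sd

__all__ = [
    "SimulationConfig",
    "make_icosphere",
    "make_atlas",
    "simulate_cohort",
    "simulate_connectome",
    "plant_epicenter",
    "plant_hub_atrophy",
    "smooth_region_map",
    "mirrored_centroids",
    "simulate_bundle",
    "SimulatedBundle",
    "CohortGroundTruth",
]


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the synthetic study, with study-condition defaults.

    Geometry: a level-3 icosphere per hemisphere (642 vertices) on a 100 mm
    registration sphere, parcellated into 34 regions per hemisphere.
    Cohort: 50 scored cases and 50 controls; severity truncated-normal on
    [0, 54]; age/sex/eTIV distributions typical of a middle-aged clinical
    sample.  Effect: partial correlation ρ = −0.43 inside a 35 mm-radius
    geodesic disc.  Connectome: 4 modules with distance-decaying weights
    and homotopic symmetry.  Epicenter: mixing coefficient λ = 0.7.
    """

    mesh_level: int = 3
    sphere_scale: float = 100.0  # mm registration-sphere radius
    n_regions_per_hemisphere: int = 34
    # cohort: 53 enrolled cases of whom 50 carry a severity score
    n_cases: int = 53
    n_unscored_cases: int = 3
    n_controls: int = 50
    severity_mean: float = 18.0
    severity_sd: float = 10.0
    age_mean: float = 44.0
    age_sd: float = 10.0
    sex_p: float = 0.79
    etiv_mean: float = 1.5e6
    etiv_sd: float = 1.5e5
    # optional clinical covariates (no planted relation to volume)
    include_optional_covariates: bool = True
    bdi_mean: float = 12.0
    bdi_sd: float = 8.0
    stai_mean: float = 42.0
    stai_sd: float = 10.0
    antidepressant_p_case: float = 0.45
    antidepressant_p_control: float = 0.32
    weakness_p_case: float = 0.64
    # vertex volume model (mm³ per vertex)
    baseline: float = 1.5
    beta_age: float = -0.005
    beta_sex: float = 0.05
    beta_etiv: float = 3.0e-7
    group_effect: float = 0.0  # case-vs-control shift inside the disc
    noise_sd: float = 0.15
    noise_fwhm: float = 25.0  # mm on the scaled sphere
    # planted severity effect
    effect_rho: float = -0.43
    disc_radius: float = 0.35  # radians of arc
    seed_vertex: int | None = None  # None -> drawn from the rng
    # connectome
    n_modules: int = 4
    within_weight: float = 0.45
    between_weight: float = 0.15
    decay: float = 1.0  # per radian of centroid separation
    conn_noise_sd: float = 0.1
    # epicenter planting
    epicenter_lambda: float = 0.7
    epicenter_region: int | None = None
    gp_length_scale: float = 0.6  # radians, smooth region-map noise
    master_seed: int = 0

    def __post_init__(self) -> None:
        if not -1 < self.effect_rho < 1:
            raise InvalidParameterError(f"effect_rho must be in (-1, 1), got {self.effect_rho}")
        if not 0 <= self.epicenter_lambda <= 1:
            raise InvalidParameterError("epicenter_lambda must be in [0, 1]")
        for name in ("n_cases", "n_controls", "n_regions_per_hemisphere", "n_modules"):
            if getattr(self, name) < 1:
                raise InvalidParameterError(f"{name} must be positive")

    def stage_rng(self, stage: str) -> np.random.Generator:
        """Deterministic per-stage generator derived from the master seed."""
        offsets = {"atlas": 1, "cohort": 2, "connectome": 3, "epicenter": 4, "extra": 5}
        if stage not in offsets:
            raise ConfigurationError(f"unknown simulation stage {stage!r}")
        return np.random.default_rng(
            np.random.SeedSequence([self.master_seed, offsets[stage]])
        )


@dataclass
class CohortGroundTruth:
    """What was planted in a simulated cohort."""

    seed_vertex: int
    disc_vertices: np.ndarray
    rho: float
    severity_beta: float
    severity_sd: float


def _truncnorm(mean: float, sd: float, lo: float, hi: float):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return st.truncnorm(a, b, loc=mean, scale=sd)


def effect_disc(surface: SurfaceLike, seed_vertex: int, radius: float) -> np.ndarray:
    """Concatenated-vertex indices within ``radius`` radians of the seed,
    restricted to the seed's hemisphere."""
    surf = as_surface(surface)
    verts = surf.vertices
    hemi = surf.vertex_hemisphere
    dots = np.clip(verts @ verts[seed_vertex], -1, 1)
    disc = np.nonzero((np.arccos(dots) <= radius) & (hemi == hemi[seed_vertex]))[0]
    if disc.size == 0:
        raise ConfigurationError(f"effect disc of radius {radius} contains no vertices")
    return disc


def simulate_cohort(
    config: SimulationConfig,
    surface: SurfaceLike,
    rng: np.random.Generator | None = None,
) -> tuple[CohortTable, VertexDataMatrix, CohortGroundTruth]:
    """Draw a cohort table and its vertex-volume matrix.

    Case vertex volumes inside the planted disc carry a severity slope
    scaled so the population partial correlation equals ``effect_rho``;
    controls have no severity score (NaN) and no severity effect.
    """
    surf = as_surface(surface)
    rng = config.stage_rng("cohort") if rng is None else rng
    n = config.n_cases + config.n_controls
    sev_dist = _truncnorm(config.severity_mean, config.severity_sd, 0.0, SEVERITY_MAX)
    severity = np.full(n, np.nan)
    severity[: config.n_cases] = sev_dist.rvs(config.n_cases, random_state=rng)
    if config.n_unscored_cases:
        if config.n_unscored_cases >= config.n_cases:
            raise ConfigurationError("n_unscored_cases must leave at least one scored case")
        severity[config.n_cases - config.n_unscored_cases : config.n_cases] = np.nan
    age = _truncnorm(config.age_mean, config.age_sd, 18.0, 80.0).rvs(n, random_state=rng)
    sex = (rng.random(n) < config.sex_p).astype(float)
    etiv = rng.normal(config.etiv_mean, config.etiv_sd, n)
    group = np.array(["case"] * config.n_cases + ["control"] * config.n_controls)
    columns = {
        "subject_id": [f"sub-{i:03d}" for i in range(n)],
        "group": group,
        "severity": severity,
        "age": age,
        "sex": sex,
        "etiv": etiv,
    }
    if config.include_optional_covariates:
        is_case_row = group == "case"
        columns["bdi"] = np.round(
            _truncnorm(config.bdi_mean, config.bdi_sd, 0.0, 63.0).rvs(n, random_state=rng), 0
        )
        columns["stai_trait"] = np.round(
            _truncnorm(config.stai_mean, config.stai_sd, 20.0, 80.0).rvs(n, random_state=rng), 0
        )
        p_anti = np.where(
            is_case_row, config.antidepressant_p_case, config.antidepressant_p_control
        )
        columns["antidepressant"] = (rng.random(n) < p_anti).astype(int)
        columns["subtype_weakness"] = (
            (rng.random(n) < config.weakness_p_case) & is_case_row
        ).astype(int)
    cohort = CohortTable(pd.DataFrame(columns))

    seed_vertex = (
        int(rng.integers(surf.n_vertices)) if config.seed_vertex is None else config.seed_vertex
    )
    disc = effect_disc(surf, seed_vertex, config.disc_radius)

    # smooth noise field with exactly unit per-vertex SD, scaled to noise_sd
    white = rng.standard_normal((n, surf.n_vertices))
    noise = smooth_surface(white, surf, config.noise_fwhm)
    noise /= smoothed_vertex_sd(surf, config.noise_fwhm)[None, :]
    noise *= config.noise_sd

    rho = config.effect_rho
    sev_sd = float(sev_dist.std())
    beta_sev = rho / np.sqrt(1.0 - rho**2) * config.noise_sd / sev_sd

    values = (
        config.baseline
        + config.beta_age * age[:, None]
        + config.beta_sex * sex[:, None]
        + config.beta_etiv * etiv[:, None]
        + noise
    )
    is_case = group == "case"
    scored = is_case & np.isfinite(severity)
    sev_centered = np.where(scored, severity - sev_dist.mean(), 0.0)
    values[:, disc] += beta_sev * sev_centered[:, None]
    if config.group_effect:
        values[np.ix_(is_case, disc)] += config.group_effect
    vdm = VertexDataMatrix(values, cohort.subject_ids, surf)
    truth = CohortGroundTruth(seed_vertex, disc, rho, beta_sev, sev_sd)
    return cohort, vdm, truth


def mirrored_centroids(atlas: ParcelAtlas) -> np.ndarray:
    """Centroids with right-hemisphere x negated, so homotopic regions of
    the two hemisphere spheres share one coordinate frame."""
    cents = atlas.centroids.copy()
    right = atlas.hemispheres == "right"
    cents[right, 0] *= -1.0
    return cents


def _cross_hemisphere_distances(atlas: ParcelAtlas) -> np.ndarray:
    cents = mirrored_centroids(atlas)
    return np.arccos(np.clip(cents @ cents.T, -1, 1))


def _module_labels(atlas: ParcelAtlas, k: int, rng: np.random.Generator) -> np.ndarray:
    """Farthest-point module seeds + nearest-centroid assignment, in the
    mirrored frame so modules are bilateral."""
    cents = mirrored_centroids(atlas)
    n = len(cents)
    seeds = [int(rng.integers(n))]
    d = np.arccos(np.clip(cents @ cents[seeds[0]], -1, 1))
    for _ in range(k - 1):
        nxt = int(np.argmax(d))
        seeds.append(nxt)
        d = np.minimum(d, np.arccos(np.clip(cents @ cents[nxt], -1, 1)))
    dist = np.arccos(np.clip(cents @ cents[seeds].T, -1, 1))
    return np.argmin(dist, axis=1)


def simulate_connectome(
    config: SimulationConfig,
    atlas: ParcelAtlas,
    rng: np.random.Generator | None = None,
) -> Connectome:
    """Modular, distance-decaying normative connectome.

    weight(i,j) = module mean · exp(−decay·d(ci,cj)) + noise, symmetrised,
    zero diagonal, clipped to [−1, 1]; cross-hemisphere distances use
    mirrored coordinates so homotopic pairs connect strongly.
    """
    rng = config.stage_rng("connectome") if rng is None else rng
    modules = _module_labels(atlas, config.n_modules, rng)
    d = _cross_hemisphere_distances(atlas)
    same = modules[:, None] == modules[None, :]
    base = np.where(same, config.within_weight, config.between_weight)
    w = base * np.exp(-config.decay * d)
    if config.conn_noise_sd > 0:
        noise = rng.normal(0.0, config.conn_noise_sd, w.shape)
        w = w + (noise + noise.T) / np.sqrt(2.0)
    w = (w + w.T) / 2.0
    np.fill_diagonal(w, 0.0)
    return Connectome(np.clip(w, -1.0, 1.0), np.asarray(atlas.region_ids))


def _zscore(x: np.ndarray) -> np.ndarray:
    return (x - x.mean()) / x.std()


def smooth_region_map(
    atlas: ParcelAtlas,
    length_scale: float = 0.6,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Spatially autocorrelated Gaussian-process sample on region centroids.

    Squared-exponential kernel in geodesic distance (mirrored frame, so the
    map is smooth across homotopic pairs too); unit marginal variance.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    d = _cross_hemisphere_distances(atlas)
    k = np.exp(-0.5 * (d / length_scale) ** 2) + 1e-8 * np.eye(len(d))
    chol = np.linalg.cholesky(k)
    return chol @ rng.standard_normal(len(d))


def plant_epicenter(
    conn: Connectome,
    region: int,
    lam: float,
    noise_seed: int | np.random.Generator | None = None,
    atlas: ParcelAtlas | None = None,
    length_scale: float = 0.6,
) -> np.ndarray:
    """Atrophy map generated by a region's connectivity profile.

    atrophy = λ·z(−conn row) + (1−λ)·z(smooth noise): strongly connected
    neighbours of the epicenter get the most negative (most atrophic)
    values.  With an atlas the noise is a smooth GP map; without, white.
    """
    if not 0 <= lam <= 1:
        raise InvalidParameterError(f"lambda must be in [0, 1], got {lam}")
    if not 0 <= region < conn.n_regions:
        raise IndexError(f"region {region} out of range for {conn.n_regions} regions")
    rng = (
        noise_seed
        if isinstance(noise_seed, np.random.Generator)
        else np.random.default_rng(noise_seed)
    )
    profile = conn.weights[region].copy()
    profile[region] = profile[np.arange(conn.n_regions) != region].mean()  # neutral self entry
    if atlas is not None:
        noise = smooth_region_map(atlas, length_scale, rng)
    else:
        noise = rng.standard_normal(conn.n_regions)
    return lam * _zscore(-profile) + (1.0 - lam) * _zscore(noise)


def plant_hub_atrophy(
    conn: Connectome,
    atlas: ParcelAtlas,
    target_r: float = -0.45,
    seed: int | np.random.Generator | None = None,
    mode: str = "positive",
    length_scale: float = 0.6,
) -> np.ndarray:
    """Atrophy map whose population correlation with weighted-degree
    centrality equals ``target_r`` (sample correlations fluctuate)."""
    from .netmap import weighted_degree

    if not -1 <= target_r <= 1:
        raise InvalidParameterError("target_r must be in [-1, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    c = _zscore(weighted_degree(conn, mode).values)
    noise = _zscore(smooth_region_map(atlas, length_scale, rng))
    return target_r * c + np.sqrt(1.0 - target_r**2) * noise


@dataclass
class SimulatedBundle:
    """Everything one synthetic study provides to the pipeline."""

    config: SimulationConfig
    surface: CorticalSurface
    atlas: ParcelAtlas
    cohort: CohortTable
    vertex_data: VertexDataMatrix
    connectome: Connectome
    atrophy_truth: CohortGroundTruth
    epicenter_region: int
    epicenter_atrophy: np.ndarray = field(repr=False, default=None)


def simulate_bundle(config: SimulationConfig) -> SimulatedBundle:
    """Generate the full, mutually consistent input set for one study."""
    surface = CorticalSurface.bilateral(config.mesh_level, config.sphere_scale)
    atlas = make_atlas(surface, config.n_regions_per_hemisphere, config.stage_rng("atlas"))
    cohort, vdm, truth = simulate_cohort(config, surface)
    conn = simulate_connectome(config, atlas)
    epi_rng = config.stage_rng("epicenter")
    region = (
        int(epi_rng.integers(conn.n_regions))
        if config.epicenter_region is None
        else config.epicenter_region
    )
    atrophy = plant_epicenter(
        conn, region, config.epicenter_lambda, epi_rng, atlas, config.gp_length_scale
    )
    return SimulatedBundle(config, surface, atlas, cohort, vdm, conn, truth, region, atrophy)
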