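# Methods

This note documents the statistical models implemented in `atrophynet`,
the choices made where the methodology is genuinely open, and what the
synthetic-data generator does and does not emulate.

## Geometry

All vertex-level computation happens on triangulated unit spheres, the
registration space of surface-based morphometry. Hemispheres are separate
spheres; a `CorticalSurface` concatenates them with block-diagonal
adjacency, so smoothing and cluster formation never cross the
inter-hemispheric gap. Physical units enter through a `scale` factor: the
default simulated surfaces use scale = 100 (a 100 mm registration sphere,
the FreeSurfer convention), so vertex areas are in mm² and FWHM values in
mm. Positions are stored as unit 3-vectors rather than latitude/longitude
to avoid pole singularities. Region and vertex indices are 0-based
internally; file formats may carry arbitrary integer region ids.

Vertex areas assign one third of each incident triangle to each corner,
so per-vertex areas sum exactly to the mesh area. Icosphere subdivision
level L gives 10·4^L + 2 vertices per hemisphere; the analyses in the test
suite run at L = 3 (642 vertices/hemisphere), a scale at which every
calibration study completes in seconds to minutes on one CPU while leaving
enough resolution for multi-vertex clusters. Nothing in the code depends
on this choice; paper-scale meshes and 10,000-iteration nulls are
configuration values.

## Surface smoothing

Gaussian smoothing of a mesh map is realised as k passes of a symmetric
nearest-neighbor averaging operator

    x_i ← x_i + (1/(d_max+1)) · Σ_{j~i} (x_j − x_i),

which is doubly stochastic: constants are fixed points and the map total
is conserved exactly. By the random-walk variance relation, k passes
approximate a Gaussian kernel with FWHM² ≈ k · 8·ln2 · s̄² (s̄ = mean edge
length), so the pass count for a requested FWHM is
k = round(FWHM² / (8·ln2·s̄²)). A positive FWHM below the mesh resolution
floors at one pass — a mesh cannot smooth by less than one neighbor
exchange; FWHM = 0 is the identity. The equivalence is approximate (the
discrete kernel is not exactly Gaussian); what matters for inference is
that data and null fields are smoothed by the *same* operator, which the
cluster-correction API enforces by checking FWHM metadata.

## Vertex-wise GLM

Each vertex's volume is regressed on [intercept, effect, nuisance…] by
ordinary least squares, vectorised across vertices with a shared design
matrix. The effect is either a case/control indicator (two-class) or the
severity score within cases (one-class); default nuisance covariates are
age (years), sex (0/1), and eTIV (mm³, untransformed), main effects only —
no interactions, the simplest reading of "adjusted for". Effect sizes are
reported as the partial correlation r = sign(t)·√(t²/(t²+df)); p-values
are two-sided.

Rank-deficient designs raise an error naming the collinear columns
(pivoted QR); missing values in any used column raise an explicit
missing-data error rather than silently dropping rows. Exclusions are the
caller's explicit act: the pipeline subsets cases with a finite severity
score and logs the count (e.g., "50 of 53 cases have severity scores").

## Cluster-wise Monte Carlo correction

Suprathreshold vertices (uncorrected p below the vertex-wise threshold,
default 0.001) are grouped into edge-connected components split by effect
sign — inference is two-sided with sign-split clusters, the signed
convention of standard surface-analysis tools, even though a study may
only report one sign. Cluster size is summed vertex area (mm²), which is
robust to mesh resolution, not vertex count.

The null reference simulates independent standard-normal fields on the
analysis mesh, smooths them at the analysis FWHM, renormalises each vertex
to unit variance (the per-vertex SD of the smoothed operator is computed
analytically, and a property test checks it against simulation), converts
to two-sided normal p-values, and records the maximum cluster size per
iteration. This is a Gaussian random-field simulation in the spirit of
FreeSurfer's cluster simulation, not a subject-label permutation; the null
is a model of smooth noise, and it is valid to share one null across
datasets with matched mesh, FWHM and threshold. Cluster p-values use the
add-one convention p = (1+#{null ≥ observed})/(1+n_iter) everywhere a
permutation or simulation null appears, so p = 0 is impossible. The
reference field is normal while observed maps are t-statistics; both are
thresholded at equal tail probability, and the family-wise error
calibration test (200 pure-noise cohorts, shared 500-iteration null)
verifies the approximation empirically. Residual-based FWHM estimation is
out of scope; the analysis FWHM is declared, and the cluster p-value API
refuses a null whose FWHM or threshold metadata differ.

Region-level (e.g., subcortical) tables use Benjamini–Hochberg FDR via
the step-up rule, cross-checked in the tests against a cutoff-enumeration
oracle.

## Network mapping

Weighted-degree centrality is the per-region sum of off-diagonal
connection weights. "Sum of all weighted connections" is ambiguous for
signed correlation matrices; the default drops negative weights
(`positive`), the common normative-connectome practice, with `signed` and
`absolute` switchable and the mode recorded in every output manifest.

Epicenter mapping correlates each region's connectivity profile with the
atrophy map, excluding the region's own entry from both vectors (the zero
diagonal would otherwise bias the correlation). Regions are ranked by
|r|; significance uses the spin test at α = 0.01 by default. No
correction across the 68 regions is applied by default; `fdr_bh` is
available. Subcortical structures, having no spherical coordinates, are
excluded from spin inference.

The spin null draws a uniform random 3-D rotation (Haar measure via
`scipy.stats.special_ortho_group`), applies it to left-hemisphere
centroids and its x-mirrored conjugate M·R·M to the right hemisphere, and
reassigns each original region the value of the nearest rotated centroid
within its hemisphere — assignment with replacement, the simplest
well-defined rule. A cost-minimising one-to-one matching
(``method="hungarian"``) and a geometry-free uniform relabeling
(``method="uniform"``, for region sets without spherical coordinates such
as subcortical structures) are available behind a flag.
Spins are done at parcel-centroid level (not vertex
level before aggregation), and always rotate the atrophy/statistic map,
never the connectome, preserving the graph structure. Tests are two-sided
by default with add-one p-values. Nearest-centroid assignment with
replacement is known to be very slightly liberal; the calibration study
(500 independent smooth map pairs, 1,000 spins) measures a type-I rate
near 6% at nominal 5%, within the binomial acceptance band.

Model objects follow the statsmodels convention: `VertexGLM(...).fit()`
returns a results object carrying stat maps, cluster follow-ups and a
`summary()`; `AtrophyNetworkModel(conn, atlas).fit(atrophy)` returns the
centrality-similarity spin result plus the epicenter table.

## Synthetic-data generator

The generator emulates the *measured* inputs of such a study, starting at
the vertex level — it does not simulate MRI images, cortical
reconstruction, or rsFC time series, so passing tests say nothing about
segmentation or preprocessing robustness. Defaults describe the study
conditions:

- **Cohort**: 53 cases (50 with severity scores — three unscored rows are
  excluded, and logged, by the one-class analyses) and 50 controls.
  Severity is truncated-normal on [0, 54] (mean 18, SD 10), a unimodal
  spread over the scale's range; age ~ N(44, 10) truncated to [18, 80];
  sex Bernoulli(0.79); eTIV ~ N(1.5·10⁶, 1.5·10⁵) mm³. Optional clinical
  covariates (BDI, STAI-trait, antidepressant and weakness-subtype flags)
  are drawn with plausible clinical frequencies and no planted relation
  to volume, so post hoc adjusted models are exercised under the null.
- **Vertex volumes**: baseline 1.5 mm³ plus small linear age/sex/eTIV
  effects plus spatially smooth noise (white noise smoothed at 25 mm FWHM
  and renormalised to SD 0.15 per vertex).
- **Severity effect**: constant inside a geodesic disc (radius 0.35 rad ≈
  35 mm) around a seed vertex, with the slope scaled as
  β = ρ/√(1−ρ²) · σ_noise/σ_severity so that the *population partial
  correlation* after covariate adjustment equals the configured ρ — ρ is
  the single interpretable effect-size knob, directly comparable to the
  analysis output. A 500-cohort property test confirms the realized mean
  partial correlation inside the disc is within ±0.03 of ρ. No
  case/control volume difference is planted by default (the two-class
  contrast is null), matching a study design in which group differences
  are absent but severity correlations are present.
- **Connectome**: weight(i,j) = module mean · exp(−decay·d(ci,cj)) +
  symmetric Gaussian noise, symmetrised, zero diagonal, clipped to
  [−1, 1]; 4 bilateral modules (within 0.45 / between 0.15, decay 1 per
  radian, noise SD 0.1). Cross-hemisphere distances use x-mirrored right
  coordinates so homotopic regions connect strongly, a first-order
  imitation of real rsFC; it does not reproduce empirical degree
  distributions or network-specific topography.
- **Epicenter**: atrophy = λ·z(−profile) + (1−λ)·z(smooth GP noise) for a
  chosen region, λ = 0.7 by default; λ = 1 makes the planted region's
  profile correlation exactly ±1, λ = 0 removes the signal entirely.
  Smooth region noise is a Gaussian-process sample with squared-
  exponential kernel (length scale 0.6 rad) on mirrored centroids.

Every generator stage draws from an rng derived from the master seed by a
fixed offset (`SeedSequence([master, k])`), making bundles bit-reproducible
and pipeline outputs byte-identical across reruns.

## Recovery estimands

The effect-recovery study evaluates the estimated partial r at the
planted disc's central (seed) vertex — the location of the true effect
peak — because there the estimate follows the textbook r sampling
distribution around ρ and the 2·SE band is exact; a maximum over disc
vertices would add a selection bias the band does not model. Epicenter
recovery plants the region uniformly at random per run; under λ = 0 this
makes the nominal region's rank exactly uniform, the basis of the χ²
goodness-of-fit null check.

## Known limitations

- The FWHM-to-iterations calibration is coarse on coarse meshes
  (quantised pass counts); sub-resolution FWHM requests floor at one pass.
- The Monte Carlo cluster null assumes stationary Gaussian noise with the
  declared smoothness; for heavy-tailed or non-stationary data the
  subject-label permutation alternative (`null_method: permutation`,
  naive shuffling of the effect column) is exposed, at the cost of one
  GLM refit per iteration.
- Nearest-centroid spin assignment duplicates some regions per rotation
  (the Hungarian variant avoids this at slightly higher cost).
- Epicenter p-values are uncorrected across regions by default.
- The generator's covariate effects are linear and its noise Gaussian;
  the pipeline's behaviour under realistic artefacts (motion, segmentation
  error) is untested by construction.
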