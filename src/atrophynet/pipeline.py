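"""End-to-end analysis driver.

Reproduces the study's analysis sequence on a real or simulated input
bundle: smooth vertex volumes → two-class (case/control) GLM → one-class
severity GLM within scored cases → cluster extraction and Monte Carlo
cluster-wise correction → post hoc covariate-adjusted reruns and the
functional-weakness subgroup rerun → region aggregation of the severity
partial-correlation map → centrality-similarity spin test → disease
epicenter mapping.  Every table is written as CSV/JSON next to a run
manifest that records all thresholds, iteration counts and seeds; results
are byte-reproducible from the same inputs and master seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .atlas import parcel_means
from .clusters import (
    cluster_table,
    correct_clusters,
    permutation_null_clusters,
    simulate_null_clusters,
)
from .data import VertexDataMatrix
from .exceptions import ConfigurationError, DesignError
from .glm import DesignSpec, VertexGLM
from .io import RunManifest, file_digest, read_bundle, write_bundle
from .netmap import AtrophyNetworkModel
from .simulate import SimulationConfig, simulate_bundle
from .smoothing import smooth_surface

logger = logging.getLogger("atrophynet")

DEFAULT_ANALYSIS = {
    "fwhm": 10.0,
    "vertex_p_threshold": 0.001,
    "cluster_alpha": 0.05,
    "n_cluster_iter": 1000,
    "n_perm": 1000,
    "epicenter_alpha": 0.01,
    "weight_mode": "positive",
    "posthoc": True,
    "network": True,
    "null_method": "gaussian",  # or "permutation" (subject-label shuffling)
    "spin_method": "nearest",  # or "hungarian" / "uniform"
}

POSTHOC_VARIANTS = {
    "bdi_stai": ("bdi", "stai_trait"),
    "antidepressant": ("antidepressant",),
    "subtype": ("subtype_weakness",),
}


@dataclass
class PipelineResult:
    """In-memory handles to everything one run produced."""

    output_dir: Path
    manifest: RunManifest
    group_results: object
    severity_results: object
    network_results: object
    tables: dict


def _load_config(config) -> dict:
    if isinstance(config, (str, Path)):
        config = yaml.safe_load(Path(config).read_text())
    if not isinstance(config, dict):
        raise ConfigurationError("pipeline config must be a mapping or a YAML path")
    return config


def run_pipeline(config, output_dir: str | Path | None = None) -> PipelineResult:
    """Execute the full pipeline from a config mapping or YAML file.

    Config keys: ``simulate`` (SimulationConfig overrides) or ``input_dir``
    (a bundle on disk); ``analysis`` (thresholds, counts — see
    ``DEFAULT_ANALYSIS``); ``master_seed``; ``output_dir``.
    """
    cfg = _load_config(config)
    analysis = {**DEFAULT_ANALYSIS, **cfg.get("analysis", {})}
    master_seed = int(cfg.get("master_seed", 0))
    outdir = Path(output_dir or cfg.get("output_dir", "atrophynet_run"))
    outdir.mkdir(parents=True, exist_ok=True)

    # ---------------------------------------------------------- inputs
    if "input_dir" in cfg:
        surface, atlas, cohort, vdm, conn, _ = read_bundle(cfg["input_dir"])
        input_paths = {"input_dir": str(cfg["input_dir"])}
        logger.info("loaded input bundle from %s", cfg["input_dir"])
    else:
        sim_overrides = dict(cfg.get("simulate", {}))
        sim_overrides.setdefault("master_seed", master_seed)
        sim_config = SimulationConfig(**sim_overrides)
        bundle = simulate_bundle(sim_config)
        surface, atlas, cohort, vdm, conn = (
            bundle.surface, bundle.atlas, bundle.cohort, bundle.vertex_data, bundle.connectome,
        )
        paths = write_bundle(bundle, outdir / "inputs")
        input_paths = {k: str(p) for k, p in paths.items()}
        logger.info("simulated input bundle (master seed %d)", sim_config.master_seed)
    if conn.n_regions != atlas.n_regions:
        raise ConfigurationError(
            f"connectome has {conn.n_regions} regions but atlas has {atlas.n_regions}"
        )
    if vdm.n_vertices != surface.n_vertices:
        raise ConfigurationError(
            f"vertex matrix has {vdm.n_vertices} columns but surface has "
            f"{surface.n_vertices} vertices"
        )

    tables: dict[str, Path] = {}

    def save(name: str, df: pd.DataFrame) -> None:
        p = outdir / f"{name}.csv"
        df.to_csv(p, index=False, float_format="%.12g")
        tables[name] = p

    # ---------------------------------------------------- smoothing + null
    fwhm = float(analysis["fwhm"])
    smoothed = VertexDataMatrix(
        smooth_surface(vdm.values, surface, fwhm), vdm.subject_ids, surface
    )
    logger.info("smoothed %d subject maps at FWHM %.1f", smoothed.n_subjects, fwhm)
    vertex_thr = float(analysis["vertex_p_threshold"])
    n_null = int(analysis["n_cluster_iter"])
    shared_null = None
    if analysis["null_method"] == "gaussian":
        shared_null = simulate_null_clusters(
            surface, fwhm, vertex_thr, n_null,
            seed=np.random.default_rng(np.random.SeedSequence([master_seed, 101])),
        )
        logger.info("simulated %d null fields for cluster correction", n_null)
    elif analysis["null_method"] != "permutation":
        raise ConfigurationError(
            f"null_method must be 'gaussian' or 'permutation', got {analysis['null_method']!r}"
        )

    null_counter = [0]

    def analyse(cohort_part, design: DesignSpec):
        res = VertexGLM(smoothed, cohort_part, design).fit()
        if shared_null is not None:
            null = shared_null
        else:
            null_counter[0] += 1
            null = permutation_null_clusters(
                smoothed, cohort_part, design, surface, vertex_thr, n_null,
                seed=np.random.default_rng(
                    np.random.SeedSequence([master_seed, 300 + null_counter[0]])
                ),
                fwhm=fwhm,
            )
        clusters = correct_clusters(
            res.extract_clusters(vertex_thr), null, fwhm, vertex_thr
        )
        return res, cluster_table(clusters, surface)

    # ------------------------------------------------- two-class group GLM
    group_design = DesignSpec(effect="group_contrast")
    group_res, group_clusters = analyse(cohort, group_design)
    save("group_statmap", group_res.to_frame().reset_index())
    save("group_clusters", group_clusters)

    # ---------------------------------------------- one-class severity GLM
    cases = cohort.cases()
    scored, n_excluded = cases.with_severity()
    logger.info(
        "%d of %d cases have severity scores; %d excluded from one-class analyses",
        len(scored), len(cases), n_excluded,
    )
    severity_design = DesignSpec(effect="severity")
    severity_res, severity_clusters = analyse(scored, severity_design)
    save("severity_statmap", severity_res.to_frame().reset_index())
    save("severity_clusters", severity_clusters)

    # ------------------------------------------------------ post hoc reruns
    designs = {"group": group_design, "severity": severity_design}
    if analysis["posthoc"]:
        for name, extra in POSTHOC_VARIANTS.items():
            if not all(c in scored.table.columns for c in extra):
                logger.info("post hoc variant %s skipped: columns %s absent", name, extra)
                continue
            design = DesignSpec(effect="severity", extra_nuisance=extra)
            try:
                _, tbl = analyse(scored, design)
            except DesignError as exc:
                logger.warning("post hoc variant %s not estimable: %s", name, exc)
                continue
            designs[f"posthoc_{name}"] = design
            save(f"posthoc_{name}_clusters", tbl)
        if "subtype_weakness" in scored.table.columns:
            design = DesignSpec(effect="severity", subset="subtype_weakness")
            try:
                _, tbl = analyse(scored, design)
                designs["subgroup_weakness"] = design
                save("subgroup_weakness_clusters", tbl)
            except DesignError as exc:
                logger.warning("weakness subgroup rerun not estimable: %s", exc)

    # --------------------------------------------------- network mapping
    net_res = None
    if analysis["network"]:
        atrophy = parcel_means(severity_res.stat_map.r, atlas, surface.vertex_areas)
        save(
            "region_atrophy",
            pd.DataFrame(
                {"region_id": atlas.region_ids, "region_name": atlas.region_names,
                 "atrophy_r": atrophy}
            ),
        )
        net_model = AtrophyNetworkModel(conn, atlas, str(analysis["weight_mode"]))
        net_res = net_model.fit(
            atrophy,
            n_perm=int(analysis["n_perm"]),
            alpha=float(analysis["epicenter_alpha"]),
            seed=np.random.default_rng(np.random.SeedSequence([master_seed, 202])),
            spin_method=str(analysis["spin_method"]),
        )
        save(
            "centrality",
            pd.DataFrame(
                {"region_id": atlas.region_ids, "region_name": atlas.region_names,
                 "weighted_degree": net_model.centrality.values}
            ),
        )
        save("epicenters", net_res.epicenters.to_frame())
        similarity = {
            "r": net_res.similarity.observed,
            "p_spin": net_res.similarity.p,
            "n_perm": net_res.similarity.n_perm,
            "tail": net_res.similarity.tail,
            "weight_mode": net_model.weight_mode,
        }
        sim_path = outdir / "similarity.json"
        sim_path.write_text(json.dumps(similarity, indent=2, sort_keys=True))
        tables["similarity"] = sim_path
        logger.info(
            "centrality similarity r=%+.3f (p_spin=%.4f); %d epicenter(s) at alpha=%g",
            similarity["r"], similarity["p_spin"],
            int(net_res.epicenters.significant.sum()), analysis["epicenter_alpha"],
        )

    # ----------------------------------------------------------- manifest
    manifest = RunManifest(
        input_digests={
            k: file_digest(v) for k, v in input_paths.items() if Path(v).is_file()
        },
        parameters={
            "analysis": {k: analysis[k] for k in DEFAULT_ANALYSIS},
            "designs": {k: dataclasses.asdict(d) for k, d in designs.items()},
            "n_cases_scored": len(scored),
            "n_cases_excluded": n_excluded,
        },
        seeds={"master": master_seed, "cluster_null": [master_seed, 101],
               "network": [master_seed, 202]},
    )
    manifest.to_json(outdir / "manifest.json")
    return PipelineResult(outdir, manifest, group_res, severity_res, net_res, tables)
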