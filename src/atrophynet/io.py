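"""Plain-text readers and writers plus the run manifest.

All interchange formats are text: OFF meshes, CSV tables and matrices,
YAML configuration, JSON manifests.  Every reader re-validates the type
invariants at load time and raises :class:`LoadError` citing the offending
location — silent coercion is forbidden.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .atlas import ParcelAtlas
from .data import CohortTable, Connectome, VertexDataMatrix
from .exceptions import AtrophyNetError, LoadError
from .geometry import CorticalSurface, SphereMesh, as_surface


# ---------------------------------------------------------------- OFF meshes

def write_mesh(mesh: SphereMesh, path: str | Path) -> None:
    """OFF-format triangle mesh (header, counts, coordinates, faces)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("OFF\n")
        fh.write(f"{mesh.n_vertices} {len(mesh.faces)} 0\n")
        for v in mesh.vertices:
            fh.write(f"{v[0]:.17g} {v[1]:.17g} {v[2]:.17g}\n")
        for f in mesh.faces:
            fh.write(f"3 {f[0]} {f[1]} {f[2]}\n")


def read_mesh(path: str | Path, hemisphere: str = "left", scale: float = 1.0) -> SphereMesh:
    path = Path(path)
    lines = [ln.strip() for ln in path.read_text().splitlines() if ln.strip()]
    if not lines or lines[0] != "OFF":
        raise LoadError(f"{path}: not an OFF file (missing 'OFF' header)")
    try:
        nv, nf, _ = (int(x) for x in lines[1].split())
        verts = np.array([[float(x) for x in ln.split()] for ln in lines[2 : 2 + nv]])
        faces = []
        for ln in lines[2 + nv : 2 + nv + nf]:
            parts = [int(x) for x in ln.split()]
            if parts[0] != 3:
                raise LoadError(f"{path}: non-triangular face '{ln}'")
            faces.append(parts[1:4])
    except (ValueError, IndexError) as exc:
        raise LoadError(f"{path}: malformed OFF content ({exc})") from exc
    try:
        return SphereMesh(verts, np.array(faces, dtype=np.int64), hemisphere, scale)
    except AtrophyNetError as exc:
        raise LoadError(f"{path}: {exc}") from exc


# ------------------------------------------------------------------- atlases

def write_atlas(atlas: ParcelAtlas, path: str | Path,
                assignment_path: str | Path | None = None) -> None:
    df = pd.DataFrame(
        {
            "region_id": atlas.region_ids,
            "region_name": atlas.region_names,
            "hemisphere": atlas.hemispheres,
            "cx": atlas.centroids[:, 0],
            "cy": atlas.centroids[:, 1],
            "cz": atlas.centroids[:, 2],
        }
    )
    df.to_csv(path, index=False, float_format="%.17g")
    if assignment_path is not None and atlas.vertex_assignment is not None:
        pd.DataFrame(
            {
                "vertex": np.arange(len(atlas.vertex_assignment)),
                "region_id": atlas.region_ids[atlas.vertex_assignment],
            }
        ).to_csv(assignment_path, index=False)


def read_atlas(path: str | Path, assignment_path: str | Path | None = None,
               surface: CorticalSurface | None = None) -> ParcelAtlas:
    path = Path(path)
    df = pd.read_csv(path)
    required = {"region_id", "region_name", "hemisphere", "cx", "cy", "cz"}
    if not required.issubset(df.columns):
        raise LoadError(f"{path}: atlas CSV must have columns {sorted(required)}")
    assignment = None
    if assignment_path is not None:
        adf = pd.read_csv(assignment_path)
        id_to_index = {rid: i for i, rid in enumerate(df["region_id"])}
        try:
            assignment = np.array([id_to_index[r] for r in adf["region_id"]])
        except KeyError as exc:
            raise LoadError(
                f"{assignment_path}: vertex assigned to unknown region_id {exc.args[0]}"
            ) from exc
    try:
        return ParcelAtlas(
            region_ids=df["region_id"].to_numpy(),
            region_names=df["region_name"].tolist(),
            hemispheres=df["hemisphere"].to_numpy(dtype=object),
            centroids=df[["cx", "cy", "cz"]].to_numpy(dtype=float),
            vertex_assignment=assignment,
            surface=surface,
        )
    except AtrophyNetError as exc:
        raise LoadError(f"{path}: {exc}") from exc


# -------------------------------------------------------------------- tables

def write_cohort(cohort: CohortTable, path: str | Path) -> None:
    cohort.table.to_csv(path, index=False, float_format="%.17g")


def read_cohort(path: str | Path) -> CohortTable:
    try:
        return CohortTable(pd.read_csv(Path(path)))
    except AtrophyNetError as exc:
        raise LoadError(f"{path}: {exc}") from exc


def write_vertex_matrix(vdm: VertexDataMatrix, path: str | Path) -> None:
    df = pd.DataFrame(
        vdm.values, columns=[f"v{i:05d}" for i in range(vdm.n_vertices)]
    )
    df.insert(0, "subject_id", vdm.subject_ids)
    df.to_csv(path, index=False, float_format="%.17g")


def read_vertex_matrix(path: str | Path, surface: CorticalSurface | None = None) -> VertexDataMatrix:
    df = pd.read_csv(Path(path))
    if "subject_id" not in df.columns:
        raise LoadError(f"{path}: vertex matrix CSV needs a subject_id column")
    values = df.drop(columns="subject_id").to_numpy(dtype=float)
    try:
        return VertexDataMatrix(values, df["subject_id"].to_numpy(), surface)
    except AtrophyNetError as exc:
        raise LoadError(f"{path}: {exc}") from exc


def write_connectome(conn: Connectome, path: str | Path) -> None:
    ids = [str(r) for r in conn.region_ids]
    pd.DataFrame(conn.weights, index=ids, columns=ids).to_csv(path, float_format="%.17g")


def read_connectome(path: str | Path) -> Connectome:
    path = Path(path)
    df = pd.read_csv(path, index_col=0)
    w = df.to_numpy(dtype=float)
    asym = np.abs(w - w.T)
    if w.shape[0] == w.shape[1] and asym.size and asym.max() > 1e-9:
        i, j = np.unravel_index(np.argmax(asym), asym.shape)
        raise LoadError(
            f"{path}: asymmetric connectome at row {str(df.index[i])!r}, "
            f"column {str(df.columns[j])!r} ({w[i, j]:g} vs {w[j, i]:g})"
        )
    try:
        return Connectome(w, df.index.to_numpy(dtype=np.int64))
    except (AtrophyNetError, ValueError) as exc:
        raise LoadError(f"{path}: {exc}") from exc


# ------------------------------------------------------------------ manifest

@dataclass
class RunManifest:
    """Reproducibility record written next to every output bundle.

    Every stochastic result in a bundle is traceable to the seeds stored
    here; thresholds and iteration counts are recorded verbatim.
    """

    version: str = __version__
    created: str = ""
    input_digests: dict = field(default_factory=dict)
    parameters: dict = field(default_factory=dict)
    seeds: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.created:
            self.created = datetime.now(timezone.utc).isoformat()

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "RunManifest":
        return cls(**json.loads(Path(path).read_text()))

    def comparable(self) -> dict:
        """Manifest content minus wall-clock fields, for run-to-run diffs."""
        d = dataclasses.asdict(self)
        d.pop("created", None)
        return d


def file_digest(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


# ------------------------------------------------------------- bundle on disk

def write_bundle(bundle, outdir: str | Path) -> dict[str, Path]:
    """Write a :class:`~atrophynet.simulate.SimulatedBundle` as plain text."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    surface = as_surface(bundle.surface)
    paths: dict[str, Path] = {}
    for mesh in surface.meshes:
        p = outdir / f"mesh_{mesh.hemisphere}.off"
        write_mesh(mesh, p)
        paths[f"mesh_{mesh.hemisphere}"] = p
    paths["atlas"] = outdir / "atlas.csv"
    paths["vertex_assignment"] = outdir / "vertex_assignment.csv"
    write_atlas(bundle.atlas, paths["atlas"], paths["vertex_assignment"])
    paths["cohort"] = outdir / "cohort.csv"
    write_cohort(bundle.cohort, paths["cohort"])
    paths["vertex_data"] = outdir / "vertex_data.csv"
    write_vertex_matrix(bundle.vertex_data, paths["vertex_data"])
    paths["connectome"] = outdir / "connectome.csv"
    write_connectome(bundle.connectome, paths["connectome"])
    truth = {
        "seed_vertex": int(bundle.atrophy_truth.seed_vertex),
        "disc_vertices": [int(v) for v in bundle.atrophy_truth.disc_vertices],
        "rho": float(bundle.atrophy_truth.rho),
        "severity_beta": float(bundle.atrophy_truth.severity_beta),
        "epicenter_region": int(bundle.epicenter_region),
        "epicenter_lambda": float(bundle.config.epicenter_lambda),
    }
    paths["ground_truth"] = outdir / "ground_truth.json"
    paths["ground_truth"].write_text(json.dumps(truth, indent=2, sort_keys=True))
    paths["config"] = outdir / "simulation_config.yaml"
    paths["config"].write_text(yaml.safe_dump(dataclasses.asdict(bundle.config), sort_keys=True))
    return paths


def read_bundle(indir: str | Path, scale: float | None = None):
    """Load the input set written by :func:`write_bundle`.

    Returns (surface, atlas, cohort, vertex_data, connectome, config dict).
    """
    indir = Path(indir)
    cfg_path = indir / "simulation_config.yaml"
    cfg = yaml.safe_load(cfg_path.read_text()) if cfg_path.exists() else {}
    if scale is None:
        scale = float(cfg.get("sphere_scale", 1.0))
    meshes = []
    for hemi in ("left", "right"):
        p = indir / f"mesh_{hemi}.off"
        if p.exists():
            meshes.append(read_mesh(p, hemi, scale))
    if not meshes:
        raise LoadError(f"{indir}: no mesh_left.off / mesh_right.off found")
    surface = CorticalSurface(meshes)
    assignment = indir / "vertex_assignment.csv"
    atlas = read_atlas(
        indir / "atlas.csv",
        assignment if assignment.exists() else None,
        surface,
    )
    cohort = read_cohort(indir / "cohort.csv")
    vdm = read_vertex_matrix(indir / "vertex_data.csv", surface)
    conn = read_connectome(indir / "connectome.csv")
    return surface, atlas, cohort, vdm, conn, cfg
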