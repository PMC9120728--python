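"""Tabular containers: cohort, vertex-data matrix, connectome.

These wrap pandas/numpy objects with invariant checks enforced at
construction (and therefore at load time), so downstream statistics can
assume clean inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import InvalidConnectomeError, LoadError
from .geometry import SurfaceLike

SEVERITY_MAX = 54.0  # S-FMDRS total score ceiling

REQUIRED_COHORT_COLUMNS = ("subject_id", "group", "severity", "age", "sex", "etiv")
OPTIONAL_COHORT_COLUMNS = ("bdi", "stai_trait", "antidepressant", "subtype_weakness")


@dataclass
class CohortTable:
    """Subjects × covariates design information.

    ``group`` is "case"/"control"; ``severity`` is an S-FMDRS-like score in
    [0, 54] (NaN allowed for controls and unscored cases); ``sex`` is
    0/1-coded; ``etiv`` is estimated total intracranial volume in mm³.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.table
        missing = [c for c in REQUIRED_COHORT_COLUMNS if c not in df.columns]
        if missing:
            raise LoadError(f"cohort table missing required columns: {missing}")
        if df["subject_id"].duplicated().any():
            dup = df.loc[df["subject_id"].duplicated(), "subject_id"].iloc[0]
            raise LoadError(f"duplicate subject_id {dup!r} in cohort table")
        bad_group = set(df["group"].unique()) - {"case", "control"}
        if bad_group:
            raise LoadError(f"group values must be case/control, got {sorted(bad_group)}")
        sev = df["severity"].to_numpy(dtype=float)
        finite = np.isfinite(sev)
        if finite.any() and ((sev[finite] < 0) | (sev[finite] > SEVERITY_MAX)).any():
            raise LoadError(f"severity scores must lie in [0, {SEVERITY_MAX:g}]")
        for col in ("age", "sex", "etiv"):
            if not np.isfinite(df[col].to_numpy(dtype=float)).all():
                raise LoadError(f"non-finite values in cohort column {col!r}")
        self.table = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def subject_ids(self) -> np.ndarray:
        return self.table["subject_id"].to_numpy()

    def subset(self, mask: np.ndarray) -> "CohortTable":
        return CohortTable(self.table.loc[np.asarray(mask)].reset_index(drop=True))

    def cases(self) -> "CohortTable":
        return self.subset((self.table["group"] == "case").to_numpy())

    def with_severity(self) -> tuple["CohortTable", int]:
        """Rows with a finite severity score, plus the number excluded."""
        ok = np.isfinite(self.table["severity"].to_numpy(dtype=float))
        return self.subset(ok), int((~ok).sum())


@dataclass
class VertexDataMatrix:
    """Subjects × vertices morphometric values (e.g., vertex volume, mm³).

    Row order is bijective with a :class:`CohortTable`; column count must
    match the surface vertex count.
    """

    values: np.ndarray
    subject_ids: np.ndarray
    surface: SurfaceLike | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        self.subject_ids = np.asarray(self.subject_ids)
        if self.values.shape[0] != len(self.subject_ids):
            raise LoadError(
                f"vertex matrix has {self.values.shape[0]} rows but "
                f"{len(self.subject_ids)} subject ids"
            )
        if self.surface is not None and self.values.shape[1] != self.surface.n_vertices:
            raise LoadError(
                f"vertex matrix has {self.values.shape[1]} columns but the "
                f"surface has {self.surface.n_vertices} vertices"
            )

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_vertices(self) -> int:
        return self.values.shape[1]

    def aligned_to(self, cohort: CohortTable) -> np.ndarray:
        """Rows reordered to the cohort's subject order."""
        index = {s: i for i, s in enumerate(self.subject_ids)}
        try:
            rows = [index[s] for s in cohort.subject_ids]
        except KeyError as exc:  # pragma: no cover - defensive
            raise LoadError(f"subject {exc.args[0]!r} missing from vertex matrix") from exc
        return self.values[rows]


@dataclass
class Connectome:
    """Symmetric region × region weighted connectivity (correlation-like).

    Weights live in [−1, 1] with a zero diagonal; region order matches a
    :class:`ParcelAtlas`.
    """

    weights: np.ndarray
    region_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise InvalidConnectomeError(f"connectome must be square, got {w.shape}")
        asym = np.abs(w - w.T)
        if asym.max() > 1e-9:
            i, j = np.unravel_index(np.argmax(asym), asym.shape)
            raise InvalidConnectomeError(
                f"connectome asymmetric at ({i}, {j}): {w[i, j]!r} vs {w[j, i]!r}"
            )
        if np.abs(np.diag(w)).max() > 1e-12:
            k = int(np.argmax(np.abs(np.diag(w))))
            raise InvalidConnectomeError(f"nonzero diagonal at region {k}")
        if np.abs(w).max() > 1.0 + 1e-9:
            raise InvalidConnectomeError("connectome weights must lie in [-1, 1]")
        self.weights = w
        if self.region_ids is None:
            self.region_ids = np.arange(w.shape[0], dtype=np.int64)
        else:
            self.region_ids = np.asarray(self.region_ids, dtype=np.int64)
            if len(self.region_ids) != w.shape[0]:
                raise InvalidConnectomeError("region id count does not match matrix size")

    @property
    def n_regions(self) -> int:
        return self.weights.shape[0]
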