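"""Vertex-wise general linear models.

The morphometric question is posed per vertex: does volume differ between
cases and controls (two-class GLM), or does it track symptom severity
within cases (one-class GLM), adjusting for age, sex and estimated total
intracranial volume?  Ordinary least squares is fitted massively in
parallel across vertices with a shared design matrix; the effect column's
t statistic is converted to the partial correlation

    r = sign(t) * sqrt(t² / (t² + df)),

the scale on which effect sizes are reported.

Follows the statsmodels convention: construct a :class:`VertexGLM` from
data, call :meth:`~VertexGLM.fit`, and read estimates, maps and the
summary table off the returned :class:`VertexGLMResults`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as st
from statsmodels.stats.multitest import multipletests

from .data import CohortTable, VertexDataMatrix
from .exceptions import DesignError, InvalidParameterError, MissingDataError
from .geometry import SurfaceLike

DEFAULT_NUISANCE = ("age", "sex", "etiv")


@dataclass(frozen=True)
class DesignSpec:
    """Which effect is tested and which covariates are partialled out.

    effect : "group_contrast" (case vs control indicator) or "severity".
    nuisance : ordered covariate names, default (age, sex, etiv).
    extra_nuisance : post hoc covariates appended to the nuisance set,
        e.g. ("bdi", "stai_trait") or ("antidepressant",).
    subset : optional boolean cohort column restricting the fitted rows
        (e.g. "subtype_weakness" for the functional-weakness subgroup).
    """

    effect: str = "severity"
    nuisance: tuple[str, ...] = DEFAULT_NUISANCE
    extra_nuisance: tuple[str, ...] = ()
    subset: str | None = None

    def __post_init__(self) -> None:
        if self.effect not in ("group_contrast", "severity"):
            raise DesignError(f"unknown effect {self.effect!r}")
        covs = self.nuisance + self.extra_nuisance
        if len(set(covs)) != len(covs):
            raise DesignError("duplicate nuisance covariates")
        effect_col = "severity" if self.effect == "severity" else "group"
        if effect_col in covs:
            raise DesignError(f"effect column {effect_col!r} also listed as nuisance")

    @property
    def covariates(self) -> tuple[str, ...]:
        return self.nuisance + self.extra_nuisance


@dataclass
class StatMap:
    """Per-vertex (or per-region) effect statistics from one GLM."""

    estimate: np.ndarray
    t: np.ndarray
    r: np.ndarray  # partial correlation of effect with outcome
    p: np.ndarray  # two-sided, uncorrected
    df: int
    effect: str
    surface: SurfaceLike | None = field(default=None, repr=False)

    def __len__(self) -> int:
        return len(self.t)


def _collinear_columns(X: np.ndarray, names: list[str]) -> list[str]:
    """Columns implicated in a rank deficiency, via pivoted QR."""
    from scipy.linalg import qr

    _, r, piv = qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
    bad = [names[piv[i]] for i in range(len(diag)) if diag[i] <= tol]
    return bad or names


def build_design(cohort: CohortTable, design: DesignSpec) -> tuple[np.ndarray, list[str], np.ndarray]:
    """Assemble (X, column names, row mask) from a cohort table.

    X columns are [intercept, effect, *covariates]; the effect sits in
    column 1.  Raises :class:`MissingDataError` on any NaN in a used column
    — rows are never dropped silently.
    """
    df = cohort.table
    mask = np.ones(len(df), dtype=bool)
    if design.subset is not None:
        if design.subset not in df.columns:
            raise DesignError(f"subset column {design.subset!r} not in cohort table")
        mask &= df[design.subset].to_numpy(dtype=float) > 0
    sub = df.loc[mask]
    if design.effect == "severity":
        effect = sub["severity"].to_numpy(dtype=float)
    else:
        effect = (sub["group"] == "case").to_numpy(dtype=float)
    cols = {"intercept": np.ones(len(sub)), design.effect: effect}
    for name in design.covariates:
        if name not in sub.columns:
            raise DesignError(f"covariate {name!r} not in cohort table")
        cols[name] = sub[name].to_numpy(dtype=float)
    names = list(cols)
    X = np.column_stack(list(cols.values()))
    bad = [n for n, c in cols.items() if not np.isfinite(c).all()]
    if bad:
        raise MissingDataError(
            f"missing or non-finite values in design columns {bad}; "
            "subset the cohort explicitly before fitting"
        )
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise DesignError(f"design matrix is rank deficient; collinear columns: "
                          f"{_collinear_columns(X, names)}")
    return X, names, mask


class VertexGLM:
    """Mass-univariate OLS of vertex data on an effect plus nuisance terms.

    Parameters
    ----------
    data : VertexDataMatrix or (subjects × vertices) array in cohort order.
    cohort : CohortTable supplying effect and covariate columns.
    design : DesignSpec.
    """

    def __init__(
        self,
        data: VertexDataMatrix | np.ndarray,
        cohort: CohortTable,
        design: DesignSpec = DesignSpec(),
    ):
        if isinstance(data, VertexDataMatrix):
            self.surface = data.surface
            values = data.aligned_to(cohort)
        else:
            self.surface = None
            values = np.atleast_2d(np.asarray(data, dtype=float))
            if values.shape[0] != len(cohort):
                raise DesignError(
                    f"data has {values.shape[0]} rows but cohort has {len(cohort)} subjects"
                )
        self.cohort = cohort
        self.design = design
        self.X, self.columns, self.row_mask = build_design(cohort, design)
        self.Y = values[self.row_mask]
        n, p = self.X.shape
        if n <= p + 2:
            raise DesignError(f"need n > {p + 2} subjects for a {p}-column design, got {n}")
        if not np.isfinite(self.Y).all():
            raise MissingDataError("non-finite values in the vertex data matrix")

    def fit(self) -> "VertexGLMResults":
        X, Y = self.X, self.Y
        n, p = X.shape
        df = n - p
        xtx_inv = np.linalg.inv(X.T @ X)
        beta = xtx_inv @ X.T @ Y
        resid = Y - X @ beta
        sigma2 = np.einsum("ij,ij->j", resid, resid) / df
        se = np.sqrt(np.maximum(sigma2 * xtx_inv[1, 1], 0.0))
        est = beta[1]
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(se > 0, est / se, np.where(est == 0, 0.0, np.inf * np.sign(est)))
            r = np.where(np.isinf(t), np.sign(t), np.sign(t) * np.sqrt(t**2 / (t**2 + df)))
        pvals = np.where(np.isinf(t), 0.0, 2.0 * st.t.sf(np.abs(t), df))
        stat = StatMap(est, t, r, pvals, df, self.design.effect, self.surface)
        return VertexGLMResults(self, stat)


class VertexGLMResults:
    """Fitted vertex-wise GLM: stat maps plus cluster-level follow-ups."""

    def __init__(self, model: VertexGLM, stat_map: StatMap):
        self.model = model
        self.stat_map = stat_map

    @property
    def df_resid(self) -> int:
        return self.stat_map.df

    def extract_clusters(self, vertex_p_threshold: float = 0.001):
        from .clusters import extract_clusters

        if self.model.surface is None:
            raise DesignError("cluster extraction needs a surface-backed model")
        return extract_clusters(self.stat_map, self.model.surface, vertex_p_threshold)

    def to_frame(self) -> pd.DataFrame:
        s = self.stat_map
        return pd.DataFrame(
            {"estimate": s.estimate, "t": s.t, "r": s.r, "p_uncorrected": s.p}
        ).rename_axis("vertex")

    def summary(self) -> str:
        s = self.stat_map
        peak = int(np.argmax(np.abs(s.t)))
        lines = [
            "Vertex-wise GLM results",
            "=" * 47,
            f"effect:            {self.model.design.effect}",
            f"nuisance:          {', '.join(self.model.design.covariates)}",
            f"n subjects:        {self.model.X.shape[0]}",
            f"residual df:       {s.df}",
            f"n vertices:        {len(s)}",
            f"peak |t|:          {np.abs(s.t).max():.3f} at vertex {peak}",
            f"peak partial r:    {s.r[peak]:+.3f}",
            f"min p (uncorr.):   {s.p.min():.3g}",
        ]
        return "\n".join(lines)


def fit_vertex_glm(
    data: VertexDataMatrix | np.ndarray,
    cohort: CohortTable,
    design: DesignSpec = DesignSpec(),
) -> StatMap:
    """Functional entry point; returns just the :class:`StatMap`."""
    return VertexGLM(data, cohort, design).fit().stat_map


def fdr_bh(pvalues: np.ndarray, q: float = 0.05) -> tuple[np.ndarray, float]:
    """Benjamini–Hochberg step-up over a p-value vector.

    Returns (rejection mask, largest rejected p or 0.0 when nothing is
    rejected).  Used for region-table (subcortical-style) corrections.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), 0.0
    if np.any((p < 0) | (p > 1)) or not np.isfinite(p).all():
        raise InvalidParameterError("p-values must lie in [0, 1]")
    if not 0 < q < 1:
        raise InvalidParameterError(f"q must be in (0, 1), got {q}")
    reject, _, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    threshold = float(p[reject].max()) if reject.any() else 0.0
    return reject, threshold
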