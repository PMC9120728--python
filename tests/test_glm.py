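"""Vertex-wise GLM: estimates, partial correlations, error handling, FDR."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from atrophynet import CohortTable, DesignSpec, VertexGLM, fdr_bh, fit_vertex_glm
from atrophynet.exceptions import DesignError, InvalidParameterError, MissingDataError


def make_cohort(n=40, seed=0, group=None, severity=None):
    rng = np.random.default_rng(seed)
    df = pd.DataFrame(
        {
            "subject_id": [f"s{i}" for i in range(n)],
            "group": group if group is not None else ["case"] * n,
            "severity": severity if severity is not None else rng.uniform(0, 54, n),
            "age": rng.uniform(20, 70, n),
            "sex": rng.integers(0, 2, n).astype(float),
            "etiv": rng.normal(1.5e6, 1e5, n),
        }
    )
    return CohortTable(df)


def test_perfect_linear_dependence_gives_r_one():
    cohort = make_cohort(30, seed=1)
    y = cohort.table["severity"].to_numpy()[:, None] * np.ones((1, 5))
    stat = fit_vertex_glm(y, cohort, DesignSpec(effect="severity"))
    np.testing.assert_allclose(stat.r, 1.0)
    np.testing.assert_allclose(stat.p, 0.0, atol=1e-12)


def test_identical_groups_give_null_contrast():
    half = 15
    rng = np.random.default_rng(3)
    base = rng.standard_normal((half, 4))
    cohort = make_cohort(
        2 * half, seed=2, group=["case"] * half + ["control"] * half,
        severity=np.r_[rng.uniform(0, 54, half), np.full(half, np.nan)],
    )
    # same covariates and identical vertex values in both groups
    tbl = cohort.table
    for col in ("age", "sex", "etiv"):
        tbl.loc[half:, col] = tbl.loc[: half - 1, col].to_numpy()
    stat = fit_vertex_glm(np.vstack([base, base]), CohortTable(tbl),
                          DesignSpec(effect="group_contrast"))
    np.testing.assert_allclose(stat.t, 0.0, atol=1e-10)
    np.testing.assert_allclose(stat.p, 1.0, atol=1e-10)


def test_intercept_only_nuisance_reproduces_pearson_r(rng):
    """With no covariates the partial r must equal the plain Pearson
    correlation to 1e-10."""
    cohort = make_cohort(35, seed=4)
    y = rng.standard_normal((35, 50))
    stat = fit_vertex_glm(y, cohort, DesignSpec(effect="severity", nuisance=()))
    sev = cohort.table["severity"].to_numpy()
    expected = [np.corrcoef(sev, y[:, v])[0, 1] for v in range(50)]
    np.testing.assert_allclose(stat.r, expected, atol=1e-10)


def test_against_statsmodels_ols(rng):
    """Estimates, t and p agree with an independent statsmodels fit."""
    cohort = make_cohort(42, seed=5)
    y = rng.standard_normal((42, 3))
    stat = fit_vertex_glm(y, cohort, DesignSpec(effect="severity"))
    X = sm.add_constant(
        cohort.table[["severity", "age", "sex", "etiv"]].to_numpy()
    )
    for v in range(3):
        fit = sm.OLS(y[:, v], X).fit()
        assert stat.estimate[v] == pytest.approx(fit.params[1], rel=1e-10)
        assert stat.t[v] == pytest.approx(fit.tvalues[1], rel=1e-10)
        assert stat.p[v] == pytest.approx(fit.pvalues[1], rel=1e-8)
    assert stat.df == 42 - 5


def test_partial_r_t_monotone_and_sign_consistent(rng):
    cohort = make_cohort(40, seed=6)
    y = rng.standard_normal((40, 200))
    stat = fit_vertex_glm(y, cohort, DesignSpec(effect="severity"))
    order = np.argsort(stat.t)
    assert (np.diff(stat.r[order]) >= -1e-12).all()
    nonzero = stat.estimate != 0
    assert (np.sign(stat.r[nonzero]) == np.sign(stat.estimate[nonzero])).all()
    assert (np.abs(stat.r) <= 1).all()
    assert ((stat.p >= 0) & (stat.p <= 1)).all()


def test_rank_deficient_design_names_columns():
    cohort = make_cohort(30, seed=7)
    tbl = cohort.table.copy()
    tbl["etiv"] = 2.0 * tbl["age"]  # exact collinearity
    with pytest.raises(DesignError, match="etiv|age"):
        fit_vertex_glm(np.zeros((30, 2)), CohortTable(tbl), DesignSpec(effect="severity"))


def test_missing_covariate_is_an_error_not_silent_deletion():
    cohort = make_cohort(30, seed=8)
    tbl = cohort.table.copy()
    tbl.loc[3, "severity"] = np.nan
    with pytest.raises(MissingDataError, match="severity"):
        fit_vertex_glm(np.zeros((30, 2)), CohortTable(tbl), DesignSpec(effect="severity"))


def test_effect_column_cannot_double_as_nuisance():
    with pytest.raises(DesignError):
        DesignSpec(effect="severity", nuisance=("severity", "age"))


def test_subset_restricts_rows():
    cohort = make_cohort(40, seed=9)
    tbl = cohort.table.copy()
    tbl["subtype_weakness"] = ([1] * 25 + [0] * 15)
    model = VertexGLM(
        np.random.default_rng(0).standard_normal((40, 4)),
        CohortTable(tbl),
        DesignSpec(effect="severity", subset="subtype_weakness"),
    )
    assert model.X.shape[0] == 25


# ----------------------------------------------------------------- FDR

def brute_force_bh(p, q):
    """Enumerate every step-up cutoff directly."""
    p = np.asarray(p)
    m = len(p)
    order = np.argsort(p)
    best = 0
    for i in range(1, m + 1):
        if p[order[i - 1]] <= i * q / m:
            best = i
    mask = np.zeros(m, dtype=bool)
    mask[order[:best]] = True
    return mask


def test_fdr_step_up_worked_example():
    p = [0.001, 0.01, 0.02, 0.03, 0.2]
    mask, thr = fdr_bh(p, q=0.05)
    assert mask.tolist() == [True, True, True, True, False]
    assert thr == pytest.approx(0.03)


def test_fdr_degenerate_inputs():
    assert fdr_bh([], 0.05)[0].size == 0
    mask_all_one, _ = fdr_bh(np.ones(7), 0.05)
    assert not mask_all_one.any()
    mask_all_zero, _ = fdr_bh(np.zeros(7), 0.05)
    assert mask_all_zero.all()


def test_fdr_matches_bruteforce_enumeration(rng):
    for _ in range(1000):
        m = int(rng.integers(1, 40))
        p = rng.random(m) ** rng.uniform(0.5, 3)
        q = float(rng.uniform(0.01, 0.2))
        mask, _ = fdr_bh(p, q)
        np.testing.assert_array_equal(mask, brute_force_bh(p, q))


def test_fdr_rejects_invalid_pvalues():
    with pytest.raises(InvalidParameterError):
        fdr_bh([0.5, 1.5], 0.05)
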