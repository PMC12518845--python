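import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from statsmodels.stats.multitest import multipletests

from fosmap.evaluation import _bh_bruteforce
from fosmap.stats import (
    DataMatrix,
    anova_fdr,
    bootstrap_saliences,
    data_matrix_from_table,
    permutation_test,
    posthoc_pairwise,
    task_pls,
)
from fosmap.synthetic import simulate_counts_table


def _toy_matrix(seed=0, n_per=8, p=20, structured=False):
    """Random 3-condition matrix; ``structured`` plants two effects of
    different strengths so the singular values are well separated (LV
    directions are only identified when the spectrum is non-degenerate)."""
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(3 * n_per, p))
    if structured:
        X[:n_per, : p // 4] += 6.0       # strong LV1 contrast
        X[n_per:2 * n_per, p // 4: p // 2] += 2.5  # weaker LV2 contrast
    return DataMatrix(X=X, subjects=[f"s{i}" for i in range(3 * n_per)],
                      conditions=["a"] * n_per + ["b"] * n_per + ["c"] * n_per,
                      regions=list(range(p)))


# ---------------------------------------------------------------------------
# task PLS

def test_worked_two_by_two_example():
    """Condition means [[1,0],[0,1]] → R=[[.5,−.5],[−.5,.5]], sv (1,0)."""
    X = np.array([[1.0, 0.0], [1.0, 0.0], [0.0, 1.0], [0.0, 1.0]])
    dm = DataMatrix(X=X, subjects=list("abcd"),
                    conditions=["c1", "c1", "c2", "c2"], regions=["r1", "r2"])
    res = task_pls(dm)
    assert np.allclose(res.singular_values, [1.0, 0.0], atol=1e-12)
    v1 = res.region_saliences[:, 0]
    assert np.allclose(np.abs(v1), 1 / np.sqrt(2), atol=1e-12)
    assert v1[0] * v1[1] < 0  # proportional to (1, -1)/sqrt(2)
    # cross-check against an independent SVD oracle on the hand-computed R
    R = np.array([[0.5, -0.5], [-0.5, 0.5]])
    s_oracle = np.linalg.svd(R, compute_uv=False)
    assert np.allclose(res.singular_values, s_oracle, atol=1e-12)


def test_identical_condition_means_give_zero_contrast():
    X = np.tile(np.arange(5.0), (6, 1))
    dm = DataMatrix(X=X, subjects=[f"s{i}" for i in range(6)],
                    conditions=["a", "a", "b", "b", "c", "c"], regions=list(range(5)))
    res = task_pls(dm)
    assert np.allclose(res.singular_values, 0.0, atol=1e-12)


def test_region_permutation_equivariance():
    dm = _toy_matrix(3, structured=True)
    res = task_pls(dm)
    perm = np.random.default_rng(1).permutation(len(dm.regions))
    dm_p = DataMatrix(X=dm.X[:, perm], subjects=dm.subjects,
                      conditions=dm.conditions, regions=[dm.regions[i] for i in perm])
    res_p = task_pls(dm_p)
    assert np.allclose(res_p.singular_values, res.singular_values)
    # saliences permute with the regions, up to LV sign
    for lv in range(2):  # LV3 of a rank-2 contrast is not identified
        a, b = res.region_saliences[perm, lv], res_p.region_saliences[:, lv]
        assert np.allclose(a, b, atol=1e-10) or np.allclose(a, -b, atol=1e-10)


def test_energy_conservation():
    dm = _toy_matrix(7, p=50)
    res = task_pls(dm)
    cond = np.asarray(dm.conditions)
    M = np.stack([dm.X[cond == lv].mean(axis=0) for lv in res.conditions])
    R = M - M.mean(axis=0)
    assert abs((res.singular_values**2).sum() - (R**2).sum()) <= 1e-10 * (R**2).sum()


def test_pls_input_validation():
    X = np.zeros((3, 4))
    with pytest.raises(ValueError):
        task_pls(DataMatrix(X=X, subjects=list("abc"),
                            conditions=["a", "a", "a"], regions=list(range(4))))
    with pytest.raises(ValueError):
        task_pls(DataMatrix(X=X, subjects=list("abc"),
                            conditions=["a", "a", "b"], regions=list(range(4))))


# ---------------------------------------------------------------------------
# permutation test

def test_permutation_deterministic_and_bounded():
    dm = _toy_matrix(2)
    p1 = permutation_test(dm, n_perm=199, seed=42)
    p2 = permutation_test(dm, n_perm=199, seed=42)
    assert np.array_equal(p1, p2)
    assert np.all(p1 > 0) and np.all(p1 <= 1)


def test_permutation_warns_below_100(caplog):
    dm = _toy_matrix(2, n_per=3, p=5)
    with caplog.at_level("WARNING"):
        permutation_test(dm, n_perm=50, seed=0)
    assert any("n_perm" in r.message for r in caplog.records)


def test_permutation_p_invariant_to_affine_rescaling():
    dm = _toy_matrix(5)
    p1 = permutation_test(dm, n_perm=199, seed=7)
    dm2 = DataMatrix(X=dm.X * 3.0 + 11.0, subjects=dm.subjects,
                     conditions=dm.conditions, regions=dm.regions)
    p2 = permutation_test(dm2, n_perm=199, seed=7)
    assert np.array_equal(p1, p2)


def test_permutation_detects_planted_effect():
    table = simulate_counts_table(n_regions=50, n_per_condition=8,
                                  effect_regions=(1, 2, 3, 4, 5),
                                  effect_factor=2.0, seed=0)
    dm = data_matrix_from_table(table)
    p = permutation_test(dm, n_perm=199, seed=0)
    assert p[0] < 0.05


# ---------------------------------------------------------------------------
# bootstrap saliences

def test_bootstrap_ratio_scale_invariant():
    dm = _toy_matrix(9, structured=True)
    r1, _ = bootstrap_saliences(dm, n_boot=200, seed=3)
    dm2 = DataMatrix(X=dm.X * 5.0, subjects=dm.subjects,
                     conditions=dm.conditions, regions=dm.regions)
    r2, _ = bootstrap_saliences(dm2, n_boot=200, seed=3)
    assert np.allclose(r1, r2, atol=1e-8)


def test_bootstrap_degenerate_data_flags_infinite():
    X = np.zeros((8, 4))
    X[4:, 0] = 1.0  # constant within condition: zero bootstrap variance
    dm = DataMatrix(X=X, subjects=[f"s{i}" for i in range(8)],
                    conditions=["a"] * 4 + ["b"] * 4, regions=list(range(4)))
    ratio, se = bootstrap_saliences(dm, n_boot=100, seed=0)
    assert not np.isnan(ratio).any()
    assert np.isinf(ratio[0, 0])


def test_bootstrap_requires_two_subjects_per_condition():
    X = np.random.default_rng(0).normal(size=(3, 4))
    dm = DataMatrix(X=X, subjects=list("abc"),
                    conditions=["a", "a", "b"], regions=list(range(4)))
    with pytest.raises(ValueError):
        bootstrap_saliences(dm, n_boot=100, seed=0)


# ---------------------------------------------------------------------------
# Benjamini–Hochberg and ANOVA

def test_bh_worked_example():
    """p = (.01, .03, .04), m = 3 → q = (.03, .04, .04) by the step-up rule."""
    q = _bh_bruteforce(np.array([0.01, 0.03, 0.04]))
    assert np.allclose(q, [0.03, 0.04, 0.04])
    _, q_impl, _, _ = multipletests([0.01, 0.03, 0.04], method="fdr_bh")
    assert np.allclose(q_impl, q)


@settings(deadline=None, max_examples=200, derandomize=True)
@given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=40))
def test_bh_matches_bruteforce_oracle(pvals):
    p = np.asarray(pvals)
    _, q_impl, _, _ = multipletests(p, method="fdr_bh")
    assert np.allclose(q_impl, _bh_bruteforce(p), atol=1e-12)


def test_anova_identical_groups():
    rows = []
    for cond in ("a", "b", "c"):
        for i, v in enumerate((1.0, 2.0, 3.0)):
            rows.append({"subject": f"{cond}{i}", "condition": cond, "region_id": 1,
                         "acronym": "R", "label_class": "cFos", "cells": int(v),
                         "area_mm2": 1.0, "density": v})
    res = anova_fdr(pd.DataFrame(rows))
    assert res.iloc[0]["F"] == 0.0 and res.iloc[0]["p"] == 1.0
    assert res.iloc[0]["q"] >= res.iloc[0]["p"]


def test_anova_fdr_monotone_and_detects_effect():
    table = simulate_counts_table(n_regions=30, n_per_condition=8,
                                  effect_regions=(1, 2, 3), effect_factor=2.0, seed=5)
    res = anova_fdr(table)
    assert (res["q"] >= res["p"] - 1e-12).all()
    hits = res[res["region_id"].isin((1, 2, 3))]["significant"]
    assert hits.sum() >= 2


def test_anova_requires_two_groups():
    table = simulate_counts_table(n_regions=3, conditions=("only",), seed=0)
    with pytest.raises(ValueError):
        anova_fdr(table)


def test_posthoc_bonferroni_caps_and_counts():
    table = simulate_counts_table(n_regions=2, n_per_condition=6, seed=8)
    res = posthoc_pairwise(table, region_id=1)
    assert len(res) == 3  # 3 conditions -> 3 comparisons
    assert np.allclose(res["p_adj"], np.minimum(1.0, res["p_raw"] * 3))
    assert (res["p_adj"] <= 1.0).all()


def test_posthoc_identical_groups_p_one():
    rows = []
    for cond in ("a", "b"):
        for i in range(3):
            rows.append({"subject": f"{cond}{i}", "condition": cond, "region_id": 1,
                         "acronym": "R", "label_class": "cFos", "cells": 5,
                         "area_mm2": 1.0, "density": 5.0})
    res = posthoc_pairwise(pd.DataFrame(rows), region_id=1)
    assert (res["p_adj"] == 1.0).all()


def test_posthoc_single_condition_rejected():
    table = simulate_counts_table(n_regions=2, conditions=("only",), seed=0)
    with pytest.raises(ValueError):
        posthoc_pairwise(table, region_id=1)


# ---------------------------------------------------------------------------
# table -> matrix

def test_data_matrix_drops_incomplete_regions(caplog):
    table = simulate_counts_table(n_regions=5, n_per_condition=3, seed=1)
    table = table[~((table["subject"] == "baseline-01") & (table["region_id"] == 2))]
    with caplog.at_level("INFO"):
        dm = data_matrix_from_table(table)
    assert 2 not in dm.regions
    assert len(dm.regions) == 4
    assert not np.isnan(dm.X).any()
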