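"""Condition-contrast statistics: mean-centered task PLS and region-wise ANOVA.

Task PLS decomposes the condition-mean activity matrix, centered by the
grand column means, with an SVD.  Each latent variable (LV) pairs a
condition-salience profile with a region-salience profile; LV significance
comes from permuting condition labels across subjects, and per-region
stability from bootstrap resampling subjects within condition.  The
bootstrap ratio (observed salience / bootstrap SE) is a z-like score; the
default significance cut ``|ratio| ≥ 2.576`` corresponds to two-tailed
p < 0.01.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "DataMatrix",
    "PLSResult",
    "data_matrix_from_table",
    "task_pls",
    "permutation_test",
    "bootstrap_saliences",
    "anova_fdr",
    "posthoc_pairwise",
]

BOOTSTRAP_RATIO_THRESHOLD = 2.576  # two-tailed p < 0.01


@dataclass
class DataMatrix:
    """Subjects × regions value matrix with condition labels."""

    X: np.ndarray
    subjects: list[str]
    conditions: list[str]
    regions: list

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        if self.X.shape != (len(self.subjects), len(self.regions)):
            raise ValueError("X shape must be (n_subjects, n_regions)")
        if len(self.conditions) != len(self.subjects):
            raise ValueError("one condition label per subject required")
        if np.isnan(self.X).any():
            raise ValueError("DataMatrix may not contain missing values")

    @property
    def condition_levels(self) -> list[str]:
        seen = []
        for c in self.conditions:
            if c not in seen:
                seen.append(c)
        return seen


def data_matrix_from_table(
    table: pd.DataFrame,
    value: str = "density",
    label_class: str | None = None,
) -> DataMatrix:
    """Pivot a counts table into a complete subjects × regions matrix.

    Regions not sampled by every subject are dropped (logged), matching
    the no-missing-entries contract of the analysis layer.
    """
    df = table
    if label_class is not None:
        df = df[df["label_class"] == label_class]
    elif df["label_class"].nunique() > 1:
        raise ValueError("table has multiple label classes; pass label_class")
    wide = df.pivot_table(index="subject", columns="region_id", values=value,
                          aggfunc="first")
    incomplete = wide.columns[wide.isna().any()].tolist()
    if incomplete:
        logger.info("dropping %d region(s) incomplete across subjects: %s",
                    len(incomplete), incomplete)
        wide = wide.drop(columns=incomplete)
    cond_of = df.drop_duplicates("subject").set_index("subject")["condition"]
    subjects = list(wide.index)
    return DataMatrix(
        X=wide.to_numpy(float),
        subjects=subjects,
        conditions=[cond_of[s] for s in subjects],
        regions=list(wide.columns),
    )


@dataclass
class PLSResult:
    singular_values: np.ndarray          # (L,)
    condition_saliences: np.ndarray      # (k, L)
    region_saliences: np.ndarray         # (p, L)
    subject_scores: np.ndarray           # (n, L)
    conditions: list[str]
    regions: list
    perm_p: np.ndarray | None = None
    bootstrap_ratio: np.ndarray | None = None   # (p, L)
    bootstrap_se: np.ndarray | None = None
    threshold: float = BOOTSTRAP_RATIO_THRESHOLD

    def significant_regions(self, lv: int = 0) -> list:
        if self.bootstrap_ratio is None:
            raise ValueError("run bootstrap_saliences first")
        mask = np.abs(self.bootstrap_ratio[:, lv]) >= self.threshold
        return [r for r, m in zip(self.regions, mask) if m]


def _condition_mean_matrix(data: DataMatrix) -> tuple[np.ndarray, list[str]]:
    levels = data.condition_levels
    cond = np.asarray(data.conditions)
    M = np.stack([data.X[cond == lv].mean(axis=0) for lv in levels])
    return M, levels


def task_pls(data: DataMatrix) -> PLSResult:
    """Mean-centered task PLS point estimates.

    The condition-mean matrix ``M`` (conditions × regions) is centered by
    its grand column means and decomposed, ``R = U S Vᵀ``: columns of ``U``
    are condition saliences, of ``V`` region saliences, and subject scores
    are the projections ``X V``.  Energy is conserved: ``Σ sₖ² = ‖R‖²_F``.
    A rank-0 contrast (identical condition means) yields all-zero singular
    values, not an error.
    """
    levels = data.condition_levels
    if len(levels) < 2:
        raise ValueError("task PLS needs at least 2 conditions")
    counts = [sum(c == lv for c in data.conditions) for lv in levels]
    if min(counts) < 2:
        raise ValueError("task PLS needs at least 2 subjects per condition")
    if len(data.regions) < 2:
        raise ValueError("task PLS needs at least 2 regions")
    M, levels = _condition_mean_matrix(data)
    R = M - M.mean(axis=0, keepdims=True)
    U, s, Vt = np.linalg.svd(R, full_matrices=False)
    V = Vt.T
    return PLSResult(
        singular_values=s,
        condition_saliences=U,
        region_saliences=V,
        subject_scores=data.X @ V,
        conditions=levels,
        regions=list(data.regions),
    )


def permutation_test(
    data: DataMatrix, n_perm: int = 1000, seed: int = 0
) -> np.ndarray:
    """Permutation p-value per LV by shuffling condition labels across subjects.

    ``p_k = (#{s*_k ≥ s_k} + 1) / (n_perm + 1)`` — the add-one estimator
    never returns an exact zero.  Seeded and reproducible.
    """
    if n_perm < 100:
        logger.warning("n_perm=%d < 100; permutation p-values will be coarse", n_perm)
    rng = np.random.default_rng(seed)
    observed = task_pls(data).singular_values
    exceed = np.zeros_like(observed)
    cond = np.asarray(data.conditions)
    for _ in range(n_perm):
        perm = DataMatrix(
            X=data.X,
            subjects=data.subjects,
            conditions=list(cond[rng.permutation(len(cond))]),
            regions=data.regions,
        )
        s_perm = task_pls(perm).singular_values
        exceed += s_perm[: len(observed)] >= observed
    p = (exceed + 1.0) / (n_perm + 1.0)
    # LVs that are numerically zero (beyond the rank of the contrast) carry
    # no signal; comparing rounding noise would make their p arbitrary
    p[observed <= 1e-12 * max(observed.max(), 1e-300)] = 1.0
    return p


def bootstrap_saliences(
    data: DataMatrix, n_boot: int = 1000, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Bootstrap ratios (salience / bootstrap SE) per region per LV.

    Subjects are resampled with replacement within their condition.  Each
    replicate's centered condition-mean matrix ``R_b`` is projected onto
    the *observed* condition saliences, ``R_bᵀ u_k`` — the fixed-direction
    analogue of re-running the SVD and aligning its LVs to the observed
    ones by inner product, but immune to the order/sign instabilities of
    per-replicate SVDs (which concentrate replicates around the observed
    solution and deflate the SE).  The observed statistic on that scale is
    ``s_k v_k``, so the ratio is ``s_k v_k / SE_b(R_bᵀ u_k)``.

    Zero bootstrap SE with a nonzero salience is reported as ±inf
    (flagged, never NaN).  Returns ``(ratio, se)``, both
    (n_regions, n_LVs).
    """
    if n_boot < 100:
        logger.warning("n_boot=%d < 100; bootstrap ratios will be noisy", n_boot)
    levels = data.condition_levels
    cond = np.asarray(data.conditions)
    idx_by_cond = {lv: np.flatnonzero(cond == lv) for lv in levels}
    if min(len(v) for v in idx_by_cond.values()) < 2:
        raise ValueError("bootstrap needs >= 2 subjects per condition")
    obs = task_pls(data)
    obs_stat = obs.region_saliences * obs.singular_values[None, :]
    U = obs.condition_saliences
    rng = np.random.default_rng(seed)
    boots = np.empty((n_boot,) + obs_stat.shape)
    for b in range(n_boot):
        take = np.concatenate([
            rng.choice(idx_by_cond[lv], size=len(idx_by_cond[lv]), replace=True)
            for lv in levels
        ])
        Xb = data.X[take]
        condb = cond[take]
        M = np.stack([Xb[condb == lv].mean(axis=0) for lv in levels])
        R = M - M.mean(axis=0, keepdims=True)
        boots[b] = R.T @ U
    se = boots.std(axis=0, ddof=1)
    # numerically-zero saliences (e.g. the structurally absent k-th LV of a
    # mean-centered contrast) are reported as 0; a genuinely nonzero
    # salience over a degenerate (constant) resampling distribution is
    # ±inf — never NaN
    scale = max(1e-300, float(np.abs(obs_stat).max()))
    zero_obs = np.abs(obs_stat) <= 1e-12 * scale
    zero_se = se <= 1e-12 * scale
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(
            ~zero_se,
            obs_stat / np.where(~zero_se, se, 1.0),
            np.where(zero_obs, 0.0, np.sign(obs_stat) * np.inf),
        )
    ratio[zero_obs] = 0.0
    return ratio, se


def run_pls(
    data: DataMatrix, n_perm: int = 1000, n_boot: int = 1000, seed: int = 0
) -> PLSResult:
    """Point estimates + permutation p per LV + bootstrap ratios, one call."""
    result = task_pls(data)
    result.perm_p = permutation_test(data, n_perm=n_perm, seed=seed)
    result.bootstrap_ratio, result.bootstrap_se = bootstrap_saliences(
        data, n_boot=n_boot, seed=seed + 1
    )
    return result


# ---------------------------------------------------------------------------
# region-wise ANOVA with FDR, and post hoc pairwise tests

def anova_fdr(
    table: pd.DataFrame,
    value: str = "density",
    label_class: str | None = None,
    alpha_q: float = 0.05,
) -> pd.DataFrame:
    """One-way ANOVA across conditions per region, Benjamini–Hochberg q-values.

    Subjects missing a region are dropped for that region (logged); regions
    without ≥ 2 conditions of ≥ 2 subjects are skipped.  Returns one row
    per tested region with F, p, q, per-condition means/SEMs and a
    significance flag at ``q < alpha_q``.
    """
    df = table
    if label_class is not None:
        df = df[df["label_class"] == label_class]
    rows = []
    for (rid, acr), grp in df.groupby(["region_id", "acronym"], sort=True):
        vals = grp.dropna(subset=[value])
        groups = [g[value].to_numpy(float) for _, g in vals.groupby("condition")]
        if len(groups) < 2 or min(len(g) for g in groups) < 2:
            logger.info("region %s skipped (insufficient groups)", acr)
            continue
        if all(np.ptp(g) == 0 for g in groups) and len({g[0] for g in groups}) == 1:
            F, p = 0.0, 1.0
        else:
            F, p = sps.f_oneway(*groups)
            if not np.isfinite(F):
                F, p = 0.0, 1.0
        row = {"region_id": rid, "acronym": acr, "F": float(F), "p": float(p)}
        for cname, g in vals.groupby("condition"):
            v = g[value].to_numpy(float)
            row[f"mean_{cname}"] = float(v.mean())
            row[f"sem_{cname}"] = float(v.std(ddof=1) / np.sqrt(len(v))) if len(v) > 1 else np.nan
        rows.append(row)
    if not rows:
        raise ValueError("no region had >= 2 conditions with >= 2 subjects each")
    out = pd.DataFrame(rows)
    _, q, _, _ = multipletests(out["p"].to_numpy(), method="fdr_bh")
    out["q"] = q
    out["significant"] = out["q"] < alpha_q
    return out


def posthoc_pairwise(
    table: pd.DataFrame,
    region_id: int,
    value: str = "density",
    label_class: str | None = None,
    method: str = "bonferroni",
) -> pd.DataFrame:
    """All pairwise two-sample t-tests for one region, Bonferroni-adjusted.

    Adjusted p = raw p × number of comparisons, capped at 1.
    """
    if method != "bonferroni":
        raise ValueError(f"unsupported method {method!r}")
    df = table[table["region_id"] == region_id]
    if label_class is not None:
        df = df[df["label_class"] == label_class]
    df = df.dropna(subset=[value])
    levels = sorted(df["condition"].unique())
    if len(levels) < 2:
        raise ValueError("post hoc tests need at least 2 conditions")
    pairs = [(a, b) for i, a in enumerate(levels) for b in levels[i + 1:]]
    rows = []
    for a, b in pairs:
        ga = df.loc[df["condition"] == a, value].to_numpy(float)
        gb = df.loc[df["condition"] == b, value].to_numpy(float)
        if np.ptp(np.concatenate([ga, gb])) == 0:
            t, p = 0.0, 1.0
        else:
            t, p = sps.ttest_ind(ga, gb)
            if not np.isfinite(p):
                t, p = 0.0, 1.0
        rows.append({
            "condition_a": a, "condition_b": b,
            "t": float(t), "p_raw": float(p),
            "p_adj": float(min(1.0, p * len(pairs))),
        })
    return pd.DataFrame(rows)
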