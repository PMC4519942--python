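"""Voxel-wise group statistics: two-factor ANCOVA and t maps.

The group model is an ordinary least-squares GLM fitted independently at
every mask voxel.  Factors (sex, diagnosis) are effect-coded (-1/+1)
and covariates centred, so main effects remain interpretable in the
presence of the interaction.  F tests for the interaction and the main
effects are partial F statistics from full-vs-reduced model comparison;
post-hoc two-sample t tests are restricted to the voxels of an
interaction (or main-effect) mask; hub topography uses one-sample
(intercept) t tests with covariates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .masks import GrayMatterMask

__all__ = [
    "StatMap",
    "VoxelGLMFit",
    "build_design",
    "fit_glm_voxelwise",
    "f_contrast",
    "posthoc_t_within_mask",
    "one_sample_t",
]

DESIGN_TERMS = ("intercept", "sex", "diagnosis", "interaction")


@dataclass
class StatMap:
    """Voxel-wise statistic with degrees of freedom and p-values.

    Arrays are flat per-mask-voxel; voxels carrying no statistic (e.g.
    outside a post-hoc mask) hold NaN.
    """

    stat_value: np.ndarray
    stat_kind: str  # "t" or "F"
    df: float | tuple[float, float]
    p_value: np.ndarray
    mask: GrayMatterMask | None = None

    def __post_init__(self) -> None:
        if self.stat_kind not in ("t", "F"):
            raise ValueError("stat_kind must be 't' or 'F'")
        self.stat_value = np.asarray(self.stat_value, dtype=float)
        self.p_value = np.asarray(self.p_value, dtype=float)
        valid = np.isfinite(self.p_value)
        if np.any((self.p_value[valid] < 0) | (self.p_value[valid] > 1)):
            raise ValueError("p-values outside [0, 1]")
        if self.stat_kind == "F" and np.any(self.stat_value[valid] < -1e-12):
            raise ValueError("F statistics must be non-negative")


@dataclass
class VoxelGLMFit:
    """Shared-design OLS fit across voxels (betas, residual SS, df)."""

    X: np.ndarray
    columns: list[str]
    betas: np.ndarray  # (p, V)
    rss: np.ndarray  # (V,)
    df_resid: int
    Y: np.ndarray  # (n, V), kept for model-comparison F tests


def build_design(
    cohort: pd.DataFrame, covariates: tuple[str, ...] = ("age",)
) -> tuple[np.ndarray, list[str]]:
    """Effect-coded sex x diagnosis design with centred covariates.

    Columns: intercept, sex (+1 male / -1 female), diagnosis (+1 FES /
    -1 HC), their product (interaction), then each covariate centred.
    """
    for col in ("sex", "diagnosis", *covariates):
        if col not in cohort.columns:
            raise ValueError(f"cohort table lacks column '{col}'")
        if cohort[col].isna().any():
            raise ValueError(f"missing values in '{col}'")
    sex = np.where(cohort["sex"].to_numpy() == "male", 1.0, -1.0)
    diag = np.where(cohort["diagnosis"].to_numpy() == "FES", 1.0, -1.0)
    cols = [np.ones(len(cohort)), sex, diag, sex * diag]
    names = list(DESIGN_TERMS)
    for cov in covariates:
        v = cohort[cov].to_numpy(dtype=float)
        cols.append(v - v.mean())
        names.append(cov)
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient (empty cell or collinear covariate)")
    return X, names


def fit_glm_voxelwise(maps: np.ndarray, X: np.ndarray, columns: list[str] | None = None) -> VoxelGLMFit:
    """OLS per voxel with a shared design matrix.

    `maps` is (n_subjects, n_voxels); df_resid = n - rank(X).
    """
    Y = np.atleast_2d(np.asarray(maps, dtype=float))
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if Y.shape[0] != n:
        raise ValueError("one map per design row required")
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        raise ValueError("design matrix is rank deficient")
    if n <= p:
        raise ValueError("more design columns than subjects")
    betas, _, _, _ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ betas
    rss = np.einsum("ij,ij->j", resid, resid)
    cols = columns if columns is not None else [f"x{i}" for i in range(p)]
    return VoxelGLMFit(X, list(cols), betas, rss, n - rank, Y)


def f_contrast(fit: VoxelGLMFit, term: str, mask: GrayMatterMask | None = None) -> StatMap:
    """Partial F test for one design term via full/reduced model comparison."""
    if term not in fit.columns:
        raise ValueError(f"term '{term}' not in design ({fit.columns})")
    if term == "intercept":
        raise ValueError("use one_sample_t for the intercept")
    keep = [j for j, c in enumerate(fit.columns) if c != term]
    Xr = fit.X[:, keep]
    br, _, _, _ = np.linalg.lstsq(Xr, fit.Y, rcond=None)
    resid_r = fit.Y - Xr @ br
    rss_r = np.einsum("ij,ij->j", resid_r, resid_r)
    q = fit.X.shape[1] - Xr.shape[1]
    with np.errstate(divide="ignore", invalid="ignore"):
        F = ((rss_r - fit.rss) / q) / (fit.rss / fit.df_resid)
    F = np.where(fit.rss > 0, F, np.inf)
    F = np.maximum(F, 0.0)  # guard tiny negative round-off
    p = stats.f.sf(F, q, fit.df_resid)
    return StatMap(F, "F", (q, fit.df_resid), p, mask)


def _t_from_fit(Y: np.ndarray, X: np.ndarray, coef_index: int) -> tuple[np.ndarray, int]:
    n, p = X.shape
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        raise ValueError("design matrix is rank deficient")
    df = n - rank
    if df < 1:
        raise ValueError("no residual degrees of freedom")
    betas, _, _, _ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ betas
    rss = np.einsum("ij,ij->j", resid, resid)
    sigma2 = rss / df
    xtx_inv = np.linalg.inv(X.T @ X)
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(sigma2 * xtx_inv[coef_index, coef_index])
        t = betas[coef_index] / se
    # zero-residual degenerate voxels: t -> +/- infinity, p -> 0
    t = np.where(se == 0, np.sign(betas[coef_index]) * np.inf, t)
    t = np.where((se == 0) & (betas[coef_index] == 0), 0.0, t)
    return t, df


def posthoc_t_within_mask(
    mapsA: np.ndarray,
    mapsB: np.ndarray,
    interaction_mask: np.ndarray,
    covariates: tuple[np.ndarray, np.ndarray] | None = None,
    mask: GrayMatterMask | None = None,
) -> StatMap:
    """Covariate-adjusted two-sample t (A minus B) inside a voxel mask.

    `interaction_mask` is a boolean per-mask-voxel vector (e.g. the
    suprathreshold voxels of the interaction F map).  Voxels outside it
    carry NaN.  `covariates` supplies per-group covariate columns which
    are concatenated and centred.
    """
    sel = np.asarray(interaction_mask, dtype=bool)
    if not sel.any():
        raise ValueError("empty post-hoc mask")
    A = np.atleast_2d(np.asarray(mapsA, float))[:, sel]
    B = np.atleast_2d(np.asarray(mapsB, float))[:, sel]
    nA, nB = A.shape[0], B.shape[0]
    if nA < 2 or nB < 2:
        raise ValueError("each group needs at least 2 subjects")
    Y = np.vstack([A, B])
    group = np.concatenate([np.ones(nA), np.zeros(nB)])
    cols = [np.ones(nA + nB), group]
    if covariates is not None:
        for covA, covB in [covariates] if isinstance(covariates, tuple) else covariates:
            v = np.concatenate([np.asarray(covA, float), np.asarray(covB, float)])
            cols.append(v - v.mean())
    X = np.column_stack(cols)
    t_sel, df = _t_from_fit(Y, X, coef_index=1)
    t = np.full(sel.shape, np.nan)
    p = np.full(sel.shape, np.nan)
    t[sel] = t_sel
    p[sel] = 2.0 * stats.t.sf(np.abs(t_sel), df)
    return StatMap(t, "t", df, p, mask)


def one_sample_t(
    maps: np.ndarray,
    covariates: np.ndarray | None = None,
    mask: GrayMatterMask | None = None,
) -> StatMap:
    """Intercept t test across subjects with centred covariates."""
    Y = np.atleast_2d(np.asarray(maps, float))
    n = Y.shape[0]
    if n < 3:
        raise ValueError("one-sample t needs at least 3 subjects")
    cols = [np.ones(n)]
    if covariates is not None:
        C = np.atleast_2d(np.asarray(covariates, float))
        if C.shape[0] != n:
            C = C.T
        for j in range(C.shape[1]):
            cols.append(C[:, j] - C[:, j].mean())
    X = np.column_stack(cols)
    t, df = _t_from_fit(Y, X, coef_index=0)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return StatMap(t, "t", df, p, mask)
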