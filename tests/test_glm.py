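"""Group GLM: design coding, F contrasts, post-hoc and one-sample t."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from restmap.glm import (
    build_design,
    f_contrast,
    fit_glm_voxelwise,
    one_sample_t,
    posthoc_t_within_mask,
)


def toy_cohort(n_per_cell: int, age_fn=None, seed: int = 0) -> pd.DataFrame:
    rng = np.random.default_rng(seed)
    rows = []
    for diag in ("FES", "HC"):
        for sex in ("male", "female"):
            for _ in range(n_per_cell):
                rows.append(
                    {
                        "diagnosis": diag,
                        "sex": sex,
                        "age": float(age_fn() if age_fn else rng.uniform(18, 40)),
                    }
                )
    return pd.DataFrame(rows)


def twoway_anova_oracle(cells: dict[tuple[str, str], np.ndarray]) -> dict[str, float]:
    """Textbook balanced two-way ANOVA from cell means and sums of squares."""
    a_levels = sorted({k[0] for k in cells})
    b_levels = sorted({k[1] for k in cells})
    n = len(next(iter(cells.values())))
    all_vals = np.concatenate(list(cells.values()))
    grand = all_vals.mean()
    cell_means = {k: v.mean() for k, v in cells.items()}
    a_means = {a: np.mean([cell_means[(a, b)] for b in b_levels]) for a in a_levels}
    b_means = {b: np.mean([cell_means[(a, b)] for a in a_levels]) for b in b_levels}
    ss_a = n * len(b_levels) * sum((a_means[a] - grand) ** 2 for a in a_levels)
    ss_b = n * len(a_levels) * sum((b_means[b] - grand) ** 2 for b in b_levels)
    ss_ab = n * sum(
        (cell_means[(a, b)] - a_means[a] - b_means[b] + grand) ** 2
        for a in a_levels
        for b in b_levels
    )
    ss_err = sum(((v - cell_means[k]) ** 2).sum() for k, v in cells.items())
    df_err = len(a_levels) * len(b_levels) * (n - 1)
    return {
        "A": (ss_a / 1) / (ss_err / df_err),
        "B": (ss_b / 1) / (ss_err / df_err),
        "AB": (ss_ab / 1) / (ss_err / df_err),
    }


class TestBuildDesign:
    def test_balanced_design_is_orthogonal(self):
        cohort = toy_cohort(5)
        X, names = build_design(cohort)
        gram = X[:, :4].T @ X[:, :4]
        np.testing.assert_allclose(gram, np.diag(np.diag(gram)), atol=1e-10)

    def test_empty_cell_rejected(self):
        cohort = toy_cohort(3)
        cohort = cohort[~((cohort.diagnosis == "FES") & (cohort.sex == "male"))]
        with pytest.raises(ValueError):
            build_design(cohort)

    def test_interaction_is_product_of_factors(self):
        cohort = toy_cohort(1)
        X, names = build_design(cohort, covariates=())
        i_sex, i_diag, i_int = names.index("sex"), names.index("diagnosis"), names.index("interaction")
        np.testing.assert_array_equal(X[:, i_int], X[:, i_sex] * X[:, i_diag])

    def test_missing_values_rejected(self):
        cohort = toy_cohort(2)
        cohort.loc[0, "age"] = np.nan
        with pytest.raises(ValueError):
            build_design(cohort)


class TestFitGlm:
    def test_exact_recovery_of_noiseless_maps(self):
        cohort = toy_cohort(3)
        X, names = build_design(cohort)
        rng = np.random.default_rng(1)
        true_beta = rng.standard_normal((X.shape[1], 10))
        fit = fit_glm_voxelwise(X @ true_beta, X, names)
        assert fit.rss.max() < 1e-10
        np.testing.assert_allclose(fit.betas, true_beta, atol=1e-8)

    def test_betas_match_normal_equations_on_toy(self):
        rng = np.random.default_rng(2)
        cohort = toy_cohort(3)
        X, names = build_design(cohort)
        Y = rng.standard_normal((len(cohort), 4))
        fit = fit_glm_voxelwise(Y, X, names)
        expected = np.linalg.solve(X.T @ X, X.T @ Y)
        np.testing.assert_allclose(fit.betas, expected, atol=1e-10)

    def test_residual_df_counts_columns(self):
        cohort = toy_cohort(4)
        X, names = build_design(cohort)
        fit = fit_glm_voxelwise(np.random.default_rng(3).standard_normal((16, 2)), X, names)
        assert fit.df_resid == 16 - 5

    def test_underdetermined_rejected(self):
        cohort = toy_cohort(1)
        X, names = build_design(cohort, covariates=())
        with pytest.raises(ValueError):
            fit_glm_voxelwise(np.zeros((4, 2)), X, names)


class TestFContrast:
    def test_matches_textbook_twoway_anova(self):
        rng = np.random.default_rng(4)
        n = 8
        cohort = toy_cohort(n, age_fn=lambda: 30.0)
        # covariate constant -> drop it to keep the design full rank
        X, names = build_design(cohort[["sex", "diagnosis"]].assign(age=0.0), covariates=())
        effects = {"FES": 0.7, "male": -0.4}
        y = []
        cells: dict[tuple[str, str], list[float]] = {}
        for _, row in cohort.iterrows():
            val = (
                effects["FES"] * (row.diagnosis == "FES")
                + effects["male"] * (row.sex == "male")
                + 0.3 * (row.diagnosis == "FES") * (row.sex == "male")
                + rng.standard_normal()
            )
            y.append(val)
            cells.setdefault((row.diagnosis, row.sex), []).append(val)
        Y = np.array(y)[:, None]
        fit = fit_glm_voxelwise(Y, X, names)
        oracle = twoway_anova_oracle({k: np.array(v) for k, v in cells.items()})
        assert f_contrast(fit, "diagnosis").stat_value[0] == pytest.approx(oracle["A"], rel=1e-8)
        assert f_contrast(fit, "sex").stat_value[0] == pytest.approx(oracle["B"], rel=1e-8)
        assert f_contrast(fit, "interaction").stat_value[0] == pytest.approx(oracle["AB"], rel=1e-8)

    def test_null_p_values_uniform(self):
        rng = np.random.default_rng(5)
        cohort = toy_cohort(6)
        X, names = build_design(cohort)
        Y = rng.standard_normal((len(cohort), 1000))
        fit = fit_glm_voxelwise(Y, X, names)
        p = f_contrast(fit, "interaction").p_value
        assert stats.kstest(p, "uniform").pvalue > 0.01

    def test_invariant_to_constant_shift(self):
        rng = np.random.default_rng(6)
        cohort = toy_cohort(4)
        X, names = build_design(cohort)
        Y = rng.standard_normal((len(cohort), 20))
        f1 = f_contrast(fit_glm_voxelwise(Y, X, names), "sex").stat_value
        f2 = f_contrast(fit_glm_voxelwise(Y + 100.0, X, names), "sex").stat_value
        np.testing.assert_allclose(f1, f2, rtol=1e-8)

    def test_unknown_term_rejected(self):
        cohort = toy_cohort(3)
        X, names = build_design(cohort)
        fit = fit_glm_voxelwise(np.zeros((len(cohort), 1)), X, names)
        with pytest.raises(ValueError):
            f_contrast(fit, "dose")


class TestPosthocT:
    def test_identical_groups_give_zero_t(self):
        rng = np.random.default_rng(7)
        maps = rng.standard_normal((10, 30))
        out = posthoc_t_within_mask(maps, maps.copy(), np.ones(30, bool))
        np.testing.assert_allclose(out.stat_value, 0.0, atol=1e-10)

    def test_mean_shift_matches_noncentrality(self):
        # delta=1, sigma=1, n=30/30 -> noncentrality sqrt(15) ~ 3.87
        rng = np.random.default_rng(8)
        V = 400
        A = rng.standard_normal((30, V)) + 1.0
        B = rng.standard_normal((30, V))
        out = posthoc_t_within_mask(A, B, np.ones(V, bool))
        assert np.nanmean(out.stat_value) == pytest.approx(np.sqrt(15.0), abs=0.6)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            posthoc_t_within_mask(
                np.zeros((5, 4)), np.zeros((5, 4)), np.zeros(4, bool)
            )

    def test_statistic_confined_to_mask(self):
        rng = np.random.default_rng(9)
        sel = np.zeros(10, bool)
        sel[:3] = True
        out = posthoc_t_within_mask(
            rng.standard_normal((6, 10)), rng.standard_normal((6, 10)), sel
        )
        assert np.isnan(out.stat_value[~sel]).all()
        assert np.isfinite(out.stat_value[sel]).all()

    def test_covariate_adjustment_removes_age_confound(self):
        rng = np.random.default_rng(10)
        ageA = rng.uniform(20, 30, 20)
        ageB = rng.uniform(30, 40, 20)
        # maps depend only on age; adjusting for it should kill the effect
        A = np.outer(ageA, np.ones(15)) + 0.1 * rng.standard_normal((20, 15))
        B = np.outer(ageB, np.ones(15)) + 0.1 * rng.standard_normal((20, 15))
        raw = posthoc_t_within_mask(A, B, np.ones(15, bool))
        adj = posthoc_t_within_mask(A, B, np.ones(15, bool), covariates=(ageA, ageB))
        assert np.nanmean(np.abs(adj.stat_value)) < np.nanmean(np.abs(raw.stat_value)) / 3


class TestOneSampleT:
    def test_noiseless_constant_maps_degenerate(self):
        out = one_sample_t(np.full((8, 5), 2.0))
        assert (out.p_value <= 1e-15).all()
        assert (out.stat_value > 0).all()

    def test_null_false_positive_rate_nominal(self):
        rng = np.random.default_rng(11)
        out = one_sample_t(rng.standard_normal((20, 4000)))
        rate = (out.p_value < 0.05).mean()
        assert rate == pytest.approx(0.05, abs=0.02)

    def test_matches_scalar_t_formula(self):
        x = np.array([1.2, 0.8, 1.5, 0.9, 1.1])
        out = one_sample_t(x[:, None])
        expected = x.mean() / (x.std(ddof=1) / np.sqrt(5))
        assert out.stat_value[0] == pytest.approx(expected, rel=1e-10)
        t_ref, p_ref = stats.ttest_1samp(x, 0.0)
        assert out.stat_value[0] == pytest.approx(t_ref)
        assert out.p_value[0] == pytest.approx(p_ref)

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError):
            one_sample_t(np.zeros((2, 3)))
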