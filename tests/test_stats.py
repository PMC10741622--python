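"""t tests, Pearson screening, Lasso-CV selection and the OLS refit."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from examcoh.features import FeatureTable
from examcoh.stats import (compare_groups, default_lambda_grid, lasso_cv,
                           pearson_screen, post_lasso_ols,
                           ttest_from_summary, ttest_independent)


class TestTTests:
    def test_identical_groups_null(self):
        res = ttest_independent([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t == 0.0 and res.p == 1.0

    def test_separated_groups_tiny_p(self, rng):
        x = rng.normal(0.0, 0.1, 10)
        res = ttest_independent(x + 100.0, x)
        assert res.p < 1e-6

    def test_swapping_groups_flips_sign_only(self, rng):
        x, y = rng.normal(0, 1, 8), rng.normal(0.5, 1, 8)
        a = ttest_independent(x, y)
        b = ttest_independent(y, x)
        assert a.t == pytest.approx(-b.t)
        assert a.p == pytest.approx(b.p)

    @pytest.mark.parametrize("variant", ["pooled", "welch"])
    def test_agrees_with_scipy(self, rng, variant):
        x = rng.normal(0, 1, 9)
        y = rng.normal(0.4, 2, 14)
        mine = ttest_independent(x, y, variant=variant)
        ref = sps.ttest_ind(x, y, equal_var=(variant == "pooled"))
        assert mine.t == pytest.approx(ref.statistic, rel=1e-12)
        assert mine.p == pytest.approx(ref.pvalue, rel=1e-12)

    def test_summary_equals_raw_exactly(self, rng):
        x, y = rng.normal(0, 1, 8), rng.normal(1, 2, 8)
        raw = ttest_independent(x, y)
        summ = ttest_from_summary(x.mean(), x.std(ddof=1), 8,
                                  y.mean(), y.std(ddof=1), 8)
        assert raw.t == pytest.approx(summ.t, rel=1e-14)
        assert raw.p == pytest.approx(summ.p, rel=1e-14)

    def test_degenerate_variances(self):
        equal = ttest_from_summary(1.0, 0.0, 5, 1.0, 0.0, 5)
        assert equal.p == 1.0
        apart = ttest_from_summary(2.0, 0.0, 5, 1.0, 0.0, 5)
        assert apart.p == 0.0

    def test_type_one_error_rate_near_nominal(self):
        # vectorized null simulation at n=8 per group
        r = np.random.default_rng(77)
        reps = 4000
        x = r.normal(size=(reps, 8))
        y = r.normal(size=(reps, 8))
        sp = np.sqrt((x.var(axis=1, ddof=1) + y.var(axis=1, ddof=1)) / 2)
        t = (x.mean(axis=1) - y.mean(axis=1)) / (sp * np.sqrt(2 / 8))
        p = 2 * sps.t.sf(np.abs(t), 14)
        rate = (p < 0.05).mean()
        assert rate == pytest.approx(0.05, abs=0.012)

    def test_too_small_groups_rejected(self):
        with pytest.raises(ValueError):
            ttest_independent([1.0], [2.0, 3.0])


class TestCompareGroups:
    @pytest.fixture()
    def table(self, rng):
        pids = [f"e{i}" for i in range(4)] + [f"n{i}" for i in range(4)]
        groups = pd.Series(["experienced"] * 4 + ["novice"] * 4, index=pids)
        values = pd.DataFrame(
            {"reading.theta.coh.FC5-FC6": np.r_[rng.normal(0.1, 0.03, 4),
                                                rng.normal(0.7, 0.03, 4)],
             "reading.delta.coh.AF3-F7": rng.uniform(0, 1, 8),
             "answer1.beta.psd.F7": rng.normal(1.0, 0.1, 8)},
            index=pids)
        return FeatureTable(values, groups, "normalized")

    def test_detects_designed_difference_and_skips_delta(self, table):
        out = compare_groups(table)
        assert set(out["feature"]) == {"reading.theta.coh.FC5-FC6",
                                       "answer1.beta.psd.F7"}
        row = out.set_index("feature").loc["reading.theta.coh.FC5-FC6"]
        assert row["significant"] and row["t"] < 0

    def test_group_order_swap_flips_direction(self, table):
        a = compare_groups(table)
        b = compare_groups(table, group_order=("novice", "experienced"))
        merged = a.merge(b, on="feature", suffixes=("_a", "_b"))
        assert np.allclose(merged["t_a"], -merged["t_b"])
        assert np.allclose(merged["p_a"], merged["p_b"])

    def test_bh_flag_adds_adjusted_column(self, table):
        out = compare_groups(table, bh_correction=True)
        assert "p_adj" in out.columns
        assert (out["p_adj"] >= out["p"] - 1e-15).all()

    def test_small_group_rejected(self, table):
        tiny = FeatureTable(table.values.iloc[[0, 4, 5, 6]],
                            table.groups.iloc[[0, 4, 5, 6]], "normalized")
        with pytest.raises(ValueError, match=">= 2"):
            compare_groups(tiny)


class TestPearsonScreen:
    def test_identical_feature_screened_in(self, rng):
        y = pd.Series(rng.normal(size=16))
        X = pd.DataFrame({"same": y.values,
                          "noise": rng.normal(size=16)})
        assert "same" in pearson_screen(X, y)

    def test_constant_feature_excluded_with_warning(self, rng):
        y = pd.Series(rng.normal(size=10))
        X = pd.DataFrame({"flat": np.ones(10)})
        with pytest.warns(UserWarning, match="constant feature"):
            assert pearson_screen(X, y) == []

    def test_constant_outcome_empty_with_warning(self, rng):
        X = pd.DataFrame({"a": rng.normal(size=10)})
        with pytest.warns(UserWarning, match="outcome is constant"):
            assert pearson_screen(X, pd.Series(np.ones(10))) == []

    def test_null_inclusion_rate_near_alpha(self):
        r = np.random.default_rng(5)
        n, reps = 16, 3000
        x = r.normal(size=(reps, n))
        y = r.normal(size=(reps, n))
        xc = x - x.mean(axis=1, keepdims=True)
        yc = y - y.mean(axis=1, keepdims=True)
        rho = (xc * yc).sum(axis=1) / np.sqrt(
            (xc ** 2).sum(axis=1) * (yc ** 2).sum(axis=1))
        t = rho * np.sqrt((n - 2) / (1 - rho ** 2))
        p = 2 * sps.t.sf(np.abs(t), n - 2)
        assert (p < 0.05).mean() == pytest.approx(0.05, abs=0.015)


def _sparse_problem(seed, n=16, p=10, sigma=0.01):
    r = np.random.default_rng(seed)
    X = pd.DataFrame(r.normal(size=(n, p)),
                     columns=[f"f{i}" for i in range(p)])
    beta = np.zeros(p)
    beta[:3] = [1.0, -1.0, 0.8]
    y = pd.Series(X.values @ beta + r.normal(0, sigma, n) + 0.5,
                  index=X.index)
    return X, y, beta


class TestLasso:
    def test_infinite_penalty_selects_nothing(self):
        X, y, _ = _sparse_problem(0)
        res = lasso_cv(X, y, lambda_grid=np.array([1e6]), seed=0)
        assert res.selected == []

    def test_zero_penalty_equals_ols(self):
        X, y, _ = _sparse_problem(1)
        res = lasso_cv(X, y, lambda_grid=np.array([0.0]), seed=0)
        Xs = (X - X.mean()) / X.std(ddof=0)
        ref = np.linalg.lstsq(Xs.values, y - y.mean(), rcond=None)[0]
        mine = np.array([res.coef_std[c] for c in X.columns])
        assert np.allclose(mine, ref, atol=1e-8)

    def test_path_support_monotone_on_orthogonal_design(self):
        # orthogonal design -> soft thresholding -> support shrinks with
        # the penalty
        r = np.random.default_rng(3)
        q, _ = np.linalg.qr(r.normal(size=(40, 8)))
        X = pd.DataFrame(q, columns=[f"f{i}" for i in range(8)])
        y = pd.Series(X.values @ np.linspace(2, 0.1, 8)
                      + r.normal(0, 0.1, 40))
        grid = default_lambda_grid(X, y, n_lambdas=40)
        sizes = []
        for lam in np.sort(grid)[::-1]:
            res = lasso_cv(X, y, lambda_grid=np.array([lam]), seed=0)
            sizes.append(len(res.selected))
        assert all(a <= b for a, b in zip(sizes, sizes[1:]))

    def test_deterministic_under_seed(self):
        X, y, _ = _sparse_problem(4)
        a = lasso_cv(X, y, seed=11)
        b = lasso_cv(X, y, seed=11)
        assert a.chosen_lambda == b.chosen_lambda
        assert a.selected == b.selected
        assert np.array_equal(a.cv_mse, b.cv_mse)

    def test_n_smaller_than_folds_rejected(self):
        X, y, _ = _sparse_problem(5, n=4)
        with pytest.raises(ValueError, match="folds"):
            lasso_cv(X, y, folds=5)


class TestPostLassoOLS:
    def test_exact_linear_fit_r2_one(self, rng):
        X = pd.DataFrame({"a": rng.normal(size=12),
                          "b": rng.normal(size=12)})
        y = pd.Series(2.0 * X["a"] - X["b"] + 3.0)
        fit = post_lasso_ols(X, y)
        assert fit.r2 == pytest.approx(1.0)
        assert fit.coef["a"] == pytest.approx(2.0)
        assert fit.intercept == pytest.approx(3.0)

    def test_intercept_only_r2_zero(self, rng):
        y = pd.Series(rng.normal(size=10))
        fit = post_lasso_ols(pd.DataFrame(index=y.index), y)
        assert fit.r2 == 0.0 and fit.selected == []
        assert fit.intercept == pytest.approx(y.mean())

    def test_aliased_column_dropped_with_warning(self, rng):
        a = rng.normal(size=12)
        X = pd.DataFrame({"a": a, "twice_a": 2 * a})
        y = pd.Series(a + rng.normal(0, 0.1, 12))
        with pytest.warns(UserWarning, match="aliased"):
            fit = post_lasso_ols(X, y)
        assert fit.selected == ["a"]

    def test_coefficients_within_2se_at_low_noise(self):
        X, y, beta = _sparse_problem(6, sigma=0.02)
        fit = post_lasso_ols(X[["f0", "f1", "f2"]], y)
        for name, truth in zip(["f0", "f1", "f2"], beta[:3]):
            assert abs(fit.coef[name] - truth) <= 2 * fit.se[name]
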