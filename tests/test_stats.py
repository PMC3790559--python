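"""PGLS, per-axis ANOVA, CVA/Wilks, and repeatability."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from opermorph import (anova_per_axis, cva_wilks, generate_tree, pgls,
                       repeatability, simulate_traits)


def star_like_gls_data(n=20, seed=0):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(rng.normal(size=(n, 3)), columns=["ES1", "ES2", "ES3"],
                     index=[f"sp{i:03d}" for i in range(n)])
    y = pd.Series(1.0 + 0.5 * X["ES1"] + rng.normal(0, 0.3, n), index=X.index)
    return X, y


class TestPGLS:
    def test_identity_correlation_equals_ols(self):
        import statsmodels.api as sm

        X, y = star_like_gls_data()
        res = pgls(None, y, X, correlation=np.eye(len(y)))
        ols = sm.OLS(y.to_numpy(), sm.add_constant(X.to_numpy())).fit()
        np.testing.assert_allclose(res.coefficients["coef"], ols.params,
                                   atol=1e-10)
        assert res.fvalue == pytest.approx(ols.fvalue)

    def test_star_tree_equals_ols(self):
        # equal tip branches from the root: C proportional to identity
        import statsmodels.api as sm
        from opermorph import Phylogeny

        n = 12
        parent = [n] * n + [-1]
        tree = Phylogeny(parent, [1.0] * n + [0.0],
                         [f"sp{i:03d}" for i in range(n)])
        X, y = star_like_gls_data(n)
        res = pgls(tree, y, X)
        ols = sm.OLS(y.to_numpy(), sm.add_constant(X.to_numpy())).fit()
        np.testing.assert_allclose(res.coefficients["coef"], ols.params,
                                   atol=1e-10)

    def test_slope_recovery_on_tree(self):
        # response = 0.5 * predictor + BM noise on the tree
        tree = generate_tree(21, 1.0, seed=2)
        slopes = []
        for seed in range(150):
            pred = simulate_traits(tree, "BM", {"sigma2": 1.0},
                                   seed=1000 + seed)["trait1"]
            noise = simulate_traits(tree, "BM", {"sigma2": 0.25},
                                    seed=5000 + seed)["trait1"]
            y = 0.5 * pred + noise
            res = pgls(tree, y, pred.to_frame("ES1"))
            slopes.append(res.coefficients.loc["ES1", "coef"])
        assert np.mean(slopes) == pytest.approx(0.5, abs=0.05)

    def test_type_one_error_calibrated(self):
        # under the null the PGLS F test is exact: ~5% rejections at alpha=.05
        tree = generate_tree(21, 1.0, seed=3)
        rejections = 0
        n_rep = 1000
        for seed in range(n_rep):
            y = simulate_traits(tree, "BM", {"sigma2": 1.0},
                                seed=seed)["trait1"]
            x = simulate_traits(tree, "BM", {"sigma2": 1.0},
                                seed=10_000 + seed)["trait1"]
            res = pgls(tree, y, x.to_frame("ES1"))
            rejections += res.f_pvalue < 0.05
        assert rejections / n_rep == pytest.approx(0.05, abs=0.02)

    def test_collinear_design_named(self):
        X, y = star_like_gls_data()
        X["ES_dup"] = 2.0 * X["ES1"]
        with pytest.raises(ValueError, match="ES_dup"):
            pgls(None, y, X, correlation=np.eye(len(y)))


def grouped_scores(n_per=20, shift=0.0, seed=0, k=3):
    rng = np.random.default_rng(seed)
    groups, rows = [], []
    for gi, name in enumerate(["A", "B", "C"]):
        x = rng.normal(size=(n_per, k))
        x[:, 0] += shift * gi
        rows.append(x)
        groups += [name] * n_per
    idx = [f"s{i}" for i in range(3 * n_per)]
    scores = pd.DataFrame(np.vstack(rows), index=idx,
                          columns=[f"ES{i + 1}" for i in range(k)])
    return scores, pd.Series(groups, index=idx)


class TestAnova:
    def test_null_p_values_uniform(self):
        pvals = []
        for seed in range(1000):
            scores, groups = grouped_scores(n_per=8, seed=seed, k=1)
            table, _ = anova_per_axis(scores, groups)
            pvals.append(table["p"].iloc[0])
        assert sps.kstest(pvals, "uniform").pvalue > 0.01

    def test_power_with_strong_signal(self):
        scores, groups = grouped_scores(n_per=25, shift=2.0, seed=1)
        table, posthoc = anova_per_axis(scores, groups)
        assert table.loc["ES1", "p_bonferroni"] < 0.001
        assert table.loc["ES1", "df1"] == 2
        assert table.loc["ES1", "df2"] == 72
        extreme = posthoc.query("axis == 'ES1' and group1 == 'A' and group2 == 'C'")
        assert extreme["p_bonferroni"].iloc[0] < 0.001

    def test_bonferroni_multiplies_by_axes(self):
        scores, groups = grouped_scores(n_per=10, seed=2, k=4)
        table, _ = anova_per_axis(scores, groups)
        np.testing.assert_allclose(table["p_bonferroni"],
                                   np.minimum(1.0, table["p"] * 4))

    def test_single_group_rejected(self):
        scores, groups = grouped_scores(n_per=5, seed=3)
        with pytest.raises(ValueError, match="2 groups"):
            anova_per_axis(scores, pd.Series("A", index=scores.index))


class TestCVA:
    def test_function_count_and_variance_sum(self):
        # 4 groups on 8 axes -> exactly 3 canonical functions summing to 100%
        rng = np.random.default_rng(4)
        n = 120
        scores = pd.DataFrame(rng.normal(size=(n, 8)),
                              columns=[f"ES{i + 1}" for i in range(8)],
                              index=[f"s{i}" for i in range(n)])
        groups = pd.Series(np.repeat(["A", "B", "C", "D"], n // 4),
                           index=scores.index)
        res = cva_wilks(scores, groups)
        assert res.coefficients.shape == (8, 3)
        assert res.variance_pct.sum() == pytest.approx(100.0)

    def test_canonical_scores_unit_within_group_covariance(self):
        scores, groups = grouped_scores(n_per=40, shift=1.5, seed=5)
        res = cva_wilks(scores, groups)
        pooled = np.zeros((res.scores.shape[1], res.scores.shape[1]))
        for lv in groups.unique():
            sub = res.scores[(groups == lv).to_numpy()].to_numpy()
            dev = sub - sub.mean(axis=0)
            pooled += dev.T @ dev
        pooled /= len(scores) - len(groups.unique())
        np.testing.assert_allclose(pooled, np.eye(pooled.shape[0]), atol=1e-8)

    def test_two_groups_one_axis_matches_t_statistic(self):
        # squared canonical correlation lambda/(1+lambda) = t^2/(t^2 + df)
        rng = np.random.default_rng(6)
        a = rng.normal(size=30)
        b = rng.normal(size=30) + 0.8
        scores = pd.DataFrame({"ES1": np.concatenate([a, b])},
                              index=[f"s{i}" for i in range(60)])
        groups = pd.Series(["A"] * 30 + ["B"] * 30, index=scores.index)
        res = cva_wilks(scores, groups)
        t, _ = sps.ttest_ind(a, b)
        df = 58
        lam = res.eigenvalues[0]
        assert lam / (1 + lam) == pytest.approx(t**2 / (t**2 + df), abs=1e-10)

    def test_null_wilks_p_uniform(self):
        pvals = []
        for seed in range(400):
            scores, groups = grouped_scores(n_per=40, seed=seed, k=2)
            res = cva_wilks(scores, groups)
            pvals.append(res.wilks["p"].iloc[0])
        assert sps.kstest(pvals, "uniform").pvalue > 0.01


class TestRepeatability:
    def _frame(self, values, ids):
        idx = [f"r{i}" for i in range(len(values))]
        scores = pd.DataFrame({"ES1": values}, index=idx)
        return scores, pd.Series(ids, index=idx)

    def test_perfect_repeatability(self):
        scores, ids = self._frame([1, 1, 1, 5, 5, 5], list("aaabbb"))
        res = repeatability(scores, ids)
        assert res[0].R == 1.0

    def test_no_among_individual_variance_clamped(self):
        rng = np.random.default_rng(7)
        vals = np.concatenate([rng.normal(0, 1, 10), rng.normal(0, 1, 10)])
        scores, ids = self._frame(vals, ["a"] * 10 + ["b"] * 10)
        res = repeatability(scores, ids)
        assert 0.0 <= res[0].R < 0.4

    def test_hand_computed_balanced_anova(self):
        # groups {1,1,1} and {2,2,4}: MS_among = 25/6, MS_within = 2/3,
        # n0 = 3 -> s2_among = 7/6, R = (7/6)/(7/6 + 2/3) = 7/11
        scores, ids = self._frame([1, 1, 1, 2, 2, 4], list("aaabbb"))
        res = repeatability(scores, ids)
        assert res[0].MS_among == pytest.approx(25 / 6, abs=1e-12)
        assert res[0].MS_within == pytest.approx(2 / 3, abs=1e-12)
        assert res[0].n0 == pytest.approx(3.0, abs=1e-12)
        assert res[0].R == pytest.approx(7 / 11, abs=1e-12)

    def test_affine_invariance(self):
        rng = np.random.default_rng(8)
        vals = np.concatenate([rng.normal(i, 0.3, 4) for i in range(5)])
        ids = np.repeat(list("abcde"), 4)
        scores, s_ids = self._frame(vals, ids)
        r1 = repeatability(scores, s_ids)[0].R
        r2 = repeatability(scores * 13.7 - 4.0, s_ids)[0].R
        assert r1 == pytest.approx(r2, abs=1e-12)

    def test_single_individual_rejected(self):
        scores, ids = self._frame([1, 2, 3], list("aaa"))
        with pytest.raises(ValueError, match="2 individuals"):
            repeatability(scores, ids)
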