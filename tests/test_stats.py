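"""Statistical battery: rank tests, critical differences, type-III ANOVA,
cell means and loess."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from oracles import type3_ss_oracle
from siterates.stats import (
    InestimableTermError,
    RateFactorAnalysis,
    anova_type3,
    cell_means,
    kruskal_wallis,
    loess_disorder_content,
    loess_fit,
    mann_whitney,
    pairwise_rank_comparisons,
    tricube,
)


class TestMannWhitney:
    def test_complete_separation(self):
        r = mann_whitney([1, 2, 3], [4, 5, 6])
        assert r.u == 0.0
        assert r.delta_median == 3.0

    def test_identical_groups(self):
        r = mann_whitney([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.delta_median == 0.0
        assert r.p > 0.9

    @pytest.mark.parametrize("seed", range(8))
    def test_exact_p_matches_permutation_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.integers(0, 6, int(rng.integers(3, 9))).astype(float)
        b = rng.integers(0, 6, int(rng.integers(3, 9))).astype(float)
        mine = mann_whitney(a, b)
        assert mine.method == "exact"

        def u_stat(x, y, axis=-1):
            return sps.mannwhitneyu(x, y, alternative="two-sided", axis=axis).statistic

        ref = sps.permutation_test(
            (a, b),
            u_stat,
            permutation_type="independent",
            alternative="two-sided",
            n_resamples=np.inf,
        )
        assert mine.p == pytest.approx(float(ref.pvalue), abs=1e-12)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])

    def test_rank_invariance_under_monotone_transform(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(0, 1, 40), rng.normal(0.5, 1, 35)
        r1 = mann_whitney(a, b)
        r2 = mann_whitney(np.exp(a), np.exp(b))
        assert r1.u == r2.u
        assert r1.p == pytest.approx(r2.p)


class TestKruskalWallis:
    def test_two_groups_equals_squared_normal_statistic(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(0, 1, 25), rng.normal(0.6, 1, 30)  # continuous: no ties
        h, p = kruskal_wallis([a, b])
        n1, n2 = len(a), len(b)
        u = sps.mannwhitneyu(a, b).statistic
        z = (u - n1 * n2 / 2) / math.sqrt(n1 * n2 * (n1 + n2 + 1) / 12)
        assert h == pytest.approx(z**2, rel=1e-10)

    def test_identical_values_degenerate(self):
        h, p = kruskal_wallis([np.ones(5), np.ones(7)])
        assert h == 0.0 and p == 1.0

    def test_type_one_error_calibration(self):
        rng = np.random.default_rng(7)
        rejections = 0
        n_sim = 1000
        for _ in range(n_sim):
            groups = [rng.normal(0, 1, 10) for _ in range(3)]
            _, p = kruskal_wallis(groups)
            rejections += p < 0.05
        rate = rejections / n_sim
        sd = math.sqrt(0.05 * 0.95 / n_sim)
        assert abs(rate - 0.05) < 3 * sd


class TestPairwiseRankComparisons:
    def test_two_identical_groups_not_significant(self):
        out = pairwise_rank_comparisons({"a": np.ones(5), "b": np.ones(5)})
        assert out.significant.tolist() == [False]

    def test_shifted_group_has_exactly_its_seven_pairs(self):
        rng = np.random.default_rng(2)
        groups = {f"g{i}": rng.normal(0, 1, 40) for i in range(7)}
        groups["shifted"] = rng.normal(0, 1, 40) + 100.0
        out = pairwise_rank_comparisons(groups, alpha=0.05)
        sig = out[out.significant.astype(bool)]
        assert len(sig) == 7
        assert all("shifted" in (r.group_a, r.group_b) for r in sig.itertuples())

    def test_three_group_toy_matches_hand_arithmetic(self):
        groups = {
            "a": np.array([1.0, 2.0, 3.0, 4.0, 5.0]),
            "b": np.array([2.0, 3.0, 4.0, 5.0, 6.0]),
            "c": np.array([10.0, 11.0, 12.0, 13.0, 14.0]),
        }
        out = pairwise_rank_comparisons(groups, alpha=0.05)
        n_total = 15
        # critical difference computed longhand from the published rule
        z = sps.norm.ppf(1 - 0.05 / (3 * 2))
        crit = z * math.sqrt(n_total * (n_total + 1) / 12.0 * (1 / 5 + 1 / 5))
        pooled = np.concatenate([groups["a"], groups["b"], groups["c"]])
        ranks = sps.rankdata(pooled)
        mr = {"a": ranks[:5].mean(), "b": ranks[5:10].mean(), "c": ranks[10:].mean()}
        for row in out.itertuples():
            assert row.critical_diff == pytest.approx(crit)
            expected = abs(mr[row.group_a] - mr[row.group_b]) >= crit
            assert row.significant == expected
        # hand computation: mean ranks are a=4.6, b=6.4, c=13 and the
        # critical difference is ~6.77, so only a-vs-c (8.4) clears it;
        # b-vs-c (6.6) falls just short - a deliberate boundary case
        verdicts = {(r.group_a, r.group_b): r.significant for r in out.itertuples()}
        assert verdicts == {("a", "b"): False, ("a", "c"): True, ("b", "c"): False}

    def test_empty_group_not_evaluable(self):
        out = pairwise_rank_comparisons({"a": np.ones(3), "b": np.array([])})
        assert out.significant.isna().all()

    def test_pair_count_is_28_for_eight_groups(self):
        rng = np.random.default_rng(0)
        groups = {f"g{i}": rng.normal(size=10) for i in range(8)}
        assert len(pairwise_rank_comparisons(groups)) == 28


def _factorial_frame(counts, seed=1):
    rng = np.random.default_rng(seed)
    cells = [
        (d, s, m)
        for d in ("ordered", "disordered")
        for s in ("structured", "coil")
        for m in ("domain", "linker")
    ]
    rows = []
    for cell, k in zip(cells, counts):
        for _ in range(k):
            rows.append(
                {"disorder": cell[0], "ss": cell[1], "domain": cell[2],
                 "z_rate": float(rng.normal())}
            )
    return pd.DataFrame(rows)


class TestAnovaType3:
    def test_unbalanced_16_rows_matches_design_matrix_oracle(self):
        df = _factorial_frame([3, 2, 1, 2, 3, 1, 2, 2])
        res = anova_type3(df)
        oracle = type3_ss_oracle(df)
        for term, ss in oracle.items():
            assert float(res.table.loc[term, "sum_sq"]) == pytest.approx(ss, abs=1e-8)

    def test_balanced_type3_equals_type1(self):
        import statsmodels.api as sm
        import statsmodels.formula.api as smf

        df = _factorial_frame([4] * 8, seed=3)
        res3 = anova_type3(df)
        model = smf.ols(
            "z_rate ~ C(disorder, Sum) * C(ss, Sum) * C(domain, Sum)", data=df
        ).fit()
        res1 = sm.stats.anova_lm(model, typ=1)
        for term_full, term in [
            ("C(disorder, Sum)", "disorder"),
            ("C(ss, Sum)", "ss"),
            ("C(domain, Sum)", "domain"),
            ("C(disorder, Sum):C(ss, Sum)", "disorder:ss"),
            ("C(disorder, Sum):C(ss, Sum):C(domain, Sum)", "disorder:ss:domain"),
        ]:
            assert float(res3.table.loc[term, "sum_sq"]) == pytest.approx(
                float(res1.loc[term_full, "sum_sq"]), rel=1e-8
            )

    def test_degrees_of_freedom_and_nonnegative_ss(self):
        df = _factorial_frame([5, 3, 4, 6, 2, 7, 3, 4], seed=4)
        res = anova_type3(df)
        terms = [t for t in res.table.index if t != "Intercept"]
        assert res.table.loc[terms, "df"].sum() == len(df) - 1
        assert (res.table.loc[terms, "sum_sq"] >= 0).all()

    def test_missing_cell_is_inestimable(self):
        df = _factorial_frame([3, 2, 1, 2, 0, 1, 2, 2])
        with pytest.raises(InestimableTermError, match="disordered"):
            anova_type3(df)

    def test_f_invariant_under_affine_transform(self):
        df = _factorial_frame([3, 4, 5, 3, 4, 5, 3, 4], seed=9)
        res1 = anova_type3(df)
        df2 = df.assign(z_rate=3.0 * df.z_rate - 7.0)
        res2 = anova_type3(df2)
        terms = [t for t in res1.table.index if t not in ("Intercept", "Residual")]
        np.testing.assert_allclose(
            res1.table.loc[terms, "F"].to_numpy(dtype=float),
            res2.table.loc[terms, "F"].to_numpy(dtype=float),
            rtol=1e-9,
        )


class TestCellMeans:
    def test_single_row_per_cell_identity(self):
        df = _factorial_frame([1] * 8, seed=5)
        means = cell_means(df)
        merged = means.cells.merge(df, on=["disorder", "ss", "domain"])
        np.testing.assert_allclose(merged.mean_z, merged.z_rate)

    def test_marginal_means_recompute_from_cells(self):
        df = _factorial_frame([5, 3, 4, 6, 2, 7, 3, 4], seed=6)
        means = cell_means(df)
        margin = means.margin("disorder", "ss")
        for row in margin.itertuples():
            direct = df[(df.disorder == row.disorder) & (df.ss == row.ss)].z_rate.mean()
            assert row.mean_z == pytest.approx(direct)

    def test_empty_cell_reported_missing(self):
        df = _factorial_frame([1, 1, 1, 1, 0, 1, 1, 1], seed=7)
        means = cell_means(df)
        assert means.cells.mean_z.isna().sum() == 1


class TestLoess:
    def test_linear_data_reproduced_exactly(self):
        x = np.linspace(0, 1, 40)
        y = 2.0 * x + 1.0
        grid = np.linspace(0.1, 0.9, 9)
        gx, gy = loess_fit(x, y, span=0.5, grid=grid)
        np.testing.assert_allclose(gy, 2.0 * grid + 1.0, atol=1e-8)

    def test_tricube_kernel_endpoints(self):
        assert tricube(np.array([0.0]))[0] == pytest.approx(1.0)
        assert tricube(np.array([1.0]))[0] == 0.0
        assert tricube(np.array([0.5]))[0] == pytest.approx((1 - 0.125) ** 3)

    def test_focal_fit_equals_hand_weighted_least_squares(self):
        rng = np.random.default_rng(8)
        x = np.sort(rng.uniform(0, 1, 30))
        y = np.sin(3 * x) + rng.normal(0, 0.05, 30)
        x0 = 0.4
        span = 0.5
        q = math.ceil(span * len(x))
        d = np.abs(x - x0)
        h = np.sort(d)[q - 1]
        w = tricube(d / h)
        mask = w > 0
        X = np.column_stack([np.ones(mask.sum()), x[mask] - x0])
        W = np.diag(w[mask])
        beta = np.linalg.solve(X.T @ W @ X, X.T @ W @ y[mask])
        _, fit = loess_fit(x, y, span=span, grid=np.array([x0]))
        assert fit[0] == pytest.approx(beta[0], rel=1e-9)

    def test_matches_statsmodels_lowess(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(10)
        x = np.sort(rng.uniform(0, 1, 60))
        y = np.sin(2 * x) + rng.normal(0, 0.05, 60)
        _, gy = loess_fit(x, y, span=0.5, grid=x)
        ref = sm.nonparametric.lowess(y, x, frac=0.5, it=0, return_sorted=False)
        np.testing.assert_allclose(gy, ref, atol=1e-10)

    def test_too_few_families_rejected(self):
        with pytest.raises(ValueError, match="10 families"):
            loess_disorder_content(np.linspace(0, 1, 5), np.zeros(5))

    def test_window_too_small_rejected(self):
        x = np.linspace(0, 1, 12)
        with pytest.raises(ValueError, match="too small"):
            loess_fit(x, x, span=0.05)


class TestRateFactorAnalysis:
    def _site_table(self, seed=0, n=400):
        rng = np.random.default_rng(seed)
        rows = []
        for k in range(n):
            d = rng.choice(["ordered", "disordered"])
            s = rng.choice(["structured", "coil"])
            m = rng.choice(["domain", "linker"])
            z = rng.normal() + (0.5 if d == "disordered" else 0.0)
            rows.append(
                {
                    "family_id": f"f{k % 10}",
                    "column_index": k,
                    "z_rate": z,
                    "disorder_label": d,
                    "ss_label": s,
                    "domain_label": m,
                    "tri_factor_complete": True,
                    "gap_free": True,
                }
            )
        return pd.DataFrame(rows)

    def test_full_battery_runs_and_reports(self):
        res = RateFactorAnalysis(self._site_table()).fit()
        assert set(res.mw) == {
            "disorder_minus_order",
            "coil_minus_structure",
            "linker_minus_domain",
        }
        assert res.mw["disorder_minus_order"].delta_median > 0
        assert res.mw["disorder_minus_order"].p < 0.01
        assert len(res.pairwise) == 28
        assert res.anova is not None
        text = res.summary()
        assert "Kruskal-Wallis" in text and "adjusted R^2" in text

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError, match="missing columns"):
            RateFactorAnalysis(pd.DataFrame({"z_rate": [1.0]}))
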