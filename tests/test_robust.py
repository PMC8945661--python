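import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from tempodisc import (
    ancova_f,
    cohens_d_paired,
    kendall_tau,
    m_location,
    mm_regression,
    ols_regression,
)


def brute_force_tau(x, y):
    """O(n^2) pure-python pair counting oracle for tau-b."""
    n = len(x)
    conc = disc = 0
    tx = ty = 0
    for i in range(n):
        for j in range(i + 1, n):
            dx = int(x[j] > x[i]) - int(x[j] < x[i])
            dy = int(y[j] > y[i]) - int(y[j] < y[i])
            if dx * dy > 0:
                conc += 1
            elif dx * dy < 0:
                disc += 1
            if dx == 0:
                tx += 1
            if dy == 0:
                ty += 1
    n0 = n * (n - 1) // 2
    denom = ((n0 - tx) * (n0 - ty)) ** 0.5
    return (conc - disc) / denom, conc, disc


class TestKendallTau:
    @pytest.mark.parametrize(
        "x, y, expected",
        [
            ((1, 2, 3), (1, 2, 3), 1.0),
            ((1, 2, 3), (3, 2, 1), -1.0),
            ((1, 2, 3, 4), (1, 3, 2, 4), 4 / 6),  # 5 concordant, 1 discordant
        ],
    )
    def test_examples(self, x, y, expected):
        res = kendall_tau(x, y)
        assert res.tau == pytest.approx(expected, abs=1e-12)

    def test_matches_scipy(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n = rng.integers(5, 40)
            x = rng.integers(0, 8, n).astype(float)
            y = 0.5 * x + rng.integers(0, 6, n)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            res = kendall_tau(x, y)
            ref = stats.kendalltau(x, y)
            assert res.tau == pytest.approx(ref.statistic, abs=1e-12)
            assert res.p_value == pytest.approx(ref.pvalue, abs=5e-3)

    def test_brute_force_with_ties(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            n = int(rng.integers(4, 50))
            x = rng.integers(0, 6, n).astype(float)
            y = rng.integers(0, 6, n).astype(float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            tau, conc, disc = brute_force_tau(x, y)
            res = kendall_tau(x, y)
            assert res.tau == pytest.approx(tau, abs=1e-12)
            assert (res.concordant, res.discordant) == (conc, disc)

    @given(st.lists(st.integers(0, 20), min_size=4, max_size=25))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_monotone_transform_invariance(self, xs):
        rng = np.random.default_rng(1)
        x = np.array(xs, float)
        y = rng.permutation(len(x)).astype(float)
        if np.ptp(x) == 0:
            return
        a = kendall_tau(x, y)
        b = kendall_tau(np.exp(x / 5.0), y)  # strictly increasing transform
        c = kendall_tau(-x, y)
        assert a.tau == pytest.approx(b.tau, abs=1e-12)
        assert a.tau == pytest.approx(-c.tau, abs=1e-12)

    def test_exact_small_n(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        y = np.array([2.0, 1.0, 4.0, 3.0, 6.0, 5.0])
        exact = kendall_tau(x, y, method="exact")
        ref = stats.kendalltau(x, y, method="exact")
        assert exact.p_value == pytest.approx(ref.pvalue, abs=1e-12)
        with pytest.raises(ValueError):
            kendall_tau(np.arange(12.0), np.arange(12.0), method="exact")

    def test_constant_variable_signalled(self):
        with pytest.raises(ValueError, match="constant"):
            kendall_tau([1, 1, 1], [1, 2, 3])


class TestMLocation:
    def test_symmetric(self):
        assert m_location([1, 2, 3]) == pytest.approx(2.0, abs=1e-10)

    def test_bounded_influence(self):
        est = m_location([1, 2, 3, 1000])
        assert 1.0 <= est <= 3.5

    def test_within_data_range_always(self):
        rng = np.random.default_rng(2)
        for _ in range(30):
            x = rng.standard_cauchy(int(rng.integers(3, 50)))
            est = m_location(x)
            assert x.min() <= est <= x.max()

    def test_translation_equivariance(self):
        x = np.array([0.3, 1.2, -4.0, 2.2, 9.0])
        assert m_location(x + 17.5) == pytest.approx(
            m_location(x) + 17.5, abs=1e-8)

    def test_reduces_to_mean_without_outliers(self):
        x = np.array([1.0, 1.5, 2.0, 2.5, 3.0])
        assert m_location(x) == pytest.approx(x.mean(), abs=1e-10)

    def test_zero_mad_warns_median(self):
        with pytest.warns(UserWarning, match="MAD"):
            assert m_location([5, 5, 5, 5, 9]) == 5.0


class TestOLS:
    def test_noiseless_line(self):
        x = np.arange(10.0)
        X = np.column_stack([np.ones(10), x])
        res = ols_regression(X, 1 + 2 * x)
        assert res.params == pytest.approx([1.0, 2.0], abs=1e-10)
        assert res.r_squared == pytest.approx(1.0)

    def test_matches_normal_equations(self):
        rng = np.random.default_rng(3)
        X = np.column_stack([np.ones(40), rng.standard_normal((40, 2))])
        y = rng.standard_normal(40)
        res = ols_regression(X, y)
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert res.params == pytest.approx(beta, abs=1e-10)

    def test_orthogonal_slope_zero(self):
        x = np.array([-1.0, 1.0, -1.0, 1.0])
        y = np.array([1.0, 1.0, -1.0, -1.0])
        res = ols_regression(np.column_stack([np.ones(4), x]), y)
        assert res.params[1] == pytest.approx(0.0, abs=1e-12)

    def test_rank_deficiency_signalled(self):
        X = np.column_stack([np.ones(10), np.ones(10)])
        with pytest.raises(np.linalg.LinAlgError):
            ols_regression(X, np.arange(10.0))


class TestMMRegression:
    def test_noiseless_exact(self):
        x = np.linspace(0, 5, 30)
        X = np.column_stack([np.ones(30), x])
        res = mm_regression(X, 1 + 2 * x, seed=0)
        assert res.params == pytest.approx([1.0, 2.0], abs=1e-6)

    def test_clean_data_near_ols(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal(200)
        y = 1 + 0.8 * x + rng.standard_normal(200)
        X = np.column_stack([np.ones(200), x])
        mm = mm_regression(X, y, seed=0)
        ols = ols_regression(X, y)
        assert np.all(np.abs(mm.params - ols.params) <= 3 * ols.bse)

    def test_breakdown_resistance(self):
        rng = np.random.default_rng(5)
        n = 100
        x = rng.uniform(0, 10, n)
        y = 1 + 2 * x + rng.standard_normal(n)
        y_bad = y.copy()
        y_bad[rng.choice(n, n // 5, replace=False)] += 1000.0
        X = np.column_stack([np.ones(n), x])
        mm = mm_regression(X, y_bad, seed=0)
        ols = ols_regression(X, y_bad)
        assert abs(mm.params[1] - 2.0) < 0.1
        assert abs(ols.params[1] - 2.0) > 0.5

    def test_equivariance(self):
        rng = np.random.default_rng(6)
        x = rng.standard_normal(80)
        y = 2 - x + rng.standard_normal(80)
        y[:8] += 30  # some contamination
        X = np.column_stack([np.ones(80), x])
        base = mm_regression(X, y, seed=1)
        scaled = mm_regression(X, 3.0 * y, seed=1)
        shifted = mm_regression(X, y + X @ np.array([5.0, -2.0]), seed=1)
        assert scaled.params == pytest.approx(3.0 * base.params, rel=1e-6)
        assert shifted.params == pytest.approx(
            base.params + np.array([5.0, -2.0]), rel=1e-6, abs=1e-6)

    def test_needs_enough_observations(self):
        X = np.column_stack([np.ones(4), np.arange(4.0)])
        with pytest.raises(ValueError):
            mm_regression(X, np.arange(4.0), seed=0)


class TestAncova:
    def test_equals_partial_t_squared_for_two_groups(self):
        # single-df factor: the nested-model F must equal the squared
        # partial t of the group dummy, computed independently via the
        # coefficient pivot rather than an RSS comparison
        import statsmodels.api as sm

        rng = np.random.default_rng(7)
        y = np.concatenate([rng.standard_normal(30),
                            1.0 + rng.standard_normal(35)])
        group = np.array(["a"] * 30 + ["b"] * 35)
        cov = rng.standard_normal(65)
        f, df1, df2, p = ancova_f(y, group, cov)
        X = np.column_stack([np.ones(65), cov, (group == "b").astype(float)])
        t = sm.OLS(y, X).fit().tvalues[2]
        assert f == pytest.approx(t ** 2, rel=1e-10)
        assert df1 == 1

    def test_df_contract(self):
        rng = np.random.default_rng(8)
        y = rng.standard_normal(50)
        group = np.repeat(["a", "b", "c"], [20, 15, 15])
        f, df1, df2, p = ancova_f(y, group, rng.standard_normal(50))
        assert (df1, df2) == (2, 50 - 3 - 1)

    def test_no_group_difference(self):
        rng = np.random.default_rng(9)
        cov = rng.standard_normal(60)
        y = 2 * cov + 0.001 * rng.standard_normal(60)
        group = np.tile(["a", "b"], 30)
        f, *_ = ancova_f(y, group, cov)
        assert f < 4.0  # no real group signal

    def test_relabeling_symmetry(self):
        rng = np.random.default_rng(10)
        y = rng.standard_normal(40)
        cov = rng.standard_normal(40)
        group = np.tile(["a", "b"], 20)
        f1, *_ = ancova_f(y, group, cov)
        swapped = np.where(group == "a", "b", "a")
        f2, *_ = ancova_f(y, swapped, cov)
        assert f1 == pytest.approx(f2, rel=1e-10)

    def test_small_group_signalled(self):
        with pytest.raises(ValueError):
            ancova_f(np.arange(5.0), np.array(["a"] * 4 + ["b"]),
                     np.zeros(5))


class TestCohensD:
    def test_identical_pairs(self):
        assert cohens_d_paired([1, 2, 3], [1, 2, 3]) == 0.0

    def test_constant_shift_undefined(self):
        with pytest.raises(ValueError):
            cohens_d_paired([2, 3, 4], [1, 2, 3])

    def test_direct_arithmetic(self):
        # differences (1, 2, 3): mean 2, sample sd 1
        assert cohens_d_paired([2, 4, 6], [1, 2, 3]) == pytest.approx(2.0)
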