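"""Longitudinal statistics: elimination/imputation, RM-ANOVA, Mann-Whitney, Pearson."""


import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mfoct import stats as ms


def _frame(arr, months=None):
    arr = np.asarray(arr, dtype=float)
    months = months or list(range(2, 2 + arr.shape[1]))
    return pd.DataFrame(arr, columns=months)


class TestPrepareMatrix:
    def test_column_with_30pct_missing_eliminated(self):
        arr = np.ones((10, 4))
        arr[:3, 1] = np.nan                       # 30% missing in month 3
        out = ms.prepare_matrix(_frame(arr))
        assert out.dropped_columns == [3]
        assert 3 not in out.data.columns

    def test_linear_interpolation_of_interior_gap(self):
        """Series (2, _, 6) at equal month spacing imputes the gap as 4."""
        arr = np.array([[2.0, np.nan, 6.0, 8.0]] * 8)
        arr[1:, 1] = 4.0                          # keep the column alive
        out = ms.prepare_matrix(_frame(arr))
        assert out.data.iloc[0, 1] == pytest.approx(4.0)
        assert out.imputed.iloc[0, 1]

    def test_endpoint_gap_extrapolated_linearly(self):
        arr = np.tile([1.0, 2.0, 3.0, np.nan], (20, 1))
        arr[1:, 3] = 4.0
        out = ms.prepare_matrix(_frame(arr))
        assert out.data.iloc[0, 3] == pytest.approx(4.0)

    def test_complete_matrix_unchanged(self):
        rng = np.random.default_rng(0)
        arr = rng.random((6, 5))
        out = ms.prepare_matrix(_frame(arr))
        assert np.allclose(out.data.to_numpy(), arr)
        assert not out.imputed.to_numpy().any()

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        arr = rng.random((8, 5))
        arr[0, 2] = np.nan
        arr[3, 4] = np.nan
        once = ms.prepare_matrix(_frame(arr))
        twice = ms.prepare_matrix(once.data)
        assert np.allclose(once.data.to_numpy(), twice.data.to_numpy())

    def test_rows_eliminated_after_columns(self):
        arr = np.ones((4, 8))
        arr[0, :3] = np.nan                       # row missing 37.5%
        out = ms.prepare_matrix(_frame(arr))
        assert len(out.dropped_rows) == 1

    def test_empty_result_raises(self):
        arr = np.full((4, 3), np.nan)
        with pytest.raises(ValueError):
            ms.prepare_matrix(_frame(arr))


def rm_anova_oracle(x):
    """From-scratch sums-of-squares repeated-measures ANOVA (explicit loops)."""
    n, k = x.shape
    grand = x.sum() / x.size
    ss_subj = sum(k * (row.mean() - grand) ** 2 for row in x)
    ss_time = sum(n * (x[:, j].mean() - grand) ** 2 for j in range(k))
    ss_total = sum((v - grand) ** 2 for v in x.ravel())
    ss_err = ss_total - ss_subj - ss_time
    return (ss_time / (k - 1)) / (ss_err / ((n - 1) * (k - 1)))


class TestRmAnova:
    def test_null_effect_gives_zero_f_and_p_one(self):
        arr = np.tile(np.array([[1.0], [5.0], [2.0]]), (1, 4))
        result = ms.rm_anova_bonferroni(ms.prepare_matrix(_frame(arr)))
        assert result.statistic == 0.0
        assert result.p_value == 1.0

    def test_matches_from_scratch_oracle(self):
        rng = np.random.default_rng(2)
        x = rng.random((4, 3)) * 10
        result = ms.rm_anova_bonferroni(ms.prepare_matrix(_frame(x)))
        assert result.statistic == pytest.approx(rm_anova_oracle(x), abs=1e-10)

    def test_matches_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(3)
        x = rng.random((8, 4)) * 5 + np.arange(4)[None, :]
        result = ms.rm_anova_bonferroni(ms.prepare_matrix(_frame(x)))
        long = pd.DataFrame({
            "subject": np.repeat(np.arange(8), 4),
            "time": np.tile(np.arange(4), 8),
            "value": x.ravel(),
        })
        ref = pingouin.rm_anova(data=long, dv="value", within="time",
                                subject="subject")
        assert result.statistic == pytest.approx(float(ref["F"][0]), rel=1e-6)
        assert result.p_value == pytest.approx(float(ref["p_unc"][0]), rel=1e-6)

    def test_bonferroni_arithmetic(self):
        # 3 post hoc comparisons at raw p → adjusted p = min(1, 3p)
        rng = np.random.default_rng(4)
        x = rng.random((6, 4))
        matrix = ms.prepare_matrix(_frame(x))
        result = ms.rm_anova_bonferroni(matrix)
        assert len(result.adjusted) == 3
        from scipy.stats import ttest_rel

        for col in matrix.data.columns[1:]:
            raw = ttest_rel(matrix.data[col], matrix.data[matrix.baseline]).pvalue
            assert result.adjusted[f"{col} vs {matrix.baseline}"] == pytest.approx(
                min(1.0, raw * 3)
            )

    def test_invariant_under_per_subject_constant(self):
        rng = np.random.default_rng(5)
        x = rng.random((5, 4))
        shifted = x + rng.normal(size=(5, 1)) * 100
        f1 = ms.rm_anova_bonferroni(ms.prepare_matrix(_frame(x))).statistic
        f2 = ms.rm_anova_bonferroni(ms.prepare_matrix(_frame(shifted))).statistic
        assert f1 == pytest.approx(f2, rel=1e-8)


class TestMannWhitney:
    def test_separated_groups_exact_p(self):
        """{1,2,3} vs {4,5,6}: U = 0; 2 of the 20 assignments reach it →
        exact two-sided p = 0.1."""
        result = ms.mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert result.statistic == 0.0
        assert result.p_value == pytest.approx(0.1)

    def test_identical_multisets_give_half_u(self):
        result = ms.mann_whitney_u([1, 2, 3], [1, 2, 3])
        assert result.statistic == pytest.approx(9 / 2)

    def test_symmetric_in_groups(self):
        rng = np.random.default_rng(0)
        a, b = rng.random(5), rng.random(4)
        r1 = ms.mann_whitney_u(a, b)
        r2 = ms.mann_whitney_u(b, a)
        assert r1.statistic == r2.statistic
        assert r1.p_value == r2.p_value

    @given(st.lists(st.integers(0, 50), min_size=2, max_size=5),
           st.lists(st.integers(0, 50), min_size=2, max_size=5))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_invariant_under_monotone_transform(self, a, b):
        r1 = ms.mann_whitney_u(a, b)
        f = lambda v: [np.exp(x / 10.0) + 3 for x in v]
        r2 = ms.mann_whitney_u(f(a), f(b))
        assert r1.statistic == pytest.approx(r2.statistic)
        assert r1.p_value == pytest.approx(r2.p_value)

    def test_normal_approximation_against_scipy(self):
        from scipy.stats import mannwhitneyu

        rng = np.random.default_rng(1)
        a = rng.normal(0, 1, 40)
        b = rng.normal(0.6, 1, 35)
        result = ms.mann_whitney_u(a, b)
        ref = mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        assert result.p_value == pytest.approx(ref.pvalue, rel=0.02)


class TestPearson:
    def test_perfect_linear(self):
        x = np.arange(10.0)
        assert ms.pearson_r(x, 2 * x + 1).statistic == pytest.approx(1.0)

    def test_perfect_antilinear(self):
        x = np.arange(10.0)
        assert ms.pearson_r(x, -x).statistic == pytest.approx(-1.0)

    def test_zero_variance_flagged(self):
        result = ms.pearson_r([1, 2, 3], [5, 5, 5])
        assert np.isnan(result.statistic)
        assert result.flags

    def test_monte_carlo_consistency_at_rho_084(self):
        """n=50 bivariate Gaussian with ρ₀=0.84: the mean estimate over 500
        replicates is within 0.03 of ρ₀."""
        rng = np.random.default_rng(6)
        rho = 0.84
        estimates = []
        for _ in range(500):
            x = rng.standard_normal(50)
            y = rho * x + np.sqrt(1 - rho**2) * rng.standard_normal(50)
            estimates.append(ms.pearson_r(x, y).statistic)
        assert np.mean(estimates) == pytest.approx(rho, abs=0.03)


class TestReporting:
    def test_stars_thresholds(self):
        assert ms.significance_stars(0.04) == "*"
        assert ms.significance_stars(0.009) == "**"
        assert ms.significance_stars(0.0009) == "***"
        assert ms.significance_stars(0.2) == ""

    def test_report_lists_post_hoc(self):
        rng = np.random.default_rng(7)
        x = rng.random((6, 3))
        result = ms.rm_anova_bonferroni(ms.prepare_matrix(_frame(x)))
        text = ms.report([result])
        assert "post hoc" in text
        assert "ANOVA" in text
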