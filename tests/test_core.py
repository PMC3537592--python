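"""Core statistic: log-ratios, underflow-safe association, p-gain arithmetic."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from pgain import associate, compute_pgain, log_ratio, pgain_linear
from pgain.core import t_log10_sf_two_sided
from pgain.exceptions import (
    DegenerateInputError,
    InsufficientSamplesError,
    NonPositiveConcentrationError,
    ValidationError,
)

# Frozen log upper-tail values of the t-distribution from
# R: pt(t, df, lower.tail=FALSE, log.p=TRUE)   (natural log, one-sided)
R_T_LOGSF = [
    (0.5, 5, -1.14209583504),
    (2, 10, -3.30514155123),
    (5, 10, -8.22203860272),
    (50, 100, -166.109631911),
    (200, 998, -1858.40688727),
    (1000, 998, -3452.83820513),
    (1e4, 1000, -5760.84079364),
    (1.2, 3, -1.84433111289),
    (3, 2, -3.04213264974),
]


class TestLogRatio:
    def test_identity_and_e(self):
        assert log_ratio([2.0], [2.0]) == pytest.approx([0.0])
        assert log_ratio([np.e], [1.0]) == pytest.approx([1.0])

    @settings(max_examples=50, deadline=None)
    @given(
        hnp.arrays(
            float,
            st.integers(1, 20),
            elements=st.floats(1e-6, 1e6, allow_nan=False),
        )
    )
    def test_antisymmetry(self, a):
        b = np.roll(a, 1) + 0.5
        np.testing.assert_array_equal(log_ratio(a, b), -log_ratio(b, a))

    @pytest.mark.parametrize("bad", [0.0, -1.0, np.nan, np.inf])
    def test_rejects_invalid_concentrations_naming_samples(self, bad):
        a = np.array([1.0, bad, 2.0])
        with pytest.raises(NonPositiveConcentrationError) as exc:
            log_ratio(a, np.ones(3))
        assert exc.value.samples == [1]

    def test_length_mismatch(self):
        with pytest.raises(ValidationError):
            log_ratio([1.0, 2.0], [1.0])


class TestTLogTail:
    @pytest.mark.parametrize("t,df,expected", R_T_LOGSF)
    def test_matches_reference_tail(self, t, df, expected):
        """Two-sided log10 p agrees with the R t-tail to ~10 digits,
        including p-values around 1e-2500 that underflow a linear scale."""
        got = float(t_log10_sf_two_sided(t, df))
        want = (np.log(2.0) + expected) / np.log(10.0)
        assert got == pytest.approx(want, rel=1e-9)

    def test_monotone_in_t(self):
        t = np.array([0.1, 1.0, 5.0, 30.0, 100.0, 1000.0])
        vals = t_log10_sf_two_sided(t, 50)
        assert np.all(np.diff(vals) < 0)
        assert np.all(np.isfinite(vals))


class TestAssociate:
    def test_matches_independent_least_squares(self):
        """Normal-equations fit + t tail reproduces associate to 1e-8."""
        rng = np.random.default_rng(42)
        n = 100
        x = rng.normal(size=n)
        y = 0.4 * x + rng.normal(size=n)
        res = associate(x, y)

        X = np.column_stack([np.ones(n), x])
        coef = np.linalg.solve(X.T @ X, X.T @ y)
        resid = y - X @ coef
        sigma2 = resid @ resid / (n - 2)
        se = np.sqrt(sigma2 * np.linalg.inv(X.T @ X)[1, 1])
        tstat = coef[1] / se
        want_log10p = float(t_log10_sf_two_sided(tstat, n - 2))
        assert res.log10_p == pytest.approx(want_log10p, abs=1e-8)
        assert res.beta == pytest.approx(coef[1], rel=1e-10)
        assert res.n_used == n

    def test_matches_statsmodels_ols(self):
        statsmodels = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(3)
        n = 80
        x = rng.normal(size=n)
        cov = rng.normal(size=(n, 2))
        y = 0.3 * x + cov @ [0.5, -0.2] + rng.normal(size=n)
        res = associate(x, y, covariates=cov)
        X = statsmodels.add_constant(np.column_stack([x, cov]))
        fit = statsmodels.OLS(y, X).fit()
        assert res.log10_p == pytest.approx(np.log10(fit.pvalues[1]), abs=1e-8)
        assert res.beta == pytest.approx(fit.params[1], rel=1e-8)

    def test_null_pvalues_uniform(self):
        """Under independence the p-value is Uniform(0,1) (KS over replicates)."""
        from scipy import stats

        rng = np.random.default_rng(5)
        ps = np.empty(10_000)
        for i in range(ps.size):
            x = rng.normal(size=20)
            y = rng.normal(size=20)
            ps[i] = 10.0 ** associate(x, y).log10_p
        assert stats.kstest(ps, "uniform").pvalue > 1e-3

    def test_perfect_fit_is_p_zero(self):
        x = np.arange(10.0)
        res = associate(x, 2.0 * x + 1.0)
        assert res.log10_p == -np.inf
        assert res.explained_variance == pytest.approx(1.0)

    def test_extreme_association_stays_finite(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=2000)
        y = x + 1e-3 * rng.normal(size=2000)
        res = associate(x, y)
        assert np.isfinite(res.log10_p)
        assert res.log10_p < -1000  # far below linear-scale underflow

    def test_degenerate_inputs(self):
        x = np.arange(10.0)
        with pytest.raises(DegenerateInputError):
            associate(np.ones(10), x)
        with pytest.raises(DegenerateInputError):
            associate(x, np.ones(10))
        with pytest.raises(InsufficientSamplesError):
            associate(x[:2], x[:2] * 2)

    def test_complete_case_filtering(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=50)
        y = 0.5 * x + rng.normal(size=50)
        x2, y2 = x.copy(), y.copy()
        x2[3] = np.nan
        y2[7] = np.nan
        res = associate(x2, y2)
        assert res.n_used == 48
        ref = associate(np.delete(x, [3, 7]), np.delete(y, [3, 7]))
        assert res.log10_p == pytest.approx(ref.log10_p, abs=1e-12)

    def test_explained_variance_is_incremental(self):
        """With a strong covariate, R² of x is its increment, not the total."""
        rng = np.random.default_rng(9)
        n = 200
        c = rng.normal(size=n)
        x = rng.normal(size=n)
        y = 2.0 * c + 0.1 * x + rng.normal(size=n)
        res = associate(x, y, covariates=c.reshape(-1, 1))
        assert res.explained_variance < 0.2


class TestComputePGain:
    def test_direct_arithmetic(self):
        got = compute_pgain(np.log10(1e-5), np.log10(1e-3), np.log10(1e-8))
        assert got == pytest.approx(3.0)

    def test_substrate_product_example(self):
        """p = 2.3e-21 for the best single metabolite vs 9.987e-66 for the
        ratio gives a p-gain near 10^44.36."""
        got = compute_pgain(np.log10(2.3e-21), np.log10(1e-5), np.log10(9.987e-66))
        assert got == pytest.approx(44.36, abs=0.01)

    @settings(max_examples=50, deadline=None)
    @given(
        st.floats(-300, 0),
        st.floats(-300, 0),
        st.floats(-300, 0),
    )
    def test_swap_invariance(self, p1, p2, pr):
        assert compute_pgain(p1, p2, pr) == compute_pgain(p2, p1, pr)

    def test_rejects_positive_log_p(self):
        with pytest.raises(ValidationError):
            compute_pgain(0.5, -1.0, -2.0)

    def test_linear_accessor_saturates(self):
        val, sat = pgain_linear(44.36)
        assert val == pytest.approx(10**44.36, rel=1e-10)
        assert not sat
        val, sat = pgain_linear(400.0)
        assert sat and val == np.finfo(float).max

    def test_log_pipeline_matches_linear_when_representable(self):
        p1, p2, pr = 1e-7, 1e-4, 1e-12
        linear = min(p1, p2) / pr
        got, sat = pgain_linear(
            compute_pgain(np.log10(p1), np.log10(p2), np.log10(pr))
        )
        assert not sat
        assert got == pytest.approx(linear, rel=1e-12)
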