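"""Mann–Kendall, Theil–Sen, OLS and the decoupling-ratio machinery."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from amazonfires.trends import (DEFAULT_PHASES, PhaseDefinition, exact_mk_p,
                                fires_per_area_ratio, mann_kendall, ols_regression,
                                phase_regressions, theil_sen)


def brute_force_mk_p(values):
    """Two-tailed P(|S| >= |s_obs|) by enumerating every ordering."""
    v = np.asarray(values, dtype=float)
    n = len(v)

    def s_stat(x):
        return sum(np.sign(x[j] - x[i]) for i in range(n) for j in range(i + 1, n))

    s_obs = abs(s_stat(v))
    hits = sum(abs(s_stat(np.array(p))) >= s_obs
               for p in itertools.permutations(v))
    import math
    return hits / math.factorial(n)


class TestMannKendall:
    def test_constant_series_is_degenerate(self):
        r = mann_kendall(pd.Series([5.0] * 6, index=range(2000, 2006)))
        assert r.mk_s == 0 and r.p_two_tailed == 1.0
        assert r.degenerate and not r.significant

    def test_strictly_increasing_n4(self):
        r = mann_kendall(pd.Series([1.0, 2, 3, 4], index=range(4)))
        assert r.mk_s == 6
        assert r.p_exact == pytest.approx(2 / 24, abs=1e-15)

    @pytest.mark.parametrize("n", [4, 5, 6, 7])
    def test_exact_p_equals_enumeration(self, n):
        rng = np.random.default_rng(n)
        for _ in range(3):
            v = rng.normal(size=n)
            r = mann_kendall(pd.Series(v, index=range(n)))
            assert r.p_exact == pytest.approx(brute_force_mk_p(v), abs=1e-12)

    def test_exact_p_matches_scipy_kendalltau(self):
        # independent oracle: exact Kendall tau test against the time axis
        rng = np.random.default_rng(0)
        for n in (6, 8, 10):
            v = rng.normal(size=n)
            r = mann_kendall(pd.Series(v, index=range(n)))
            p_scipy = stats.kendalltau(np.arange(n), v, method="exact").pvalue
            assert r.p_exact == pytest.approx(p_scipy, abs=1e-12)

    def test_normal_approx_close_to_exact_for_n10(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            v = rng.normal(size=10)
            r = mann_kendall(pd.Series(v, index=range(10)))
            assert abs(r.p_two_tailed - r.p_exact) < 0.02

    def test_tie_corrected_variance(self):
        # n=5 with one pair tied: Var = (n(n-1)(2n+5) - t(t-1)(2t+5))/18
        r = mann_kendall(pd.Series([1.0, 2, 2, 3, 4], index=range(5)))
        assert r.mk_var == pytest.approx((5 * 4 * 15 - 2 * 1 * 9) / 18)

    def test_decreasing_trend_detected(self):
        y = pd.Series(np.arange(17, 0, -1.0), index=range(2003, 2020))
        r = mann_kendall(y, alpha=0.01)
        assert r.mk_s == -(17 * 16) // 2 and r.significant and r.sen_slope == -1.0


class TestTheilSen:
    def test_exact_linear(self):
        t = np.arange(2000, 2010)
        slope, intercept, lo, hi = theil_sen(pd.Series(3.0 * t + 7, index=t))
        assert slope == pytest.approx(3.0)
        assert intercept == pytest.approx(7.0)
        assert lo <= slope <= hi

    def test_hand_enumeration(self):
        # pairwise slopes of {0,0,10} at years {1,2,3}: {0, 5, 10} -> median 5
        slope, *_ = theil_sen(pd.Series([0.0, 0, 10], index=[1, 2, 3]))
        assert slope == pytest.approx(5.0)

    def test_shift_invariance(self):
        rng = np.random.default_rng(11)
        y = pd.Series(rng.normal(size=12), index=range(12))
        assert theil_sen(y)[0] == pytest.approx(theil_sen(y + 100.0)[0], abs=1e-12)

    def test_breakdown_point(self):
        # 4/17 (= 23.5% <= 29%) gross outliers leave the slope exactly intact
        t = np.arange(2003, 2020)
        y = 2.5 * (t - 2003) + 1.0
        y = y.astype(float)
        y[[2, 7, 11, 16]] += np.array([300.0, -500.0, 250.0, -400.0])
        slope, *_ = theil_sen(pd.Series(y, index=t))
        assert slope == pytest.approx(2.5, abs=1e-12)


class TestPropertyInvariances:
    values = st.lists(st.floats(-1e6, 1e6, allow_nan=False, allow_infinity=False),
                      min_size=4, max_size=12, unique=True)

    @given(values, st.floats(-1e3, 1e3, allow_nan=False))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_theil_sen_shift_and_scale_equivariance(self, vals, shift):
        s = pd.Series(vals, index=range(len(vals)))
        base = theil_sen(s)[0]
        assert theil_sen(s + shift)[0] == pytest.approx(base, rel=1e-9, abs=1e-9)
        assert theil_sen(2.0 * s)[0] == pytest.approx(2.0 * base, rel=1e-9, abs=1e-9)

    @given(values)
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_mk_antisymmetric_under_negation(self, vals):
        s = pd.Series(vals, index=range(len(vals)))
        a = mann_kendall(s)
        b = mann_kendall(-s)
        assert a.mk_s == -b.mk_s
        assert a.p_two_tailed == pytest.approx(b.p_two_tailed, abs=1e-12)
        assert abs(a.mk_s) <= len(vals) * (len(vals) - 1) / 2


class TestOLS:
    def test_perfect_fit(self):
        x = np.arange(10.0)
        r = ols_regression(x, 2 * x)
        assert r.slope == pytest.approx(2.0) and r.r_squared == pytest.approx(1.0)

    def test_matches_normal_equations(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=5)
        y = rng.normal(size=5)
        X = np.column_stack([np.ones(5), x])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        r = ols_regression(x, y)
        assert r.intercept == pytest.approx(beta[0], abs=1e-12)
        assert r.slope == pytest.approx(beta[1], abs=1e-12)

    def test_null_p_values_uniform(self):
        # y independent of x: slope p-values should be U(0,1)
        rng = np.random.default_rng(99)
        ps = [ols_regression(rng.normal(size=15), rng.normal(size=15)).p_value
              for _ in range(1000)]
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_zero_variance_x_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            ols_regression(np.ones(5), np.arange(5.0))


class TestRatioAndPhases:
    def test_elementwise_ratio(self):
        fires = pd.Series([100.0, 60], index=[2003, 2004])
        defor = pd.Series([50.0, 30], index=[2003, 2004])
        r = fires_per_area_ratio(fires, defor)
        assert list(r) == [2.0, 2.0]

    def test_scale_homogeneity(self):
        years = range(2003, 2010)
        fires = pd.Series(np.arange(7, 0, -1.0) * 100, index=years)
        defor = pd.Series(np.linspace(50, 20, 7), index=years)
        r1 = fires_per_area_ratio(fires, defor)
        r2 = fires_per_area_ratio(3 * fires, 3 * defor)
        assert np.allclose(r1, r2)

    def test_zero_deforestation_names_year(self):
        fires = pd.Series([1.0, 1, 1], index=[2003, 2004, 2005])
        defor = pd.Series([1.0, 0, 1], index=[2003, 2004, 2005])
        with pytest.raises(ValueError, match="2004"):
            fires_per_area_ratio(fires, defor)

    def test_phase_results_match_manual_subsets(self):
        rng = np.random.default_rng(8)
        years = pd.Index(range(2003, 2020))
        fires = pd.Series(rng.uniform(1e4, 1e5, len(years)), index=years)
        defor = pd.Series(rng.uniform(5e3, 3e4, len(years)), index=years)
        res = phase_regressions(fires, defor, DEFAULT_PHASES)
        for ph in DEFAULT_PHASES:
            yrs = [y for y in years if ph.start <= y <= ph.end]
            manual = ols_regression(defor.loc[yrs], fires.loc[yrs])
            assert res[ph.name].slope == manual.slope
            assert res[ph.name].r_squared == manual.r_squared

    def test_noise_free_affine_gives_r2_one(self):
        years = pd.Index(range(2003, 2020))
        defor = pd.Series(np.linspace(27000, 5000, len(years)), index=years)
        fires = 2.0 * defor + 1000.0
        assert phase_regressions(fires, defor)["full"].r_squared == pytest.approx(1.0)

    def test_three_year_phase_flagged_low_n(self):
        years = pd.Index(range(2003, 2020))
        rng = np.random.default_rng(2)
        fires = pd.Series(rng.uniform(1, 2, len(years)), index=years)
        defor = pd.Series(rng.uniform(1, 2, len(years)), index=years)
        res = phase_regressions(fires, defor)
        assert res["Phase II"].low_n and res["Phase II"].testable  # 2009-2011

    def test_phase_outside_span_rejected(self):
        years = pd.Index(range(2003, 2010))
        s = pd.Series(1.0 * np.arange(7) + 1, index=years)
        with pytest.raises(ValueError, match="outside"):
            phase_regressions(s, s + 1, [PhaseDefinition("x", 2050, 2055)])
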