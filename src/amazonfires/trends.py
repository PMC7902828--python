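"""Trend and regression machinery for annual fire and emission series.

Two families of tests are provided, matching common practice in fire and
land-use time-series work:

* non-parametric trend detection — the two-tailed Mann–Kendall test with the
  tie-corrected variance and ±1 continuity correction, plus an exact
  enumeration p-value for short series, and the Theil–Sen robust slope;
* ordinary least squares with R² and the two-sided t-test on the slope, used
  for fire–deforestation and [CO] regressions.

Series are plain :class:`pandas.Series` indexed by integer year.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TrendResult",
    "RegressionResult",
    "PhaseDefinition",
    "DEFAULT_PHASES",
    "mann_kendall",
    "theil_sen",
    "ols_regression",
    "fires_per_area_ratio",
    "phase_regressions",
]


def _as_series(ts, min_n: int = 2) -> pd.Series:
    s = pd.Series(ts, dtype=float) if not isinstance(ts, pd.Series) else ts.astype(float)
    if s.index.has_duplicates:
        raise ValueError("duplicate years in series")
    s = s.sort_index()
    if len(s) < min_n:
        raise ValueError(f"series needs at least {min_n} points, got {len(s)}")
    return s


@dataclass
class TrendResult:
    """Mann–Kendall statistic and Theil–Sen slope for one series."""

    sen_slope: float
    sen_intercept: float
    sen_ci_low: float
    sen_ci_high: float
    mk_s: int
    mk_var: float
    mk_z: float
    p_two_tailed: float
    alpha: float
    significant: bool
    p_exact: float | None = None
    degenerate: bool = False
    n: int = 0


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int
    low_n: bool = False
    testable: bool = True


@dataclass(frozen=True)
class PhaseDefinition:
    """A named inclusive year range (e.g. a deforestation-policy phase)."""

    name: str
    start: int
    end: int

    def years(self) -> range:
        return range(self.start, self.end + 1)


#: PPCDAm deforestation-control policy phases used to stratify regressions.
DEFAULT_PHASES = (
    PhaseDefinition("Phase I", 2004, 2008),
    PhaseDefinition("Phase II", 2009, 2011),
    PhaseDefinition("Phase III", 2012, 2015),
    PhaseDefinition("Phase IV", 2016, 2019),
)


def _mk_s_and_var(values: np.ndarray) -> tuple[int, float, bool]:
    """Return (S, tie-corrected Var(S), has_ties)."""
    n = len(values)
    diff = np.sign(values[None, :] - values[:, None])
    s = int(np.triu(diff, k=1).sum())
    _, counts = np.unique(values, return_counts=True)
    ties = counts[counts > 1]
    var = (n * (n - 1) * (2 * n + 5) - np.sum(ties * (ties - 1) * (2 * ties + 5))) / 18.0
    return s, float(var), ties.size > 0


@lru_cache(maxsize=32)
def _s_null_distribution(n: int) -> tuple[np.ndarray, float]:
    """Null distribution of the MK S statistic for tie-free data.

    Uses the classical inversion-count (Mahonian) recurrence: the number of
    permutations of n items with k inversions; S = n(n-1)/2 - 2k.  Returns the
    counts array indexed by k and the total n!.
    """
    counts = np.array([1.0])
    for m in range(2, n + 1):
        counts = np.convolve(counts, np.ones(m))
    return counts, float(math.factorial(n))


def exact_mk_p(s_obs: int, n: int) -> float:
    """Exact two-tailed P(|S| >= |s_obs|) under random ordering (no ties)."""
    counts, total = _s_null_distribution(n)
    c = n * (n - 1) // 2
    k = np.arange(len(counts))
    s_vals = c - 2 * k
    return float(counts[np.abs(s_vals) >= abs(s_obs)].sum() / total)


def mann_kendall(ts, alpha: float = 0.05, exact_max_n: int = 10) -> TrendResult:
    """Two-tailed Mann–Kendall trend test with Theil–Sen slope.

    The normal approximation uses the tie-corrected variance of S and the ±1
    continuity correction; for tie-free series with ``n <= exact_max_n`` the
    exact enumeration p-value is additionally reported in ``p_exact``.

    An all-equal series is degenerate: S = 0, p = 1, flagged.
    """
    s = _as_series(ts)
    values = s.to_numpy()
    years = s.index.to_numpy(dtype=float)
    n = len(values)

    mk_s, var, has_ties = _mk_s_and_var(values)

    degenerate = bool(np.all(values == values[0]))
    if degenerate:
        slope, intercept, lo, hi = 0.0, float(values[0]), 0.0, 0.0
        return TrendResult(slope, intercept, lo, hi, 0, 0.0, 0.0, 1.0, alpha,
                           False, p_exact=None, degenerate=True, n=n)

    if mk_s > 0:
        z = (mk_s - 1) / math.sqrt(var)
    elif mk_s < 0:
        z = (mk_s + 1) / math.sqrt(var)
    else:
        z = 0.0
    p = 2.0 * (1.0 - stats.norm.cdf(abs(z)))

    p_exact = None
    if not has_ties and n <= exact_max_n:
        p_exact = exact_mk_p(mk_s, n)

    slope, intercept, lo, hi = theil_sen(s)
    return TrendResult(slope, intercept, lo, hi, mk_s, var, float(z), float(p),
                       alpha, bool(p < alpha), p_exact=p_exact, n=n)


def theil_sen(ts, ci: float = 0.95) -> tuple[float, float, float, float]:
    """Theil–Sen slope: median of all pairwise slopes, with CI bounds.

    Returns ``(slope, intercept, ci_low, ci_high)``.  The intercept follows
    the median-residual convention ``median(y - slope * t)``; the confidence
    limits on the slope are the distribution-free Sen bounds at level ``ci``.
    """
    s = _as_series(ts)
    t = s.index.to_numpy(dtype=float)
    y = s.to_numpy()
    res = stats.theilslopes(y, t, alpha=ci)
    slope = float(res.slope)
    intercept = float(np.median(y - slope * t))
    return slope, intercept, float(res.low_slope), float(res.high_slope)


def ols_regression(x, y, alpha: float = 0.05) -> RegressionResult:
    """OLS of y on x with R² and the two-sided t-test p-value on the slope."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    n = len(x)
    if n < 3:
        raise ValueError("regression requires n >= 3 for a p-value")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in x")
    fit = stats.linregress(x, y)
    return RegressionResult(float(fit.slope), float(fit.intercept),
                            float(fit.rvalue) ** 2, float(fit.pvalue), n)


def fires_per_area_ratio(fires: pd.Series, defor_km2: pd.Series) -> pd.Series:
    """Annual number of active fires per km² deforested.

    High values flag fire activity in excess of what deforestation alone
    would drive — the decoupling diagnostic.
    """
    fires = _as_series(fires)
    defor = _as_series(defor_km2)
    if not fires.index.equals(defor.index):
        raise ValueError("fires and deforestation series must share the same years")
    bad = defor.index[defor <= 0]
    if len(bad):
        raise ValueError(f"non-positive deforestation in year(s) {list(bad)}")
    out = fires / defor
    out.name = "fires_per_km2"
    return out


def phase_regressions(fires: pd.Series, defor_km2: pd.Series,
                      phases=DEFAULT_PHASES) -> dict[str, RegressionResult]:
    """Fire-on-deforestation OLS per policy phase plus the full span.

    Phases with fewer than 3 overlapping years are returned flagged
    non-testable rather than dropped; 3-year phases carry a low-n flag.
    """
    fires = _as_series(fires)
    defor = _as_series(defor_km2)
    common = fires.index.intersection(defor.index)
    results: dict[str, RegressionResult] = {}
    span = (int(common.min()), int(common.max()))
    for ph in phases:
        if ph.start > span[1] or ph.end < span[0]:
            raise ValueError(f"phase {ph.name} ({ph.start}-{ph.end}) outside data span {span}")
        yrs = common[(common >= ph.start) & (common <= ph.end)]
        if len(yrs) < 3:
            results[ph.name] = RegressionResult(np.nan, np.nan, np.nan, np.nan,
                                                len(yrs), low_n=True, testable=False)
            continue
        r = ols_regression(defor.loc[yrs], fires.loc[yrs])
        r.low_n = len(yrs) <= 3
        results[ph.name] = r
    results["full"] = ols_regression(defor.loc[common], fires.loc[common])
    return results
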