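"""Trend and sensitivity analysis of the annual carbon-monoxide series.

Annual mean [CO] at 800 hPa tracks biomass-burning emissions over the biome.
Three operations are provided:

* recomputing one year's annual mean over a shifted 12-month window (used
  when a late fire-season onset pushes emissions into the next calendar
  year, e.g. Apr 2015 – Mar 2016);
* regressing [CO] on time (OLS with t-test) and on annual deforestation;
* an increment-based sensitivity scan: selected years' [CO] values are
  reduced in fixed percentage steps (representing emissions imported from
  outside the biome) until the time trend becomes significant, reporting the
  minimal reduction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .trends import RegressionResult, ols_regression

__all__ = ["SensitivityResult", "window_adjust", "co_trend", "co_on_deforestation",
           "sensitivity_scan"]


@dataclass
class SensitivityResult:
    target_years: tuple[int, ...]
    step_pct: float
    alpha: float
    minimal_reduction_pct: float | None  # None when never significant
    p_at_minimum: float | None
    r2_at_minimum: float | None
    profile: pd.DataFrame  # columns: reduction_pct, slope, p_value, r_squared
    monotone: bool = True


def window_adjust(annual: pd.Series, monthly: pd.Series, year: int,
                  start_month: int = 4, end_month: int = 3) -> pd.Series:
    """Recompute one year's annual mean over a shifted 12-month window.

    ``monthly`` is indexed by a monthly ``PeriodIndex``.  The window runs
    from ``start_month`` of ``year`` through ``end_month`` of the following
    year when ``end_month < start_month`` (e.g. April–March), else within
    ``year``.  Only the target year's value changes.
    """
    if not isinstance(monthly.index, pd.PeriodIndex):
        monthly = pd.Series(monthly.to_numpy(),
                            index=pd.PeriodIndex(monthly.index, freq="M"))
    start = pd.Period(f"{year}-{start_month:02d}", freq="M")
    periods = pd.period_range(start, periods=12, freq="M")
    if end_month >= start_month:
        periods = pd.period_range(start, pd.Period(f"{year}-{end_month:02d}", freq="M"),
                                  freq="M")
    missing = [str(p) for p in periods if p not in monthly.index]
    if missing:
        raise ValueError(f"monthly values missing for: {', '.join(missing)}")
    out = annual.copy()
    out.loc[year] = float(monthly.loc[periods].mean())
    return out


def co_trend(co: pd.Series, alpha: float = 0.05) -> RegressionResult:
    """OLS regression of [CO] on year: slope, R² and two-sided p."""
    co = co.sort_index()
    return ols_regression(co.index.to_numpy(dtype=float), co.to_numpy(), alpha=alpha)


def co_on_deforestation(co: pd.Series, defor: pd.Series,
                        alpha: float = 0.05) -> RegressionResult:
    """OLS regression of annual [CO] on annual deforestation rate."""
    common = co.index.intersection(defor.index)
    if len(common) < 3:
        raise ValueError("need at least 3 overlapping years")
    return ols_regression(defor.loc[common].to_numpy(), co.loc[common].to_numpy(),
                          alpha=alpha)


def sensitivity_scan(co: pd.Series, target_years, step_pct: float = 5.0,
                     alpha: float = 0.05, max_reduction_pct: float = 50.0) -> SensitivityResult:
    """Minimal percentage reduction of the target years making the trend significant.

    For k = 0, step, 2·step, … ≤ max_reduction the target years' [CO] values
    are multiplied by (1 − k/100), the OLS-on-time regression is re-run, and
    the smallest k with p < alpha is reported (or None when the scan never
    reaches significance).  The full (k → slope, p, R²) profile is returned.
    """
    if step_pct <= 0:
        raise ValueError("step must be positive")
    target_years = tuple(int(y) for y in target_years)
    missing = [y for y in target_years if y not in co.index]
    if missing:
        raise ValueError(f"target years not in series: {missing}")

    rows = []
    k = 0.0
    while k <= max_reduction_pct + 1e-9:
        adj = co.copy()
        adj.loc[list(target_years)] = co.loc[list(target_years)] * (1 - k / 100.0)
        r = co_trend(adj, alpha=alpha)
        rows.append((k, r.slope, r.p_value, r.r_squared))
        k += step_pct
    profile = pd.DataFrame(rows, columns=["reduction_pct", "slope", "p_value",
                                          "r_squared"])
    hits = profile[profile["p_value"] < alpha]
    monotone = bool(np.all(np.diff(profile["p_value"].to_numpy()) <= 1e-12) or
                    len(profile) < 2)
    if len(hits):
        best = hits.iloc[0]
        return SensitivityResult(target_years, step_pct, alpha,
                                 float(best["reduction_pct"]), float(best["p_value"]),
                                 float(best["r_squared"]), profile, monotone)
    return SensitivityResult(target_years, step_pct, alpha, None, None, None,
                             profile, monotone)
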