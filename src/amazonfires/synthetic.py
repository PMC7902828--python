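"""Seeded generator of synthetic Amazon fire seasons with known ground truth.

The generator emulates the study's inputs at desk scale: a ~1-km landscape
grid (year-2000 tree cover, progressive annual deforestation), multi-year
daily active-fire detections of three behavioural types, and an annual [CO]
series coupled to total fire counts.  Every stochastic quantity derives from
one root seed through named child streams, so regeneration is bit-identical,
and a :class:`SyntheticTruth` records the labels and injected parameters
that downstream parameter-recovery tests check against.

The three fire types are generated on disjoint landscape strata so a perfect
rule-based classifier recovers the truth labels exactly:

* deforestation fires sit on actively clearing pixels (annual rate ≥ 5%,
  low tree cover) and burn on ≥ 2 distinct days (piled slash re-ignited);
* forest (understory) fires sit on high-tree-cover (≥ 70%), uncleared
  pixels and burn on at most 3 days;
* maintenance fires sit on low-cover pixels without active clearing and
  burn on exactly one day.

Annual expected totals follow a geometric trend; drought years multiply the
per-type expectation by type-specific factors (forest fires respond most,
deforestation fires barely — they are policy-, not weather-, driven).
"""

from __future__ import annotations

import calendar
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import xarray as xr
import yaml

from .io import GridSpec

__all__ = ["SyntheticConfig", "SyntheticTruth", "InfeasibleTypeError",
           "generate_landscape", "generate_fire_seasons", "generate_co_series",
           "generate_monthly_co"]

FIRE_TYPES = ("deforestation", "maintenance", "forest")


class InfeasibleTypeError(ValueError):
    """Raised when a requested fire type has no eligible pixels."""

    def __init__(self, fire_type: str, year: int):
        self.fire_type = fire_type
        super().__init__(f"no eligible pixels for fire type '{fire_type}' in {year}")


@dataclass
class SyntheticConfig:
    """Free parameters of the synthetic study region and fire regime.

    Defaults reproduce the study conditions: a 2003–2019 span, drought years
    2005/2007/2010/2015, a declining detection trend, a type mix of
    8% deforestation / 39% maintenance / 53% forest, and lognormal FRP with
    a much heavier tail for deforestation fires (FRP90 ≈ 4× forest fires).
    """

    grid_rows: int = 60
    grid_cols: int = 60
    years: tuple[int, ...] = tuple(range(2003, 2020))
    seed: int = 0
    # (deforestation, maintenance, forest)
    type_mix: tuple[float, float, float] = (0.08, 0.39, 0.53)
    annual_trend: float = -0.05
    base_detections_per_pixel: float = 3.0  # expected detections/pixel in the first year
    drought_years: tuple[int, ...] = (2005, 2007, 2010, 2015)
    drought_multiplier_by_type: dict = field(default_factory=lambda: {
        "deforestation": 1.0, "maintenance": 2.0, "forest": 3.0})
    # lognormal (mu, sigma) of FRP in MW per type
    frp_params_by_type: dict = field(default_factory=lambda: {
        "deforestation": (3.4, 1.1), "maintenance": (2.3, 0.8), "forest": (2.4, 0.8)})
    tree_cover_mix: tuple[float, float] = (0.6, 0.4)  # (high >= 70%, low) pixel fractions
    defor_front_fraction: float = 0.02   # fraction of all pixels clearing >= 5%/yr
    co_intercept: float = 95.0           # ppbv at zero fire activity
    co_slope: float = 0.002              # ppbv per annual detection
    co_noise_sd: float = 1.5             # ppbv
    season_months: tuple[int, ...] = (7, 8, 9, 10, 11)
    # multiplicative log-linear year modulation of FRP: (knot year, pre, post slopes)
    frp_breakpoint: tuple[int, float, float] | None = (2013, -0.06, 0.08)

    def __post_init__(self):
        if self.grid_rows <= 0 or self.grid_cols <= 0:
            raise ValueError(
                f"grid dimensions must be positive, got {self.grid_rows}x{self.grid_cols}")
        if self.grid_rows * self.grid_cols < 4:
            raise ValueError("grid must have at least 4 pixels")
        years = tuple(self.years)
        if any(b <= a for a, b in zip(years, years[1:])):
            raise ValueError("years must be strictly increasing")
        mix = np.asarray(self.type_mix, dtype=float)
        if mix.min() < 0 or abs(mix.sum() - 1.0) > 1e-12:
            raise ValueError("type_mix must be nonnegative and sum to 1")
        if any(m < 1 for m in self.drought_multiplier_by_type.values()):
            raise ValueError("drought multipliers must be >= 1")
        tc = np.asarray(self.tree_cover_mix, dtype=float)
        if tc.min() < 0 or abs(tc.sum() - 1.0) > 1e-9:
            raise ValueError("tree_cover_mix fractions must sum to 1")
        if not 0 <= self.defor_front_fraction <= tc[1] + 1e-12:
            raise ValueError("defor_front_fraction must be <= the low-cover fraction")

    @property
    def grid_spec(self) -> GridSpec:
        return GridSpec(rows=self.grid_rows, cols=self.grid_cols)

    @property
    def type_mix_by_name(self) -> dict:
        return dict(zip(FIRE_TYPES, self.type_mix))

    def expected_totals(self) -> pd.Series:
        """Expected detections per year (all types, drought factors included)."""
        base = self.base_detections_per_pixel * self.grid_rows * self.grid_cols
        out = {}
        for i, y in enumerate(self.years):
            level = base * (1.0 + self.annual_trend) ** i
            mult = 1.0
            if y in self.drought_years:
                mult = sum(self.type_mix_by_name[t] * self.drought_multiplier_by_type[t]
                           for t in FIRE_TYPES)
            out[y] = level * mult
        return pd.Series(out, name="expected_total")

    def to_yaml(self, path) -> None:
        d = asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "SyntheticConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        for k in ("years", "type_mix", "drought_years", "tree_cover_mix",
                  "season_months", "frp_breakpoint"):
            if k in d and d[k] is not None:
                d[k] = tuple(d[k])
        if "frp_params_by_type" in d:
            d["frp_params_by_type"] = {k: tuple(v) for k, v in d["frp_params_by_type"].items()}
        return cls(**d)


@dataclass
class SyntheticTruth:
    """Ground truth recorded at generation time for recovery tests."""

    detection_labels: pd.Series        # index aligned with the detections table
    pixel_stratum: xr.DataArray        # 'forest' | 'low' per pixel (static cover class)
    injected_trend: float              # relative change per year of expected totals
    injected_breakpoint_year: int | None
    expected_totals: pd.Series         # year -> expected detections


def _streams(seed: int) -> dict[str, np.random.Generator]:
    """Named child RNG streams spawned from one root seed, in fixed order."""
    root = np.random.SeedSequence(seed)
    names = ["landscape", "seasons", "co", "monthly_co"]
    return {n: np.random.default_rng(s) for n, s in zip(names, root.spawn(len(names)))}


def generate_landscape(config: SyntheticConfig) -> xr.Dataset:
    """Tree cover and progressive deforestation on the analysis grid.

    High-cover pixels (tree cover drawn in [70, 100)) are never cleared; each
    year a fixed share of the grid — ``defor_front_fraction`` of all pixels,
    drawn without replacement from the low-cover clearable pool — forms that
    year's clearing front with annual rates in [5, 15)%, emulating the smooth
    year-to-year deforestation totals of operational monitoring.  Cumulative
    deforestation from 2001 accumulates and is capped at 100%; pixels near
    exhaustion leave the clearable pool.
    """
    rng = _streams(config.seed)["landscape"]
    R, C = config.grid_rows, config.grid_cols
    n = R * C
    high = rng.random(n) < config.tree_cover_mix[0]
    tree = np.where(high, 70.0 + 30.0 * rng.random(n), 70.0 * rng.random(n))

    years = list(config.years)
    rate = np.zeros((len(years), n))
    cum = np.zeros((len(years), n))
    running = np.zeros(n)
    n_front = int(round(config.defor_front_fraction * n))
    for i, y in enumerate(years):
        pool = np.flatnonzero((~high) & (running <= 85.0))
        front = rng.choice(pool, size=min(n_front, pool.size), replace=False) \
            if n_front > 0 and pool.size else np.array([], dtype=int)
        rate[i, front] = 5.0 + 10.0 * rng.random(front.size)
        running = np.minimum(running + rate[i], 100.0)
        cum[i] = running

    coords = {"year": years}
    ds = xr.Dataset(
        {
            "tree_cover_2000": (("row", "col"), tree.reshape(R, C)),
            "annual_defor_rate": (("year", "row", "col"), rate.reshape(-1, R, C)),
            "cum_defor": (("year", "row", "col"), cum.reshape(-1, R, C)),
            "high_cover": (("row", "col"), high.reshape(R, C)),
        },
        coords=coords,
    )
    ds.attrs["seed"] = config.seed
    return ds


def _season_days(year: int, months) -> np.ndarray:
    days = []
    for m in months:
        ndays = calendar.monthrange(year, m)[1]
        days.extend(pd.Timestamp(year, m, d) for d in range(1, ndays + 1))
    return np.array(days, dtype="datetime64[ns]")


def _frp_year_factor(config: SyntheticConfig, year: int) -> float:
    if config.frp_breakpoint is None:
        return 1.0
    knot, pre, post = config.frp_breakpoint
    dy = year - knot
    return float(np.exp((pre if dy <= 0 else post) * dy))


def generate_fire_seasons(config: SyntheticConfig,
                          landscape: xr.Dataset) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Draw the multi-year detection table and its ground truth.

    Per year and type the detection count is Poisson with mean
    ``base · (1 + trend)^i · mix_t · drought_mult_t``.  Detections are placed
    on the type's eligible stratum; dates fall inside the configured fire
    season; FRP is lognormal per type times the year's intensity factor.
    """
    rng = _streams(config.seed)["seasons"]
    gs = config.grid_spec
    R, C = gs.shape
    n = R * C
    high = landscape["high_cover"].to_numpy().reshape(-1)
    rate = landscape["annual_defor_rate"].to_numpy().reshape(len(config.years), -1)

    base = config.base_detections_per_pixel * n
    mix = config.type_mix_by_name

    recs = {k: [] for k in ("pixel", "date", "frp", "label", "year")}
    for i, y in enumerate(config.years):
        level = base * (1.0 + config.annual_trend) ** i
        days = _season_days(y, config.season_months)
        ffac = _frp_year_factor(config, y)
        eligible = {
            "deforestation": np.flatnonzero((~high) & (rate[i] >= 5.0)),
            "maintenance": np.flatnonzero((~high) & (rate[i] < 5.0)),
            "forest": np.flatnonzero(high),
        }
        for t in FIRE_TYPES:
            lam = level * mix[t]
            if y in config.drought_years:
                lam *= config.drought_multiplier_by_type[t]
            if lam == 0:
                continue
            n_det = int(rng.poisson(lam))
            if n_det == 0:
                continue
            pool = eligible[t]
            if pool.size == 0:
                raise InfeasibleTypeError(t, y)

            if t == "maintenance":
                # exactly one detection day per pixel-year
                px = rng.choice(pool, size=n_det)
                uniq, inv = np.unique(px, return_inverse=True)
                day_of = rng.choice(len(days), size=len(uniq))
                det_days = days[day_of[inv]]
            elif t == "forest":
                # at most 3 distinct days per pixel-year
                px = rng.choice(pool, size=n_det)
                uniq, inv = np.unique(px, return_inverse=True)
                allowed = rng.integers(0, len(days), size=(len(uniq), 3))
                pick = rng.integers(0, 3, size=n_det)
                det_days = days[allowed[inv, pick]]
            else:  # deforestation: >= 2 distinct days per pixel-year
                n_det = max(n_det, 2)
                n_px = max(1, n_det // 3)
                px_sel = rng.choice(pool, size=min(n_px, pool.size), replace=False)
                # two guaranteed distinct days per selected pixel, extras random
                base_px = np.repeat(px_sel, 2)
                base_days = np.empty(2 * len(px_sel), dtype=int)
                for j in range(len(px_sel)):
                    base_days[2 * j:2 * j + 2] = rng.choice(len(days), size=2,
                                                            replace=False)
                extra = n_det - len(base_px)
                if extra > 0:
                    extra_px = rng.choice(px_sel, size=extra)
                    extra_days = rng.integers(0, len(days), size=extra)
                    px = np.concatenate([base_px, extra_px])
                    det_days = days[np.concatenate([base_days, extra_days])]
                else:
                    px = base_px
                    det_days = days[base_days]
                n_det = len(px)

            frp_mu, frp_sigma = config.frp_params_by_type[t]
            frp = rng.lognormal(frp_mu, frp_sigma, size=n_det) * ffac
            recs["pixel"].append(px)
            recs["date"].append(det_days)
            recs["frp"].append(frp)
            recs["label"].append(np.full(n_det, t, dtype=object))
            recs["year"].append(np.full(n_det, y))

    pixel = np.concatenate(recs["pixel"]) if recs["pixel"] else np.array([], dtype=int)
    rows, cols = pixel // C, pixel % C
    lon, lat = gs.rowcol_to_lonlat(rows, cols)
    detections = pd.DataFrame({
        "pixel_row": rows,
        "pixel_col": cols,
        "lon": lon,
        "lat": lat,
        "date": np.concatenate(recs["date"]) if recs["date"] else
        np.array([], dtype="datetime64[ns]"),
        "frp_mw": np.concatenate(recs["frp"]) if recs["frp"] else np.array([]),
    })
    labels = pd.Series(np.concatenate(recs["label"]) if recs["label"] else
                       np.array([], dtype=object), name="true_type")

    stratum = xr.DataArray(np.where(high, "forest", "low").reshape(R, C),
                           dims=("row", "col"), name="stratum")
    truth = SyntheticTruth(
        detection_labels=labels,
        pixel_stratum=stratum,
        injected_trend=config.annual_trend,
        injected_breakpoint_year=None if config.frp_breakpoint is None
        else int(config.frp_breakpoint[0]),
        expected_totals=config.expected_totals(),
    )
    return detections, truth


def generate_co_series(config: SyntheticConfig, annual_totals: pd.Series) -> pd.Series:
    """Annual mean [CO] affinely coupled to total detections plus noise.

    [CO]_y = intercept + slope · totals_y + N(0, sd).  Non-positive draws are
    resampled so the emitted series is strictly positive.
    """
    rng = _streams(config.seed)["co"]
    totals = annual_totals.sort_index()
    vals = np.empty(len(totals))
    for i, tot in enumerate(totals.to_numpy(dtype=float)):
        mean = config.co_intercept + config.co_slope * tot
        v = mean + rng.normal(0.0, config.co_noise_sd) if config.co_noise_sd > 0 else mean
        while v <= 0:
            v = mean + rng.normal(0.0, config.co_noise_sd)
        vals[i] = v
    out = pd.Series(vals, index=totals.index.astype(int), name="co_ppbv")
    return out


def generate_monthly_co(config: SyntheticConfig, annual_co: pd.Series,
                        wobble_sd: float = 0.5) -> pd.Series:
    """Monthly [CO] whose calendar-year mean equals the annual value exactly.

    Each year gets zero-mean monthly deviations (seasonal wobble), so
    recomputing a Jan–Dec mean reproduces the annual series while shifted
    windows (e.g. Apr–Mar) genuinely differ.
    """
    rng = _streams(config.seed)["monthly_co"]
    periods, values = [], []
    for y, v in annual_co.sort_index().items():
        dev = rng.normal(0.0, wobble_sd, size=12)
        dev -= dev.mean()
        for m in range(1, 13):
            periods.append(pd.Period(f"{int(y)}-{m:02d}", freq="M"))
            values.append(float(v) + dev[m - 1])
    return pd.Series(values, index=pd.PeriodIndex(periods, freq="M"), name="co_ppbv")
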