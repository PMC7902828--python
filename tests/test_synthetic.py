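"""Ground-truthed behaviour of the synthetic landscape/fire/CO generator."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from amazonfires.synthetic import (InfeasibleTypeError, SyntheticConfig,
                                   generate_co_series, generate_fire_seasons,
                                   generate_landscape, generate_monthly_co)
from amazonfires.trends import mann_kendall, ols_regression

NO_DROUGHT = {"deforestation": 1.0, "maintenance": 1.0, "forest": 1.0}


def cfg(**kw):
    base = dict(grid_rows=20, grid_cols=20, seed=7, base_detections_per_pixel=1.0)
    base.update(kw)
    return SyntheticConfig(**base)


class TestConfigValidation:
    @pytest.mark.parametrize("bad", [
        {"grid_rows": 0},
        {"grid_rows": -3},
        {"grid_rows": 1, "grid_cols": 2},          # < 4 pixels
        {"years": (2005, 2004)},                   # not increasing
        {"type_mix": (0.5, 0.4, 0.2)},             # sums to 1.1
        {"type_mix": (-0.1, 0.6, 0.5)},
        {"drought_multiplier_by_type": {"deforestation": 0.5,
                                        "maintenance": 1.0, "forest": 1.0}},
        {"defor_front_fraction": 0.9},             # exceeds low-cover share
    ])
    def test_invalid_configs_rejected(self, bad):
        with pytest.raises(ValueError):
            cfg(**bad)

    def test_yaml_round_trip(self, tmp_path):
        c = cfg()
        p = tmp_path / "c.yaml"
        c.to_yaml(p)
        assert SyntheticConfig.from_yaml(p) == c


class TestLandscape:
    def test_zero_front_means_no_clearing(self):
        land = generate_landscape(cfg(defor_front_fraction=0.0))
        assert float(land["annual_defor_rate"].max()) == 0.0
        assert float(land["cum_defor"].max()) == 0.0

    def test_all_high_cover_mix(self):
        land = generate_landscape(cfg(tree_cover_mix=(1.0, 0.0),
                                      defor_front_fraction=0.0))
        assert float(land["tree_cover_2000"].min()) >= 70.0

    def test_front_fraction_within_binomial_bounds(self):
        # 99% binomial bounds on the per-pixel-year front share at f = 0.02
        f = 0.02
        c = SyntheticConfig(grid_rows=50, grid_cols=50, seed=3,
                            defor_front_fraction=f)
        land = generate_landscape(c)
        frac = (land["annual_defor_rate"] >= 5.0).mean(dim=("row", "col"))
        n = 50 * 50
        half = 2.576 * np.sqrt(f * (1 - f) / n)
        assert ((frac >= f - half) & (frac <= f + half)).all()

    def test_cumulative_deforestation_monotone_and_bounded(self, small_landscape):
        cum = small_landscape["cum_defor"]
        assert float(cum.min()) >= 0 and float(cum.max()) <= 100
        diffs = cum.diff("year")
        assert float(diffs.min()) >= -1e-12
        assert float(small_landscape["tree_cover_2000"].min()) >= 0
        assert float(small_landscape["tree_cover_2000"].max()) <= 100


def distinct_days(det):
    d = det.copy()
    d["year"] = pd.to_datetime(d["date"]).dt.year
    return (d.drop_duplicates(["pixel_row", "pixel_col", "year", "date"])
             .groupby(["pixel_row", "pixel_col", "year"]).size())


class TestFireSeasons:
    def test_pure_maintenance_is_single_day(self):
        c = cfg(type_mix=(0.0, 1.0, 0.0), drought_multiplier_by_type=NO_DROUGHT)
        det, truth = generate_fire_seasons(c, generate_landscape(c))
        assert (truth.detection_labels == "maintenance").all()
        assert (distinct_days(det) == 1).all()

    def test_per_type_day_preconditions(self, small_config, small_landscape,
                                        small_season):
        det, truth = small_season
        det = det.assign(true_type=truth.detection_labels.to_numpy(),
                         year=pd.to_datetime(det["date"]).dt.year)
        days = distinct_days(det)
        for t, bound in (("deforestation", (2, None)), ("forest", (1, 3)),
                         ("maintenance", (1, 1))):
            sub = det[det.true_type == t]
            nd = days.loc[list(sub.groupby(["pixel_row", "pixel_col", "year"])
                               .groups)]
            lo, hi = bound
            assert (nd >= lo).all()
            if hi is not None:
                assert (nd <= hi).all()

    def test_types_sit_on_their_strata(self, small_config, small_landscape,
                                       small_season):
        det, truth = small_season
        land = small_landscape
        years = np.asarray(small_config.years)
        yi = np.searchsorted(years, pd.to_datetime(det["date"]).dt.year.to_numpy())
        rate = land["annual_defor_rate"].to_numpy()[yi, det["pixel_row"],
                                                    det["pixel_col"]]
        tree = land["tree_cover_2000"].to_numpy()[det["pixel_row"], det["pixel_col"]]
        lbl = truth.detection_labels.to_numpy()
        assert (rate[lbl == "deforestation"] >= 5.0).all()
        assert (tree[lbl == "forest"] >= 70.0).all()
        assert (rate[lbl == "maintenance"] < 5.0).all()
        assert (tree[lbl == "maintenance"] < 70.0).all()

    def test_truth_shares_converge_to_mix(self):
        # ~100k detections; shares within ±1.5 percentage points of the mix
        c = SyntheticConfig(grid_rows=20, grid_cols=20, seed=123,
                            base_detections_per_pixel=23.0,
                            type_mix=(0.08, 0.39, 0.53),
                            drought_multiplier_by_type=NO_DROUGHT)
        det, truth = generate_fire_seasons(c, generate_landscape(c))
        assert len(det) > 80_000
        shares = truth.detection_labels.value_counts(normalize=True)
        for t, m in c.type_mix_by_name.items():
            assert shares[t] == pytest.approx(m, abs=0.015)

    def test_no_drought_totals_follow_trend_line(self):
        c = cfg(drought_multiplier_by_type=NO_DROUGHT, annual_trend=-0.05)
        exp = c.expected_totals()
        base = exp.iloc[0]
        assert np.allclose(exp.to_numpy(), base * 0.95 ** np.arange(len(exp)))

    def test_dates_within_season_months(self, small_config, small_season):
        det, _ = small_season
        months = pd.to_datetime(det["date"]).dt.month
        assert months.isin(small_config.season_months).all()

    def test_same_seed_bit_identical(self):
        c = cfg()
        d1, t1 = generate_fire_seasons(c, generate_landscape(c))
        d2, t2 = generate_fire_seasons(c, generate_landscape(c))
        pd.testing.assert_frame_equal(d1, d2)
        pd.testing.assert_series_equal(t1.detection_labels, t2.detection_labels)

    def test_missing_stratum_raises_named_error(self):
        c = cfg(tree_cover_mix=(1.0, 0.0), defor_front_fraction=0.0,
                type_mix=(0.0, 0.5, 0.5))
        with pytest.raises(InfeasibleTypeError, match="maintenance"):
            generate_fire_seasons(c, generate_landscape(c))


class TestCoSeries:
    totals = pd.Series(np.linspace(5000, 2000, 17), index=range(2003, 2020))

    def test_zero_noise_exactly_affine(self):
        c = cfg(co_noise_sd=0.0, co_slope=0.002, co_intercept=95.0)
        co = generate_co_series(c, self.totals)
        assert np.allclose(co.to_numpy(), 95.0 + 0.002 * self.totals.to_numpy())
        r = ols_regression(self.totals.to_numpy(), co.to_numpy())
        assert r.r_squared == pytest.approx(1.0)

    def test_zero_slope_estimate_centered_on_zero(self):
        slopes = []
        for seed in range(60):
            c = cfg(seed=seed, co_slope=0.0, co_noise_sd=1.5)
            co = generate_co_series(c, self.totals)
            slopes.append(ols_regression(self.totals.to_numpy(), co.to_numpy()).slope)
        # mean slope within 3 SE of zero
        assert abs(np.mean(slopes)) < 3 * np.std(slopes) / np.sqrt(len(slopes))

    def test_positive_values_always(self):
        c = cfg(co_intercept=0.5, co_slope=0.0, co_noise_sd=5.0)
        co = generate_co_series(c, self.totals)
        assert (co > 0).all()

    def test_mk_power_on_declining_totals(self):
        # power of the MK test on [CO] estimated by 500-rep simulation
        hits = 0
        for seed in range(500):
            c = cfg(seed=seed, co_slope=0.002, co_noise_sd=1.5)
            co = generate_co_series(c, self.totals)
            r = mann_kendall(co, alpha=0.05)
            hits += r.significant and r.mk_s < 0
        assert hits / 500 > 0.8

    def test_monthly_means_reproduce_annual(self):
        c = cfg()
        co = generate_co_series(c, self.totals)
        monthly = generate_monthly_co(c, co)
        for y in (2003, 2010, 2019):
            window = monthly.loc[str(y)]
            assert float(window.mean()) == pytest.approx(co.loc[y], abs=1e-9)
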