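"""AnnMinTemp aggregation and linear trend/effect models."""

import numpy as np
import pandas as pd
import pytest

import tnzsize as tz
from tnzsize.climate import (
    annual_min_temp,
    fit_lm,
    site_climate_table,
    spatial_ann_min_temp,
    tnz_effect_models,
)
from tnzsize.errors import DataError, FitError
from tnzsize.synthetic import gen_daily_min_series, gen_sites


def make_series(site, year, values):
    dates = pd.date_range(f"{year}-01-01", periods=len(values), freq="D")
    return pd.DataFrame(
        {"site": site, "date": dates.strftime("%Y-%m-%d"), "tmin_C": values}
    )


class TestAnnualMean:
    def test_constant_year_returns_the_constant(self):
        s = make_series("X", 2022, [-3.0] * 365)
        assert annual_min_temp(s, "X", 2022) == pytest.approx(-3.0)

    def test_half_zero_half_ten_averages_to_five(self):
        s = make_series("X", 2022, [0.0] * 182 + [10.0] * 182 + [5.0])
        assert annual_min_temp(s, "X", 2022) == pytest.approx(
            (182 * 0 + 182 * 10 + 5) / 365
        )

    def test_row_order_does_not_matter(self):
        rng = np.random.default_rng(0)
        s = make_series("X", 2022, rng.normal(5, 3, 365))
        shuffled = s.sample(frac=1.0, random_state=1).reset_index(drop=True)
        assert annual_min_temp(shuffled, "X", 2022) == pytest.approx(
            annual_min_temp(s, "X", 2022), abs=1e-12
        )

    def test_incomplete_year_is_rejected(self):
        s = make_series("X", 2022, [1.0] * 100)
        with pytest.raises(DataError, match="completeness"):
            annual_min_temp(s, "X", 2022)

    def test_generated_series_matches_ground_truth(self, small_config):
        _, truth = gen_sites(small_config)
        site, year = "S05", small_config.years[-1]
        series = gen_daily_min_series(site, year, small_config, truth)
        assert annual_min_temp(series, site, year) == pytest.approx(
            truth.ann_min_temp(site, year), abs=1e-9
        )


class TestSpatialMean:
    def test_mean_of_two_years(self):
        s = pd.concat(
            [make_series("X", 2022, [12.0] * 365), make_series("X", 2023, [13.0] * 365)]
        )
        assert spatial_ann_min_temp(s, "X") == pytest.approx(12.5)

    def test_identical_years_return_that_value(self):
        s = pd.concat(
            [make_series("X", 2022, [9.0] * 365), make_series("X", 2023, [9.0] * 365)]
        )
        assert spatial_ann_min_temp(s, "X") == pytest.approx(9.0)

    def test_missing_year_error_names_site_and_year(self):
        s = make_series("X", 2022, [12.0] * 365)
        with pytest.raises(DataError, match="X.*2023"):
            spatial_ann_min_temp(s, "X")

    def test_generator_output_matches_closed_form_from_config(self, small_config):
        _, truth = gen_sites(small_config)
        site = "S02"
        frames = [
            gen_daily_min_series(site, y, small_config, truth) for y in (2022, 2023)
        ]
        got = spatial_ann_min_temp(pd.concat(frames), site, years=(2022, 2023))
        base = truth.sites.set_index("site").loc[site, "ann_min_temp_base"]
        y0 = small_config.years[0]
        expected = base + small_config.temp_year_slope * np.mean(
            [2022 - y0, 2023 - y0]
        )
        assert got == pytest.approx(expected, abs=1e-9)


class TestLinearFit:
    def test_perfect_line(self):
        f = fit_lm([0, 1, 2], [0, 1, 2])
        assert f.slope == pytest.approx(1.0)
        assert f.r_squared == pytest.approx(1.0)

    def test_matches_textbook_closed_form(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            n = rng.integers(5, 40)
            x = rng.normal(size=n)
            y = 2.0 + 0.7 * x + rng.normal(scale=0.5, size=n)
            f = fit_lm(x, y)
            sxx = np.sum((x - x.mean()) ** 2)
            slope = np.sum((x - x.mean()) * (y - y.mean())) / sxx
            intercept = y.mean() - slope * x.mean()
            resid = y - intercept - slope * x
            se = np.sqrt(np.sum(resid ** 2) / (n - 2) / sxx)
            assert f.slope == pytest.approx(slope, abs=1e-10)
            assert f.intercept == pytest.approx(intercept, abs=1e-10)
            assert f.slope_se == pytest.approx(se, abs=1e-10)

    def test_constant_predictor_is_rank_deficient(self):
        with pytest.raises(FitError):
            fit_lm([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_too_few_points(self):
        with pytest.raises(FitError):
            fit_lm([0.0, 1.0], [0.0, 1.0])

    def test_null_slope_t_test_is_calibrated(self):
        rng = np.random.default_rng(2)
        n_rep, n = 1000, 20
        x = rng.normal(size=n)
        rejections = 0
        for _ in range(n_rep):
            y = rng.normal(size=n)
            if fit_lm(x, y).p_value < 0.05:
                rejections += 1
        assert 0.03 <= rejections / n_rep <= 0.07


class TestEffectModels:
    def site_tables(self, tnz_b=None, n=9, seed=0):
        rng = np.random.default_rng(seed)
        sites = [f"S{i:02d}" for i in range(n)]
        temp = np.linspace(9.0, 13.0, n)
        if tnz_b is None:
            tnz_b = 2.0 - 0.34 * (temp - temp.mean())
        ult = 31.5 + tnz_b / 2
        llt = ult - tnz_b
        est = pd.DataFrame(
            {"site": sites, "llt_C": llt, "ult_C": ult, "tnz_b_C": tnz_b}
        )
        clim = pd.DataFrame({"site": sites, "ann_min_temp": temp})
        return est, clim

    def test_constant_breadth_gives_zero_slope(self):
        est, clim = self.site_tables(tnz_b=np.full(9, 2.0))
        fits = tnz_effect_models(est, clim)
        assert fits["tnz_b"]["natural"].slope == pytest.approx(0.0, abs=1e-12)

    def test_generating_breadth_slope_recovered_exactly_without_noise(self):
        est, clim = self.site_tables()
        fits = tnz_effect_models(est, clim)
        assert fits["tnz_b"]["natural"].slope == pytest.approx(-0.34, abs=1e-9)
        # standardized slope = natural slope * sd(x)
        sd = clim["ann_min_temp"].std(ddof=1)
        assert fits["tnz_b"]["standardized"].slope == pytest.approx(
            -0.34 * sd, abs=1e-9
        )

    def test_site_order_permutation_is_irrelevant(self):
        est, clim = self.site_tables()
        f1 = tnz_effect_models(est, clim)
        f2 = tnz_effect_models(
            est.sample(frac=1.0, random_state=3), clim.sample(frac=1.0, random_state=4)
        )
        assert f1["ult"]["natural"].slope == pytest.approx(
            f2["ult"]["natural"].slope, abs=1e-12
        )

    def test_fewer_than_three_joined_sites_is_an_error(self):
        est, clim = self.site_tables(n=3)
        with pytest.raises(DataError):
            tnz_effect_models(est.iloc[:2], clim)

    def test_ground_truth_sites_recover_configured_tnz_slopes(self):
        cfg = tz.SyntheticConfig(n_sites=12, tnz_site_sd=0.0, seed=21)
        _, truth = gen_sites(cfg)
        est = truth.sites.rename(
            columns={"llt": "llt_C", "ult": "ult_C", "tnz_b": "tnz_b_C"}
        )[["site", "llt_C", "ult_C", "tnz_b_C"]]
        clim = truth.sites.rename(columns={"ann_min_temp_spatial": "ann_min_temp"})[
            ["site", "ann_min_temp"]
        ]
        fits = tnz_effect_models(est, clim)
        assert fits["llt"]["natural"].slope == pytest.approx(0.15, abs=1e-9)
        assert fits["ult"]["natural"].slope == pytest.approx(-0.19, abs=1e-9)
        assert fits["tnz_b"]["natural"].slope == pytest.approx(-0.34, abs=1e-9)


def test_site_climate_table_covers_every_complete_site_year(small_config, small_data):
    tab = site_climate_table(small_data["climate"])
    assert len(tab) == small_config.n_sites * len(small_config.years)
    truth = small_data["truth"]
    merged = tab.merge(truth.site_years, on=["site", "year"], suffixes=("", "_t"))
    assert np.allclose(merged["ann_min_temp"], merged["ann_min_temp_t"], atol=1e-9)
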