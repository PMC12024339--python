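"""Stage classification, filters, standardization, and the gamma GLMM."""

import numpy as np
import pandas as pd
import pytest

import tnzsize as tz
from tnzsize.body_size import (
    GammaGLMM,
    ModelSpec,
    classify_stage,
    cyear,
    filter_records,
    fit_gamma_glmm,
    standardize,
    trend_and_effect_suite,
)
from tnzsize.climate import site_climate_table
from tnzsize.errors import DataError, FitError
from conftest import glmm_sim_frame


class TestClassifyStage:
    @pytest.mark.parametrize(
        "mass,stage",
        [
            (10.0, "juvenile"),
            (15.99, "juvenile"),
            (16.0, "sub-adult"),
            (23.0, "sub-adult"),
            (23.01, "adult I"),
            (29.0, "adult I"),
            (30.0, "adult II"),
            (37.0, "adult II"),
            (37.5, "old"),
        ],
    )
    def test_band_boundaries(self, mass, stage):
        assert classify_stage(mass) == stage

    def test_alternative_overlap_assignment(self):
        assert classify_stage(20.0, ambiguous_band="adult I") == "adult I"
        assert classify_stage(25.0, ambiguous_band="adult I") == "adult I"
        assert classify_stage(10.0, ambiguous_band="adult I") == "juvenile"

    def test_nonpositive_mass_rejected(self):
        with pytest.raises(ValueError):
            classify_stage(0.0)

    def test_array_input_partitions_all_masses(self):
        rng = np.random.default_rng(0)
        masses = rng.uniform(1.0, 60.0, size=500)
        stages = classify_stage(masses)
        assert set(stages) <= set(tz.STAGES)
        # round trip: every stage's band contains its masses
        for s, (lo, hi) in tz.STAGE_BANDS.items():
            sel = stages == s
            assert np.all((masses[sel] > lo) | (np.isclose(masses[sel], lo) & (s != "juvenile")))
            assert np.all(masses[sel] <= hi)


class TestFilterRecords:
    def test_worked_example_retains_three_of_six(self, toy_records, caplog):
        with caplog.at_level("INFO"):
            out = filter_records(toy_records)
        assert len(out) == 3
        assert set(out["id"]) == {"A3", "A4", "A5"}
        counts = out.attrs["filter_counts"]
        assert counts == {"juvenile": 1, "old": 1, "pregnant": 1, "retained": 3}
        assert "1 juvenile" in caplog.text and "1 pregnant" in caplog.text

    def test_no_exclusions_is_identity(self, toy_records):
        clean = toy_records[toy_records["stage"].isin(["sub-adult", "adult I", "adult II"])]
        clean = clean[~clean["pregnant"]]
        out = filter_records(clean)
        pd.testing.assert_frame_equal(
            out.reset_index(drop=True), clean.reset_index(drop=True)
        )

    def test_everything_excluded_raises(self, toy_records):
        bad = toy_records[toy_records["stage"].isin(["juvenile", "old"])]
        with pytest.raises(DataError):
            filter_records(bad)


class TestStandardize:
    def test_closed_form_three_points(self):
        assert np.allclose(standardize([1, 2, 3]), [-1, 0, 1])

    def test_idempotent_on_z_scores(self):
        rng = np.random.default_rng(1)
        z = standardize(rng.normal(5, 3, 50))
        assert np.allclose(standardize(z), z, atol=1e-12)

    def test_output_moments(self):
        rng = np.random.default_rng(2)
        z = standardize(rng.uniform(-5, 20, 101))
        assert abs(z.mean()) <= 1e-12
        assert z.std(ddof=1) == pytest.approx(1.0, abs=1e-12)

    def test_constant_input_rejected(self):
        with pytest.raises(DataError):
            standardize([4.0, 4.0, 4.0])


def test_cyear_counts_years_since_study_start():
    assert list(cyear([2013, 2014, 2020])) == [0, 1, 7]
    assert list(cyear([2016, 2018], origin=2013)) == [3, 5]


class TestGammaGLMM:
    def sim(self, n=400, G=8, slope=1.0, sigma=0.5, shape=200.0, seed=0):
        rng = np.random.default_rng(seed)
        gidx = np.repeat(np.arange(G), n // G)
        xs = np.linspace(-1.5, 1.5, G)
        b = rng.normal(0, sigma, G)
        mu = 100.0 + slope * xs[gidx] + b[gidx]
        y = rng.gamma(shape, mu / shape)
        return xs[gidx][:, None], y, gidx

    def test_zero_variance_profile_reproduces_plain_gamma_glm(self):
        import statsmodels.api as sm

        X, y, _ = self.sim(seed=3)
        est = GammaGLMM(force_zero_variance=True).fit(X, y)
        glm = sm.GLM(
            y, sm.add_constant(X), family=sm.families.Gamma(sm.families.links.Identity())
        ).fit()
        assert est.intercept_ == pytest.approx(glm.params[0], abs=1e-4)
        assert est.coef_[0] == pytest.approx(glm.params[1], abs=1e-4)
        assert est.se_[1] == pytest.approx(glm.bse[1], rel=0.05)

    def test_positive_responses_required(self):
        X, y, gidx = self.sim()
        y[0] = -1.0
        with pytest.raises(DataError):
            GammaGLMM().fit(X, y, groups=gidx)

    def test_single_group_suggests_plain_glm(self):
        X, y, _ = self.sim()
        with pytest.raises(FitError, match="plain GLM"):
            GammaGLMM().fit(X, y, groups=np.zeros(len(y)))

    def test_scale_equivariance_of_the_natural_slope(self):
        X, y, gidx = self.sim(seed=5)
        f1 = GammaGLMM().fit(X, y, groups=gidx)
        f2 = GammaGLMM().fit(2.0 * X, y, groups=gidx)
        assert f2.coef_[0] == pytest.approx(f1.coef_[0] / 2.0, rel=1e-9)
        assert f2.se_[1] == pytest.approx(f1.se_[1] / 2.0, rel=1e-9)

    def test_inner_likelihood_trace_is_monotone(self):
        X, y, gidx = self.sim(seed=6)
        est = GammaGLMM().fit(X, y, groups=gidx)
        trace = est.inner_ll_trace_
        assert np.all(np.diff(trace) >= -1e-9 * np.maximum(1.0, np.abs(trace[:-1])))

    def test_slope_recovery_on_generated_records(self):
        cfg = tz.SyntheticConfig(years=(2023,), n_per_site_year=120, seed=17)
        df, _ = glmm_sim_frame(cfg)
        fit = fit_gamma_glmm(df, ModelSpec("length", "ann_min_temp", "site"))
        assert fit.converged
        assert abs(fit.slope_natural - cfg.length_temp_slope) <= 2.5 * fit.slope_se_natural
        # natural and standardized scales are exact reparameterizations
        sd = df["ann_min_temp"].std(ddof=1)
        assert fit.slope_standardized == pytest.approx(fit.slope_natural * sd, rel=1e-9)

    def test_shape_and_random_intercept_estimates_are_sane(self):
        cfg = tz.SyntheticConfig(years=(2023,), n_per_site_year=120, seed=23)
        df, _ = glmm_sim_frame(cfg)
        fit = fit_gamma_glmm(df, ModelSpec("length", "ann_min_temp", "site"))
        assert 100 < fit.gamma_shape_estimate < 900      # truth 300
        assert 0.0 <= fit.random_intercept_sd < 5.0      # truth 0.8 mm

    def test_model_spec_validation(self):
        with pytest.raises(ValueError):
            ModelSpec("weight", "x")
        with pytest.raises(ValueError):
            ModelSpec("length", "site", random_group="site")


class TestSuite:
    def test_battery_sign_pattern_matches_generating_config(self, small_data, small_config):
        sc = site_climate_table(small_data["climate"])
        table = trend_and_effect_suite(
            small_data["records"], small_data["sites"], sc,
            spatial_years=small_config.years[-2:],
        )
        assert {"temporal", "spatial"} == set(table["dataset"])
        row = table.query("dataset == 'spatial' and response == 'length' and predictor == 'ann_min_temp'")
        assert len(row) == 1
        # positive generating slope recovered within 3 SE
        assert abs(row["slope"].iloc[0] - small_config.length_temp_slope) <= 3 * row["se"].iloc[0]

    def test_empty_join_raises(self, small_data):
        sc = site_climate_table(small_data["climate"])
        orphan_sites = small_data["sites"].assign(site=lambda d: d["site"] + "_x")
        with pytest.raises(DataError):
            trend_and_effect_suite(
                small_data["records"], orphan_sites, sc.assign(site=sc["site"] + "_x"),
            )
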