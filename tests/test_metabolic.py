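"""RMR extraction, gradient-descent curve fitting, TNZ limit derivation."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import tnzsize as tz
from tnzsize.errors import FitError, NoTNZError, TraceTooShortError
from tnzsize.metabolic import (
    PolynomialRMRCurve,
    derive_tnz,
    estimate_population_tnz,
    fit_rmr_curve,
    min_window_rmr,
    to_mass_specific,
)
from tnzsize.synthetic import gen_rmr_traces, gen_sites


def brute_force_min_window(readings, w):
    return min(
        np.mean(readings[i:i + w]) for i in range(len(readings) - w + 1)
    )


class TestMinWindow:
    def test_constant_trace_returns_the_constant(self):
        assert min_window_rmr([1.2] * 10) == pytest.approx(1.2)

    def test_disjoint_blocks_pick_the_low_block(self):
        assert min_window_rmr([5, 5, 5, 5, 5, 1, 1, 1, 1, 1], 5) == pytest.approx(1.0)

    def test_too_short_trace_names_the_trace(self):
        with pytest.raises(TraceTooShortError, match="T7"):
            min_window_rmr([1.0, 2.0], 5, trace_id="T7")

    @given(
        st.lists(st.floats(0.0, 100.0), min_size=5, max_size=30),
        st.integers(min_value=1, max_value=5),
    )
    def test_matches_exhaustive_window_enumeration(self, readings, w):
        got = min_window_rmr(readings, w)
        assert got == pytest.approx(brute_force_min_window(np.array(readings), w))


class TestMassSpecific:
    @pytest.mark.parametrize(
        "rmr,mass,expected", [(30.0, 30.0, 1.0), (0.0, 25.0, 0.0), (45.5, 26.0, 1.75)]
    )
    def test_division_by_mass(self, rmr, mass, expected):
        assert to_mass_specific(rmr, mass) == pytest.approx(expected)

    def test_nonpositive_mass_rejected(self):
        with pytest.raises(ValueError):
            to_mass_specific(10.0, 0.0)


class TestCurveFit:
    def test_exact_quadratic_data_recovered(self):
        t = np.array([20, 22, 25, 28, 30, 32, 35, 37.5])
        y = 0.1 * (t - 30) ** 2 + 1.0
        curve = fit_rmr_curve(t, y, degree=2)
        assert curve.sse <= 1e-10
        # 0.1*(T-30)^2 + 1 = 91 - 6 T + 0.1 T^2
        assert np.allclose(curve.coefficients, [91.0, -6.0, 0.1], atol=1e-6)
        assert curve.converged

    def test_gradient_descent_agrees_with_normal_equations(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            t = np.sort(rng.uniform(5, 37.5, size=rng.integers(8, 15)))
            y = rng.uniform(1.0, 4.0, size=len(t))
            curve = fit_rmr_curve(t, y, degree=4)
            # closed-form LS oracle on the same standardized basis
            z = (t - t.mean()) / t.std()
            V = np.vander(z, 5, increasing=True)
            ref = V @ np.linalg.lstsq(V, y, rcond=None)[0]
            assert np.max(np.abs(curve(t) - ref)) <= 1e-6

    def test_single_temperature_is_rank_deficient(self):
        with pytest.raises(FitError):
            fit_rmr_curve([30.0] * 8, [1.0] * 8, degree=2)

    def test_insufficient_distinct_temperatures(self):
        with pytest.raises(FitError, match="distinct"):
            fit_rmr_curve([5, 10, 15, 20], [3, 2, 1.5, 1.2], degree=4)

    def test_estimator_exposes_sklearn_params(self):
        est = PolynomialRMRCurve(degree=3)
        assert est.get_params()["degree"] == 3
        est.set_params(degree=5)
        assert est.degree == 5


class TestDeriveTnz:
    def make_parabola(self, a=0.05, center=30.0, level=1.0, domain=(20.0, 40.0)):
        # a*(T-c)^2 + level as a MetabolicCurve
        from tnzsize.metabolic import MetabolicCurve

        coef = np.array([a * center ** 2 + level, -2 * a * center, a])
        return MetabolicCurve(coef, domain, 0.0, True, 1)

    def test_symmetric_parabola_closed_form_limits(self):
        curve = self.make_parabola()
        est = derive_tnz(curve, slope_threshold=0.02)
        assert est.t_min == pytest.approx(30.0, abs=1e-6)
        assert est.llt == pytest.approx(29.8, abs=1e-6)
        assert est.ult == pytest.approx(30.2, abs=1e-6)
        assert est.tnz_b == pytest.approx(0.4, abs=1e-6)
        assert est.bmr == pytest.approx(1.0, abs=1e-9)

    def test_breadth_is_exactly_ult_minus_llt(self):
        est = derive_tnz(self.make_parabola(a=0.03), slope_threshold=0.05)
        assert est.tnz_b == est.ult - est.llt

    def test_monotone_curve_has_no_tnz(self):
        from tnzsize.metabolic import MetabolicCurve

        rising = MetabolicCurve(np.array([0.0, 1.0, 0.001]), (5.0, 37.5), 0.0, True, 1)
        with pytest.raises(NoTNZError):
            derive_tnz(rising)

    def test_widening_threshold_never_narrows_the_zone(self, noiseless_tnz_config):
        cfg = noiseless_tnz_config
        sites, truth = gen_sites(cfg)
        traces = gen_rmr_traces(sites, cfg, truth)
        one = traces[traces["site"] == "S01"]
        pts = one.groupby(["animal_id", "chamber_temp_C"]).apply(
            lambda g: min_window_rmr(g["o2_ml_per_h"].to_numpy()) / g["mass_g"].iloc[0],
            include_groups=False,
        )
        temps = [k[1] for k in pts.index]
        curve = fit_rmr_curve(temps, pts.to_numpy(), degree=4)
        prev = derive_tnz(curve, slope_threshold=0.005)
        for delta in (0.01, 0.02, 0.03, 0.05, 0.08):
            est = derive_tnz(curve, slope_threshold=delta)
            assert est.ult >= prev.ult - 1e-9
            assert est.llt <= prev.llt + 1e-9
            prev = est

    def test_enormous_threshold_clips_to_the_domain(self):
        est = derive_tnz(self.make_parabola(), slope_threshold=50.0)
        assert est.boundary_clipped
        assert est.llt == 20.0 and est.ult == 40.0

    def test_shift_equivariance_of_limits(self):
        rng = np.random.default_rng(4)
        t = np.array([5, 10, 15, 20, 25, 27.5, 30, 32.5, 35, 37.5])
        y = tz.scholander_rmr(t, 29.0, 31.0, 1.8, -0.12, 0.2) + rng.normal(0, 0.01, t.size)
        c = 7.0
        e1 = derive_tnz(fit_rmr_curve(t, y, degree=4))
        e2 = derive_tnz(fit_rmr_curve(t + c, y, degree=4))
        assert e2.llt - e1.llt == pytest.approx(c, abs=1e-6)
        assert e2.ult - e1.ult == pytest.approx(c, abs=1e-6)
        assert e2.t_min - e1.t_min == pytest.approx(c, abs=1e-6)
        assert e2.tnz_b == pytest.approx(e1.tnz_b, abs=1e-6)
        assert e2.bmr == pytest.approx(e1.bmr, abs=1e-6)


class TestPopulationEstimates:
    def test_single_noiseless_animal_equals_direct_derivation(self, noiseless_tnz_config):
        cfg = noiseless_tnz_config
        sites, truth = gen_sites(cfg)
        traces = gen_rmr_traces(sites, cfg, truth)
        one_animal = traces[traces["animal_id"] == "S01-R01"]
        est_tab = estimate_population_tnz(one_animal)
        temps = sorted(one_animal["chamber_temp_C"].unique())
        pts = [
            min_window_rmr(
                one_animal[one_animal["chamber_temp_C"] == tt]["o2_ml_per_h"].to_numpy()
            ) / one_animal["mass_g"].iloc[0]
            for tt in temps
        ]
        direct = derive_tnz(fit_rmr_curve(temps, pts, degree=4))
        assert est_tab["llt_C"].iloc[0] == pytest.approx(direct.llt, abs=1e-9)
        assert est_tab["ult_C"].iloc[0] == pytest.approx(direct.ult, abs=1e-9)

    def test_duplicating_every_point_leaves_the_estimate_unchanged(self, small_data):
        traces = small_data["traces"]
        one = traces[traces["site"] == "S02"]
        doubled = one.copy()
        doubled["animal_id"] = doubled["animal_id"] + "_copy"
        import pandas as pd

        est1 = estimate_population_tnz(one)
        est2 = estimate_population_tnz(pd.concat([one, doubled], ignore_index=True))
        assert est2["llt_C"].iloc[0] == pytest.approx(est1["llt_C"].iloc[0], abs=1e-7)
        assert est2["ult_C"].iloc[0] == pytest.approx(est1["ult_C"].iloc[0], abs=1e-7)

    def test_site_with_too_few_temperatures_is_skipped(self, caplog, small_data):
        traces = small_data["traces"]
        poor = traces[traces["chamber_temp_C"].isin([30.0, 25.0, 20.0])]
        with caplog.at_level("WARNING"):
            out = estimate_population_tnz(poor)
        assert out.empty
        assert "skipped" in caplog.text
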