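"""Growth factors, the bioenergetic rate, integration and calibration."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import rasim
from rasim.growth import (
    WEIGHT_FLOOR_G,
    default_rate_reference,
    integrate_growth,
    interval_mean_rate_terms,
)
from rasim.params import EnvironmentSchedule, GrowthParams, ScheduleMode, TauLowDenominator


class TestFactors:
    def test_temperature_factor_peaks_at_optimum(self):
        assert rasim.temperature_factor(28.0) == pytest.approx(1.0)
        assert rasim.temperature_factor(32.0) == pytest.approx(0.94479, abs=1e-5)

    def test_temperature_factor_below_optimum_both_normalizations(self):
        p_min = GrowthParams(tau_low_denominator=TauLowDenominator.t_min)
        p_max = GrowthParams(tau_low_denominator=TauLowDenominator.t_max)
        assert rasim.temperature_factor(24.0, p_min) == pytest.approx(0.95961, abs=1e-5)
        assert rasim.temperature_factor(24.0, p_max) == pytest.approx(0.94479, abs=1e-5)

    @given(st.floats(min_value=15.0, max_value=40.0))
    def test_temperature_factor_bounded_and_maximal_at_opt(self, T):
        tau = rasim.temperature_factor(T)
        assert 0.0 < tau <= 1.0
        assert tau <= rasim.temperature_factor(28.0)

    @pytest.mark.parametrize(
        ("T", "expected"), [(15.0, 0.25), (28.0, 0.30383), (32.0, 0.32262)]
    )
    def test_catabolism_coefficient(self, T, expected):
        assert rasim.catabolism_coefficient(T) == pytest.approx(expected, abs=1e-5)

    def test_catabolism_scales_with_k_scale_and_warns_below_t_min(self):
        p = GrowthParams(k_scale=0.5)
        assert rasim.catabolism_coefficient(28.0, p) == pytest.approx(0.30383 / 2, abs=1e-5)
        with pytest.warns(UserWarning, match="t_min"):
            assert rasim.catabolism_coefficient(10.0, p) == pytest.approx(0.125)

    def test_catabolism_strictly_increasing_in_temperature(self):
        grid = np.linspace(15.0, 40.0, 1000)
        vals = [rasim.catabolism_coefficient(t) for t in grid]
        assert np.all(np.diff(vals) > 0)

    @pytest.mark.parametrize(("do", "expected"), [(5.0, 1.0), (4.0, 0.5), (2.9, 0.0), (8.0, 1.0)])
    def test_do_factor_three_stages(self, do, expected):
        assert rasim.do_factor(do) == pytest.approx(expected)

    @pytest.mark.parametrize(
        ("nh3", "expected"), [(0.01, 1.0), (0.025, 1.0), (0.3125, 0.5), (0.6, 0.0), (0.7, 0.0)]
    )
    def test_ammonia_factor_three_stages(self, nh3, expected):
        assert rasim.ammonia_factor(nh3) == pytest.approx(expected)

    def test_do_and_ammonia_factors_monotone_on_dense_grid(self):
        do_grid = np.linspace(0.0, 10.0, 1000)
        deltas = [rasim.do_factor(x) for x in do_grid]
        assert np.all(np.diff(deltas) >= 0) and min(deltas) == 0.0 and max(deltas) == 1.0
        nh3_grid = np.linspace(0.0, 1.0, 1000)
        phis = [rasim.ammonia_factor(x) for x in nh3_grid]
        assert np.all(np.diff(phis) <= 0) and min(phis) == 0.0 and max(phis) == 1.0

    @pytest.mark.parametrize(("h", "expected"), [(12.0, 1.0), (6.0, 0.5), (0.0, 0.0), (18.0, 1.5)])
    def test_photoperiod_factor(self, h, expected):
        assert rasim.photoperiod_factor(h) == pytest.approx(expected)

    def test_photoperiod_out_of_range(self):
        with pytest.raises(ValueError):
            rasim.photoperiod_factor(25.0)


class TestFeedingRatio:
    def test_curve_maximum_at_characteristic_weight(self, defaults):
        w_peak = math.exp(-defaults.feeding.fr_shift)
        assert rasim.feeding_ratio(w_peak) == pytest.approx(17.02)
        # peak really is a maximum
        assert rasim.feeding_ratio(w_peak * 1.5) < 17.02
        assert rasim.feeding_ratio(w_peak / 1.5) < 17.02

    @pytest.mark.parametrize(("W", "expected"), [(3.0, 13.166), (226.25, 1.8745)])
    def test_curve_values(self, W, expected):
        assert rasim.feeding_ratio(W) == pytest.approx(expected, abs=1e-3)

    def test_table_mode_steps(self, defaults):
        feeding = defaults.feeding.model_copy(update={"schedule_mode": ScheduleMode.table2})
        assert rasim.feeding_ratio(70.0, feeding) == pytest.approx(3.75)  # 3.5-4 band
        assert rasim.feeding_ratio(500.0, feeding) == pytest.approx(1.25)  # clamps high
        assert rasim.feeding_ratio(0.01, feeding) == pytest.approx(17.5)  # clamps low

    def test_nonpositive_weight_rejected(self):
        with pytest.raises(ValueError):
            rasim.feeding_ratio(0.0)


class TestDailyGrowthRate:
    def test_tabulated_defaults_give_negative_growth(self):
        # with the literature constants and full ration the catabolism
        # term dominates: the known internal inconsistency the k_scale
        # knob exists to resolve
        p = GrowthParams(f_feed=1.0)
        assert rasim.daily_growth_rate(3.0, 28.0, 8.0, 0.0, 12.0, p) == pytest.approx(
            -0.2462, abs=1e-4
        )

    def test_zero_ration_is_pure_catabolism(self):
        p = GrowthParams(f_feed=0.0)
        got = rasim.daily_growth_rate(10.0, 28.0, 8.0, 0.0, 12.0, p)
        assert got == pytest.approx(-rasim.catabolism_coefficient(28.0) * 10.0**0.81)

    def test_anoxic_water_shuts_feeding_off(self):
        p = GrowthParams(f_feed=1.0)
        got = rasim.daily_growth_rate(10.0, 28.0, 2.0, 0.0, 12.0, p)  # DO < do_min
        assert got == pytest.approx(-rasim.catabolism_coefficient(28.0) * 10.0**0.81)

    def test_unset_feeding_level_rejected(self):
        with pytest.raises(ValueError, match="f_feed"):
            rasim.daily_growth_rate(10.0, 28.0, 8.0, 0.0, 12.0, GrowthParams())

    @given(st.floats(min_value=0.05, max_value=1.0), st.floats(min_value=0.01, max_value=0.95))
    def test_growth_strictly_increasing_in_ration(self, f_hi, frac):
        f_lo = f_hi * frac
        p_hi = GrowthParams(f_feed=f_hi)
        p_lo = GrowthParams(f_feed=f_lo)
        hi = rasim.daily_growth_rate(50.0, 28.0, 8.0, 0.0, 12.0, p_hi)
        lo = rasim.daily_growth_rate(50.0, 28.0, 8.0, 0.0, 12.0, p_lo)
        assert hi > lo


class TestIntegration:
    def test_euler_accumulation_matches_independent_replay(self, calibrated):
        days = 40
        env = EnvironmentSchedule(temperature=28.0, do_ambient=8.0, nh3=0.0)
        traj = integrate_growth(3.0, days, env, calibrated.growth, calibrated.feeding)
        # independent oracle: raw Euler recursion on the same closed form
        g = calibrated.growth
        W = 3.0
        weights = [W]
        for _ in range(days):
            anab = g.anabolism_const * 1.0 * 1.0 * 1.0 * 1.0 * g.h_food * g.f_feed * W**g.m_exp
            catab = g.k_scale * g.k_min * math.exp(g.s_const * (28.0 - g.t_min)) * W**g.n_exp
            W = W + (anab - catab)
            weights.append(W)
        got = [r.weight_g for r in traj.records]
        assert got == pytest.approx(weights, rel=1e-12)
        assert not traj.halted

    def test_zero_day_horizon_is_single_record(self, calibrated):
        traj = integrate_growth(3.0, 0, calibrated.environment, calibrated.growth)
        assert len(traj.records) == 1
        assert traj.records[0].weight_g == 3.0

    def test_weight_floor_halts_integration(self):
        growth = GrowthParams(f_feed=0.0)  # starvation: monotone decline
        traj = integrate_growth(1.0, 100, EnvironmentSchedule(), growth)
        assert traj.halted
        assert len(traj.records) < 101
        assert all(r.weight_g >= WEIGHT_FLOOR_G for r in traj.records)

    def test_records_carry_feed_bookkeeping(self, calibrated):
        traj = integrate_growth(
            3.0, 5, calibrated.environment, calibrated.growth, calibrated.feeding, n_fish=20000
        )
        r0 = traj.records[0]
        assert r0.feed_kg_day == pytest.approx(r0.feeding_ratio_pct * 3.0 * 20000 / 100000)

    @pytest.mark.parametrize(
        ("fr", "W", "n", "expected"), [(2.5, 100.0, 20000, 50.0), (0.0, 50.0, 100, 0.0),
                                       (13.166, 3.0, 20000, 7.8996)]
    )
    def test_daily_feed_mass(self, fr, W, n, expected):
        assert rasim.daily_feed_mass(fr, W, n) == pytest.approx(expected, abs=1e-3)


class TestCalibration:
    def test_grid_contract(self, defaults):
        result = rasim.calibrate_relative_feeding(defaults, refine=True)
        assert len(result.grid) == 101
        assert all(np.isfinite(obj) for _, obj in result.grid)
        assert result.f_star in [f for f, _ in result.grid]
        assert result.objective == min(obj for _, obj in result.grid)

    def test_recovers_planted_feeding_level_exactly(self, defaults):
        # build a reference produced by the model itself at f*=0.42 with
        # the catabolism rescale frozen; the grid must find it exactly
        params = defaults.model_copy(deep=True)
        params.growth.k_scale = 0.25
        intervals = [(5.0, 20.0), (20.0, 50.0), (50.0, 100.0), (100.0, 250.0)]
        A, B, _ = interval_mean_rate_terms(
            [(lo, hi, 0.0) for lo, hi in intervals], (28.0, 8.0, 0.0, 12.0), params.growth
        )
        planted = [(lo, hi, float(0.42 * a - 0.25 * b))
                   for (lo, hi), a, b in zip(intervals, A, B)]
        result = rasim.calibrate_relative_feeding(params, reference=planted, refine=False)
        assert result.f_star == pytest.approx(0.42, abs=1e-12)
        assert result.objective == pytest.approx(0.0, abs=1e-18)

    def test_joint_refinement_beats_fixed_catabolism(self, defaults):
        fixed = rasim.calibrate_relative_feeding(defaults, refine=False)
        joint = rasim.calibrate_relative_feeding(defaults, refine=True)
        assert joint.objective <= fixed.objective
        assert 0.0 < joint.k_scale_star < 1.0

    def test_all_zero_reference_prefers_smallest_rates(self, defaults):
        ref = [(lo, hi, 0.0) for lo, hi, _ in default_rate_reference()]
        result = rasim.calibrate_relative_feeding(defaults, reference=ref, refine=True)
        # f = 0 with the catabolism profiled to zero reproduces a flat
        # schedule exactly, so the degenerate reference is fit perfectly
        assert result.f_star == 0.0
        assert result.objective == pytest.approx(0.0, abs=1e-12)

    def test_empty_reference_rejected(self, defaults):
        with pytest.raises(ValueError, match="non-empty"):
            rasim.calibrate_relative_feeding(defaults, reference=[])

    def test_final_weight_anchor_reproduces_its_own_reference(self, calibrated):
        # the shipped preset's (f, k_scale) must place every grow-out
        # endpoint within a few percent of its anchor value
        sums = rasim.temperature_sweep(
            calibrated, sorted(rasim.FINAL_WEIGHT_REFERENCE_150D), days=150, hourly=False
        )
        for s in sums:
            ref = rasim.FINAL_WEIGHT_REFERENCE_150D[s.temperature_c]
            assert s.final_weight_g == pytest.approx(ref, rel=0.06)
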