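"""Residual canopy transpiration: integration, elevation scenarios, sweeps."""

import numpy as np
import pytest

from gmincanopy.canopy import (
    CanopySpec,
    DiurnalClimate,
    elevate_climate,
    instantaneous_flux,
    integrate_emin_day,
    leaf_area_sweep,
    scenario_sweep,
    sweep_to_frame,
)
from gmincanopy.psychro import saturation_vapor_pressure
from gmincanopy.simulate import ClimateSimParams, climate_from_extremes, simulate_diurnal_climate
from gmincanopy.temperature import ExpFit


def constant_climate(t=25.0, vpd=1.0, hours=12.0, step=300.0, pressure=94.9):
    """Uniform day with exactly the requested VPD at temperature t."""
    n = int(hours * 3600 / step) + 1
    rh = 100.0 * (1.0 - vpd / saturation_vapor_pressure(t))
    return DiurnalClimate.from_temperature_rh(
        np.arange(n) * step, np.full(n, t), np.full(n, rh), pressure=pressure
    )


@pytest.fixture(scope="module")
def hot_day():
    return climate_from_extremes(t_max=32.2, rh_min=29.4)


class TestInstantaneousFlux:
    def test_unit_case(self):
        assert instantaneous_flux(1.0, 1.0, 94.9) == pytest.approx(1 / 94.9)

    def test_zero_vpd(self):
        assert instantaneous_flux(3.0, 0.0, 94.9) == 0.0

    def test_bilinear_scaling(self):
        base = instantaneous_flux(1.0, 1.0, 94.9)
        assert instantaneous_flux(2.0, 3.0, 94.9) == pytest.approx(6 * base)


class TestIntegrateDay:
    def test_constant_climate_closed_form(self):
        """12 h at g=1, VPD=1, P=94.9, R=100 -> 0.820 L m-2 (43200*100*18.015e-6/94.9)."""
        result = integrate_emin_day(1.0, constant_climate(), CanopySpec("x", r_ratio=100.0))
        assert round(result.e_std, 3) == 0.820

    def test_refinement_stability(self, hot_day):
        """Halving the time step moves the daily total by < 0.5%."""
        fine = climate_from_extremes(t_max=32.2, rh_min=29.4, step=150.0)
        spec = CanopySpec("x", r_ratio=100.0)
        coarse_e = integrate_emin_day(2.0, hot_day, spec).e_std
        fine_e = integrate_emin_day(2.0, fine, spec).e_std
        assert abs(fine_e - coarse_e) / coarse_e < 0.005

    def test_tree_total_scales_with_basal_area(self, hot_day):
        spec = CanopySpec("x", r_ratio=100.0, basal_area=0.12)
        result = integrate_emin_day(2.0, hot_day, spec)
        assert result.e_tree == pytest.approx(result.e_std * 0.12)

    def test_exponential_model_uses_temperature(self, hot_day):
        fit = ExpFit(a=0.5, b=0.06, n=24, rss=0.0, t_range=(25.0, 50.0))
        fixed = integrate_emin_day(fit.predict(hot_day.temperature.mean()), hot_day,
                                   CanopySpec("x", r_ratio=100.0))
        varying = integrate_emin_day(fit, hot_day, CanopySpec("x", r_ratio=100.0))
        # hotter (higher-VPD) samples carry more weight under the exponential
        assert varying.e_std > 0 and varying.e_std != pytest.approx(fixed.e_std)

    def test_extrapolation_warns(self, hot_day):
        fit = ExpFit(a=0.5, b=0.06, n=24, rss=0.0, t_range=(20.0, 25.0))
        with pytest.warns(UserWarning, match="extrapolating"):
            integrate_emin_day(fit, hot_day, CanopySpec("x", r_ratio=100.0))

    def test_r_must_be_positive(self):
        with pytest.raises(ValueError):
            CanopySpec("x", r_ratio=0.0)


class TestElevation:
    def test_zero_delta_is_identity(self, hot_day):
        el = elevate_climate(hot_day, 0.0)
        np.testing.assert_array_equal(el.temperature, hot_day.temperature)
        np.testing.assert_array_equal(el.rh, hot_day.rh)

    def test_vapor_pressure_conserved_bitwise(self, hot_day):
        for delta in (0.1, 5.0, 17.8):
            el = elevate_climate(hot_day, delta)
            assert np.array_equal(el.vapor_pressure, hot_day.vapor_pressure)

    def test_max_temperature_arithmetic(self, hot_day):
        assert elevate_climate(hot_day, 7.8).max_temperature == pytest.approx(40.0)

    def test_vpd_strictly_rises_where_unsaturated(self, hot_day):
        el = elevate_climate(hot_day, 3.0)
        unsat = el.rh < 100.0
        assert np.all(el.vpd[unsat] > hot_day.vpd[unsat])

    def test_cooling_can_saturate_with_flag(self):
        cl = simulate_diurnal_climate(ClimateSimParams(t_min=18.0, t_max=30.0,
                                                       vapor_pressure=2.0))
        cooled = elevate_climate(cl, -5.0)
        assert cooled.rh_capped is not None
        assert np.all(cooled.rh <= 100.0)


class TestScenarioSweep:
    def test_scenario_count_to_cap(self, hot_day):
        results = scenario_sweep(2.0, hot_day, CanopySpec("x", r_ratio=100.0))
        assert len(results) == 179  # deltas 0.0 .. 17.8
        assert results[-1].max_temperature == pytest.approx(50.0)

    def test_daily_total_strictly_increases(self, hot_day):
        results = scenario_sweep(2.0, hot_day, CanopySpec("x", r_ratio=100.0), step=0.5)
        e = [r.e_std for r in results]
        assert np.all(np.diff(e) > 0)

    def test_temperature_insensitive_model_still_increases(self, hot_day):
        """Even with b=0 the daily total rises with warming because VPD rises."""
        flat = ExpFit(a=2.0, b=0.0, n=24, rss=0.0, t_range=(20.0, 55.0))
        results = scenario_sweep(flat, hot_day, CanopySpec("x", r_ratio=100.0), step=1.0)
        e = [r.e_std for r in results]
        assert np.all(np.diff(e) > 0)

    def test_sweep_frame_tidy(self, hot_day):
        tidy = sweep_to_frame(
            scenario_sweep(2.0, hot_day, CanopySpec("Fagus", r_ratio=100.0), step=5.0)
        )
        assert set(tidy.columns) >= {"species", "delta_C", "max_T_C", "e_std_L_per_m2"}
        assert (tidy["species"] == "Fagus").all()


class TestLeafAreaSweep:
    def test_linear_through_origin(self, hot_day):
        table = leaf_area_sweep(2.0, hot_day, [0.0, 10.0, 20.0, 200.0])
        loss = table["water_loss_L"].to_numpy()
        assert loss[0] == 0.0
        assert loss[2] == pytest.approx(2 * loss[1])
        assert loss[3] == pytest.approx(20 * loss[1])

    def test_constant_climate_matches_closed_form(self):
        table = leaf_area_sweep(1.0, constant_climate(), [100.0])
        assert round(float(table["water_loss_L"][0]), 3) == 0.820

    def test_negative_area_rejected(self, hot_day):
        with pytest.raises(ValueError):
            leaf_area_sweep(2.0, hot_day, [-1.0])
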