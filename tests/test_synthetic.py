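"""Generator behaviour: shapes, limits, seeds, and agreement with brute-force
integration oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cdsorb import (DehydrationParams, SorptionModelParams, generate_dsc,
                    generate_isotherm, generate_staged_uptake, generate_tg,
                    rh_to_pressure)


class TestIsothermGenerator:
    def test_loading_vanishes_at_zero_humidity(self, sorption_params):
        assert sorption_params.loading(1e-12, 298.0) == pytest.approx(0.0, abs=1e-9)

    def test_colder_isotherm_sits_higher(self, sorption_params, rh_grid):
        """With a positive van't Hoff heat, loadings fall as T rises."""
        cold = generate_isotherm(sorption_params, 283.0, rh_grid)
        hot = generate_isotherm(sorption_params, 313.0, rh_grid)
        assert np.all(cold.loadings > hot.loadings)

    def test_type_iii_convexity(self):
        """Second differences of q(rh) are positive on an even grid."""
        p = SorptionModelParams(q_m=5.0, c0=1e-4, Q_c=22.0, k_gab=0.95,
                                hysteresis_factor=1.0)
        rh = np.linspace(0.1, 0.9, 17)
        with pytest.warns(UserWarning):  # c(283) slightly above 1
            iso = generate_isotherm(p, 283.0, rh)
        assert np.all(np.diff(iso.loadings, 2) > 0)

    def test_default_model_is_type_iii(self, sorption_params, rh_grid):
        iso = generate_isotherm(sorption_params, 298.0, rh_grid)
        assert np.all(np.diff(iso.loadings, 2) > 0)

    def test_divergence_near_unit_activity(self):
        p = SorptionModelParams(k_gab=1.0)
        with pytest.raises(ValueError):
            p.loading(1.0 - 1e-12, 298.0)

    def test_desorption_branch_stored_in_measurement_order(self, sorption_params, rh_grid):
        des = generate_isotherm(sorption_params, 298.0, rh_grid, branch="desorption")
        assert np.all(np.diff(des.pressures) < 0)

    def test_seeded_noise_reproducible(self, sorption_params, rh_grid):
        a = generate_isotherm(sorption_params, 298.0, rh_grid, noise_sd=0.05, seed=7)
        b = generate_isotherm(sorption_params, 298.0, rh_grid, noise_sd=0.05, seed=7)
        c = generate_isotherm(sorption_params, 298.0, rh_grid, noise_sd=0.05, seed=8)
        np.testing.assert_array_equal(a.loadings, b.loadings)
        assert not np.array_equal(a.loadings, c.loadings)


class TestGabInversion:
    @given(rh=st.floats(0.01, 0.95), T=st.floats(280.0, 320.0))
    @settings(max_examples=100, derandomize=True)
    def test_roundtrip(self, rh, T):
        p = SorptionModelParams()
        q = p.loading(rh, T)
        assert p.equilibrium_rh(q, T) == pytest.approx(rh, rel=1e-9)

    def test_zero_loading_maps_to_zero_activity(self):
        assert SorptionModelParams().equilibrium_rh(0.0, 298.0) == 0.0

    def test_loading_above_range_rejected(self):
        p = SorptionModelParams()
        with pytest.raises(ValueError):
            p.equilibrium_rh(1e4, 298.0)


class TestStagedUptake:
    def test_initial_slope_scales_with_rate_constant(self, sorption_params):
        """Doubling k doubles the finite-difference slope of the first step."""
        kw = dict(T=298.0, rh_stages=[0.1, 0.2], dt=0.02, stage_duration=10.0)
        t1 = generate_staged_uptake(8e-5, sorption_params, **kw)
        t2 = generate_staged_uptake(16e-5, sorption_params, **kw)
        s1 = t1.loadings[0] / t1.times[0]
        s2 = t2.loadings[0] / t2.times[0]
        assert s2 / s1 == pytest.approx(2.0, rel=0.02)

    def test_stage_start_slope_matches_rate_law(self, sorption_params):
        """First-step slope approximates k*P_i*(1 - P_{i-1}/P_i)."""
        tr = generate_staged_uptake(1.1e-4, sorption_params, 283.0,
                                    [0.1, 0.2], dt=0.02, stage_duration=60.0)
        slope0 = tr.loadings[0] / tr.times[0]
        assert slope0 == pytest.approx(1.1e-4 * tr.stage_pressures[0], rel=0.01)

    def test_rate_decays_toward_zero_within_stage(self, uptake_trace_283):
        sl = uptake_trace_283.stage_slice(0)
        q = uptake_trace_283.loadings[sl]
        t = uptake_trace_283.times[sl]
        early = (q[10] - q[0]) / (t[10] - t[0])
        late = (q[-1] - q[-11]) / (t[-1] - t[-11])
        assert late < 0.05 * early

    def test_loading_continuous_and_nondecreasing(self, uptake_trace_283):
        assert np.all(np.diff(uptake_trace_283.loadings) >= 0)
        jumps = np.abs(np.diff(uptake_trace_283.loadings))
        assert jumps.max() < 0.05  # no discontinuity at stage boundaries

    def test_stage_pressures_follow_humidity_program(self, uptake_trace_283):
        expected = [rh_to_pressure(rh, 283.0)
                    for rh in np.round(np.arange(0.1, 0.61, 0.1), 10)]
        np.testing.assert_allclose(uptake_trace_283.stage_pressures, expected,
                                   rtol=1e-12)


class TestTgGenerator:
    def test_noiseless_total_mass_loss_matches_water_fraction(self, thermogram_set):
        for tg in thermogram_set:
            loss = (tg.masses[0] - tg.masses[-1]) / tg.masses[0]
            assert loss == pytest.approx(0.12, abs=1e-3)

    def test_alpha_matches_fine_euler_oracle(self, dehydration_params):
        """Closed-form quadrature vs brute-force Euler at 10x smaller step."""
        tg = generate_tg(dehydration_params, 10.0, dt=0.5)
        T = tg.temperatures
        dt_fine = 0.05
        t_f = np.arange(0.0, (T[-1] - T[0]) / (10.0 / 60.0) + 1e-9, dt_fine)
        T_f = T[0] + 10.0 / 60.0 * t_f
        a = np.zeros_like(T_f)
        for i in range(1, T_f.size):
            a[i] = a[i - 1] + dt_fine * dehydration_params.rate_constant(T_f[i - 1]) * (1 - a[i - 1])
        alpha_pkg = dehydration_params.alpha_on_ramp(T, 10.0)
        assert np.max(np.abs(alpha_pkg - np.interp(T, T_f, a))) < 1e-4

    def test_incomplete_ramp_warns(self, dehydration_params):
        with pytest.warns(UserWarning, match="incomplete"):
            generate_tg(dehydration_params, 5.0, T_range=(303.0, 360.0))

    def test_seeded_mass_noise_reproducible(self):
        p = DehydrationParams(noise_sd_mass=0.01)
        a = generate_tg(p, 5.0, seed=3)
        b = generate_tg(p, 5.0, seed=3)
        np.testing.assert_array_equal(a.masses, b.masses)


class TestDscGenerator:
    def test_endotherm_is_negative(self, dsc_set):
        for d in dsc_set:
            assert d.heat_flow.min() < 0
            assert np.abs(d.heat_flow.min()) > np.abs(d.heat_flow.max())

    def test_integral_identity(self, dehydration_params, thermogram_set, dsc_set):
        """With zero baseline and noise, |heat flow| integrates to dH per mol."""
        from cdsorb import CONSTANTS
        d = dsc_set[0]
        mol = dehydration_params.m_wet * dehydration_params.w_true * 1e-3 / CONSTANTS.M_water
        energy_mJ = np.trapezoid(np.abs(d.heat_flow), d.times_s)
        assert energy_mJ / 1e6 / mol == pytest.approx(dehydration_params.dH_true,
                                                      rel=1e-3)

    def test_peak_colocated_with_dtg_peak(self, thermogram_set, dsc_set):
        from cdsorb import dtg_peak
        for tg, d in zip(thermogram_set, dsc_set):
            T_dsc = d.temperatures[np.argmax(np.abs(d.heat_flow))]
            T_dtg, _ = dtg_peak(tg)
            assert abs(T_dsc - T_dtg) < 2.0
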