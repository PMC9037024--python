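"""Initial-rate extraction, stage rate constants and the Arrhenius fit."""

import itertools

import numpy as np
import pytest

from cdsorb import (ArrheniusModel, UptakeTrace, arrhenius_fit,
                    generate_staged_uptake, initial_rate, stage_rate_constants)
from cdsorb.datasets import uptake_rate_constants, uptake_window_rates


def _linear_trace(slopes, n=20, dt=0.5, T=283.0):
    """Piecewise-linear loading trace, one slope per stage."""
    times, loadings = [], []
    q = 0.0
    t = 0.0
    bounds = []
    for s in slopes:
        bounds.append(len(times))
        for _ in range(n):
            t += dt
            q += s * dt
            times.append(t)
            loadings.append(q)
    pressures = 122.8 * np.arange(1, len(slopes) + 1)
    return UptakeTrace(T=T, times=np.array(times), loadings=np.array(loadings),
                       stage_boundaries=np.array(bounds),
                       stage_pressures=pressures)


class TestInitialRate:
    def test_exact_on_linear_segment(self):
        tr = _linear_trace([0.01, 0.02])
        assert initial_rate(tr, 0).rate == pytest.approx(0.01, rel=1e-9)
        assert initial_rate(tr, 1).rate == pytest.approx(0.02, rel=1e-9)

    def test_constant_trace_gives_zero(self):
        tr = _linear_trace([0.0, 0.0])
        assert initial_rate(tr, 0).rate == 0.0

    def test_stage_isolation(self):
        """The fit never mixes samples across a stage boundary."""
        tr = _linear_trace([0.01, 0.5], n=12)
        r = initial_rate(tr, 0, n_points=12)
        assert r.rate == pytest.approx(0.01, rel=1e-9)

    def test_too_few_samples_rejected(self):
        tr = _linear_trace([0.01], n=8)
        with pytest.raises(ValueError):
            initial_rate(tr, 0, n_points=10)

    def test_negative_slope_warned_and_returned(self):
        tr = _linear_trace([0.01])
        obj = UptakeTrace(T=tr.T, times=tr.times, loadings=tr.loadings[::-1].copy(),
                          stage_boundaries=tr.stage_boundaries,
                          stage_pressures=tr.stage_pressures)
        with pytest.warns(UserWarning, match="negative"):
            r = initial_rate(obj, 0)
        assert r.rate < 0

    def test_matches_rate_law_on_synthetic_trace(self, uptake_trace_283):
        """First-stage initial rate vs the closed-form t=0 slope."""
        r = initial_rate(uptake_trace_283, 0)
        analytic = 1.1e-4 * uptake_trace_283.stage_pressures[0]
        assert r.rate == pytest.approx(analytic, rel=0.02)


class TestStageRateConstants:
    def test_equal_slopes_equal_driving_forces_give_equal_k(self):
        tr = _linear_trace([0.01, 0.01, 0.01])
        rates, summary = stage_rate_constants(tr, rh_window=(0.0, 1.0))
        ks = [r.k for r in rates]
        assert max(ks) == pytest.approx(min(ks), rel=1e-9)
        assert summary.k_mean == pytest.approx(ks[0], rel=1e-9)

    def test_window_mean_division_of_reference_rates(self):
        """Window-mean rate / driving force at 283 K gives k = 1.10e-4 —
        which does not coincide with the reference fitted constant."""
        ref = uptake_window_rates()
        row = ref[ref.T_K == 283.0].iloc[0]
        k = row.mean_rate / row.driving_force
        assert k == pytest.approx(1.10e-4, rel=5e-3)
        table_k = uptake_rate_constants().set_index("T_K").k[283.0]
        assert k != pytest.approx(table_k, rel=0.02)

    def test_parameter_recovery_within_five_percent(self, sorption_params):
        tr = generate_staged_uptake(8e-5, sorption_params, 298.0,
                                    np.round(np.arange(0.1, 0.61, 0.1), 10))
        _, summary = stage_rate_constants(tr)
        assert summary.k_mean == pytest.approx(8e-5, rel=0.05)

    def test_empty_window_rejected(self, uptake_trace_283):
        with pytest.raises(ValueError):
            stage_rate_constants(uptake_trace_283, rh_window=(0.95, 0.96))


class TestArrheniusModel:
    def test_reference_constants_reproduce_reported_activation_energy(self):
        ds = uptake_rate_constants()
        fit = ArrheniusModel(ds.T_K, ds.k).fit()
        assert round(fit.activation_energy, 1) == 7.4
        assert fit.pre_exponential == pytest.approx(4.7e-6, rel=0.02)

    def test_reference_log_constants_match_reported_row(self):
        ds = uptake_rate_constants()
        np.testing.assert_allclose(np.round(np.log(ds.k), 2),
                                   [-9.15, -9.30, -9.45])

    def test_flat_rates_give_zero_activation_energy(self):
        fit = arrhenius_fit([2e-5, 2e-5], [283.0, 313.0])
        assert fit.activation_energy == pytest.approx(0.0, abs=1e-12)

    def test_permutation_invariance(self):
        T = [283.0, 298.0, 313.0]
        k = [10.64e-5, 9.12e-5, 7.88e-5]
        fits = [ArrheniusModel([T[i] for i in p], [k[i] for i in p]).fit()
                for p in itertools.permutations(range(3))]
        eas = {round(f.activation_energy, 12) for f in fits}
        assert len(eas) == 1

    def test_nonpositive_rate_rejected(self):
        with pytest.raises(ValueError):
            ArrheniusModel([283.0, 298.0], [1e-5, -1e-5])


class TestSamplingConvergence:
    def test_recovered_activation_energy_converges_with_dt(self, sorption_params):
        """Finer sampling moves the recovered Ea toward the generating value."""
        temps = (283.0, 313.0)
        k_true = {283.0: 1.1e-4, 313.0: 0.9e-4}
        ea_true = ArrheniusModel(list(temps), [k_true[t] for t in temps]).fit().activation_energy
        errors = []
        for dt in (0.2, 0.1, 0.05):
            ks = []
            for T in temps:
                tr = generate_staged_uptake(k_true[T], sorption_params, T,
                                            [0.1, 0.2, 0.3], dt=dt,
                                            stage_duration=60.0)
                _, s = stage_rate_constants(tr, rh_window=(0.0, 1.0))
                ks.append(s.k_mean)
            ea = ArrheniusModel(list(temps), ks).fit().activation_energy
            errors.append(abs(ea - ea_true))
        assert errors[2] < errors[0]
        assert errors[2] < errors[1] * 1.5  # allow mild non-monotonicity mid-grid
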