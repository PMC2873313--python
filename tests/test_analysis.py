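"""Half-times, significance curves, transport speeds and variability."""

import numpy as np
import pytest

from auxinflow import (Geometry, ModelParameters, ensemble, integrate,
                       steady_state)
from auxinflow import layout
from auxinflow.analysis import (SteadyStateError, estimate_steady_level,
                                first_crossing, half_time,
                                half_time_asymptotic, noise_scaling_check,
                                se_difference, transport_speed,
                                variability_summary)
from auxinflow.stochastic import EnsembleResult


class TestCrossing:
    def test_linear_interpolation_is_exact_for_lines(self):
        t = np.linspace(0, 10, 11)
        assert first_crossing(t, 2.0 * t, 7.0, rising=True) == \
            pytest.approx(3.5)
        assert first_crossing(t, 20.0 - 2.0 * t, 7.0, rising=False) == \
            pytest.approx(6.5)

    def test_never_crossed_raises(self):
        t = np.linspace(0, 10, 11)
        with pytest.raises(SteadyStateError):
            first_crossing(t, 0.1 * t, 5.0, rising=True)


class TestSteadyLevel:
    def test_ramp_has_no_plateau(self):
        t = np.linspace(0, 1, 200)
        with pytest.raises(SteadyStateError):
            estimate_steady_level(t, t.copy())

    def test_all_zero_record(self):
        t = np.linspace(0, 1, 200)
        assert estimate_steady_level(t, np.zeros_like(t)) == 0.0

    def test_saturating_record(self):
        t = np.linspace(0, 10, 500)
        v = 1.0 - np.exp(-2.0 * t)
        assert estimate_steady_level(t, v) == pytest.approx(1.0, abs=1e-3)


class TestHalfTime:
    def test_invariant_to_initial_load(self):
        g = Geometry(N=5)
        t_end = 160000.0
        times = []
        for C in (1000, 10000):
            sol = integrate(ModelParameters(geometry=g, C=C), t_end=t_end)
            times.append(half_time(sol, "source").crossing_time_min)
        assert times[0] == pytest.approx(times[1], abs=1e-6)

    def test_invariant_to_grid_refinement(self, params):
        t_end = 150000.0
        a = integrate(params, t_end=t_end, n_grid=2000)
        b = integrate(params, t_end=t_end, n_grid=6000)
        assert half_time(a, "sink").crossing_time_min == \
            pytest.approx(half_time(b, "sink").crossing_time_min, abs=0.02)

    def test_half_level_is_midpoint_of_initial_and_steady(self, ode_long,
                                                          params):
        res = half_time(ode_long, "source")
        S0 = params.initial_source_concentration
        assert res.half_level == pytest.approx(
            0.5 * (S0 + res.steady_level), rel=1e-12)
        assert 0.0 < res.crossing_time_s < ode_long.times[-1]

    def test_asymptotic_source_and_sink_agree(self, params):
        s = half_time_asymptotic(params, "source")
        f = half_time_asymptotic(params, "sink")
        assert s.crossing_time_s == f.crossing_time_s
        assert s.half_level == f.half_level


class TestSeDifference:
    def _fake_ensemble(self, sol, params, sd_value):
        areas = layout.compartment_areas(params.geometry)
        counts = sol.at(sol.times) * areas[None, :]
        sd = np.full_like(counts, sd_value)
        agg = np.zeros((counts.shape[0], 4))
        return EnsembleResult(times=sol.times, mean=counts, sd=sd,
                              type_mean=agg, type_sd=agg, n_runs=100,
                              base_seed=0, N=params.geometry.N)

    def test_deterministic_against_itself_is_zero(self, params):
        sol = integrate(params, t_end=2000.0, n_grid=100)
        ens = self._fake_ensemble(sol, params, sd_value=1.0)
        curve = se_difference(ens, sol, "sink", params)
        assert np.allclose(curve.z, 0.0, atol=1e-7)
        assert not curve.significant.any()

    def test_zero_se_is_masked(self, params):
        sol = integrate(params, t_end=2000.0, n_grid=100)
        ens = self._fake_ensemble(sol, params, sd_value=0.0)
        curve = se_difference(ens, sol, "sink", params)
        assert np.isnan(curve.z).all()


class TestTransportSpeed:
    def test_constant_arrivals_give_exact_speed(self):
        v = transport_speed(np.full(10, 250.0), L=2.0105e-3)
        assert v.speed_m_per_s == pytest.approx(2.0105e-3 / 250.0)
        assert v.sd_speed_m_per_s == 0.0

    def test_requires_two_finite_arrivals(self):
        with pytest.raises(ValueError):
            transport_speed(np.array([np.inf, 100.0]), L=1.0)


class TestVariability:
    def test_empty_system_has_zero_variability(self, params_small):
        p = ModelParameters(geometry=params_small.geometry, C=0)
        ens = ensemble(p, n_runs=3, t_end=100.0, dt_record=10.0, base_seed=0)
        summ = variability_summary(ens, p)
        assert all(v == 0.0 for v in summ.mean.values())

    def test_agar_blocks_fluctuate_most(self, params_small):
        """Relative concentration noise concentrates in the agar blocks,
        whose occupancy makes an order-one excursion; the thin stem
        compartments carry far smaller relative fluctuations."""
        p = ModelParameters(geometry=Geometry(N=5), C=3000)
        ens = ensemble(p, n_runs=60, t_end=40000.0, dt_record=500.0,
                       base_seed=11)
        m = variability_summary(ens, p).mean
        assert m["source"] > 3.0 * m["cytoplasm"]
        assert m["sink"] > 3.0 * m["cytoplasm"]
        assert m["cytoplasm"] > m["apoplast"] > 0.0

    def test_identical_loads_show_no_systematic_reduction(self):
        p = ModelParameters(geometry=Geometry(N=4), C=2000)
        e1 = ensemble(p, n_runs=60, t_end=20000.0, dt_record=500.0,
                      base_seed=1)
        e2 = ensemble(p, n_runs=60, t_end=20000.0, dt_record=500.0,
                      base_seed=2)
        out = noise_scaling_check(e1, e2, p, p)
        assert out["theoretical_percent"] == pytest.approx(0.0)
        assert abs(out["observed_percent"]) < 15.0

    def test_mismatched_grids_rejected(self):
        p = ModelParameters(geometry=Geometry(N=4), C=100)
        e1 = ensemble(p, n_runs=3, t_end=100.0, dt_record=10.0, base_seed=0)
        e2 = ensemble(p, n_runs=3, t_end=100.0, dt_record=25.0, base_seed=0)
        with pytest.raises(ValueError):
            noise_scaling_check(e1, e2, p, p)
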