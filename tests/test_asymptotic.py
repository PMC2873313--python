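"""Continuum-limit formulas and their agreement with the full ODE system."""

import numpy as np
import pytest

from auxinflow import (Geometry, ModelParameters, Physiology,
                       M_PER_S_TO_CM_PER_H, agar_half_time,
                       composite_solution, dimensionless_parameters,
                       early_time_sink, early_time_sink_molecules,
                       effective_velocity, front_arrival_time, integrate,
                       long_time_agar, regime_timescales, transfer_rate)
from auxinflow import layout


class TestDimensionlessParameters:
    def test_epsilon_for_reference_geometry(self, params):
        dp = dimensionless_parameters(params)
        assert dp.epsilon == pytest.approx(0.05, rel=1e-3)
        assert dp.Ls_bar == pytest.approx(params.geometry.L_s /
                                          params.geometry.L)
        assert 0.5 < dp.Ls_bar < 2.0  # agar blocks comparable to the tissue

    def test_epsilon_vanishes_with_cell_count(self):
        eps = [dimensionless_parameters(
            ModelParameters(geometry=Geometry(N=N), C=1)).epsilon
            for N in (10, 40, 160)]
        assert eps[0] > eps[1] > eps[2]
        assert eps[2] < 0.01

    def test_rescaled_membrane_groups_are_order_one(self, params):
        dp = dimensionless_parameters(params)
        # the raw membrane ratios are O(epsilon); rescaled they are O(1)
        assert dp.uptake_hat < 0.1 and dp.backflux_hat < 0.1
        assert 0.1 < dp.uptake_tilde < 10.0
        assert 0.1 < dp.backflux_tilde < 10.0


class TestEffectiveVelocity:
    def test_reference_value(self, params):
        v = effective_velocity(params) * M_PER_S_TO_CM_PER_H
        assert v == pytest.approx(2.01731, rel=1e-4)

    def test_monotone_in_pin_permeability(self, params):
        weaker = ModelParameters(
            geometry=params.geometry,
            physiology=Physiology(P_PIN=0.5 * params.physiology.P_PIN),
            C=params.C)
        assert 0.0 < effective_velocity(weaker) < effective_velocity(params)

    def test_vanishes_without_carriers(self, params):
        p0 = ModelParameters(geometry=params.geometry,
                             physiology=Physiology(P_PIN=0.0), C=params.C)
        assert effective_velocity(p0) == 0.0

    def test_independent_of_initial_load(self, params):
        other = ModelParameters(geometry=params.geometry,
                                physiology=params.physiology, C=10 * params.C)
        assert effective_velocity(other) == effective_velocity(params)

    def test_front_matches_numerical_bulk_arrival(self, params, ode_long):
        """The numerical sink half-time lags the source half-time by roughly
        the front traversal time L/v_eff."""
        from auxinflow.analysis import half_time
        lag = half_time(ode_long, "sink").crossing_time_s - \
            half_time(ode_long, "source").crossing_time_s
        assert lag == pytest.approx(front_arrival_time(params), rel=0.25)


class TestEarlyTimeSink:
    def test_zero_before_front_arrives(self, params):
        assert early_time_sink(0.0, params) == 0.0
        assert early_time_sink(0.9 * front_arrival_time(params), params) == 0.0

    def test_nondecreasing(self, params):
        ts = np.linspace(0, 1200, 60)
        vals = [early_time_sink(t, params) for t in ts]
        assert (np.diff(vals) >= 0).all()

    def test_reference_molecule_count(self, params):
        # linear filling at the undepleted-source rate behind the front
        assert early_time_sink_molecules(723.78, params) == \
            pytest.approx(246.27, abs=0.5)

    def test_tracks_full_ode_after_front(self, params):
        sol = integrate(params, t_end=1500.0, n_grid=600)
        N = params.geometry.N
        area = layout.compartment_areas(params.geometry)[layout.idx_sink(N)]
        t = 1200.0
        ode_count = sol.at(t)[layout.idx_sink(N)] * area
        assert early_time_sink_molecules(t, params) == \
            pytest.approx(ode_count, rel=0.25)


class TestLongTimeAgar:
    def test_source_sink_half_times_coincide(self, params):
        t_half = agar_half_time(params)
        S, F = long_time_agar(t_half, params)
        S0 = params.initial_source_concentration
        assert S == pytest.approx(0.5 * S0, rel=1e-12)
        assert F == pytest.approx(0.5 * S0, rel=1e-12)
        assert t_half / 60.0 == pytest.approx(206.215, abs=0.01)

    def test_conservation_between_blocks(self, params):
        S0 = params.initial_source_concentration
        for t in (0.0, 5000.0, 50000.0):
            S, F = long_time_agar(t, params)
            assert S + F == pytest.approx(S0, rel=1e-12)
            assert S >= 0 and F >= 0

    def test_half_time_scales_with_agar_length_as_in_full_ode(self, params):
        """Doubling L_s slows both the diffusive exchange (q = 2D/L_s) and
        the per-block dilution; the closed form must track the full solve."""
        from auxinflow.analysis import half_time
        big = ModelParameters(geometry=Geometry(N=20, L_s=4e-3),
                              physiology=params.physiology, C=params.C)
        predicted = agar_half_time(big)
        sol = integrate(big, t_end=9.0 / transfer_rate(big), n_grid=4000)
        measured = half_time(sol, "source").crossing_time_s
        assert measured == pytest.approx(predicted, rel=0.01)
        assert predicted > 2.0 * agar_half_time(params)


class TestCompositeSolution:
    def test_zero_ahead_of_front(self, params):
        t = 100.0
        x_front = effective_velocity(params) * t / params.geometry.L
        assert composite_solution(min(1.0, 2 * x_front), t, params) == 0.0

    def test_out_of_range_rejected(self, params):
        with pytest.raises(ValueError):
            composite_solution(1.5, 10.0, params)

    def test_uniform_profile_behind_front_at_long_times(self, params):
        t = 20000.0  # front long gone; long-scale regime
        vals = [composite_solution(x, t, params) for x in (0.1, 0.5, 0.9)]
        assert np.ptp(vals) == 0.0

    @pytest.mark.parametrize("compartment", ["cytoplasm", "apoplast"])
    def test_error_against_ode_shrinks_with_epsilon(self, compartment):
        """With the front at x = 0.6, the worst relative error over the
        region well behind it shrinks as the cell count grows at fixed
        tissue length (apoplast thickness scaled with epsilon**2, the
        regime in which the leading-order front speed applies)."""
        errors = []
        for N in (20, 100):
            lam_over_l = 0.005 * (20.0 / N) ** 2
            l = 2e-3 / (N + (N + 1) * lam_over_l)
            geom = Geometry(N=N, l=l, lambda_=lam_over_l * l)
            p = ModelParameters(geometry=geom, C=12044)
            t = 0.6 * geom.L / effective_velocity(p)
            sol = integrate(p, t_end=t, n_grid=400)
            y = sol.at(t)
            errs = []
            for i in range(1, N + 1):
                x = i * (geom.l + geom.lambda_) / geom.L
                if not 0.05 <= x <= 0.45:
                    continue
                idx = layout.idx_cytoplasm(i, N) if compartment == "cytoplasm" \
                    else layout.idx_apoplast(i, N)
                pred = composite_solution(x, t, p, compartment=compartment)
                errs.append(abs(pred - y[idx]) / y[idx])
            errors.append(max(errs))
        assert errors[1] < errors[0]
        assert errors[1] < 0.05


class TestRegimeTimescales:
    def test_two_disparate_scales(self, params):
        ts = regime_timescales(params)
        assert ts["transport_s"] < 600.0
        assert ts["diffusive_s"] > 10000.0
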