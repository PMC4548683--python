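"""Column geometry, forward transport, analytic oracles, mass balance."""

import math
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mnasim import (
    EQUILIBRIUM,
    BreakthroughCurve,
    ColumnSpec,
    InletSchedule,
    Numerics,
    TransportParams,
    analytic_ade,
    analytic_btc,
    mass_balance,
    pore_volume,
    residence_time,
    retardation_factor,
    simulate_column,
    steady_state_ratio,
    temporal_moments,
)
from mnasim.exceptions import InvalidSpecError


class TestGeometry:
    @pytest.mark.parametrize(
        "porosity, expected_cm3", [(0.296, 697), (0.289, 681)]
    )
    def test_pore_volume_matches_measured_totals(self, porosity, expected_cm3):
        spec = ColumnSpec(0.30, 0.10, porosity, 1850.0, 1.44e-4)
        assert round(pore_volume(spec) * 1e6) == expected_cm3

    def test_degenerate_porosity_rejected(self):
        with pytest.raises(InvalidSpecError):
            ColumnSpec(0.30, 0.10, 0.0, 1850.0, 1.44e-4)
        with pytest.raises(InvalidSpecError):
            ColumnSpec(-0.30, 0.10, 0.3, 1850.0, 1.44e-4)

    @pytest.mark.parametrize("porosity, expected_d", [(0.296, 4.84), (0.289, 4.73)])
    def test_residence_time_at_reduced_flow(self, porosity, expected_d):
        # 0.1 mL/min through the measured pore volume
        spec = ColumnSpec(0.30, 0.10, porosity, 1850.0, 1.44e-4)
        assert residence_time(spec) == pytest.approx(expected_d, abs=0.005)

    def test_residence_time_halves_when_flow_doubles(self, spec1):
        doubled = replace(spec1, flow_rate=2 * spec1.flow_rate)
        assert residence_time(doubled) == pytest.approx(residence_time(spec1) / 2)

    @settings(max_examples=25, deadline=None)
    @given(scale=st.floats(0.2, 5.0))
    def test_pore_volume_scales_linearly_with_length(self, scale):
        base = ColumnSpec(0.30, 0.10, 0.296, 1850.0, 1.44e-4)
        stretched = replace(base, length=base.length * scale)
        assert pore_volume(stretched) == pytest.approx(scale * pore_volume(base))


class TestSteadyStateRatio:
    def test_limits(self):
        assert steady_state_ratio(0.0, 4.84) == 1.0
        assert steady_state_ratio(math.inf, 4.84) == 0.0

    def test_calibrated_value_reproduces_plateau_difference(self, spec1):
        ratio = steady_state_ratio(0.0045, residence_time(spec1))
        assert ratio == pytest.approx(0.9785, abs=5e-4)
        assert round(31.36 * (1 - ratio), 2) == 0.68

    @settings(max_examples=25, deadline=None)
    @given(
        k1=st.floats(0.0, 1.0),
        dk=st.floats(0.0, 1.0),
        t_res=st.floats(0.1, 50.0),
    )
    def test_bounded_and_monotone_in_decay(self, k1, dk, t_res):
        r1 = steady_state_ratio(k1, t_res)
        r2 = steady_state_ratio(k1 + dk, t_res)
        assert 0.0 < r2 <= r1 <= 1.0


class TestInletSchedule:
    def test_segments_must_be_contiguous_from_zero(self):
        with pytest.raises(InvalidSpecError):
            InletSchedule(((1.0, 2.0, 5.0),))
        with pytest.raises(InvalidSpecError):
            InletSchedule(((0.0, 2.0, 5.0), (3.0, 4.0, 5.0)))
        with pytest.raises(InvalidSpecError):
            InletSchedule(((0.0, 2.0, -1.0),))

    def test_concentration_and_integral(self):
        sched = InletSchedule(((0.0, 2.0, 10.0), (2.0, 5.0, 4.0)))
        assert sched.concentration(1.0) == 10.0
        assert sched.concentration(3.0) == 4.0
        assert sched.concentration(7.0) == 0.0  # beyond the schedule: pulse semantics
        assert sched.integral(0.0, 5.0) == pytest.approx(2 * 10 + 3 * 4)
        assert sched.mean(1.0, 3.0) == pytest.approx((10 + 4) / 2)


class TestForwardModel:
    def test_conservative_step_reaches_inlet_plateau(self, spec1):
        params = TransportParams.for_column(spec1, dispersivity=0.005)
        run = simulate_column(
            spec1, params, InletSchedule.constant(3.0), t_end=25.0,
            numerics=Numerics(nx=100, save_states=False),
        )
        assert run.effluent[-1] == pytest.approx(3.0, rel=1e-6)

    def test_steady_effluent_matches_plug_flow_decay_law(self, spec1):
        params = TransportParams.for_column(
            spec1, dispersivity=0.005, sorption_coeff=6.8e-5, decay=0.0045
        )
        run = simulate_column(
            spec1, params, InletSchedule.constant(31.36), t_end=60.0,
            numerics=Numerics(nx=100, save_states=False),
        )
        expected = 31.36 * steady_state_ratio(0.0045, residence_time(spec1))
        assert run.effluent[-1] == pytest.approx(expected, rel=2e-3)

    def test_effluent_agrees_with_flux_averaged_analytic_solution(self, spec1):
        """Numerical BTC vs closed form, < 1 % relative L2 at nx = 400."""
        params = TransportParams.for_column(
            spec1, dispersivity=0.005, sorption_coeff=6.8e-5, decay=0.0045
        )
        times = np.linspace(0.5, 25.0, 50)
        run = simulate_column(
            spec1, params, InletSchedule.constant(31.36), sample_times=times,
            numerics=Numerics(nx=400, save_states=False),
        )
        oracle = analytic_ade(
            spec1.length, times, params, 31.36,
            retardation=retardation_factor(spec1, params), concentration="flux",
        )
        l2 = np.linalg.norm(run.btc.concentrations - oracle) / np.linalg.norm(oracle)
        assert l2 < 0.01

    def test_btc_pointwise_non_increasing_in_decay(self, spec1, sample_times):
        curves = []
        for k in (0.0, 0.0045, 0.02):
            params = TransportParams.for_column(
                spec1, dispersivity=0.005, sorption_coeff=6.8e-5,
                sorption_rate=0.1, decay=k,
            )
            run = simulate_column(
                spec1, params, InletSchedule.constant(31.36),
                sample_times=sample_times, numerics=Numerics(nx=100, save_states=False),
            )
            curves.append(run.btc.concentrations)
        assert np.all(curves[0] >= curves[1] - 1e-12)
        assert np.all(curves[1] >= curves[2] - 1e-12)

    def test_mean_arrival_non_decreasing_in_sorption(self, spec1):
        inlet = InletSchedule.constant(31.36)
        times = np.linspace(0.25, 40.0, 160)
        arrivals = []
        for kd in (0.0, 3.4e-5, 6.8e-5):
            params = TransportParams.for_column(
                spec1, dispersivity=0.005, sorption_coeff=kd
            )
            run = simulate_column(
                spec1, params, inlet, sample_times=times,
                numerics=Numerics(nx=100, save_states=False),
            )
            arrivals.append(temporal_moments(run.btc, inlet).mean_arrival)
        assert arrivals[0] <= arrivals[1] <= arrivals[2]

    def test_grid_convergence_under_refinement(self, spec1, sample_times):
        params = TransportParams.for_column(
            spec1, dispersivity=0.005, sorption_coeff=6.8e-5,
            sorption_rate=0.1, decay=0.0045,
        )
        runs = [
            simulate_column(
                spec1, params, InletSchedule.constant(31.36),
                sample_times=sample_times,
                numerics=Numerics(nx=nx, courant=c, save_states=False),
            )
            for nx, c in ((100, 0.5), (200, 0.25))
        ]
        change = np.abs(runs[0].btc.concentrations - runs[1].btc.concentrations).max()
        assert change / 31.36 < 0.005

    def test_no_spurious_negative_concentrations(self, spec1):
        params = TransportParams.for_column(spec1, dispersivity=0.005, sorption_coeff=6.8e-5)
        run = simulate_column(
            spec1, params, InletSchedule.constant(31.36), t_end=25.0,
            numerics=Numerics(nx=100),
        )
        floor = -1e-9 * 31.36
        assert run.effluent.min() >= floor
        assert min(st.aqueous.min() for st in run.states) >= floor

    def test_equilibrium_sentinel_is_fast_kinetics_limit(self, spec1, sample_times):
        inlet = InletSchedule.constant(31.36)
        eq = TransportParams.for_column(spec1, dispersivity=0.005, sorption_coeff=6.8e-5)
        fast = replace(eq, sorption_rate=200.0)
        run_eq = simulate_column(
            spec1, eq, inlet, sample_times=sample_times,
            numerics=Numerics(nx=100, save_states=False),
        )
        run_fast = simulate_column(
            spec1, fast, inlet, sample_times=sample_times,
            numerics=Numerics(nx=100, save_states=False),
        )
        diff = np.abs(run_eq.btc.concentrations - run_fast.btc.concentrations).max()
        assert diff / 31.36 < 0.02


class TestAnalyticSolution:
    def test_initial_and_long_time_limits(self, spec1):
        params = TransportParams.for_column(spec1, dispersivity=0.005)
        assert analytic_ade(0.1, 0.0, params, 5.0) == 0.0
        assert analytic_ade(0.3, 1e5, params, 5.0) == pytest.approx(5.0, rel=1e-9)

    def test_domain_errors(self, spec1):
        params = TransportParams.for_column(spec1, dispersivity=0.005)
        with pytest.raises(InvalidSpecError):
            analytic_ade(-0.1, 1.0, params, 5.0)
        with pytest.raises(InvalidSpecError):
            analytic_ade(0.1, -1.0, params, 5.0)
        kinetic = replace(params, sorption_rate=0.1, sorption_coeff=1e-5)
        with pytest.raises(InvalidSpecError):
            analytic_ade(0.1, 1.0, kinetic, 5.0)

    @settings(max_examples=25, deadline=None)
    @given(
        x=st.floats(0.0, 0.3),
        t=st.floats(0.0, 60.0),
        k=st.floats(0.0, 0.1),
    )
    def test_bounded_by_inlet_concentration(self, spec1, x, t, k):
        params = TransportParams.for_column(spec1, dispersivity=0.005, decay=k)
        for mode in ("resident", "flux"):
            c = analytic_ade(x, t, params, 31.36, concentration=mode)
            assert 0.0 <= c <= 31.36

    def test_step_superposition_returns_to_baseline(self, spec1):
        params = TransportParams.for_column(spec1, dispersivity=0.005)
        inlet = InletSchedule.pulse(3.0, 14.5)
        times = np.linspace(0.5, 60.0, 60)
        btc = analytic_btc(spec1.length, times, params, inlet)
        assert btc.max() == pytest.approx(3.0, rel=1e-4)
        assert btc[-1] < 1e-6


class TestMassBalance:
    def _run(self, spec, params, inlet, t_end=25.0):
        return simulate_column(
            spec, params, inlet, t_end=t_end, numerics=Numerics(nx=100)
        )

    def test_closure_with_sorption_and_decay(self, spec1):
        params = TransportParams.for_column(
            spec1, dispersivity=0.005, sorption_coeff=6.8e-5,
            sorption_rate=0.1, decay=0.0045,
        )
        inlet = InletSchedule.constant(31.36)
        run = self._run(spec1, params, inlet)
        mb = mass_balance(run.states, run.btc, inlet, spec1, params)
        assert mb.closure_error < 1e-3
        assert mb.degraded > 0

    def test_conservative_run_has_zero_degradation(self, spec1):
        params = TransportParams.for_column(spec1, dispersivity=0.005)
        inlet = InletSchedule.constant(3.0)
        run = self._run(spec1, params, inlet)
        mb = mass_balance(run.states, run.btc, inlet, spec1, params)
        assert mb.degraded == 0.0
        assert mb.closure_error < 1e-3

    def test_zero_inlet_run_is_identically_zero(self, spec1):
        params = TransportParams.for_column(spec1, dispersivity=0.005)
        inlet = InletSchedule.constant(0.0)
        run = self._run(spec1, params, inlet)
        mb = mass_balance(run.states, run.btc, inlet, spec1, params)
        assert mb.mass_in == mb.mass_out == mb.degraded == 0.0
        assert mb.aqueous_stored == mb.sorbed_stored == 0.0

    def test_inconsistent_grids_rejected(self, spec1):
        params = TransportParams.for_column(spec1, dispersivity=0.005)
        inlet = InletSchedule.constant(3.0)
        import dataclasses

        run = self._run(spec1, params, inlet, t_end=5.0)
        states = run.states
        broken = dataclasses.replace(states[-1], aqueous=states[-1].aqueous[:-10])
        with pytest.raises(InvalidSpecError):
            mass_balance([states[0], broken], run.btc, inlet, spec1, params)


class TestBreakthroughCurve:
    def test_validation(self, spec1):
        with pytest.raises(InvalidSpecError):
            BreakthroughCurve(np.array([1.0, 1.0]), np.array([0.1, 0.1]), np.array([1.0, 2.0]))
        with pytest.raises(InvalidSpecError):
            BreakthroughCurve(np.array([1.0, 2.0]), np.array([0.1, 0.2]), np.array([-1.0, 2.0]))

    def test_pore_volume_axis(self, spec1):
        btc = BreakthroughCurve.from_times([1.0, 25.0], [0.1, 30.0], spec1)
        assert btc.pore_volumes[-1] == pytest.approx(
            25.0 * spec1.flow_rate / spec1.pore_volume
        )

    def test_window_selection(self, spec1, sample_times):
        btc = BreakthroughCurve.from_times(sample_times, np.ones(13), spec1)
        win = btc.window(4.0, 5.2)
        assert len(win) == 3  # the 21, 23 and 25 d samples
        assert win.pore_volumes.min() >= 4.0
        with pytest.raises(InvalidSpecError):
            btc.window(9.0, 10.0)
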