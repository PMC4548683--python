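"""Steady flow solve, plume transport laws, metrics, well comparison."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mnasim import (
    PlumeState,
    SiteModel,
    WellRecord,
    compare_wells,
    plume_metrics,
    simulate_plume,
    solve_steady_flow,
)
from mnasim.exceptions import InvalidSpecError
from mnasim.site import total_mass
from mnasim.synthetic import (
    DEFAULT_ANCHORS,
    generate_site,
    generate_well_observations,
)


def small_site(**kw):
    defaults = dict(nx=20, ny=10, nlayers=2, head_west=10.0, head_east=9.0)
    defaults.update(kw)
    return SiteModel.uniform(**defaults)


class TestFlow:
    def test_homogeneous_two_face_heads_are_exactly_linear(self):
        flow = solve_steady_flow(small_site())
        expected = np.linspace(10.0, 9.0, 20)
        assert np.abs(flow.heads - expected[None, None, :]).max() < 1e-10
        assert flow.residual_norm < 1e-10

    def test_doubling_conductivity_doubles_fluxes_not_heads(self):
        f1 = solve_steady_flow(small_site())
        f2 = solve_steady_flow(small_site(conductivity=2 * 0.1944))
        assert np.abs(f2.heads - f1.heads).max() < 1e-10
        assert f2.qx[0, 0, 5] == pytest.approx(2 * f1.qx[0, 0, 5])

    def test_heterogeneous_field_is_discretely_divergence_free(self):
        site = small_site(nx=15, ny=12, nlayers=3)
        rng = np.random.default_rng(1)
        site.conductivity = site.conductivity * np.exp(
            rng.standard_normal(site.conductivity.shape)
        )
        flow = solve_steady_flow(site)
        assert flow.residual_norm < 1e-8

    def test_missing_constant_head_cells_rejected(self):
        with pytest.raises(InvalidSpecError):
            SiteModel(
                nx=10, ny=10, nlayers=2, dx=1.0, dy=1.0,
                layer_thickness=np.full(2, 2.0),
                conductivity=np.full((2, 10, 10), 0.1),
                porosity=np.full((2, 10, 10), 0.3),
                fixed_head=np.zeros((2, 10, 10), dtype=bool),
                fixed_head_values=np.zeros((2, 10, 10)),
            )


class TestTransport:
    def test_stagnant_conservative_plume_is_unchanged(self):
        site = small_site(head_east=10.0)  # equal heads: no flow
        flow = solve_steady_flow(site)
        c0 = np.zeros((2, 10, 20))
        c0[0, 5, 5] = 42.0
        states = simulate_plume(
            flow, PlumeState(c0, 0.0), retardation=1.0, decay=0.0,
            times=[1.0, 365.0, 1825.0],
        )
        for st_ in states:
            # heads from the linear solve carry O(1e-13) noise, so the
            # advective fluxes are not exactly zero
            np.testing.assert_allclose(st_.concentration, c0, atol=1e-9)

    def test_total_mass_follows_retarded_decay_law(self):
        site = small_site(head_east=10.0)
        flow = solve_steady_flow(site)
        c0 = np.zeros((2, 10, 20))
        c0[0, 5, 5] = 42.0
        c0[1, 3, 8] = 10.0
        retardation, decay = 1.425, 0.0045
        init = PlumeState(c0, 0.0, retardation)
        states = simulate_plume(
            flow, init, retardation=retardation, decay=decay,
            times=[1.0, 183.0, 365.0, 730.0, 1825.0],
        )
        m0 = total_mass(init, site)
        for st_ in states:
            expected = m0 * math.exp(-decay * st_.time / retardation)
            assert total_mass(st_, site) == pytest.approx(expected, rel=5e-3)

    def test_conservative_mass_conserved_under_flow(self):
        site = small_site(nx=30, ny=20, head_east=9.9)
        flow = solve_steady_flow(site)
        c0 = np.zeros((2, 20, 30))
        c0[0, 10, 5] = 50.0
        init = PlumeState(c0, 0.0)
        states = simulate_plume(flow, init, retardation=1.0, decay=0.0, times=[1825.0])
        ratio = total_mass(states[0], site) / total_mass(init, site)
        assert abs(ratio - 1.0) < 1e-3

    def test_point_mass_centroid_advects_at_retarded_velocity(self):
        site = small_site(nx=30, ny=20, head_east=9.9)
        flow = solve_steady_flow(site)
        c0 = np.zeros((2, 20, 30))
        c0[0, 10, 5] = 50.0
        retardation = 2.0
        states = simulate_plume(
            flow, PlumeState(c0, 0.0), retardation=retardation, decay=0.0,
            times=[1825.0],
        )
        v = flow.qx[0, 10, 6] / site.porosity[0, 10, 6]
        moved = (
            plume_metrics(states[0], [1.0], site).centroid[0]
            - plume_metrics(PlumeState(c0, 0.0), [1.0], site).centroid[0]
        )
        assert abs(moved - v * 1825.0 / retardation) < site.dx

    def test_max_concentration_monotone_decreasing_with_decay(self):
        site = small_site(nx=30, ny=20, head_east=9.9)
        flow = solve_steady_flow(site)
        c0 = np.zeros((2, 20, 30))
        c0[0, 10, 5] = 50.0
        states = simulate_plume(
            flow, PlumeState(c0, 0.0), retardation=1.425, decay=0.0045,
            times=[1.0, 183.0, 365.0, 730.0, 1825.0],
        )
        maxima = [st_.concentration.max() for st_ in states]
        assert all(a >= b for a, b in zip(maxima, maxima[1:]))


class TestPlumeMetrics:
    def test_zero_state(self):
        site = small_site()
        metrics = plume_metrics(PlumeState(np.zeros((2, 10, 20)), 0.0), [25.0], site)
        assert metrics.max_concentration == 0.0
        assert metrics.areas[25.0] == 0.0
        assert math.isnan(metrics.centroid[0])

    def test_threshold_is_inclusive_single_cell(self):
        site = small_site()
        c = np.zeros((2, 10, 20))
        c[0, 4, 7] = 25.0
        metrics = plume_metrics(PlumeState(c, 0.0), [25.0], site)
        assert metrics.areas[25.0] == pytest.approx(site.dx * site.dy)
        assert metrics.cell_counts[25.0] == 1

    def test_gaussian_peak_equals_array_max(self):
        site = small_site()
        rr, cc = np.meshgrid(np.arange(10), np.arange(20), indexing="ij")
        blob = 30.0 * np.exp(-((rr - 5) ** 2 + (cc - 9) ** 2) / 8.0)
        c = np.stack([blob, 0.5 * blob])
        metrics = plume_metrics(PlumeState(c, 0.0), [1.0], site)
        assert metrics.max_concentration == pytest.approx(c.max())

    @settings(max_examples=20, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_area_monotone_non_increasing_in_threshold(self, seed):
        site = small_site()
        rng = np.random.default_rng(seed)
        c = rng.uniform(0.0, 50.0, size=(2, 10, 20))
        metrics = plume_metrics(PlumeState(c, 0.0), [1.0, 10.0, 25.0, 40.0], site)
        areas = [metrics.areas[t] for t in (1.0, 10.0, 25.0, 40.0)]
        assert all(a >= b for a, b in zip(areas, areas[1:]))


class TestWellComparison:
    def _states(self):
        site = small_site(head_east=10.0)
        flow = solve_steady_flow(site)
        c0 = np.zeros((2, 10, 20))
        c0[0, 5, 5] = 42.0
        states = simulate_plume(
            flow, PlumeState(c0, 0.0), retardation=1.0, decay=0.002,
            times=np.linspace(1.0, 1000.0, 25),
        )
        return site, states

    def test_perfect_observations_have_zero_mse(self):
        _, states = self._states()
        times = np.linspace(1.0, 1000.0, 12)
        series = np.interp(
            times,
            [s.time for s in states],
            [s.concentration[0, 5, 5] for s in states],
        )
        well = WellRecord("W", 0, 5, 5, times, series)
        assert compare_wells([well], states)["W"] == pytest.approx(0.0, abs=1e-20)

    def test_constant_offset_gives_squared_offset(self):
        _, states = self._states()
        times = np.linspace(1.0, 1000.0, 12)
        series = np.interp(
            times,
            [s.time for s in states],
            [s.concentration[0, 5, 5] for s in states],
        )
        well = WellRecord("W", 0, 5, 5, times, series + 0.7)
        assert compare_wells([well], states)["W"] == pytest.approx(0.49)

    def test_twin_experiment_mse_approaches_noise_variance(self):
        """Synthetic twin: with n = 200 samples/well the MSE estimates the
        observation noise variance to ~10 % (law of large numbers)."""
        _, states = self._states()
        sigma = 0.5

        class W:
            def __init__(s, i):
                # all at the plume cell: concentrations stay well above the
                # noise floor so zero-clipping does not bias the MSE
                s.well_id, s.layer, s.row, s.col = f"W{i}", 0, 5, 5

        obs = generate_well_observations(
            states, [W(0), W(1), W(2)], np.linspace(1.0, 1000.0, 200),
            noise_sd=sigma, seed=0,
        )
        mse = compare_wells(obs, states)
        pooled = np.mean(list(mse.values()))
        assert pooled == pytest.approx(sigma**2, rel=0.2)

    def test_well_outside_grid_or_range_rejected(self):
        _, states = self._states()
        with pytest.raises(IndexError):
            compare_wells([WellRecord("X", 5, 0, 0, [10.0], [1.0])], states)
        with pytest.raises(InvalidSpecError):
            compare_wells([WellRecord("Y", 0, 0, 0, [2000.0], [1.0])], states)


class TestSyntheticSite:
    def test_anchor_concentrations_reproduced_exactly(self):
        syn = generate_site(seed=0, nx=100, ny=100, nlayers=4)
        for anchor in syn.anchors:
            got = syn.initial.concentration[anchor.layer, anchor.row, anchor.col]
            assert got == pytest.approx(anchor.concentration, rel=1e-6)

    def test_single_anchor_peak_is_at_anchor_cell(self):
        anchor = DEFAULT_ANCHORS[0]
        syn = generate_site([anchor], seed=0, nx=100, ny=100, nlayers=4)
        c = syn.initial.concentration
        assert c.max() == pytest.approx(anchor.concentration)
        assert np.unravel_index(np.argmax(c), c.shape) == (
            anchor.layer, anchor.row, anchor.col,
        )

    def test_vanishing_kernel_scale_localises_to_anchor_cells(self):
        syn = generate_site(kernel_scale=1e-6, vertical_scale=1e-6, seed=0,
                            nx=100, ny=100, nlayers=4)
        c = syn.initial.concentration
        nonzero = np.argwhere(c > 1e-12 * c.max())
        assert len(nonzero) == len(syn.anchors)

    def test_anchor_outside_grid_rejected(self):
        from mnasim.synthetic import Anchor

        with pytest.raises(InvalidSpecError):
            generate_site([Anchor("bad", 0, 500, 0, 1.0)], nx=60, ny=60)

    def test_well_observations_reproducible_under_seed(self):
        _, states = TestWellComparison()._states()

        class W:
            well_id, layer, row, col = "W", 0, 5, 5

        a = generate_well_observations(states, [W], [10.0, 500.0], noise_sd=0.3, seed=4)
        b = generate_well_observations(states, [W], [10.0, 500.0], noise_sd=0.3, seed=4)
        assert np.array_equal(a[0].concentrations, b[0].concentrations)
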