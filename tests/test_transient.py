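"""Transient layered-diffusion solver and its analytic oracle."""

import math
import warnings

import numpy as np
import pytest

from oxygel.transient import (
    BoundaryDriver,
    Layer,
    LayerStack,
    SolverSettings,
    analytic_single_layer,
    boundary_value,
    cylinder_volume_mL,
    gel_stack,
    sample_probe,
    solve_transient,
    water_stack,
)


class TestBoundaryDriver:
    def test_fopdt_holds_initial_before_dead_time(self):
        drv = BoundaryDriver("fopdt", C0=1.0, C_final=0.0, theta_s=3.0, tau_s=23.0)
        assert boundary_value(drv, 2.0) == 1.0

    def test_fopdt_one_time_constant(self):
        drv = BoundaryDriver("fopdt", C0=1.0, C_final=0.0, theta_s=3.0, tau_s=23.0)
        assert boundary_value(drv, 26.0) == pytest.approx(math.exp(-1.0), rel=1e-12)

    def test_fopdt_one_percent_crossing(self):
        # closed-form inversion: t = theta + tau·ln(100) ≈ 108.93 s < 2 min
        drv = BoundaryDriver("fopdt", C0=1.0, C_final=0.0, theta_s=3.0, tau_s=23.0)
        t = 3.0 + 23.0 * math.log(100.0)
        assert boundary_value(drv, t) == pytest.approx(0.01, rel=1e-12)
        assert t < 120.0

    def test_constant_and_step_modes(self):
        assert boundary_value(BoundaryDriver("constant", C0=0.7), 1e4) == 0.7
        assert boundary_value(BoundaryDriver("ideal_step", C0=1.0, C_final=0.2), 0.0) == 0.2

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            boundary_value(BoundaryDriver("constant", C0=1.0), -1.0)

    def test_invalid_driver_rejected(self):
        with pytest.raises(ValueError):
            BoundaryDriver("ramp", C0=1.0)
        with pytest.raises(ValueError):
            BoundaryDriver("fopdt", C0=1.0, tau_s=0.0)


class TestAnalyticOracle:
    def test_initial_condition(self):
        assert analytic_single_layer(3.1e-5, 4.0, 1.0, 0.0, n_terms=400) == pytest.approx(
            1.0, abs=5e-3
        )

    def test_dirichlet_surface(self):
        assert analytic_single_layer(3.1e-5, 4.0, 4.0, 1000.0) == pytest.approx(0.0, abs=1e-12)

    def test_reference_point(self):
        # first-mode dominance at one hour, probe at 1.8 of 4 mm
        assert analytic_single_layer(3.1e-5, 4.0, 1.8, 3600.0) == pytest.approx(0.173, abs=5e-4)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            analytic_single_layer(3.1e-5, 4.0, 1.8, 100.0, n_terms=0)
        with pytest.raises(ValueError):
            analytic_single_layer(3.1e-5, 4.0, 5.0, 100.0)


class TestSolver:
    def test_constant_driver_is_equilibrium(self, coarse_solver):
        fld = solve_transient(
            water_stack(), BoundaryDriver("constant", C0=0.16), [0.0, 600.0, 3600.0], coarse_solver
        )
        assert np.allclose(fld.C, 0.16, atol=1e-12)

    def test_matches_cosine_series(self):
        stack = water_stack()
        drv = BoundaryDriver("ideal_step", C0=1.0, C_final=0.0)
        times = np.array([30.0, 60.0, 120.0, 300.0, 900.0, 1800.0, 3600.0])
        settings = SolverSettings(dz_mm=0.05, dt_s=1.0)
        trace = sample_probe(solve_transient(stack, drv, times, settings), 1.8)
        exact = analytic_single_layer(3.1e-5, 4.0, 1.8, times)
        assert np.abs(trace.values - exact).max() < 5e-3  # 0.5% of C0 = 1

    def test_two_equal_layers_degenerate_to_one(self, coarse_solver):
        drv = BoundaryDriver("ideal_step", C0=1.0, C_final=0.0)
        times = np.arange(0.0, 3601.0, 60.0)
        one = sample_probe(solve_transient(water_stack(), drv, times, coarse_solver), 1.8)
        two_stack = gel_stack(3.1e-5, 3.1e-5, gel_height_mm=2.5, medium_height_mm=1.5)
        two = sample_probe(solve_transient(two_stack, drv, times, coarse_solver), 1.8)
        assert np.abs(one.values - two.values).max() < 1e-6

    def test_monotone_and_bounded_after_step_down(self, coarse_solver):
        drv = BoundaryDriver("fopdt", C0=1.0, C_final=0.0, theta_s=3.0, tau_s=23.0)
        times = np.arange(0.0, 7201.0, 30.0)
        fld = solve_transient(water_stack(), drv, times, coarse_solver)
        trace = sample_probe(fld, 1.8)
        assert np.all(np.diff(trace.values) <= 1e-9)
        assert fld.C.min() >= -1e-6 and fld.C.max() <= 1.0 + 1e-6

    def test_long_time_limit_is_zero(self, coarse_solver):
        drv = BoundaryDriver("ideal_step", C0=1.0, C_final=0.0)
        trace = sample_probe(
            solve_transient(water_stack(), drv, [0.0, 40000.0], coarse_solver), 1.8
        )
        assert trace.values[-1] < 1e-3

    def test_sealed_domain_conserves_mass(self):
        stack = water_stack()
        settings = SolverSettings(dz_mm=0.02, dt_s=0.5)
        probe_fld = solve_transient(
            stack, BoundaryDriver("constant", C0=1.0), [0.0], settings
        )
        z = probe_fld.z_mm
        initial = 1.0 + 0.5 * np.cos(np.pi * z / 4.0)
        fld = solve_transient(
            stack,
            BoundaryDriver("constant", C0=1.0),
            [0.0, 500.0],
            settings,
            initial=initial,
            top_bc="no_flux",
        )
        m0 = np.trapezoid(fld.C[:, 0], fld.z_mm)
        m1 = np.trapezoid(fld.C[:, 1], fld.z_mm)
        assert abs(m1 - m0) / m0 < 1e-10

    def test_refinement_convergence_contract(self):
        drv = BoundaryDriver("fopdt", C0=1.0, C_final=0.0, theta_s=3.0, tau_s=23.0)
        times = np.arange(60.0, 3601.0, 60.0)
        base = sample_probe(
            solve_transient(water_stack(), drv, times, SolverSettings(0.08, 2.0)), 1.8
        )
        fine = sample_probe(
            solve_transient(water_stack(), drv, times, SolverSettings(0.04, 1.0)), 1.8
        )
        assert np.abs(base.values - fine.values).max() < 2e-3  # < 0.2% of C0

    def test_no_clamp_warning_at_default_resolution(self):
        drv = BoundaryDriver("ideal_step", C0=1.0, C_final=0.0)
        with warnings.catch_warnings():
            warnings.simplefilter("error")
            solve_transient(water_stack(), drv, np.arange(0.0, 601.0, 10.0))

    def test_invalid_inputs_rejected(self, coarse_solver):
        drv = BoundaryDriver("constant", C0=1.0)
        with pytest.raises(ValueError):
            solve_transient(water_stack(), drv, [10.0, 5.0], coarse_solver)
        with pytest.raises(ValueError):
            Layer(0.0, 3.1e-5)
        with pytest.raises(ValueError):
            Layer(4.0, -1.0)
        with pytest.raises(ValueError):
            LayerStack((Layer(4.0, 3.1e-5),), probe_height_mm=5.0)


class TestSampleProbe:
    def test_interpolation_and_node_exactness(self, coarse_solver):
        fld = solve_transient(
            water_stack(), BoundaryDriver("constant", C0=1.0), [0.0, 10.0], coarse_solver
        )
        fld.C[:, :] = fld.z_mm[:, None] * 0.1  # synthetic linear-in-z field
        node = sample_probe(fld, float(fld.z_mm[5]))
        assert node.values[0] == pytest.approx(fld.C[5, 0], rel=1e-12)
        mid = 0.5 * (fld.z_mm[5] + fld.z_mm[6])
        assert sample_probe(fld, float(mid)).values[0] == pytest.approx(
            0.5 * (fld.C[5, 0] + fld.C[6, 0]), rel=1e-12
        )

    def test_probe_outside_domain_rejected(self, coarse_solver):
        fld = solve_transient(
            water_stack(), BoundaryDriver("constant", C0=1.0), [0.0, 10.0], coarse_solver
        )
        with pytest.raises(ValueError):
            sample_probe(fld, 4.5)


def test_slab_volume_helper():
    assert cylinder_volume_mL(50.0, 4.0) == pytest.approx(math.pi * 625 * 4 / 1000, rel=1e-12)
    assert water_stack().volume_mL == pytest.approx(7.854, abs=1e-3)
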