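"""Regularized-delta spreading/interpolation and tether-spring mechanics."""

import numpy as np
import pytest

from trabeflow.ib_solver import (
    FluidGrid,
    FlowParams,
    delta_kernel,
    inflow_gate,
    inflow_profile,
    interpolate_velocity,
    spread_force,
    tether_forces,
)


@pytest.fixture(scope="module")
def grid():
    return FluidGrid(64, 32, 4.0, 2.0)


class TestDeltaKernel:
    def test_partition_of_unity(self):
        # sum over integer-offset samples equals 1 for any sub-grid shift
        for shift in (0.0, 0.13, 0.5, 0.77):
            r = np.arange(-3, 4) - shift
            assert delta_kernel(r).sum() == pytest.approx(1.0, abs=1e-14)

    def test_compact_support(self):
        assert delta_kernel(np.array([-2.0, 2.0, 2.5])).max() == 0.0
        assert delta_kernel(0.0) == pytest.approx(0.5)


class TestSpreading:
    def test_zero_force_spreads_to_zero(self, grid):
        fx, fy = spread_force(
            grid, np.array([[1.0, 1.0]]), np.zeros((1, 2)), np.array([0.01])
        )
        assert not fx.any() and not fy.any()

    def test_total_force_conserved(self, grid):
        pts = np.array([[1.234, 0.897]])
        F = np.array([[1.0, -0.5]])
        ds = np.array([0.0123])
        fx, fy = spread_force(grid, pts, F, ds)
        # sum(f) h^2 == sum(F ds); support is a 4x4 patch
        assert fx.sum() * grid.h**2 == pytest.approx(F[0, 0] * ds[0], rel=1e-12)
        assert fy.sum() * grid.h**2 == pytest.approx(F[0, 1] * ds[0], rel=1e-12)
        assert (np.abs(fx) > 0).sum() <= 16

    def test_whole_cell_translation_invariance(self, grid):
        pts = np.array([[1.234, 0.897]])
        F = np.array([[1.0, 0.3]])
        ds = np.array([0.01])
        fx1, _ = spread_force(grid, pts, F, ds)
        fx2, _ = spread_force(grid, pts + [[grid.h, 0.0]], F, ds)
        assert np.allclose(np.roll(fx1, 1, axis=0), fx2, atol=1e-14)

    def test_adjointness_with_interpolation(self, grid, rng):
        """<spread(F), U>_grid h^2 == <F, interp(U)>_boundary ds."""
        n = 37
        pts = np.column_stack(
            [rng.uniform(0.5, 3.5, n), rng.uniform(0.3, 1.7, n)]
        )
        F = rng.standard_normal((n, 2))
        ds = rng.uniform(0.005, 0.02, n)
        U = rng.standard_normal((grid.nx, grid.ny))
        V = rng.standard_normal((grid.nx, grid.ny))
        fx, fy = spread_force(grid, pts, F, ds)
        lhs = (fx * U + fy * V).sum() * grid.h**2
        vel = interpolate_velocity(grid, U, V, pts)
        rhs = ((F[:, 0] * vel[:, 0] + F[:, 1] * vel[:, 1]) * ds).sum()
        assert lhs == pytest.approx(rhs, rel=1e-12)


class TestInterpolation:
    def test_uniform_field_exact(self, grid, rng):
        u = np.full((grid.nx, grid.ny), 2.5)
        v = np.full((grid.nx, grid.ny), -0.7)
        pts = np.column_stack([rng.uniform(0, 4, 25), rng.uniform(0, 2, 25)])
        vel = interpolate_velocity(grid, u, v, pts)
        assert np.allclose(vel[:, 0], 2.5, atol=1e-13)
        assert np.allclose(vel[:, 1], -0.7, atol=1e-13)

    def test_zero_field_gives_zero(self, grid):
        vel = interpolate_velocity(
            grid,
            np.zeros((grid.nx, grid.ny)),
            np.zeros((grid.nx, grid.ny)),
            np.array([[1.0, 1.0]]),
        )
        assert not vel.any()

    def test_linear_shear_exact(self):
        """The 4-point kernel's first-moment property makes interpolation
        of a linear shear field exact to round-off."""
        g = FluidGrid(64, 64, 2.0, 2.0)
        X, Y = g.meshgrid()
        u = 0.8 * Y - 0.2 * X
        pts = np.array([[0.7341, 0.9873], [1.2211, 0.4457]])
        vel = interpolate_velocity(g, u, np.zeros_like(u), pts)
        expect = 0.8 * pts[:, 1] - 0.2 * pts[:, 0]
        assert np.abs(vel[:, 0] - expect).max() < 1e-12

    def test_quadratic_field_second_order(self):
        """Taylor-expansion oracle: error on a quadratic field is O(h^2)."""
        errs = []
        for n in (32, 64):
            g = FluidGrid(n, n, 2.0, 2.0)
            X, Y = g.meshgrid()
            u = Y**2
            pts = np.array([[0.7341, 0.9873], [1.2211, 0.4457]])
            vel = interpolate_velocity(g, u, np.zeros_like(u), pts)
            errs.append(np.abs(vel[:, 0] - pts[:, 1] ** 2).max())
        assert errs[1] < 0.35 * errs[0]


class TestTetherForces:
    def test_at_target_no_force(self, rng):
        X = rng.standard_normal((10, 2))
        assert not tether_forces(X, X, 1e4).any()

    def test_linear_restoring(self):
        X = np.array([[1.0, 1.0]])
        T = np.array([[1.0, 0.9]])
        F = tether_forces(X, T, 500.0)
        assert F[0, 1] == pytest.approx(-500.0 * 0.1)
        assert F[0, 0] == 0.0

    def test_doubling_stiffness_halves_static_deflection(self):
        """Linear spring balance: deflection = load / k."""
        load = np.array([[0.0, 2.0]])
        for k in (100.0, 200.0):
            # static balance: -k (X - T) + load = 0 -> X - T = load / k
            defl = load / k
            F = tether_forces(defl, np.zeros((1, 2)), k)
            assert np.allclose(F + load, 0.0, atol=1e-12)


class TestInflow:
    def test_pulsatile_waveform_endpoints(self):
        flow = FlowParams(re=1.0, mode="pulsatile", vin=1.0, f_nd=0.10)
        T = flow.period
        assert T == pytest.approx(0.8 / (0.10 * 0.5))
        assert inflow_gate(0.0, flow) == pytest.approx(0.0)  # near zero at cycle ends
        assert inflow_gate(T, flow) == pytest.approx(0.0, abs=1e-12)
        assert inflow_gate(T / 2, flow) == pytest.approx(1.0)  # maximal mid-cycle

    def test_pulsatile_time_mean_is_half_peak(self):
        flow = FlowParams(re=1.0, mode="pulsatile", vin=1.0)
        t = np.linspace(0, flow.period, 10001)
        mean = np.trapezoid([inflow_gate(ti, flow) for ti in t], t) / flow.period
        assert mean == pytest.approx(0.5, rel=1e-6)

    def test_steady_ramp_reaches_plateau(self):
        flow = FlowParams(re=1.0, mode="steady", vin=1.0, ramp_tau=0.5)
        assert inflow_gate(0.0, flow) == 0.0
        assert inflow_gate(0.25, flow) == pytest.approx(0.5)
        assert inflow_gate(0.5, flow) == 1.0
        assert inflow_gate(10.0, flow) == 1.0

    def test_parabolic_profile_shape(self):
        flow = FlowParams(re=1.0, mode="steady")
        y = np.linspace(0.2, 1.0, 33)
        prof = inflow_profile(y, t=10.0, flow=flow, y_bot=0.2, y_top=1.0)
        assert prof[0] == pytest.approx(0.0)
        assert prof[-1] == pytest.approx(0.0)
        assert prof.max() == pytest.approx(1.0)
        assert y[np.argmax(prof)] == pytest.approx(0.6, abs=0.02)
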