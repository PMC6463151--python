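"""Stream function, vortex detection, transects, WSS/TAWSS/OSI."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from trabeflow.flow_metrics import (
    ChamberMasks,
    StreamFunctionField,
    detect_vortices,
    is_nonmonotone_near_wall,
    region_average,
    region_masks,
    stream_function,
    tawss_osi,
    trace_particle,
    velocity_transect,
    wall_shear_stress,
    ShearRecord,
)
from trabeflow.geometry import GeometryParams, build_channel
from trabeflow.ib_solver import FluidGrid, FluidState, divergence
from trabeflow.oracles import make_constructed_psi, make_poiseuille


def _state_from_psi(grid, psi):
    """Discretely divergence-free velocity via centered differences of psi."""
    h = grid.h
    u = (np.roll(psi, -1, axis=1) - np.roll(psi, 1, axis=1)) / (2 * h)
    v = -(np.roll(psi, -1, axis=0) - np.roll(psi, 1, axis=0)) / (2 * h)
    return FluidState(u, v, np.zeros_like(u), 0.0)


class TestStreamFunction:
    def test_uniform_flow_linear_psi(self):
        g = FluidGrid(64, 32, 4.0, 2.0)
        st_ = FluidState(
            np.full((64, 32), 0.7), np.zeros((64, 32)), np.zeros((64, 32)), 0.0
        )
        f = stream_function(st_, g)
        X, Y = g.meshgrid()
        expect = 0.7 * Y
        assert np.abs((f.psi - f.psi.mean()) - (expect - expect.mean())).max() < 1e-10

    def test_zero_field_constant_psi(self):
        g = FluidGrid(32, 16, 4.0, 2.0)
        z = np.zeros((32, 16))
        f = stream_function(FluidState(z, z, z, 0.0), g)
        assert np.abs(f.psi - f.psi[0, 0]).max() < 1e-12

    def test_recovers_generating_psi(self):
        """For velocity built from psi by centered differences, the solve
        returns that psi (up to a constant) and derivatives reconstruct u."""
        g = FluidGrid(64, 32, 4.0, 2.0)
        X, Y = g.meshgrid()
        psi0 = 0.3 * np.sin(2 * np.pi * X / 4.0) * np.cos(2 * np.pi * Y / 2.0)
        st_ = _state_from_psi(g, psi0)
        assert np.abs(divergence(g, st_.u, st_.v)).max() < 1e-12
        f = stream_function(st_, g)
        d = (f.psi - f.psi.mean()) - (psi0 - psi0.mean())
        assert np.abs(d).max() < 1e-10

    def test_rotation_patch_single_extremum(self):
        g = FluidGrid(64, 64, 4.0, 4.0)
        X, Y = g.meshgrid()
        psi_fn, _ = make_constructed_psi([(2.0, 2.0, 0.4, 0.3)])
        st_ = _state_from_psi(g, psi_fn(X, Y))
        f = stream_function(st_, g)
        interior = f.psi[8:-8, 8:-8]
        i, j = np.unravel_index(np.argmax(interior), interior.shape)
        assert ((i + 8) * g.h, (j + 8) * g.h) == pytest.approx((2.0, 2.0), abs=0.1)

    def test_rejects_divergent_input(self):
        g = FluidGrid(32, 16, 4.0, 2.0)
        X, Y = g.meshgrid()
        st_ = FluidState(X.copy(), np.zeros_like(X), np.zeros_like(X), 0.0)
        with pytest.raises(ValueError, match="divergence"):
            stream_function(st_, g)


def _open_masks(grid):
    fluid = np.ones((grid.nx, grid.ny), dtype=bool)
    return ChamberMasks(
        fluid=fluid,
        cavity=fluid.copy(),
        intracardial=fluid.copy(),
        intertrabecular={},
        cavity_area=grid.lx * grid.ly,
    )


class TestVortexDetection:
    def test_constructed_two_gaussian_field(self, smooth_chamber):
        g = FluidGrid(96, 48, 4.0, 2.0)
        X, Y = g.meshgrid()
        psi_fn, truth = make_constructed_psi(
            [(1.2, 1.0, 0.5, 0.12), (2.8, 1.0, -0.5, 0.12)]
        )
        field = StreamFunctionField(psi_fn(X, Y), g)
        rep = detect_vortices(field, _open_masks(g), smooth_chamber)
        assert len(rep) == 2
        got = sorted((v.center, v.sense) for v in rep.vortices)
        for (center, sense), tc, ts in zip(got, truth.centers, truth.senses):
            assert center == pytest.approx(tc, abs=0.08)
            assert sense == ts

    def test_zero_field_reports_none(self, smooth_chamber):
        g = FluidGrid(64, 32, 4.0, 2.0)
        field = StreamFunctionField(np.zeros((64, 32)), g)
        assert len(detect_vortices(field, _open_masks(g), smooth_chamber)) == 0

    def test_agrees_with_particle_tracing(self, smooth_chamber):
        """A particle seeded in a detected vortex returns near its start."""
        g = FluidGrid(96, 48, 4.0, 2.0)
        X, Y = g.meshgrid()
        psi_fn, _ = make_constructed_psi([(2.0, 1.0, 0.4, 0.15)])
        psi = psi_fn(X, Y)
        st_ = _state_from_psi(g, psi)
        field = StreamFunctionField(psi, g)
        rep = detect_vortices(field, _open_masks(g), smooth_chamber)
        assert len(rep) == 1
        x0 = np.array(rep.vortices[0].center) + [0.08, 0.0]
        traj = trace_particle(g, st_.u, st_.v, x0, dt=0.01, n_steps=4000)
        dist = np.hypot(*(traj - x0).T)
        # it must leave the start and come back: a closed orbit
        assert dist.max() > 0.05
        assert dist[len(dist) // 2 :].min() < 0.02


class TestTransects:
    def test_quiescent_region_zeros(self):
        g = FluidGrid(32, 16, 4.0, 2.0)
        z = np.zeros((32, 16))
        tr = velocity_transect(FluidState(z, z, z, 0.0), g, (0.5, 0.5), (3.0, 1.5))
        assert not tr.speed.any()
        assert len(tr.frac) >= 100

    def test_poiseuille_cross_profile(self):
        g = FluidGrid(128, 64, 4.0, 2.0)
        ref = make_poiseuille(0.8, 1.0, y0=0.6)
        X, Y = g.meshgrid()
        st_ = FluidState(ref.u(X, Y, 0), ref.v(X, Y, 0), np.zeros_like(X), 0.0)
        tr = velocity_transect(st_, g, (2.0, 0.6), (2.0, 1.4), n=201)
        expect = ref.u(2.0, 0.6 + tr.frac * 0.8, 0.0)
        assert np.abs(tr.speed - expect).max() < 0.03

    def test_endpoint_outside_domain_rejected(self):
        g = FluidGrid(32, 16, 4.0, 2.0)
        z = np.zeros((32, 16))
        with pytest.raises(ValueError, match="outside"):
            velocity_transect(FluidState(z, z, z, 0.0), g, (0, 0), (5.0, 1.0))

    def test_nonmonotone_signature_detector(self):
        """Synthetic decay-dip-rise-decay profile is recognized; a monotone
        decay is not."""
        n = 200
        frac = np.linspace(0, 1, n)

        class T:
            p0, p1 = (0.0, 0.0), (1.0, 0.0)

        hT = 0.1
        d_wall = 1.0 - frac
        dip = np.exp(-(((d_wall - 0.1) / 0.04) ** 2))
        speed = np.exp(-3 * frac) * (1 - 0.9 * dip)
        speed[-3:] = 1e-4
        t1 = T()
        t1.frac, t1.speed = frac, speed
        assert is_nonmonotone_near_wall(t1, hT)
        t2 = T()
        t2.frac, t2.speed = frac, np.exp(-5 * frac) * (1 - frac) ** 2
        assert not is_nonmonotone_near_wall(t2, hT)


class TestWallShearStress:
    def test_poiseuille_wall_shear_from_sampled_field(self):
        g = FluidGrid(128, 64, 4.0, 2.0)
        p = GeometryParams()
        curve = build_channel(p, g.h)
        mu = 0.8
        ref = make_poiseuille(p.wAV, 1.0, y0=curve.meta["y_bot"], mu=mu)
        X, Y = g.meshgrid()
        u = np.where(
            (Y >= curve.meta["y_bot"]) & (Y <= curve.meta["y_top"]), ref.u(X, Y, 0), 0.0
        )
        st_ = FluidState(u, np.zeros_like(u), np.zeros_like(u), 0.0)
        wss, valid = wall_shear_stress(st_, curve, g, mu)
        mag = np.hypot(wss[:, 0], wss[:, 1])
        assert valid.all()
        assert np.median(np.abs(mag - ref.params["wall_shear"])) < 0.05 * ref.params[
            "wall_shear"
        ]

    def test_quiescent_fluid_zero_wss(self, smooth_chamber, coarse_grid):
        z = np.zeros((coarse_grid.nx, coarse_grid.ny))
        wss, _ = wall_shear_stress(
            FluidState(z, z, z, 0.0), smooth_chamber, coarse_grid, 1.0
        )
        assert not wss.any()


class TestTawssOsi:
    def _record(self, wss):
        n_t, n_p = wss.shape[:2]
        return ShearRecord(
            wss=wss,
            times=np.linspace(0, 1, n_t),
            valid=np.ones(n_p, bool),
            labels=np.array(["chamber-wall"] * n_p, dtype=object),
            spacing=np.ones(n_p),
        )

    def test_constant_direction_gives_zero(self):
        wss = np.tile([[1.0, 0.5]], (50, 3, 1)) * np.linspace(0.5, 2, 50)[:, None, None]
        tawss, osi = tawss_osi(self._record(wss))
        assert np.allclose(osi, 0.0, atol=1e-12)

    def test_perfect_reversal_gives_half(self):
        wss = np.zeros((40, 2, 2))
        wss[:20, :, 0] = 1.0
        wss[20:, :, 0] = -1.0
        tawss, osi = tawss_osi(self._record(wss))
        assert np.allclose(osi, 0.5)
        assert np.allclose(tawss, 0.0)

    def test_zero_everywhere_defined_as_zero(self):
        tawss, osi = tawss_osi(self._record(np.zeros((10, 4, 2))))
        assert np.allclose(osi, 0.0)

    def test_quarter_circle_rotation_matches_quadrature(self):
        """WSS direction sweeping a quarter circle: OSI from the closed-form
        mean 0.5 (1 - 2 sqrt(2) / pi)."""
        theta = np.linspace(0, np.pi / 2, 20001)
        wss = np.stack([np.cos(theta), np.sin(theta)], axis=1)[:, None, :]
        tawss, osi = tawss_osi(self._record(wss))
        expect = 0.5 * (1 - 2 * np.sqrt(2) / np.pi)
        assert osi[0] == pytest.approx(expect, abs=1e-4)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        st.integers(3, 30),
        st.integers(1, 6),
        st.integers(0, 2**31 - 1),
    )
    def test_osi_bounded(self, n_t, n_p, seed):
        rng = np.random.default_rng(seed)
        wss = rng.standard_normal((n_t, n_p, 2)) * rng.lognormal(0, 2)
        _, osi = tawss_osi(self._record(wss))
        assert np.all(osi >= 0.0) and np.all(osi <= 0.5)


class TestRegionAverage:
    labels = np.array(
        ["trabecula[0]", "trabecula[1]", "intertrabecular[1]", "chamber-wall"],
        dtype=object,
    )
    spacing = np.array([0.1, 0.3, 0.2, 0.4])

    def test_uniform_field_any_region(self):
        vals = np.full(4, 3.3)
        for region in ("trabecula", "intertrabecular", "chamber-wall"):
            assert region_average(vals, self.labels, self.spacing, region) == pytest.approx(3.3)

    def test_single_point_arc_weighting(self):
        vals = np.array([5.0, 0.0, 0.0, 0.0])
        avg = region_average(vals, self.labels, self.spacing, "trabecula")
        assert avg == pytest.approx(5.0 * 0.1 / 0.4)

    def test_union_consistency(self, rng):
        """Whole mean equals the arc-length-weighted combination of parts."""
        vals = rng.uniform(0, 2, 4)
        whole = region_average(vals, self.labels, self.spacing, "")
        parts = 0.0
        for region in ("trabecula", "intertrabecular", "chamber-wall"):
            sel = np.char.startswith(self.labels.astype(str), region)
            w = self.spacing[sel].sum()
            parts += region_average(vals, self.labels, self.spacing, region) * w
        assert whole == pytest.approx(parts / self.spacing.sum())

    def test_empty_region_is_error(self):
        with pytest.raises(ValueError, match="no"):
            region_average(np.ones(4), self.labels, self.spacing, "septum")

    def test_time_series_input(self):
        vals = np.ones((7, 4))
        out = region_average(vals, self.labels, self.spacing, "trabecula")
        assert out.shape == (7,)
        assert np.allclose(out, 1.0)
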