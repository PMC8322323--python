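"""D3Q19 BGK solver: equilibria, moments, streaming, walls, forcing."""

import numpy as np
import pytest

from ctcsim import lattice_fluid as lf
from ctcsim._kernels import fused_fluid_step
from ctcsim.errors import InvalidStateError, StabilityError


def scalar_equilibrium(rho, u, i):
    """Independent scalar evaluation of the discrete equilibrium."""
    e = lf.D3Q19.e[i]
    w = lf.D3Q19.w[i]
    eu = e[0] * u[0] + e[1] * u[1] + e[2] * u[2]
    usq = u[0] ** 2 + u[1] ** 2 + u[2] ** 2
    return w * rho * (1 + 3 * eu + 4.5 * eu**2 - 1.5 * usq)


class TestVelocitySet:
    def test_moment_identities(self):
        vs = lf.D3Q19
        assert vs.q == 19
        assert vs.w.sum() == pytest.approx(1.0, abs=1e-15)
        assert np.abs(vs.w @ vs.e.astype(float)).max() < 1e-15
        second = np.einsum("i,ia,ib->ab", vs.w, vs.e.astype(float), vs.e.astype(float))
        assert np.allclose(second, vs.cs2 * np.eye(3), atol=1e-15)

    def test_opposites(self):
        vs = lf.D3Q19
        assert np.array_equal(vs.e[vs.opposite], -vs.e)


class TestEquilibrium:
    def test_rest_state_returns_weights(self):
        feq = lf.equilibrium_distribution(1.0, np.zeros(3))
        assert np.allclose(feq, lf.D3Q19.w, atol=1e-16)

    def test_zeroth_moment_is_density(self, rng):
        rho = rng.uniform(0.5, 2.0, size=(4, 4, 4))
        u = rng.uniform(-0.05, 0.05, size=(3, 4, 4, 4))
        feq = lf.equilibrium_distribution(rho, u)
        assert np.allclose(feq.sum(axis=0), rho, rtol=1e-14)

    def test_matches_scalar_oracle(self):
        u = np.array([0.01, 0.0, 0.0])
        feq = lf.equilibrium_distribution(1.0, u)
        expected = [scalar_equilibrium(1.0, u, i) for i in range(19)]
        assert np.allclose(feq, expected, rtol=1e-15)

    def test_rejects_nonpositive_density(self):
        with pytest.raises(InvalidStateError):
            lf.equilibrium_distribution(0.0, np.zeros(3))


class TestMoments:
    def test_weights_give_rest_fluid(self):
        rho, u = lf.compute_moments(lf.D3Q19.w.copy())
        assert rho == pytest.approx(1.0)
        assert np.allclose(u, 0.0, atol=1e-16)

    def test_equilibrium_roundtrip(self, rng):
        rho0 = rng.uniform(0.8, 1.2, size=(3, 3, 3))
        u0 = rng.uniform(-0.03, 0.03, size=(3, 3, 3, 3))
        u0 = np.moveaxis(u0, -1, 0)
        rho, u = lf.compute_moments(lf.equilibrium_distribution(rho0, u0))
        assert np.allclose(rho, rho0, rtol=1e-13)
        assert np.allclose(u, u0, atol=1e-15)

    def test_matches_brute_force_loops(self, rng):
        f = rng.uniform(0.01, 0.2, size=19)
        rho, u = lf.compute_moments(f)
        rho_ref = sum(f[i] for i in range(19))
        u_ref = sum(f[i] * lf.D3Q19.e[i] for i in range(19)) / rho_ref
        assert rho == pytest.approx(rho_ref, rel=1e-14)
        assert np.allclose(u, u_ref, rtol=1e-13)

    def test_rejects_nonpositive_density(self):
        with pytest.raises(InvalidStateError):
            lf.compute_moments(-lf.D3Q19.w)


class TestCollision:
    def _random_field(self, rng, shape=(4, 4, 4)):
        fld = lf.FluidField(shape)
        fld.f = rng.uniform(0.01, 0.1, size=fld.f.shape)
        return fld

    def test_equilibrium_is_fixed_point(self, rng):
        fld = lf.FluidField((3, 3, 3))
        u = np.full((3, 3, 3, 3), 0.01)
        fld.set_equilibrium(1.1, u)
        before = fld.f.copy()
        for tau in (0.6, 1.0, 1.7):
            lf.bgk_collide(fld, tau)
            assert np.allclose(fld.f, before, atol=1e-15)

    def test_mass_and_momentum_conserved(self, rng):
        fld = self._random_field(rng)
        rho0, u0 = lf.compute_moments(fld.f)
        lf.bgk_collide(fld, tau=0.8)
        rho1, u1 = lf.compute_moments(fld.f)
        assert np.allclose(rho1, rho0, rtol=1e-12)
        assert np.allclose(u1 * rho1, u0 * rho0, atol=1e-14)

    def test_tau_one_lands_exactly_on_equilibrium(self, rng):
        fld = self._random_field(rng, shape=(1, 1, 1))
        rho, u = lf.compute_moments(fld.f)
        lf.bgk_collide(fld, tau=1.0)
        assert np.allclose(fld.f, lf.equilibrium_distribution(rho, u), rtol=1e-13)

    def test_rejects_unstable_tau(self, rng):
        with pytest.raises(StabilityError):
            lf.bgk_collide(self._random_field(rng), tau=0.5)


class TestStreaming:
    def test_uniform_field_unchanged(self):
        fld = lf.FluidField((4, 4, 4))
        fld.set_equilibrium(1.0, np.zeros((3, 4, 4, 4)))
        before = fld.f.copy()
        lf.stream_periodic(fld)
        assert np.array_equal(fld.f, before)

    def test_tracer_moves_one_link_every_direction(self):
        for i in range(1, 19):
            fld = lf.FluidField((4, 4, 4))
            fld.f[i, 1, 2, 3] = 1.0
            lf.stream_periodic(fld)
            target = (np.array([1, 2, 3]) + lf.D3Q19.e[i]) % 4
            assert fld.f[i, target[0], target[1], target[2]] == 1.0
            assert fld.f.sum() == 1.0

    def test_mass_conserved_over_100_steps(self, rng):
        fld = lf.FluidField((5, 5, 5))
        fld.f = rng.uniform(0.01, 0.1, size=fld.f.shape)
        m0 = fld.f.sum()
        for _ in range(100):
            lf.stream_periodic(fld)
        assert abs(fld.f.sum() - m0) / m0 < 1e-12


class TestBounceBack:
    def _channel(self, ny=22):
        # plane walls at y=0 and y=ny-1, periodic x/z
        flags = np.zeros((4, ny, 4), dtype=np.uint8)
        flags[:, 0, :] = lf.WALL
        flags[:, -1, :] = lf.WALL
        fld = lf.FluidField(flags.shape, flags)
        fld.set_equilibrium(1.0, np.zeros((3, *flags.shape)))
        return fld

    def test_mass_conserved_in_closed_channel(self, rng):
        fld = self._channel(ny=8)
        fld.f[:, fld.fluid_mask] *= rng.uniform(0.9, 1.1, size=fld.f[:, fld.fluid_mask].shape)
        m0 = fld.total_mass()
        for _ in range(50):
            lf.fluid_step(fld, tau=0.9)
        assert abs(fld.total_mass() - m0) / m0 < 1e-12

    def test_wall_normal_velocity_suppressed(self):
        fld = self._channel(ny=8)
        u = np.zeros((3, *fld.shape))
        u[1] = 0.01  # uniform flow toward the +y wall
        fld.set_equilibrium(1.0, u)
        for _ in range(20):
            lf.fluid_step(fld, tau=1.0)
        _, u = fld.moments()
        # wall-adjacent normal velocity is driven toward zero (no slip)
        assert np.abs(u[1][:, 1, :]).max() < 0.5 * 0.01
        assert np.abs(u[1][:, -2, :]).max() < 0.5 * 0.01

    def test_forced_channel_matches_plane_poiseuille(self):
        """Body-forced flow between plates converges to the parabola."""
        ny = 22  # 20 fluid nodes across
        fld = self._channel(ny=ny)
        g = 1e-6
        tau = 1.0
        nu = (tau - 0.5) / 3.0
        # analytic steady profile (halfway walls at y=0.5, ny-1.5; width h)
        y = np.arange(ny)
        h = ny - 2
        yc = y - 0.5
        u_an_full = np.clip(g / (2 * nu) * yc * (h - yc), 0.0, None)
        u0 = np.zeros((3, *fld.shape))
        u0[2] = u_an_full[None, :, None]
        fld.set_equilibrium(1.0, u0)
        for _ in range(1200):  # settle the discrete steady state
            lf.fluid_step(fld, tau, body_accel=(0.0, 0.0, g))
        _, u = fld.moments()
        uz = u[2][1, 1:-1, 1]
        u_an = u_an_full[1:-1]
        assert np.abs(uz - u_an).max() / u_an.max() < 0.02


class TestBodyForce:
    def test_zero_force_is_identity(self, rng):
        fld = lf.FluidField((3, 3, 3))
        fld.f = rng.uniform(0.01, 0.1, size=fld.f.shape)
        before = fld.f.copy()
        lf.apply_body_force(fld, np.zeros(3))
        assert np.array_equal(fld.f, before)

    def test_adds_exactly_rho_g_momentum(self, rng):
        fld = lf.FluidField((3, 3, 3))
        fld.set_equilibrium(1.0, np.zeros((3, 3, 3, 3)))
        g = np.array([1e-5, -2e-5, 3e-5])
        rho0, u0 = fld.moments()
        lf.apply_body_force(fld, g)
        rho1, u1 = fld.moments()
        assert np.allclose(rho1, rho0, rtol=1e-13)
        assert np.allclose((u1 - u0) * rho1, np.broadcast_to(g[:, None, None, None], u1.shape),
                           rtol=1e-10)

    def test_steady_flow_linear_in_forcing(self):
        # doubling g doubles the steady plane-channel u_max within 1%
        maxes = []
        for g in (5e-7, 1e-6):
            flags = np.zeros((3, 12, 3), dtype=np.uint8)
            flags[:, 0, :] = lf.WALL
            flags[:, -1, :] = lf.WALL
            fld = lf.FluidField(flags.shape, flags)
            fld.set_equilibrium(1.0, np.zeros((3, *flags.shape)))
            for _ in range(1500):
                lf.fluid_step(fld, 1.0, body_accel=(0.0, 0.0, g))
            _, u = fld.moments()
            maxes.append(u[2][fld.fluid_mask].max())
        assert maxes[1] / maxes[0] == pytest.approx(2.0, rel=0.01)


class TestInitializePoiseuille:
    def _setup(self, re=0.025):
        from ctcsim.scenario_geometry import VesselGeometry, build_vessel

        geom = VesselGeometry(diameter=10.0, length=4.0, dx=0.5)
        cfg = lf.LatticeConfig(shape=(0, 0, 0), dx=0.5, tau=1.0, re=re)
        return cfg, geom, build_vessel(geom)

    def test_profile_and_reynolds(self):
        cfg, geom, vessel = self._setup()
        fld = lf.initialize_poiseuille(cfg, geom)
        _, u = fld.moments()
        R = vessel.radius_nodes
        u_max = u[2][fld.fluid_mask].max()
        # Re recomputed from the field
        re = u_max * (2 * R) / cfg.nu_lattice
        assert re == pytest.approx(0.025, abs=1e-6)
        # parabola: u(R/2) = 0.75 u_max, u(wall) ~ 0
        x, y, z = vessel.node_coordinates()
        r = np.sqrt((x - vessel.axis_xy[0]) ** 2 + (y - vessel.axis_xy[1]) ** 2)
        mid = np.isclose(r, R / 2, atol=0.05) & fld.fluid_mask
        assert np.allclose(u[2][mid], 0.75 * u_max, rtol=0.02)

    def test_unstable_reynolds_raises(self):
        cfg, geom, _ = self._setup(re=2000.0)
        with pytest.raises(StabilityError):
            lf.initialize_poiseuille(cfg, geom)


class TestLatticeConfig:
    def test_viscosity_relation_and_roundtrip(self):
        cfg = lf.LatticeConfig(shape=(4, 4, 4), dx=0.5, tau=0.9)
        assert cfg.nu_lattice == pytest.approx((0.9 - 0.5) / 3.0, rel=1e-15)
        # diffusive scaling roundtrip: nu_phys = nu_lat dx^2/dt
        assert cfg.nu_lattice * cfg.dx_m**2 / cfg.dt == pytest.approx(cfg.nu_phys, rel=1e-12)

    def test_tau_must_exceed_half(self):
        with pytest.raises(StabilityError):
            lf.LatticeConfig(shape=(2, 2, 2), tau=0.5)


class TestFusedKernel:
    def test_matches_reference_step(self, rng):
        flags = np.zeros((6, 6, 6), dtype=np.uint8)
        flags[:, 0, :] = lf.WALL
        flags[2, 3, 2] = lf.WALL  # interior obstacle
        a = lf.FluidField(flags.shape, flags)
        a.set_equilibrium(1.0, np.zeros((3, *flags.shape)))
        a.f[:, a.fluid_mask] *= rng.uniform(0.95, 1.05, size=a.f[:, a.fluid_mask].shape)
        b = a.copy()
        force = np.zeros((3, *flags.shape))
        force[:, a.fluid_mask] = 1e-6 * rng.standard_normal((3, int(a.fluid_mask.sum())))
        g = (1e-7, 0.0, 2e-6)
        buf = None
        for _ in range(3):
            lf.fluid_step(a, 0.8, force=force.copy(), body_accel=g)
            b, buf = fused_fluid_step(b, 0.8, force=force.copy(), body_accel=g, buffer=buf)
        assert np.allclose(a.f, b.f, atol=1e-14)


def test_global_mass_conservation_1000_steps(rng):
    fld = lf.FluidField((6, 6, 6))
    fld.f = lf.equilibrium_distribution(
        rng.uniform(0.9, 1.1, size=(6, 6, 6)), rng.uniform(-0.02, 0.02, size=(3, 6, 6, 6))
    )
    m0 = fld.f.sum()
    buf = None
    for _ in range(1000):
        fld, buf = fused_fluid_step(fld, 0.9, buffer=buf)
    assert abs(fld.f.sum() - m0) / m0 < 1e-10
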