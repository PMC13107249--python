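"""Lattice-Boltzmann kernel correctness, boundaries, and voxelization."""

import warnings

import numpy as np
import pytest
import trimesh

from airwayflow import flow_lbm as fl


def _random_f(shape=(50,), scale=0.02, seed=0):
    rng = np.random.default_rng(seed)
    return np.tile(fl.W.reshape(19, *([1] * len(shape))), (1, *shape)) * (
        1.0 + scale * rng.standard_normal((19, *shape))
    )


class TestLatticeSpec:
    def test_weight_identities_hold(self):
        spec = fl.LatticeSpec(dx=0.5, dt=1e-4, tau=0.8)
        assert spec.nu_lattice == pytest.approx((0.8 - 0.5) / 3.0)

    def test_subcritical_tau_rejected(self):
        with pytest.raises(ValueError, match="0.5"):
            fl.LatticeSpec(dx=0.5, dt=1e-4, tau=0.5)


class TestEquilibrium:
    def test_rest_state_is_weights(self):
        feq = fl.equilibrium(np.ones(1), np.zeros((3, 1)))
        assert np.allclose(feq[:, 0], fl.W, atol=1e-15)
        assert feq.sum() == pytest.approx(1.0, abs=1e-14)

    def test_moment_identities(self):
        rng = np.random.default_rng(1)
        rho = 1.0 + 0.05 * rng.standard_normal(40)
        u = 0.05 * rng.standard_normal((3, 40))
        feq = fl.equilibrium(rho, u)
        assert np.allclose(feq.sum(axis=0), rho, atol=1e-14)
        mom = np.tensordot(fl.C.astype(float).T, feq, axes=(1, 0))
        assert np.allclose(mom, rho * u, atol=1e-14)

    def test_rest_population_at_u01(self):
        feq = fl.equilibrium(np.ones(1), np.array([[0.1], [0.0], [0.0]]))
        assert feq[0, 0] == pytest.approx((1.0 / 3.0) * (1.0 - 0.015), abs=1e-15)


class TestCollisions:
    def test_equilibrium_fixed_point(self):
        feq = fl.equilibrium(np.ones(30), 0.03 * np.ones((3, 30)))
        out = fl.collide_srt(feq, 0.77)
        assert np.allclose(out, feq, atol=1e-14)

    def test_conservation(self):
        f = _random_f()
        out = fl.collide_srt(f, 0.66)
        assert np.allclose(out.sum(axis=0), f.sum(axis=0), atol=1e-13)
        mom_in = np.tensordot(fl.C.astype(float).T, f, axes=(1, 0))
        mom_out = np.tensordot(fl.C.astype(float).T, out, axes=(1, 0))
        assert np.allclose(mom_in, mom_out, atol=1e-13)

    def test_full_relaxation_at_tau_one(self):
        f = _random_f(seed=2)
        rho, u, _ = fl.macroscopics(f)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            feq = fl.equilibrium(rho, u)
        assert np.allclose(fl.collide_srt(f, 1.0), feq, atol=1e-15)

    def test_mrt_with_equal_rates_matches_srt(self):
        f = _random_f(seed=3)
        tau = 0.73
        a = fl.collide_srt(f, tau)
        b = fl.collide_mrt(f, np.full(19, 1.0 / tau))
        assert np.abs(a - b).max() < 1e-12

    def test_mrt_equilibrium_fixed_point(self):
        feq = fl.equilibrium(np.ones(10), 0.02 * np.ones((3, 10)))
        out = fl.collide_mrt(feq, fl.default_mrt_rates(0.8))
        assert np.allclose(out, feq, atol=1e-13)

    def test_mrt_rate_out_of_range_rejected(self):
        rates = fl.default_mrt_rates(0.8)
        rates[9] = 2.5
        with pytest.raises(ValueError, match="\\(0, 2\\)"):
            fl.collide_mrt(_random_f(), rates)


class TestStreaming:
    def test_single_population_advects_one_link(self):
        f = np.zeros((19, 5, 5, 5))
        f[1, 2, 2, 2] = 1.0  # c_1 = (+1, 0, 0)
        out = fl.stream(f)
        assert out[1, 3, 2, 2] == 1.0
        assert out.sum() == 1.0

    def test_closed_box_mass_conserved(self):
        solid = np.zeros((8, 8, 8), bool)
        for axis in range(3):
            sl = [slice(None)] * 3
            sl[axis] = 0
            solid[tuple(sl)] = True
            sl[axis] = -1
            solid[tuple(sl)] = True
        f = _random_f((8, 8, 8), scale=0.05, seed=4)
        fluid = ~solid
        m0 = f[:, fluid].sum()
        for _ in range(500):
            f = fl.collide_srt(f, 0.7)
            f = fl.stream(f, solid)
        assert abs(f[:, fluid].sum() - m0) / m0 < 1e-12

    def test_uniform_flow_in_periodic_box_is_steady(self):
        u0 = np.full((3, 6, 6, 6), 0.04)
        f = fl.equilibrium(np.ones((6, 6, 6)), u0)
        g = f.copy()
        for _ in range(20):
            g = fl.stream(fl.collide_srt(g, 0.8))
        assert np.allclose(g, f, atol=1e-13)

    def test_channel_poiseuille_two_percent(self):
        """Body-force plane channel, 21 nodes across: <=2% max profile error."""
        ny = 23
        solid = np.zeros((2, ny, 2), bool)
        solid[:, 0, :] = True
        solid[:, -1, :] = True
        f = np.tile(fl.W.reshape(19, 1, 1, 1), (1, 2, ny, 2))
        F = np.array([1e-6, 0.0, 0.0])
        for _ in range(6000):
            f = fl.collide_srt(f, 0.8, force=F)
            f = fl.stream(f, solid)
        _, u, _ = fl.macroscopics(f, force=F)
        ux = u[0, 0, 1:-1, 0]
        H = ny - 2
        nu = (0.8 - 0.5) / 3.0
        yy = np.arange(H) + 0.5
        ana = F[0] / (2 * nu) * yy * (H - yy)
        assert np.abs(ux - ana).max() / ana.max() <= 0.02


class TestMacroscopics:
    def test_rest_weights(self):
        f = fl.W.reshape(19, 1)
        rho, u, p = fl.macroscopics(f)
        assert rho[0] == pytest.approx(1.0)
        assert np.allclose(u, 0.0, atol=1e-16)
        assert p[0] == pytest.approx(0.0, abs=1e-15)

    def test_pressure_from_density(self):
        feq = fl.equilibrium(np.array([1.02]), np.zeros((3, 1)))
        _, _, p = fl.macroscopics(feq)
        assert p[0] == pytest.approx(fl.CS2 * 0.02, abs=1e-14)

    def test_nonpositive_density_aborts(self):
        f = -fl.W.reshape(19, 1)
        with pytest.raises(FloatingPointError):
            fl.macroscopics(f)


class TestVoxelize:
    def test_cylinder_slice_counts(self):
        dx = 1.0
        cyl = trimesh.creation.cylinder(radius=5 * dx, height=30 * dx, sections=128)
        cyl.apply_translation([0, 0, 15 * dx])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            lat = fl.voxelize(cyl, dx)
        per = (lat.occupancy != fl.SOLID).sum(axis=(0, 1))
        counts = per[per > 0]
        assert np.all(np.abs(counts.astype(int) - np.pi * 25) <= 3)

    def test_sphere_volume(self):
        sph = trimesh.creation.icosphere(subdivisions=3, radius=10.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            lat = fl.voxelize(sph, 1.0)
        assert lat.n_fluid == pytest.approx(4.0 / 3.0 * np.pi * 1000, rel=0.05)

    def test_translation_changes_only_boundary_voxels(self):
        dx = 1.0
        cyl = trimesh.creation.cylinder(radius=5 * dx, height=20 * dx, sections=128)
        cyl.apply_translation([0, 0, 10 * dx])
        moved = cyl.copy()
        moved.apply_translation([dx / 2, dx / 2, 0])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = fl.voxelize(cyl, dx)
            b = fl.voxelize(moved, dx)
        # surface-voxel budget: perimeter x height
        budget = int(2 * np.pi * 5 * 20 * 1.5)
        assert abs(a.n_fluid - b.n_fluid) <= budget

    def test_non_watertight_rejected(self):
        cyl = trimesh.creation.cylinder(radius=3, height=10, sections=32)
        broken = trimesh.Trimesh(
            vertices=cyl.vertices, faces=cyl.faces[:-5], process=False
        )
        with pytest.raises(ValueError, match="watertight"):
            fl.voxelize(broken, 1.0)


class TestOscillatoryMode:
    def test_short_period_cycle_average_is_finite(self):
        """Pulsatile inflow over a (shortened) breathing cycle runs stably."""
        dx = 0.5
        cyl = trimesh.creation.cylinder(radius=2.6, height=12.0, sections=64)
        cyl.apply_translation([0, 0, 6.0])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            lat = fl.voxelize(cyl, dx)
            cfg = fl.SimConfig(re_target=20.0, u_lat=0.05, collision="srt",
                               ramp_steps=100, n_cycles=2)
            spec, _ = fl.derive_units(lat, 1.0, cfg)
            cfg.period_s = 1200 * spec.dt  # shortened cycle for the smoke test
            field = fl.run_simulation(lat, 1.0, mode="oscillatory", config=cfg)
        assert field.meta["mode"] == "oscillatory"
        fluid = lat.fluid_mask
        assert np.isfinite(field.rho[fluid]).all()
        assert np.isfinite(field.u[2][fluid]).all()
        # cycle-averaged axial flow is positive (pulsatile, never reversed)
        assert np.nanmean(field.u[2][fluid]) > 0

    def test_unknown_mode_rejected(self):
        occ = np.zeros((4, 4, 4), np.uint8)
        with pytest.raises(ValueError, match="mode"):
            fl.run_simulation(fl.VoxelLattice(occ, 1.0), 1.0, mode="pulsed")


class TestDeriveUnits:
    def _tube_lattice(self, n_inlet_cells=630, dx=0.5, length=20):
        nx = 30
        ny = 21
        occ = np.zeros((nx + 2, ny + 2, length), np.uint8)
        occ[1:-1, 1:-1, :] = fl.FLUID
        lat = fl.VoxelLattice(occ, dx)
        lat.classify_ends()
        return lat

    def test_flow_rate_maps_to_mean_inlet_speed(self):
        """9.45 L/min across 157.5 mm^2 gives exactly 1 m/s."""
        lat = self._tube_lattice()
        assert (lat.occupancy == fl.INLET).sum() == 630
        _, meta = fl.derive_units(lat, 9.45, fl.SimConfig())
        assert meta["inlet_area_mm2"] == pytest.approx(157.5)
        assert meta["u_inlet_phys_m_s"] == pytest.approx(1.0)

    def test_reynolds_and_tau_logged_consistently(self):
        lat = self._tube_lattice()
        cfg = fl.SimConfig(re_target=150.0, u_lat=0.05)
        spec, meta = fl.derive_units(lat, 5.0, cfg)
        assert meta["reynolds"] == pytest.approx(150.0)
        # tau consistent with the viscosity mapping
        nu_lat = meta["nu_sim_mm2_s"] * meta["dt_s"] / meta["dx_mm"] ** 2
        assert spec.tau == pytest.approx(3 * nu_lat + 0.5)

    def test_nonpositive_inflow_rejected(self):
        with pytest.raises(ValueError):
            fl.derive_units(self._tube_lattice(), 0.0, fl.SimConfig())
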