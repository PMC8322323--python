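"""Membrane model: mesh construction, force channels, stretch test."""

import numpy as np
import pytest

from ctcsim import membrane_mechanics as mm
from ctcsim.errors import ConvergenceError, DegenerateGeometryError, ParameterError

CHANNELS = {
    "link": dict(k_link=5.0, k_bend=0, k_area_local=0, k_area_global=0, k_volume=0),
    "bending": dict(k_link=0, k_bend=5.0, k_area_local=0, k_area_global=0, k_volume=0),
    "area_local": dict(k_link=0, k_bend=0, k_area_local=5.0, k_area_global=0, k_volume=0),
    "area_global": dict(k_link=0, k_bend=0, k_area_local=0, k_area_global=5.0, k_volume=0),
    "volume": dict(k_link=0, k_bend=0, k_area_local=0, k_area_global=0, k_volume=5.0),
}

FORCE_FN = {
    "link": mm.link_forces,
    "bending": mm.bending_forces,
    "area_local": mm.area_forces,
    "area_global": mm.area_forces,
    "volume": mm.volume_forces,
}


@pytest.fixture()
def perturbed(sphere42, rng):
    mesh = sphere42.copy()
    ref = mm.ReferenceState.from_mesh(mesh)
    mesh.vertices = mesh.vertices + 0.03 * rng.standard_normal(mesh.vertices.shape)
    return mesh, ref


class TestIcosphere:
    @pytest.mark.parametrize("target", [12, 42, 162, 642])
    def test_exact_subdivision_counts(self, target):
        mesh = mm.build_icosphere_mesh(4.0, target)
        assert mesh.n_vertices == target
        assert mesh.euler_characteristic == 2

    def test_trimmed_count_1382_is_reachable(self):
        """The tumor-cell resolution sits between subdivision levels."""
        mesh = mm.build_icosphere_mesh(8.0, 1382)
        assert mesh.n_vertices == 1382
        assert mesh.euler_characteristic == 2
        radii = np.linalg.norm(mesh.vertices, axis=1)
        assert np.abs(radii - 4.0).max() < 0.005 * 4.0
        assert mesh.diameter() == pytest.approx(8.0, abs=0.04)

    def test_volume_close_to_analytic_sphere(self):
        mesh = mm.build_icosphere_mesh(8.0, 1382)
        v_sphere = 4.0 / 3.0 * np.pi * 4.0**3
        assert abs(mesh.volume() - v_sphere) / v_sphere < 0.01

    def test_watertight_per_trimesh(self):
        import trimesh

        mesh = mm.build_icosphere_mesh(8.0, 300)
        tm = trimesh.Trimesh(mesh.vertices, mesh.faces, process=False)
        assert tm.is_watertight and tm.is_winding_consistent

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ParameterError):
            mm.build_icosphere_mesh(-1.0, 42)
        with pytest.raises(ParameterError):
            mm.build_icosphere_mesh(8.0, 5)

    def test_oblate_and_biconcave_shapes(self):
        plt = mm.build_oblate_mesh(2.0, aspect=0.5, target_vertices=42)
        assert plt.euler_characteristic == 2
        spans = plt.vertices.max(axis=0) - plt.vertices.min(axis=0)
        assert spans[2] == pytest.approx(0.5 * spans[0], rel=1e-6)
        rbc = mm.build_biconcave_mesh(7.82, target_vertices=162)
        assert rbc.euler_characteristic == 2
        # dimple: the axis is thinner than the rim region
        r = np.linalg.norm(rbc.vertices[:, :2], axis=1)
        axis_thickness = rbc.vertices[r < 1.0, 2].max() - rbc.vertices[r < 1.0, 2].min()
        max_thickness = rbc.vertices[:, 2].max() - rbc.vertices[:, 2].min()
        assert axis_thickness < 0.6 * max_thickness


class TestForceChannels:
    @pytest.mark.parametrize("name", list(CHANNELS))
    def test_zero_at_reference_state(self, sphere42, name):
        ref = mm.ReferenceState.from_mesh(sphere42)
        mat = mm.MaterialModel(**CHANNELS[name])
        f = FORCE_FN[name](sphere42, ref, mat)
        assert np.abs(f).max() < 1e-10

    @pytest.mark.parametrize("name", list(CHANNELS))
    def test_force_is_minus_energy_gradient(self, perturbed, rng, name):
        """Central-difference oracle for every channel's analytic gradient."""
        mesh, ref = perturbed
        mat = mm.MaterialModel(**CHANNELS[name])
        f = FORCE_FN[name](mesh, ref, mat)
        h = 1e-6
        for _ in range(8):
            vi = rng.integers(mesh.n_vertices)
            c = rng.integers(3)
            m2 = mesh.copy()
            m2.vertices[vi, c] += h
            ep = mm.membrane_energy(m2, ref, mat)
            m2.vertices[vi, c] -= 2 * h
            em = mm.membrane_energy(m2, ref, mat)
            fnum = -(ep - em) / (2 * h)
            assert f[vi, c] == pytest.approx(fnum, rel=2e-4, abs=1e-7)

    @pytest.mark.parametrize("name", list(CHANNELS))
    def test_momentum_free(self, perturbed, name):
        mesh, ref = perturbed
        f = FORCE_FN[name](mesh, ref, mm.MaterialModel(**CHANNELS[name]))
        assert np.abs(f.sum(axis=0)).max() < 1e-10 * max(np.abs(f).sum(), 1e-30)

    @pytest.mark.parametrize("name", list(CHANNELS))
    def test_torque_free(self, perturbed, name):
        mesh, ref = perturbed
        f = FORCE_FN[name](mesh, ref, mm.MaterialModel(**CHANNELS[name]))
        torque = np.cross(mesh.vertices - mesh.centroid(), f).sum(axis=0)
        assert np.abs(torque).max() < 1e-8 * max(np.abs(f).max(), 1e-30)

    def test_link_force_linear_regime_and_antisymmetry(self, sphere42):
        ref = mm.ReferenceState.from_mesh(sphere42)
        mat = mm.MaterialModel(**CHANNELS["link"], strain_max=2.0)
        mesh = sphere42.copy()
        # stretch radially by 1%: every edge strain ~ 0.01
        mesh.vertices = mesh.vertices * 1.01
        f = mm.link_forces(mesh, ref, mat)
        d = mesh.edge_vectors()[0] / np.linalg.norm(mesh.edge_vectors()[0])
        # per-edge tension = k * strain * (1 + o(1))
        strain = mesh.edge_lengths() / ref.rest_lengths - 1.0
        assert np.allclose(strain, 0.01, atol=1e-12)
        # forces point inward (restoring) on an inflated sphere
        nhat = mesh.vertices / np.linalg.norm(mesh.vertices, axis=1)[:, None]
        assert (np.einsum("ij,ij->i", f, nhat) < 0).all()

    def test_link_divergence_factor_caps_with_warning(self, sphere42):
        ref = mm.ReferenceState.from_mesh(sphere42)
        mat = mm.MaterialModel(**CHANNELS["link"], strain_max=0.5, link_force_cap=100.0)
        mesh = sphere42.copy()
        mesh.vertices = mesh.vertices * 1.5  # strain 0.5 == saturation
        with pytest.warns(RuntimeWarning):
            f = mm.link_forces(mesh, ref, mat)
        assert np.isfinite(f).all()

    def test_bending_opposes_outward_dimple(self, sphere42):
        ref = mm.ReferenceState.from_mesh(sphere42)
        mat = mm.MaterialModel(**CHANNELS["bending"])
        mesh = sphere42.copy()
        disp = np.zeros_like(mesh.vertices)
        nhat = mesh.vertices[0] / np.linalg.norm(mesh.vertices[0])
        disp[0] = 0.05 * nhat
        mesh.vertices = mesh.vertices + disp
        f = mm.bending_forces(mesh, ref, mat)
        assert f[0] @ nhat < 0  # pushes the spike back

    def test_area_forces_oppose_inflation(self, sphere42):
        ref = mm.ReferenceState.from_mesh(sphere42)
        mat = mm.MaterialModel(**CHANNELS["area_local"])
        mesh = sphere42.copy()
        mesh.vertices = mesh.vertices * 1.05
        f = mm.area_forces(mesh, ref, mat)
        nhat = mesh.vertices / np.linalg.norm(mesh.vertices, axis=1)[:, None]
        assert (np.einsum("ij,ij->i", f, nhat) < 0).all()

    def test_volume_forces_oppose_shrinkage(self, sphere42):
        ref = mm.ReferenceState.from_mesh(sphere42)
        mat = mm.MaterialModel(**CHANNELS["volume"])
        mesh = sphere42.copy()
        mesh.vertices = mesh.vertices * 0.98
        f = mm.volume_forces(mesh, ref, mat)
        nhat = mesh.vertices / np.linalg.norm(mesh.vertices, axis=1)[:, None]
        assert (np.einsum("ij,ij->i", f, nhat) > 0).all()

    def test_total_equals_sum_of_channels(self, perturbed):
        mesh, ref = perturbed
        mat = mm.MaterialModel(
            k_link=5, k_bend=2, k_area_local=3, k_area_global=1, k_volume=4
        )
        total, mag, integral = mm.total_membrane_force(mesh, ref, mat)
        parts = (
            mm.link_forces(mesh, ref, mat)
            + mm.bending_forces(mesh, ref, mat)
            + mm.area_forces(mesh, ref, mat)
            + mm.volume_forces(mesh, ref, mat)
        )
        assert np.allclose(total, parts, atol=1e-12)
        assert np.allclose(mag, np.linalg.norm(parts, axis=1), atol=1e-12)
        # integral consistent with a direct weighted sum
        w = mesh.vertex_areas() / mesh.total_area() * mesh.n_vertices
        assert integral == pytest.approx(float((mag * w).sum()), rel=1e-12)

    def test_stiffness_scaling_is_exact(self, perturbed):
        mesh, ref = perturbed
        mat = mm.MaterialModel(k_link=5, k_bend=2, k_area_local=3, k_area_global=1, k_volume=4)
        f1, _, _ = mm.total_membrane_force(mesh, ref, mat)
        f2, _, _ = mm.total_membrane_force(mesh, ref, mat.scaled(1.3))
        assert np.allclose(f2, 1.3 * f1, rtol=1e-12)


class TestReferenceState:
    def test_recomputation_reproduces_stored_values(self, sphere162):
        ref = mm.ReferenceState.from_mesh(sphere162)
        ref2 = mm.ReferenceState.from_mesh(sphere162)
        assert np.allclose(ref.rest_lengths, ref2.rest_lengths, rtol=1e-12)
        assert ref.rest_volume == pytest.approx(ref2.rest_volume, rel=1e-12)

    def test_open_mesh_rejected(self, sphere42):
        with pytest.raises(DegenerateGeometryError):
            mm.CellMesh(sphere42.vertices, sphere42.faces[:-1])


class TestRelaxationAndStretch:
    def test_free_relaxation_preserves_volume(self, sphere42, rng):
        mesh = sphere42.copy()
        ref = mm.ReferenceState.from_mesh(mesh)
        mat = mm.MaterialModel(k_link=20, k_bend=2, k_area_local=10, k_area_global=10, k_volume=50)
        mesh.vertices = mesh.vertices + 0.02 * rng.standard_normal(mesh.vertices.shape)
        mm.relax_to_equilibrium(mesh, ref, mat, residual_tol=0.05)
        assert abs(mesh.volume() - ref.rest_volume) / ref.rest_volume < 0.01

    def test_nonconvergence_raises_with_residual(self, sphere42):
        mesh = sphere42.copy()
        ref = mm.ReferenceState.from_mesh(mesh)
        mat = mm.MaterialModel(k_link=20)
        ext = np.zeros_like(mesh.vertices)
        ext[0, 0] = 50.0  # unbalanced external force: no equilibrium exists
        with pytest.raises(ConvergenceError) as exc:
            mm.relax_to_equilibrium(mesh, ref, mat, ext, max_iter=50)
        assert exc.value.residual is not None

    def test_stretch_curve_monotone_and_zero_at_rest(self, sphere162, ctc_material):
        curve = mm.stretch_test(
            sphere162, ctc_material, max_force=1000.0, n_levels=4,
            solver_opts={"residual_tol": 0.5},
        )
        assert curve.aspect_ratio[0] == pytest.approx(0.0, abs=1e-3)
        assert (np.diff(curve.aspect_ratio) > -1e-4).all()
        assert (np.diff(curve.aspect_ratio) > 0).sum() >= 3

    def test_rejects_nonpositive_force(self, sphere162, ctc_material):
        with pytest.raises(ParameterError):
            mm.stretch_test(sphere162, ctc_material, max_force=0.0)


class TestCalibratedStretchEndpoint:
    def test_taylor_ratio_at_2000_pN(self, stretch_curves):
        """The calibrated 8 um tumor cell reaches aspect ratio ~0.31."""
        c8 = stretch_curves[8.0]
        assert c8.forces[-1] == 2000.0
        assert c8.aspect_ratio[-1] == pytest.approx(0.31, abs=0.02)

    def test_max_nodal_force_positive_and_finite(self, stretch_curves):
        c8 = stretch_curves[8.0]
        assert np.isfinite(c8.max_nodal_force).all()
        assert c8.max_nodal_force[-1] > 0
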