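"""Finite-element core: element stiffness, patch behaviour, nonlinear solves."""

import numpy as np
import pytest

from conftest import elastic_material, uniform_material
from oracles import DenseNonlinearFE, brute_force_element_stiffness
from tbfe.errors import AnchoringError, ConvergenceError
from tbfe.materials import ElementMaterial, material_from_ash, swift_voce_stress
from tbfe.mesh import build_mesh
from tbfe.solver import (LoadCase, SolverSettings, element_stiffness,
                         reaction_forces, solve_displacement_controlled,
                         solve_load_case, von_mises)


def scalar_material(E=1000.0, S_max=10.0, S_sat=6.0):
    return uniform_material(1, E=E, S_max=S_max, S_sat=S_sat).take(0)


class TestVonMises:
    def test_uniaxial(self):
        assert von_mises([5.0, 0, 0, 0, 0, 0]) == pytest.approx(5.0)

    def test_hydrostatic_is_zero(self):
        assert von_mises([3.0, 3.0, 3.0, 0, 0, 0]) == pytest.approx(0.0, abs=1e-12)

    def test_pure_shear(self):
        assert von_mises([0, 0, 0, 2.0, 0, 0]) == pytest.approx(np.sqrt(3) * 2.0)

    def test_nonnegative_on_random_tensors(self, rng):
        s = rng.normal(size=(100, 6))
        assert np.all(von_mises(s) >= 0)


class TestElementStiffness:
    @pytest.fixture(params=["full", "b_bar"])
    def K(self, request):
        return element_stiffness(scalar_material(E=2500.0), 0.15,
                                 quadrature=request.param)

    def test_symmetric(self, K):
        assert np.abs(K - K.T).max() < 1e-12 * np.abs(K).max()

    def test_rigid_body_modes_are_zero_energy(self, K):
        for d in range(3):
            u = np.zeros(24)
            u[d::3] = 1.0  # rigid translation
            assert np.abs(K @ u).max() < 1e-9 * np.abs(K).max()

    def test_positive_semidefinite_with_6_zero_modes(self, K):
        w = np.linalg.eigvalsh(K)
        scale = w.max()
        assert np.all(w > -1e-10 * scale)
        assert (np.abs(w) < 1e-9 * scale).sum() == 6

    def test_full_quadrature_matches_brute_force_4x4x4_oracle(self):
        E, nu, h = 2500.0, 0.3, 0.15
        K = element_stiffness(scalar_material(E=E), h, quadrature="full")
        K_ref = brute_force_element_stiffness(E, nu, h, n_gauss=4)
        np.testing.assert_allclose(np.sort(np.linalg.eigvalsh(K)),
                                   np.sort(np.linalg.eigvalsh(K_ref)),
                                   rtol=1e-6, atol=1e-9 * np.abs(K_ref).max())
        np.testing.assert_allclose(K, K_ref, rtol=1e-6,
                                   atol=1e-9 * np.abs(K_ref).max())

    def test_scales_linearly_with_modulus_and_edge(self):
        K1 = element_stiffness(scalar_material(E=1000.0), 0.1)
        K2 = element_stiffness(scalar_material(E=2000.0), 0.1)
        K3 = element_stiffness(scalar_material(E=1000.0), 0.2)
        np.testing.assert_allclose(K2, 2 * K1, rtol=1e-12)
        np.testing.assert_allclose(K3, 2 * K1, rtol=1e-12)

    def test_per_gauss_tangent_moduli_accepted(self):
        from tbfe.elements import elastic_moduli_matrix
        D = np.stack([elastic_moduli_matrix(1000.0, 0.3)] * 8)
        Ka = element_stiffness(scalar_material(E=1000.0), 0.15,
                               tangent_moduli=D, quadrature="full")
        Kb = element_stiffness(scalar_material(E=1000.0), 0.15, quadrature="full")
        np.testing.assert_allclose(Ka, Kb, rtol=1e-12)


class TestPatchAndLinearity:
    def test_linear_field_reproduced_on_2x2x2_mesh(self, rng):
        """Constant-strain patch test: boundary-driven linear displacement
        field is reproduced exactly at the interior node."""
        mesh = build_mesh(np.ones((2, 2, 2), bool), 150.0)
        mat = elastic_material(mesh.n_elements, E=1234.0)
        A = rng.normal(0, 1e-3, (3, 3))
        c = rng.normal(0, 1e-3, 3)
        exact = mesh.node_coords @ A.T + c
        interior = [i for i, x in enumerate(mesh.node_coords)
                    if np.all((x > 0) & (x < mesh.node_coords.max(0)))]
        assert len(interior) == 1
        boundary = np.setdiff1d(np.arange(mesh.n_nodes), interior)
        dofs = np.concatenate([boundary * 3 + d for d in range(3)])
        vals = np.concatenate([exact[boundary, d] for d in range(3)])
        states = solve_displacement_controlled(mesh, mat, dofs, vals,
                                               n_substeps=1)
        got = states[-1].nodal_displacements
        scale = np.abs(exact).max()
        np.testing.assert_allclose(got, exact, atol=1e-9 * scale)
        # constant stress across all elements (uniform material)
        sig = states[-1].stress
        assert np.abs(sig - sig[0]).max() < 1e-9 * np.abs(sig).max()

    def test_heterogeneous_mesh_reproduces_prescribed_constant_strain(self, rng):
        """With every node prescribed, arbitrary per-element densities must
        still measure the exact constant strain of a linear field."""
        mesh = build_mesh(np.ones((2, 2, 2), bool), 150.0)
        mat = material_from_ash(rng.uniform(0.1, 1.2, mesh.n_elements))
        A = rng.normal(0, 1e-3, (3, 3))
        exact = mesh.node_coords @ A.T
        dofs = np.arange(3 * mesh.n_nodes)
        states = solve_displacement_controlled(mesh, mat, dofs, exact.ravel(),
                                               n_substeps=1)
        eps_sym = 0.5 * (A + A.T)
        expected_vm = von_mises(np.array([
            eps_sym[0, 0], eps_sym[1, 1], eps_sym[2, 2],
            2 * eps_sym[0, 1], 2 * eps_sym[1, 2], 2 * eps_sym[2, 0]]))
        del expected_vm  # stresses differ per element; strains must not
        got = states[-1].nodal_displacements
        np.testing.assert_allclose(got, exact, atol=1e-12)

    def test_homogeneous_column_closed_form(self, column_mesh):
        """Validation-BC compression of a uniform column: von Mises = E*eps
        everywhere and displacements linear in z."""
        E = 1700.0
        mat = elastic_material(column_mesh.n_elements, E=E)
        states = solve_load_case(column_mesh, mat,
                                 LoadCase(bc_mode="validation", n_substeps=2))
        s = states[-1]
        np.testing.assert_allclose(s.von_mises, E * 0.001, rtol=1e-9)
        uz = s.nodal_displacements[:, 2]
        z = column_mesh.node_coords[:, 2]
        np.testing.assert_allclose(uz, -0.001 * z, atol=1e-12)

    def test_elastic_solution_scales_linearly_with_strain(self):
        mesh = build_mesh(np.ones((3, 3, 3), bool), 150.0)
        mat = elastic_material(mesh.n_elements,
                               E=np.linspace(500, 5000, mesh.n_elements))
        s1 = solve_load_case(mesh, mat, LoadCase(total_strain=0.001, n_substeps=2))[-1]
        s2 = solve_load_case(mesh, mat, LoadCase(total_strain=0.002, n_substeps=2))[-1]
        np.testing.assert_allclose(s2.nodal_displacements,
                                   2 * s1.nodal_displacements, atol=1e-12)
        np.testing.assert_allclose(s2.von_mises, 2 * s1.von_mises, rtol=1e-9)

    def test_global_equilibrium_of_reactions(self):
        mesh = build_mesh(np.ones((4, 4, 4), bool), 150.0)
        mat = elastic_material(mesh.n_elements,
                               E=np.linspace(100, 8000, mesh.n_elements))
        state = solve_load_case(mesh, mat, LoadCase(n_substeps=1))[-1]
        f = reaction_forces(mesh, mat, state)
        z = mesh.node_coords[:, 2]
        bottom = np.isclose(z, z.min())
        top = np.isclose(z, z.max())
        f_bot = f[bottom].sum(axis=0)
        f_top = f[top].sum(axis=0)
        np.testing.assert_allclose(f_bot, -f_top,
                                   atol=0.005 * np.linalg.norm(f_top))


class TestNonlinearSolver:
    def test_3x3x3_matches_dense_brute_force_oracle(self):
        """Sparse consistent-tangent solve vs dense modified-Newton oracle."""
        rng = np.random.default_rng(7)
        mask = np.ones((3, 3, 3), bool)
        mesh = build_mesh(mask, 500.0)
        ne = mesh.n_elements
        E = rng.uniform(800.0, 4000.0, ne)
        S_max = E * rng.uniform(2e-4, 5e-4, ne) / 1.0  # yields within 0.1%
        S_sat = 0.7 * S_max
        mat = ElementMaterial(E=E, S_max=S_max, S_sat=S_sat, eps_el=S_max / E,
                              R1=S_sat - S_max)
        settings = SolverSettings(force_tol=1e-9, disp_tol=1e-9,
                                  quadrature="full", max_newton_iters=60)
        case = LoadCase(total_strain=0.001, n_substeps=4)
        states = solve_load_case(mesh, mat, case, settings)
        assert states[-1].eq_plastic_strain.max() > 0  # genuinely nonlinear

        from tbfe.solver import _build_bcs
        dofs, vals, _, _ = _build_bcs(mesh, case)
        mats = [{"E": E[e], "S_max": S_max[e], "R1": S_sat[e] - S_max[e],
                 "R2": 0.0, "b": 10.0, "eps_el": S_max[e] / E[e]}
                for e in range(ne)]
        oracle = DenseNonlinearFE(mask, 0.5, mats)
        hist = oracle.solve(dict(zip(dofs.tolist(), vals.tolist())),
                            n_substeps=4, tol=1e-12)
        u_o, sig_o = hist[-1]
        u_p = states[-1].nodal_displacements.ravel()
        scale = np.abs(u_o).max()
        np.testing.assert_allclose(u_p, u_o, atol=1e-8 * scale)
        vm_o = von_mises(sig_o)
        np.testing.assert_allclose(states[-1].von_mises, vm_o,
                                   rtol=1e-6, atol=1e-6 * vm_o.max())

    def test_single_softening_element_converges_and_tracks_curve(self, column_mesh):
        mat = uniform_material(column_mesh.n_elements, E=1000.0,
                               S_max=10.0, S_sat=6.0)
        case = LoadCase(bc_mode="validation", total_strain=0.51, n_substeps=60)
        states = solve_load_case(column_mesh, mat, case)
        one = mat.take(0)
        for s in states:
            ref = float(swift_voce_stress(one, s.applied_strain))
            assert s.von_mises.mean() == pytest.approx(ref, rel=5e-3)

    def test_substep_insensitivity_in_small_strain_regime(self):
        """50 vs 100 sub-steps change the extracted modulus by < 0.1%."""
        from tbfe.loading import curve_from_states, extract_modulus
        mesh = build_mesh(np.ones((2, 2, 2), bool), 150.0)
        ne = mesh.n_elements
        rng = np.random.default_rng(3)
        E = rng.uniform(1000, 3000, ne)
        S_max = E * 5e-4   # yield midway through the ramp
        S_sat = 0.8 * S_max
        mat = ElementMaterial(E=E, S_max=S_max, S_sat=S_sat,
                              eps_el=S_max / E, R1=S_sat - S_max)
        secants, slopes = [], []
        for n in (50, 100):
            st = solve_load_case(mesh, mat, LoadCase(total_strain=0.001, n_substeps=n))
            c = curve_from_states(mesh, st, "compression")
            secants.append(c.stresses[-1] / c.strains[-1])
            slopes.append(extract_modulus(c).modulus)
        # the stress integrator is sub-step-insensitive to < 0.1%; the window
        # heuristic adds its own (larger) sampling sensitivity
        assert abs(secants[1] - secants[0]) / secants[0] < 1e-3
        assert abs(slopes[1] - slopes[0]) / slopes[0] < 5e-3

    def test_cg_and_direct_agree(self):
        mesh = build_mesh(np.ones((3, 3, 4), bool), 150.0)
        mat = elastic_material(mesh.n_elements,
                               E=np.linspace(500, 5000, mesh.n_elements))
        sd = solve_load_case(mesh, mat, LoadCase(n_substeps=1),
                             SolverSettings(linear_solver="direct"))[-1]
        sc = solve_load_case(mesh, mat, LoadCase(n_substeps=1),
                             SolverSettings(linear_solver="cg", cg_tol=1e-12))[-1]
        np.testing.assert_allclose(sc.nodal_displacements, sd.nodal_displacements,
                                   atol=1e-8 * np.abs(sd.nodal_displacements).max())

    def test_updated_geometry_option_stays_close_at_small_strain(self, column_mesh):
        mat = elastic_material(column_mesh.n_elements, E=2000.0)
        a = solve_load_case(column_mesh, mat, LoadCase(n_substeps=5))[-1]
        b = solve_load_case(column_mesh, mat, LoadCase(n_substeps=5),
                            SolverSettings(geometric_nonlinearity=True))[-1]
        assert b.von_mises.mean() == pytest.approx(a.von_mises.mean(), rel=5e-3)

    def test_unanchored_mesh_raises(self):
        mask = np.zeros((1, 1, 4), bool)
        mask[0, 0, 1:] = True  # column floats above an empty bottom layer? no:
        # meshing trims to occupied region, so build a truly split mesh instead
        mask = np.zeros((3, 1, 3), bool)
        mask[0, 0, :] = True           # anchored column
        mask[2, 0, 2] = True           # floating voxel, disconnected
        mesh = build_mesh(mask, 150.0)
        mat = elastic_material(mesh.n_elements)
        with pytest.raises((AnchoringError, ConvergenceError)):
            solve_load_case(mesh, mat, LoadCase(n_substeps=1))

    def test_prescribed_nodes_carry_exact_values(self, column_mesh):
        mat = elastic_material(column_mesh.n_elements)
        state = solve_load_case(column_mesh, mat, LoadCase(n_substeps=1))[-1]
        z = column_mesh.node_coords[:, 2]
        top = np.isclose(z, z.max())
        height = z.max() - z.min()
        np.testing.assert_array_equal(
            state.nodal_displacements[top, 2], -0.001 * height)
        np.testing.assert_array_equal(
            state.nodal_displacements[np.isclose(z, z.min())], 0.0)
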