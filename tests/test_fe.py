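"""FE homogenization: mesh construction, embedded ties, periodic
constraints, the closed-form oracle, bounds and averaging identities."""

import math

import numpy as np
import pytest

from axonrve.errors import ConvergenceError, ParameterError
from axonrve.fe import (
    MacroDeformation,
    assemble_pbc,
    build_host_mesh,
    embed_fibers,
    face_traction_asymmetry,
    hill_mandel_gap,
    homogenize_stress,
    localized_metrics,
    solve_quasistatic,
)
from axonrve.materials import ConstituentSet, study_constituents, uniaxial_nominal_stress
from axonrve.rve import FiberSpec, RveGeometry
from axonrve.surrogate import affine_axial_stress


class TestHostMesh:
    def test_structured_counts(self):
        mesh = build_host_mesh(8.0, 2)
        assert len(mesh.elems) == 8
        assert mesh.n_nodes == 27

    def test_element_volumes_fill_cube(self):
        mesh = build_host_mesh(5.0, 3)
        assert mesh.element_volumes().sum() == pytest.approx(5.0**3, rel=1e-12)

    def test_every_boundary_node_paired_once_per_direction(self):
        mesh = build_host_mesh(4.0, 3)
        for d in range(3):
            pairs = mesh.boundary_pairs(d)
            assert len(pairs) == (mesh.n + 1) ** 2
            slaves = [s for s, _ in pairs]
            assert len(set(slaves)) == len(slaves)
            for s, m in pairs:
                dx = mesh.nodes[s] - mesh.nodes[m]
                assert dx[d] == pytest.approx(mesh.edge)

    def test_invalid_density_rejected(self):
        with pytest.raises(ParameterError):
            build_host_mesh(4.0, 0)


class TestEmbedding:
    def test_element_center_weights(self):
        mesh = build_host_mesh(4.0, 2)
        geom = RveGeometry(
            edge=4.0,
            fibers=[FiberSpec((0.0, 1.0, 1.0), (1.0, 0, 0), 0.5,
                              (((0.0, 1.0, 1.0), (4.0, 1.0, 1.0)),))],
            target_vf=0, nominal_vf=0, effective_vf=0,
        )
        fib = embed_fibers(mesh, geom, resolution=2.0)
        # node at (1, 1, 1) is an element center of the 2x2x2 grid
        center = np.where(np.all(np.isclose(fib.positions, [1.0, 1.0, 1.0]), axis=1))[0]
        assert len(center) == 1
        assert np.allclose(fib.weights[center[0]], 1.0 / 8.0, atol=1e-12)

    def test_partition_of_unity(self, small_rve):
        mesh = build_host_mesh(small_rve.edge, 4)
        fib = embed_fibers(mesh, small_rve)
        assert np.allclose(fib.weights.sum(axis=1), 1.0, atol=1e-12)

    def test_ties_reproduce_affine_fields(self, small_rve):
        """Interpolated displacement at every tied node equals a random
        affine host field evaluated at the node position."""
        mesh = build_host_mesh(small_rve.edge, 4)
        fib = embed_fibers(mesh, small_rve)
        rng = np.random.default_rng(2)
        A = rng.normal(size=(3, 3))
        b = rng.normal(size=3)
        u_host = mesh.nodes @ A.T + b
        u_tied = np.einsum("fa,fai->fi", fib.weights, u_host[fib.host_nodes])
        expected = fib.positions @ A.T + b
        assert np.allclose(u_tied, expected, atol=1e-10)


class TestPbc:
    def test_constraint_count_matches_paired_dofs(self):
        mesh = build_host_mesh(4.0, 3)
        cons = assemble_pbc(mesh)
        n_paired_nodes = mesh.n_nodes - mesh.n_classes
        assert cons.n_constraints == 3 * n_paired_nodes

    def test_affine_field_satisfies_constraints_identically(self):
        mesh = build_host_mesh(4.0, 2)
        cons = assemble_pbc(mesh)
        F = np.array([[1.1, 0.02, 0.0], [0.01, 0.95, 0.0], [0.0, 0.0, 1.03]])
        u = mesh.nodes @ (F - np.eye(3)).T  # zero fluctuation
        res = cons.residuals(u, F, mesh.nodes)
        assert np.max(np.abs(res)) < 1e-12

    def test_traction_antisymmetry_after_solve(self, solved_fiber_rve):
        """Averaged face tractions satisfy t+ = -t- within 1%."""
        out = face_traction_asymmetry(solved_fiber_rve)
        assert out["worst_rel_asymmetry"] < 0.01


class TestSolver:
    def test_identity_load_gives_zero_state(self, control_constituents):
        mesh = build_host_mesh(4.0, 2)
        sol = solve_quasistatic(
            mesh, None, control_constituents,
            MacroDeformation(stretch=1.0 + 1e-12, n_steps=1, mode="prescribed",
                             lambda_transverse=1.0),
        )
        assert np.abs(sol.final.fluct).max() < 1e-10
        assert np.abs(sol.final.P_bar).max() < 1e-6 * control_constituents.ecm.mu

    @pytest.mark.parametrize("group", ["control", "preconditioned"])
    def test_homogeneous_material_matches_closed_form(self, group):
        """Equal constituents (mu* = 0): homogenized P11 within 1% of the
        incompressible uniaxial Ogden closed form at 20% strain."""
        cs = study_constituents(group)
        homog = ConstituentSet.from_moduli(cs.ecm.mu, cs.ecm.mu, cs.alpha)
        mesh = build_host_mesh(4.0, 2)
        sol = solve_quasistatic(mesh, None, homog,
                                MacroDeformation(stretch=1.2, n_steps=5))
        got = homogenize_stress(sol).nominal_stress[-1]
        ref = uniaxial_nominal_stress(cs.ecm, 1.2)
        assert got == pytest.approx(ref, rel=0.01)

    def test_homogeneous_material_third_parameter_set(self):
        cs = ConstituentSet.from_moduli(300.0, 300.0, 8.0)
        mesh = build_host_mesh(4.0, 2)
        sol = solve_quasistatic(mesh, None, cs, MacroDeformation(stretch=1.2, n_steps=5))
        got = homogenize_stress(sol).nominal_stress[-1]
        assert got == pytest.approx(uniaxial_nominal_stress(cs.ecm, 1.2), rel=0.01)

    def test_single_aligned_fiber_reproduces_voigt_mixture_exactly(
        self, control_constituents
    ):
        """One spanning axial fiber admits the uniform-field exact solution:
        FE equals (1-Vf) P_m(mu_ecm) + Vf P_f(mu_axon)."""
        a, d = 4.0, 1.0
        vf = math.pi * d * d / 4 * a / a**3
        geom = RveGeometry(
            edge=a,
            fibers=[FiberSpec((0.0, 1.7, 2.3), (1.0, 0, 0), d,
                              (((0.0, 1.7, 2.3), (a, 1.7, 2.3)),))],
            target_vf=vf, nominal_vf=vf, effective_vf=vf,
        )
        mesh = build_host_mesh(a, 4)
        sol = solve_quasistatic(mesh, embed_fibers(mesh, geom), control_constituents,
                                MacroDeformation(stretch=1.2, n_steps=5))
        fe = homogenize_stress(sol).nominal_stress[-1]
        cs = control_constituents
        voigt = (1 - vf) * uniaxial_nominal_stress(cs.ecm, 1.2) + vf * uniaxial_nominal_stress(cs.axon, 1.2)
        assert fe == pytest.approx(voigt, rel=1e-3)

    def test_fiber_reinforced_response_is_bounded(self, solved_fiber_rve, small_rve,
                                                  control_constituents):
        """Matrix-only < homogenized < Voigt bound (aligned surrogate at the
        same effective Vf)."""
        resp = homogenize_stress(solved_fiber_rve)
        lam = resp.stretch[1:]
        matrix_only = uniaxial_nominal_stress(control_constituents.ecm, lam)
        voigt = affine_axial_stress(
            control_constituents, np.array([[1.0, 0.0, 0.0]]),
            [small_rve.effective_vf], lam,
        )
        assert np.all(resp.nominal_stress[1:] > matrix_only)
        assert np.all(resp.nominal_stress[1:] <= voigt * (1 + 1e-6))

    def test_zero_stress_at_unit_stretch(self, solved_fiber_rve):
        resp = homogenize_stress(solved_fiber_rve)
        assert resp.stretch[0] == 1.0
        assert resp.nominal_stress[0] == 0.0


class TestAveraging:
    def test_hill_mandel_gap_small(self, solved_fiber_rve, solved_homogeneous):
        for sol in (solved_fiber_rve, solved_homogeneous):
            assert hill_mandel_gap(sol, rng_seed=0) < 1e-3

    def test_homogeneous_state_average_equals_pointwise(self, solved_homogeneous):
        """Uniform field: sigma_max/sigma_avg = 1, average = pointwise."""
        m = localized_metrics(solved_homogeneous)
        assert m["sigma_max_over_avg"] == pytest.approx(1.0, rel=1e-9)

    def test_heterogeneous_state_localizes(self, solved_fiber_rve):
        m = localized_metrics(solved_fiber_rve)
        assert m["sigma_max_over_avg"] > 1.0

    def test_refusal_on_unconverged_input(self, solved_homogeneous):
        import copy

        bad = copy.copy(solved_homogeneous)
        bad.steps = [
            type(s)(**{**s.__dict__, "converged": False}) for s in solved_homogeneous.steps
        ]
        with pytest.raises(ConvergenceError):
            homogenize_stress(bad)

    def test_overall_stress_approximately_mesh_independent(self, small_rve,
                                                           control_constituents):
        """Fixed geometry, refined host grid: homogenized stress stable."""
        vals = []
        for n in (2, 4):
            mesh = build_host_mesh(small_rve.edge, n)
            sol = solve_quasistatic(mesh, embed_fibers(mesh, small_rve),
                                    control_constituents,
                                    MacroDeformation(stretch=1.2, n_steps=4))
            vals.append(homogenize_stress(sol).nominal_stress[-1])
        assert abs(vals[1] - vals[0]) / vals[0] < 0.05
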