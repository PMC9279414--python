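"""Stabilized FEM solver: analytic benchmarks, conservation, equivariance,
and the unsteady generalized-alpha path."""

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.optimize import brentq

from ostiaflow import (CarreauParams, FlowSolution, NewtonianParams,
                       SolverOptions, carreau_viscosity, outlet_flux,
                       residual_norm, solve_steady, solve_unsteady)
from ostiaflow.errors import StateError, ValidationError
from ostiaflow.flow_solver import ConvergenceRecord
from ostiaflow.geometry import (CYL_OUTLET, CYL_WALL, VolumeMesh,
                                build_cylinder_mesh)
from tests.conftest import DP, L_CYL, MU_NEWT, R_CYL, cylinder_bcs


class TestNullForcing:
    def test_equal_pressures_and_static_wall_give_rest(self, cylinder_mesh_coarse):
        bcs = cylinder_bcs(p_in=5.0, p_out=5.0, wall_speed=0.0)
        opts = SolverOptions(nonlinear_tol=1e-8)
        sol = solve_steady(cylinder_mesh_coarse, bcs, NewtonianParams(MU_NEWT),
                           opts)
        assert sol.convergence.converged
        assert np.abs(sol.velocity).max() < 1e-9
        assert np.abs(sol.pressure - 5.0).max() < 1e-6


class TestPoiseuilleBenchmark:
    def test_centerline_velocity(self, poiseuille_solution, poiseuille_analytic):
        mesh = poiseuille_solution.mesh
        r = np.hypot(mesh.nodes[:, 0], mesh.nodes[:, 1])
        z = mesh.nodes[:, 2]
        sel = (r < R_CYL / 6) & (z > L_CYL / 3) & (z < 2 * L_CYL / 3)
        umax = poiseuille_solution.velocity[sel, 2].max()
        assert umax == pytest.approx(poiseuille_analytic.u_max, rel=0.05)

    def test_flow_rate(self, poiseuille_solution, poiseuille_analytic):
        Q = outlet_flux(poiseuille_solution, CYL_OUTLET)
        assert Q == pytest.approx(poiseuille_analytic.Q, rel=0.05)

    def test_mass_conservation(self, poiseuille_solution):
        net, gross = poiseuille_solution.mass_balance()
        assert abs(net) / gross < 1e-3

    def test_dirichlet_wall_exact(self, poiseuille_solution):
        mesh = poiseuille_solution.mesh
        wall_nodes = np.unique(mesh.boundary_tris[mesh.patch_faces(CYL_WALL)])
        assert np.abs(poiseuille_solution.velocity[wall_nodes]).max() == 0.0


class TestCarreauChannel:
    def test_profile_matches_1d_bvp_oracle(self):
        """Pressure-driven pipe flow of a Carreau fluid against an
        independent 1D two-point BVP oracle (per-radius root-find for the
        slope, quadrature for the profile)."""
        params = CarreauParams()
        mesh = build_cylinder_mesh(R_CYL, L_CYL, R_CYL / 5.0)
        sol = solve_steady(mesh, cylinder_bcs(), params)
        assert sol.convergence.converged

        def slope(r):
            if r == 0.0:
                return 0.0
            rhs = DP * r / (2 * L_CYL)
            return brentq(lambda s: carreau_viscosity(
                s / np.sqrt(2.0), params) * s - rhs, 0.0, 1e7, xtol=1e-14)

        def u_oracle(r):
            return quad(slope, r, R_CYL, limit=200)[0]

        r = np.hypot(mesh.nodes[:, 0], mesh.nodes[:, 1])
        z = mesh.nodes[:, 2]
        sel = (z > L_CYL / 3) & (z < 2 * L_CYL / 3)
        uo = np.array([u_oracle(x) for x in r[sel]])
        err = np.abs(sol.velocity[sel, 2] - uo) / uo.max()
        assert err.max() < 0.03

    def test_viscosity_field_bounded_by_asymptotes(self):
        params = CarreauParams()
        mesh = build_cylinder_mesh(R_CYL, 1.0e-3, R_CYL / 4.0)
        sol = solve_steady(mesh, cylinder_bcs(), params)
        mu = sol.element_viscosity()
        assert mu.min() >= params.mu_inf - 1e-15
        assert mu.max() <= params.mu0 + 1e-15


class TestOutletFlux:
    def test_zero_field_zero_flux(self, cylinder_mesh_coarse):
        sol = _manual_solution(cylinder_mesh_coarse,
                               np.zeros((cylinder_mesh_coarse.n_nodes, 3)))
        assert outlet_flux(sol, CYL_OUTLET) == 0.0

    def test_uniform_axial_speed(self, cylinder_mesh_coarse):
        U = 7.0e-3
        u = np.zeros((cylinder_mesh_coarse.n_nodes, 3))
        u[:, 2] = U
        sol = _manual_solution(cylinder_mesh_coarse, u)
        patch_area = cylinder_mesh_coarse.patch_area(CYL_OUTLET)
        assert outlet_flux(sol, CYL_OUTLET) == pytest.approx(
            U * patch_area, rel=1e-12)
        # patch area itself approximates pi R^2 to discretization accuracy
        assert patch_area == pytest.approx(np.pi * R_CYL**2, rel=0.02)

    def test_poiseuille_flow_rate_closed_form(self, poiseuille_solution,
                                              poiseuille_analytic):
        assert outlet_flux(poiseuille_solution, CYL_OUTLET) == pytest.approx(
            poiseuille_analytic.Q, rel=0.05)

    def test_unknown_patch_rejected(self, poiseuille_solution):
        with pytest.raises(KeyError):
            outlet_flux(poiseuille_solution, 99)


class TestResidualNorm:
    def test_first_iterate_is_unity(self, poiseuille_solution):
        assert poiseuille_solution.convergence.residual_history[0] == 1.0

    def test_converged_below_tolerance(self, poiseuille_solution):
        assert residual_norm(poiseuille_solution) < 1e-3

    def test_before_any_assembly_is_state_error(self):
        with pytest.raises(StateError):
            residual_norm(ConvergenceRecord())


class TestRotationEquivariance:
    def test_rotated_configuration_rotates_velocity(self, cylinder_mesh_coarse):
        bcs = cylinder_bcs()
        base = solve_steady(cylinder_mesh_coarse, bcs, NewtonianParams(MU_NEWT))
        th = np.deg2rad(30.0)
        R = np.array([[1, 0, 0],
                      [0, np.cos(th), -np.sin(th)],
                      [0, np.sin(th), np.cos(th)]])
        m = cylinder_mesh_coarse
        rotated = VolumeMesh(
            nodes=m.nodes @ R.T, tets=m.tets.copy(),
            boundary_tris=m.boundary_tris.copy(),
            boundary_labels=m.boundary_labels.copy(),
            characteristic_edge_length=m.characteristic_edge_length,
            patch_names=dict(m.patch_names))
        sol_r = solve_steady(rotated, bcs, NewtonianParams(MU_NEWT))
        umax = np.linalg.norm(base.velocity, axis=1).max()
        diff = np.linalg.norm(sol_r.velocity - base.velocity @ R.T, axis=1)
        assert diff.max() < 0.01 * umax
        assert np.abs(sol_r.pressure - base.pressure).max() < 0.01 * DP


class TestUnsteadyGeneralizedAlpha:
    MESH_KW = dict(radius=R_CYL, length=0.8e-3, edge_length=R_CYL / 3.0)

    def test_mode_and_end_time_required(self, cylinder_mesh_coarse):
        with pytest.raises(ValidationError):
            solve_unsteady(cylinder_mesh_coarse, cylinder_bcs(),
                           NewtonianParams(MU_NEWT), SolverOptions())

    def test_terminal_state_matches_steady(self):
        mesh = build_cylinder_mesh(**self.MESH_KW)
        bcs = cylinder_bcs()
        steady = solve_steady(mesh, bcs, NewtonianParams(MU_NEWT))
        # viscous time constant rho R^2 / mu ~ 0.02 s; march well past it
        opts = SolverOptions(mode="unsteady", time_step=4e-3, end_time=0.12)
        snaps = solve_unsteady(mesh, bcs, NewtonianParams(MU_NEWT), opts)
        rel = np.linalg.norm(snaps[-1].velocity - steady.velocity) \
            / np.linalg.norm(steady.velocity)
        assert rel < 0.02

        # halving the step leaves the (steady) terminal state unchanged
        opts2 = SolverOptions(mode="unsteady", time_step=2e-3, end_time=0.12)
        snaps2 = solve_unsteady(mesh, bcs, NewtonianParams(MU_NEWT), opts2)
        rel2 = np.linalg.norm(snaps2[-1].velocity - snaps[-1].velocity) \
            / np.linalg.norm(snaps[-1].velocity)
        assert rel2 < 0.01

    def test_zero_driving_stays_at_rest(self):
        mesh = build_cylinder_mesh(**self.MESH_KW)
        bcs = cylinder_bcs(p_in=0.0, p_out=0.0)
        opts = SolverOptions(mode="unsteady", time_step=4e-3, end_time=0.02)
        snaps = solve_unsteady(mesh, bcs, NewtonianParams(MU_NEWT), opts)
        assert all(np.abs(s.velocity).max() < 1e-12 for s in snaps)


def _manual_solution(mesh, velocity):
    return FlowSolution(
        mesh=mesh, velocity=velocity, pressure=np.zeros(mesh.n_nodes),
        rheology=NewtonianParams(MU_NEWT), density=1060.0,
        options=SolverOptions(),
        convergence=ConvergenceRecord(iterations=1, residual_history=[0.0],
                                      converged=True))
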