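"""WSS extraction, ostial averaging, comparison metrics, Womersley number."""

import numpy as np
import pytest

from ostiaflow import (NewtonianParams, SolverOptions, percent_reduction,
                       solve_steady, womersley_number)
from ostiaflow.errors import RegionError, StateError, ValidationError
from ostiaflow.flow_solver import ConvergenceRecord, FlowSolution
from ostiaflow.geometry import CYL_WALL
from ostiaflow.wss_postprocess import (OstialRegion, WSSField,
                                       regional_mean_wss, wall_shear_stress)
from tests.conftest import L_CYL, MU_NEWT, cylinder_bcs

WOMERSLEY_EMBRYO = 0.347354818635316   # R=0.25 mm, 240 bpm, 1060 kg/m3, mu0


class TestWallShearStress:
    def test_quiescent_solution_has_zero_wss(self, cylinder_mesh_coarse):
        sol = solve_steady(cylinder_mesh_coarse,
                           cylinder_bcs(p_in=0.0, p_out=0.0),
                           NewtonianParams(MU_NEWT))
        wss = wall_shear_stress(sol)
        assert wss.wss_pa.max() < 1e-12

    def test_poiseuille_wall_wss_closed_form(self, poiseuille_solution,
                                             poiseuille_analytic):
        wss = wall_shear_stress(poiseuille_solution, patch_label=CYL_WALL,
                                recovery=True)
        # evaluate away from the traction end faces
        z = wss.centroids[:, 2]
        sel = (z > L_CYL / 4) & (z < 3 * L_CYL / 4)
        mean = np.sum(wss.areas[sel] * wss.wss_pa[sel]) / np.sum(wss.areas[sel])
        assert mean == pytest.approx(poiseuille_analytic.wall_wss, rel=0.05)
        # cgs is exactly ten times the Pa value
        np.testing.assert_allclose(wss.wss_cgs, 10.0 * wss.wss_pa, rtol=0.0)

    def test_refuses_non_converged_solution(self, cylinder_mesh_coarse):
        sol = FlowSolution(
            mesh=cylinder_mesh_coarse,
            velocity=np.zeros((cylinder_mesh_coarse.n_nodes, 3)),
            pressure=np.zeros(cylinder_mesh_coarse.n_nodes),
            rheology=NewtonianParams(MU_NEWT), density=1060.0,
            options=SolverOptions(),
            convergence=ConvergenceRecord(iterations=200,
                                          residual_history=[1.0, 0.5],
                                          converged=False))
        with pytest.raises(StateError, match="non-converged"):
            wall_shear_stress(sol)

    def test_wss_magnitude_rotation_invariant(self, poiseuille_solution):
        # tangential traction magnitude must not depend on where on the
        # circumference a face sits (axisymmetric flow)
        wss = wall_shear_stress(poiseuille_solution, patch_label=CYL_WALL)
        z = wss.centroids[:, 2]
        sel = (z > L_CYL / 3) & (z < 2 * L_CYL / 3)
        vals = wss.wss_pa[sel]
        assert vals.std() / vals.mean() < 0.15


def _uniform_wss_field(values, areas):
    k = len(values)
    return WSSField(
        patch_label=CYL_WALL, face_indices=np.arange(k),
        traction=np.zeros((k, 3)), wss_vector=np.zeros((k, 3)),
        wss_pa=np.asarray(values, dtype=float) / 10.0,   # cgs -> Pa
        areas=np.asarray(areas, dtype=float),
        centroids=np.zeros((k, 3)))


class TestRegionalMeanWss:
    REGION = OstialRegion("test", np.zeros(3), 1.0)

    def test_constant_field_returns_value(self):
        f = _uniform_wss_field([12.5] * 7, [3.0e-9] * 7)
        assert regional_mean_wss(f, self.REGION) == pytest.approx(12.5)

    def test_equal_area_two_face_mean(self):
        f = _uniform_wss_field([10.0, 30.0], [2.0e-9, 2.0e-9])
        assert regional_mean_wss(f, self.REGION) == pytest.approx(20.0)

    def test_area_weighting(self):
        f = _uniform_wss_field([10.0, 30.0], [3.0e-9, 1.0e-9])
        assert regional_mean_wss(f, self.REGION) == pytest.approx(15.0)

    def test_mean_between_min_and_max(self, poiseuille_solution):
        wss = wall_shear_stress(poiseuille_solution, patch_label=CYL_WALL)
        region = OstialRegion("mid", np.array([0.0, 0.0, L_CYL / 2]), L_CYL / 4)
        m = regional_mean_wss(wss, region)
        sel = region.select(wss)
        assert wss.wss_cgs[sel].min() <= m <= wss.wss_cgs[sel].max()

    def test_empty_region_rejected(self):
        f = _uniform_wss_field([10.0], [1.0e-9])
        far = OstialRegion("far", np.array([1.0, 1.0, 1.0]), 1e-6)
        with pytest.raises(RegionError):
            regional_mean_wss(f, far)


class TestPercentReduction:
    def test_reported_ostial_case(self):
        # the 82 -> 55 cgs drop rounds to the reported ~33%
        assert percent_reduction(82.0, 55.0) == pytest.approx(32.9, abs=0.05)

    def test_identity_gives_zero(self):
        assert percent_reduction(42.0, 42.0) == 0.0

    def test_total_loss_gives_hundred(self):
        assert percent_reduction(17.0, 0.0) == 100.0

    def test_nonpositive_control_rejected(self):
        with pytest.raises(ValidationError):
            percent_reduction(0.0, 1.0)


class TestWomersleyNumber:
    def test_embryonic_aortic_value(self):
        assert womersley_number(0.25e-3, 240.0, 1060.0, 1.38e-2) \
            == pytest.approx(WOMERSLEY_EMBRYO, rel=1e-9)

    def test_zero_heart_rate_limit(self):
        assert womersley_number(0.25e-3, 0.0, 1060.0, 1.38e-2) == 0.0

    def test_linear_in_radius(self):
        a = womersley_number(0.25e-3, 240.0, 1060.0, 1.38e-2)
        assert womersley_number(0.5e-3, 240.0, 1060.0, 1.38e-2) \
            == pytest.approx(2 * a, rel=1e-12)

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValidationError):
            womersley_number(-1.0, 240.0, 1060.0, 1e-3)
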