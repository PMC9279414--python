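"""Shared fixtures: analytic cylinder benchmarks and the root comparison.

Expensive flow solutions are session-scoped so benchmark, conservation and
comparison tests share them.
"""

from __future__ import annotations

import pytest

from ostiaflow import (BoundaryConditionSet, CarreauParams, HemodynamicsConfig,
                       NewtonianParams, PressureOutlet, WallMotion,
                       assemble_bcs, build_root_geometry, mesh_geometry,
                       solve_steady)
from ostiaflow.geometry import (CYL_INLET, CYL_OUTLET, CYL_WALL,
                                build_cylinder_mesh)
from ostiaflow.synthetic_data import generate_geometry_pair, poiseuille_fixture
from ostiaflow.wss_postprocess import (ostial_region, regional_mean_wss,
                                       wall_shear_stress)

# Poiseuille benchmark scale: embryonic-aorta-like pipe
R_CYL = 0.25e-3
L_CYL = 2.0e-3
DP = 10.0
MU_NEWT = 3.03e-3

#: default desk-scale target edge length for the root (< coronary_diameter/3)
ROOT_EDGE = 4.8e-5


def cylinder_bcs(p_in=DP, p_out=0.0, wall_speed=0.0):
    return BoundaryConditionSet(
        descriptors={CYL_WALL: WallMotion(wall_speed),
                     CYL_INLET: PressureOutlet(p_in),
                     CYL_OUTLET: PressureOutlet(p_out)},
        wall_normal_speed=wall_speed, murray_constant=0.0, R_eq=0.0)


@pytest.fixture(scope="session")
def poiseuille_analytic():
    return poiseuille_fixture(R_CYL, L_CYL, DP, MU_NEWT)


@pytest.fixture(scope="session")
def cylinder_mesh_fine():
    return build_cylinder_mesh(R_CYL, L_CYL, R_CYL / 6.0)


@pytest.fixture(scope="session")
def poiseuille_solution(cylinder_mesh_fine):
    sol = solve_steady(cylinder_mesh_fine, cylinder_bcs(), NewtonianParams(MU_NEWT))
    assert sol.convergence.converged
    return sol


@pytest.fixture(scope="session")
def cylinder_mesh_coarse():
    return build_cylinder_mesh(R_CYL, 1.0e-3, R_CYL / 4.0)


def solve_root_scenario(geom_config, edge_length=ROOT_EDGE, rheology=None,
                        hemo=None):
    """Mesh and solve one root scenario; returns (geom, mesh, bcs, solution,
    LCA-ostial mean WSS in cgs)."""
    hemo = hemo or HemodynamicsConfig()
    rheology = rheology or CarreauParams()
    geom = build_root_geometry(geom_config)
    mesh = mesh_geometry(geom, edge_length)
    bcs = assemble_bcs(mesh, hemo, geom_config)
    sol = solve_steady(mesh, bcs, rheology, density=hemo.density)
    ostial = None
    if sol.convergence.converged:
        wss = wall_shear_stress(sol)
        ostial = regional_mean_wss(wss, ostial_region(geom, "LCA"))
    return geom, mesh, bcs, sol, ostial


@pytest.fixture(scope="session")
def root_pair_default():
    """Control and displaced-LCO scenarios solved at the default desk-scale
    density with Carreau rheology."""
    control_cfg, mutant_cfg = generate_geometry_pair()
    out = {}
    for label, cfg in (("control", control_cfg), ("mutant", mutant_cfg)):
        geom, mesh, bcs, sol, ostial = solve_root_scenario(cfg)
        assert sol.convergence.converged, f"{label} solve did not converge"
        out[label] = {"config": cfg, "geom": geom, "mesh": mesh, "bcs": bcs,
                      "solution": sol, "ostial_wss_cgs": ostial}
    return out
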