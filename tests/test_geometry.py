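"""Parametric root geometry, meshing, and mesh validation."""

import dataclasses

import numpy as np
import pytest

from ostiaflow.errors import (GeometryConflictError, ValidationError)
from ostiaflow.geometry import (AORTIC_OUTLET, LCA_OUTLET, RCA_OUTLET, WALL,
                                GeometryConfig, VolumeMesh,
                                build_cylinder_mesh, build_root_geometry,
                                displace_lco, mesh_geometry, validate_mesh)
from tests.conftest import ROOT_EDGE


class TestGeometryConfig:
    @pytest.mark.parametrize("bad", [
        dict(coronary_stub_length=0.0),
        dict(aortic_diameter=-1e-4),
        dict(coronary_diameter=6e-4),            # >= aortic diameter
        dict(lco_axial_fraction=1.5),
        dict(lco_azimuth_deg=360.0),
        dict(sinus_bulge_ratio=0.9),
    ])
    def test_invariant_violations_rejected(self, bad):
        with pytest.raises(ValidationError):
            GeometryConfig(**bad)

    def test_defaults_are_e16_5_scale(self):
        cfg = GeometryConfig()
        assert cfg.aortic_diameter == 5.0e-4
        assert cfg.coronary_diameter < cfg.aortic_diameter


class TestDisplaceLco:
    def test_zero_shift_is_identity(self):
        cfg = GeometryConfig()
        assert displace_lco(cfg, 0.0, 0.0) == cfg

    def test_axial_shift_arithmetic(self):
        cfg = GeometryConfig(lco_axial_fraction=0.3)
        assert displace_lco(cfg, 0.4, 0.0).lco_axial_fraction == pytest.approx(
            0.7, abs=1e-15)

    def test_out_of_range_shift_rejected(self):
        cfg = GeometryConfig(lco_axial_fraction=0.8)
        with pytest.raises(ValidationError):
            displace_lco(cfg, 0.4, 0.0)

    def test_azimuth_wraps_mod_360(self):
        cfg = GeometryConfig(lco_azimuth_deg=350.0)
        assert displace_lco(cfg, 0.0, 30.0).lco_azimuth_deg == pytest.approx(20.0)

    def test_inverse_shift_round_trips_bit_exactly(self):
        cfg = GeometryConfig(lco_axial_fraction=0.25, lco_azimuth_deg=10.0)
        back = displace_lco(displace_lco(cfg, 0.5, 45.0), -0.5, -45.0)
        assert back == cfg

    def test_only_lco_fields_change(self):
        cfg = GeometryConfig()
        shifted = displace_lco(cfg, 0.4, 30.0)
        diff = {f.name for f in dataclasses.fields(cfg)
                if getattr(cfg, f.name) != getattr(shifted, f.name)}
        assert diff == {"lco_axial_fraction", "lco_azimuth_deg"}


class TestBuildRootGeometry:
    def test_overlapping_stubs_raise_naming_both(self):
        cfg = GeometryConfig(rco_azimuth_deg=10.0, rco_axial_fraction=0.3)
        with pytest.raises(GeometryConflictError, match="LCA.*RCA"):
            build_root_geometry(cfg)

    def test_zero_stub_length_is_validation_error(self):
        with pytest.raises(ValidationError):
            GeometryConfig(coronary_stub_length=0.0)

    def test_stub_axes_pierce_wall_at_configured_position(self):
        cfg = GeometryConfig()
        geom = build_root_geometry(cfg)
        lca = geom.stubs[0]
        assert lca.ostium_center[2] == pytest.approx(
            cfg.lco_axial_fraction * cfg.sinus_height)
        # ostium center lies on the wall surface
        r = np.hypot(*lca.ostium_center[:2])
        th = np.arctan2(lca.ostium_center[1], lca.ostium_center[0])
        assert r == pytest.approx(float(geom.wall_radius(
            np.array([lca.ostium_center[2]]), np.array([th]))[0]), rel=1e-12)


class TestMeshGeometry:
    @pytest.fixture(scope="class")
    def root_mesh(self):
        geom = build_root_geometry(GeometryConfig())
        return geom, mesh_geometry(geom, ROOT_EDGE)

    def test_aortic_outlet_disc_area(self, root_mesh):
        _, mesh = root_mesh
        assert mesh.patch_area(AORTIC_OUTLET) == pytest.approx(
            np.pi * (0.25e-3) ** 2, rel=0.01)

    def test_all_patches_present_and_labels_partition(self, root_mesh):
        _, mesh = root_mesh
        assert set(mesh.patch_ids()) == {WALL, AORTIC_OUTLET, LCA_OUTLET,
                                         RCA_OUTLET}
        assert len(mesh.boundary_labels) == len(mesh.boundary_tris)

    def test_positive_volumes_and_watertight(self, root_mesh):
        _, mesh = root_mesh
        assert np.all(mesh.tet_volumes() > 0)
        assert validate_mesh(mesh).watertight

    def test_outlet_patches_planar(self, root_mesh):
        geom, mesh = root_mesh
        for pid, center, normal, radius in geom.outlet_planes():
            nodes = mesh.nodes[np.unique(
                mesh.boundary_tris[mesh.patch_faces(pid)])]
            dev = np.abs((nodes - center) @ normal)
            assert dev.max() < 0.01 * 2 * radius

    def test_too_coarse_edge_rejected(self):
        geom = build_root_geometry(GeometryConfig())
        with pytest.raises(ValidationError):
            mesh_geometry(geom, 1e-4)

    def test_bare_cylinder_volume_matches_closed_form(self):
        # test hook: no stubs, no bulge -> analytic pi r^2 L
        cfg = GeometryConfig(sinus_bulge_ratio=1.0, sinus_lobes=0)
        geom = build_root_geometry(cfg, include_stubs=False)
        mesh = mesh_geometry(geom, ROOT_EDGE)
        analytic = np.pi * (cfg.aortic_diameter / 2) ** 2 * cfg.root_length
        assert validate_mesh(mesh).volume_total == pytest.approx(
            analytic, rel=0.02)


class TestCylinderFixtureRefinement:
    def test_volume_error_decreases_monotonically(self):
        R, L = 0.25e-3, 1.0e-3
        analytic = np.pi * R * R * L
        errors = []
        for edge in (R / 2.0, R / 4.0, R / 8.0):
            mesh = build_cylinder_mesh(R, L, edge)
            errors.append(abs(validate_mesh(mesh).volume_total - analytic))
        assert errors[0] > errors[1] > errors[2]

    def test_patch_areas_sum_to_total_boundary_area(self):
        mesh = build_cylinder_mesh(0.25e-3, 1.0e-3, 0.25e-3 / 4)
        report = validate_mesh(mesh)
        assert sum(report.patch_areas.values()) == pytest.approx(
            float(mesh.face_areas().sum()), rel=1e-12)


def _regular_tet_mesh(edge=1.0e-3):
    a = edge
    nodes = np.array([[0, 0, 0], [a, 0, 0], [a / 2, a * np.sqrt(3) / 2, 0],
                      [a / 2, a * np.sqrt(3) / 6, a * np.sqrt(2.0 / 3.0)]])
    tets = np.array([[0, 1, 2, 3]])
    tris = np.array([[0, 2, 1], [0, 1, 3], [1, 2, 3], [0, 3, 2]])
    return VolumeMesh(nodes=nodes, tets=tets, boundary_tris=tris,
                      boundary_labels=np.ones(4, dtype=int),
                      characteristic_edge_length=a)


class TestValidateMesh:
    def test_single_regular_tet_volume_closed_form(self):
        a = 1.0e-3
        report = validate_mesh(_regular_tet_mesh(a))
        assert report.n_tets == 1
        assert report.volume_total == pytest.approx(
            a**3 / (6 * np.sqrt(2.0)), rel=1e-12)
        assert report.watertight
        # all six dihedral angles of a regular tet: arccos(1/3)
        expected = np.degrees(np.arccos(1.0 / 3.0))
        assert report.min_dihedral_deg == pytest.approx(expected, rel=1e-9)
        assert report.max_dihedral_deg == pytest.approx(expected, rel=1e-9)

    def test_deleted_boundary_face_breaks_watertightness(self):
        mesh = _regular_tet_mesh()
        mesh.boundary_tris = mesh.boundary_tris[:3]
        mesh.boundary_labels = mesh.boundary_labels[:3]
        assert not validate_mesh(mesh).watertight
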