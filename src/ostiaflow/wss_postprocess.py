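"""Wall shear stress extraction and control-vs-variant comparison metrics.

The traction on a boundary face is t = sigma . n evaluated from the
adjacent element's (constant, P1-consistent) velocity gradient and the
face-mean pressure, sigma = -p I + 2 mu_eff(gamma_dot) E. The WSS vector is
the tangential part t - (t.n) n; magnitudes are reported in Pa and in cgs
units (dyn/cm^2, 1 Pa = 10 dyn/cm^2), the unit system used for embryonic
ostial shear levels.

The "ostial" averaging region is the set of WALL faces (sinus wall and
proximal stub wall alike) whose centroid lies within one coronary diameter
of the stub-axis/wall intersection point: the reported ostial WSS is the
area-weighted mean over that patch. Means, not maxima, are compared
between scenarios because maxima concentrate at re-entrant mesh corners.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import RegionError, StateError, ValidationError
from .flow_solver import FlowSolution
from .geometry import ParametricGeometry, VolumeMesh, WALL
from .rheology import effective_viscosity, shear_rate
from .units import PA_TO_CGS

__all__ = [
    "WSSField",
    "OstialRegion",
    "ComparisonReport",
    "wall_shear_stress",
    "regional_mean_wss",
    "ostial_region",
    "percent_reduction",
    "womersley_number",
]


@dataclass
class WSSField:
    """Per-face traction and wall-shear-stress data on one patch."""

    patch_label: int
    face_indices: np.ndarray      # indices into mesh.boundary_tris
    traction: np.ndarray          # (k, 3) Pa
    wss_vector: np.ndarray        # (k, 3) Pa, tangential part
    wss_pa: np.ndarray            # (k,) magnitudes, Pa
    areas: np.ndarray             # (k,) m^2
    centroids: np.ndarray         # (k, 3) m

    @property
    def wss_cgs(self):
        return PA_TO_CGS * self.wss_pa


@dataclass(frozen=True)
class OstialRegion:
    """Spherical face-selection region around an ostium center."""

    name: str
    center: np.ndarray
    radius: float

    def select(self, wss: WSSField):
        d = np.linalg.norm(wss.centroids - self.center, axis=1)
        return np.flatnonzero(d <= self.radius)


@dataclass
class ComparisonReport:
    """Control-vs-variant ostial WSS comparison with diagnostics."""

    scenarios: dict               # label -> per-scenario result dict
    ostial_regions: dict          # label -> region description
    percent_reduction: float | None
    diagnostics: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def to_dict(self):
        return {
            "scenarios": self.scenarios,
            "ostial_regions": self.ostial_regions,
            "percent_reduction": self.percent_reduction,
            "diagnostics": self.diagnostics,
            "provenance": self.provenance,
        }


def _boundary_face_tets(mesh: VolumeMesh):
    """Adjacent tet index for every boundary face."""
    local = np.array([[1, 2, 3], [0, 3, 2], [0, 1, 3], [0, 2, 1]])
    all_faces = np.sort(mesh.tets[:, local].reshape(-1, 3), axis=1)
    lookup = {tuple(f): i // 4 for i, f in enumerate(all_faces)}
    return np.array([lookup[tuple(f)]
                     for f in np.sort(mesh.boundary_tris, axis=1)], dtype=int)


def _recovered_face_gradients(solution: FlowSolution, faces):
    """Superconvergent-patch-recovered velocity gradients at face centroids.

    For every node of the given faces, a linear polynomial is fitted by
    least squares to the adjacent elements' (centroid-sampled) constant
    gradients and evaluated at the node; face values average the three
    node values. Exact for quadratic velocity fields on smooth patches.
    """
    mesh = solution.mesh
    G = solution.velocity_gradients().reshape(-1, 9)
    # the P1 gradient of a quadratic field equals the true gradient at the
    # element circumcenter, so the fit samples there (falling back to the
    # centroid for slivers whose circumcenter flies far away)
    p = mesh.nodes[mesh.tets]
    M = 2.0 * (p[:, 1:] - p[:, :1])
    rhs = np.einsum("mij,mij->mi", p[:, 1:], p[:, 1:]) \
        - np.einsum("mj,mj->m", p[:, 0], p[:, 0])[:, None]
    centroid = p.mean(axis=1)
    try:
        circ = np.linalg.solve(M, rhs[..., None])[..., 0]
    except np.linalg.LinAlgError:
        circ = centroid.copy()
    h_loc = np.linalg.norm(p[:, 1] - p[:, 0], axis=1)
    far = ~np.all(np.isfinite(circ), axis=1) \
        | (np.linalg.norm(circ - centroid, axis=1) > 3.0 * h_loc)
    circ[far] = centroid[far]
    cent = circ
    need = np.unique(faces)
    node_ids = mesh.tets.ravel()
    elem_ids = np.repeat(np.arange(mesh.n_tets), 4)
    order = np.argsort(node_ids, kind="stable")
    node_sorted, elem_sorted = node_ids[order], elem_ids[order]
    starts = np.searchsorted(node_sorted, need)
    ends = np.searchsorted(node_sorted, need, side="right")
    G_node = np.empty((len(need), 9))
    for k, (n, s, e) in enumerate(zip(need, starts, ends)):
        els = elem_sorted[s:e]
        dx = cent[els] - mesh.nodes[n]
        if len(els) >= 4:
            A = np.column_stack([np.ones(len(els)), dx])
            coef, *_ = np.linalg.lstsq(A, G[els], rcond=None)
            G_node[k] = coef[0]
        else:
            G_node[k] = G[els].mean(axis=0)
    lookup = np.full(mesh.n_nodes, -1)
    lookup[need] = np.arange(len(need))
    return G_node[lookup[faces]].mean(axis=1).reshape(-1, 3, 3)


def wall_shear_stress(solution: FlowSolution, rheology=None,
                      patch_label: int = WALL,
                      recovery: bool = False) -> WSSField:
    """Traction and WSS on every face of the given patch.

    By default uses the adjacent element's constant gradient (consistent
    with linear elements, no smoothing — robust at re-entrant corners) and
    the face-mean nodal pressure. ``recovery=True`` switches to
    superconvergent patch recovery of the gradients, appropriate on smooth
    walls (used by the analytic benchmarks). Refuses non-converged
    solutions.
    """
    if not solution.convergence.converged:
        raise StateError(
            "refusing WSS extraction on a non-converged solution "
            f"(final normalized residual "
            f"{solution.convergence.residual_history[-1]:.3e} after "
            f"{solution.convergence.iterations} iterations)")
    rheology = rheology if rheology is not None else solution.rheology
    mesh = solution.mesh
    idx = mesh.patch_faces(patch_label)
    if idx.size == 0:
        raise ValidationError(f"patch {patch_label} not present in mesh")
    adj = _boundary_face_tets(mesh)[idx]

    if recovery:
        G = _recovered_face_gradients(solution, mesh.boundary_tris[idx])
    else:
        G = solution.velocity_gradients()[adj]
    E = 0.5 * (G + np.swapaxes(G, -1, -2))
    gdot = shear_rate(G, convention=solution.options.shear_rate_convention)
    mu = np.asarray(effective_viscosity(gdot, rheology))
    p_face = solution.pressure[mesh.boundary_tris[idx]].mean(axis=1)
    n = mesh.face_normals()[idx]

    traction = 2.0 * mu[:, None] * np.einsum("kij,kj->ki", E, n) \
        - p_face[:, None] * n
    t_n = np.einsum("ki,ki->k", traction, n)
    wss_vec = traction - t_n[:, None] * n
    return WSSField(
        patch_label=patch_label, face_indices=idx, traction=traction,
        wss_vector=wss_vec, wss_pa=np.linalg.norm(wss_vec, axis=1),
        areas=mesh.face_areas()[idx], centroids=mesh.face_centroids()[idx],
    )


def regional_mean_wss(wss: WSSField, region: OstialRegion) -> float:
    """Area-weighted mean WSS magnitude over the region, in cgs units."""
    sel = region.select(wss)
    if sel.size == 0:
        raise RegionError(
            f"region {region.name!r} (center {region.center}, radius "
            f"{region.radius:g} m) selects no faces")
    w = wss.areas[sel]
    return float(np.sum(w * wss.wss_cgs[sel]) / np.sum(w))


def ostial_region(geom: ParametricGeometry, stub_name: str = "LCA",
                  radius_diameters: float = 1.0) -> OstialRegion:
    """Averaging region around one coronary ostium.

    Faces within ``radius_diameters`` coronary diameters (Euclidean) of the
    stub-axis/sinus-wall intersection; this captures the sinus wall ring
    around the ostium plus the proximal stub wall.
    """
    for st in geom.stubs:
        if st.name == stub_name:
            return OstialRegion(
                name=f"{stub_name}_ostium", center=st.ostium_center,
                radius=radius_diameters * geom.config.coronary_diameter)
    raise ValidationError(f"geometry has no stub named {stub_name!r}")


def percent_reduction(control_wss: float, variant_wss: float) -> float:
    """100 (control - variant) / control; requires control > 0."""
    if control_wss <= 0:
        raise ValidationError(f"control WSS must be > 0, got {control_wss}")
    return 100.0 * (control_wss - variant_wss) / control_wss


def womersley_number(radius: float, heart_rate_bpm: float, density: float,
                     viscosity: float) -> float:
    """Standard Womersley number alpha = R sqrt(2 pi f rho / mu).

    Quantifies transient inertia against viscous diffusion over the cardiac
    cycle; values well below 1 justify the quasi-steady treatment.
    """
    if radius <= 0 or density <= 0 or viscosity <= 0:
        raise ValidationError("radius, density and viscosity must be > 0")
    if heart_rate_bpm < 0:
        raise ValidationError("heart rate must be >= 0")
    omega = 2.0 * np.pi * heart_rate_bpm / 60.0
    return float(radius * np.sqrt(omega * density / viscosity))
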