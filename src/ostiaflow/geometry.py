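"""Parametric idealized aortic-root geometry and tetrahedral meshing.

The idealized root is a tube aligned with the z-axis: valve base (closed
during diastole) at z = 0, aortic outlet at z = root_length. Over the sinus
segment 0 <= z <= sinus_height the wall bulges radially; by default the bulge
is modulated azimuthally into three lobes, mimicking the three sinuses of
Valsalva (set ``sinus_lobes = 0`` for an axisymmetric bulge). Two cylindrical
coronary stubs pierce the sinus wall horizontally at configurable
(axial fraction, azimuth) positions and end in planar outlet discs.

Azimuth is measured from +x toward +y; all lengths are SI metres.

Meshing is done in-house: boundary surfaces are sampled at the target edge
length, interior points come from a body-centred-cubic lattice, and a
Delaunay triangulation restricted to the solid yields the tetrahedra. A
structured extruded mesher provides the straight-cylinder benchmark fixture
with fully predictable quality.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import brentq
from scipy.spatial import Delaunay, cKDTree

from .errors import GeometryConflictError, MeshingError, ValidationError

__all__ = [
    "WALL",
    "AORTIC_OUTLET",
    "LCA_OUTLET",
    "RCA_OUTLET",
    "PATCH_NAMES",
    "GeometryConfig",
    "ParametricGeometry",
    "VolumeMesh",
    "MeshQualityReport",
    "build_root_geometry",
    "displace_lco",
    "mesh_geometry",
    "build_cylinder_mesh",
    "validate_mesh",
]

# Canonical patch ids. Smaller id wins label ties.
WALL = 1
AORTIC_OUTLET = 2
LCA_OUTLET = 3
RCA_OUTLET = 4
PATCH_NAMES = {WALL: "WALL", AORTIC_OUTLET: "AORTIC_OUTLET",
               LCA_OUTLET: "LCA_OUTLET", RCA_OUTLET: "RCA_OUTLET"}


@dataclass(frozen=True)
class GeometryConfig:
    """Dimensions and coronary-ostium placement of the idealized root.

    Lengths in metres; azimuths in degrees from +x toward +y; axial
    fractions are measured in units of ``sinus_height`` from the valve base
    (0 = base, 1 = sinotubular junction).
    """

    aortic_diameter: float = 5.0e-4
    root_length: float = 1.2e-3
    sinus_height: float = 5.0e-4
    sinus_bulge_ratio: float = 1.3
    coronary_diameter: float = 1.5e-4
    coronary_stub_length: float = 3.0e-4
    lco_axial_fraction: float = 0.3
    lco_azimuth_deg: float = 0.0
    rco_axial_fraction: float = 0.3
    rco_azimuth_deg: float = 120.0
    #: number of azimuthal sinus lobes (0 = axisymmetric bulge)
    sinus_lobes: int = 3

    def __post_init__(self):
        for name in ("aortic_diameter", "root_length", "sinus_height",
                     "coronary_diameter", "coronary_stub_length"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.coronary_diameter >= self.aortic_diameter:
            raise ValidationError("coronary_diameter must be < aortic_diameter")
        if self.sinus_bulge_ratio < 1.0:
            raise ValidationError("sinus_bulge_ratio must be >= 1")
        if self.sinus_height > self.root_length:
            raise ValidationError("sinus_height must be <= root_length")
        for name in ("lco_axial_fraction", "rco_axial_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {v}")
        for name in ("lco_azimuth_deg", "rco_azimuth_deg"):
            v = getattr(self, name)
            if not 0.0 <= v < 360.0:
                raise ValidationError(f"{name} must be in [0, 360), got {v}")
        if self.sinus_lobes < 0:
            raise ValidationError("sinus_lobes must be >= 0")

    def to_dict(self):
        return dataclasses.asdict(self)


def displace_lco(config: GeometryConfig, axial_shift_fraction: float,
                 azimuth_shift_deg: float) -> GeometryConfig:
    """Shift the left coronary ostium axially and azimuthally.

    The axial shift is in units of sinus_height (positive = toward the
    sinotubular junction); the azimuth wraps modulo 360. Only the LCO
    placement fields change.
    """
    new_frac = config.lco_axial_fraction + axial_shift_fraction
    if not 0.0 <= new_frac <= 1.0:
        raise ValidationError(
            f"axial shift {axial_shift_fraction} pushes lco_axial_fraction to "
            f"{new_frac}, outside [0, 1]"
        )
    new_az = (config.lco_azimuth_deg + azimuth_shift_deg) % 360.0
    return replace(config, lco_axial_fraction=new_frac, lco_azimuth_deg=new_az)


@dataclass(frozen=True)
class Stub:
    """A cylindrical coronary stub: horizontal axis from the z-axis outward."""

    patch_id: int
    name: str
    origin: np.ndarray          # point on the z-axis at ostium height
    direction: np.ndarray       # unit horizontal direction
    radius: float
    s_wall: float               # axis coordinate of the wall pierce point
    s_end: float                # axis coordinate of the outlet plane

    @property
    def ostium_center(self):
        return self.origin + self.s_wall * self.direction

    @property
    def outlet_center(self):
        return self.origin + self.s_end * self.direction


class ParametricGeometry:
    """Implicit surface description of the idealized root (plus stubs)."""

    def __init__(self, config: GeometryConfig, include_stubs: bool = True):
        self.config = config
        self.include_stubs = include_stubs
        self.stubs: list[Stub] = []
        if include_stubs:
            for patch_id, name, frac, az in (
                (LCA_OUTLET, "LCA", config.lco_axial_fraction, config.lco_azimuth_deg),
                (RCA_OUTLET, "RCA", config.rco_axial_fraction, config.rco_azimuth_deg),
            ):
                z0 = frac * config.sinus_height
                th = np.deg2rad(az)
                d = np.array([np.cos(th), np.sin(th), 0.0])
                s_wall = float(self.wall_radius(np.array([z0]), np.array([th]))[0])
                self.stubs.append(Stub(
                    patch_id=patch_id, name=name,
                    origin=np.array([0.0, 0.0, z0]), direction=d,
                    radius=config.coronary_diameter / 2.0,
                    s_wall=s_wall, s_end=s_wall + config.coronary_stub_length,
                ))
            self._check_stub_conflict()

    # -- surface ------------------------------------------------------------

    def wall_radius(self, z, theta):
        """Root wall radius at height z and azimuth theta (radians)."""
        cfg = self.config
        z = np.asarray(z, dtype=float)
        theta = np.asarray(theta, dtype=float)
        r0 = cfg.aortic_diameter / 2.0
        fz = np.where(
            (z >= 0) & (z <= cfg.sinus_height),
            np.sin(np.pi * np.clip(z, 0, cfg.sinus_height) / cfg.sinus_height),
            0.0,
        )
        if cfg.sinus_lobes > 0:
            g = 0.5 * (1.0 + np.cos(cfg.sinus_lobes * theta))
        else:
            g = np.ones_like(np.broadcast_arrays(z, theta)[0], dtype=float)
        return r0 * (1.0 + (cfg.sinus_bulge_ratio - 1.0) * fz * g)

    def inside(self, points, tol: float = 0.0):
        """Boolean mask: which points lie inside the solid (union of root
        tube and stub cylinders). ``tol > 0`` shrinks the solid."""
        p = np.atleast_2d(np.asarray(points, dtype=float))
        z = p[:, 2]
        r = np.hypot(p[:, 0], p[:, 1])
        th = np.arctan2(p[:, 1], p[:, 0])
        mask = (z >= tol) & (z <= self.config.root_length - tol) & \
               (r <= self.wall_radius(z, th) - tol)
        for st in self.stubs:
            rel = p - st.origin
            s = rel @ st.direction
            perp = np.linalg.norm(rel - np.outer(s, st.direction), axis=1)
            mask |= (perp <= st.radius - tol) & (s >= tol) & (s <= st.s_end - tol)
        return mask

    def outlet_planes(self):
        """List of (patch_id, center, outward unit normal, radius)."""
        cfg = self.config
        planes = [(AORTIC_OUTLET,
                   np.array([0.0, 0.0, cfg.root_length]),
                   np.array([0.0, 0.0, 1.0]),
                   cfg.aortic_diameter / 2.0)]
        for st in self.stubs:
            planes.append((st.patch_id, st.outlet_center, st.direction, st.radius))
        return planes

    # -- validation ---------------------------------------------------------

    def _check_stub_conflict(self):
        if len(self.stubs) < 2:
            return
        a, b = self.stubs
        d = _segment_distance(
            a.ostium_center - 0.5 * a.radius * a.direction, a.outlet_center,
            b.ostium_center - 0.5 * b.radius * b.direction, b.outlet_center,
        )
        if d < a.radius + b.radius:
            raise GeometryConflictError(
                f"coronary stubs {a.name} and {b.name} intersect "
                f"(axis separation {d:.3e} m < {a.radius + b.radius:.3e} m)"
            )


def _segment_distance(p0, p1, q0, q1):
    """Minimum distance between segments [p0,p1] and [q0,q1]."""
    u = p1 - p0
    v = q1 - q0
    w = p0 - q0
    a, b, c = u @ u, u @ v, v @ v
    d, e = u @ w, v @ w
    den = a * c - b * b
    if den > 1e-30:
        s = np.clip((b * e - c * d) / den, 0.0, 1.0)
    else:
        s = 0.0
    t = np.clip((b * s + e) / c, 0.0, 1.0) if c > 1e-30 else 0.0
    s = np.clip((b * t - d) / a, 0.0, 1.0) if a > 1e-30 else 0.0
    return float(np.linalg.norm(w + s * u - t * v))


def build_root_geometry(config: GeometryConfig,
                        include_stubs: bool = True) -> ParametricGeometry:
    """Build the parametric surface description of the idealized root.

    ``include_stubs=False`` is a test hook producing the bare (possibly
    bulged) tube, used for closed-form volume benchmarks.
    """
    return ParametricGeometry(config, include_stubs=include_stubs)


# ---------------------------------------------------------------------------
# Volume mesh container
# ---------------------------------------------------------------------------

@dataclass
class VolumeMesh:
    """Labeled tetrahedral mesh.

    ``nodes``: (n, 3) coordinates in metres. ``tets``: (m, 4) node indices,
    positively oriented. ``boundary_tris``: (k, 3) node indices wound so the
    right-hand normal points outward. ``boundary_labels``: (k,) patch ids.
    """

    nodes: np.ndarray
    tets: np.ndarray
    boundary_tris: np.ndarray
    boundary_labels: np.ndarray
    characteristic_edge_length: float
    patch_names: dict = field(default_factory=lambda: dict(PATCH_NAMES))

    # cached derived quantities
    def __post_init__(self):
        self._face_cache = None

    @property
    def n_nodes(self):
        return self.nodes.shape[0]

    @property
    def n_tets(self):
        return self.tets.shape[0]

    def tet_volumes(self):
        p = self.nodes[self.tets]
        return np.einsum("ij,ij->i",
                         np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]),
                         p[:, 3] - p[:, 0]) / 6.0

    def _faces(self):
        if self._face_cache is None:
            p = self.nodes[self.boundary_tris]
            cross = np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
            areas = 0.5 * np.linalg.norm(cross, axis=1)
            normals = cross / np.maximum(2.0 * areas[:, None], 1e-300)
            centroids = p.mean(axis=1)
            self._face_cache = (areas, normals, centroids)
        return self._face_cache

    def face_areas(self):
        return self._faces()[0]

    def face_normals(self):
        return self._faces()[1]

    def face_centroids(self):
        return self._faces()[2]

    def patch_faces(self, patch_id):
        return np.flatnonzero(self.boundary_labels == patch_id)

    def patch_area(self, patch_id):
        return float(self.face_areas()[self.patch_faces(patch_id)].sum())

    def patch_ids(self):
        return sorted(set(int(v) for v in np.unique(self.boundary_labels)))


@dataclass(frozen=True)
class MeshQualityReport:
    n_nodes: int
    n_tets: int
    n_boundary_tris: int
    min_dihedral_deg: float
    max_dihedral_deg: float
    volume_total: float
    patch_areas: dict
    watertight: bool


# ---------------------------------------------------------------------------
# Meshing: boundary sampling + interior lattice + restricted Delaunay
# ---------------------------------------------------------------------------

_GOLDEN = 0.3819660112501051


def _ring(n, offset=0.0):
    return 2.0 * np.pi * (np.arange(n) + offset) / n


def _row_offset(j):
    # irrational per-row phase: avoids mirror symmetries that would make
    # exactly coplanar point quadruples (degenerate Delaunay tets)
    return (j * _GOLDEN) % 1.0


def _disc_points(center, normal, radius, h, r_max_fn=None):
    """Concentric-ring sampling of a planar disc (rim excluded)."""
    e1, e2 = _plane_basis(normal)
    pts = [center]
    n_rings = max(1, int(round(radius / h)))
    for k in range(1, n_rings):
        r = radius * k / n_rings
        m = max(6, int(np.ceil(2 * np.pi * r / h)))
        ang = _ring(m, offset=_row_offset(k))
        ring = center + r * (np.outer(np.cos(ang), e1) + np.outer(np.sin(ang), e2))
        pts.append(ring)
    pts = np.vstack([np.atleast_2d(a) for a in pts])
    if r_max_fn is not None:
        rad = np.linalg.norm(pts - center, axis=1)
        pts = pts[rad <= r_max_fn(pts) - 0.4 * h]
    return pts


def _plane_basis(normal):
    n = np.asarray(normal, dtype=float)
    n = n / np.linalg.norm(n)
    a = np.array([0.0, 0.0, 1.0]) if abs(n[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    e1 = np.cross(n, a)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(n, e1)
    return e1, e2


def _sample_root_surface(geom: ParametricGeometry, h: float):
    """Sample all boundary surfaces of the solid at spacing ~h.

    Returns (feature_points, regular_points): feature points (rims and hole
    edges) take precedence during deduplication.
    """
    cfg = geom.config
    feature, regular = [], []

    # Rim circles of the tube ends (radius is R0 there: bulge vanishes).
    r0 = cfg.aortic_diameter / 2.0
    for z in (0.0, cfg.root_length):
        m = max(12, int(np.ceil(2 * np.pi * r0 / h)))
        ang = _ring(m)
        feature.append(np.column_stack(
            [r0 * np.cos(ang), r0 * np.sin(ang), np.full(m, z)]))

    # Stub hole rims, lateral surfaces, outlet rims and discs.
    hole_rims = []
    for st in geom.stubs:
        e1 = np.array([0.0, 0.0, 1.0])
        e2 = np.cross(st.direction, e1)
        m = max(10, int(np.ceil(2 * np.pi * st.radius / h)))
        ang = _ring(m)
        offs = st.radius * (np.outer(np.cos(ang), e1) + np.outer(np.sin(ang), e2))

        # hole rim: where each axial line of the stub surface meets the wall
        rim = np.empty((m, 3))
        for i in range(m):
            def f(s, o=offs[i]):
                q = st.origin + s * st.direction + o
                return np.hypot(q[0], q[1]) - float(geom.wall_radius(
                    np.array([q[2]]), np.array([np.arctan2(q[1], q[0])]))[0])
            s_lo, s_hi = 0.3 * st.s_wall, st.s_wall + 4 * st.radius
            rim[i] = st.origin + brentq(f, s_lo, s_hi, xtol=1e-12) * st.direction + offs[i]
        feature.append(rim)
        hole_rims.append((st, rim))

        # outlet rim (exact circle in the outlet plane)
        feature.append(st.outlet_center + offs)

        # lateral surface rows between hole rim and outlet
        s_rim = (rim - st.origin) @ st.direction
        s_start = s_rim.min()
        n_rows = max(2, int(np.ceil((st.s_end - s_start) / h)))
        for j in range(1, n_rows):
            s = s_start + (st.s_end - s_start) * j / n_rows
            ang_j = _ring(m, offset=_row_offset(j))
            offs_j = st.radius * (np.outer(np.cos(ang_j), e1) + np.outer(np.sin(ang_j), e2))
            row = st.origin + s * st.direction + offs_j
            # keep only points clearly outside the root tube
            r = np.hypot(row[:, 0], row[:, 1])
            wall_r = geom.wall_radius(row[:, 2], np.arctan2(row[:, 1], row[:, 0]))
            regular.append(row[r > wall_r + 0.35 * h])

        # outlet disc interior
        regular.append(_disc_points(st.outlet_center, st.direction, st.radius, h))

    # Root wall lateral surface (z rows), skipping stub holes.
    nz = max(4, int(np.ceil(cfg.root_length / h)))
    for j in range(nz + 1):
        z = cfg.root_length * j / nz
        r_mean = float(np.mean(geom.wall_radius(
            np.full(64, z), np.linspace(0, 2 * np.pi, 64, endpoint=False))))
        m = max(12, int(np.ceil(2 * np.pi * r_mean / h)))
        ang = _ring(m, offset=_row_offset(j))
        r = geom.wall_radius(np.full(m, z), ang)
        row = np.column_stack([r * np.cos(ang), r * np.sin(ang), np.full(m, z)])
        if j in (0, nz):
            continue  # rim circles already added as features
        keep = np.ones(m, dtype=bool)
        for st in geom.stubs:
            rel = row - st.origin
            s = rel @ st.direction
            perp = np.linalg.norm(rel - np.outer(s, st.direction), axis=1)
            keep &= ~((perp < st.radius + 0.45 * h) & (s > 0))
        regular.append(row[keep])

    # End discs (valve base z=0 closed wall; aortic outlet z=root_length).
    for z, nrm in ((0.0, np.array([0, 0, -1.0])), (cfg.root_length, np.array([0, 0, 1.0]))):
        regular.append(_disc_points(np.array([0.0, 0.0, z]), nrm, r0, h))

    feature = np.vstack(feature) if feature else np.empty((0, 3))
    regular = np.vstack([a for a in regular if len(a)]) if regular else np.empty((0, 3))
    return feature, regular


def _dedupe(points, tol):
    """Keep-first deduplication with distance tolerance."""
    if len(points) == 0:
        return points
    tree = cKDTree(points)
    pairs = tree.query_pairs(tol, output_type="ndarray")
    drop = np.zeros(len(points), dtype=bool)
    for i, j in pairs[np.argsort(pairs[:, 0])]:
        if not drop[i]:
            drop[max(i, j) if i != j else j] = True
    return points[~drop]


def _interior_lattice(geom, h, surface_pts, bbox):
    """BCC lattice points inside the solid, clear of the sampled surface."""
    g = h * 2.0 / np.sqrt(3.0)
    lo, hi = bbox
    axes = [np.arange(lo[i], hi[i] + g, g) for i in range(3)]
    X, Y, Z = np.meshgrid(*axes, indexing="ij")
    corner = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    center = corner + 0.5 * g
    pts = np.vstack([corner, center])
    pts = pts[geom.inside(pts, tol=0.3 * h)]
    if len(pts) == 0:
        return pts
    tree = cKDTree(surface_pts)
    dist, _ = tree.query(pts, k=1)
    pts = pts[dist > 0.7 * h]
    # deterministic jitter breaks lattice co-sphericity for Delaunay
    rng = np.random.default_rng(987654321)
    pts = pts + (rng.random(pts.shape) - 0.5) * 0.08 * h
    return pts


def _bad_boundary_edges(faces):
    edges = np.sort(np.vstack([faces[:, [0, 1]], faces[:, [1, 2]],
                               faces[:, [2, 0]]]), axis=1)
    uniq, counts = np.unique(edges, axis=0, return_counts=True)
    return uniq[counts != 2]


def _peel_nonmanifold(tets, max_rounds=25):
    """Remove tets pinched along non-manifold boundary edges.

    A boundary edge shared by != 2 boundary faces marks a pinch; peeling
    off tets incident to such edges (preferring ones already exposed on
    the boundary) restores a watertight surface in a few rounds, at the
    cost of a sub-edge-length notch.
    """
    for _ in range(max_rounds):
        faces = _extract_boundary(None, tets)
        bad = _bad_boundary_edges(faces)
        if len(bad) == 0:
            return tets
        bad_set = {tuple(e) for e in bad}
        face_set = {tuple(f) for f in np.sort(faces, axis=1)}
        epairs = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
        fl = np.array([[1, 2, 3], [0, 3, 2], [0, 1, 3], [0, 2, 1]])
        drop = np.zeros(len(tets), dtype=bool)
        fallback = np.zeros(len(tets), dtype=bool)
        for t_idx, t in enumerate(tets):
            st = np.sort(t)
            if not any((st[i], st[j]) in bad_set for i, j in epairs):
                continue
            fallback[t_idx] = True
            if any(tuple(np.sort(t[f])) in face_set for f in fl):
                drop[t_idx] = True
        if not drop.any():
            drop = fallback
        if not drop.any():
            return None
        tets = tets[~drop]
    return None


def _best_watertight_subset(nodes, tets, vols, h):
    for cut in (1e-2, 1e-3, 1e-4, 0.0):
        sub = tets[vols > cut * h**3 / 6.0]
        faces = _extract_boundary(nodes, sub)
        if len(_bad_boundary_edges(faces)) == 0:
            return sub
        repaired = _peel_nonmanifold(sub)
        if repaired is not None:
            return repaired
    return tets[vols > 0]


def _extract_boundary(nodes, tets):
    """Boundary faces (appearing in exactly one tet), wound outward."""
    local = np.array([[1, 2, 3], [0, 3, 2], [0, 1, 3], [0, 2, 1]])
    faces = tets[:, local].reshape(-1, 3)                 # (4m, 3) wound outward
    key = np.sort(faces, axis=1)
    order = np.lexsort((key[:, 2], key[:, 1], key[:, 0]))
    ks = key[order]
    boundary_mask_sorted = np.ones(len(ks), dtype=bool)
    same = np.all(ks[1:] == ks[:-1], axis=1)
    boundary_mask_sorted[1:][same] = False
    boundary_mask_sorted[:-1][same] = False
    bmask = np.zeros(len(key), dtype=bool)
    bmask[order] = boundary_mask_sorted
    return faces[bmask]


def _orient_tets(nodes, tets):
    p = nodes[tets]
    vol = np.einsum("ij,ij->i",
                    np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]),
                    p[:, 3] - p[:, 0]) / 6.0
    flip = vol < 0
    tets = tets.copy()
    tets[flip] = tets[flip][:, [0, 1, 3, 2]]
    return tets, np.abs(vol)


def _label_boundary(nodes, faces, planes, h):
    """Outlet label if all three nodes sit on an outlet plane; else WALL."""
    labels = np.full(len(faces), WALL, dtype=int)
    assigned = np.zeros(len(faces), dtype=bool)
    for patch_id, center, normal, radius in sorted(planes, key=lambda p: p[0]):
        tol = max(1e-3 * 2 * radius, 1e-9)
        p = nodes[faces]                                   # (k, 3, 3)
        on_plane = np.all(np.abs((p - center) @ normal) <= tol, axis=1)
        within = np.all(np.linalg.norm(
            (p - center) - ((p - center) @ normal)[..., None] * normal, axis=2)
            <= radius + 0.75 * h, axis=1)
        sel = on_plane & within & ~assigned
        labels[sel] = patch_id
        assigned |= sel
    return labels


def _edge_length_stats(nodes, tets):
    e = tets[:, [0, 0, 0, 1, 1, 2]], tets[:, [1, 2, 3, 2, 3, 3]]
    d = np.linalg.norm(nodes[e[0]] - nodes[e[1]], axis=2)
    return float(d.mean())


def mesh_geometry(geom: ParametricGeometry, target_edge_length: float) -> VolumeMesh:
    """Tetrahedralize the parametric solid at the given target edge length.

    Raises MeshingError (with diagnostic counts) if the restricted Delaunay
    produces a non-watertight boundary.
    """
    h = float(target_edge_length)
    if h <= 0:
        raise ValidationError("target_edge_length must be > 0")
    if geom.stubs and h >= geom.config.coronary_diameter / 3.0:
        raise ValidationError(
            f"target_edge_length {h:g} must be < coronary_diameter/3 = "
            f"{geom.config.coronary_diameter / 3.0:g} to resolve the stubs"
        )

    feature, regular = _sample_root_surface(geom, h)
    surface = _dedupe(np.vstack([feature, regular]), 0.35 * h)

    cfg = geom.config
    r_max = cfg.aortic_diameter / 2.0 * cfg.sinus_bulge_ratio \
        + cfg.coronary_stub_length + cfg.coronary_diameter
    bbox = (np.array([-r_max, -r_max, 0.0]),
            np.array([r_max, r_max, cfg.root_length]))
    interior = _interior_lattice(geom, h, surface, bbox)
    nodes = np.vstack([surface, interior]) if len(interior) else surface

    tri = Delaunay(nodes)
    tets = tri.simplices
    centroids = nodes[tets].mean(axis=1)
    keep = geom.inside(centroids)
    tets = tets[keep]
    tets, vols = _orient_tets(nodes, tets)
    # largest sliver cut that keeps the boundary watertight
    tets = _best_watertight_subset(nodes, tets, vols, h)

    # drop nodes not referenced by any kept tet
    used = np.unique(tets)
    remap = -np.ones(len(nodes), dtype=int)
    remap[used] = np.arange(len(used))
    nodes = nodes[used]
    tets = remap[tets]

    faces = _extract_boundary(nodes, tets)
    labels = _label_boundary(nodes, faces, geom.outlet_planes(), h)
    mesh = VolumeMesh(
        nodes=nodes, tets=tets, boundary_tris=faces, boundary_labels=labels,
        characteristic_edge_length=_edge_length_stats(nodes, tets),
        patch_names=dict(PATCH_NAMES),
    )
    ok, n_bad = _watertight(mesh)
    if not ok:
        raise MeshingError(
            "restricted Delaunay produced a non-watertight boundary",
            diagnostics={"n_nodes": mesh.n_nodes, "n_tets": mesh.n_tets,
                         "n_boundary_tris": len(faces), "n_bad_edges": n_bad},
        )
    return mesh


# ---------------------------------------------------------------------------
# Structured cylinder fixture (no external mesher needed)
# ---------------------------------------------------------------------------

#: patch ids of the cylinder fixture
CYL_WALL, CYL_OUTLET, CYL_INLET = WALL, 2, 3
CYL_PATCH_NAMES = {CYL_WALL: "WALL", CYL_OUTLET: "OUTLET", CYL_INLET: "INLET"}


def _disc_triangulation(radius, h):
    """Structured concentric-ring disc point set and its 2D triangulation."""
    n_rings = max(2, int(round(radius / h)))
    pts = [np.zeros((1, 2))]
    for k in range(1, n_rings + 1):
        r = radius * k / n_rings
        m = 6 * k
        ang = _ring(m, offset=0.5 * (k % 2))
        pts.append(np.column_stack([r * np.cos(ang), r * np.sin(ang)]))
    pts = np.vstack(pts)
    tri = Delaunay(pts)
    # drop degenerate outer slivers (co-circular artifacts)
    p = pts[tri.simplices]
    d1, d2 = p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]
    a2 = np.abs(d1[:, 0] * d2[:, 1] - d1[:, 1] * d2[:, 0])
    tris = tri.simplices[a2 > 1e-12 * radius**2]
    return pts, tris


_PRISM_ROTATIONS = [
    (0, 1, 2, 3, 4, 5), (1, 2, 0, 4, 5, 3), (2, 0, 1, 5, 3, 4),
    (3, 5, 4, 0, 2, 1), (4, 3, 5, 1, 0, 2), (5, 4, 3, 2, 1, 0),
]


def _split_prism(v):
    """Split prism (bottom v0 v1 v2, top v3 v4 v5) into 3 conforming tets.

    Quad-face diagonals are chosen through the globally smallest vertex
    index, which makes adjacent prisms agree (indirect splitting method).
    """
    i_min = int(np.argmin(v))
    rot = _PRISM_ROTATIONS[i_min]
    w = [v[i] for i in rot]
    if min(w[1], w[5]) < min(w[2], w[4]):
        tets = [(w[0], w[1], w[2], w[5]), (w[0], w[1], w[5], w[4]),
                (w[0], w[4], w[5], w[3])]
    else:
        tets = [(w[0], w[1], w[2], w[4]), (w[0], w[4], w[2], w[5]),
                (w[0], w[4], w[5], w[3])]
    return tets


def build_cylinder_mesh(radius: float, length: float, edge_length: float) -> VolumeMesh:
    """Structured extruded tet mesh of a z-aligned cylinder.

    Patches: lateral surface WALL (1), z=length disc OUTLET (2), z=0 disc
    INLET (3). Used as the analytic benchmark fixture.
    """
    if radius <= 0 or length <= 0 or edge_length <= 0:
        raise ValidationError("radius, length and edge_length must be > 0")
    pts2d, tris2d = _disc_triangulation(radius, edge_length)
    n2d = len(pts2d)
    nz = max(2, int(round(length / edge_length)))
    zs = np.linspace(0.0, length, nz + 1)
    nodes = np.vstack([
        np.column_stack([pts2d[:, 0], pts2d[:, 1], np.full(n2d, z)]) for z in zs
    ])
    tets = []
    for j in range(nz):
        lo, hi = j * n2d, (j + 1) * n2d
        for (a, b, c) in tris2d:
            tets.extend(_split_prism((lo + a, lo + b, lo + c, hi + a, hi + b, hi + c)))
    tets = np.asarray(tets, dtype=int)
    tets, vols = _orient_tets(nodes, tets)
    tets = tets[vols > 1e-30]

    faces = _extract_boundary(nodes, tets)
    planes = [
        (CYL_OUTLET, np.array([0.0, 0.0, length]), np.array([0.0, 0.0, 1.0]), radius),
        (CYL_INLET, np.array([0.0, 0.0, 0.0]), np.array([0.0, 0.0, -1.0]), radius),
    ]
    labels = _label_boundary(nodes, faces, planes, edge_length)
    mesh = VolumeMesh(
        nodes=nodes, tets=tets, boundary_tris=faces, boundary_labels=labels,
        characteristic_edge_length=_edge_length_stats(nodes, tets),
        patch_names=dict(CYL_PATCH_NAMES),
    )
    ok, n_bad = _watertight(mesh)
    if not ok:
        raise MeshingError("structured cylinder mesh is not watertight",
                           diagnostics={"n_bad_edges": n_bad})
    return mesh


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

def _watertight(mesh: VolumeMesh):
    """Every boundary edge must be shared by exactly two boundary faces."""
    f = mesh.boundary_tris
    edges = np.sort(np.vstack([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]]), axis=1)
    _, counts = np.unique(edges, axis=0, return_counts=True)
    bad = int(np.sum(counts != 2))
    return bad == 0, bad


def _dihedral_angles(mesh: VolumeMesh):
    p = mesh.nodes[mesh.tets]
    # outward normals of the four faces of each tet
    local = np.array([[1, 2, 3], [0, 3, 2], [0, 1, 3], [0, 2, 1]])
    normals = np.empty((mesh.n_tets, 4, 3))
    for i, (a, b, c) in enumerate(local):
        nrm = np.cross(p[:, b] - p[:, a], p[:, c] - p[:, a])
        normals[:, i] = nrm / np.maximum(np.linalg.norm(nrm, axis=1)[:, None], 1e-300)
    pairs = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
    cosang = np.stack([-np.einsum("ij,ij->i", normals[:, i], normals[:, j])
                       for i, j in pairs], axis=1)
    return np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))


def validate_mesh(mesh: VolumeMesh) -> MeshQualityReport:
    """Compute quality metrics; reports rather than raises."""
    vols = mesh.tet_volumes()
    dih = _dihedral_angles(mesh)
    ok, _ = _watertight(mesh)
    areas = {mesh.patch_names.get(pid, str(pid)): mesh.patch_area(pid)
             for pid in mesh.patch_ids()}
    return MeshQualityReport(
        n_nodes=mesh.n_nodes,
        n_tets=mesh.n_tets,
        n_boundary_tris=len(mesh.boundary_tris),
        min_dihedral_deg=float(dih.min()) if len(dih) else float("nan"),
        max_dihedral_deg=float(dih.max()) if len(dih) else float("nan"),
        volume_total=float(np.abs(vols).sum()),
        patch_areas=areas,
        watertight=ok,
    )
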