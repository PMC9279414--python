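"""Stabilized finite-element solver for quasi-steady diastolic flow.

Incompressible Navier-Stokes with shear-dependent viscosity,

    rho (u . grad) u = div sigma,   div u = 0,
    sigma = -p I + 2 mu_eff(gamma_dot) E(u),

discretized with equal-order linear (P1) velocity and pressure on
tetrahedra. Equal-order interpolation is stabilized with residual-based
PSPG/SUPG terms plus a grad-div (LSIC) term, using standard element-wise
stabilization parameters

    tau_M = [(2|a|/h)^2 + (12 nu/h^2)^2]^(-1/2),   tau_C = h^2 / (12 tau_M).

The nonlinearity (convection and viscosity) is resolved by Picard iteration
with under-relaxation; iterations stop when the normalized residual
||r_k|| / ||r_0|| drops below ``nonlinear_tol`` (default 1e-3).

Boundary conditions: moving-wall Dirichlet velocity (u = -s n at wall
nodes, n the area-weighted node normal), constant-pressure outlets imposed
as normal traction, and lumped resistance outlets coupled implicitly
through a rank-one augmentation of the system matrix (traction
-(R Q + p_distal) n with Q the instantaneous patch flux). Backflow at
traction boundaries is stabilized by the beta * rho * (u.n)_- u boundary
term.

Linear systems use a sparse LU factorization reused as a GMRES
preconditioner across Picard iterations; all components are deterministic,
so repeated runs are bit-reproducible.

An unsteady mode (generalized-alpha time integration with spectral radius
rho_inf) is provided for parity with the time-accurate formulation; the
steady path is primary since the Womersley number of the application is
small.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .boundary_conditions import (BoundaryConditionSet, PressureOutlet,
                                  ResistanceOutlet, WallMotion)
from .errors import SolverError, StateError, ValidationError
from .geometry import VolumeMesh
from .rheology import effective_viscosity, shear_rate

__all__ = [
    "SolverOptions",
    "ConvergenceRecord",
    "FlowSolution",
    "solve_steady",
    "solve_unsteady",
    "outlet_flux",
    "residual_norm",
]


@dataclass
class SolverOptions:
    """Numerical controls of the nonlinear flow solve."""

    mode: str = "steady"
    nonlinear_tol: float = 1e-3
    max_nonlinear_iters: int = 200
    relaxation: float = 0.7
    backflow_beta: float = 0.2
    time_step: float = 1e-4
    end_time: float | None = None
    gen_alpha_rho_inf: float = 0.5
    linear_tol: float = 1e-8
    shear_rate_convention: str = "frobenius"

    def __post_init__(self):
        if not 0.0 < self.nonlinear_tol < 1.0:
            raise ValidationError("nonlinear_tol must be in (0, 1)")
        if not 0.0 < self.linear_tol < 1.0:
            raise ValidationError("linear_tol must be in (0, 1)")
        if self.time_step <= 0:
            raise ValidationError("time_step must be > 0")
        if not 0.0 < self.relaxation <= 1.0:
            raise ValidationError("relaxation must be in (0, 1]")
        if not 0.0 <= self.gen_alpha_rho_inf <= 1.0:
            raise ValidationError("gen_alpha_rho_inf must be in [0, 1]")


@dataclass
class ConvergenceRecord:
    iterations: int = 0
    residual_history: list = field(default_factory=list)
    converged: bool = False


@dataclass
class FlowSolution:
    """Nodal velocity/pressure fields with convergence metadata."""

    mesh: VolumeMesh
    velocity: np.ndarray          # (n, 3) m/s
    pressure: np.ndarray          # (n,) Pa
    rheology: object
    density: float
    options: SolverOptions
    convergence: ConvergenceRecord

    def __post_init__(self):
        self._grad_cache = None

    def velocity_gradients(self):
        """Per-element velocity gradient G, G_ij = du_i/dx_j (1/s)."""
        if self._grad_cache is None:
            g, _ = _element_geometry(self.mesh)
            self._grad_cache = np.einsum(
                "mbi,mbj->mij", self.velocity[self.mesh.tets], g)
        return self._grad_cache

    def strain_rate_tensors(self):
        G = self.velocity_gradients()
        return 0.5 * (G + np.swapaxes(G, -1, -2))

    def shear_rates(self):
        return shear_rate(self.velocity_gradients(),
                          convention=self.options.shear_rate_convention)

    def element_viscosity(self):
        return np.asarray(effective_viscosity(self.shear_rates(), self.rheology))

    def mass_balance(self):
        """(net, gross) boundary volume flux (m^3/s) over all patches."""
        mesh = self.mesh
        areas, normals = mesh.face_areas(), mesh.face_normals()
        umean = self.velocity[mesh.boundary_tris].mean(axis=1)
        flux = areas * np.einsum("ij,ij->i", umean, normals)
        return float(flux.sum()), float(np.abs(flux).sum())


def residual_norm(target) -> float:
    """Latest normalized nonlinear residual ||r_k|| / ||r_0||."""
    record = target.convergence if isinstance(target, FlowSolution) else target
    if not isinstance(record, ConvergenceRecord) or not record.residual_history:
        raise StateError("no assembled residual available yet")
    return float(record.residual_history[-1])


def outlet_flux(solution: FlowSolution, patch_label: int) -> float:
    """Volumetric flow Q = int_patch u.n dA (m^3/s), exact for P1 fields."""
    mesh = solution.mesh
    idx = mesh.patch_faces(patch_label)
    if idx.size == 0:
        raise KeyError(f"patch {patch_label} not present in mesh")
    areas, normals = mesh.face_areas()[idx], mesh.face_normals()[idx]
    umean = solution.velocity[mesh.boundary_tris[idx]].mean(axis=1)
    return float(np.sum(areas * np.einsum("ij,ij->i", umean, normals)))


# ---------------------------------------------------------------------------
# Element precomputation
# ---------------------------------------------------------------------------

_GEOM_CACHE = {}


def _element_geometry(mesh: VolumeMesh):
    """Barycentric-function gradients g (m,4,3) and volumes V (m,)."""
    key = id(mesh)
    cached = _GEOM_CACHE.get(key)
    if cached is not None and cached[0] is mesh:
        return cached[1], cached[2]
    p = mesh.nodes[mesh.tets]
    J = np.stack([p[:, 1] - p[:, 0], p[:, 2] - p[:, 0], p[:, 3] - p[:, 0]],
                 axis=2)                                     # column vectors
    V = np.linalg.det(J) / 6.0
    if np.any(V <= 0):
        raise SolverError("mesh contains non-positively-oriented tetrahedra")
    Jinv = np.linalg.inv(J)
    g = np.empty((len(p), 4, 3))
    g[:, 1:, :] = Jinv                                        # row i = grad lambda_i
    g[:, 0, :] = -Jinv.sum(axis=1)
    if len(_GEOM_CACHE) > 4:
        _GEOM_CACHE.clear()
    _GEOM_CACHE[key] = (mesh, g, V)
    return g, V


def _wall_node_normals(mesh: VolumeMesh, wall_patches):
    """Area-weighted outward node normals accumulated from wall faces."""
    acc = np.zeros((mesh.n_nodes, 3))
    for pid in wall_patches:
        idx = mesh.patch_faces(pid)
        areas, normals = mesh.face_areas()[idx], mesh.face_normals()[idx]
        for k in range(3):
            np.add.at(acc, mesh.boundary_tris[idx][:, k], areas[:, None] * normals)
    norm = np.linalg.norm(acc, axis=1)
    mask = norm > 0
    acc[mask] /= norm[mask][:, None]
    return acc, mask


def _patch_flux_vector(mesh: VolumeMesh, patch_id, n_nodes):
    """b with b[(node,i)] = int_patch phi_node n_i dA (velocity dofs)."""
    b = np.zeros(4 * n_nodes)
    idx = mesh.patch_faces(patch_id)
    areas, normals = mesh.face_areas()[idx], mesh.face_normals()[idx]
    contrib = (areas[:, None] / 3.0) * normals
    for k in range(3):
        nodes = mesh.boundary_tris[idx][:, k]
        for i in range(3):
            np.add.at(b, 4 * nodes + i, contrib[:, i])
    return b


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------

def _tau(abar, mu, h, rho):
    nu = mu / rho
    speed = np.linalg.norm(abar, axis=1)
    inv = np.sqrt((2.0 * speed / h) ** 2 + (12.0 * nu / h**2) ** 2)
    tau_m = 1.0 / np.maximum(inv, 1e-300)
    tau_c = h**2 / (12.0 * tau_m)
    return tau_m, tau_c


def _element_blocks(mesh, g, V, u_prev, mu_e, rho):
    """Picard-linearized volume operator as (m,4,4,4,4) blocks [a,i,b,j],
    where i,j = 0..2 are velocity components and 3 is pressure."""
    m = mesh.n_tets
    abar = u_prev[mesh.tets].mean(axis=1)
    h = (6.0 * np.sqrt(2.0) * V) ** (1.0 / 3.0)
    tau_m, tau_c = _tau(abar, mu_e, h, rho)

    adotg = np.einsum("mi,mai->ma", abar, g)                  # a . grad(phi)
    gg = np.einsum("mai,mbi->mab", g, g)
    eye3 = np.eye(3)

    B = np.zeros((m, 4, 4, 4, 4))

    # viscous 2 mu E(u):E(v): mu V (delta_ij g_a.g_b + g_a[j] g_b[i])
    muV = mu_e * V
    B[:, :, :3, :, :3] += (muV[:, None, None] * gg)[:, :, None, :, None] \
        * eye3[None, None, :, None, :]
    B[:, :, :3, :, :3] += muV[:, None, None, None, None] * \
        np.einsum("maj,mbi->mabij", g, g).transpose(0, 1, 3, 2, 4)
    # convection rho (a.grad u, v): rho V/4 (a.g_b) delta_ij (indep. of a)
    B[:, :, :3, :, :3] += (rho * V / 4.0)[:, None, None, None, None] * \
        adotg[:, None, None, :, None] * eye3[None, None, :, None, :]
    # SUPG: rho tau V (a.g_a)(a.g_b) delta_ij
    B[:, :, :3, :, :3] += (rho * tau_m * V)[:, None, None, None, None] * \
        adotg[:, :, None, None, None] * adotg[:, None, None, :, None] * \
        eye3[None, None, :, None, :]
    # LSIC grad-div: rho tau_c V g_a[i] g_b[j]
    B[:, :, :3, :, :3] += (rho * tau_c * V)[:, None, None, None, None] * \
        np.einsum("mai,mbj->maibj", g, g)
    # pressure gradient: -V/4 g_a[i] (indep. of b)
    B[:, :, :3, :, 3] += -(V[:, None, None, None] / 4.0) * g[:, :, :, None]
    # SUPG pressure coupling: tau V (a.g_a) g_b[i]
    B[:, :, :3, :, 3] += (tau_m * V)[:, None, None, None] * \
        adotg[:, :, None, None] * np.swapaxes(g, 1, 2)[:, None, :, :]
    # continuity: V/4 g_b[j] (indep. of a)
    B[:, :, 3, :, :3] += (V[:, None, None, None] / 4.0) * g[:, None, :, :]
    # PSPG convection: tau V g_a[j] (a.g_b)
    B[:, :, 3, :, :3] += (tau_m * V)[:, None, None, None] * \
        np.einsum("maj,mb->mabj", g, adotg)
    # PSPG pressure Laplacian: (tau/rho) V g_a.g_b
    B[:, :, 3, :, 3] += (tau_m / rho * V)[:, None, None] * gg
    return B


def _blocks_to_csr(mesh, B, n_dofs):
    dof = (4 * mesh.tets[:, :, None] + np.arange(4)[None, None, :]).reshape(-1, 16)
    rows = np.repeat(dof, 16, axis=1).ravel()
    cols = np.tile(dof, (1, 16)).ravel()
    data = B.reshape(len(mesh.tets), 16, 16).ravel()
    return sp.coo_matrix((data, (rows, cols)), shape=(n_dofs, n_dofs)).tocsr()


class _System:
    """One Picard-linearized assembly (volume + boundary terms).

    ``A_raw``/``rhs_raw`` exclude the Dirichlet row replacement so time
    integrators can add mass terms first; ``finalize`` applies Dirichlet.
    """

    def __init__(self, mesh, bcs, rheology, opts, density, u_prev):
        self.mesh = mesh
        n_nodes = mesh.n_nodes
        self.n_dofs = n_dofs = 4 * n_nodes
        g, V = _element_geometry(mesh)
        G = np.einsum("mbi,mbj->mij", u_prev[mesh.tets], g)
        gdot = shear_rate(G, convention=opts.shear_rate_convention)
        self.mu_e = mu_e = np.asarray(effective_viscosity(gdot, rheology))

        A = _blocks_to_csr(mesh, _element_blocks(mesh, g, V, u_prev, mu_e,
                                                 density), n_dofs)
        rhs = np.zeros(n_dofs)
        areas, normals = mesh.face_areas(), mesh.face_normals()
        tris = mesh.boundary_tris

        wall_patches = [pid for pid, d in bcs.descriptors.items()
                        if isinstance(d, WallMotion)]
        extra = []
        for pid, d in bcs.descriptors.items():
            if not isinstance(d, (PressureOutlet, ResistanceOutlet)):
                continue
            b = _patch_flux_vector(mesh, pid, n_nodes)
            if isinstance(d, PressureOutlet):
                rhs -= d.pressure * b
            else:
                rhs -= d.spec.distal_pressure * b
                nz = np.flatnonzero(b)
                br, bc = np.meshgrid(nz, nz, indexing="ij")
                extra.append(sp.coo_matrix(
                    (d.spec.resistance * np.outer(b[nz], b[nz]).ravel(),
                     (br.ravel(), bc.ravel())), shape=(n_dofs, n_dofs)))
            # backflow stabilization (Picard-linearized, lumped face mass)
            if opts.backflow_beta > 0:
                idx = mesh.patch_faces(pid)
                un = np.einsum("ij,ij->i", u_prev[tris[idx]].mean(axis=1),
                               normals[idx])
                neg = un < 0
                if np.any(neg):
                    coef = -opts.backflow_beta * density * un[neg] \
                        * areas[idx][neg] / 3.0
                    nodes = tris[idx][neg]
                    r_idx, vals = [], []
                    for k in range(3):
                        for i in range(3):
                            r_idx.append(4 * nodes[:, k] + i)
                            vals.append(coef)
                    r_idx = np.concatenate(r_idx)
                    extra.append(sp.coo_matrix(
                        (np.concatenate(vals), (r_idx, r_idx)),
                        shape=(n_dofs, n_dofs)))
        for e in extra:
            A = A + e.tocsr()
        self.A_raw = A
        self.rhs_raw = rhs

        # Dirichlet wall velocity u = -s n
        nrm, has_nrm = _wall_node_normals(mesh, wall_patches)
        s = max((bcs.descriptors[pid].speed for pid in wall_patches),
                default=0.0)
        wall_nodes = np.flatnonzero(has_nrm)
        dofs = (4 * wall_nodes[:, None] + np.arange(3)[None, :]).ravel()
        vals = (-s * nrm[wall_nodes]).ravel()
        self.dirichlet_dofs = dofs
        self.dirichlet_vals = vals

    def finalize(self, A=None, rhs=None):
        """Apply Dirichlet rows; returns (A_csc, rhs)."""
        A = self.A_raw if A is None else A
        rhs = self.rhs_raw.copy() if rhs is None else rhs.copy()
        if len(self.dirichlet_dofs):
            keep = np.ones(self.n_dofs)
            keep[self.dirichlet_dofs] = 0.0
            A = sp.diags(keep) @ A + sp.diags(1.0 - keep)
            rhs[self.dirichlet_dofs] = self.dirichlet_vals
        return A.tocsc(), rhs


class _LinearSolver:
    """Sparse LU reused as a GMRES preconditioner; refactors when stale."""

    def __init__(self, tol):
        self.lu = None
        self.tol = tol

    def solve(self, A, rhs, x0):
        if self.lu is None:
            self.lu = spla.splu(A)
            return self.lu.solve(rhs)
        M = spla.LinearOperator(A.shape, matvec=self.lu.solve)
        x, info = spla.gmres(A, rhs, x0=x0, rtol=self.tol, atol=0.0,
                             restart=60, maxiter=4, M=M)
        if info != 0:
            self.lu = spla.splu(A)
            x = self.lu.solve(rhs)
        return x


def _split(x):
    return np.column_stack([x[0::4], x[1::4], x[2::4]]), x[3::4].copy()


def solve_steady(mesh: VolumeMesh, bcs: BoundaryConditionSet, rheology,
                 opts: SolverOptions | None = None,
                 density: float = 1060.0,
                 initial: FlowSolution | None = None) -> FlowSolution:
    """Solve the quasi-steady flow problem by Picard iteration.

    Returns a converged FlowSolution, or a non-converged one (flagged in
    ``convergence.converged``) after ``max_nonlinear_iters``; only a
    singular linear system raises SolverError.
    """
    opts = opts or SolverOptions()
    bcs.validate_against(mesh)
    x = np.zeros(4 * mesh.n_nodes)
    if initial is not None:
        x[0::4] = initial.velocity[:, 0]
        x[1::4] = initial.velocity[:, 1]
        x[2::4] = initial.velocity[:, 2]
        x[3::4] = initial.pressure
    record = ConvergenceRecord()
    linsolver = _LinearSolver(opts.linear_tol)
    r0 = None
    try:
        for it in range(opts.max_nonlinear_iters):
            u_prev, _ = _split(x)
            system = _System(mesh, bcs, rheology, opts, density, u_prev)
            A, rhs = system.finalize()
            rnorm = float(np.linalg.norm(rhs - A @ x))
            if r0 is None:
                if rnorm == 0.0:          # null forcing: zero state is exact
                    record.residual_history.append(0.0)
                    record.converged = True
                    break
                r0 = rnorm
            record.residual_history.append(rnorm / r0)
            record.iterations = it + 1
            if rnorm / r0 < opts.nonlinear_tol:
                record.converged = True
                break
            x_new = linsolver.solve(A, rhs, x)
            if not np.all(np.isfinite(x_new)):
                raise SolverError("linear solve produced non-finite values",
                                  diagnostics={"iteration": it})
            x = opts.relaxation * x_new + (1.0 - opts.relaxation) * x
    except RuntimeError as exc:           # SuperLU singular matrix
        raise SolverError(f"linear solver failed: {exc}",
                          diagnostics={"iterations": record.iterations}) from exc
    u, p = _split(x)
    return FlowSolution(mesh=mesh, velocity=u, pressure=p, rheology=rheology,
                        density=density, options=opts, convergence=record)


def solve_unsteady(mesh: VolumeMesh, bcs: BoundaryConditionSet, rheology,
                   opts: SolverOptions, density: float = 1060.0):
    """March the flow in time with the generalized-alpha integrator.

    First-order generalized-alpha (Jansen-Whiting-Hulbert): with spectral
    radius rho_inf, alpha_m = (3 - rho_inf) / (2 (1 + rho_inf)),
    alpha_f = 1 / (1 + rho_inf), gamma = 1/2 + alpha_m - alpha_f. The
    momentum residual is collocated at the intermediate levels; pressure is
    treated at n+1. Returns the list of FlowSolution snapshots. Under
    time-constant BCs the terminal snapshot approaches the steady solution.
    """
    if opts.mode != "unsteady":
        raise ValidationError("opts.mode must be 'unsteady'")
    if opts.end_time is None:
        raise ValidationError("end_time must be set in unsteady mode")
    bcs.validate_against(mesh)
    rho_inf = opts.gen_alpha_rho_inf
    am = 0.5 * (3.0 - rho_inf) / (1.0 + rho_inf)
    af = 1.0 / (1.0 + rho_inf)
    gamma = 0.5 + am - af
    dt = opts.time_step
    n_steps = max(1, int(round(opts.end_time / dt)))
    n_dofs = 4 * mesh.n_nodes

    _, V = _element_geometry(mesh)
    mass = np.zeros(n_dofs)                        # lumped velocity mass
    for a in range(4):
        base = 4 * mesh.tets[:, a]
        for i in range(3):
            np.add.at(mass, base + i, density * V / 4.0)
    vmask = np.ones(n_dofs)
    vmask[3::4] = 0.0
    # velocity columns scale by alpha_f (pressure at n+1)
    Dcol = sp.diags(np.where(vmask > 0, af, 1.0))

    x = np.zeros(n_dofs)                           # state at t_n
    xdot = np.zeros(n_dofs)                        # velocity rate at t_n
    coeff = am / (gamma * dt)
    snapshots = []
    linsolver = _LinearSolver(opts.linear_tol)

    for step in range(n_steps):
        y = x.copy()                               # iterate for x_{n+1}
        last_res = 1.0
        for it in range(max(2, min(opts.max_nonlinear_iters, 10))):
            x_af = x + af * (y - x) * vmask + (y - x) * (1.0 - vmask)
            u_prev, _ = _split(x_af)
            system = _System(mesh, bcs, rheology, opts, density, u_prev)
            # residual terms: M xdot_am + K x_af - f = 0 with
            # xdot_am = (1 - am/gamma) xdot_n + coeff (y - x)
            A_t = system.A_raw @ Dcol + sp.diags(coeff * mass * vmask)
            rhs_t = system.rhs_raw \
                - system.A_raw @ ((1.0 - af) * x * vmask) \
                + mass * vmask * (coeff * x - (1.0 - am / gamma) * xdot)
            A_t, rhs_t = system.finalize(A_t, rhs_t)
            res = float(np.linalg.norm(rhs_t - A_t @ y))
            if it == 0:
                r0 = res if res > 0 else 1.0
            last_res = res / r0
            if it > 0 and last_res < opts.nonlinear_tol:
                break
            y = linsolver.solve(A_t, rhs_t, y)
            if not np.all(np.isfinite(y)):
                raise SolverError(
                    f"time integration diverged at t = {step * dt:.6g} s",
                    diagnostics={"last_stable_time": step * dt})
        xdot = (1.0 - 1.0 / gamma) * xdot + (y - x) * vmask / (gamma * dt)
        x = y
        u, p = _split(x)
        snapshots.append(FlowSolution(
            mesh=mesh, velocity=u, pressure=p, rheology=rheology,
            density=density, options=opts,
            convergence=ConvergenceRecord(iterations=it + 1,
                                          residual_history=[last_res],
                                          converged=True)))
    return snapshots
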