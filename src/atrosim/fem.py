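"""Quasi-static incremental finite elements for atrophy-driven equilibrium.

Discretization: 8-node trilinear hexahedra on the axis-aligned voxel
mesh, full Gauss integration (2x2x2 by default).  At each increment the
atrophy measure theta is updated and the elastic equilibrium

    R(u) = d/du  sum_qp  w  theta psi(Fe(u)),   Fe = theta^(-1/3) F

is re-solved with Newton's method (analytic spectral tangent,
backtracking line search, automatic bisection of the theta increment on
non-convergence).  Displacements are measured from the undeformed
pre-atrophy configuration; the outer CSF surface (inner skull surface)
is held fixed by homogeneous Dirichlet conditions.

An optional mean-dilatation mode ("F-bar": the volumetric part of F is
replaced by its element average) is available as an escape hatch
against volumetric locking at nu close to 0.5; it is off by default and
uses the local tangent evaluated at the modified gradient.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.sparse.linalg import splu

from . import atrophy as atro
from .constitutive import (
    InvertedElementError,
    MaterialTable,
    cauchy_stress_batch,
    ogden_energy_density,
    ogden_pk1,
)
from .phantom import LabeledHexMesh
from .readouts import ReadoutFields, compute_readouts, region_summary
from .regions import scheme_map

log = logging.getLogger(__name__)

_EYE = np.eye(3)

# local corner coordinates, VTK hexahedron ordering
_XI_NODES = np.array(
    [[-1, -1, -1], [1, -1, -1], [1, 1, -1], [-1, 1, -1],
     [-1, -1, 1], [1, -1, 1], [1, 1, 1], [-1, 1, 1]], dtype=float
)


class NonConvergenceError(RuntimeError):
    """Newton iteration failed to reach the residual tolerance."""


@dataclass(frozen=True)
class SolverSettings:
    """Newton/quadrature controls of the quasi-static solver."""

    newton_tol: float = 1e-8         # relative residual tolerance
    max_newton_iters: int = 25
    quadrature: int = 2              # Gauss points per axis
    substep_control: bool = True
    max_substeps: int = 8            # bisection depth of a theta increment
    line_search: bool = True
    fbar: bool = False               # mean-dilatation volumetric treatment
    linear_solver: str = "auto"      # "auto": cached-LU preconditioned CG;
                                     # "direct": factorize every iteration

    def __post_init__(self):
        if self.newton_tol <= 0:
            raise ValueError("newton_tol must be positive")
        if self.quadrature < 1:
            raise ValueError("quadrature must be >= 1")
        if self.linear_solver not in ("auto", "direct"):
            raise ValueError("linear_solver must be 'auto' or 'direct'")


class _CachedLUSolver:
    """Sparse linear solves with a lazily refreshed LU factorization.

    The tangent matrix changes little along the quasi-static
    equilibrium path, so one LU factorization serves as an excellent CG
    preconditioner for many subsequent Newton systems.  The
    factorization is refreshed whenever preconditioned CG fails to
    converge (e.g. far from the state it was built at).
    """

    def __init__(self, direct: bool = False, cg_tol: float = 1e-10,
                 cg_maxiter: int = 60):
        self.direct = direct
        self.cg_tol = cg_tol
        self.cg_maxiter = cg_maxiter
        self._lu = None

    def refresh(self, K: sp.csc_matrix) -> None:
        log.debug("factorizing tangent (%d dofs, nnz %d)", K.shape[0], K.nnz)
        self._lu = splu(K.tocsc())

    def solve(self, K: sp.spmatrix, b: np.ndarray) -> np.ndarray:
        if self.direct or self._lu is None:
            self.refresh(K)
            return self._lu.solve(b)
        M = spla.LinearOperator(K.shape, self._lu.solve)
        x, info = spla.cg(K, b, M=M, rtol=self.cg_tol, atol=0.0,
                          maxiter=self.cg_maxiter)
        if info == 0 and np.all(np.isfinite(x)):
            return x
        log.debug("preconditioned CG stalled (info=%s); refactorizing", info)
        self.refresh(K)
        return self._lu.solve(b)


@dataclass
class SimulationState:
    """Converged state of one increment."""

    u: np.ndarray              # (n_nodes, 3) nodal displacements, mm
    theta: np.ndarray          # (n_elem,) atrophy measure
    F: np.ndarray              # (n_elem, n_qp, 3, 3) total gradient
    Fe: np.ndarray             # (n_elem, n_qp, 3, 3) elastic gradient
    sigma: np.ndarray          # (n_elem, n_qp, 3, 3) Cauchy stress, kPa
    increment_index: int
    time: float                # years

    def element_mean(self, qp_field: np.ndarray) -> np.ndarray:
        return qp_field.mean(axis=1)


def _gauss_1d(n: int):
    return np.polynomial.legendre.leggauss(n)


def shape_gradients(voxel_size: float, n_gauss: int = 2):
    """Reference shape-function gradients G (n_qp, 8, 3) and weights.

    Identical for every element of an axis-aligned voxel mesh; weights
    include the constant Jacobian determinant (h/2)^3.
    """
    pts, wts = _gauss_1d(n_gauss)
    h = voxel_size
    G, W = [], []
    for ix, x in enumerate(pts):
        for iy, y in enumerate(pts):
            for iz, z in enumerate(pts):
                xi = np.array([x, y, z])
                g = np.empty((8, 3))
                for a in range(8):
                    s = _XI_NODES[a]
                    g[a, 0] = s[0] * (1 + s[1] * xi[1]) * (1 + s[2] * xi[2]) / 8
                    g[a, 1] = (1 + s[0] * xi[0]) * s[1] * (1 + s[2] * xi[2]) / 8
                    g[a, 2] = (1 + s[0] * xi[0]) * (1 + s[1] * xi[1]) * s[2] / 8
                G.append(g * 2.0 / h)
                W.append(wts[ix] * wts[iy] * wts[iz] * (h / 2.0) ** 3)
    return np.asarray(G), np.asarray(W)


def rigid_body_pins(mesh: LabeledHexMesh) -> np.ndarray:
    """Minimal 3-2-1 dof pinning that removes rigid-body modes.

    The pins are chosen on grid-aligned nodes so that a homogeneous
    dilatation about the first pinned node remains admissible — the
    natural constraint set for traction-free shrinkage problems.
    """
    coords = mesh.node_coords
    order = np.lexsort((coords[:, 0], coords[:, 1], coords[:, 2]))
    A = order[0]
    xa, ya, za = coords[A]
    on_x_line = np.nonzero((coords[:, 1] == ya) & (coords[:, 2] == za)
                           & (coords[:, 0] != xa))[0]
    in_plane = np.nonzero((coords[:, 2] == za) & (coords[:, 1] != ya))[0]
    if on_x_line.size == 0 or in_plane.size == 0:
        raise ValueError("mesh too degenerate for 3-2-1 rigid-body pinning")
    B = on_x_line[np.argmax(coords[on_x_line, 0])]
    C = in_plane[np.lexsort((coords[in_plane, 0], coords[in_plane, 1]))[0]]
    return np.array([3 * A, 3 * A + 1, 3 * A + 2,
                     3 * B + 1, 3 * B + 2, 3 * C + 2], dtype=np.int64)


def element_materials(mesh: LabeledHexMesh, table: MaterialTable):
    """Per-element (mu, alpha, kappa) arrays from a material table.

    When the table belongs to a coarser scheme than the mesh labels, the
    17R labels are first mapped through the merge hierarchy.
    """
    labels = mesh.element_region
    mapping = scheme_map(table.scheme)
    mu = np.empty(mesh.n_elements)
    alpha = np.empty(mesh.n_elements)
    kappa = np.empty(mesh.n_elements)
    for lab in np.unique(labels):
        key = str(lab)
        if key not in table.params:
            key = mapping[key]
        p = table[key]
        sel = labels == lab
        mu[sel], alpha[sel], kappa[sel] = p.mu, p.alpha, p.kappa
    return mu, alpha, kappa


class FemProblem:
    """Assembled view of one mesh + material + boundary-condition set."""

    def __init__(self, mesh: LabeledHexMesh, mu, alpha, kappa,
                 settings: SolverSettings = SolverSettings(),
                 dirichlet_nodes: np.ndarray | None = None,
                 dirichlet_values: np.ndarray | None = None,
                 pinned_dofs: np.ndarray | None = None):
        self.mesh = mesh
        self.settings = settings
        self.conn = mesh.element_connectivity
        self.n_dof = 3 * mesh.n_nodes
        self.G, self.W = shape_gradients(mesh.voxel_size, settings.quadrature)
        self.n_qp = self.G.shape[0]
        shape_eq = (mesh.n_elements, self.n_qp)
        self.mu = np.broadcast_to(np.asarray(mu, float)[:, None], shape_eq)
        self.alpha = np.broadcast_to(np.asarray(alpha, float)[:, None], shape_eq)
        self.kappa = np.broadcast_to(np.asarray(kappa, float)[:, None], shape_eq)

        # constrained dofs: nodes with all three components prescribed,
        # plus optional individually pinned dofs (for rigid-mode removal)
        if dirichlet_nodes is None:
            dirichlet_nodes = mesh.outer_boundary_nodes
        self.dirichlet_nodes = np.asarray(dirichlet_nodes, dtype=np.int64)
        if dirichlet_values is None:
            dirichlet_values = np.zeros((self.dirichlet_nodes.size, 3))
        self.dirichlet_values = np.asarray(dirichlet_values, dtype=float)
        fixed = np.zeros(self.n_dof, dtype=bool)
        fixed[(3 * self.dirichlet_nodes[:, None] + np.arange(3)).ravel()] = True
        if pinned_dofs is not None:
            fixed[np.asarray(pinned_dofs, dtype=np.int64)] = True
        self.fixed = fixed
        self.free = ~fixed

        # sparse pattern (element dof indices), built once
        edof = (3 * self.conn[:, :, None] + np.arange(3)).reshape(-1, 24)
        self._rows = np.repeat(edof, 24, axis=1).ravel()
        self._cols = np.tile(edof, (1, 24)).ravel()
        self._edof = edof

        # dof -> F mapping per quadrature point: D[q, 24, 9]
        D = np.zeros((self.n_qp, 24, 9))
        for q in range(self.n_qp):
            for a in range(8):
                for i in range(3):
                    for k in range(3):
                        D[q, 3 * a + i, 3 * i + k] = self.G[q, a, k]
        self._D = D
        self._linsolver = _CachedLUSolver(direct=(settings.linear_solver == "direct"))

    # ---- kinematics ---------------------------------------------------
    def apply_bc(self, u: np.ndarray) -> np.ndarray:
        u = u.copy()
        u[self.dirichlet_nodes] = self.dirichlet_values
        return u

    def deformation_gradients(self, u: np.ndarray) -> np.ndarray:
        ue = u[self.conn]                                   # (ne, 8, 3)
        F = np.einsum("eai,qak->eqik", ue, self.G, optimize=True)
        return F + _EYE

    def _theta_qp(self, theta_e: np.ndarray) -> np.ndarray:
        return np.broadcast_to(theta_e[:, None], (self.mesh.n_elements, self.n_qp))

    def _fbar(self, F: np.ndarray) -> np.ndarray:
        J = np.linalg.det(F)
        Jbar = np.average(J, axis=1, weights=self.W)[:, None]
        return F * (Jbar / J)[..., None, None] ** (1.0 / 3.0)

    # ---- energy / residual / tangent ----------------------------------
    def energy(self, u: np.ndarray, theta_e: np.ndarray) -> float:
        F = self.deformation_gradients(u)
        if self.settings.fbar:
            F = self._fbar(F)
        psi0 = ogden_energy_density(F, self.mu, self.alpha, self.kappa,
                                    self._theta_qp(theta_e))
        return float(np.sum(psi0 * self.W))

    def assemble(self, u: np.ndarray, theta_e: np.ndarray, tangent: bool = True):
        """Internal-force residual and (optionally) tangent matrix.

        Returns ``(R, K)`` with R of shape (n_dof,) and K in CSC format
        over all dofs; Dirichlet handling happens at solve time.
        """
        F = self.deformation_gradients(u)
        if self.settings.fbar:
            F = self._fbar(F)
        th = self._theta_qp(theta_e)
        out = ogden_pk1(F, self.mu, self.alpha, self.kappa, th, tangent=tangent)
        P0 = out[0] if tangent else out
        Pw = P0 * self.W[None, :, None, None]
        r_e = np.einsum("eqik,qak->eai", Pw, self.G, optimize=True)
        R = np.zeros(self.n_dof)
        np.add.at(R, self._edof, r_e.reshape(-1, 24))
        if not tangent:
            return R, None
        A0 = out[1]
        ne = self.mesh.n_elements
        Ke = np.zeros((ne, 24, 24))
        for q in range(self.n_qp):
            Aq = A0[:, q].reshape(ne, 9, 9) * self.W[q]
            Dq = self._D[q]
            Ke += Dq @ Aq @ Dq.T
        K = sp.coo_matrix(
            (Ke.ravel(), (self._rows, self._cols)), shape=(self.n_dof, self.n_dof)
        ).tocsc()
        return R, K

    # ---- Newton -------------------------------------------------------
    def solve_equilibrium(self, u0: np.ndarray, theta_e: np.ndarray) -> np.ndarray:
        """Newton iteration to equilibrium at fixed theta.

        ``u0`` is the starting guess; prescribed boundary values are
        enforced on entry.  Raises :class:`NonConvergenceError` or
        :class:`InvertedElementError` on failure (the caller may then
        substep theta).
        """
        st = self.settings
        u = self.apply_bc(u0)
        free = self.free
        R, K = self.assemble(u, theta_e)
        norm0 = np.linalg.norm(R[free])
        # absolute floor: a vanishing fraction of the problem's force scale
        force_scale = float(np.mean(self.mu)) * self.mesh.voxel_size**2 \
            * max(self.mesh.n_elements, 1) ** 0.5
        floor = 1e-12 * max(force_scale, 1e-30)
        target = max(st.newton_tol * norm0, floor)
        if norm0 <= floor:
            return u
        for it in range(st.max_newton_iters):
            K_ff = K[free][:, free].tocsc()
            du = np.zeros(self.n_dof)
            du[free] = self._linsolver.solve(K_ff, -R[free])
            step = 1.0
            E0 = self.energy(u, theta_e)
            slope = float(R[free] @ du[free])
            accepted = False
            for _ in range(12 if st.line_search else 1):
                u_try = u + step * du.reshape(-1, 3)
                try:
                    E1 = self.energy(u_try, theta_e)
                except InvertedElementError:
                    step *= 0.5
                    continue
                if (not st.line_search) or E1 <= E0 + 1e-4 * step * slope or \
                        abs(E1 - E0) <= 1e-14 * max(abs(E0), 1.0):
                    accepted = True
                    break
                step *= 0.5
            if not accepted:
                raise NonConvergenceError(
                    f"line search failed at iteration {it} (|R|={np.linalg.norm(R[free]):.3e})"
                )
            u = u_try
            R, K = self.assemble(u, theta_e)
            norm = np.linalg.norm(R[free])
            log.debug("newton it=%d step=%.3g |R|=%.3e", it, step, norm)
            if norm <= target:
                return u
        raise NonConvergenceError(
            f"no convergence after {st.max_newton_iters} iterations "
            f"(|R|={norm:.3e}, target {target:.3e})"
        )


def solve_increment(problem: FemProblem, u_prev: np.ndarray,
                    theta_prev: np.ndarray, theta_new: np.ndarray) -> np.ndarray:
    """Advance equilibrium from theta_prev to theta_new with substepping.

    On Newton failure the theta increment is bisected recursively (up to
    ``settings.max_substeps`` levels).
    """

    def _solve(u0, th_from, th_to, depth):
        try:
            return problem.solve_equilibrium(u0, th_to)
        except (NonConvergenceError, InvertedElementError):
            if not problem.settings.substep_control or depth >= problem.settings.max_substeps:
                raise
            th_mid = 0.5 * (th_from + th_to)
            log.info("substepping theta increment (depth %d)", depth + 1)
            u_mid = _solve(u0, th_from, th_mid, depth + 1)
            return _solve(u_mid, th_mid, th_to, depth + 1)

    return _solve(u_prev, theta_prev, theta_new, 0)


@dataclass
class SimulationResult:
    """Archive of one quasi-static atrophy run."""

    mesh: LabeledHexMesh
    scheme: str
    times: list[float]
    states: list[SimulationState]
    readouts: list[ReadoutFields]
    summaries: "object"                  # pandas DataFrame over increments
    concentration: atro.ConcentrationField

    @property
    def final_state(self) -> SimulationState:
        return self.states[-1]

    def element_J(self, k: int = -1) -> np.ndarray:
        return np.linalg.det(self.states[k].F).mean(axis=1)


def run_simulation(
    mesh: LabeledHexMesh,
    materials: MaterialTable,
    atrophy_params: atro.AtrophyParams | None = None,
    settings: SolverSettings = SolverSettings(),
    horizon: float = 100.0,
    dt: float = 1.0,
    concentration: atro.ConcentrationField | None = None,
    labels_17R: np.ndarray | None = None,
    output_dir=None,
) -> SimulationResult:
    """Incremental atrophy simulation on a labeled mesh.

    ``materials`` may belong to any region scheme; the mesh is expected
    to carry 17R labels (they are mapped through the merge hierarchy as
    needed).  ``labels_17R`` overrides the labels used for atrophy
    tissue classes and the concentration anchors — pass them when the
    mesh itself was already relabeled to a coarse scheme.  Deterministic
    given its inputs; emits per-increment readouts and region summaries.
    """
    import pandas as pd

    if atrophy_params is None:
        atrophy_params = atro.AtrophyParams()
    if horizon < 0 or dt <= 0:
        raise ValueError("horizon must be >= 0 and dt > 0")
    anat_labels = mesh.element_region if labels_17R is None else np.asarray(labels_17R)
    anat_mesh = mesh if labels_17R is None else mesh.with_labels(anat_labels)
    if concentration is None:
        concentration = atro.build_concentration(anat_mesh)
    rates = atro.atrophy_rates(concentration, anat_labels, atrophy_params)

    mu, alpha, kappa = element_materials(mesh, materials)
    problem = FemProblem(mesh, mu, alpha, kappa, settings)

    state = atro.initial_state(mesh.n_elements, rates)
    u = np.zeros((mesh.n_nodes, 3))

    states: list[SimulationState] = []
    readout_list: list[ReadoutFields] = []
    summary_frames = []

    n_inc = int(round(horizon / dt)) if horizon > 0 else 0

    def record(k, t, u, theta):
        F = problem.deformation_gradients(u)
        Fe = F / theta[:, None, None, None] ** (1.0 / 3.0)
        sigma = cauchy_stress_batch(Fe, problem.mu, problem.alpha, problem.kappa)
        sim_state = SimulationState(u=u.copy(), theta=theta.copy(), F=F, Fe=Fe,
                                    sigma=sigma, increment_index=k, time=t)
        states.append(sim_state)
        ro = compute_readouts(mesh, u, F.mean(axis=1), sigma.mean(axis=1))
        readout_list.append(ro)
        J_elem = np.linalg.det(F).mean(axis=1)
        df = region_summary(anat_mesh, J_elem, ro)
        df["increment"] = k
        df["time"] = t
        summary_frames.append(df.reset_index())
        return sim_state

    record(0, 0.0, u, state.theta)

    for k in range(1, n_inc + 1):
        new_state = atro.update_theta(state, rates, dt)
        u = solve_increment(problem, u, state.theta, new_state.theta)
        state = new_state
        log.info("increment %d/%d t=%.2f yr mean theta=%.5f",
                 k, n_inc, state.time, state.theta.mean())
        record(k, state.time, u, state.theta)

    summaries = pd.concat(summary_frames, ignore_index=True)
    result = SimulationResult(
        mesh=mesh, scheme=materials.scheme, times=[s.time for s in states],
        states=states, readouts=readout_list, summaries=summaries,
        concentration=concentration,
    )
    if output_dir is not None:
        from . import vtkio
        vtkio.write_run(result, output_dir)
    return result
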