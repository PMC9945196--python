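"""Displacement-controlled nonlinear voxel finite-element solver.

The mechanical model is small-strain J2 (von Mises) plasticity with the
Swift–Voce isotropic hardening law of :mod:`tbfe.materials`, discretized with
trilinear hexahedral elements mapped 1:1 to voxels.  Loading mimics a platen
test: the bottom surface nodes are fixed in all directions and a prescribed
displacement is applied to every top-surface node, ramped uniformly over
``n_substeps`` to a total apparent strain (default 0.1%).  For compression
the displacement acts along z; for x-/y-shear it acts along x or y while the
other top-node components are held (movements orthogonal to the applied
displacement are restricted).

Each sub-step is equilibrated by Newton–Raphson iteration with the consistent
algorithmic tangent of the backward-Euler radial-return stress update.
Convergence requires both a force check (residual norm <= force_tol x
reaction-force norm, L2) and a displacement check (correction norm <=
disp_tol x sub-step increment norm, L2), mirroring the classical 0.5% / 5%
defaults of commercial codes.

The flow stress is defined so that a strain-driven uniaxial test reproduces
the printed Swift–Voce curve *in total strain* exactly: sigma_y(alpha) is the
solution of sigma = S(sigma/E + alpha), where S is the plastic limb of the
hardening curve and alpha the accumulated equivalent plastic strain.  The
radial return then solves a single scalar equation per yielding Gauss point,

    q_trial - 3 G dgamma = S((q_trial - 3 G dgamma)/E + alpha_n + dgamma).

Assembly order is deterministic, so repeated runs are bit-identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from . import elements as el
from .errors import AnchoringError, ConfigError, ConvergenceError, MaterialError
from .materials import ElementMaterial
from .mesh import HexMesh, boundary_sets

log = logging.getLogger(__name__)

MODES = ("compression", "x_shear", "y_shear")
#: displacement direction (DOF axis) for each load mode; loading surfaces are
#: always the axial (z) faces — shear changes the displacement direction only.
_MODE_AXIS = {"compression": 2, "x_shear": 0, "y_shear": 1}
_MODE_SIGN = {"compression": -1.0, "x_shear": 1.0, "y_shear": 1.0}


@dataclass(frozen=True)
class LoadCase:
    """One displacement-controlled loading protocol.

    ``bc_mode="production"`` reproduces the constrained-platen boundary
    conditions (bottom fully fixed, top orthogonal movements restricted);
    ``bc_mode="validation"`` releases the lateral constraints (compression
    only) so closed-form uniaxial-stress states are attainable — used by
    verification tests, not by the imaging protocol.
    """

    mode: str = "compression"
    total_strain: float = 0.001
    n_substeps: int = 50
    bc_mode: str = "production"

    def __post_init__(self):
        if self.mode not in MODES:
            raise ConfigError(f"mode must be one of {MODES}, got {self.mode!r}")
        if not self.total_strain > 0:
            raise ConfigError("total_strain must be positive")
        if self.n_substeps < 1:
            raise ConfigError("n_substeps must be >= 1")
        if self.bc_mode not in ("production", "validation"):
            raise ConfigError(f"unknown bc_mode {self.bc_mode!r}")
        if self.bc_mode == "validation" and self.mode != "compression":
            raise ConfigError("validation BCs are defined for compression only")


@dataclass(frozen=True)
class SolverSettings:
    """Numerical controls for the nonlinear solve.

    ``linear_solver``: ``direct`` factorizes the tangent (SuperLU); ``cg`` runs Jacobi-preconditioned conjugate gradients —
    the memory-lean choice for large grids, where warm-started sub-steps
    leave only one hard solve per load case; ``auto`` picks ``direct`` below
    ``cg_dof_threshold`` free DOFs.  Both deliver the same solution within
    solver tolerance.
    """

    force_tol: float = 0.005
    disp_tol: float = 0.05
    max_newton_iters: int = 25
    quadrature: str = "b_bar"
    geometric_nonlinearity: bool = False
    linear_solver: str = "auto"
    cg_dof_threshold: int = 15_000
    cg_tol: float = 1e-8
    store_fields: str = "all"   # "all" | "last"

    def __post_init__(self):
        if not (0 < self.force_tol < 1 and 0 < self.disp_tol < 1):
            raise ConfigError("tolerances must lie in (0, 1)")
        if self.max_newton_iters < 1:
            raise ConfigError("max_newton_iters must be >= 1")
        if self.quadrature not in ("b_bar", "full"):
            raise ConfigError(f"unknown quadrature {self.quadrature!r}")
        if self.linear_solver not in ("auto", "direct", "cg"):
            raise ConfigError(f"unknown linear_solver {self.linear_solver!r}")
        if self.store_fields not in ("all", "last"):
            raise ConfigError("store_fields must be 'all' or 'last'")


@dataclass
class SolutionState:
    """Converged state at the end of one sub-step."""

    substep_index: int
    load_factor: float              # k / n_substeps
    applied_strain: float           # load_factor * total_strain
    nodal_displacements: np.ndarray  # (n_nodes, 3) mm
    stress: np.ndarray              # (ne, 6) element-centroid stress, MPa
    von_mises: np.ndarray           # (ne,) MPa
    eq_plastic_strain: np.ndarray   # (ne,)
    converged: bool = True
    n_newton_iters: int = 0
    residual_norm: float = 0.0


def von_mises(stress: np.ndarray) -> np.ndarray:
    """Von Mises equivalent stress of Voigt tensors (..., 6)."""
    s = np.asarray(stress, dtype=float)
    sx, sy, sz, txy, tyz, tzx = (s[..., i] for i in range(6))
    return np.sqrt(0.5 * ((sx - sy) ** 2 + (sy - sz) ** 2 + (sz - sx) ** 2)
                   + 3.0 * (txy ** 2 + tyz ** 2 + tzx ** 2))


def element_stiffness(mat: ElementMaterial, edge_length_mm: float,
                      tangent_moduli: np.ndarray | None = None,
                      quadrature: str = "b_bar") -> np.ndarray:
    """24x24 stiffness of a single cube element.

    With ``tangent_moduli`` (8, 6, 6) given, each Gauss point uses its own
    moduli matrix (elastoplastic tangent); otherwise the isotropic elastic
    moduli from ``mat`` are used.
    """
    if not edge_length_mm > 0:
        raise MaterialError("edge length must be positive")
    E = float(np.asarray(mat.E).reshape(()))
    if not E > 0:
        raise MaterialError("elastic modulus must be positive")
    B, detJw = el.cube_b_matrices(edge_length_mm, quadrature)
    if tangent_moduli is None:
        D = np.broadcast_to(el.elastic_moduli_matrix(E, mat.poisson), (8, 6, 6))
    else:
        D = np.asarray(tangent_moduli, dtype=float)
        if D.shape != (8, 6, 6):
            raise MaterialError(f"tangent_moduli must have shape (8, 6, 6), got {D.shape}")
    K = np.einsum("gia,gij,gjb,g->ab", B, D, B, detJw, optimize=True)
    return 0.5 * (K + K.T)


# ----------------------------------------------------------------------------
# stress update (vectorized backward-Euler radial return)
# ----------------------------------------------------------------------------

_ENG = np.array([1.0, 1.0, 1.0, 2.0, 2.0, 2.0])


class _MaterialArrays:
    """Per-element constitutive parameters broadcast against (ne, 8) gauss grids."""

    def __init__(self, mat: ElementMaterial, ne: int):
        def col(a):
            a = np.asarray(a, dtype=float)
            if a.ndim == 0:
                a = np.full(ne, float(a))
            if a.shape != (ne,):
                raise MaterialError(f"material field shape {a.shape} != ({ne},)")
            return a[:, None]  # broadcast over gauss axis

        self.E = col(mat.E)
        self.S_max = col(mat.S_max)
        self.R1 = col(mat.R1)
        self.R2 = col(mat.R2)
        self.b = col(mat.b)
        self.eps_el = col(mat.eps_el)
        self.poisson = float(mat.poisson)
        self.G = self.E / (2 * (1 + self.poisson))
        self.K_bulk = self.E / (3 * (1 - 2 * self.poisson))
        self.lam = self.E * self.poisson / ((1 + self.poisson) * (1 - 2 * self.poisson))

    def s_plastic(self, eps):
        """Plastic-branch Swift–Voce expression (analytic continuation).

        The exponent is clipped to keep far-below-yield trial states finite;
        the yield check only ever uses the sign of q - S there.
        """
        x = eps - self.eps_el
        ex = np.exp(np.minimum(-self.b * x, 500.0))
        return self.S_max + self.R1 * (1 - ex) + self.R2 * x

    def s_plastic_slope(self, eps):
        x = eps - self.eps_el
        return self.R1 * self.b * np.exp(np.minimum(-self.b * x, 500.0)) + self.R2


def _radial_return(ma: _MaterialArrays, eps: np.ndarray, eps_p: np.ndarray,
                   alpha: np.ndarray):
    """Backward-Euler radial return over all Gauss points.

    Parameters: total strain ``eps`` (ne, 8, 6, engineering shear), committed
    plastic strain ``eps_p`` and equivalent plastic strain ``alpha``.

    Returns (stress, eps_p_new, alpha_new, plastic_mask, H_eff, n_dir, beta)
    where the last three feed the consistent tangent.
    """
    ee = eps - eps_p
    tr = ee[..., 0] + ee[..., 1] + ee[..., 2]
    sigma = np.empty_like(ee)
    sigma[..., :3] = ma.lam[..., None] * tr[..., None] + 2 * ma.G[..., None] * ee[..., :3]
    sigma[..., 3:] = ma.G[..., None] * ee[..., 3:]

    p_mean = tr * ma.K_bulk  # hydrostatic stress = K * volumetric strain
    s_dev = sigma.copy()
    s_dev[..., :3] -= p_mean[..., None]
    q_tr = np.sqrt(1.5 * (s_dev[..., :3] ** 2).sum(-1) + 3.0 * (s_dev[..., 3:] ** 2).sum(-1))

    # yield check: q_tr > sigma_y(alpha) <=> q_tr - S((q_tr)/E + alpha) > 0
    g0 = q_tr - ma.s_plastic(q_tr / ma.E + alpha)
    plastic = g0 > 1e-10 * np.maximum(ma.S_max, q_tr)

    dgamma = np.zeros_like(q_tr)
    if plastic.any():
        idx = np.nonzero(plastic)
        qp = q_tr[idx]
        ap = alpha[idx]
        Ep = np.broadcast_to(ma.E, q_tr.shape)[idx]
        Gp = np.broadcast_to(ma.G, q_tr.shape)[idx]
        sp_ = _SubMat(ma, idx[0])
        dg = np.zeros_like(qp)
        for _ in range(40):
            sig = qp - 3 * Gp * dg
            arg = sig / Ep + ap + dg
            g = sig - sp_.s_plastic(arg)
            slope = sp_.s_plastic_slope(arg)
            dgdx = -3 * Gp - slope * (1 - 3 * Gp / Ep)
            step = g / dgdx
            dg = np.maximum(dg - step, 0.0)
            if np.all(np.abs(g) <= 1e-11 * np.maximum(qp, 1.0)):
                break
        else:
            raise ConvergenceError("radial-return scalar Newton failed",
                                   residual=float(np.abs(g).max()))
        dgamma[idx] = dg

    sig_y = q_tr - 3 * ma.G * dgamma
    safe_q = np.where(q_tr > 0, q_tr, 1.0)
    scale = np.where(plastic, 3 * ma.G * dgamma / safe_q, 0.0)
    sigma_new = sigma.copy()
    sigma_new -= scale[..., None] * s_dev  # shrinks only the deviator

    flow = (1.5 * dgamma / safe_q)[..., None] * s_dev * _ENG
    eps_p_new = eps_p + np.where(plastic[..., None], flow, 0.0)
    alpha_new = alpha + dgamma

    # implicit hardening modulus d sigma_y / d alpha at the updated state
    arg_new = sig_y / ma.E + alpha_new
    sl = ma.s_plastic_slope(arg_new)
    H_eff = sl / (1 - sl / ma.E)

    norm_s = np.sqrt((s_dev[..., :3] ** 2).sum(-1) + 2.0 * (s_dev[..., 3:] ** 2).sum(-1))
    n_dir = s_dev / np.where(norm_s > 0, norm_s, 1.0)[..., None]
    beta = np.where(plastic, sig_y / safe_q, 1.0)
    return sigma_new, eps_p_new, alpha_new, plastic, H_eff, n_dir, beta


class _SubMat:
    """Material-parameter view restricted to a subset of elements."""

    def __init__(self, ma: _MaterialArrays, elem_idx: np.ndarray):
        for name in ("E", "S_max", "R1", "R2", "b", "eps_el"):
            setattr(self, name, getattr(ma, name)[elem_idx, 0])

    s_plastic = _MaterialArrays.s_plastic
    s_plastic_slope = _MaterialArrays.s_plastic_slope


# ----------------------------------------------------------------------------
# boundary conditions
# ----------------------------------------------------------------------------

def _build_bcs(mesh: HexMesh, case: LoadCase):
    """Prescribed DOF indices and their values at full load (load factor 1)."""
    top, bottom = boundary_sets(mesh, "z")
    height = mesh.extent_mm(2)
    u_total = case.total_strain * height * _MODE_SIGN[case.mode]
    axis = _MODE_AXIS[case.mode]

    dofs, vals = [], []
    if case.bc_mode == "production":
        for d in range(3):
            dofs.append(bottom * 3 + d)
            vals.append(np.zeros(bottom.size))
        for d in range(3):
            dofs.append(top * 3 + d)
            vals.append(np.full(top.size, u_total) if d == axis else np.zeros(top.size))
    else:  # validation: uniaxial-stress compression, lateral contraction free
        dofs.append(bottom * 3 + 2)
        vals.append(np.zeros(bottom.size))
        dofs.append(top * 3 + 2)
        vals.append(np.full(top.size, u_total))
        xy = mesh.node_coords[bottom][:, :2]
        order = np.lexsort((xy[:, 0], xy[:, 1]))  # sort by (y, x)
        pin = bottom[order[0]]
        same_y = bottom[np.isclose(xy[:, 1], xy[order[0], 1])]
        far = same_y[np.argmax(mesh.node_coords[same_y, 0])]
        dofs.append(np.array([pin * 3, pin * 3 + 1, far * 3 + 1]))
        vals.append(np.zeros(3))
    return np.concatenate(dofs), np.concatenate(vals), top, bottom


# ----------------------------------------------------------------------------
# the solver
# ----------------------------------------------------------------------------

class _LinearSolver:
    """Direct (SuperLU) or Jacobi-preconditioned CG solve of K_ff x = b."""

    def __init__(self, settings: SolverSettings, n_free: int):
        if settings.linear_solver == "auto":
            self.kind = "direct" if n_free <= settings.cg_dof_threshold else "cg"
        else:
            self.kind = settings.linear_solver
        self.settings = settings
        self._lu = None

    def invalidate(self):
        self._lu = None

    def solve(self, K_ff, b, reuse_factorization: bool = False):
        if self.kind == "direct":
            try:
                if reuse_factorization:
                    # cache slot holds the (elastic) matrix that may be reused
                    if self._lu is None:
                        self._lu = spla.splu(K_ff.tocsc())
                    lu = self._lu
                else:
                    lu = spla.splu(K_ff.tocsc())
            except RuntimeError as exc:  # singular factor
                raise AnchoringError(
                    f"stiffness matrix is singular ({exc}); check that every mesh "
                    "component is anchored to the bottom surface") from exc
            return lu.solve(b)
        d = K_ff.diagonal()
        if np.any(d <= 0):
            raise AnchoringError(
                "stiffness diagonal non-positive; check that every mesh component "
                "is anchored to the bottom surface")
        d_inv = 1.0 / d
        M = spla.LinearOperator(K_ff.shape, matvec=lambda x: d_inv * x)
        x, info = spla.cg(K_ff, b, rtol=self.settings.cg_tol, atol=0.0,
                          M=M, maxiter=30_000)
        if info != 0:
            raise ConvergenceError(f"preconditioned CG did not converge (info={info})")
        return x


def _check_anchored(mesh: HexMesh) -> None:
    """Raise if a 26-connected component does not reach the fixed bottom layer."""
    from scipy import ndimage

    mask = np.zeros(mesh.shape, dtype=bool)
    v = mesh.element_to_voxel
    mask[v[:, 0], v[:, 1], v[:, 2]] = True
    labels, n = ndimage.label(mask, structure=np.ones((3, 3, 3), int))
    if n <= 1:
        return
    zmin = int(v[:, 2].min())
    anchored = set(np.unique(labels[:, :, zmin]).tolist()) - {0}
    if len(anchored) < n:
        raise AnchoringError(
            f"{n - len(anchored)} mesh component(s) are not anchored to the bottom "
            "surface; the stiffness matrix is singular under bottom-fixed loading "
            "(rebuild the mesh with drop_floating=True to remove them)")


def solve_load_case(mesh: HexMesh, materials: ElementMaterial, case: LoadCase,
                    settings: SolverSettings | None = None) -> list[SolutionState]:
    """Run one displacement-controlled load case; one SolutionState per sub-step."""
    settings = settings or SolverSettings()
    _check_anchored(mesh)
    dofs, vals, _, _ = _build_bcs(mesh, case)
    return solve_displacement_controlled(mesh, materials, dofs, vals,
                                         n_substeps=case.n_substeps,
                                         settings=settings,
                                         total_strain=case.total_strain)


def solve_displacement_controlled(mesh: HexMesh, materials: ElementMaterial,
                                  prescribed_dofs: np.ndarray,
                                  prescribed_values: np.ndarray,
                                  n_substeps: int = 1,
                                  settings: SolverSettings | None = None,
                                  total_strain: float | None = None) -> list[SolutionState]:
    """General incremental solve with explicit prescribed-DOF values.

    ``prescribed_values`` are the displacements at full load; sub-step ``k``
    applies the fraction ``k / n_substeps``.  This lower-level entry point also
    serves patch-type verification problems with arbitrary Dirichlet data.
    """
    settings = settings or SolverSettings()
    ne = mesh.n_elements
    ndof = 3 * mesh.n_nodes
    edof = (mesh.elements[:, :, None] * 3 + np.arange(3)).reshape(ne, 24)

    ma = _MaterialArrays(materials, ne)

    prescribed_dofs = np.asarray(prescribed_dofs, dtype=np.int64)
    uniq, first = np.unique(prescribed_dofs, return_index=True)
    prescribed_values = np.asarray(prescribed_values, dtype=float)[first]
    prescribed_dofs = uniq
    free = np.ones(ndof, dtype=bool)
    free[prescribed_dofs] = False
    free_idx = np.flatnonzero(free)

    coords0 = mesh.node_coords[mesh.elements]  # (ne, 8, 3)

    # committed state
    u = np.zeros(ndof)
    eps_c = np.zeros((ne, 8, 6))
    eps_p = np.zeros((ne, 8, 6))
    alpha = np.zeros((ne, 8))
    du_prev = None

    lin = _LinearSolver(settings, free_idx.size)
    results: list[SolutionState] = []

    B = detJw = K_el_ff = K_el_fp = None

    def build_operators(u_committed):
        nonlocal B, detJw, K_el_ff, K_el_fp
        if settings.geometric_nonlinearity:
            disp = u_committed.reshape(-1, 3)[mesh.elements]
            B, detJw = el.hex_b_matrices(coords0 + disp, settings.quadrature)
        else:
            Bc, dJ = el.cube_b_matrices(mesh.edge_length_mm, settings.quadrature)
            B = np.broadcast_to(Bc, (ne, 8, 6, 24))
            detJw = np.broadcast_to(dJ, (ne, 8))
        D1 = el.elastic_moduli_matrix(1.0, ma.poisson)
        if settings.geometric_nonlinearity:
            K_ref = np.einsum("ngia,ij,ngjb,ng->nab", B, D1, B, detJw, optimize=True)
        else:
            K_ref = np.einsum("gia,ij,gjb,g->ab", B[0], D1, B[0], detJw[0], optimize=True)
            K_ref = np.broadcast_to(K_ref, (ne, 24, 24))
        # chunked COO accumulation keeps the assembly's transient memory small
        edof32 = edof.astype(np.int32)
        K = None
        n_chunks = max(1, ne * 576 * 16 // (300 * 2 ** 20))
        for chunk in np.array_split(np.arange(ne), n_chunks):
            ed = edof32[chunk]
            data = (ma.E[chunk, :, None] * K_ref[chunk]).ravel()
            rows = np.repeat(ed, 24, axis=1).ravel()
            cols = np.tile(ed, (1, 24)).ravel()
            Kc = sp.coo_matrix((data, (rows, cols)), shape=(ndof, ndof)).tocsr()
            K = Kc if K is None else K + Kc
        K_el_ff = K[free_idx][:, free_idx].tocsr()
        K_el_fp = K[free_idx][:, prescribed_dofs].tocsr()
        lin.invalidate()

    build_operators(u)

    def local_strain(u_vec):
        ue = u_vec[edof]
        if settings.geometric_nonlinearity:
            due = ue - u_committed_e
            return eps_c + np.einsum("ngik,nk->ngi", B, due)
        return np.einsum("ngik,nk->ngi", B, ue)

    def internal_force(sigma):
        fe = np.einsum("ngik,ngi,ng->nk", B, sigma, detJw)
        f = np.zeros(ndof)
        np.add.at(f, edof.ravel(), fe.ravel())
        return f

    # --- substep loop -------------------------------------------------------
    n = n_substeps
    u_committed_e = u[edof]
    for k in range(1, n + 1):
        lf = k / n
        target = prescribed_values * lf
        u_new = u.copy()
        u_new[prescribed_dofs] = target
        if du_prev is not None:
            u_new[free_idx] += du_prev
        else:
            # exact elastic predictor for the first sub-step: a zero free-field
            # guess concentrates all strain at the loaded surface and can
            # spuriously trigger (softening) plasticity there
            u_new[free_idx] += lin.solve(
                K_el_ff, -(K_el_fp @ (target - u[prescribed_dofs])),
                reuse_factorization=True)
        du_corr_norm = 0.0
        n_iter = 0
        converged = False
        last_res = np.inf
        for it in range(settings.max_newton_iters + 1):
            eps = local_strain(u_new)
            sigma, eps_p_new, alpha_new, plastic, H_eff, n_dir, beta = \
                _radial_return(ma, eps, eps_p, alpha)
            f_int = internal_force(sigma)
            r_f = -f_int[free_idx]
            ref = np.linalg.norm(f_int[prescribed_dofs])
            res = np.linalg.norm(r_f)
            last_res = res
            inc = u_new - u
            inc_norm = np.linalg.norm(inc)
            force_ok = res <= settings.force_tol * max(ref, 1e-30)
            disp_ok = du_corr_norm <= settings.disp_tol * max(inc_norm, 1e-30)
            if force_ok and disp_ok:
                converged = True
                n_iter = it
                break
            if it == settings.max_newton_iters:
                break
            if plastic.any():
                K_t_ff = _assemble_tangent(K_el_ff, B, detJw, edof, free_idx, ne,
                                           ma, plastic, H_eff, n_dir, beta)
                du = lin.solve(K_t_ff, r_f)
            else:
                du = lin.solve(K_el_ff, r_f, reuse_factorization=True)
            u_new[free_idx] += du
            du_corr_norm = np.linalg.norm(du)
        if not converged:
            raise ConvergenceError(
                f"Newton failed at sub-step {k}/{n} after {settings.max_newton_iters} "
                f"iterations (|r| = {last_res:.3e})", residual=float(last_res))

        # commit
        du_prev = u_new[free_idx] - u[free_idx]
        u = u_new
        eps_c = eps
        eps_p, alpha = eps_p_new, alpha_new
        if settings.geometric_nonlinearity:
            build_operators(u)
            u_committed_e = u[edof]

        # every sub-step keeps its (small) von Mises field so stress-strain
        # curves can always be built; "last" drops only the heavy fields on
        # intermediate sub-steps
        full = settings.store_fields == "all" or k == n
        stress_c = sigma.mean(axis=1)
        state = SolutionState(
            substep_index=k, load_factor=lf,
            applied_strain=(total_strain or 0.0) * lf,
            nodal_displacements=(u.reshape(-1, 3).copy() if full
                                 else np.empty((0, 3))),
            stress=stress_c if full else np.empty((0, 6)),
            von_mises=von_mises(stress_c),
            eq_plastic_strain=(alpha.mean(axis=1).copy() if full
                               else np.empty(0)),
            converged=True, n_newton_iters=n_iter,
            residual_norm=float(last_res),
        )
        results.append(state)
    return results


def _assemble_tangent(K_el_ff, B, detJw, edof, free_idx, ne, ma,
                      plastic, H_eff, n_dir, beta):
    """Consistent tangent: elastic stiffness plus plastic Gauss-point corrections."""
    elems = np.flatnonzero(plastic.any(axis=1))
    I_d = el.deviatoric_identity()
    Gp = ma.G[elems]                      # (me, 1)
    gamma_bar = 1.0 / (1.0 + H_eff[elems] / (3.0 * Gp)) - (1.0 - beta[elems])
    nd = n_dir[elems]
    dD = (2.0 * Gp[..., None, None] * (beta[elems][..., None, None] - 1.0) * I_d
          - 2.0 * Gp[..., None, None] * gamma_bar[..., None, None]
          * nd[..., :, None] * nd[..., None, :])
    dD = np.where(plastic[elems][..., None, None], dD, 0.0)
    if B.shape[0] == ne:
        Be = B[elems]
        dJe = detJw[elems]
    else:
        Be = np.broadcast_to(B[0], (elems.size,) + B.shape[1:])
        dJe = np.broadcast_to(detJw[0], (elems.size, detJw.shape[-1]))
    dK = np.einsum("ngia,ngij,ngjb,ng->nab", Be, dD, Be, dJe, optimize=True)
    ed = edof[elems]
    rows = np.repeat(ed, 24, axis=1).ravel()
    cols = np.tile(ed, (1, 24)).ravel()
    # map to free-dof numbering; entries touching prescribed dofs are dropped
    size = int(max(rows.max(), cols.max(), free_idx.max())) + 1
    full2free = _full_to_free_map(free_idx, size)
    rf = full2free[rows]
    cf = full2free[cols]
    keep = (rf >= 0) & (cf >= 0)
    corr = sp.coo_matrix((dK.ravel()[keep], (rf[keep], cf[keep])),
                         shape=K_el_ff.shape).tocsc()
    return (K_el_ff + corr).tocsc()


def _full_to_free_map(free_idx: np.ndarray, size: int) -> np.ndarray:
    m = np.full(size, -1, dtype=np.int64)
    m[free_idx] = np.arange(free_idx.size)
    return m


def reaction_forces(mesh: HexMesh, materials: ElementMaterial,
                    state: SolutionState, settings: SolverSettings | None = None,
                    eps_p: np.ndarray | None = None) -> np.ndarray:
    """Nodal internal-force vector (reactions at constrained nodes).

    Recomputed from the stored displacement field assuming the committed
    plastic strain is ``eps_p`` (elastic if omitted); exact for elastic runs
    and for the final converged state of plastic runs when ``eps_p`` matches.
    """
    settings = settings or SolverSettings()
    ne = mesh.n_elements
    edof = (mesh.elements[:, :, None] * 3 + np.arange(3)).reshape(ne, 24)
    Bc, dJ = el.cube_b_matrices(mesh.edge_length_mm, settings.quadrature)
    B = np.broadcast_to(Bc, (ne, 8, 6, 24))
    detJw = np.broadcast_to(dJ, (ne, 8))
    ma = _MaterialArrays(materials, ne)
    eps = np.einsum("ngik,nk->ngi", B, state.nodal_displacements.reshape(-1)[edof])
    ep = eps_p if eps_p is not None else np.zeros_like(eps)
    al = np.zeros((ne, 8))
    sigma, *_ = _radial_return(ma, eps, ep, al)
    fe = np.einsum("ngik,ngi,ng->nk", B, sigma, detJw)
    f = np.zeros(3 * mesh.n_nodes)
    np.add.at(f, edof.ravel(), fe.ravel())
    return f.reshape(-1, 3)
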