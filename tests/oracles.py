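"""Independent reference implementations used only to check the package.

Everything here is deliberately written from scratch along different
algorithmic routes than the package: normal-equations least squares, a
brute-force high-order-quadrature element stiffness with its own shape
functions, a dense-matrix nonlinear FE solver with explicit constraint
elimination and a bisection-based radial return, ANOVA-sums ICC, and a
sort-based percentile.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.optimize import brentq

# ---------------------------------------------------------------------------
# least squares via normal equations
# ---------------------------------------------------------------------------


def ols_normal_equations(x, y):
    """(slope, intercept, r^2) from the closed-form normal equations."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = x.size
    sx, sy, sxx, sxy = x.sum(), y.sum(), (x * x).sum(), (x * y).sum()
    slope = (n * sxy - sx * sy) / (n * sxx - sx * sx)
    intercept = (sy - slope * sx) / n
    resid = y - slope * x - intercept
    ss_tot = ((y - y.mean()) ** 2).sum()
    r2 = 1.0 - (resid ** 2).sum() / ss_tot if ss_tot > 0 else 1.0
    return slope, intercept, r2


# ---------------------------------------------------------------------------
# brute-force hexahedral element stiffness (own shape functions, 4^3 Gauss)
# ---------------------------------------------------------------------------

# corners ordered by binary (dx, dy, dz) — differs from the package's ordering
_BIN_CORNERS = [(dx, dy, dz) for dz in (0, 1) for dy in (0, 1) for dx in (0, 1)]
# map binary ordering -> VTK hexahedron ordering used by the package
_BIN_TO_VTK = {(0, 0, 0): 0, (1, 0, 0): 1, (1, 1, 0): 2, (0, 1, 0): 3,
               (0, 0, 1): 4, (1, 0, 1): 5, (1, 1, 1): 6, (0, 1, 1): 7}


def _shape_value_and_grad(corner, r, s, t):
    """Trilinear shape function on [0,1]^3 for a binary-ordered corner."""
    cx, cy, cz = corner
    fx = r if cx else 1 - r
    fy = s if cy else 1 - s
    fz = t if cz else 1 - t
    dfx = 1.0 if cx else -1.0
    dfy = 1.0 if cy else -1.0
    dfz = 1.0 if cz else -1.0
    return fx * fy * fz, np.array([dfx * fy * fz, fx * dfy * fz, fx * fy * dfz])


def brute_force_element_stiffness(E, nu, h, n_gauss=4):
    """24x24 cube-element stiffness by full numerical integration.

    Unit-cube parametrization, Gauss-Legendre n_gauss^3 points, VTK DOF
    ordering on output so it is directly comparable with the package.
    """
    pts, wts = np.polynomial.legendre.leggauss(n_gauss)
    pts = 0.5 * (pts + 1.0)  # [0, 1]
    wts = 0.5 * wts
    lam = E * nu / ((1 + nu) * (1 - 2 * nu))
    G = E / (2 * (1 + nu))
    D = np.zeros((6, 6))
    D[:3, :3] = lam
    D[np.arange(3), np.arange(3)] += 2 * G
    D[np.arange(3, 6), np.arange(3, 6)] = G
    K = np.zeros((24, 24))
    for (r, wr), (s, ws), (t, wt) in itertools.product(zip(pts, wts), repeat=3):
        B = np.zeros((6, 24))
        for corner in _BIN_CORNERS:
            a = _BIN_TO_VTK[corner]
            _, g = _shape_value_and_grad(corner, r, s, t)
            g = g / h  # d/dx = d/dr * dr/dx
            B[0, 3 * a + 0] = g[0]
            B[1, 3 * a + 1] = g[1]
            B[2, 3 * a + 2] = g[2]
            B[3, 3 * a + 0] = g[1]
            B[3, 3 * a + 1] = g[0]
            B[4, 3 * a + 1] = g[2]
            B[4, 3 * a + 2] = g[1]
            B[5, 3 * a + 0] = g[2]
            B[5, 3 * a + 2] = g[0]
        K += (wr * ws * wt) * (h ** 3) * (B.T @ D @ B)
    return K


# ---------------------------------------------------------------------------
# dense-matrix nonlinear solver (explicit elimination, bisection radial return)
# ---------------------------------------------------------------------------


def _swift_voce_plastic(S_max, R1, R2, b, eps_el, eps):
    return S_max + R1 * (1 - np.exp(-b * (eps - eps_el))) + R2 * (eps - eps_el)


def _flow_radial_return(q_tr, alpha, E, G, S_max, R1, R2, b, eps_el):
    """Solve q_tr - 3 G dg = S((q_tr - 3 G dg)/E + alpha + dg) by bracketing."""

    def g(dg):
        sig = q_tr - 3 * G * dg
        return sig - _swift_voce_plastic(S_max, R1, R2, b, eps_el,
                                         sig / E + alpha + dg)

    if g(0.0) <= 0:
        return 0.0
    hi = q_tr / (3 * G)
    while g(hi) > 0:
        hi *= 2.0
    return brentq(g, 0.0, hi, xtol=1e-16, rtol=1e-15)


class DenseNonlinearFE:
    """Plain-loop dense FE solver for small voxel grids (verification only)."""

    def __init__(self, mask, h, materials, nu=0.3, n_gauss=2):
        self.h = h
        self.nu = nu
        self.mats = materials  # list of dicts per element: E, S_max, S_sat, R1, R2, b, eps_el
        nx, ny, nz = mask.shape
        node_id = {}
        order = []
        self.elems = []
        vox = [(x, y, z)
               for z in range(nz) for y in range(ny) for x in range(nx)
               if mask[x, y, z]]
        used = set()
        for (x, y, z) in vox:
            for dx, dy, dz in _BIN_CORNERS:
                used.add((x + dx, y + dy, z + dz))
        for z in range(nz + 1):
            for y in range(ny + 1):
                for x in range(nx + 1):
                    if (x, y, z) in used:
                        node_id[(x, y, z)] = len(order)
                        order.append((x, y, z))
        self.nodes = np.array(order, float) * h
        for (x, y, z) in vox:
            conn = [None] * 8
            for corner in _BIN_CORNERS:
                a = _BIN_TO_VTK[corner]
                conn[a] = node_id[(x + corner[0], y + corner[1], z + corner[2])]
            self.elems.append(conn)
        self.ndof = 3 * len(order)
        # per-element B matrices at n_gauss^3 points, plain loops
        pts, wts = np.polynomial.legendre.leggauss(n_gauss)
        pts = 0.5 * (pts + 1.0)
        wts = 0.5 * wts
        self.gauss = []
        for (r, wr), (s, ws), (t, wt) in itertools.product(zip(pts, wts), repeat=3):
            B = np.zeros((6, 24))
            for corner in _BIN_CORNERS:
                a = _BIN_TO_VTK[corner]
                _, g = _shape_value_and_grad(corner, r, s, t)
                g = g / h
                B[0, 3 * a + 0] = g[0]
                B[1, 3 * a + 1] = g[1]
                B[2, 3 * a + 2] = g[2]
                B[3, 3 * a + 0] = g[1]
                B[3, 3 * a + 1] = g[0]
                B[4, 3 * a + 1] = g[2]
                B[4, 3 * a + 2] = g[1]
                B[5, 3 * a + 0] = g[2]
                B[5, 3 * a + 2] = g[0]
            self.gauss.append((B, wr * ws * wt * h ** 3))

    def _d_elastic(self, E):
        lam = E * self.nu / ((1 + self.nu) * (1 - 2 * self.nu))
        G = E / (2 * (1 + self.nu))
        D = np.zeros((6, 6))
        D[:3, :3] = lam
        D[np.arange(3), np.arange(3)] += 2 * G
        D[np.arange(3, 6), np.arange(3, 6)] = G
        return D

    def assemble_elastic(self):
        K = np.zeros((self.ndof, self.ndof))
        for e, conn in enumerate(self.elems):
            D = self._d_elastic(self.mats[e]["E"])
            Ke = np.zeros((24, 24))
            for B, w in self.gauss:
                Ke += w * (B.T @ D @ B)
            dofs = [3 * n + d for n in conn for d in range(3)]
            for i, gi in enumerate(dofs):
                for j, gj in enumerate(dofs):
                    K[gi, gj] += Ke[i, j]
        return K

    def _stress(self, e, eps, eps_p, alpha):
        """Radial-return stress update for one Gauss point; returns also new state."""
        m = self.mats[e]
        E, nu = m["E"], self.nu
        lam = E * nu / ((1 + nu) * (1 - 2 * nu))
        G = E / (2 * (1 + nu))
        ee = eps - eps_p
        tr = ee[0] + ee[1] + ee[2]
        sig = np.array([lam * tr + 2 * G * ee[0], lam * tr + 2 * G * ee[1],
                        lam * tr + 2 * G * ee[2], G * ee[3], G * ee[4], G * ee[5]])
        p = sig[:3].mean()
        s = sig.copy()
        s[:3] -= p
        q = np.sqrt(1.5 * (s[0] ** 2 + s[1] ** 2 + s[2] ** 2)
                    + 3.0 * (s[3] ** 2 + s[4] ** 2 + s[5] ** 2))
        if q == 0:
            return sig, eps_p, alpha
        dg = _flow_radial_return(q, alpha, E, G, m["S_max"], m["R1"],
                                 m.get("R2", 0.0), m.get("b", 10.0), m["eps_el"])
        if dg == 0:
            return sig, eps_p, alpha
        sig_new = sig - (3 * G * dg / q) * s
        flow = (1.5 * dg / q) * s * np.array([1, 1, 1, 2, 2, 2])
        return sig_new, eps_p + flow, alpha + dg

    def solve(self, prescribed, n_substeps=1, tol=1e-12, max_iter=400):
        """Incremental solve; ``prescribed`` maps dof -> value at full load.

        Modified-Newton iteration with the elastic stiffness (robust, slow,
        independent of the package's consistent-tangent path).
        """
        K = self.assemble_elastic()
        p_dofs = sorted(prescribed)
        p_vals = np.array([prescribed[d] for d in p_dofs])
        free = np.setdiff1d(np.arange(self.ndof), p_dofs)
        Kff_inv = np.linalg.inv(K[np.ix_(free, free)])
        u = np.zeros(self.ndof)
        n_gp = len(self.gauss)
        eps_p = [[np.zeros(6) for _ in range(n_gp)] for _ in self.elems]
        alpha = [[0.0] * n_gp for _ in self.elems]
        history = []
        for k in range(1, n_substeps + 1):
            u[p_dofs] = p_vals * (k / n_substeps)
            for _ in range(max_iter):
                f = np.zeros(self.ndof)
                new_state = []
                elem_sig = []
                for e, conn in enumerate(self.elems):
                    dofs = [3 * n + d for n in conn for d in range(3)]
                    ue = u[dofs]
                    st = []
                    sigs = []
                    for g, (B, w) in enumerate(self.gauss):
                        eps = B @ ue
                        sig, ep_new, al_new = self._stress(e, eps, eps_p[e][g],
                                                           alpha[e][g])
                        st.append((ep_new, al_new))
                        sigs.append(sig)
                        fe = w * (B.T @ sig)
                        for i, gi in enumerate(dofs):
                            f[gi] += fe[i]
                    new_state.append(st)
                    elem_sig.append(np.mean(sigs, axis=0))
                r = -f[free]
                ref = np.linalg.norm(f[p_dofs])
                if np.linalg.norm(r) <= tol * max(ref, 1e-30):
                    break
                u[free] += Kff_inv @ r
            for e, st in enumerate(new_state):
                for g, (ep, al) in enumerate(st):
                    eps_p[e][g] = ep
                    alpha[e][g] = al
            history.append((u.copy(), np.array(elem_sig)))
        return history


# ---------------------------------------------------------------------------
# statistics oracles
# ---------------------------------------------------------------------------


def icc_anova_sums(x, y, form="A1"):
    """ICC of an n x 2 table from explicit two-way ANOVA sums.

    ``form``: "A1" absolute agreement single, "C1" consistency single.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n, k = x.size, 2
    table = np.column_stack([x, y])
    grand = table.mean()
    row_means = table.mean(axis=1)
    col_means = table.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_total = ((table - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    ms_r = ss_rows / (n - 1)
    ms_c = ss_cols / (k - 1)
    ms_e = ss_err / ((n - 1) * (k - 1))
    if form == "C1":
        return (ms_r - ms_e) / (ms_r + (k - 1) * ms_e)
    if form == "A1":
        return (ms_r - ms_e) / (ms_r + (k - 1) * ms_e + k / n * (ms_c - ms_e))
    raise ValueError(form)


def percentile_sorted(values, pct):
    """Linear-interpolation percentile computed from an explicit sort."""
    v = np.sort(np.asarray(values, float).ravel())
    pos = (v.size - 1) * pct / 100.0
    lo = int(np.floor(pos))
    hi = int(np.ceil(pos))
    frac = pos - lo
    return v[lo] * (1 - frac) + v[hi] * frac
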