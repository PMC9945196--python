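"""Trilinear 8-node hexahedral element kernels.

Strain/stress use Voigt ordering [xx, yy, zz, xy, yz, zx] with engineering
shear strains (gamma = 2 eps).  Quadrature is 2x2x2 Gauss, which integrates
the trilinear stiffness exactly on cube elements.  Two strain-displacement
operators are available:

* ``full`` — standard B matrices;
* ``b_bar`` — mean-dilatation (B-bar) operator, where the volumetric part of
  B is replaced by its element average.  This avoids volumetric locking when
  plastic flow is nearly incompressible.

Because every voxel element is an identical cube, one set of B matrices is
shared by all elements (the "reference" path).  A general isoparametric path
(per-element Jacobians) supports the updated-geometry solve option.
"""

from __future__ import annotations

import numpy as np

# VTK hexahedron natural corner coordinates
CORNER_SIGNS = np.array([
    (-1, -1, -1), (1, -1, -1), (1, 1, -1), (-1, 1, -1),
    (-1, -1, 1), (1, -1, 1), (1, 1, 1), (-1, 1, 1),
], dtype=float)

_g = 1.0 / np.sqrt(3.0)
GAUSS_POINTS = np.array([(x, y, z) for z in (-_g, _g) for y in (-_g, _g) for x in (-_g, _g)])
GAUSS_WEIGHTS = np.ones(8)

#: Voigt unit "trace" vector
M_VEC = np.array([1.0, 1.0, 1.0, 0.0, 0.0, 0.0])


def shape_gradients_natural(xi: np.ndarray) -> np.ndarray:
    """dN/dxi at natural coordinates ``xi`` (3,) -> (8, 3)."""
    s = CORNER_SIGNS
    grad = np.empty((8, 3))
    for a in range(8):
        grad[a, 0] = 0.125 * s[a, 0] * (1 + s[a, 1] * xi[1]) * (1 + s[a, 2] * xi[2])
        grad[a, 1] = 0.125 * s[a, 1] * (1 + s[a, 0] * xi[0]) * (1 + s[a, 2] * xi[2])
        grad[a, 2] = 0.125 * s[a, 2] * (1 + s[a, 0] * xi[0]) * (1 + s[a, 1] * xi[1])
    return grad


def _b_from_gradients(gradN: np.ndarray) -> np.ndarray:
    """Assemble B (..., 6, 24) from shape-function gradients (..., 8, 3)."""
    lead = gradN.shape[:-2]
    B = np.zeros(lead + (6, 24))
    gx, gy, gz = gradN[..., 0], gradN[..., 1], gradN[..., 2]
    cols = np.arange(8) * 3
    B[..., 0, cols + 0] = gx
    B[..., 1, cols + 1] = gy
    B[..., 2, cols + 2] = gz
    B[..., 3, cols + 0] = gy
    B[..., 3, cols + 1] = gx
    B[..., 4, cols + 1] = gz
    B[..., 4, cols + 2] = gy
    B[..., 5, cols + 0] = gz
    B[..., 5, cols + 2] = gx
    return B


def _apply_bbar(B: np.ndarray, detJw: np.ndarray) -> np.ndarray:
    """Mean-dilatation modification of per-gauss B operators.

    ``B`` has shape (..., n_gauss, 6, 24); ``detJw`` (..., n_gauss).
    """
    b_rows = B[..., 0:3, :]                      # dilatational rows
    b_dil = b_rows.sum(axis=-2, keepdims=True) / 3.0   # (..., ngauss, 1, 24)
    w = detJw[..., None, None]
    b_dil_mean = (b_dil * w).sum(axis=-3, keepdims=True) / w.sum(axis=-3, keepdims=True)
    Bbar = B.copy()
    Bbar[..., 0:3, :] += b_dil_mean - b_dil
    return Bbar


def cube_b_matrices(edge_mm: float, quadrature: str = "b_bar"):
    """Shared B operators for an axis-aligned cube element of edge ``edge_mm``.

    Returns ``(B, detJw)`` with B of shape (8, 6, 24) and detJw (8,).
    """
    h = float(edge_mm)
    detJ = (h / 2.0) ** 3
    detJw = GAUSS_WEIGHTS * detJ
    gradN = np.stack([shape_gradients_natural(xi) for xi in GAUSS_POINTS]) * (2.0 / h)
    B = _b_from_gradients(gradN)
    if quadrature == "b_bar":
        B = _apply_bbar(B, detJw)
    elif quadrature != "full":
        raise ValueError(f"unknown quadrature {quadrature!r}")
    return B, detJw


def hex_b_matrices(coords: np.ndarray, quadrature: str = "b_bar"):
    """Per-element B operators for general 8-node hexahedra.

    ``coords`` has shape (ne, 8, 3) in mm; returns B (ne, 8, 6, 24) and
    detJw (ne, 8).  Used by the updated-geometry solve path.
    """
    coords = np.asarray(coords, dtype=float)
    ne = coords.shape[0]
    B = np.empty((ne, 8, 6, 24))
    detJw = np.empty((ne, 8))
    for g, xi in enumerate(GAUSS_POINTS):
        dNdxi = shape_gradients_natural(xi)          # (8, 3)
        J = np.einsum("ai,naj->nij", dNdxi, coords)  # (ne, 3, 3)
        detJ = np.linalg.det(J)
        if np.any(detJ <= 0):
            raise ValueError("element Jacobian non-positive (inverted element)")
        invJ = np.linalg.inv(J)
        gradN = np.einsum("ai,nij->naj", dNdxi, invJ)
        B[:, g] = _b_from_gradients(gradN)
        detJw[:, g] = detJ * GAUSS_WEIGHTS[g]
    if quadrature == "b_bar":
        B = _apply_bbar(B, detJw)
    elif quadrature != "full":
        raise ValueError(f"unknown quadrature {quadrature!r}")
    return B, detJw


def elastic_moduli_matrix(E: float, poisson: float) -> np.ndarray:
    """Isotropic elastic moduli in Voigt form (engineering shear)."""
    lam = E * poisson / ((1 + poisson) * (1 - 2 * poisson))
    G = E / (2 * (1 + poisson))
    D = np.zeros((6, 6))
    D[:3, :3] = lam
    D[np.arange(3), np.arange(3)] += 2 * G
    D[np.arange(3, 6), np.arange(3, 6)] = G
    return D


def deviatoric_identity() -> np.ndarray:
    """I_d: Voigt deviatoric projector acting on engineering strain."""
    I_d = np.diag([1.0, 1.0, 1.0, 0.5, 0.5, 0.5])
    I_d[:3, :3] -= 1.0 / 3.0
    return I_d
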