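"""Density-dependent elastoplastic bone material model.

Every voxel of the VOI — bone and marrow alike — becomes a mesh element whose
isotropic constitutive parameters are power laws of its ash density rho_ash
(g/cc):

    E      = a_E   * rho_ash ** n_E        (MPa)   elastic modulus
    S_max  = a_S   * rho_ash ** n_S        (MPa)   maximum (yield) stress
    S_sat  = a_sat * rho_ash ** n_sat      (MPa)   saturation stress

The default coefficients follow the widely used Keyak-family relationships for
ash density (E = 14900 rho^1.86, S = 102 rho^1.8, residual S = 43.2 rho^1.81);
they are configuration, not code constants, so site-specific laws can be
substituted.  With these defaults S_sat < S_max, i.e. the post-yield limb
softens toward the saturation stress (negative R1).

Post-yield behaviour follows the mixed Swift–Voce isotropic hardening law,
written in terms of total uniaxial strain eps:

    S(eps) = S_max + R1 * (1 - exp(-b (eps - eps_el))) + R2 * (eps - eps_el)

for eps > eps_el, with R1 = S_sat - S_max, R2 = 0 and b = 10 by default, and
the linear limb S = E * eps below the elastic limit eps_el = S_max / E.  The
curve is continuous everywhere (S(eps_el) = S_max) and C1 except at eps_el.

A small stiffness floor (E_floor) keeps marrow-valued and negative-density
voxels meshable: the continuum method does not binarize bone from marrow, so
every voxel must carry a valid material.  The floor is applied by clamping the
density fed into all three power laws to the density at which E equals
E_floor, which keeps E, S_max and eps_el mutually consistent at the floor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import MaterialError


@dataclass(frozen=True)
class DensityLawConfig:
    """Power-law coefficients mapping ash density (g/cc) to material parameters.

    Defaults are the Keyak-family relationships; ``e_floor`` is the soft-tissue
    stiffness floor in MPa, ``b`` the Voce saturation rate, ``poisson`` the
    (uniform) Poisson ratio, and ``eps_el_override`` replaces the derived
    elastic limit S_max / E when set.
    """

    e_coeff: float = 14900.0     # MPa per (g/cc)^e_exp
    e_exp: float = 1.86
    smax_coeff: float = 102.0    # MPa
    smax_exp: float = 1.8
    ssat_coeff: float = 43.2     # MPa
    ssat_exp: float = 1.81
    e_floor: float = 0.01        # MPa
    poisson: float = 0.3
    b: float = 10.0
    r2: float = 0.0              # MPa, linear (Swift) hardening slope
    eps_el_override: float | None = None

    def __post_init__(self):
        if min(self.e_coeff, self.smax_coeff, self.ssat_coeff) < 0:
            raise MaterialError("power-law coefficients must be non-negative")
        if min(self.e_exp, self.smax_exp, self.ssat_exp) <= 0:
            raise MaterialError("power-law exponents must be positive")
        if not self.e_floor > 0:
            raise MaterialError("e_floor must be positive")
        if not 0 <= self.poisson < 0.5:
            raise MaterialError(f"poisson must lie in [0, 0.5), got {self.poisson}")
        if not self.b > 0:
            raise MaterialError("Voce rate b must be positive")

    @property
    def rho_floor(self) -> float:
        """Ash density at which the E power law equals e_floor."""
        return (self.e_floor / self.e_coeff) ** (1.0 / self.e_exp)


@dataclass
class ElementMaterial:
    """Per-element constitutive parameters (fields broadcast as numpy arrays).

    ``R1 = S_sat - S_max`` (negative for softening), ``R2`` is the linear
    hardening slope and ``b`` the exponential saturation rate.
    """

    E: np.ndarray          # MPa
    S_max: np.ndarray      # MPa
    S_sat: np.ndarray      # MPa
    eps_el: np.ndarray     # unitless
    R1: np.ndarray         # MPa
    R2: np.ndarray = field(default_factory=lambda: np.array(0.0))
    b: np.ndarray = field(default_factory=lambda: np.array(10.0))
    poisson: float = 0.3

    def __post_init__(self):
        for name in ("E", "S_max", "S_sat", "eps_el", "R1", "R2", "b"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if np.any(self.E <= 0) or np.any(self.S_max <= 0):
            raise MaterialError("E and S_max must be positive")
        if np.any(self.eps_el <= 0):
            raise MaterialError("eps_el must be positive")
        if np.any(self.b <= 0):
            raise MaterialError("b must be positive")

    @property
    def n_elements(self) -> int:
        return int(np.broadcast(self.E, self.S_max).size)

    def take(self, idx) -> "ElementMaterial":
        """Subset view across element-shaped fields (scalars broadcast)."""

        def pick(a):
            a = np.asarray(a)
            return a[idx] if a.ndim else a

        return ElementMaterial(
            E=pick(self.E), S_max=pick(self.S_max), S_sat=pick(self.S_sat),
            eps_el=pick(self.eps_el), R1=pick(self.R1), R2=pick(self.R2),
            b=pick(self.b), poisson=self.poisson,
        )


def material_from_ash(rho_ash, cfg: DensityLawConfig | None = None) -> ElementMaterial:
    """Map ash density (scalar or array, g/cc) to element material parameters.

    Densities at or below the stiffness-floor density are clamped, so marrow
    and negative-calibration voxels receive the floor modulus and the floor
    strength consistently.
    """
    cfg = cfg or DensityLawConfig()
    rho = np.asarray(rho_ash, dtype=float)
    if not np.all(np.isfinite(rho)):
        raise MaterialError("ash density must be finite")
    rho_eff = np.maximum(rho, cfg.rho_floor)
    E = cfg.e_coeff * rho_eff ** cfg.e_exp
    S_max = cfg.smax_coeff * rho_eff ** cfg.smax_exp
    S_sat = cfg.ssat_coeff * rho_eff ** cfg.ssat_exp
    eps_el = (np.full_like(E, cfg.eps_el_override)
              if cfg.eps_el_override is not None else S_max / E)
    return ElementMaterial(
        E=E, S_max=S_max, S_sat=S_sat, eps_el=eps_el,
        R1=S_sat - S_max, R2=np.full_like(E, cfg.r2), b=np.full_like(E, cfg.b),
        poisson=cfg.poisson,
    )


def plastic_branch(mat: ElementMaterial, eps):
    """Swift–Voce expression evaluated for any strain (no elastic limb).

    Valid as an analytic continuation below eps_el; used by the stress update,
    where softening can push the flow-stress argument slightly below eps_el.
    """
    eps = np.asarray(eps, dtype=float)
    x = eps - mat.eps_el
    return mat.S_max + mat.R1 * (1.0 - np.exp(-mat.b * x)) + mat.R2 * x


def swift_voce_stress(mat: ElementMaterial, eps):
    """Uniaxial stress at total strain eps >= 0: linear limb then Swift–Voce."""
    eps = np.asarray(eps, dtype=float)
    if np.any(eps < 0):
        raise ValueError("strain must be non-negative")
    return np.where(eps <= mat.eps_el, mat.E * eps, plastic_branch(mat, eps))


def tangent_modulus(mat: ElementMaterial, eps):
    """Analytic slope dS/deps of the uniaxial curve (one-sided at eps_el)."""
    eps = np.asarray(eps, dtype=float)
    x = eps - mat.eps_el
    plastic = mat.R1 * mat.b * np.exp(-mat.b * x) + mat.R2
    return np.where(eps <= mat.eps_el, mat.E * np.ones_like(x), plastic)
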