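"""Load-case orchestration and modulus extraction.

The apparent trabecular modulus is measured exactly as the imaging protocol
defines it: after each loading sub-step the mean von Mises stress over the
volume elements on the top (loaded) surface is recorded against the applied
apparent strain, and the modulus is the slope of the linear section of that
stress–strain curve.  "Linear section" is operationalized as the longest
initial window whose least-squares fit keeps r^2 >= ``r2_threshold``
(default 0.999).

Note on shear: the "shear modulus" reported here is the slope of mean
top-surface von Mises stress versus applied lateral strain — the protocol's
construction — not the classical engineering shear modulus.  Because the von
Mises stress of a pure shear state is sqrt(3) times the shear stress, these
values exceed the compressive modulus on many structures; that matches the
measure as defined, and comparisons should stay within one convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .densitometry import DensityVolume
from .errors import SolverError, UnitError
from .materials import DensityLawConfig, material_from_ash
from .mesh import HexMesh, build_mesh
from .solver import (LoadCase, MODES, SolutionState, SolverSettings,
                     solve_load_case)

log = logging.getLogger(__name__)


@dataclass
class StressStrainCurve:
    """Per-sub-step (applied strain, mean top-surface von Mises) samples."""

    strains: np.ndarray   # strictly increasing, unitless
    stresses: np.ndarray  # MPa, >= 0
    mode: str = "compression"

    def __post_init__(self):
        self.strains = np.asarray(self.strains, dtype=float)
        self.stresses = np.asarray(self.stresses, dtype=float)
        if self.strains.size != self.stresses.size or self.strains.size < 1:
            raise ValueError("curve needs matching, non-empty strain/stress arrays")
        if np.any(np.diff(self.strains) <= 0):
            raise ValueError("strains must be strictly increasing")


@dataclass
class ModulusResult:
    """Slope of the linear section of a stress–strain curve."""

    modulus: float                 # MPa
    mode: str
    linear_window: tuple[int, int]  # (first, last) sub-step indices, inclusive
    fit_r_squared: float


@dataclass
class ProtocolResult:
    """Everything produced for one load mode."""

    curve: StressStrainCurve
    modulus: ModulusResult
    final_state: SolutionState
    states: list[SolutionState] = field(default_factory=list)


def extract_modulus(curve: StressStrainCurve, r2_threshold: float = 0.999) -> ModulusResult:
    """Slope of the longest initial window with least-squares r^2 >= threshold.

    Falls back (with a warning) to the first-two-point secant if no window of
    at least two points meets the criterion.
    """
    x, y = curve.strains, curve.stresses
    if x.size < 2:
        raise ValueError("need at least 2 curve points")
    for end in range(x.size, 1, -1):
        res = stats.linregress(x[:end], y[:end])
        r2 = 1.0 if np.isnan(res.rvalue) else res.rvalue ** 2
        if r2 >= r2_threshold:
            return ModulusResult(modulus=float(res.slope), mode=curve.mode,
                                 linear_window=(0, end - 1), fit_r_squared=float(r2))
    log.warning("no initial window met r^2 >= %g; falling back to 2-point secant",
                r2_threshold)
    slope = (y[1] - y[0]) / (x[1] - x[0])
    return ModulusResult(modulus=float(slope), mode=curve.mode,
                         linear_window=(0, 1), fit_r_squared=1.0)


def mean_top_surface_vm(mesh: HexMesh, state: SolutionState) -> float:
    """Average element von Mises stress over the top-surface element layer."""
    top = mesh.top_surface_elements()
    return float(state.von_mises[top].mean())


def curve_from_states(mesh: HexMesh, states: list[SolutionState],
                      mode: str) -> StressStrainCurve:
    strains = np.array([s.applied_strain for s in states])
    stresses = np.array([mean_top_surface_vm(mesh, s) for s in states])
    return StressStrainCurve(strains=strains, stresses=stresses, mode=mode)


def run_protocol(ash_volume: DensityVolume, voi_mask: np.ndarray | None = None,
                 material_cfg: DensityLawConfig | None = None,
                 modes=MODES,
                 total_strain: float = 0.001,
                 n_substeps: int = 50,
                 settings: SolverSettings | None = None,
                 bc_mode: str = "production",
                 r2_threshold: float = 0.999) -> dict[str, ProtocolResult]:
    """Run the loading protocol on a calibrated ash-density volume.

    The mesh and per-element materials are built once and shared by the three
    independent solves (compression, x-shear, y-shear).  ``voi_mask`` selects
    the voxels to mesh; omitted, every voxel is meshed (the continuum model
    needs no bone/marrow separation).
    """
    if ash_volume.units != "ash":
        raise UnitError(f"run_protocol expects an ash-density volume, got {ash_volume.units!r}")
    mask = (np.ones(ash_volume.shape, dtype=bool) if voi_mask is None
            else np.asarray(voi_mask, dtype=bool))
    if mask.shape != ash_volume.shape:
        raise ValueError("VOI mask shape does not match the volume")
    settings = settings or SolverSettings()
    mesh = build_mesh(mask, ash_volume.spacing)
    rho = ash_volume.values[mesh.element_to_voxel[:, 0],
                            mesh.element_to_voxel[:, 1],
                            mesh.element_to_voxel[:, 2]]
    materials = material_from_ash(rho, material_cfg)

    out: dict[str, ProtocolResult] = {}
    for mode in modes:
        case = LoadCase(mode=mode, total_strain=total_strain,
                        n_substeps=n_substeps, bc_mode=bc_mode)
        try:
            states = solve_load_case(mesh, materials, case, settings)
        except SolverError as exc:
            raise type(exc)(f"[{mode}] {exc}") from exc
        curve = curve_from_states(mesh, states, mode)
        modulus = extract_modulus(curve, r2_threshold)
        out[mode] = ProtocolResult(curve=curve, modulus=modulus,
                                   final_state=states[-1], states=states)
    return out


def element_field_to_volume(mesh: HexMesh, values: np.ndarray,
                            fill: float = 0.0) -> np.ndarray:
    """Scatter a per-element field back onto the voxel grid (1:1 mapping)."""
    out = np.full(mesh.shape, fill, dtype=float)
    v = mesh.element_to_voxel
    out[v[:, 0], v[:, 1], v[:, 2]] = values
    return out
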