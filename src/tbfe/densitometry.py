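"""Densitometric calibration: CT numbers to BMD, CHA and ash density.

Quantitative CT expresses attenuation in Hounsfield units (HU).  A calibration
phantom with rods of known density scanned alongside the subject provides
(HU, density) pairs from which a global linear map HU -> BMD (g/cc) is fitted.
BMD is then converted voxelwise to calcium-hydroxyapatite (CHA) equivalent
density,

    rho_CHA = (rho_BMD - D_water) / (D_CHA - D_water) * D_CHA,

with D_CHA = 3.18 g/cc and D_water = 1 g/cc, and finally to ash density

    rho_ash = 0.0633 + 0.887 * rho_CHA,

which is the density measure bone constitutive laws are usually expressed in.
Both maps are affine and strictly increasing, so voxel ordering is preserved
and each map has an exact analytic inverse.

Negative CHA densities (voxels darker than water, e.g. fat-rich marrow) are
deliberately preserved rather than clipped: the material model applies its own
stiffness floor, and clipping twice would hide calibration faults.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import stats

from .errors import CalibrationError, UnitError

#: density of calcium hydroxyapatite, g/cc
D_CHA = 3.18
#: density of water, g/cc
D_WATER = 1.0
#: affine CHA -> ash conversion, g/cc
ASH_INTERCEPT = 0.0633
ASH_SLOPE = 0.887

#: recognised units tags for DensityVolume
UNITS = ("HU", "BMD", "CHA", "ash")


@dataclass(frozen=True)
class CalibrationModel:
    """Global least-squares line mapping HU to BMD in g/cc.

    Attributes
    ----------
    slope : float
        g/cc per HU; must be positive (denser tissue attenuates more).
    intercept : float
        g/cc at HU = 0.
    r_squared : float
        Coefficient of determination of the fit, in [0, 1].
    """

    slope: float
    intercept: float
    r_squared: float

    def __post_init__(self):
        if not np.isfinite(self.slope) or self.slope <= 0:
            raise CalibrationError(f"calibration slope must be positive, got {self.slope}")
        if not 0.0 <= self.r_squared <= 1.0 + 1e-12:
            raise CalibrationError(f"r_squared outside [0, 1]: {self.r_squared}")

    def apply(self, hu):
        """Map HU values (scalar or array) to BMD in g/cc."""
        return self.intercept + self.slope * np.asarray(hu, dtype=float)


@dataclass
class DensityVolume:
    """A 3D scalar grid at isotropic spacing with a units tag.

    ``values`` is indexed ``[x, y, z]``; ``spacing`` is the isotropic voxel
    edge in micrometres.  ``units`` is one of ``HU``, ``BMD``, ``CHA`` or
    ``ash`` (densities in g/cc) and always reflects the last conversion
    applied.
    """

    values: np.ndarray
    spacing: float  # micrometres, isotropic
    units: str = "HU"
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3 or min(self.values.shape) < 1:
            raise ValueError(f"values must be a non-empty 3D grid, got shape {self.values.shape}")
        if not self.spacing > 0:
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        if self.units not in UNITS:
            raise UnitError(f"unknown units tag {self.units!r}; expected one of {UNITS}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def with_values(self, values: np.ndarray, units: str) -> "DensityVolume":
        return replace(self, values=np.asarray(values, dtype=float), units=units)


def fit_calibration(samples) -> CalibrationModel:
    """Fit the global OLS calibration line through (HU, density g/cc) pairs.

    Parameters
    ----------
    samples : sequence of (hu, density) pairs, or (n, 2) array.

    Raises
    ------
    CalibrationError
        With fewer than two samples or if all HU values coincide.
    """
    arr = np.asarray(list(samples), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
        raise CalibrationError("need at least two (HU, density) pairs")
    hu, rho = arr[:, 0], arr[:, 1]
    if np.ptp(hu) == 0:
        raise CalibrationError("all HU values identical; line is undetermined")
    res = stats.linregress(hu, rho)
    # linregress r is nan for a vertical-free exact fit with zero rho variance
    r2 = 1.0 if np.isnan(res.rvalue) else float(res.rvalue) ** 2
    return CalibrationModel(slope=float(res.slope), intercept=float(res.intercept), r_squared=r2)


def calibrate_hu(volume: DensityVolume, model: CalibrationModel) -> DensityVolume:
    """Apply a fitted calibration to an HU volume, yielding a BMD volume."""
    if volume.units != "HU":
        raise UnitError(f"expected HU volume, got units={volume.units!r}")
    return volume.with_values(model.apply(volume.values), "BMD")


def bmd_to_cha(volume: DensityVolume) -> DensityVolume:
    """Convert BMD (g/cc) to CHA-equivalent density (g/cc) voxelwise."""
    if volume.units != "BMD":
        raise UnitError(f"expected BMD volume, got units={volume.units!r}")
    cha = (volume.values - D_WATER) / (D_CHA - D_WATER) * D_CHA
    return volume.with_values(cha, "CHA")


def cha_to_bmd(volume: DensityVolume) -> DensityVolume:
    """Exact analytic inverse of :func:`bmd_to_cha`."""
    if volume.units != "CHA":
        raise UnitError(f"expected CHA volume, got units={volume.units!r}")
    bmd = volume.values / D_CHA * (D_CHA - D_WATER) + D_WATER
    return volume.with_values(bmd, "BMD")


def cha_to_ash(volume: DensityVolume) -> DensityVolume:
    """Convert CHA density to ash density: rho_ash = 0.0633 + 0.887 rho_CHA."""
    if volume.units != "CHA":
        raise UnitError(f"expected CHA volume, got units={volume.units!r}")
    return volume.with_values(ASH_INTERCEPT + ASH_SLOPE * volume.values, "ash")


def ash_to_cha(volume: DensityVolume) -> DensityVolume:
    """Exact analytic inverse of :func:`cha_to_ash`."""
    if volume.units != "ash":
        raise UnitError(f"expected ash volume, got units={volume.units!r}")
    return volume.with_values((volume.values - ASH_INTERCEPT) / ASH_SLOPE, "CHA")


def bmd_to_ash(volume: DensityVolume) -> DensityVolume:
    """Full BMD -> CHA -> ash chain."""
    return cha_to_ash(bmd_to_cha(volume))


def cha_value_to_bmd(cha: float) -> float:
    """Scalar inverse CHA -> BMD, handy when constructing phantoms."""
    return cha / D_CHA * (D_CHA - D_WATER) + D_WATER


def read_calibration_table(path: str | Path):
    """Read a 2-column CSV ``hu, density_g_cc`` (with header) into sample pairs."""
    import pandas as pd

    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise CalibrationError(f"calibration table {path} needs two columns (HU, density)")
    return list(zip(df.iloc[:, 0].astype(float), df.iloc[:, 1].astype(float)))
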