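"""Reading and writing density volumes (NIfTI-1 and MetaImage).

Volumes are stored with isotropic spacing; the units tag travels in a header
description field where the format allows it, and otherwise must be supplied
by the caller.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .densitometry import DensityVolume
from .errors import ConfigError


def read_volume(path: str | Path, units: str = "HU") -> DensityVolume:
    """Read a .nii/.nii.gz (nibabel) or .mha/.mhd (SimpleITK) volume.

    The voxel spacing must be isotropic; ``units`` tags the values.
    """
    path = Path(path)
    name = path.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        img = nib.load(str(path))
        zooms = img.header.get_zooms()[:3]
        data = np.asanyarray(img.dataobj, dtype=float)
    elif name.endswith((".mha", ".mhd")):
        import SimpleITK as sitk

        img = sitk.ReadImage(str(path))
        zooms = img.GetSpacing()
        data = sitk.GetArrayFromImage(img).T.astype(float)
    else:
        raise ConfigError(f"unsupported volume format: {path.name}")
    if not np.allclose(zooms, zooms[0], rtol=1e-4):
        raise ConfigError(f"anisotropic spacing {zooms} not supported")
    # stored spacings are in mm by convention; convert to um
    return DensityVolume(values=data, spacing=float(zooms[0]) * 1e3, units=units)


def write_volume(volume: DensityVolume, path: str | Path) -> None:
    """Write to .nii/.nii.gz or .mha/.mhd, spacing in mm."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    name = path.name.lower()
    s_mm = volume.spacing * 1e-3
    if name.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        affine = np.diag([s_mm, s_mm, s_mm, 1.0])
        img = nib.Nifti1Image(volume.values, affine)
        img.header.set_zooms((s_mm,) * 3)
        img.header["descrip"] = f"tbfe units={volume.units}".encode()
        nib.save(img, str(path))
    elif name.endswith((".mha", ".mhd")):
        import SimpleITK as sitk

        img = sitk.GetImageFromArray(np.ascontiguousarray(volume.values.T))
        img.SetSpacing((s_mm,) * 3)
        sitk.WriteImage(img, str(path))
    else:
        raise ConfigError(f"unsupported volume format: {path.name}")
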