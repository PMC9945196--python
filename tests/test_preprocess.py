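"""Segmentation stand-in, bone-axis estimation, alignment, VOI selection."""

import numpy as np
import pytest

from tbfe.densitometry import DensityVolume
from tbfe.errors import SegmentationError, VoiError
from tbfe.preprocess import (VoiSpec, align_and_resample, compute_bone_axis,
                             peel_mask, segment_bone, select_voi)


def cylinder_volume(nx=40, ny=40, nz=80, radius=10.0, tilt_deg=0.0,
                    spacing=150.0, density=2.0):
    """Cylinder of given density in a water background; axis in the y-z plane."""
    x, y, z = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz),
                          indexing="ij")
    th = np.deg2rad(tilt_deg)
    d = np.array([0.0, np.sin(th), np.cos(th)])
    p = np.stack([x, y, z], -1) - np.array([nx / 2, ny / 2, 0.0])
    proj = p @ d
    r2 = ((p - proj[..., None] * d) ** 2).sum(-1)
    vals = np.where(r2 < radius ** 2, density, 1.0)
    return DensityVolume(vals, spacing, "BMD"), d


class TestSegmentBone:
    def test_cylinder_recovered(self):
        vol, _ = cylinder_volume()
        mask = segment_bone(vol, 1.5)
        truth = vol.values > 1.5
        assert (mask ^ truth).mean() < 0.01  # within a thin boundary shell

    def test_threshold_above_max_raises(self):
        vol, _ = cylinder_volume()
        with pytest.raises(SegmentationError):
            segment_bone(vol, vol.values.max() + 1.0)

    def test_largest_component_kept(self):
        vals = np.ones((20, 20, 20))
        vals[2:10, 2:10, 2:10] = 2.0     # large blob
        vals[14:17, 14:17, 14:17] = 2.0  # small blob
        mask = segment_bone(DensityVolume(vals, 150.0, "BMD"), 1.5)
        assert mask[3, 3, 3] and not mask[15, 15, 15]

    def test_holes_filled(self):
        vals = np.ones((16, 16, 16))
        vals[4:12, 4:12, 4:12] = 2.0
        vals[7:9, 7:9, 7:9] = 1.0  # internal cavity
        mask = segment_bone(DensityVolume(vals, 150.0, "BMD"), 1.5)
        assert mask[8, 8, 8]


class TestBoneAxis:
    def test_upright_cylinder(self):
        vol, _ = cylinder_volume(tilt_deg=0.0)
        mask = segment_bone(vol, 1.5)
        axis = compute_bone_axis(mask, VoiSpec(), vol.spacing)
        assert np.allclose(axis, [0, 0, 1], atol=1e-3)

    def test_tilted_cylinder_recovered_within_half_degree(self):
        vol, d = cylinder_volume(tilt_deg=10.0)
        mask = segment_bone(vol, 1.5)
        axis = compute_bone_axis(mask, VoiSpec(), vol.spacing)
        ang = np.degrees(np.arccos(np.clip(axis @ d, -1, 1)))
        assert ang < 0.5

    def test_sign_convention_positive_z(self):
        vol, _ = cylinder_volume(tilt_deg=25.0)
        mask = segment_bone(vol, 1.5)
        axis = compute_bone_axis(mask, VoiSpec(), vol.spacing)
        assert axis[2] > 0

    def test_too_few_slices_rejected(self):
        mask = np.zeros((20, 20, 20), bool)
        mask[5:15, 5:15, 3:8] = True
        with pytest.raises(SegmentationError):
            compute_bone_axis(mask, VoiSpec(), 150.0)


class TestAlignAndResample:
    def test_identity_is_exact(self, rng):
        vol = DensityVolume(rng.normal(1, 0.1, (12, 12, 12)), 150.0, "BMD")
        out = align_and_resample(vol, np.array([0.0, 0.0, 1.0]))
        np.testing.assert_allclose(out.values, vol.values, atol=1e-6)
        assert out.spacing == vol.spacing

    def test_lattice_rotation_permutes_array(self, rng):
        vol = DensityVolume(rng.normal(1, 0.1, (12, 12, 12)), 150.0, "BMD")
        out = align_and_resample(vol, np.array([0.0, 0.0, 1.0]),
                                 x_hint=np.array([0.0, 1.0, 0.0]))
        err = min(np.abs(out.values - np.rot90(vol.values, 1, (0, 1))).max(),
                  np.abs(out.values - np.rot90(vol.values, -1, (0, 1))).max())
        assert err < 1e-6

    def test_single_pass_beats_two_pass_interpolation(self):
        """A +10/-10 degree round trip through two resamplings loses more
        signal than the combined (identity) single pass."""
        x, y, z = np.meshgrid(*[np.linspace(-1, 1, 32)] * 3, indexing="ij")
        smooth = np.exp(-4 * (x ** 2 + y ** 2 + z ** 2)) + \
            0.3 * np.cos(3 * x) * np.sin(3 * y)
        vol = DensityVolume(smooth, 150.0, "BMD")
        th = np.deg2rad(10.0)
        tilt = np.array([0.0, np.sin(th), np.cos(th)])
        step1 = align_and_resample(vol, tilt)
        # rotate back: the original z-axis expressed in the tilted frame
        back = np.array([0.0, -np.sin(th), np.cos(th)])
        step2 = align_and_resample(step1, back)
        single = align_and_resample(vol, np.array([0.0, 0.0, 1.0]))
        core = (slice(8, 24),) * 3
        crop2 = step2.values[tuple(slice(0, n) for n in vol.shape)]
        rms_two = np.sqrt(np.mean((crop2[core] - vol.values[core]) ** 2))
        rms_one = np.sqrt(np.mean((single.values[core] - vol.values[core]) ** 2))
        assert rms_one < rms_two


class TestSelectVoi:
    def test_percent_site_slab_thickness(self):
        # 4%-6% of a 337.5 mm tibia at 150 um -> 45 slices (6.75 mm)
        mask = np.zeros((30, 30, 150), bool)
        x, y = np.meshgrid(np.arange(30), np.arange(30), indexing="ij")
        circ = (x - 15.0) ** 2 + (y - 15.0) ** 2 < 12 ** 2
        mask[:, :, :] = circ[:, :, None]
        spec = VoiSpec(tibial_length_mm=337.5, peel_pct=0.0)
        voi = select_voi(mask, spec, 150.0)
        ks = np.flatnonzero(voi.any(axis=(0, 1)))
        assert ks.size == 45
        assert ks[0] == int(round(0.04 * 337.5 / 0.15))

    def test_zero_peel_keeps_slab(self):
        mask = np.ones((10, 10, 100), bool)
        spec = VoiSpec(tibial_length_mm=15.0, peel_pct=0.0)
        voi = select_voi(mask, spec, 150.0)
        ks = np.flatnonzero(voi.any(axis=(0, 1)))
        np.testing.assert_array_equal(voi[:, :, ks[0]], mask[:, :, ks[0]])

    def test_thirty_percent_peel_shrinks_radius_sqrt(self):
        mask = np.zeros((40, 40, 120), bool)
        x, y = np.meshgrid(np.arange(40), np.arange(40), indexing="ij")
        circ = (x - 20.0) ** 2 + (y - 20.0) ** 2 < 15 ** 2
        mask[:, :, :] = circ[:, :, None]
        spec = VoiSpec(tibial_length_mm=18.0, peel_pct=30.0)
        voi = select_voi(mask, spec, 150.0)
        k = np.flatnonzero(voi.any(axis=(0, 1)))[0]
        r_kept = np.sqrt(voi[:, :, k].sum() / np.pi)
        assert r_kept == pytest.approx(15.0 * np.sqrt(0.7), abs=1.0)

    def test_empty_voi_raises(self):
        mask = np.zeros((10, 10, 40), bool)
        mask[4:6, 4:6, :] = True
        with pytest.raises(VoiError):
            select_voi(mask, VoiSpec(tibial_length_mm=500.0), 150.0)

    def test_peel_mask_is_per_slice_erosion(self):
        mask = np.zeros((20, 20, 2), bool)
        mask[2:18, 2:18, :] = True
        out = peel_mask(mask, 30.0)
        per_slice = out.sum(axis=(0, 1))
        assert np.all(per_slice <= 0.7 * 16 * 16)
        assert np.all(per_slice > 0)
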