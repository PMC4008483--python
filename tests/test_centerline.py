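import numpy as np
import pytest

from pcplan.centerline import (
    Centerline,
    CenterlineError,
    derivative_profile,
    extract_centerline,
)
from pcplan.artery_id import connected_components, middle_slice_sections
from pcplan.phantom import PhantomSpec, generate_phantom
from pcplan.segmentation import adaptive_artery_threshold, otsu_body_mask
from pcplan.volume_io import BinaryMask3D, Volume3D


def _tube_volume(axis_xy=(16.0, 16.0), radius=2.0, shape=(40, 40, 30), spacing=(0.8, 0.8, 1.5)):
    """Noiseless bright vertical tube on a dark background."""
    xi = np.arange(shape[0]) * spacing[0]
    yi = np.arange(shape[1]) * spacing[1]
    r2 = (xi[:, None] - axis_xy[0]) ** 2 + (yi[None, :] - axis_xy[1]) ** 2
    tube2d = r2 <= radius**2
    data = np.where(np.repeat(tube2d[:, :, None], shape[2], axis=2), 100.0, 0.0)
    return Volume3D(data=data, spacing=spacing)


def _extract(volume, threshold=50.0):
    mask = BinaryMask3D.from_parent(volume, volume.data > threshold)
    objs = connected_components(mask)
    secs = middle_slice_sections(objs, volume.shape)
    return objs[0], secs[0]


class TestExtractCenterline:
    def test_straight_tube_recovers_axis(self):
        volume = _tube_volume()
        obj, sec = _extract(volume)
        cl = extract_centerline(obj, sec, volume)
        err = np.linalg.norm(cl.points[2:-2, :2] - np.array([16.0, 16.0]), axis=1)
        assert err.max() <= 0.5 * max(volume.spacing)

    def test_phantom_va_close_to_truth(self, seg_default, phantom_default):
        volume, truth = phantom_default
        obj, sec = seg_default.labeling.arteries["LVA"]
        cl = extract_centerline(obj, sec, volume, label="LVA")
        gt = truth.centerlines["LVA"]
        # one-sided Hausdorff: every extracted point near the true curve
        d = np.array([np.linalg.norm(gt - p, axis=1).min() for p in cl.points[1:-1]])
        assert d.max() <= 1.5 * max(volume.spacing)

    def test_ica_centerline_follows_ica_branch_not_eca(self, seg_default, phantom_default):
        """Above the bifurcation the polyline must track the ICA side."""
        volume, truth = phantom_default
        obj, sec = seg_default.labeling.arteries["LICA"]
        cl = extract_centerline(obj, sec, volume, label="LICA")
        gt_ica = truth.centerlines["LICA"]
        gt_eca = truth.centerlines["LECA"]
        top = cl.points[cl.points[:, 2] > 0.7 * 70.5]
        assert len(top) > 3
        d_ica = np.array([np.linalg.norm(gt_ica - p, axis=1).min() for p in top])
        d_eca = np.array([np.linalg.norm(gt_eca - p, axis=1).min() for p in top])
        assert d_ica.max() <= 1.5 * max(volume.spacing)
        assert np.all(d_eca > d_ica + 1.0)

    def test_too_short_object_raises(self):
        volume = _tube_volume(shape=(40, 40, 30))
        volume.data[:, :, 16:] = 0.0
        volume.data[:, :, :13] = 0.0  # three slices left around the middle
        obj, sec = _extract(volume)
        with pytest.raises(CenterlineError, match="too short"):
            extract_centerline(obj, sec, volume)

    def test_arc_length_strictly_increasing(self, seg_default, phantom_default):
        volume, _ = phantom_default
        obj, sec = seg_default.labeling.arteries["RVA"]
        cl = extract_centerline(obj, sec, volume)
        assert np.all(np.diff(cl.arc_length) > 0)
        assert np.all(np.diff(cl.points[:, 2]) > -1e-9)  # travels upward


class TestDerivativeProfile:
    def _line(self, dydz=0.0, dxdz=0.0, n=40, dz=1.5):
        z = np.arange(n) * dz
        return Centerline("VA", np.column_stack([10 + dxdz * z, 20 + dydz * z, z]))

    def test_straight_vertical_line_zero_profile(self):
        prof = derivative_profile(self._line(), axis="AP", dz=1.5)
        np.testing.assert_allclose(prof.values, 0.0, atol=1e-12)

    def test_oblique_line_constant_slope(self):
        prof = derivative_profile(self._line(dydz=0.5), axis="AP", dz=1.5)
        np.testing.assert_allclose(prof.values, 0.5, atol=1e-9)

    def test_axis_selects_transverse_coordinate(self):
        prof = derivative_profile(self._line(dxdz=0.3, dydz=0.5), axis="LR", dz=1.5)
        np.testing.assert_allclose(prof.values, 0.3, atol=1e-9)

    def test_short_span_rejected(self):
        with pytest.raises(ValueError, match="z-span"):
            derivative_profile(self._line(n=8), axis="AP", dz=1.5)

    def test_phantom_va_profile_peaks_at_bend_heights(self, phantom_noiseless, noiseless_spec):
        _, truth = phantom_noiseless
        spec = noiseless_spec
        cl = Centerline("LVA", truth.centerlines["LVA"])
        prof = derivative_profile(cl, axis="AP", dz=1.5)
        # the slope band must sit between the bends: max |f| near the middle
        zs = prof.z_of(np.arange(len(prof)))
        inter = (zs > spec.z_turn_lower) & (zs < spec.z_turn_upper)
        assert prof.values[inter].mean() > 5 * abs(prof.values[~inter]).mean()

    def test_translation_invariance(self, phantom_noiseless):
        _, truth = phantom_noiseless
        cl = Centerline("LVA", truth.centerlines["LVA"])
        moved = cl.translated((5.0, -3.0, 2.0))
        p0 = derivative_profile(cl, axis="AP", dz=1.5)
        p1 = derivative_profile(moved, axis="AP", dz=1.5)
        np.testing.assert_allclose(p0.values, p1.values, atol=1e-12)

    def test_mirror_invariance_for_ap_axis(self, phantom_noiseless):
        _, truth = phantom_noiseless
        pts = truth.centerlines["LVA"].copy()
        mirrored = pts * np.array([-1.0, 1.0, 1.0])
        p0 = derivative_profile(Centerline("LVA", pts), axis="AP", dz=1.5)
        p1 = derivative_profile(Centerline("LVA", mirrored), axis="AP", dz=1.5)
        np.testing.assert_allclose(p0.values, p1.values, atol=1e-12)

    def test_half_step_resampling_decimates_to_same_profile(self):
        """On a piecewise-linear polyline with knots on the coarse grid,
        sampling at dz and dz/2 then decimating agree to 1e-6."""
        dz = 1.5
        z = np.arange(30) * dz
        y = np.where(z < 15, 0.0, (z - 15) * 0.4)  # knot at a grid point
        cl = Centerline("VA", np.column_stack([np.full_like(z, 5.0), 20 + y, z]))
        coarse = derivative_profile(cl, axis="AP", dz=dz)
        fine = derivative_profile(cl, axis="AP", dz=dz / 2)
        np.testing.assert_allclose(fine.values[::2], coarse.values, atol=1e-6)
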