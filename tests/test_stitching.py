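"""Fusion-slice selection, intensity calibration, and concatenation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ctstitch import (
    FusionSelection,
    IntensityCalibration,
    ScanSplitSpec,
    StitchConfig,
    TranslationXY,
    Volume,
    apply_intensity_calibration,
    concatenate_pair,
    fit_intensity_calibration,
    radial_reslice_preview,
    select_fusion_slice_auto,
    simulate_overlapping_scans,
    stitch_many,
    translate_xy,
    translation_from_landmarks,
)
from ctstitch.stitching import check_bit_depths, default_rois


def _vol(arr, voxel=15.0):
    return Volume(np.asarray(arr, dtype=np.float64), voxel, bit_depth=32)


class TestTranslateXY:
    def test_zero_shift_is_identity(self, coral):
        vol, _ = coral
        out = translate_xy(vol, TranslationXY(0, 0))
        assert np.array_equal(out.voxels, vol.voxels)

    def test_round_trip_in_interior(self, rng):
        vol = _vol(rng.uniform(size=(3, 12, 12)))
        fwd = translate_xy(vol, TranslationXY(2, -3), fill=-1)
        back = translate_xy(fwd, TranslationXY(-2, 3), fill=-1)
        # interior untouched by either border fill
        assert np.array_equal(back.voxels[:, 2:-2, 3:-3], vol.voxels[:, 2:-2, 3:-3])

    def test_landmarks_coincide_after_shift(self):
        bottom = np.zeros((1, 24, 32))
        top = np.zeros_like(bottom)
        bottom[0, 10, 20] = 1.0
        top[0, 12, 17] = 1.0
        t = translation_from_landmarks((10, 20), (12, 17))
        assert (t.dy_px, t.dx_px) == (-2, 3)
        moved = translate_xy(_vol(top), t)
        assert moved.voxels[0, 10, 20] == 1.0

    def test_oversized_shift_rejected(self):
        with pytest.raises(ValueError):
            translate_xy(_vol(np.zeros((1, 4, 4))), TranslationXY(4, 0))


class TestTranslationFromLandmarks:
    def test_identical_points_zero(self):
        assert translation_from_landmarks((5, 5), (5, 5)) == TranslationXY(0, 0)

    def test_componentwise_subtraction(self):
        assert translation_from_landmarks((5, 5), (9, 2)) == TranslationXY(-4, 3)

    def test_physical_units_rounded_to_pixels(self):
        # 30 um offset at 15 um pixels -> 2 px
        t = translation_from_landmarks((30.0, 0.0), (0.0, 0.0), pixel_size_um=15.0)
        assert t == TranslationXY(2, 0)
        # half-pixel rounds away from zero
        t = translation_from_landmarks((22.5, -22.5), (0.0, 0.0), pixel_size_um=15.0)
        assert t == TranslationXY(2, -2)


class TestFusionSelection:
    def test_exact_copy_scores_zero(self, coral):
        vol, _ = coral
        bottom = Volume(vol.voxels[:40], vol.voxel_size_um, 32)
        top = Volume(vol.voxels[25:], vol.voxel_size_um, 32)
        sel = select_fusion_slice_auto(bottom, top, reference_index=30)
        assert sel.top_slice == 5  # slice 30 appears at index 5 of the top stack
        assert sel.score_profile[5] == pytest.approx(0.0, abs=1e-12)
        assert sel.mode == "auto"

    @pytest.mark.parametrize("gain,offset", [(1.3, 40.0), (0.5, -20.0), (7.0, 0.0)])
    def test_invariant_under_positive_affine(self, coral, gain, offset):
        # z-scoring cancels gain/offset, the exact distortion family the
        # later straight-line calibration corrects
        vol, _ = coral
        bottom = Volume(vol.voxels[:40], vol.voxel_size_um, 32)
        top = Volume(gain * vol.voxels[25:] + offset, vol.voxel_size_um, 32)
        sel = select_fusion_slice_auto(bottom, top, reference_index=30)
        assert sel.top_slice == 5
        assert sel.score_profile[5] == pytest.approx(0.0, abs=1e-9)

    def test_recovers_simulated_split_within_one_slice(self, coral):
        vol, _ = coral
        contrast = 140.0
        scans, truth = simulate_overlapping_scans(vol, ScanSplitSpec(
            n_scans=2, overlap_slices=10, scan_gain=[1.0, 1.25],
            scan_offset=[0.0, 30.0], noise_sd=0.02 * contrast, seed=5,
        ))
        b, t = truth.fusion_pairs[0]
        sel = select_fusion_slice_auto(scans[0], scans[1], b)
        assert abs(sel.top_slice - t) <= 1

    def test_confidence_near_one_for_sharp_match(self, coral):
        vol, _ = coral
        bottom = Volume(vol.voxels[:40], vol.voxel_size_um, 32)
        top = Volume(vol.voxels[25:], vol.voxel_size_um, 32)
        sel = select_fusion_slice_auto(bottom, top, 30)
        assert sel.confidence > 0.9

    def test_mismatched_xy_extents_rejected(self, coral):
        vol, _ = coral
        cropped = Volume(vol.voxels[:, :-2, :], vol.voxel_size_um, 32)
        with pytest.raises(ValueError, match="XY"):
            select_fusion_slice_auto(vol, cropped, 0)

    def test_reference_index_bounds_checked(self, coral):
        vol, _ = coral
        with pytest.raises(IndexError):
            select_fusion_slice_auto(vol, vol, vol.z_extent)


class TestIntensityCalibration:
    def test_identity_when_slices_equal(self, coral):
        vol, _ = coral
        cal = fit_intensity_calibration(vol.voxels[20], vol.voxels[20])
        assert cal.slope == pytest.approx(1.0, abs=1e-12)
        assert cal.intercept == pytest.approx(0.0, abs=1e-9)

    def test_recovers_constructed_affine_exactly(self, coral):
        vol, _ = coral
        bottom = vol.voxels[20]
        top = (bottom - 10.0) / 1.2
        cal = fit_intensity_calibration(bottom, top)
        assert cal.slope == pytest.approx(1.2, rel=1e-12)
        assert cal.intercept == pytest.approx(10.0, rel=1e-9)

    def test_slope_within_5pct_under_1pct_noise(self, coral, rng):
        vol, _ = coral
        bottom = vol.voxels[20]
        contrast = bottom.max() - bottom.min()
        top = (bottom - 10.0) / 1.2 + rng.normal(0, 0.01 * contrast, bottom.shape)
        rois = default_rois(bottom.shape, reference=bottom, grid=4)
        assert len(rois) >= 12
        cal = fit_intensity_calibration(bottom, top, rois)
        assert cal.slope == pytest.approx(1.2, rel=0.05)

    def test_degenerate_inputs_rejected(self, coral):
        vol, _ = coral
        with pytest.raises(ValueError, match="degenerate|identical"):
            fit_intensity_calibration(vol.voxels[20], np.full_like(vol.voxels[20], 5.0))
        with pytest.raises(ValueError, match="2 ROIs"):
            fit_intensity_calibration(vol.voxels[20], vol.voxels[20],
                                      rois=[(0, 4, 0, 4)])

    def test_roi_outside_bounds_rejected(self, coral):
        vol, _ = coral
        with pytest.raises(ValueError, match="outside"):
            fit_intensity_calibration(vol.voxels[20], vol.voxels[20],
                                      rois=[(0, 4, 0, 4), (0, 999, 0, 4)])

    def test_apply_affine_on_constant(self):
        v = _vol(np.full((2, 3, 3), 10.0))
        out = apply_intensity_calibration(v, IntensityCalibration(2.0, 5.0))
        assert np.all(out.voxels == 25.0)
        assert out.bit_depth == 32

    @settings(deadline=None, derandomize=True, max_examples=20)
    @given(st.floats(0.2, 5.0), st.floats(-50, 50))
    def test_fit_inverts_any_affine_distortion(self, coral, gain, offset):
        vol, _ = coral
        bottom = vol.voxels[20]
        cal = fit_intensity_calibration(bottom, gain * bottom + offset)
        restored = cal.slope * (gain * bottom + offset) + cal.intercept
        assert np.allclose(restored, bottom, atol=1e-6 * max(1, abs(offset)))


class TestConcatenatePair:
    def test_crop_arithmetic(self):
        # 1-based: bottom_slice 25, top z-extent 40, top_slice 10 -> 55 slices
        bottom = _vol(np.zeros((30, 4, 4)))
        top = _vol(np.zeros((40, 4, 4)))
        fusion = FusionSelection(bottom_slice=24, top_slice=9)  # 0-based
        res = concatenate_pair(bottom, top, fusion)
        assert res.volume.z_extent == 55

    def test_lossless_round_trip(self, coral):
        vol, _ = coral
        scans, truth = simulate_overlapping_scans(
            vol, ScanSplitSpec(n_scans=2, overlap_slices=10)
        )
        b, t = truth.fusion_pairs[0]
        res = concatenate_pair(scans[0], scans[1], FusionSelection(b, t))
        assert res.volume.z_extent == vol.z_extent
        assert np.array_equal(res.volume.voxels, vol.voxels)

    def test_calibration_restores_seam_continuity(self, coral):
        vol, _ = coral
        scans, truth = simulate_overlapping_scans(vol, ScanSplitSpec(
            n_scans=2, overlap_slices=10, heel_gain_per_slice=0.003,
            scan_gain=[1.0, 1.3], scan_offset=[0.0, 25.0],
        ))
        b, t = truth.fusion_pairs[0]
        fusion = FusionSelection(b, t)
        # the phantom itself varies slice to slice; the seam discontinuity is
        # the excess jump over that intrinsic variation
        intrinsic = vol.voxels[b + 1].mean() - vol.voxels[b].mean()

        def seam_jump(result):
            v = result.volume.voxels
            return abs((v[b + 1].mean() - v[b].mean()) - intrinsic)

        raw = concatenate_pair(scans[0], scans[1], fusion)
        cal = fit_intensity_calibration(scans[0].voxels[b], scans[1].voxels[t])
        fixed = concatenate_pair(scans[0], scans[1], fusion, cal)
        assert seam_jump(fixed) < 0.05 * seam_jump(raw)

    def test_fusion_at_last_top_slice_warns(self):
        bottom = _vol(np.zeros((5, 4, 4)))
        top = _vol(np.zeros((5, 4, 4)))
        with pytest.warns(UserWarning, match="contributes nothing"):
            res = concatenate_pair(bottom, top, FusionSelection(4, 4))
        assert res.volume.z_extent == 5

    def test_duplicate_fusion_slice_convention(self):
        bottom = _vol(np.zeros((5, 4, 4)))
        top = _vol(np.zeros((5, 4, 4)))
        res = concatenate_pair(bottom, top, FusionSelection(2, 2),
                               duplicate_fusion_slice=True)
        assert res.volume.z_extent == 3 + 3  # fusion slice enters twice

    def test_bit_depth_mismatch_aborts(self):
        a = Volume(np.zeros((3, 4, 4), np.uint8), 10.0, bit_depth=8)
        b = Volume(np.zeros((3, 4, 4), np.uint16), 10.0, bit_depth=16)
        with pytest.raises(ValueError, match="bit depths are different"):
            concatenate_pair(a, b, FusionSelection(1, 1))
        with pytest.raises(ValueError, match="bit depths are different"):
            check_bit_depths(a, b)


class TestStitchMany:
    @pytest.mark.parametrize("n_scans,overlap", [(2, 10), (3, 6), (4, 4)])
    def test_round_trip_identity_distortions(self, coral, n_scans, overlap):
        vol, _ = coral
        scans, truth = simulate_overlapping_scans(
            vol, ScanSplitSpec(n_scans=n_scans, overlap_slices=overlap)
        )
        res = stitch_many(scans, StitchConfig(
            fusion_mode="manual", manual_fusions=truth.fusion_pairs_cumulative(), calibrate=False,
        ))
        assert np.array_equal(res.volume.voxels, vol.voxels)

    def test_auto_mode_round_trip(self, coral):
        vol, _ = coral
        scans, _ = simulate_overlapping_scans(
            vol, ScanSplitSpec(n_scans=3, overlap_slices=8)
        )
        res = stitch_many(scans, StitchConfig(fusion_mode="auto"))
        assert np.allclose(res.volume.voxels, vol.voxels, atol=1e-9)

    def test_provenance_tiles_output(self, coral):
        vol, _ = coral
        scans, truth = simulate_overlapping_scans(
            vol, ScanSplitSpec(n_scans=3, overlap_slices=6)
        )
        res = stitch_many(scans, StitchConfig(
            fusion_mode="manual", manual_fusions=truth.fusion_pairs_cumulative(),
        ))
        assert len(res.provenance) == 3
        ranges = [e["crop_range"] for e in res.provenance]
        assert ranges[0][0] == 0
        assert ranges[-1][1] == res.volume.z_extent
        for (_, stop), (start, _) in zip(ranges, ranges[1:]):
            assert stop == start
        assert sum(1 for e in res.provenance if e["fusion"] is not None) == 2

    def test_associativity_on_identity_data(self, coral):
        vol, _ = coral
        scans, truth = simulate_overlapping_scans(
            vol, ScanSplitSpec(n_scans=3, overlap_slices=8)
        )
        (b0, t0), (b1, t1) = truth.fusion_pairs
        left = stitch_many(scans, StitchConfig(
            fusion_mode="manual", manual_fusions=truth.fusion_pairs_cumulative(),
            calibrate=False,
        ))
        # right grouping: stitch (B, C) first (B-C indices are local to B,
        # which is exactly what truth.fusion_pairs holds), then A onto it
        bc = stitch_many(scans[1:], StitchConfig(
            fusion_mode="manual", manual_fusions=[(b1, t1)], calibrate=False,
        ))
        right = stitch_many([scans[0], bc.volume], StitchConfig(
            fusion_mode="manual", manual_fusions=[(b0, t0)], calibrate=False,
        ))
        assert np.array_equal(left.volume.voxels, right.volume.voxels)

    def test_single_scan_rejected(self, coral):
        vol, _ = coral
        with pytest.raises(ValueError, match="at least 2"):
            stitch_many([vol])

    def test_low_confidence_aborts_naming_pair(self, coral, rng):
        vol, _ = coral
        noise = Volume(rng.uniform(0, 200, size=vol.shape), vol.voxel_size_um, 32)
        with pytest.raises(RuntimeError, match=r"pair \(0, 1\)"):
            stitch_many([vol, noise], StitchConfig(min_confidence=0.9))

    def test_force_overrides_confidence_floor(self, coral, rng):
        vol, _ = coral
        noise = Volume(rng.uniform(50, 200, size=vol.shape), vol.voxel_size_um, 32)
        res = stitch_many([vol, noise],
                          StitchConfig(min_confidence=0.9, force=True))
        assert res.volume.z_extent > vol.z_extent


class TestRadialReslice:
    def test_symmetric_volume_gives_identical_sections(self):
        # radially symmetric: intensity depends only on radius
        yy, xx = np.mgrid[0:33, 0:33]
        r = np.hypot(yy - 16, xx - 16)
        vol = _vol(np.repeat(np.exp(-r / 8)[None], 5, axis=0))
        sections = radial_reslice_preview(vol, n_angles=8, axis_centre=(16, 16))
        for j in range(1, 8):
            assert np.allclose(sections[j], sections[0], atol=0.02)

    def test_angle_zero_equals_x_profile(self, coral):
        vol, _ = coral
        cy = (vol.shape[1] - 1) // 2
        cx = (vol.shape[2] - 1) // 2
        sections = radial_reslice_preview(vol, n_angles=1, axis_centre=(cy, cx))
        n_r = sections.shape[2]
        assert np.allclose(sections[0], vol.voxels[:, cy, cx : cx + n_r])

    def test_seam_visible_before_calibration_not_after(self, coral):
        vol, _ = coral
        scans, truth = simulate_overlapping_scans(vol, ScanSplitSpec(
            n_scans=2, overlap_slices=10, scan_gain=[1.0, 1.4], scan_offset=[0, 30],
        ))
        b, t = truth.fusion_pairs[0]
        fusion = FusionSelection(b, t)
        raw = concatenate_pair(scans[0], scans[1], fusion)
        cal = fit_intensity_calibration(scans[0].voxels[b], scans[1].voxels[t])
        fixed = concatenate_pair(scans[0], scans[1], fusion, cal)
        src_rows = radial_reslice_preview(vol, n_angles=4).mean(axis=2)
        intrinsic = src_rows[:, b + 1] - src_rows[:, b]

        def seam_band_jump(res):
            pv = radial_reslice_preview(res.volume, n_angles=4)
            rows = pv.mean(axis=2)  # (angles, z)
            return np.abs((rows[:, b + 1] - rows[:, b]) - intrinsic).max()

        assert seam_band_jump(fixed) < 0.05 * seam_band_jump(raw)

    def test_invalid_inputs(self, coral):
        vol, _ = coral
        with pytest.raises(ValueError):
            radial_reslice_preview(vol, n_angles=0)
        with pytest.raises(ValueError):
            radial_reslice_preview(vol, n_angles=1, axis_centre=(-5, 0))
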