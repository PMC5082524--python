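"""ROI resampling, thresholding, clustering, peaks and the long-axis split."""

import numpy as np
import pytest

from scenesel.first_level_glm import ZMap
from scenesel.grid import TemplateSpace, raster_argmax
from scenesel.roi_cluster import (
    ThresholdSpec,
    find_clusters,
    peak_in_roi,
    roi_has_activation,
    split_hc_long_axis,
    threshold_zmap,
    to_subject_space,
    to_template_space,
)


def _zmap(data, fwhm=0.0, space="subject"):
    return ZMap(data=np.asarray(data, float), contrast="scenes>objects", fwhm_mm=fwhm, space=space)


def _translation(mm):
    a = np.eye(4)
    a[:3, 3] = mm
    return a


class TestToSubjectSpace:
    def test_identity_affine_preserves_mask(self, space_small, rois_small):
        out = to_subject_space(rois_small["PHG"], np.eye(4), space_small)
        np.testing.assert_array_equal(out, rois_small["PHG"])

    def test_one_voxel_translation_shifts_mask_exactly(self, space_small, rois_small):
        # subject-to-template shift of +2 mm in x: the subject-space mask is
        # the template mask rolled one voxel towards -x
        mask = rois_small["HC"]
        out = to_subject_space(mask, _translation((2.0, 0.0, 0.0)), space_small)
        np.testing.assert_array_equal(out, np.roll(mask, -1, axis=0))
        assert out.sum() == mask.sum()  # voxel count preserved

    def test_roundtrip_is_idempotent(self, space_small, rois_small):
        affine = _translation((2.0, -4.0, 2.0))
        subj = to_subject_space(rois_small["TOS"], affine, space_small)
        back = to_template_space(subj, affine, space_small)
        np.testing.assert_array_equal(back, rois_small["TOS"])

    def test_singular_affine_rejected(self, space_small, rois_small):
        with pytest.raises(ValueError, match="singular"):
            to_subject_space(rois_small["PHG"], np.zeros((4, 4)), space_small)

    def test_off_grid_transform_errors(self, space_small, rois_small):
        with pytest.raises(ValueError, match="empty"):
            to_subject_space(rois_small["PHG"], _translation((500.0, 0, 0)), space_small)


class TestThresholdZmap:
    def test_all_zero_map_gives_empty_result(self):
        out = threshold_zmap(_zmap(np.zeros((4, 4, 4))), ThresholdSpec(2.3))
        assert not out.data.any()

    def test_suprathreshold_sets_are_nested(self, rng):
        z = _zmap(rng.standard_normal((10, 10, 10)) * 2)
        s39 = threshold_zmap(z, ThresholdSpec(3.9)).data
        s31 = threshold_zmap(z, ThresholdSpec(3.1)).data
        s23 = threshold_zmap(z, ThresholdSpec(2.3)).data
        assert not (s39 & ~s31).any()
        assert not (s31 & ~s23).any()

    def test_boundary_voxel_membership(self):
        data = np.zeros((3, 3, 3))
        data[1, 1, 1] = 3.5
        z = _zmap(data)
        assert threshold_zmap(z, ThresholdSpec(2.3)).data[1, 1, 1]
        assert threshold_zmap(z, ThresholdSpec(3.1)).data[1, 1, 1]
        assert not threshold_zmap(z, ThresholdSpec(3.9)).data[1, 1, 1]

    def test_smoothing_metadata_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            threshold_zmap(_zmap(np.zeros((2, 2, 2)), fwhm=5.0), ThresholdSpec(2.3, 0.0))

    def test_nonpositive_threshold_rejected(self):
        with pytest.raises(ValueError):
            ThresholdSpec(0.0)


class TestFindClusters:
    def test_single_isolated_voxel(self):
        m = np.zeros((5, 5, 5), bool)
        m[2, 2, 2] = True
        cs = find_clusters(m)
        assert cs.n_clusters == 1
        assert list(cs.sizes) == [1]

    def test_corner_neighbours_depend_on_connectivity(self):
        m = np.zeros((4, 4, 4), bool)
        m[0, 0, 0] = m[1, 1, 1] = True  # share only a corner
        assert find_clusters(m, connectivity=26).n_clusters == 1
        assert find_clusters(m, connectivity=6).n_clusters == 2

    def test_sizes_partition_suprathreshold_set(self, rng):
        m = rng.random((12, 12, 12)) > 0.7
        cs = find_clusters(m)
        assert cs.sizes.sum() == m.sum()
        assert (cs.labels > 0).sum() == m.sum()

    def test_invalid_connectivity_rejected(self):
        with pytest.raises(ValueError):
            find_clusters(np.zeros((2, 2, 2), bool), connectivity=8)


class TestRoiHasActivation:
    def test_voxel_just_outside_roi_not_counted(self, space_small, rois_small):
        roi = rois_small["PHG"]
        outside = np.argwhere(~roi)[0]
        data = np.zeros(space_small.grid_shape)
        data[tuple(outside)] = 10.0
        flag, count = roi_has_activation(_zmap(data), roi, ThresholdSpec(2.3))
        assert not flag and count == 0

    def test_strong_in_roi_effect_detected_at_all_thresholds(self, space_small, rois_small):
        roi = rois_small["TOS"]
        data = np.zeros(space_small.grid_shape)
        data[tuple(np.argwhere(roi)[0])] = 10.0
        for thr in (2.3, 3.1, 3.9):
            flag, count = roi_has_activation(_zmap(data), roi, ThresholdSpec(thr))
            assert flag and count == 1

    def test_empty_roi_rejected(self, space_small):
        with pytest.raises(ValueError, match="empty"):
            roi_has_activation(
                _zmap(np.zeros(space_small.grid_shape)),
                np.zeros(space_small.grid_shape, bool),
                ThresholdSpec(2.3),
            )

    def test_space_mismatch_rejected(self, space_small, rois_small):
        z = _zmap(np.zeros(space_small.grid_shape), space="template")
        with pytest.raises(ValueError, match="space"):
            roi_has_activation(z, rois_small["PHG"], ThresholdSpec(2.3), roi_space="subject")


class TestPeakInRoi:
    def test_unique_maximum_found(self, space_small, rois_small):
        roi = rois_small["HC"]
        data = np.zeros(space_small.grid_shape)
        target = np.argwhere(roi)[5]
        data[tuple(target)] = 4.2
        rec = peak_in_roi(_zmap(data), roi, space_small, roi_name="HC", z_threshold=2.3)
        np.testing.assert_array_equal(space_small.world_to_voxel(rec.coord_mm), target)
        assert rec.peak_z == pytest.approx(4.2)
        assert rec.suprathreshold

    def test_tie_broken_by_raster_order_x_fastest(self):
        space = TemplateSpace(grid_shape=(4, 4, 4), voxel_size_mm=2.0, origin_mm=(0, 0, 0))
        data = np.zeros((4, 4, 4))
        data[3, 0, 1] = data[0, 2, 1] = data[1, 1, 2] = 5.0
        roi = np.ones((4, 4, 4), bool)
        # raster order: x fastest, then y, then z -> (3,0,1) precedes (0,2,1)
        rec = peak_in_roi(_zmap(data), roi, space)
        np.testing.assert_array_equal(space.world_to_voxel(rec.coord_mm), (3, 0, 1))

    def test_agrees_with_brute_force_scan(self, rng):
        space = TemplateSpace(grid_shape=(8, 7, 6), voxel_size_mm=2.0, origin_mm=(-8, -7, -6))
        for _ in range(100):
            data = np.round(rng.standard_normal((8, 7, 6)), 1)  # induce ties
            roi = rng.random((8, 7, 6)) > 0.4
            if not roi.any():
                continue
            rec = peak_in_roi(_zmap(data), roi, space)
            # oracle: exhaustive scan in documented raster order
            best, best_val = None, -np.inf
            for iz in range(6):
                for iy in range(7):
                    for ix in range(8):
                        if roi[ix, iy, iz] and data[ix, iy, iz] > best_val:
                            best, best_val = (ix, iy, iz), data[ix, iy, iz]
            np.testing.assert_array_equal(space.world_to_voxel(rec.coord_mm), best)

    def test_subthreshold_peak_flagged_not_errored(self, space_small, rois_small):
        rec = peak_in_roi(
            _zmap(np.zeros(space_small.grid_shape)),
            rois_small["RSC"],
            space_small,
            z_threshold=2.3,
        )
        assert not rec.suprathreshold

    def test_hemisphere_from_sign_of_x(self, space_small, rois_small):
        roi = rois_small["PHG"]
        data = np.zeros(space_small.grid_shape)
        coords = np.argwhere(roi)
        mms = coords * 2.0 + np.asarray(space_small.origin_mm)
        left = coords[mms[:, 0] < 0][0]
        data[tuple(left)] = 1.0
        rec = peak_in_roi(_zmap(data), roi, space_small)
        assert rec.hemisphere == "left"


class TestSplitHcLongAxis:
    def test_reported_anterior_peak_classified_anterior(self):
        # right anterior hippocampal peak with the conventional -21 mm split
        assert split_hc_long_axis((22, -16, -22), -21.0) == "anterior"

    def test_boundary_counts_anterior(self):
        assert split_hc_long_axis((20, -21.0, -22), -21.0) == "anterior"

    def test_below_split_is_posterior(self):
        assert split_hc_long_axis((20, -31.0, -22), -21.0) == "posterior"

    def test_coordinate_outside_mask_rejected(self, space_small, rois_small):
        with pytest.raises(ValueError, match="outside"):
            split_hc_long_axis(
                (0.0, 30.0, 20.0),
                rois_small.hc_split_y_mm,
                hc_mask=rois_small["HC"],
                space=space_small,
            )
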