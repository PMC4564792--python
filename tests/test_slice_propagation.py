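import numpy as np
import pytest
from scipy import ndimage

from toothprop import (
    GrowParams,
    PropagationParams,
    SliceSegState,
    ThresholdSearchParams,
    ToothSeedSet,
    check_segmentation,
    generate_phantom,
    median_denoise,
    propagate_slice,
    remove_branches,
    segment_teeth,
)
from toothprop.errors import ReferenceSegmentationError
from toothprop.region_grow import BoundingBox
from toothprop.volume_io import VolumeImage

from conftest import small_config


class TestMedianDenoise:
    def test_constant_image_unchanged(self):
        img = np.full((9, 9), 1300, dtype=np.int16)
        np.testing.assert_array_equal(median_denoise(img, 3), img)

    def test_salt_pixel_removed(self):
        img = np.full((9, 9), 100, dtype=np.int16)
        img[4, 4] = 3000
        out = median_denoise(img, 3)
        assert out[4, 4] == 100

    def test_kernel_one_is_identity(self):
        rng = np.random.default_rng(0)
        img = rng.integers(0, 2000, (8, 8)).astype(np.int16)
        np.testing.assert_array_equal(median_denoise(img, 1), img)

    def test_even_kernel_rejected(self):
        with pytest.raises(ValueError):
            median_denoise(np.zeros((4, 4)), 2)


class TestRemoveBranches:
    def test_mask_within_own_dilation_unchanged(self):
        mask = np.zeros((20, 20), bool)
        mask[5:10, 5:10] = True
        out = remove_branches(mask, mask, 3, [(7, 7)])
        np.testing.assert_array_equal(out, mask)

    def test_leaking_arm_is_clipped_to_dilation(self):
        prev = np.zeros((20, 40), bool)
        prev[5:10, 5:10] = True
        cur = prev.copy()
        cur[7, 10:30] = True  # 20-px arm leaking sideways
        out = remove_branches(cur, prev, 3, [(7, 7)])
        # containment oracle: Euclidean dilation via distance transform
        dilated = ndimage.distance_transform_edt(~prev) <= 3
        assert not out[~dilated].any()
        assert out[5:10, 5:10].all()
        assert not out[7, 13:].any()  # distal arm removed
        assert out[7, 10:13].any()  # proximal stub may survive

    def test_disjoint_masks_give_empty(self):
        prev = np.zeros((15, 15), bool)
        prev[2:5, 2:5] = True
        cur = np.zeros((15, 15), bool)
        cur[11:14, 11:14] = True
        assert not remove_branches(cur, prev, 3, [(12, 12)]).any()

    def test_empty_prev_rejected(self):
        with pytest.raises(ValueError):
            remove_branches(np.ones((5, 5), bool), np.zeros((5, 5), bool), 3, [(2, 2)])


class TestCheckSegmentation:
    def test_identical_masks_ok(self):
        m = np.ones((5, 5), bool)
        assert check_segmentation(m, m, 0.3) == "ok"

    def test_doubled_area_is_over(self):
        prev = np.zeros((10, 10), bool)
        prev[:5, :2] = True  # 10 px
        cur = np.zeros((10, 10), bool)
        cur[:5, :4] = True  # 20 px, r = 2.0
        assert check_segmentation(cur, prev, 0.3) == "over"

    def test_empty_current_is_under(self):
        prev = np.ones((4, 4), bool)
        assert check_segmentation(np.zeros((4, 4), bool), prev, 0.3) == "under"


def _state_from_truth(gt, z, t_value=1400.0):
    masks = {tid: gt.data[:, :, z] == tid for tid in gt.labels()}
    return SliceSegState(
        z=z,
        masks=masks,
        t_values={tid: t_value for tid in masks},
        status={tid: "active" for tid in masks},
    )


@pytest.fixture(scope="module")
def flat_phantom():
    """Noiseless constant-radius phantom: adjacent slices are identical."""
    return generate_phantom(small_config(noise_sigma=0.0, taper=0.0, contrast_gap=200.0))


class TestPropagateSlice:
    def _params(self):
        return (
            PropagationParams(),
            ThresholdSearchParams(t_min=900.0),
            GrowParams(delta=150.0),
        )

    def test_identical_slices_are_a_fixed_point(self, flat_phantom):
        """Without noise there is nothing to denoise (kernel 1): propagating
        the true masks onto an identical slice returns them exactly, with an
        unchanged T-value."""
        vol, gt, seedset = flat_phantom
        z = seedset.reference_slice
        params = PropagationParams(median_kernel=1)
        _, tparams, gparams = self._params()
        state1 = propagate_slice(_state_from_truth(gt, z), vol.data[:, :, z + 1], z + 1, params, tparams, gparams)
        state2 = propagate_slice(state1, vol.data[:, :, z + 2], z + 2, params, tparams, gparams)
        for tid in gt.labels():
            np.testing.assert_array_equal(state1.masks[tid], gt.data[:, :, z + 1] == tid)
            np.testing.assert_array_equal(state2.masks[tid], state1.masks[tid])
            assert state2.t_values[tid] == state1.t_values[tid]

    def test_fixed_point_with_median_denoising(self, flat_phantom):
        """With a 3x3 median the first propagated slice settles onto the
        median-shaped geometry (a boundary-pixel nibble of the true section)
        and stays exactly there afterwards."""
        vol, gt, seedset = flat_phantom
        z = seedset.reference_slice
        params, tparams, gparams = self._params()
        state1 = propagate_slice(_state_from_truth(gt, z), vol.data[:, :, z + 1], z + 1, params, tparams, gparams)
        state2 = propagate_slice(state1, vol.data[:, :, z + 2], z + 2, params, tparams, gparams)
        for tid in gt.labels():
            truth = gt.data[:, :, z + 1] == tid
            assert (state1.masks[tid] ^ truth).sum() <= 4
            np.testing.assert_array_equal(state2.masks[tid], state1.masks[tid])
            assert state2.t_values[tid] == state1.t_values[tid]

    def test_tapering_tooth_tracked_within_band(self):
        def disk_img(radius):
            img = np.full((40, 40), 1300, dtype=np.int16)
            yy, xx = np.mgrid[:40, :40]
            img[(xx - 20) ** 2 + (yy - 20) ** 2 <= radius**2] = 1500
            return img

        prev_img = disk_img(6.0)
        cur_img = disk_img(5.4)  # radius -10%, area ~0.81x
        prev_mask = prev_img == 1500
        state = SliceSegState(0, {1: prev_mask}, {1: 1400.0}, {1: "active"})
        params, tparams, gparams = self._params()
        out = propagate_slice(state, cur_img, 1, params, tparams, gparams)
        assert out.status[1] == "active"
        ratio = out.masks[1].sum() / prev_mask.sum()
        assert 0.8 <= ratio <= 1.0

    def test_tooth_terminates_past_the_crown(self, flat_phantom):
        vol, gt, seedset = flat_phantom
        z = seedset.reference_slice
        tissue = np.full(vol.data[:, :, 0].shape, 200, dtype=np.int16)
        params, tparams, gparams = self._params()
        out = propagate_slice(_state_from_truth(gt, z), tissue, z + 1, params, tparams, gparams)
        assert out.active_ids == []
        assert all(s == "terminated" for s in out.status.values())

    def test_masks_stay_pairwise_disjoint(self, flat_phantom):
        vol, gt, seedset = flat_phantom
        z = seedset.reference_slice
        params, tparams, gparams = self._params()
        out = propagate_slice(_state_from_truth(gt, z), vol.data[:, :, z + 1], z + 1, params, tparams, gparams)
        total = np.zeros(vol.data[:, :, 0].shape, dtype=int)
        for m in out.masks.values():
            total += m
        assert total.max() <= 1


class TestSegmentTeeth:
    def test_small_phantom_recovers_every_tooth(self, small_phantom):
        vol, gt, seedset = small_phantom
        from toothprop import evaluate_labels

        lab = segment_teeth(vol, seedset)
        assert lab.labels() == gt.labels()
        rep = evaluate_labels(lab, gt)
        assert rep.mean("e_vol_abs") < 10.0
        # per-slice disjointness is structural: labels are single-valued

    def test_single_slice_volume_is_reference_only(self, small_phantom):
        vol, gt, seedset = small_phantom
        z = seedset.reference_slice
        single = VolumeImage(vol.data[:, :, z : z + 1], vol.spacing)
        box = seedset.bbox
        seeds1 = ToothSeedSet(
            reference_slice=0,
            seeds=seedset.seeds,
            bbox=BoundingBox((box.mins[0], box.mins[1], 0), (box.maxs[0], box.maxs[1], 1)),
        )
        lab = segment_teeth(single, seeds1)
        assert lab.shape[2] == 1
        assert lab.labels() == gt.labels()

    def test_z_mirrored_volume_gives_z_mirrored_labels(self, small_phantom):
        """Direction consistency: propagation treats +z and -z identically."""
        vol, gt, seedset = small_phantom
        nz = vol.shape[2]
        mvol = VolumeImage(vol.data[:, :, ::-1].copy(), vol.spacing)
        box = seedset.bbox
        mseeds = ToothSeedSet(
            reference_slice=nz - 1 - seedset.reference_slice,
            seeds=seedset.seeds,
            bbox=BoundingBox(
                (box.mins[0], box.mins[1], nz - box.maxs[2]),
                (box.maxs[0], box.maxs[1], nz - box.mins[2]),
            ),
        )
        lab = segment_teeth(vol, seedset)
        mlab = segment_teeth(mvol, mseeds)
        np.testing.assert_array_equal(mlab.data[:, :, ::-1], lab.data)

    def test_bad_reference_seed_is_hard_error(self, small_phantom):
        vol, gt, seedset = small_phantom
        box = seedset.bbox
        bad = dict(seedset.seeds)
        bad[1] = [(box.mins[0], box.mins[1])]  # air/tissue corner pixel
        seeds_bad = ToothSeedSet(seedset.reference_slice, bad, box)
        with pytest.raises(ReferenceSegmentationError, match="tooth 1"):
            segment_teeth(vol, seeds_bad)


def test_seed_set_json_round_trip(tmp_path, small_phantom):
    seedset = small_phantom[2]
    path = tmp_path / "seeds.json"
    seedset.to_json(path)
    back = ToothSeedSet.from_json(path)
    assert back.reference_slice == seedset.reference_slice
    assert back.seeds == seedset.seeds
    assert back.bbox == seedset.bbox


def test_propagation_params_validated():
    with pytest.raises(ValueError):
        PropagationParams(median_kernel=4)
    with pytest.raises(ValueError):
        PropagationParams(dilation_radius=7)
    with pytest.raises(ValueError):
        PropagationParams(size_change_max=0.0)
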