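"""Preprocessing: bubble removal, median filter, Otsu+5% segmentation,
body masks, rigid alignment and the DVC evaluation VOI."""

import numpy as np
import pytest
from scipy import ndimage

from spinedvc import (
    GreyVolume,
    PhantomSpec,
    align_rigid,
    build_body_mask,
    denoise_median,
    generate_phantom,
    make_voi_dvc,
    remove_air_bubbles,
    segment_bone,
    simulate_repeat_scan,
)
from spinedvc.volumes import BinaryMask


class TestBubbleRemoval:
    def test_no_low_voxels_means_no_change(self, small_phantom):
        _, vol, truth = small_phantom
        out = remove_air_bubbles(vol, truth.body_mask, air_cutoff=10.0,
                                 marrow_stats=(60.0, 5.0), seed=0)
        assert np.array_equal(out.data, vol.data)

    def test_bubbles_are_fully_replaced_with_marrow_stats(self):
        spec = PhantomSpec(shape=(64, 64, 64), target_bvtv=0.15, noise_sd=0.0,
                           n_bubbles=3, seed=8)
        vol, truth = generate_phantom(spec)
        cutoff = 30.0
        replaced = truth.body_mask.data & (vol.data < cutoff)
        n = replaced.sum()
        assert n > 0
        out = remove_air_bubbles(vol, truth.body_mask, cutoff, (60.0, 4.0), seed=1)
        assert (out.data[truth.body_mask.data] < cutoff).sum() == 0
        # replaced-region mean within 3 standard errors of the marrow mean
        vals = out.data[replaced]
        assert abs(vals.mean() - 60.0) <= 3 * 4.0 / np.sqrt(n)

    def test_negative_marrow_sd_rejected(self, small_phantom):
        _, vol, truth = small_phantom
        with pytest.raises(ValueError):
            remove_air_bubbles(vol, truth.body_mask, 10.0, (60.0, -1.0))


class TestMedianFilter:
    def test_constant_volume_unchanged(self):
        vol = GreyVolume(np.full((20, 20, 20), 7.0))
        assert np.array_equal(denoise_median(vol).data, vol.data)

    def test_single_impulse_removed(self):
        data = np.zeros((21, 21, 21))
        data[10, 10, 10] = 100.0
        out = denoise_median(GreyVolume(data))
        assert out.data[10, 10, 10] == 0.0

    def test_matches_brute_force_neighborhood_median(self, rng):
        data = rng.random((24, 24, 24))
        out = denoise_median(GreyVolume(data)).data
        for _ in range(20):
            x, y, z = rng.integers(1, 23, size=3)
            nb = data[x - 1:x + 2, y - 1:y + 2, z - 1:z + 2]
            assert out[x, y, z] == np.median(nb)


def _otsu_bruteforce(values):
    """Exhaustive between-class-variance scan over a 256-bin histogram."""
    hist, edges = np.histogram(values, bins=256)
    centers = 0.5 * (edges[:-1] + edges[1:])
    best_t, best_var = centers[0], -1.0
    total = hist.sum()
    for k in range(1, 256):
        w0 = hist[:k].sum() / total
        w1 = 1 - w0
        if w0 == 0 or w1 == 0:
            continue
        m0 = (hist[:k] * centers[:k]).sum() / hist[:k].sum()
        m1 = (hist[k:] * centers[k:]).sum() / hist[k:].sum()
        var = w0 * w1 * (m0 - m1) ** 2
        if var > best_var:
            best_var, best_t = var, centers[k - 1]
    return best_t


class TestSegmentBone:
    def _two_valued(self, lo=100.0, hi=200.0):
        data = np.full((32, 32, 32), lo)
        data[:, :, 16:] = hi  # equal counts
        return GreyVolume(data), BinaryMask(np.ones((32, 32, 32), bool))

    def test_two_valued_volume_threshold_between_modes(self):
        vol, voi = self._two_valued()
        mask = segment_bone(vol, voi)
        t_ref = _otsu_bruteforce(vol.data[voi.data])
        assert 100.0 < t_ref * 1.05 < 200.0
        assert np.array_equal(mask.data, vol.data == 200.0)

    def test_threshold_tracks_raised_bone_grey(self):
        vol, voi = self._two_valued()
        mask1 = segment_bone(vol, voi)
        vol2, _ = self._two_valued(hi=240.0)
        mask2 = segment_bone(vol2, voi)
        assert np.array_equal(mask1.data, mask2.data)

    def test_single_valued_voi_is_degenerate(self):
        vol = GreyVolume(np.full((32, 32, 32), 50.0))
        with pytest.raises(ValueError, match="degenerate"):
            segment_bone(vol, BinaryMask(np.ones((32, 32, 32), bool)))

    def test_idempotent(self, small_phantom):
        _, vol, truth = small_phantom
        m1 = segment_bone(vol, truth.nocort_mask)
        m2 = segment_bone(vol, truth.nocort_mask)
        assert np.array_equal(m1.data, m2.data)


class TestBodyMask:
    def test_phantom_body_bracketed_by_ground_truth(self, small_phantom):
        spec, vol, truth = small_phantom
        level = 0.5 * (spec.grey_air + spec.grey_marrow)
        mask = build_body_mask(vol, level=level)
        inner = ndimage.binary_erosion(truth.body_mask.data, iterations=2)
        outer = ndimage.binary_dilation(truth.body_mask.data, iterations=2)
        assert np.all(mask.data[inner])
        assert not np.any(mask.data & ~outer)

    def test_hollow_sphere_interior_filled(self):
        x = np.arange(48) - 23.5
        r2 = x[:, None, None] ** 2 + x[None, :, None] ** 2 + x[None, None, :] ** 2
        shell = (r2 <= 18**2) & (r2 >= 14**2)
        mask = build_body_mask(GreyVolume(shell * 100.0), level=30.0)
        assert mask.data[24, 24, 24]

    def test_largest_component_kept(self):
        data = np.zeros((48, 48, 48))
        data[4:30, 4:30, 4:30] = 100.0
        data[38:44, 38:44, 38:44] = 100.0
        mask = build_body_mask(data := GreyVolume(data), level=30.0)
        assert mask.data[16, 16, 16]
        assert not mask.data[40, 40, 40]

    def test_output_is_a_fixed_point_of_hole_filling(self, small_phantom):
        spec, vol, _ = small_phantom
        level = 0.5 * (spec.grey_air + spec.grey_marrow)
        m1 = build_body_mask(vol, level=level)
        assert np.array_equal(ndimage.binary_fill_holes(m1.data), m1.data)


class TestRigidAlign:
    def test_identity_recovered_exactly(self, small_phantom):
        _, vol, _ = small_phantom
        _, params = align_rigid(vol, vol)
        assert np.abs(params["translation_voxels"]).max() < 1e-6
        assert np.abs(params["rotation_matrix"] - np.eye(3)).max() < 1e-6

    def test_known_translation_recovered(self, small_phantom):
        _, vol, truth = small_phantom
        moved = simulate_repeat_scan(vol, truth, {"translation": (3.0, -2.0, 1.5)},
                                     noise_sd=0.0, seed=1)
        _, params = align_rigid(moved, vol)
        # align_rigid estimates the inverse of the applied motion
        assert np.abs(np.asarray(params["translation_voxels"])
                      - np.array([-3.0, 2.0, -1.5])).max() <= 0.2

    def test_known_rotation_recovered(self, small_phantom):
        _, vol, truth = small_phantom
        moved = simulate_repeat_scan(vol, truth, {"rotation": (0, 0, 2.0)},
                                     noise_sd=0.0, seed=1)
        _, params = align_rigid(moved, vol)
        R = params["rotation_matrix"]
        ang = np.degrees(np.arctan2(R[1, 0], R[0, 0]))
        assert abs(ang - (-2.0)) <= 0.2


class TestVoiDvc:
    def test_cube_erosion_analytic(self):
        m = np.zeros((128, 128, 128), bool)
        m[10:110, 10:110, 10:110] = True
        _, voi = make_voi_dvc(BinaryMask(m), BinaryMask(m), margin=25)
        assert voi.count() == 50**3

    def test_zero_margin_is_identity_and_merge_is_intersection(self):
        a = np.zeros((40, 40, 40), bool)
        a[5:30, 5:30, 5:30] = True
        b = np.zeros_like(a)
        b[10:35, 10:35, 10:35] = True
        merged, voi = make_voi_dvc(BinaryMask(a), BinaryMask(b), margin=0)
        assert np.array_equal(voi.data, a)
        assert np.array_equal(merged.data, a & b)

    def test_sphere_erosion_close_to_analytic_ball(self):
        x = np.arange(96) - 47.5
        r2 = x[:, None, None] ** 2 + x[None, :, None] ** 2 + x[None, None, :] ** 2
        sphere = r2 <= 40**2
        _, voi = make_voi_dvc(BinaryMask(sphere), BinaryMask(sphere), margin=25)
        # cubic erosion of a ball r=40 by half-width 25 contains the ball
        # r=15 and is contained in it up to corner effects; compare volume
        assert abs(voi.count() - 4 / 3 * np.pi * 15**3) <= 0.05 * 4 / 3 * np.pi * 15**3

    def test_erosion_monotone_in_margin(self):
        m = np.zeros((64, 64, 64), bool)
        m[4:60, 4:60, 4:60] = True
        _, v_small = make_voi_dvc(BinaryMask(m), BinaryMask(m), margin=5)
        _, v_big = make_voi_dvc(BinaryMask(m), BinaryMask(m), margin=10)
        assert not np.any(v_big.data & ~v_small.data)

    def test_overerosion_raises(self):
        m = np.zeros((40, 40, 40), bool)
        m[15:25, 15:25, 15:25] = True
        with pytest.raises(ValueError, match="margin"):
            make_voi_dvc(BinaryMask(m), BinaryMask(m), margin=10)


def test_noiseless_pipeline_recovers_ground_truth_bone():
    """segment_bone ∘ denoise_median on a clean phantom: Dice >= 0.95."""
    spec = PhantomSpec(shape=(80, 80, 80), target_bvtv=0.25,
                       mean_struct_thickness=6.0, noise_sd=0.0, seed=13)
    vol, truth = generate_phantom(spec)
    bone = segment_bone(denoise_median(vol), truth.nocort_mask)
    gt = truth.bone_mask.data & truth.nocort_mask.data
    got = bone.data & truth.nocort_mask.data
    dice = 2 * (gt & got).sum() / (gt.sum() + got.sum())
    assert dice >= 0.95
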