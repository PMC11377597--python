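import numpy as np
import pytest

from tauvbm.pet import (
    HRRT_KERNEL,
    PETCT_KERNEL,
    SmoothingKernel,
    average_frames,
    compute_suvr,
    percent_positivity,
    smooth,
    threshold_positivity,
)
from tauvbm.volume_io import ImageVolume, LabelAtlas


def vol(data, vx=(2.0, 2.0, 2.0)):
    return ImageVolume(np.asarray(data, dtype=float), vx)


def const(shape, c):
    return vol(np.full(shape, float(c)))


class TestFrameAveraging:
    def test_single_exact_frame_unchanged(self, rng):
        f = vol(rng.normal(size=(4, 4, 4)))
        out = average_frames([(f, 80.0, 100.0)], (80.0, 100.0))
        np.testing.assert_array_equal(out.data, f.data)

    def test_two_equal_frames_average(self):
        out = average_frames(
            [(const((4, 4, 4), 1.0), 80, 90), (const((4, 4, 4), 3.0), 90, 100)],
            (80, 100),
        )
        np.testing.assert_allclose(out.data, 2.0)

    def test_duration_weighted_partial_overlap(self):
        # frames [80,90]=1 and [90,100]=4, window [80,95]: (10*1 + 5*4)/15 = 2
        out = average_frames(
            [(const((4, 4, 4), 1.0), 80, 90), (const((4, 4, 4), 4.0), 90, 100)],
            (80, 95),
        )
        np.testing.assert_allclose(out.data, 2.0)

    def test_uncovered_window_names_gap(self):
        with pytest.raises(ValueError, match=r"gap"):
            average_frames([(const((4, 4, 4), 1.0), 80, 90)], (80, 100))

    def test_overlapping_frames_rejected(self):
        with pytest.raises(ValueError, match="non-overlapping"):
            average_frames(
                [(const((4, 4, 4), 1.0), 80, 91), (const((4, 4, 4), 2.0), 90, 100)],
                (80, 100),
            )


class TestSuvr:
    def test_uniform_activity_gives_unit_suvr(self):
        ref = vol(np.zeros((4, 4, 4)))
        ref.data[0] = 1.0
        out = compute_suvr(const((4, 4, 4), 7.3), ref)
        np.testing.assert_allclose(out.data, 1.0)

    def test_brute_force_oracle_on_random_volume(self, rng):
        act = vol(rng.uniform(0.5, 3.0, size=(8, 8, 8)))
        refmask = vol((rng.uniform(size=(8, 8, 8)) < 0.2).astype(float))
        expected_ref = act.data[refmask.data > 0.5].mean()  # hand mean
        out = compute_suvr(act, refmask)
        np.testing.assert_allclose(out.data, act.data / expected_ref, rtol=1e-12)

    def test_empty_reference_fatal(self):
        with pytest.raises(ValueError, match="empty"):
            compute_suvr(const((4, 4, 4), 1.0), const((4, 4, 4), 0.0))


class TestSmoothing:
    def test_constant_volume_invariant_under_any_kernel(self):
        v = const((10, 10, 10), 2.5)
        for kern in (PETCT_KERNEL, HRRT_KERNEL):
            out = smooth(v, kern)
            np.testing.assert_allclose(out.data, 2.5, rtol=1e-12)

    def test_interior_point_source_mass_conserved(self):
        v = vol(np.zeros((33, 33, 33)), vx=(2.0, 2.0, 2.0))
        v.data[16, 16, 16] = 1.0
        out = smooth(v, PETCT_KERNEL, mode="zero")
        assert out.data.sum() == pytest.approx(1.0, rel=1e-6)

    def test_impulse_matches_dense_convolution_oracle(self):
        # 1-D impulse, sigma = 1 voxel: compare against an explicit sampled
        # Gaussian convolution
        n = 41
        fwhm = np.sqrt(8 * np.log(2))  # sigma = 1 voxel at 1 mm voxels
        v = vol(np.zeros((1, 1, n)), vx=(1.0, 1.0, 1.0))
        v.data[0, 0, n // 2] = 1.0
        out = smooth(v, SmoothingKernel((1e-9, 1e-9, fwhm)), mode="zero")
        x = np.arange(-(n // 2), n // 2 + 1, dtype=float)
        radius = int(4 * 1.0 + 0.5)  # scipy's default truncation at 4 sigma
        kern = np.exp(-0.5 * np.clip(np.abs(x), None, None) ** 2)
        kern[np.abs(x) > radius] = 0.0
        kern /= kern.sum()
        np.testing.assert_allclose(out.data[0, 0], kern, atol=1e-12)

    def test_renormalized_mode_ignores_out_of_mask_values(self):
        data = np.full((12, 12, 12), 1.0)
        mask = np.zeros_like(data, dtype=bool)
        mask[3:9, 3:9, 3:9] = True
        data[~mask] = 1e6  # garbage outside the analysis mask
        out = smooth(vol(data), PETCT_KERNEL, mask=mask)
        np.testing.assert_allclose(out.data[mask], 1.0, rtol=1e-9)
        assert np.isnan(out.data[~mask]).all()

    def test_scanner_kernels_sigma_conversion(self):
        sx, sy, sz = PETCT_KERNEL.sigma_voxels((2.0, 2.0, 2.0))
        assert sx == pytest.approx(6.55 / (2.0 * np.sqrt(8 * np.log(2))))
        assert sz == pytest.approx(7.75 / (2.0 * np.sqrt(8 * np.log(2))))


class TestPositivity:
    def test_all_below_and_boundary_conventions(self):
        gm = np.ones((3, 3, 3), dtype=bool)
        res = threshold_positivity(const((3, 3, 3), 1.0), gm)
        assert res.positive_mask.sum() == 0
        assert res.negative_mask.sum() == 27
        # boundary: exactly 1.30 is positive under the default '>=' convention
        at = threshold_positivity(const((3, 3, 3), 1.30), gm)
        assert at.positive_mask.sum() == 27
        strict = threshold_positivity(const((3, 3, 3), 1.30), gm, comparator="gt")
        assert strict.positive_mask.sum() == 0

    def test_brute_force_oracle_random_volumes(self, rng):
        for _ in range(20):
            suvr = vol(rng.uniform(1.0, 1.6, size=(4, 4, 4)))
            gm = rng.uniform(size=(4, 4, 4)) < 0.7
            if not gm.any():
                continue
            res = threshold_positivity(suvr, gm)
            for idx in np.ndindex(4, 4, 4):
                expected_pos = bool(gm[idx]) and suvr.data[idx] >= 1.30
                assert res.positive_mask[idx] == expected_pos
                assert res.negative_mask[idx] == (bool(gm[idx]) and not expected_pos)

    def test_masks_partition_gm(self, rng):
        suvr = vol(rng.uniform(1.0, 1.6, size=(6, 6, 6)))
        gm = rng.uniform(size=(6, 6, 6)) < 0.5
        res = threshold_positivity(suvr, gm)
        np.testing.assert_array_equal(res.positive_mask | res.negative_mask, gm)
        assert not (res.positive_mask & res.negative_mask).any()

    def test_missing_voxels_belong_to_neither_mask(self):
        data = np.full((3, 3, 3), 1.5)
        data[0, 0, 0] = np.nan
        res = threshold_positivity(vol(data), np.ones((3, 3, 3), dtype=bool))
        assert res.n_missing == 1
        assert not res.positive_mask[0, 0, 0] and not res.negative_mask[0, 0, 0]

    def test_empty_gm_mask_fatal(self):
        with pytest.raises(ValueError, match="empty"):
            threshold_positivity(const((3, 3, 3), 1.0), np.zeros((3, 3, 3), dtype=bool))


class TestPercentPositivity:
    def test_extremes_and_hand_count(self, rng):
        gm = np.ones((3, 3, 3), dtype=bool)
        assert threshold_positivity(const((3, 3, 3), 2.0), gm).pct_positive_global == 100.0
        assert threshold_positivity(const((3, 3, 3), 1.0), gm).pct_positive_global == 0.0
        data = np.full((3, 3, 3), 1.0)
        data.flat[:7] = 1.5  # 7 positive of 27
        res = threshold_positivity(vol(data), gm)
        assert res.pct_positive_global == pytest.approx(100.0 * 7 / 27)

    def test_per_region_loop_oracle(self, rng):
        suvr = vol(rng.uniform(1.0, 1.6, size=(6, 6, 6)))
        gm = rng.uniform(size=(6, 6, 6)) < 0.8
        labels = rng.integers(0, 4, size=(6, 6, 6)).astype(np.int32)
        atlas = LabelAtlas(labels, {1: "r1", 2: "r2", 3: "r3"})
        res = threshold_positivity(suvr, gm)
        _, by_region = percent_positivity(res, atlas)
        for lab in (1, 2, 3):
            npos = ndenom = 0
            for idx in np.ndindex(6, 6, 6):
                if labels[idx] == lab and gm[idx]:
                    ndenom += 1
                    npos += int(suvr.data[idx] >= 1.30)
            if ndenom:
                assert by_region[lab] == pytest.approx(100.0 * npos / ndenom)

    def test_region_without_gm_voxels_is_missing(self, rng):
        suvr = vol(np.full((4, 4, 4), 1.5))
        gm = np.zeros((4, 4, 4), dtype=bool)
        gm[:2] = True
        labels = np.zeros((4, 4, 4), dtype=np.int32)
        labels[3, :, :] = 2  # entirely outside GM
        res = threshold_positivity(suvr, gm)
        _, by_region = percent_positivity(res, LabelAtlas(labels, {2: "outside"}))
        assert np.isnan(by_region[2])

    def test_monotone_nonincreasing_in_threshold(self, rng):
        suvr = vol(rng.uniform(1.0, 1.8, size=(6, 6, 6)))
        gm = np.ones((6, 6, 6), dtype=bool)
        pcts = [
            threshold_positivity(suvr, gm, threshold=t).pct_positive_global
            for t in (1.1, 1.3, 1.5, 1.7)
        ]
        assert all(a >= b for a, b in zip(pcts, pcts[1:]))


class TestProcessingOrder:
    def test_smooth_then_threshold_differs_from_threshold_then_smooth(self):
        # an isolated hot voxel below-threshold neighbourhood: smoothing first
        # dilutes the spike below threshold; thresholding first keeps it
        data = np.full((9, 9, 9), 1.0)
        data[4, 4, 4] = 3.0
        gm = np.ones((9, 9, 9), dtype=bool)
        v = vol(data)
        smooth_first = threshold_positivity(smooth(v, PETCT_KERNEL, mask=gm), gm)
        thr_first_mask = (data >= 1.30) & gm
        assert smooth_first.positive_mask.sum() != thr_first_mask.sum()
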