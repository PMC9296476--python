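"""SUVR, smoothing, GTM/RBV partial-volume correction, ROI tables, z-maps."""

import numpy as np
import pytest

from hdacscope.core import DynamicImage, FrameSchedule, LabelMap, StatImage
from hdacscope.pet_quant import (
    TRACER_PROTOCOLS,
    TracerProtocol,
    compute_suvr,
    gtm_means,
    rbv_correct,
    roi_extract,
    smooth_to_fwhm,
    zscore_map,
)


def _affine(vox=2.0):
    a = np.eye(4)
    a[0, 0] = a[1, 1] = a[2, 2] = vox
    return a


@pytest.fixture()
def window_frames(three_region_map):
    """Three 10-min frames inside the 60-90 min HDAC-tracer window."""
    sched = FrameSchedule([3600.0, 4200.0, 4800.0], [600.0, 600.0, 600.0])
    data = np.ones(three_region_map.data.shape + (3,))
    return DynamicImage(data, three_region_map.affine, sched)


class TestTracerProtocols:
    def test_builtin_windows_and_references(self):
        assert TRACER_PROTOCOLS["martinostat"].reference_role == "reference_white_matter"
        assert TRACER_PROTOCOLS["martinostat"].window_min == (60.0, 90.0)
        assert TRACER_PROTOCOLS["mk6240"].window_min == (90.0, 110.0)
        assert TRACER_PROTOCOLS["azd4694"].window_min == (40.0, 70.0)
        for proto in TRACER_PROTOCOLS.values():
            assert proto.reference_role.startswith("reference")

    def test_inverted_window_rejected(self):
        with pytest.raises(ValueError):
            TracerProtocol("bad", "reference_white_matter", (90.0, 60.0))


class TestComputeSuvr:
    def test_uniform_activity_gives_unit_suvr(self, three_region_map, window_frames):
        suvr = compute_suvr(
            window_frames, TRACER_PROTOCOLS["martinostat"], three_region_map, [2]
        )
        assert np.allclose(suvr.data, 1.0)

    def test_double_activity_target_reads_two(self, three_region_map, window_frames):
        window_frames.data[three_region_map.data == 1] = 2.0
        suvr = compute_suvr(
            window_frames, TRACER_PROTOCOLS["martinostat"], three_region_map, [2]
        )
        assert np.allclose(suvr.data[three_region_map.data == 1], 2.0)

    def test_reference_mean_is_exactly_one(self, three_region_map, window_frames):
        rng = np.random.default_rng(0)
        window_frames.data[:] = rng.uniform(0.5, 3.0, size=window_frames.data.shape)
        suvr = compute_suvr(
            window_frames, TRACER_PROTOCOLS["martinostat"], three_region_map, [2]
        )
        assert suvr.data[three_region_map.data == 2].mean() == pytest.approx(1.0, abs=1e-12)

    def test_frames_outside_window_rejected(self, three_region_map):
        sched = FrameSchedule([0.0], [600.0])     # 0-10 min, outside 60-90
        dyn = DynamicImage(
            np.ones(three_region_map.data.shape + (1,)), three_region_map.affine, sched
        )
        with pytest.raises(ValueError, match="window"):
            compute_suvr(dyn, TRACER_PROTOCOLS["martinostat"], three_region_map, [2])

    def test_empty_reference_rejected(self, three_region_map, window_frames):
        with pytest.raises(ValueError, match="empty"):
            compute_suvr(
                window_frames, TRACER_PROTOCOLS["martinostat"], three_region_map, [99]
            )


class TestSmoothing:
    def test_equal_fwhm_is_identity(self):
        rng = np.random.default_rng(1)
        img = StatImage(rng.standard_normal((16, 16, 16)), _affine())
        out = smooth_to_fwhm(img, 8.0, 8.0)
        assert np.allclose(out.data, img.data)

    def test_target_below_intrinsic_rejected(self):
        img = StatImage(np.zeros((8, 8, 8)), _affine())
        with pytest.raises(ValueError):
            smooth_to_fwhm(img, 4.0, 8.0)

    def test_impulse_response_fwhm(self):
        """The impulse response of an 8-mm kernel measures 8 mm FWHM within 5%."""
        shape = (41, 41, 41)
        img = np.zeros(shape)
        img[20, 20, 20] = 1.0
        out = smooth_to_fwhm(StatImage(img, _affine(2.0)), 8.0, 0.0)
        profile = out.data[:, 20, 20]
        half = profile.max() / 2.0
        above = np.where(profile >= half)[0]
        # linear interpolation at the half-maximum crossings, in mm
        lo, hi = above[0], above[-1]
        f = lambda i, j: i + (half - profile[i]) / (profile[j] - profile[i]) * (j - i)
        width_vox = f(hi, hi + 1) - f(lo, lo - 1)
        assert width_vox * 2.0 == pytest.approx(8.0, rel=0.05)

    def test_sum_conserved_under_zero_padding(self):
        rng = np.random.default_rng(2)
        img = np.zeros((24, 24, 24))
        img[6:18, 6:18, 6:18] = rng.uniform(0, 2, size=(12, 12, 12))
        out = smooth_to_fwhm(StatImage(img, _affine(2.0)), 6.0, 0.0)
        assert out.data.sum() == pytest.approx(img.sum(), rel=1e-6)

    def test_variance_additivity_of_sequential_passes(self):
        """Smoothing at f1 then f2 equals one pass at sqrt(f1^2+f2^2).

        Checked on an interior-supported random image: with zero padding the
        identity holds away from the volume boundary (cropping the
        intermediate image discards kernel tails at the very edge).
        """
        rng = np.random.default_rng(3)
        data = np.zeros((40, 40, 40))
        data[12:28, 12:28, 12:28] = rng.standard_normal((16, 16, 16))
        img = StatImage(data, _affine(2.0))
        two_pass = smooth_to_fwhm(smooth_to_fwhm(img, 5.0, 0.0), np.hypot(5.0, 6.0), 5.0)
        one_pass = smooth_to_fwhm(img, np.hypot(5.0, 6.0), 0.0)
        rms = np.sqrt(np.mean((two_pass.data - one_pass.data) ** 2))
        assert rms < 1e-6


def _two_cube_phantom():
    labels = np.zeros((32, 32, 32), dtype=np.int32)
    labels[6:14, 6:14, 6:14] = 1
    labels[18:26, 18:26, 18:26] = 2
    return LabelMap(labels, _affine(2.0))


class TestGtmRbv:
    def test_zero_psf_returns_observed_means(self):
        lm = _two_cube_phantom()
        rng = np.random.default_rng(4)
        img = StatImage(rng.uniform(1, 3, size=lm.data.shape), lm.affine)
        m = gtm_means(img, lm, psf_fwhm_mm=0.0)
        for label in (1, 2):
            assert m.loc[label] == pytest.approx(img.data[lm.data == label].mean())

    def test_blur_roundtrip_recovers_true_means(self):
        lm = _two_cube_phantom()
        truth = {1: 4.0, 2: 1.0}
        img = np.zeros(lm.data.shape)
        for label, val in truth.items():
            img[lm.data == label] = val
        blurred = smooth_to_fwhm(StatImage(img, lm.affine), 8.0, 0.0)
        m = gtm_means(blurred, lm, psf_fwhm_mm=8.0)
        for label, val in truth.items():
            assert m.loc[label] == pytest.approx(val, rel=0.02)

    def test_transfer_matrix_rows_sum_to_one_when_tiling(self):
        labels = np.zeros((16, 16, 16), dtype=np.int32)
        labels[:8] = 1
        labels[8:] = 2
        lm = LabelMap(labels, _affine(2.0))
        img = StatImage(np.ones(lm.data.shape), lm.affine)
        # access the matrix through its effect: a uniform tiled image is a
        # fixed point, so the recovered means equal the observed value
        m = gtm_means(img, lm, psf_fwhm_mm=8.0)
        assert np.allclose(m.to_numpy(), 1.0, atol=1e-10)

    def test_indistinguishable_regions_raise_with_condition_number(self):
        labels = np.zeros((12, 12, 12), dtype=np.int32)
        labels[::2, 0, 0] = 1
        labels[1::2, 0, 0] = 2
        lm = LabelMap(labels, _affine(2.0))
        img = StatImage(np.ones(lm.data.shape), lm.affine)
        with pytest.raises(ValueError, match="condition"):
            gtm_means(img, lm, psf_fwhm_mm=80.0, cond_limit=100.0)

    def test_rbv_zero_psf_is_identity(self):
        lm = _two_cube_phantom()
        rng = np.random.default_rng(5)
        img = StatImage(rng.uniform(1, 2, size=lm.data.shape), lm.affine)
        res = rbv_correct(img, lm, psf_fwhm_mm=0.0)
        assert np.allclose(res.image.data, img.data)
        assert res.n_floored == 0

    def test_rbv_uniform_image_is_fixed_point(self):
        """A uniform image over a volume-tiling label map is left unchanged.

        (GTM assumes zero activity outside labelled regions, so the tiling
        map is the setting where a globally uniform image is model-consistent.)
        """
        labels = np.ones((16, 16, 16), dtype=np.int32)
        labels[8:] = 2
        lm = LabelMap(labels, _affine(2.0))
        img = StatImage(np.full(lm.data.shape, 2.5), lm.affine)
        res = rbv_correct(img, lm, psf_fwhm_mm=8.0)
        assert np.allclose(res.image.data, 2.5, rtol=1e-6)

    def test_rbv_corrects_blurred_phantom_within_three_percent(self):
        lm = _two_cube_phantom()
        truth = {1: 4.0, 2: 1.0}
        img = np.zeros(lm.data.shape)
        for label, val in truth.items():
            img[lm.data == label] = val
        blurred = smooth_to_fwhm(StatImage(img, lm.affine), 8.0, 0.0)
        res = rbv_correct(blurred, lm, psf_fwhm_mm=8.0)
        for label, val in truth.items():
            got = res.image.data[lm.data == label].mean()
            assert got == pytest.approx(val, rel=0.03)


class TestRoiExtract:
    def test_constant_region(self, three_region_map):
        img = np.zeros(three_region_map.data.shape)
        img[three_region_map.data == 1] = 7.0
        table = roi_extract(
            StatImage(img, three_region_map.affine), three_region_map, {"t": 1}
        )
        row = table.iloc[0]
        assert row["mean"] == 7.0 and row["sd"] == 0.0 and row["n_voxels"] == 216

    def test_checker_pattern_mean(self):
        labels = np.ones((8, 8, 8), dtype=np.int32)
        lm = LabelMap(labels, _affine())
        img = np.indices((8, 8, 8)).sum(axis=0) % 2 * 2.0
        table = roi_extract(StatImage(img, lm.affine), lm, {"all": 1})
        assert table.iloc[0]["mean"] == pytest.approx(1.0)

    def test_matches_bruteforce_with_missing_values(self, three_region_map):
        rng = np.random.default_rng(6)
        img = rng.standard_normal(three_region_map.data.shape)
        img[3, 3, 3] = np.nan     # inside region 1
        stat = StatImage(img, three_region_map.affine)
        table = roi_extract(stat, three_region_map, {"a": 1})
        m = (three_region_map.data == 1) & np.isfinite(img)
        assert table.iloc[0]["mean"] == pytest.approx(img[m].mean())
        assert table.iloc[0]["n_voxels"] == int(m.sum())

    def test_unknown_label_rejected(self, three_region_map):
        img = StatImage(np.zeros(three_region_map.data.shape), three_region_map.affine)
        with pytest.raises(ValueError, match="ghost"):
            roi_extract(img, three_region_map, {"ghost": 42})


class TestZscoreMap:
    def _norm(self, shape=(10, 10, 10)):
        aff = _affine()
        mean = StatImage(np.full(shape, 1.2), aff)
        sd = StatImage(np.full(shape, 0.1), aff)
        return mean, sd

    def test_image_at_mean_is_zero(self):
        mean, sd = self._norm()
        z, n_bad = zscore_map(StatImage(np.full((10, 10, 10), 1.2), mean.affine), mean, sd)
        assert np.allclose(z.data, 0.0)
        assert n_bad == 0

    def test_two_sd_above_reads_two(self):
        mean, sd = self._norm()
        img = StatImage(np.full((10, 10, 10), 1.4), mean.affine)
        z, _ = zscore_map(img, mean, sd)
        assert np.allclose(z.data, 2.0)

    def test_zero_sd_voxels_flagged_and_counted(self):
        mean, sd = self._norm()
        sd.data[0, 0, 0] = 0.0
        img = StatImage(np.full((10, 10, 10), 1.3), mean.affine)
        z, n_bad = zscore_map(img, mean, sd)
        assert n_bad == 1
        assert np.isnan(z.data[0, 0, 0])
        assert not z.mask[0, 0, 0]

    def test_resubstitution_of_normative_sample(self):
        """z-scoring the normative subjects gives mean ~0, SD ~1 per voxel."""
        rng = np.random.default_rng(8)
        aff = _affine()
        sample = rng.normal(1.0, 0.2, size=(30, 6, 6, 6))
        mean = StatImage(sample.mean(axis=0), aff)
        sd = StatImage(sample.std(axis=0, ddof=1), aff)
        zs = np.stack(
            [zscore_map(StatImage(s, aff), mean, sd)[0].data for s in sample]
        )
        assert np.allclose(zs.mean(axis=0), 0.0, atol=1e-10)
        assert np.allclose(zs.std(axis=0, ddof=1), 1.0, atol=1e-10)
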