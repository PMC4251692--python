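"""Enhancement operators: percentile stretch, DoG, Laplacian, ROI, pipeline."""

import numpy as np
import pytest

from veinviz.camera import CameraSettings
from veinviz.enhance import (
    LAPLACIAN_KERNEL,
    EnhanceConfig,
    apply_roi,
    contrast_enhance,
    difference_of_gaussians,
    dog_response,
    laplacian,
    log_response,
    process_frame,
    process_stream,
)
from veinviz.image import NIRImage
from veinviz.phantom import PhantomSpec, render_phantom

from conftest import straight_vein


def _img(arr, pitch=0.1):
    return NIRImage(np.asarray(arr, dtype=float), pixel_pitch=pitch)


def _impulse(n, pitch=0.1):
    px = np.zeros((n, n))
    px[n // 2, n // 2] = 1.0
    return _img(px, pitch)


def _gauss_kernel_1d(sigma_px: float) -> np.ndarray:
    """Sampled, truncated, normalized Gaussian — the independent oracle."""
    radius = int(4.0 * sigma_px + 0.5)
    x = np.arange(-radius, radius + 1, dtype=float)
    k = np.exp(-0.5 * (x / sigma_px) ** 2)
    return k / k.sum()


def _embed(kernel: np.ndarray, n: int) -> np.ndarray:
    out = np.zeros((n, n))
    r = kernel.shape[0] // 2
    c = n // 2
    out[c - r:c + r + 1, c - r:c + r + 1] = kernel
    return out


class TestContrastEnhance:
    def test_constant_frame_unchanged(self):
        img = _img(np.full((16, 16), 0.4))
        out = contrast_enhance(img, (1, 99))
        np.testing.assert_array_equal(out.pixels, img.pixels)

    def test_two_level_frame_maps_to_full_range(self):
        px = np.where(np.arange(256).reshape(16, 16) % 2 == 0, 0.4, 0.6)
        out = contrast_enhance(_img(px), (0, 100)).pixels
        assert set(np.unique(out)) == {0.0, 1.0}

    def test_ramp_percentiles_land_on_bounds(self):
        """After a (1, 99) stretch of a linear ramp, the output's own 1st
        and 99th percentiles are 0 and 1 within 1/255."""
        ramp = np.tile(np.linspace(0, 1, 100), (100, 1))
        out = contrast_enhance(_img(ramp), (1, 99)).pixels
        lo, hi = np.percentile(out, [1, 99])
        assert lo == pytest.approx(0.0, abs=1 / 255)
        assert hi == pytest.approx(1.0, abs=1 / 255)

    def test_bad_percentile_order_rejected(self, ramp_image):
        with pytest.raises(ValueError):
            contrast_enhance(ramp_image, (50, 50))


class TestDifferenceOfGaussians:
    def test_constant_frame_is_neutral(self):
        out = difference_of_gaussians(_img(np.full((32, 32), 0.7)), 0.4, 2.0)
        np.testing.assert_array_equal(out.pixels, 0.5)

    def test_impulse_response_equals_kernel_difference(self):
        """Impulse response matches a directly evaluated G(sn) - G(sw)
        kernel grid to 1e-6."""
        sn_mm, sw_mm, pitch, n = 0.2, 0.5, 0.1, 81
        resp = dog_response(_impulse(n, pitch), sn_mm, sw_mm)
        kn = _gauss_kernel_1d(sn_mm / pitch)
        kw = _gauss_kernel_1d(sw_mm / pitch)
        expected = _embed(np.outer(kn, kn), n) - _embed(np.outer(kw, kw), n)
        np.testing.assert_allclose(resp, expected, atol=1e-6)

    def test_linearity_of_signed_response(self):
        rng = np.random.default_rng(0)
        px = rng.uniform(0.0, 0.4, (32, 32))
        r1 = dog_response(_img(px), 0.3, 1.0)
        r2 = dog_response(_img(2 * px), 0.3, 1.0)
        np.testing.assert_allclose(r2, 2 * r1, atol=1e-12)

    def test_sigma_ordering_enforced(self):
        with pytest.raises(ValueError):
            dog_response(_impulse(32), 2.0, 0.4)


class TestLaplacian:
    def test_planar_ramp_annihilated_in_interior(self):
        r, c = np.meshgrid(np.arange(32.0), np.arange(32.0), indexing="ij")
        px = (0.3 * r + 0.5 * c) / 50.0
        resp = log_response(_img(px), 0.0)
        np.testing.assert_allclose(resp[1:-1, 1:-1], 0.0, atol=1e-12)

    def test_impulse_gives_four_neighbor_kernel(self):
        resp = log_response(_impulse(9), 0.0)
        center = resp[3:6, 3:6]
        np.testing.assert_allclose(center, LAPLACIAN_KERNEL, atol=1e-12)
        assert resp[0, 0] == 0.0

    def test_impulse_log_matches_direct_evaluation(self):
        """LoG impulse response equals an independently assembled
        smooth-then-Laplacian kernel grid to 1e-6."""
        sigma_mm, pitch, n = 1.0, 0.1, 101
        resp = log_response(_impulse(n, pitch), sigma_mm)
        k = _gauss_kernel_1d(sigma_mm / pitch)
        g2d = _embed(np.outer(k, k), n)
        expected = np.zeros_like(g2d)
        # manual 4-neighbour convolution, independent of scipy
        expected[1:-1, 1:-1] = (
            g2d[:-2, 1:-1] + g2d[2:, 1:-1] + g2d[1:-1, :-2] + g2d[1:-1, 2:]
            - 4 * g2d[1:-1, 1:-1]
        )
        np.testing.assert_allclose(resp[1:-1, 1:-1], expected[1:-1, 1:-1], atol=1e-6)

    def test_negative_sigma_rejected(self):
        with pytest.raises(ValueError):
            log_response(_impulse(16), -0.5)


class TestRoi:
    def test_full_frame_roi_equals_global(self, ramp_image):
        stage = lambda im: difference_of_gaussians(im, 0.4, 2.0)
        full = apply_roi(ramp_image, (0, 0, 100, 100), stage)
        glob = stage(ramp_image)
        np.testing.assert_array_equal(full.pixels, glob.pixels)

    def test_outside_pixels_bit_identical(self):
        rng = np.random.default_rng(1)
        img = _img(rng.uniform(0, 1, (128, 128)))
        roi = (40, 50, 72, 82)
        out = apply_roi(img, roi, lambda im: laplacian(im, 0.5))
        mask = np.ones((128, 128), dtype=bool)
        mask[roi[0]:roi[2], roi[1]:roi[3]] = False
        np.testing.assert_array_equal(out.pixels[mask], img.pixels[mask])

    def test_inside_matches_crop_process_paste(self):
        rng = np.random.default_rng(2)
        img = _img(rng.uniform(0, 1, (128, 128)))
        roi = (40, 50, 72, 82)
        stage = lambda im: difference_of_gaussians(im, 0.3, 1.0)
        out = apply_roi(img, roi, stage)
        # independent route: crop as a standalone frame, process, paste
        crop = NIRImage(img.pixels[40:72, 50:82].copy(), pixel_pitch=0.1)
        pasted = img.pixels.copy()
        pasted[40:72, 50:82] = stage(crop).pixels
        np.testing.assert_array_equal(out.pixels, pasted)

    def test_roi_outside_bounds_rejected(self, ramp_image):
        with pytest.raises(ValueError):
            apply_roi(ramp_image, (0, 0, 101, 50), lambda im: im)


class TestProcessFrame:
    def test_raw_contrast_mode_equals_stretch_alone(self, ramp_image):
        cfg = EnhanceConfig(mode="raw-contrast", stretch_percentiles=(1, 99))
        out = process_frame(ramp_image, CameraSettings(), cfg)
        expected = contrast_enhance(ramp_image, (1, 99))
        np.testing.assert_array_equal(out.pixels, expected.pixels)

    def test_identity_on_full_range_frame(self, ramp_image):
        cfg = EnhanceConfig(mode="none", stretch_percentiles=(0, 100))
        out = process_frame(ramp_image, CameraSettings(), cfg)
        np.testing.assert_allclose(out.pixels, ramp_image.pixels, atol=1e-12)

    def test_vein_centerline_is_perpendicular_minimum(self):
        """Along every cross-vein profile the dog1 response is minimal at
        the true centerline row (noise off, brute-force scan)."""
        from veinviz.phantom import VeinSegment

        spec = PhantomSpec(noise_sigma=0.0)
        # centerline on an exact pixel row so the minimum is untied
        vein = VeinSegment(np.array([[12.8, 2.0], [12.8, 36.3]]), 1.0, 2.0)
        out = render_phantom(spec, [vein])
        resp = process_frame(
            out.image, CameraSettings(), EnhanceConfig.for_mode("dog1")
        ).pixels
        r_c = 128
        for col in range(40, 344, 8):
            window = resp[r_c - 15:r_c + 16, col]
            assert int(window.argmin()) == 15, col

    def test_deterministic(self, single_vein_phantom):
        cfg = EnhanceConfig.for_mode("dog2")
        a = process_frame(single_vein_phantom.image, CameraSettings(), cfg)
        b = process_frame(single_vein_phantom.image, CameraSettings(), cfg)
        np.testing.assert_array_equal(a.pixels, b.pixels)

    @pytest.mark.parametrize("mode", ["raw-contrast", "dog1", "dog2", "log1", "log2"])
    def test_preserves_shape_and_range(self, mode, single_vein_phantom):
        out = process_frame(
            single_vein_phantom.image, CameraSettings(), EnhanceConfig.for_mode(mode)
        )
        assert out.shape == single_vein_phantom.image.shape
        assert out.pixels.min() >= 0.0 and out.pixels.max() <= 1.0


class TestProcessStream:
    def test_singleton_equals_process_frame(self, ramp_image):
        cfg = EnhanceConfig.for_mode("log1")
        outs, report = process_stream([ramp_image], CameraSettings(), cfg)
        single = process_frame(ramp_image, CameraSettings(), cfg)
        assert report.frame_count == 1
        np.testing.assert_array_equal(outs[0].pixels, single.pixels)

    def test_stateless_across_identical_frames(self, ramp_image):
        outs, report = process_stream(
            [ramp_image] * 3, CameraSettings(), EnhanceConfig.for_mode("dog1")
        )
        assert report.frame_count == 3
        for o in outs[1:]:
            np.testing.assert_array_equal(o.pixels, outs[0].pixels)

    def test_frame_count_reported(self, default_spec):
        rng = np.random.default_rng(0)
        frames = [
            NIRImage(rng.uniform(0, 1, (16, 16)), pixel_pitch=0.1) for _ in range(10)
        ]
        _, report = process_stream(
            frames, CameraSettings(), EnhanceConfig.for_mode("dog1")
        )
        assert report.frame_count == 10
        assert report.frames_per_second > 0

    def test_empty_stream_rejected(self):
        with pytest.raises(ValueError):
            process_stream([], CameraSettings(), EnhanceConfig())
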