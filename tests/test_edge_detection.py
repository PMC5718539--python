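"""Unit and property tests for the five-stage Canny detector."""

import numpy as np
import pytest

from epidiso.edge_detection import (
    DIR_HORIZONTAL,
    DIR_MINUS_45,
    DIR_PLUS_45,
    CannyConfig,
    EdgeDetectionError,
    canny,
    gaussian_blur,
    hysteresis,
    non_max_suppression,
    sobel_gradient,
)


class TestGaussianBlur:
    def test_constant_image_unchanged(self):
        img = np.full((20, 20), 7.0)
        np.testing.assert_allclose(gaussian_blur(img, 2.0), img, atol=1e-12)

    def test_impulse_reproduces_gaussian_kernel(self):
        # independent oracle: direct evaluation of the normalised Gaussian
        sigma = 1.0
        n = 17
        img = np.zeros((n, n))
        img[n // 2, n // 2] = 1.0
        out = gaussian_blur(img, sigma)
        r = int(np.ceil(4 * sigma))
        x = np.arange(-r, r + 1)
        k = np.exp(-0.5 * (x / sigma) ** 2)
        k /= k.sum()
        expected = np.outer(k, k)
        center = out[n // 2 - r : n // 2 + r + 1, n // 2 - r : n // 2 + r + 1]
        np.testing.assert_allclose(center, expected, atol=1e-12)

    def test_total_intensity_preserved_for_interior_content(self):
        img = np.zeros((40, 40))
        img[15:25, 15:25] = 3.0
        out = gaussian_blur(img, 1.5)
        assert abs(out.sum() - img.sum()) / img.sum() < 0.01

    def test_step_profile_stays_monotone(self):
        img = np.tile((np.arange(30) >= 15).astype(float), (10, 1))
        out = gaussian_blur(img, 2.0)
        assert np.all(np.diff(out[5]) >= -1e-12)

    def test_rejects_non_finite(self):
        img = np.ones((10, 10))
        img[3, 3] = np.nan
        with pytest.raises(EdgeDetectionError):
            gaussian_blur(img, 1.0)


class TestSobel:
    def test_vertical_step_gives_horizontal_gradient(self):
        img = np.tile((np.arange(20) >= 10).astype(float), (20, 1))
        mag, direction = sobel_gradient(img)
        row = 10
        peak_col = int(np.argmax(mag[row]))
        assert peak_col in (9, 10)
        assert direction[row, peak_col] == DIR_HORIZONTAL

    def test_diagonal_ramp_gives_45_category(self):
        i, j = np.mgrid[0:20, 0:20]
        mag, direction = sobel_gradient((i + j).astype(float))
        assert direction[10, 10] == DIR_PLUS_45
        mag, direction = sobel_gradient((i - j).astype(float))
        assert direction[10, 10] == DIR_MINUS_45

    def test_flat_image_zero_magnitude(self):
        mag, _ = sobel_gradient(np.full((15, 15), 4.2))
        np.testing.assert_allclose(mag, 0.0, atol=1e-12)

    def test_too_small_image_rejected(self):
        with pytest.raises(EdgeDetectionError):
            sobel_gradient(np.ones((2, 5)))


class TestNonMaxSuppression:
    def test_ridge_keeps_single_peak(self):
        mag = np.zeros((5, 5))
        mag[:, 1:4] = [1.0, 3.0, 1.0]
        direction = np.full((5, 5), DIR_HORIZONTAL, dtype=np.int8)
        out = non_max_suppression(mag, direction)
        np.testing.assert_allclose(out[2], [0, 0, 3, 0, 0])

    def test_plateau_tie_keeps_smaller_index(self):
        # both tie-break choices enumerated: [0,3,3,0] can keep index 1 or 2;
        # the configured rule keeps the smaller index along the scan direction
        mag = np.zeros((5, 6))
        mag[:, 2:4] = 3.0
        direction = np.full((5, 6), DIR_HORIZONTAL, dtype=np.int8)
        out = non_max_suppression(mag, direction)
        assert out[2, 2] == 3.0 and out[2, 3] == 0.0
        assert (out[2] > 0).sum() == 1

    def test_zero_field_unchanged(self):
        mag = np.zeros((8, 8))
        out = non_max_suppression(mag, np.zeros((8, 8), dtype=np.int8))
        np.testing.assert_array_equal(out, mag)


class TestHysteresis:
    def _cfg(self, high=2.0, low=None):
        return CannyConfig(threshold_high=high, threshold_low=low)

    def test_weak_chain_connected_to_strong_kept(self):
        mag = np.zeros((5, 7))
        mag[2, 1:6] = [1.0, 1.0, 3.0, 1.0, 1.0]
        em = hysteresis(mag, self._cfg(high=2.0, low=0.5))
        assert em.edges[2, 1:6].all()

    def test_isolated_weak_pixel_removed(self):
        mag = np.zeros((5, 5))
        mag[2, 2] = 1.0
        em = hysteresis(mag, self._cfg(high=2.0, low=0.5))
        assert not em.edges.any()

    def test_all_below_low_empty(self):
        em = hysteresis(np.full((6, 6), 0.1), self._cfg(high=2.0, low=0.5))
        assert not em.edges.any()

    def test_inverted_thresholds_rejected(self):
        with pytest.raises(EdgeDetectionError):
            CannyConfig(threshold_high=0.1, threshold_low=0.5)


def _erf_step(n=60, x0=29.3, sigma=2.0):
    from scipy.special import ndtr

    x = np.arange(n, dtype=float)
    return np.tile(ndtr((x - x0) / sigma), (n, 1))


class TestCanny:
    def test_synthetic_field_edges_near_truth(self, view_zero, edges_zero):
        """Detected jaw-edge pixels lie within 1 px of the rendered edges."""
        img = view_zero
        mag = img.sid_mm / img.sad_mm
        pitch = img.pixel_spacing_mm[1]
        n = img.pixels.shape[1]
        center = (n - 1) / 2.0
        edge_cols = [center + s * 50.0 * mag / pitch for s in (-1, +1)]
        rows = slice(n // 2 - 40, n // 2 + 40)
        for col in edge_cols:
            window = edges_zero.edges[rows, int(round(col)) - 1 : int(round(col)) + 2]
            assert window.any(axis=1).mean() > 0.9

    def test_raising_threshold_never_adds_edges(self, view_zero, edges_zero):
        base = CannyConfig()
        px = view_zero.pixels / np.percentile(view_zero.pixels, 99)
        doubled = canny(px, CannyConfig(threshold_high=2 * base.threshold_high))
        assert doubled.edges.sum() <= edges_zero.edges.sum()

    def test_raising_sigma_never_adds_edges(self, view_zero, edges_zero):
        base = CannyConfig()
        px = view_zero.pixels / np.percentile(view_zero.pixels, 99)
        blurrier = canny(px, CannyConfig(gaussian_sigma=2 * base.gaussian_sigma))
        assert blurrier.edges.sum() <= edges_zero.edges.sum()

    def test_deterministic(self, view_ap):
        px = view_ap.pixels
        a = canny(px, CannyConfig())
        b = canny(px, CannyConfig())
        np.testing.assert_array_equal(a.edges, b.edges)
        np.testing.assert_array_equal(a.gradient_direction, b.gradient_direction)

    @pytest.mark.parametrize("seed", range(20))
    def test_threshold_monotonicity_on_random_images(self, seed):
        rng = np.random.default_rng(seed)
        img = gaussian_blur(rng.normal(size=(48, 48)), 1.5)
        lo = canny(img, CannyConfig(threshold_high=0.02, gaussian_sigma=1.0))
        hi = canny(img, CannyConfig(threshold_high=0.04, gaussian_sigma=1.0))
        assert hi.edges.sum() <= lo.edges.sum()

    def test_step_edge_pixel_contains_half_crossing(self):
        """On a noise-free step, the kept pixel straddles the 50% crossing."""
        x0 = 29.3
        em = canny(_erf_step(x0=x0), CannyConfig(threshold_high=0.05, gaussian_sigma=1.5))
        cols = np.flatnonzero(em.edges[30])
        assert len(cols) == 1
        assert abs(cols[0] - x0) <= 1.0

    def test_single_pixel_wide_edges(self, view_zero, edges_zero):
        """At most one edge pixel per row across each vertical jaw edge."""
        edges = edges_zero.edges
        img = view_zero
        n = edges.shape[0]
        mag = img.sid_mm / img.sad_mm
        pitch = img.pixel_spacing_mm[1]
        col = int(round((n - 1) / 2.0 - 50.0 * mag / pitch))  # left jaw edge
        band = edges[n // 2 - 30 : n // 2 + 30, col - 5 : col + 6]
        assert band.sum(axis=1).max() <= 1

    def test_agrees_with_reference_implementation(self, view_zero):
        """Independent cross-check against scikit-image's Canny."""
        from skimage import feature

        px = view_zero.pixels / np.percentile(view_zero.pixels, 99)
        ours = canny(px, CannyConfig())
        theirs = feature.canny(px, sigma=2.0, low_threshold=0.048 / 8, high_threshold=0.12 / 8)
        # every one of our edge pixels has a reference edge within 2 px
        from scipy import ndimage

        dilated = ndimage.binary_dilation(theirs, iterations=2)
        overlap = (ours.edges & dilated).sum() / ours.edges.sum()
        assert overlap > 0.95
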