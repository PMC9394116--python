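"""Calibration, wavelet denoising, ROI averaging, truncation, normalization."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from spectrafuse.preprocessing import (
    BandWindow,
    CalibrationSet,
    DegenerateCurveError,
    DegenerateReferenceError,
    ROISet,
    WaveletSpec,
    calibrate,
    denoise_curve,
    max_normalize,
    roi_mean_curve,
    truncate_bands,
)


class TestCalibrate:
    def setup_method(self):
        rng = np.random.default_rng(0)
        self.black = rng.uniform(0.0, 0.1, size=(4, 5))
        self.white = self.black + rng.uniform(0.5, 1.0, size=(4, 5))

    def test_white_gives_one(self):
        out = calibrate(CalibrationSet(self.white, self.black, self.white))
        np.testing.assert_allclose(out, 1.0)

    def test_black_gives_zero(self):
        out = calibrate(CalibrationSet(self.black, self.black, self.white))
        np.testing.assert_allclose(out, 0.0)

    def test_midpoint_gives_half(self):
        mid = (self.black + self.white) / 2
        out = calibrate(CalibrationSet(mid, self.black, self.white))
        np.testing.assert_allclose(out, 0.5)

    def test_degenerate_reference_rejected(self):
        with pytest.raises(DegenerateReferenceError):
            calibrate(CalibrationSet(self.white, self.black, self.black))

    @given(a=st.floats(0.0, 1.0))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_affine_in_raw(self, a):
        rng = np.random.default_rng(1)
        r1 = rng.uniform(size=(3, 4))
        r2 = rng.uniform(size=(3, 4))
        black = np.zeros((3, 4))
        white = np.ones((3, 4))
        mix = calibrate(CalibrationSet(a * r1 + (1 - a) * r2, black, white))
        c1 = calibrate(CalibrationSet(r1, black, white))
        c2 = calibrate(CalibrationSet(r2, black, white))
        np.testing.assert_allclose(mix, a * c1 + (1 - a) * c2, atol=1e-12)


class TestDenoiseCurve:
    def test_constant_signal_unchanged(self):
        x = np.full(396, 3.7)
        np.testing.assert_allclose(denoise_curve(x), x, atol=1e-10)

    @pytest.mark.parametrize("n", [286, 396])
    def test_length_preserved(self, n):
        rng = np.random.default_rng(0)
        out = denoise_curve(rng.normal(size=n))
        assert out.shape == (n,)

    def test_cubic_polynomial_reproduced_interior(self):
        # Daubechies-8 annihilates low-order polynomials; boundary
        # extension can perturb the edges, so assert on the interior.
        t = np.linspace(-1, 1, 396)
        x = 0.3 + 0.5 * t - 1.2 * t**2 + 0.7 * t**3
        out = denoise_curve(x)
        interior = slice(40, -40)
        np.testing.assert_allclose(out[interior], x[interior], atol=1e-6)

    def test_monte_carlo_noise_reduction(self):
        """Denoising reduces RMSE to the clean signal on average
        (smooth sine + Gaussian noise sd 0.05, 100 repetitions)."""
        t = np.linspace(0, 4 * np.pi, 396)
        clean = np.sin(t)
        rng = np.random.default_rng(1234)
        rmse_noisy, rmse_den = [], []
        for _ in range(100):
            noisy = clean + rng.normal(0.0, 0.05, size=clean.size)
            den = denoise_curve(noisy)
            rmse_noisy.append(np.sqrt(np.mean((noisy - clean) ** 2)))
            rmse_den.append(np.sqrt(np.mean((den - clean) ** 2)))
        assert np.mean(rmse_den) < np.mean(rmse_noisy)

    def test_empty_signal_rejected(self):
        with pytest.raises(ValueError):
            denoise_curve(np.array([]))

    def test_hard_threshold_mode_runs(self):
        x = np.sin(np.linspace(0, 6, 300)) + 0.01 * np.random.default_rng(0).normal(size=300)
        out = denoise_curve(x, WaveletSpec(threshold_mode="hard"))
        assert out.shape == x.shape


class TestRoiMeanCurve:
    def _roiset(self, cube):
        leaf = np.zeros(cube.shape[:2], dtype=bool)
        stem = np.zeros(cube.shape[:2], dtype=bool)
        leaf[0, 0] = True
        stem[1, 1] = True
        return ROISet(cube=cube, leaf_mask=leaf, stem_mask=stem)

    def test_single_pixel_identity(self, rng):
        cube = rng.uniform(size=(3, 3, 20))
        rs = self._roiset(cube)
        np.testing.assert_array_equal(roi_mean_curve(rs, "leaf"), cube[0, 0])

    def test_two_pixel_average(self, rng):
        cube = rng.uniform(size=(2, 2, 10))
        leaf = np.array([[True, True], [False, False]])
        rs = ROISet(cube=cube, leaf_mask=leaf, stem_mask=leaf)
        np.testing.assert_allclose(
            roi_mean_curve(rs, "leaf"), (cube[0, 0] + cube[0, 1]) / 2
        )

    def test_constant_cube_with_denoising(self):
        cube = np.full((2, 2, 300), 2.5)
        mask = np.ones((2, 2), dtype=bool)
        rs = ROISet(cube=cube, leaf_mask=mask, stem_mask=mask)
        np.testing.assert_allclose(
            roi_mean_curve(rs, "leaf", WaveletSpec()), np.full(300, 2.5), atol=1e-10
        )

    def test_fast_path_denoises_the_mean(self, rng):
        # average-then-denoise equals denoise_curve applied to the ROI mean
        cube = rng.uniform(size=(3, 3, 300))
        mask = np.ones((3, 3), dtype=bool)
        rs = ROISet(cube=cube, leaf_mask=mask, stem_mask=mask)
        spec = WaveletSpec()
        fast = roi_mean_curve(rs, "leaf", spec, pixelwise=False)
        np.testing.assert_allclose(
            fast, denoise_curve(roi_mean_curve(rs, "leaf"), spec)
        )

    def test_empty_mask_rejected(self, rng):
        cube = rng.uniform(size=(2, 2, 5))
        empty = np.zeros((2, 2), dtype=bool)
        some = np.ones((2, 2), dtype=bool)
        rs = ROISet(cube=cube, leaf_mask=empty, stem_mask=some)
        with pytest.raises(ValueError):
            roi_mean_curve(rs, "leaf")

    def test_mask_split_commutes_with_averaging(self, rng):
        cube = rng.uniform(size=(4, 4, 8))
        full = np.ones((4, 4), dtype=bool)
        top = np.zeros_like(full); top[:2] = True
        bottom = ~top
        rs_full = ROISet(cube=cube, leaf_mask=full, stem_mask=full)
        rs_top = ROISet(cube=cube, leaf_mask=top, stem_mask=top)
        rs_bot = ROISet(cube=cube, leaf_mask=bottom, stem_mask=bottom)
        weighted = (
            top.sum() * roi_mean_curve(rs_top, "leaf")
            + bottom.sum() * roi_mean_curve(rs_bot, "leaf")
        ) / full.sum()
        np.testing.assert_allclose(roi_mean_curve(rs_full, "leaf"), weighted)


class TestTruncateBands:
    def test_integer_grid_count(self):
        wl = np.arange(380.0, 1031.0)
        curve = np.zeros(wl.size)
        out = truncate_bands(curve, BandWindow(wavelengths=wl))
        assert out.size == 504  # integers in [454, 957]

    def test_window_spanning_all_is_identity(self, rng):
        wl = np.linspace(400, 900, 50)
        curve = rng.uniform(size=50)
        out = truncate_bands(curve, BandWindow(wavelengths=wl, low=399, high=901))
        np.testing.assert_array_equal(out, curve)

    def test_boundary_inclusion(self):
        wl = np.array([450.0, 500.0, 550.0])
        curve = np.array([1.0, 2.0, 3.0])
        out = truncate_bands(curve, BandWindow(wavelengths=wl, low=500, high=500.5))
        np.testing.assert_array_equal(out, [2.0])

    def test_empty_window_rejected(self):
        wl = np.array([450.0, 500.0])
        with pytest.raises(ValueError):
            truncate_bands(np.zeros(2), BandWindow(wavelengths=wl, low=460, high=470))


class TestMaxNormalize:
    def test_example(self):
        np.testing.assert_allclose(
            max_normalize(np.array([2.0, 4.0, 8.0])), [0.25, 0.5, 1.0]
        )

    def test_constant_positive_gives_ones(self):
        np.testing.assert_allclose(max_normalize(np.full(7, 3.0)), np.ones(7))

    def test_idempotent(self, rng):
        x = rng.uniform(0.1, 2.0, size=30)
        once = max_normalize(x)
        np.testing.assert_allclose(max_normalize(once), once)

    @given(k=st.floats(1e-3, 1e3))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_scale_invariance(self, k):
        x = np.array([0.1, 0.7, 0.3, 1.9])
        np.testing.assert_allclose(max_normalize(k * x), max_normalize(x), rtol=1e-10)

    def test_nonpositive_rejected(self):
        with pytest.raises(DegenerateCurveError):
            max_normalize(np.array([-1.0, 0.0]))
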