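import numpy as np
import pytest
from scipy.special import j1

from pulmoct.geometry import ImageVolume
from pulmoct.imaging import PSFModel, add_noise, simulate_wire_acquisition
from pulmoct.mtf import (
    MTFCurve,
    MTFOptions,
    RadialProfile,
    average_slices,
    default_frequency_grid_lp_cm,
    estimate_mtf,
    estimate_wire_center,
    hankel_mtf,
    mtf_cutoff,
    normalize_mtf,
    radial_profile,
    subtract_background,
    wire_correction,
)

SP = (0.13, 0.13)


def gaussian_image(sigma, n=161, center=None):
    if center is None:
        center = ((n - 1) / 2 * SP[0], (n - 1) / 2 * SP[1])
    x = np.arange(n) * SP[0] - center[0]
    y = np.arange(n) * SP[1] - center[1]
    return np.exp(-(x[:, None] ** 2 + y[None, :] ** 2) / (2 * sigma**2)), center


class TestAverageSlices:
    def test_identical_slices_average_to_one_slice(self, rng):
        plane = rng.normal(size=(8, 8))
        vol = ImageVolume(np.repeat(plane[:, :, None], 5, axis=2), (1, 1, 1))
        np.testing.assert_allclose(average_slices(vol), plane)

    def test_noise_reduced_by_sqrt_n(self, rng):
        n = 16
        vol = ImageVolume(rng.normal(0, 10, (50, 50, n)), (1, 1, 1))
        averaged = average_slices(vol)
        assert averaged.std() == pytest.approx(10 / np.sqrt(n), rel=0.15)


class TestWireCenter:
    @pytest.mark.parametrize("offset", [(0.0, 0.0), (0.044, -0.031)])
    def test_subpixel_accuracy(self, offset):
        true = (80 * SP[0] + offset[0], 80 * SP[1] + offset[1])
        img, _ = gaussian_image(0.25, center=true)
        cx, cy = estimate_wire_center(img, SP, refine_window_mm=2.0)
        assert np.hypot(cx - true[0], cy - true[1]) < 0.1 * SP[0]

    def test_uniform_image_rejected(self):
        with pytest.raises(ValueError, match="no wire found"):
            estimate_wire_center(np.zeros((20, 20)), SP)

    def test_invariant_to_constant_background(self):
        img, center = gaussian_image(0.25)
        a = estimate_wire_center(img, SP)
        b = estimate_wire_center(img + 500.0, SP)
        assert a == pytest.approx(b, abs=1e-9)


class TestBackground:
    def test_uniform_image_becomes_zero(self):
        img = np.full((50, 50), -321.0)
        out = subtract_background(img, (3.25, 3.25), SP, 1.0)
        np.testing.assert_allclose(out, 0.0)

    def test_far_field_mean_zero_by_construction(self):
        img, center = gaussian_image(0.25)
        out = subtract_background(img + 100.0, center, SP, 2.0)
        rr = np.hypot(
            np.arange(img.shape[0])[:, None] * SP[0] - center[0],
            np.arange(img.shape[1])[None, :] * SP[1] - center[1],
        )
        assert abs(out[rr > 2.0].mean()) < 1e-12


class TestRadialProfile:
    def test_gaussian_profile_matches_analytic(self):
        sigma = 0.3
        img, center = gaussian_image(sigma)
        prof = radial_profile(img, center, SP, bin_width_mm=SP[0] / 4)
        expected = np.exp(-prof.radii_mm**2 / (2 * sigma**2))
        measured = prof.pixel_counts > 0  # interpolated empty bins excluded
        assert np.abs(prof.values_hu - expected)[measured].max() < 0.02

    def test_zero_image_gives_zero_profile(self):
        prof = radial_profile(np.zeros((40, 40)), (2.6, 2.6), SP, 0.0325)
        np.testing.assert_allclose(prof.values_hu, 0.0)

    def test_total_signal_conserved_in_quadrature(self):
        img, center = gaussian_image(0.4)
        prof = radial_profile(img, center, SP, SP[0] / 4)
        integral = float(
            np.sum(prof.values_hu * prof.pixel_counts) * prof.pixel_area_mm2
        )
        rr = np.hypot(
            np.arange(img.shape[0])[:, None] * SP[0] - center[0],
            np.arange(img.shape[1])[None, :] * SP[1] - center[1],
        )
        inscribed = img[rr < prof.radii_mm[-1] + prof.bin_width_mm]
        assert integral == pytest.approx(inscribed.sum() * SP[0] * SP[1], rel=0.03)


def disk_profile(d, dr=0.002):
    r = np.arange(0, 3 * d, dr) + dr / 2
    return RadialProfile(r, (r <= d / 2).astype(float), dr)


def gaussian_profile(sigma, dr=0.005, rmax=12.0):
    r = np.arange(0, rmax, dr) + dr / 2
    return RadialProfile(r, np.exp(-(r**2) / (2 * sigma**2)), dr)


class TestHankel:
    def test_uniform_disk_matches_airy_closed_form(self):
        d = 1.2
        freqs = default_frequency_grid_lp_cm(11.0, 0.1)  # below first null ~ 1.02/d lp/mm
        curve = normalize_mtf(hankel_mtf(disk_profile(d), freqs))
        f_mm = freqs / 10
        x = np.pi * d * f_mm
        expected = np.where(x > 0, 2 * j1(np.maximum(x, 1e-12)) / np.maximum(x, 1e-12), 1.0)
        sel = expected > 0.05
        assert np.abs(curve.modulation[sel] - expected[sel]).max() < 0.01

    def test_gaussian_matches_closed_form(self):
        sigma = 0.25
        freqs = default_frequency_grid_lp_cm()
        curve = normalize_mtf(hankel_mtf(gaussian_profile(sigma), freqs))
        expected = np.exp(-2 * np.pi**2 * sigma**2 * (freqs / 10) ** 2)
        assert np.abs(curve.modulation - expected).max() < 0.01

    def test_central_impulse_gives_flat_curve(self):
        prof = RadialProfile(np.array([0.0, 0.01]), np.array([1.0, 0.0]), 0.01,
                             pixel_counts=np.array([1, 0]), pixel_area_mm2=1.0)
        curve = hankel_mtf(prof, default_frequency_grid_lp_cm(20.0, 1.0))
        np.testing.assert_allclose(curve.modulation, curve.modulation[0], rtol=1e-9)

    def test_truncated_tail_warns(self):
        r = np.arange(0, 0.5, 0.01) + 0.005
        prof = RadialProfile(r, np.exp(-(r**2) / (2 * 0.4**2)), 0.01)
        with pytest.warns(RuntimeWarning, match="tail"):
            hankel_mtf(prof, default_frequency_grid_lp_cm(10, 1))


class TestWireCorrection:
    def test_vanishing_wire_is_identity(self):
        curve = MTFCurve(np.arange(0, 30.0, 0.5), np.linspace(1, 0.2, 60))
        out = wire_correction(curve, 1e-6)
        np.testing.assert_allclose(out.modulation, curve.modulation, rtol=1e-6)

    def test_known_divisor_value(self):
        # 0.1 mm wire at 21.7 LP/cm: 2 J1(x)/x with x = pi*0.1*2.17
        curve = MTFCurve(np.array([0.0, 21.7]), np.array([1.0, 1.0]))
        out = wire_correction(curve, 0.1)
        assert out.modulation[1] == pytest.approx(1 / 0.943, abs=2e-3)

    def test_correction_raises_modulation_everywhere(self):
        freqs = np.arange(0, 30.0, 0.5)
        curve = MTFCurve(freqs, np.exp(-0.003 * freqs**2))
        out = wire_correction(curve, 0.2)
        assert np.all(out.modulation[1:] > curve.modulation[1 : out.modulation.size])

    def test_frequencies_beyond_first_null_truncated(self):
        freqs = np.arange(0.0, 80.0, 1.0)
        curve = MTFCurve(freqs, np.ones_like(freqs))
        with pytest.warns(RuntimeWarning, match="first null"):
            out = wire_correction(curve, 0.2)  # first null at ~61 LP/cm
        assert out.frequencies_lp_cm[-1] < 61.0


class TestNormalizeAndCutoff:
    def test_scale_invariance(self):
        curve = MTFCurve(np.arange(5.0), np.array([2.0, 1.5, 1.0, 0.5, 0.2]))
        out = normalize_mtf(curve)
        out7 = normalize_mtf(MTFCurve(curve.frequencies_lp_cm, 7 * curve.modulation))
        assert out.modulation[0] == 1.0
        np.testing.assert_allclose(out.modulation, out7.modulation)

    def test_interpolated_crossing(self):
        curve = MTFCurve(np.array([0.0, 10.0, 12.0]), np.array([1.0, 0.6, 0.4]))
        assert mtf_cutoff(curve, 0.5) == pytest.approx(11.0)

    def test_level_one_is_zero_frequency(self):
        curve = MTFCurve(np.array([0.0, 10.0]), np.array([1.0, 0.5]))
        assert mtf_cutoff(curve, 1.0) == 0.0

    def test_analytic_gaussian_cutoff(self):
        freqs = default_frequency_grid_lp_cm()
        sigma = 0.1704
        curve = MTFCurve(freqs, np.exp(-2 * np.pi**2 * sigma**2 * (freqs / 10) ** 2))
        assert mtf_cutoff(curve, 0.5) == pytest.approx(11.0, rel=0.001)

    def test_no_crossing_rejected(self):
        curve = MTFCurve(np.array([0.0, 10.0]), np.array([1.0, 0.9]))
        with pytest.raises(ValueError, match="never crosses"):
            mtf_cutoff(curve, 0.5)


class TestFullChain:
    def test_gaussian_oracle_equivalence(self):
        """Estimated MTF matches exp(-2 pi^2 s^2 f^2) for blurred wires."""
        for sigma in (0.16, 0.25, 0.35):
            for d in (0.1, 0.2):
                vol = simulate_wire_acquisition(
                    d, PSFModel(sigma, 0.2), center_offset_mm=(0.031, -0.047)
                )
                curve, cuts = estimate_mtf(vol, d)
                f_mm = curve.frequencies_lp_cm / 10
                expected = np.exp(-2 * np.pi**2 * sigma**2 * f_mm**2)
                sel = curve.frequencies_lp_cm <= cuts[0.1]
                assert np.abs(curve.modulation[sel] - expected[sel]).max() < 0.03

    def test_monotone_blur_ordering(self):
        cutoffs = []
        for sigma in (0.16, 0.25, 0.35):
            vol = simulate_wire_acquisition(0.2, PSFModel(sigma, 0.2))
            _, cuts = estimate_mtf(vol, 0.2)
            cutoffs.append(cuts[0.5])
        assert cutoffs[0] > cutoffs[1] > cutoffs[2]

    def test_contrast_scale_invariance(self):
        a = simulate_wire_acquisition(0.2, PSFModel(0.25, 0.2), wire_hu=3000)
        b = simulate_wire_acquisition(0.2, PSFModel(0.25, 0.2), wire_hu=30000)
        _, ca = estimate_mtf(a, 0.2)
        _, cb = estimate_mtf(b, 0.2)
        assert abs(ca[0.5] - cb[0.5]) / ca[0.5] < 0.005
        assert abs(ca[0.1] - cb[0.1]) / ca[0.1] < 0.005

    def test_moderate_noise_tolerated(self):
        vol = simulate_wire_acquisition(
            0.2, PSFModel(0.3072, 0.2), n_slices=15, noise_sigma_hu=5.0, noise_seed=4
        )
        _, cuts = estimate_mtf(vol, 0.2)
        assert cuts[0.5] == pytest.approx(6.1, rel=0.05)
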