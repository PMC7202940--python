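"""Phasor-core tests: reference construction, correlation against a
brute-force spatial oracle, localization and phase extraction."""

import numpy as np
import pytest

from phasortrack import protocols
from phasortrack.optics import BeadPose, render_hologram
from phasortrack.phasor import (
    FLAG_NO_BEAD,
    analyze_frame,
    build_reference_set,
    cross_correlate,
    extract_phase,
    locate_xy,
    radial_bandpass,
    reference_image,
)


class TestReferenceSet:
    def test_center_pixel_value_is_unity(self):
        ref = reference_image(100, 10.0)
        assert ref[50, 50] == pytest.approx(1.0 + 0.0j)

    def test_zero_outside_half_roi(self):
        s = 100
        ref = reference_image(s, 10.0)
        x = np.arange(s) - s // 2
        r = np.hypot(x[None, :], x[:, None])
        assert np.all(ref[r >= s / 2] == 0)

    def test_spectral_peak_sits_at_reference_frequency(self):
        """|DFT| of the constructed reference peaks at 1/k_n cycles/pixel,
        within one frequency bin (brute-force transform)."""
        s, k = 100, 10.0
        spec = np.abs(np.fft.fft2(reference_image(s, k)))
        f = np.fft.fftfreq(s)
        q = np.hypot(f[None, :], f[:, None])
        peak_q = q.ravel()[np.argmax(spec.ravel())]
        assert abs(peak_q - 1.0 / k) <= 1.0 / s

    def test_constraints(self):
        with pytest.raises(ValueError, match="roi_size"):
            build_reference_set(100, [10.0, 60.0])
        with pytest.raises(ValueError, match="increasing"):
            build_reference_set(100, [10.0, 8.0])
        with pytest.warns(UserWarning, match="distinct"):
            build_reference_set(100, [5.0, 10.0])


class TestCrossCorrelate:
    def test_matches_spatial_domain_oracle_on_small_instances(self, rng):
        """FFT correlation equals brute-force cyclic spatial correlation
        with the band-passed reference, on 32x32 images."""
        s = 32
        refs = build_reference_set(s, [8.0])
        img = rng.uniform(0, 255, (s, s))
        cc = cross_correlate(img, refs)[0]
        # brute force: band-passed reference in the spatial domain, then a
        # double loop over all cyclic lags
        ref_bp = np.fft.ifft2(
            np.fft.fft2(refs.references[0]) * radial_bandpass(s, 8.0, 0.2 / 8.0)
        )
        oracle = np.empty((s, s), dtype=complex)
        for uy in range(s):
            for ux in range(s):
                shifted = np.roll(np.roll(img, -uy, axis=0), -ux, axis=1)
                oracle[uy, ux] = np.sum(np.conj(ref_bp) * shifted)
        oracle = np.fft.fftshift(oracle)
        np.testing.assert_allclose(cc, oracle, rtol=1e-10, atol=1e-8)

    def test_autocorrelation_peaks_at_center(self):
        s = 100
        refs = build_reference_set(s, [10.0])
        img = refs.references[0].real
        amp = np.abs(cross_correlate(img, refs)[0])
        assert np.unravel_index(np.argmax(amp), amp.shape) == (s // 2, s // 2)

    def test_constant_image_has_no_correlation(self):
        refs = build_reference_set(64, [8.0])
        cc = cross_correlate(np.full((64, 64), 120.0), refs)
        peak = np.abs(cc[0]).max()
        auto = np.abs(cross_correlate(refs.references[0].real, refs)[0]).max()
        assert peak < 1e-4 * auto  # f_B leaks exp(-12.5) at DC

    def test_size_mismatch_rejected(self):
        refs = build_reference_set(64, [8.0])
        with pytest.raises(ValueError, match="ROI size"):
            cross_correlate(np.zeros((32, 32)), refs)

    def test_integer_cyclic_shift_moves_the_peak_exactly(self, model, rng):
        img = render_hologram(model, BeadPose(0, 0, 10_000), 100,
                              quantize=False).image
        refs = build_reference_set(100, protocols.log_spaced_periods(3))
        for _ in range(4):
            dx, dy = rng.integers(-20, 20, 2)
            rolled = np.roll(np.roll(img, int(dy), axis=0), int(dx), axis=1)
            amp = np.abs(cross_correlate(rolled, refs))
            prod = np.prod(amp, axis=0)
            iy, ix = np.unravel_index(np.argmax(prod), prod.shape)
            assert (ix - 50, iy - 50) == (dx, dy)


class TestLocateXY:
    def test_centered_bead_locates_at_origin(self, model, small_refs):
        img = render_hologram(model, BeadPose(0, 0, 10_000), 100,
                              quantize=False).image
        x, y, peak, flag = locate_xy(cross_correlate(img, small_refs))
        assert flag == ""
        assert abs(x) < 0.01 and abs(y) < 0.01
        assert peak > 0

    def test_integer_pixel_offset(self, model, small_refs):
        img = render_hologram(
            model, BeadPose(3 * model.pixel_size_nm, 0, 10_000), 100,
            quantize=False,
        ).image
        x, y, _, _ = locate_xy(cross_correlate(img, small_refs))
        assert x == pytest.approx(3.0, abs=0.02)
        assert y == pytest.approx(0.0, abs=0.02)

    def test_subpixel_offset(self, model, small_refs):
        img = render_hologram(
            model, BeadPose(0.3 * model.pixel_size_nm, 0, 10_000), 100,
            quantize=False,
        ).image
        x, _, _, _ = locate_xy(cross_correlate(img, small_refs))
        assert x == pytest.approx(0.3, abs=0.05)

    def test_all_zero_maps_flagged_no_bead(self):
        cc = np.zeros((2, 64, 64), dtype=complex)
        *_, flag = locate_xy(cc)
        assert flag == FLAG_NO_BEAD


class TestExtractPhase:
    def test_uniform_phase_window_is_exact(self):
        cc = np.full((64, 64), np.exp(1j * 1.0))
        phi, amp, flag = extract_phase(cc, (0.0, 0.0))
        assert phi == pytest.approx(1.0, abs=1e-12)
        assert flag == ""

    def test_circular_averaging_near_pi(self):
        """Phases pi-0.1 and -(pi-0.1) average to +/-pi, not zero."""
        cc = np.zeros((64, 64), dtype=complex)
        cc[32, 32] = np.exp(1j * (np.pi - 0.1))
        cc[32, 33] = np.exp(-1j * (np.pi - 0.1))
        phi, _, _ = extract_phase(cc, (0.0, 0.0))
        assert abs(phi) == pytest.approx(np.pi, abs=1e-9)

    def test_result_in_half_open_interval(self, rng):
        cc = np.exp(1j * rng.uniform(-np.pi, np.pi, (64, 64)))
        phi, _, _ = extract_phase(cc, (0.0, 0.0))
        assert -np.pi < phi <= np.pi

    def test_window_near_border_is_flagged(self):
        cc = np.full((64, 64), 1.0 + 0j)
        _, _, flag = extract_phase(cc, (-31.0, 0.0))
        assert flag == "window_clipped"

    def test_phase_increment_matches_calibration_slope(self, model,
                                                       fitted_tracker):
        """Finite-difference d(phi)/dz of rendered holograms agrees with the
        local slope of the fitted calibration curve within 5%."""
        cal = fitted_tracker.calibration_
        refs = fitted_tracker.reference_set_
        z0, dz = 10_000.0, 100.0
        f0 = analyze_frame(
            render_hologram(model, BeadPose(0, 0, z0), 100, quantize=False).image,
            refs,
        )
        f1 = analyze_frame(
            render_hologram(model, BeadPose(0, 0, z0 + dz), 100,
                            quantize=False).image,
            refs,
        )
        amp_max = f0.amplitudes.max()
        checked = 0
        for j_cal, j_src in enumerate(cal.source_indices):
            if f0.amplitudes[j_src] < 0.1 * amp_max:
                continue  # period has ~no correlation signal at this height
            dphi = np.angle(np.exp(1j * (f1.phases[j_src] - f0.phases[j_src])))
            slope = (cal.phase(j_cal, z0 + dz) - cal.phase(j_cal, z0))
            assert dphi == pytest.approx(slope, rel=0.05, abs=1e-4)
            checked += 1
        assert checked >= 2


class TestShiftEquivariance:
    def test_integer_shifts_move_xy_and_preserve_phase(self, model, rng):
        """Cyclically shifting the input shifts the located xy by the same
        amount and leaves every per-period phase unchanged (<= 1e-6 rad)."""
        refs = build_reference_set(100, protocols.log_spaced_periods(4))
        img = render_hologram(model, BeadPose(0, 0, 10_000), 100,
                              quantize=False).image
        base = analyze_frame(img, refs)
        for _ in range(5):
            dx, dy = (int(v) for v in rng.integers(-15, 15, 2))
            rolled = np.roll(np.roll(img, dy, axis=0), dx, axis=1)
            fix = analyze_frame(rolled, refs)
            assert fix.x_px == pytest.approx(base.x_px + dx, abs=1e-6)
            assert fix.y_px == pytest.approx(base.y_px + dy, abs=1e-6)
            np.testing.assert_allclose(
                np.angle(np.exp(1j * (fix.phases - base.phases))), 0.0,
                atol=1e-6,
            )
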