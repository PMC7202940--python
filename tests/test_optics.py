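"""Simulator tests: Mie series against an independent oracle, rendering
invariants, and forward-model fitting."""

import numpy as np
import pytest
from scipy.ndimage import shift as nd_shift
from scipy.special import spherical_jn, spherical_yn

from phasortrack.optics import (
    BeadPose,
    OpticalModel,
    Trajectory,
    fit_lmst,
    mie_coefficients,
    mie_n_terms,
    render_hologram,
    render_video,
    scattering_amplitude,
)
from phasortrack.lut import radial_profile


def mie_coefficients_oracle(x: float, m: float, n_max: int):
    """Textbook Riccati-Bessel formulation, independent of the
    logarithmic-derivative recursion used by the implementation:

    a_n = (m psi_n(mx) psi_n'(x) - psi_n(x) psi_n'(mx))
          / (m psi_n(mx) xi_n'(x) - xi_n(x) psi_n'(mx))
    and b_n with the two m factors swapped.
    """
    n = np.arange(1, n_max + 1)
    mx = m * x

    def psi(v, arg):
        return arg * spherical_jn(v, arg)

    def dpsi(v, arg):
        return spherical_jn(v, arg) + arg * spherical_jn(v, arg, derivative=True)

    def xi(v, arg):
        return arg * (spherical_jn(v, arg) + 1j * spherical_yn(v, arg))

    def dxi(v, arg):
        return (spherical_jn(v, arg) + 1j * spherical_yn(v, arg)) + arg * (
            spherical_jn(v, arg, derivative=True)
            + 1j * spherical_yn(v, arg, derivative=True)
        )

    a = (m * psi(n, mx) * dpsi(n, x) - psi(n, x) * dpsi(n, mx)) / (
        m * psi(n, mx) * dxi(n, x) - xi(n, x) * dpsi(n, mx)
    )
    b = (psi(n, mx) * dpsi(n, x) - m * psi(n, x) * dpsi(n, mx)) / (
        psi(n, mx) * dxi(n, x) - m * xi(n, x) * dpsi(n, mx)
    )
    return a, b


class TestMieSeries:
    def test_matches_independent_recursion_for_standard_bead(self):
        # 0.5 um bead, n_m = 1.33, 645 nm -> size parameter ~ 6.477
        model = OpticalModel()
        x = model.size_parameter
        assert x == pytest.approx(6.477, abs=2e-3)
        a, b = mie_coefficients(x, model.relative_index)
        ao, bo = mie_coefficients_oracle(x, model.relative_index, len(a))
        np.testing.assert_allclose(a, ao, rtol=1e-8)
        np.testing.assert_allclose(b, bo, rtol=1e-8)

    def test_matches_oracle_over_random_size_parameters(self, rng):
        for _ in range(10):
            x = rng.uniform(0.5, 20.0)
            m = rng.uniform(1.05, 2.0)
            a, b = mie_coefficients(x, m)
            ao, bo = mie_coefficients_oracle(x, m, len(a))
            np.testing.assert_allclose(a, ao, rtol=1e-8, atol=1e-12)
            np.testing.assert_allclose(b, bo, rtol=1e-8, atol=1e-12)

    def test_index_matched_bead_scatters_nothing(self):
        a, b = mie_coefficients(6.0, 1.0 + 1e-12)
        assert np.max(np.abs(a)) < 1e-9
        assert np.max(np.abs(b)) < 1e-9

    def test_rayleigh_limit_of_leading_coefficient(self):
        x, m = 0.01, 1.5
        a, _ = mie_coefficients(x, m, n_max=3)
        rayleigh = -2j / 3 * x**3 * (m**2 - 1) / (m**2 + 2)
        assert abs(a[0] - rayleigh) / abs(rayleigh) < 0.01

    def test_truncation_grows_with_size_parameter(self):
        assert mie_n_terms(10.0) > mie_n_terms(1.0) >= 3


class TestScatteringAmplitude:
    def test_rejects_points_inside_the_bead(self, model):
        with pytest.raises(ValueError, match="inside the bead"):
            scattering_amplitude(model, (0.0, 0.0, 100.0))

    def test_amplitude_decays_with_distance(self, model):
        near = abs(scattering_amplitude(model, (0, 0, 5_000.0)))
        far = abs(scattering_amplitude(model, (0, 0, 20_000.0)))
        assert far < near


class TestRenderHologram:
    def test_alpha_zero_gives_uniform_background(self, model):
        m0 = OpticalModel(alpha=0.0)
        img = render_hologram(m0, BeadPose(), 64, quantize=False).image
        np.testing.assert_allclose(img, m0.beta)

    def test_standard_parameters_render_and_rings_expand_with_z(self, model):
        """The first intensity minimum moves outward monotonically in z."""
        radii = []
        for z in np.linspace(5_000, 15_000, 6):
            img = render_hologram(model, BeadPose(z_nm=z), 150,
                                  quantize=False).image
            prof = radial_profile(img)
            minima = np.flatnonzero(
                (prof[1:-1] < prof[:-2]) & (prof[1:-1] <= prof[2:])
            )
            radii.append(minima[0] + 1)
        assert all(r2 >= r1 for r1, r2 in zip(radii, radii[1:]))

    def test_circular_symmetry_under_rotation(self, model):
        img = render_hologram(model, BeadPose(), 150, quantize=False).image
        core = img[1:, 1:]  # odd-sized view centered on the bead pixel
        assert np.max(np.abs(core - np.rot90(core))) < 1.0

    def test_translation_equivariance(self, model):
        """Rendering at +500 nm in x equals the centered render translated
        by 500 / pixel_size pixels, to interpolation tolerance."""
        dx_px = 500.0 / model.pixel_size_nm
        ref = render_hologram(model, BeadPose(0, 0, 12_000), 150,
                              quantize=False).image
        moved = render_hologram(model, BeadPose(500.0, 0, 12_000), 150,
                                quantize=False).image
        translated = nd_shift(ref, (0, dx_px), order=3, mode="nearest")
        core = np.s_[30:120, 30:120]  # exclude edge extrapolation
        assert np.max(np.abs(moved[core] - translated[core])) < 1.5

    def test_quantized_output_is_uint8_in_range(self, model):
        img = render_hologram(model, BeadPose(), 64).image
        assert img.dtype == np.uint8

    def test_invalid_roi_and_envelope_args(self, model):
        with pytest.raises(ValueError):
            render_hologram(model, BeadPose(), 16)
        with pytest.raises(ValueError):
            render_hologram(model, BeadPose(), 64, envelope="both")

    def test_literal_envelope_darkens_roi_edge(self, model):
        img = render_hologram(model, BeadPose(), 150, quantize=False,
                              envelope="full").image
        assert img[0, 0] < 1.0  # background decays to zero outside gamma


class TestRenderVideo:
    def test_identical_poses_give_identical_frames(self, model):
        traj = Trajectory([BeadPose()] * 10)
        stack = render_video(model, traj, 64)
        assert stack.shape == (10, 64, 64)
        assert all(np.array_equal(stack[0], f) for f in stack)

    def test_empty_trajectory_rejected(self, model):
        with pytest.raises(ValueError, match="empty"):
            render_video(model, Trajectory([]), 64)

    def test_trajectory_frame_round_trip(self):
        traj = Trajectory([BeadPose(1, 2, 9_000), BeadPose(3, 4, 9_100)],
                          f_s=30.0)
        back = Trajectory.from_frame(traj.to_frame())
        assert back.poses[1].z_nm == 9_100
        assert back.f_s == pytest.approx(30.0)


class TestFitLMST:
    def test_truth_initialized_fit_is_exact(self, model):
        pose = BeadPose(30.0, -20.0, 9_000.0)
        img = render_hologram(model, pose, 80, quantize=False).image
        fit = fit_lmst(img, model, pose)
        assert fit.success
        assert fit.pose.z_nm == pytest.approx(9_000.0, abs=1e-3)
        assert np.max(np.abs(fit.residual)) < 1e-6

    def test_recovers_reported_bead_parameters_from_perturbed_init(self):
        """Round trip at the fitted parameter set of a real 1 um bead
        hologram: x=-70, y=33 nm, z=8300 nm, n_p=1.9, alpha=0.9, beta=57,
        gamma=57; init perturbed by ~10%."""
        true_m = OpticalModel(bead_index=1.9, alpha=0.9, beta=57.0,
                              gamma_px=57.0)
        true_p = BeadPose(-70.0, 33.0, 8_300.0)
        img = render_hologram(true_m, true_p, 100, quantize=False).image
        init_m = OpticalModel(bead_index=2.05, alpha=0.99, beta=52.0,
                              gamma_px=52.0)
        init_p = BeadPose(-77.0, 36.0, 9_130.0)
        fit = fit_lmst(img, init_m, init_p)
        assert fit.pose.x_nm == pytest.approx(-70.0, abs=2.0)
        assert fit.pose.y_nm == pytest.approx(33.0, abs=2.0)
        assert fit.pose.z_nm == pytest.approx(8_300.0, abs=50.0)
        # fixed parameters must not move
        assert fit.model.bead_radius_um == 0.5
        assert fit.model.medium_index == 1.33

    def test_pose_recovery_under_poisson_noise(self, rng):
        true_m = OpticalModel(bead_index=1.9, alpha=0.9, beta=57.0,
                              gamma_px=57.0)
        true_p = BeadPose(-70.0, 33.0, 8_300.0)
        img = render_hologram(true_m, true_p, 100, quantize=False).image
        errs = []
        for _ in range(5):
            noisy = img + rng.normal(
                0.0, np.sqrt(3.0 * np.maximum(img, 0) / img.mean()), img.shape
            )
            fit = fit_lmst(noisy, true_m, BeadPose(-77, 36, 8_500))
            errs.append(
                (fit.pose.x_nm + 70, fit.pose.y_nm - 33, fit.pose.z_nm - 8_300)
            )
        errs = np.abs(np.array(errs))
        assert errs[:, :2].max() < 10.0
        assert errs[:, 2].max() < 250.0
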