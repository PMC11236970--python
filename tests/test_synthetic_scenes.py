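"""Ground-truth generators: contours, rendering, flows, textures, beads."""

import numpy as np
import pytest

from cortexshape import contour_shape as cs
from cortexshape import synthetic_scenes as ss


class TestContourSampling:
    def test_zero_amplitudes_give_circle(self):
        c = ss.contour_from_modes(20.0, {})
        m = cs.shape_metrics(c)
        assert m.circularity == pytest.approx(1.0, abs=1e-4)

    @pytest.mark.parametrize("kappa,gamma,slope", [(1.0, 0.0, -4.0),
                                                   (0.0, 1.0, -2.0)])
    def test_ensemble_spectrum_slope(self, kappa, gamma, slope):
        contours, _ = ss.sample_contour_series(
            20.0, kappa, gamma, n_modes=8, n_frames=500, seed=13,
            amplitude_rms_um=0.2)
        u = np.array([cs.radial_decomposition(c)[2] for c in contours])
        from cortexshape.spectral_analysis import (
            deformation_power_spectrum, fit_scaling_exponent)
        spec = deformation_power_spectrum(u)
        alpha = fit_scaling_exponent(spec, (2, 8))
        assert alpha == pytest.approx(-slope, abs=0.3)

    def test_ensemble_matches_sampling_law_per_mode(self):
        n_modes, n_frames, rms = 8, 600, 0.2
        contours, _ = ss.sample_contour_series(
            20.0, 1.0, 0.0, n_modes, n_frames, seed=7, amplitude_rms_um=rms)
        u = np.array([cs.radial_decomposition(c)[2] for c in contours])
        from cortexshape.spectral_analysis import deformation_power_spectrum
        spec = deformation_power_spectrum(u)
        qs = np.arange(2, n_modes + 1)
        var = 1.0 / qs**4
        expected = 360 * rms**2 / var.sum() * var   # N * s_q^2
        ratio = spec.power[2:n_modes + 1] / expected
        assert np.all(np.abs(ratio - 1) < 0.15)

    def test_mode_truth_reproduces_contour(self):
        contours, truth = ss.sample_contour_series(15.0, 1.0, 0.1, 6, 3,
                                                   seed=3)
        rebuilt = ss.contour_from_modes(truth.radius_um,
                                        truth.mode_amplitude_series[2])
        assert np.allclose(rebuilt.vertices, contours[2].vertices)

    def test_oversized_amplitudes_rejected(self):
        with pytest.raises(ss.SceneError):
            ss.sample_contour_series(5.0, 1.0, 0.0, 6, 2, seed=1,
                                     amplitude_rms_um=50.0, max_attempts=5)

    def test_low_modes_excluded_from_truth(self):
        _, truth = ss.sample_contour_series(20.0, 1.0, 0.0, 6, 1, seed=0)
        assert 0 not in truth.mode_amplitudes
        assert 1 not in truth.mode_amplitudes


class TestRendering:
    def test_cortex_must_be_brightest(self, circle_contour):
        with pytest.raises(ValueError, match="brightest"):
            ss.render_two_channel_frame(
                circle_contour, 0.3, 0.119,
                {"I_S": 0.5, "I_out": 0.8}, None, 0.2)

    def test_subresolution_thickness_warns(self, circle_contour):
        with pytest.warns(UserWarning, match="sub-resolution"):
            ss.render_two_channel_frame(circle_contour, 0.05, 0.119,
                                        None, None, 0.0938)

    def test_equal_plateaus_put_actin_peak_at_half_thickness(self):
        """With I_V = I_out the peak-shift delta vanishes: the blurred
        actin peak sits exactly h/2 inside the membrane peak."""
        contour = ss.contour_from_modes(10.0, {})
        h = 0.4
        memb, act, _ = ss.render_two_channel_frame(
            contour, h, 0.119, {"I_V": 0.2, "I_out": 0.2}, None, 0.08)
        cy = (memb.shape[0] - 1) // 2
        row_m = memb[cy]
        row_a = act[cy]
        x = np.arange(memb.shape[1]) * 0.08
        i_m = np.argmax(row_m[: memb.shape[1] // 2])
        i_a = np.argmax(row_a[: memb.shape[1] // 2])
        delta = (x[i_a] - x[i_m])   # actin peak further from the edge
        assert delta == pytest.approx(h / 2, abs=0.08)

    def test_membrane_peak_on_contour(self, rendered_circle):
        contour, memb, _, _ = rendered_circle
        cy = (memb.shape[0] - 1) // 2
        x_um = (np.arange(memb.shape[1]) - (memb.shape[1] - 1) / 2) * 0.0938
        i = np.argmax(memb[cy, memb.shape[1] // 2:])
        assert x_um[memb.shape[1] // 2 + i] == pytest.approx(12.0, abs=0.0938)


class TestSpeckleFlows:
    def test_translation_truth(self):
        truth = ss.FlowTruth(ss.TranslationFlow(2.0, -1.0), dt_s=3.0)
        ux, uy = truth.displacement_um(np.zeros(4), np.zeros(4))
        assert np.allclose(ux, 6.0) and np.allclose(uy, -3.0)
        assert truth.divergence == 0.0

    def test_radial_contraction_divergence_exact(self):
        flow = ss.RadialContractionFlow(0.03, (5.0, 5.0))
        truth = ss.FlowTruth(flow, dt_s=2.0)
        assert truth.divergence == pytest.approx(-2 * 0.03 * 2.0, rel=1e-15)
        # numerical divergence of the analytic field agrees to machine eps
        x = np.linspace(0, 10, 21)
        xx, yy = np.meshgrid(x, x)
        ux, uy = flow.velocity(xx, yy)
        div = np.gradient(ux, x, axis=1) + np.gradient(uy, x, axis=0)
        assert np.allclose(div, -0.06, atol=1e-12)

    def test_swirl_divergence_zero(self):
        flow = ss.SwirlFlow(0.1, (0.0, 0.0))
        x = np.linspace(-5, 5, 11)
        xx, yy = np.meshgrid(x, x)
        ux, uy = flow.velocity(xx, yy)
        div = np.gradient(ux, x, axis=1) + np.gradient(uy, x, axis=0)
        assert np.allclose(div, 0.0, atol=1e-13)

    def test_excessive_displacement_names_window(self):
        flow = ss.TranslationFlow(50.0, 0.0)
        with pytest.raises(ss.SceneError, match="search window"):
            ss.make_speckle_pair(flow, 200, 1.0, (128, 128), 1.0, seed=0,
                                 max_displacement_px=16)

    def test_minimum_particle_count(self):
        with pytest.raises(ValueError):
            ss.make_speckle_pair(ss.TranslationFlow(1, 0), 10, 1.0,
                                 (64, 64), 1.0)


class TestFilamentTexture:
    def test_fully_aligned_realized_order_one(self):
        _, realized, ang = ss.make_filament_texture(1.0, 200, 20, (256, 256),
                                                    seed=0)
        assert realized == pytest.approx(1.0, abs=1e-12)
        assert np.allclose(ang, ang[0])

    def test_uniform_orientations_clt_bound(self):
        n = 4000
        _, realized, _ = ss.make_filament_texture(0.0, n, 10, (512, 512),
                                                  seed=1)
        assert abs(realized) < 3 / np.sqrt(n)

    def test_no_filaments_is_error(self):
        with pytest.raises(ss.SceneError):
            ss.make_filament_texture(0.5, 0, 20, (128, 128))

    def test_target_matches_realized_mean(self):
        vals = [ss.make_filament_texture(0.4, 3000, 20, (512, 512), seed=s)[1]
                for s in range(4)]
        assert np.mean(vals) == pytest.approx(0.4, abs=0.02)


class TestPolarizedCortex:
    def test_uniform_profile_zero_polarity(self, circle_contour):
        I, achieved = ss.make_polarized_cortex(circle_contour, 0.0, "cosine")
        assert np.allclose(I, 1.0)
        assert achieved == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("profile,target", [
        ("cosine", 0.3), ("step", 2 / np.pi), ("vonmises", 0.24),
        ("vonmises", 0.6),
    ])
    def test_target_achieved_to_tolerance(self, circle_contour, profile,
                                          target):
        _, achieved = ss.make_polarized_cortex(circle_contour, target, profile)
        assert achieved == pytest.approx(target, abs=1e-6)

    def test_unreachable_target_reports_maximum(self, circle_contour):
        with pytest.raises(ss.SceneError, match="maximum attainable"):
            ss.make_polarized_cortex(circle_contour, 0.9, "cosine")

    def test_half_circle_step_gives_two_over_pi(self, circle_contour):
        I, achieved = ss.make_polarized_cortex(circle_contour, 2 / np.pi,
                                               "step")
        assert achieved == pytest.approx(2 / np.pi, abs=1e-6)
        # roughly half the vertices are lit
        assert 0.45 < (I > 0.5).mean() < 0.55


class TestBeads:
    def test_truth_recorded(self):
        img, truth = ss.make_bead_image(5, 0.119, 0.0938, seed=4)
        assert truth.psf_sigma_um == 0.119
        assert img.max() > 0

    def test_overcrowding_raises(self):
        with pytest.raises(ss.SceneError):
            ss.make_bead_image(500, 0.3, 0.0938, seed=0,
                               image_shape=(64, 64))


class TestSceneIO:
    def test_save_load_roundtrip(self, tmp_path):
        contours, truth = ss.sample_contour_series(15.0, 1.0, 0.0, 6, 2,
                                                   seed=3)
        memb, act, _ = ss.render_two_channel_frame(contours[0], 0.29, 0.119,
                                                   None, None, 0.25)
        ss.save_scene(tmp_path, "scene",
                      {"membrane": memb[None], "actin": act[None]}, truth)
        stacks, loaded = ss.load_scene(tmp_path, "scene")
        assert np.allclose(stacks["membrane"][0], memb, atol=1e-6)
        assert loaded.mode_amplitudes == truth.mode_amplitudes
        assert loaded.radius_um == truth.radius_um
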