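"""Contour extraction, circularity / membrane strain, actin polarity."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import ellipe

from cortexshape import contour_shape as cs
from cortexshape import synthetic_scenes as ss


class TestShapeMetrics:
    def test_circle_circularity_one(self, circle_contour):
        m = cs.shape_metrics(circle_contour)
        assert m.circularity == pytest.approx(1.0, abs=1e-4)
        assert m.membrane_strain == pytest.approx(0.0, abs=1e-4)
        assert m.max_radial_deformation == pytest.approx(1.0, abs=1e-6)

    def test_square_circularity_closed_form(self, square_contour):
        m = cs.shape_metrics(square_contour)
        assert m.circularity == pytest.approx(np.pi / 4, rel=1e-9)
        assert m.membrane_strain == pytest.approx(1 - np.pi / 4, rel=1e-8)

    def test_ellipse_matches_elliptic_integral_oracle(self):
        a, b = 20.0, 10.0
        t = np.linspace(0, 2 * np.pi, 1440, endpoint=False)
        ell = cs.MembraneContour(np.column_stack([a * np.cos(t),
                                                  b * np.sin(t)]))
        C_poly = cs.shape_metrics(ell).circularity
        L = 4 * a * ellipe(1 - (b / a) ** 2)     # exact perimeter
        C_oracle = 4 * np.pi * (np.pi * a * b) / L**2
        assert C_poly == pytest.approx(C_oracle, abs=1e-4)

    def test_isoperimetric_bound_on_random_contours(self):
        for seed in range(5):
            contours, _ = ss.sample_contour_series(
                20.0, 1.0, 0.5, n_modes=8, n_frames=3, seed=seed,
                amplitude_rms_um=0.5)
            for c in contours:
                assert cs.shape_metrics(c).circularity <= 1.0

    @given(scale=st.floats(0.1, 10.0))
    @settings(max_examples=20, deadline=None)
    def test_strain_invariant_under_uniform_scaling(self, scale):
        c = ss.contour_from_modes(20.0, {2: 1.0 + 0.5j, 4: 0.3})
        scaled = cs.MembraneContour(c.vertices * scale)
        assert cs.shape_metrics(scaled).membrane_strain == pytest.approx(
            cs.shape_metrics(c).membrane_strain, rel=1e-9)

    def test_degenerate_contour_rejected(self):
        with pytest.raises(ValueError):
            cs.MembraneContour(np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0]]))


class TestRadialDecomposition:
    def test_circle_gives_zero_deformation(self, circle_contour):
        _, R, u, R_mean = cs.radial_decomposition(circle_contour)
        assert R_mean == pytest.approx(20.0, abs=1e-3)
        assert np.abs(u).max() < 1e-6

    def test_pure_mode_recovered(self):
        R0, a = 20.0, 1.0
        c = ss.contour_from_modes(R0, {2: a})
        theta, R, u, _ = cs.radial_decomposition(c)
        assert np.abs(u - a * np.cos(2 * theta)).max() < 1e-3

    def test_mean_deformation_is_zero(self):
        c = ss.contour_from_modes(15.0, {2: 0.7, 3: 0.4j, 5: 0.2})
        _, _, u, _ = cs.radial_decomposition(c)
        assert abs(u.mean()) < 1e-12

    def test_non_star_shaped_contour_raises(self):
        # kidney-shaped curve: rays from the centroid cross the dimple twice
        t = np.linspace(0, 2 * np.pi, 400, endpoint=False)
        v = np.column_stack([np.cos(t) - 0.8 * np.cos(2 * t), np.sin(t)]) * 10
        contour = cs.MembraneContour(v)
        with pytest.raises(cs.ContourError, match="star-shaped"):
            cs.radial_decomposition(contour)


class TestExtraction:
    def test_circle_radius_recovered(self, rendered_circle):
        _, memb, _, _ = rendered_circle
        rec = cs.extract_contour(memb, 0.0938)
        assert rec.mean_radius == pytest.approx(12.0, abs=0.1)

    def test_deformed_contour_subpixel(self):
        truth = ss.contour_from_modes(12.0, {2: 0.6, 3: 0.3j})
        memb, _, _ = ss.render_two_channel_frame(truth, 0.3, 0.119, None,
                                                 None, 0.0938)
        rec = cs.extract_contour(memb, 0.0938)
        _, R_rec, _, _ = cs.radial_decomposition(rec, 360)
        _, R_true, _, _ = cs.radial_decomposition(truth, 360)
        assert np.abs(R_rec - R_true).max() < 0.0938  # < 1 px

    def test_roundtrip_under_noise_below_one_pixel(self, rendered_circle_noisy):
        truth, memb, _, _ = rendered_circle_noisy
        rec = cs.extract_contour(memb, 0.0938)
        _, R_rec, _, _ = cs.radial_decomposition(rec, 360)
        assert np.abs(R_rec - 12.0).max() < 0.0938

    def test_blank_image_raises(self):
        with pytest.raises(cs.ContourError):
            cs.extract_contour(np.zeros((64, 64)), 0.1)


class TestPolarity:
    def test_uniform_intensity_zero(self, circle_contour):
        P = cs.polarity_from_vertex_intensity(
            circle_contour, np.ones(len(circle_contour.vertices)))
        assert P == pytest.approx(0.0, abs=1e-12)

    def test_single_lit_vertex_is_one(self, circle_contour):
        I = np.zeros(len(circle_contour.vertices))
        I[17] = 5.0
        P = cs.polarity_from_vertex_intensity(circle_contour, I)
        assert P == pytest.approx(1.0, abs=1e-3)

    def test_half_circle_step_is_two_over_pi(self, circle_contour):
        v = circle_contour.vertices - circle_contour.center_of_mass
        theta = np.arctan2(v[:, 1], v[:, 0])
        I = (np.abs(theta) <= np.pi / 2).astype(float)
        P = cs.polarity_from_vertex_intensity(circle_contour, I)
        # brute-force polygon sum equals the arc-centroid integral 2/pi
        lit = I > 0
        r_act = circle_contour.vertices[lit].mean(axis=0)
        P_brute = np.hypot(*(r_act - circle_contour.center_of_mass)) \
            / circle_contour.mean_radius
        assert P == pytest.approx(P_brute, rel=1e-12)
        assert P == pytest.approx(2 / np.pi, abs=0.01)

    def test_invariant_under_rigid_motion(self, circle_contour):
        rng = np.random.default_rng(0)
        I = rng.uniform(0.5, 2.0, len(circle_contour.vertices))
        P0 = cs.polarity_from_vertex_intensity(circle_contour, I)
        ang = 0.7
        rot = np.array([[np.cos(ang), -np.sin(ang)],
                        [np.sin(ang), np.cos(ang)]])
        moved = cs.MembraneContour(circle_contour.vertices @ rot.T + [5.0, -3.0])
        assert cs.polarity_from_vertex_intensity(moved, I) == pytest.approx(
            P0, rel=1e-9)

    def test_all_zero_intensity_raises(self, circle_contour):
        with pytest.raises(ValueError):
            cs.polarity_from_vertex_intensity(
                circle_contour, np.zeros(len(circle_contour.vertices)))

    def test_image_sampled_polarity_matches_construction(self):
        contour = ss.contour_from_modes(12.0, {})
        I_vertex, achieved = ss.make_polarized_cortex(contour, 0.24, "vonmises")
        memb, act, _ = ss.render_two_channel_frame(contour, 0.29, 0.119,
                                                   None, None, 0.0938)
        from cortexshape.pipeline import _modulate_cortex
        act = _modulate_cortex(act, contour, I_vertex, 0.0938)
        rec = cs.extract_contour(memb, 0.0938)
        P = cs.actin_polarity(rec, act, 0.0938)
        assert P == pytest.approx(achieved, abs=0.02)


class TestTimeseries:
    def _series(self, ramp):
        contours = []
        for k, amp in enumerate(ramp):
            contours.append(
                cs.MembraneContour(
                    ss.contour_from_modes(15.0, {3: amp}).vertices, frame=k))
        return contours

    def test_static_scene_max_is_initial(self):
        contours = self._series([0.5, 0.5, 0.5])
        ts = cs.metric_timeseries(contours, None, 0.1)
        assert ts.max_membrane_strain == pytest.approx(
            ts.table["eps_memb"].iloc[0])

    def test_monotone_ramp_peaks_at_final_frame(self):
        contours = self._series([0.0, 0.3, 0.6, 0.9])
        ts = cs.metric_timeseries(contours, None, 0.1)
        assert ts.table["eps_memb"].idxmax() == 3

    def test_size_gate(self):
        assert cs.passes_size_gate(20.0)
        assert not cs.passes_size_gate(8.0)
        assert cs.passes_size_gate(17.5)
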