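"""Power spectrum, scaling fits, autocorrelation size, Pratt curvature."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cortexshape import spectral_analysis as sa
from cortexshape import synthetic_scenes as ss

N = 360
THETA = np.linspace(-np.pi, np.pi, N, endpoint=False)


class TestPowerSpectrum:
    def test_single_mode_carries_all_power(self):
        a = 0.3
        spec = sa.deformation_power_spectrum((a * np.cos(3 * THETA))[None, :])
        assert spec.power[3] == pytest.approx(a**2 * N / 2, rel=1e-12)
        others = np.delete(spec.power, 3)
        assert others.max() < 1e-20

    def test_parseval(self):
        rng = np.random.default_rng(2)
        u = rng.normal(size=N)
        u -= u.mean()
        spec = sa.deformation_power_spectrum(u[None, :])
        assert spec.power.sum() == pytest.approx(N * u.var(), abs=1e-10)

    def test_frame_averaging(self):
        u = np.vstack([np.cos(2 * THETA), 3 * np.cos(2 * THETA)])
        spec = sa.deformation_power_spectrum(u)
        single = sa.deformation_power_spectrum(u[:1])
        assert spec.n_frames_averaged == 2
        assert spec.power[2] == pytest.approx(5 * single.power[2])


class TestScalingExponent:
    @pytest.mark.parametrize("exponent", [2.0, 4.0])
    def test_exact_power_law(self, exponent):
        q = np.arange(0, 16)
        power = np.zeros_like(q, dtype=float)
        power[2:] = q[2:].astype(float) ** -exponent
        spec = sa.DeformationSpectrum(q=q, power=power, n_frames_averaged=1)
        assert sa.fit_scaling_exponent(spec) == pytest.approx(exponent,
                                                              abs=1e-10)

    def test_zero_power_modes_excluded_with_warning(self):
        q = np.arange(0, 10)
        power = np.zeros_like(q, dtype=float)
        power[2:] = q[2:].astype(float) ** -4.0
        power[7] = 0.0
        spec = sa.DeformationSpectrum(q=q, power=power, n_frames_averaged=1)
        with pytest.warns(UserWarning, match="zero-power"):
            alpha = sa.fit_scaling_exponent(spec)
        assert alpha == pytest.approx(4.0, abs=1e-10)

    def test_too_few_modes_raises(self):
        spec = sa.DeformationSpectrum(q=np.arange(4),
                                      power=np.ones(4), n_frames_averaged=1)
        with pytest.raises(ValueError):
            sa.fit_scaling_exponent(spec, (2, 3))


class TestFluctuationModelFit:
    def _ensemble_spectrum(self, kappa, gamma, seed, n_frames=600, rms=0.2,
                           n_modes=8):
        contours, _ = ss.sample_contour_series(
            20.0, kappa, gamma, n_modes, n_frames, seed=seed,
            amplitude_rms_um=rms)
        from cortexshape.contour_shape import radial_decomposition
        u = np.array([radial_decomposition(c)[2] for c in contours])
        return sa.deformation_power_spectrum(u)

    def test_bending_only_data_pins_gamma(self):
        n_modes, rms = 8, 0.2
        spec = self._ensemble_spectrum(1.0, 0.0, seed=7)
        kappa, gamma = sa.fit_fluctuation_model(spec, (2, n_modes))
        # generator scale: power(q) = N * A0 / q^4 with A0 = rms^2/sum(q^-4)
        A0 = rms**2 / np.sum(1.0 / np.arange(2, n_modes + 1) ** 4.0)
        assert kappa * 360 * A0 == pytest.approx(1.0, abs=0.15)
        # tension term is pinned near its zero bound: < 10% of the
        # bending term even at the lowest mode
        assert gamma * 2**2 < 0.10 * kappa * 2**4

    def test_crossover_mode_recovered(self):
        # kappa q^4 = gamma q^2 at q = 3  =>  gamma/kappa = 9
        spec = self._ensemble_spectrum(1.0, 9.0, seed=9)
        kappa, gamma = sa.fit_fluctuation_model(spec, (2, 8))
        assert np.sqrt(gamma / kappa) == pytest.approx(3.0, abs=1.0)

    def test_scale_invariance(self):
        spec = self._ensemble_spectrum(1.0, 9.0, seed=9)
        k1, g1 = sa.fit_fluctuation_model(spec, (2, 8))
        scaled = sa.DeformationSpectrum(q=spec.q, power=spec.power * 7.0,
                                        n_frames_averaged=1)
        k2, g2 = sa.fit_fluctuation_model(scaled, (2, 8))
        assert g2 / k2 == pytest.approx(g1 / k1, rel=1e-6)
        assert scaled.amplitude_fit / spec.amplitude_fit == pytest.approx(
            7.0, rel=1e-6)


class TestAutocorrelationSize:
    def test_cos2_zero_at_45_degrees(self):
        size = sa.angular_autocorrelation_size(np.cos(2 * THETA)[None, :])
        assert size.theta_c_deg == pytest.approx(45.0, abs=1e-9)

    @pytest.mark.parametrize("m", [2, 3, 5, 9])
    def test_single_mode_zero_at_90_over_m(self, m):
        size = sa.angular_autocorrelation_size(np.cos(m * THETA)[None, :])
        assert size.theta_c_deg == pytest.approx(90.0 / m, abs=1e-9)

    def test_theta_c_monotone_in_mode_number(self):
        zeros = [sa.angular_autocorrelation_size(
            np.cos(m * THETA)[None, :]).theta_c_deg for m in range(2, 10)]
        assert np.all(np.diff(zeros) < 0)

    def test_acf_is_symmetric(self):
        rng = np.random.default_rng(3)
        u = rng.normal(size=N)
        acf = sa.angular_autocorrelation(u)
        assert np.allclose(acf[1:], acf[1:][::-1], atol=1e-12)

    def test_three_mode_mixture_matches_dense_oracle(self):
        amps = {2: 0.5 + 0.1j, 3: 0.3 - 0.2j, 5: 0.25 + 0.05j}

        def u_of(grid):
            u = np.zeros_like(grid)
            for q, aq in amps.items():
                u += np.real(aq * np.exp(1j * q * grid))
            return u

        size = sa.angular_autocorrelation_size(u_of(THETA)[None, :])
        # brute force on a 10x finer grid
        nd = 10 * N
        dense = u_of(-np.pi + 2 * np.pi * (np.arange(nd) + 1) / nd)
        acf = np.array([(dense * np.roll(dense, -k)).mean()
                        for k in range(nd // 2 + 1)])
        acf /= acf[0]
        k = np.where((acf[:-1] > 0) & (acf[1:] < 0))[0][0]
        frac = acf[k] / (acf[k] - acf[k + 1])
        oracle = 360.0 * (k + frac) / nd
        assert size.theta_c_deg == pytest.approx(oracle, abs=0.5)

    def test_minimum_over_frames_and_t_prime(self):
        u = np.vstack([np.cos(2 * THETA), np.cos(6 * THETA)])
        size = sa.angular_autocorrelation_size(u)
        assert size.theta_c_deg == pytest.approx(15.0, abs=1e-9)
        assert size.t_prime == 1

    def test_all_positive_acf_raises(self):
        u = np.full((1, N), 0.0)
        u[0] += np.cos(0 * THETA)  # constant: zero-variance frame
        with pytest.raises(ValueError):
            sa.angular_autocorrelation_size(u)


class TestCurvature:
    def test_circle_curvature_is_inverse_radius(self, circle_contour):
        prof = sa.local_curvature(circle_contour, separation=5)
        assert np.allclose(prof.curvature_per_um, 0.05, rtol=1e-6)

    def test_collinear_points_give_zero_flagged(self):
        _, _, r = sa.pratt_circle_fit(
            np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0]]))
        assert np.isinf(r)

    def test_two_mode_profile_matches_polar_oracle(self):
        R, eps = 20.0, 0.05
        c = ss.contour_from_modes(R, {2: R * eps}, n_vertices=360)
        prof = sa.local_curvature(c, separation=5)
        th = np.linspace(-np.pi, np.pi, 360, endpoint=False)
        r = R * (1 + eps * np.cos(2 * th))
        rp = -2 * R * eps * np.sin(2 * th)
        rpp = -4 * R * eps * np.cos(2 * th)
        oracle = (r**2 + 2 * rp**2 - r * rpp) / (r**2 + rp**2) ** 1.5
        assert np.abs(prof.curvature_per_um / oracle - 1).max() < 0.02

    @given(seed=st.integers(0, 30))
    @settings(max_examples=10, deadline=None)
    def test_total_turning_is_two_pi(self, seed):
        contours, _ = ss.sample_contour_series(
            20.0, 1.0, 0.5, n_modes=8, n_frames=1, seed=seed,
            amplitude_rms_um=0.4)
        prof = sa.local_curvature(contours[0], separation=5)
        assert sa.total_turning(contours[0], prof) == pytest.approx(
            2 * np.pi, rel=0.01)
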