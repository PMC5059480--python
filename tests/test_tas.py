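import numpy as np
import pytest
from scipy import integrate

from thiodyn.synthetic import generate_tas
from thiodyn.tas import (
    DASet,
    GlobalFitResult,
    IRFModel,
    SequentialModel,
    SpectroTemporalMap,
    apply_chirp,
    chirp_correct,
    compose_map,
    emg_profile,
    global_fit,
    kinetic_trace,
    read_map,
    sequential_profiles,
    write_map,
)

IRF200 = IRFModel(200.0, 0.0)


def quadrature_emg(rate, irf, delays):
    """Independent oracle: adaptive quadrature of the convolution
    integral of exp(-k u) H(u) with the unit-area Gaussian IRF."""
    sigma = irf.sigma
    out = np.empty_like(delays, dtype=float)
    for j, t in enumerate(delays):
        tau = t - irf.t0

        def integrand(u, tau=tau):
            return (
                np.exp(-rate * u)
                * np.exp(-((tau - u) ** 2) / (2 * sigma**2))
                / (sigma * np.sqrt(2 * np.pi))
            )

        upper = max(tau, 0.0) + 12 * sigma
        val, _ = integrate.quad(
            integrand, 0.0, upper, epsabs=1e-13, epsrel=1e-12, limit=400,
            points=[max(tau, 0.0)] if 0.0 < tau < upper else None,
        )
        out[j] = val
    return out


class TestEmgProfile:
    def test_zero_rate_is_irf_convolved_step(self):
        from scipy.special import erfc

        t = np.linspace(-600.0, 600.0, 41)
        expected = 0.5 * erfc(-t / (IRF200.sigma * np.sqrt(2.0)))
        np.testing.assert_allclose(emg_profile(0.0, IRF200, t), expected, atol=1e-14)

    def test_narrow_irf_approaches_plain_exponential(self):
        irf = IRFModel(1e-4, 0.0)
        t = np.array([50.0, 210.0, 700.0])
        np.testing.assert_allclose(
            emg_profile(1 / 210.0, irf, t), np.exp(-t / 210.0), rtol=1e-9
        )

    def test_matches_quadrature_convolution(self):
        """Closed form vs adaptive-quadrature oracle on the fitting grid."""
        t = np.arange(-1000.0, 3000.0, 1.0)
        c = emg_profile(1 / 210.0, IRF200, t)
        sub = t[::97]  # spot-check a spread of delays at full quad accuracy
        ref = quadrature_emg(1 / 210.0, IRF200, sub)
        assert np.abs(c[::97] - ref).max() < 1e-6
        assert c.min() > -1e-9 and c.max() < 1 + 1e-9

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            emg_profile(-0.1, IRF200, np.array([0.0]))


class TestSequentialProfiles:
    def test_matches_ode_convolution_oracle(self):
        """c_A, c_B, c_C against an explicit ODE integration of the
        sequential scheme convolved numerically with the Gaussian IRF."""
        model = SequentialModel(210.0, 480.0)
        irf = IRF200
        dt = 0.05
        tt = np.arange(0.0, 8000.0, dt)
        sol = integrate.solve_ivp(
            lambda t, y: [-y[0] / 210.0, y[0] / 210.0 - y[1] / 480.0],
            (0.0, tt[-1]),
            [1.0, 0.0],
            t_eval=tt,
            rtol=1e-11,
            atol=1e-13,
        )
        a_fine, b_fine = sol.y
        gauss_norm = 1.0 / (irf.sigma * np.sqrt(2 * np.pi))

        def convolved_at(series, t):
            # trapezoid quadrature of int_0^inf series(u) g(t - u) du
            g = gauss_norm * np.exp(-((t - tt) ** 2) / (2 * irf.sigma**2))
            return np.trapezoid(series * g, tt)

        delays = np.arange(-800.0, 3000.0, 90.0)
        c_a, c_b, c_c = sequential_profiles(model, irf, delays)
        ref_a = np.array([convolved_at(a_fine, t) for t in delays])
        ref_b = np.array([convolved_at(b_fine, t) for t in delays])
        assert np.abs(c_a - ref_a).max() < 1e-5
        assert np.abs(c_b - ref_b).max() < 1e-5

    @pytest.mark.parametrize(
        "tau1,tau2", [(210.0, 480.0), (50.0, 2000.0), (480.0, 210.0)]
    )
    def test_completeness(self, tau1, tau2):
        """c_A + c_B + c_C equals the IRF-convolved step everywhere."""
        delays = np.arange(-900.0, 6000.0, 7.0)
        c_a, c_b, c_c = sequential_profiles(SequentialModel(tau1, tau2), IRF200, delays)
        step = emg_profile(0.0, IRF200, delays)
        assert np.abs(c_a + c_b + c_c - step).max() < 1e-10

    def test_long_delay_limit(self):
        delays = np.array([6000.0])
        c_a, c_b, c_c = sequential_profiles(SequentialModel(210.0, 480.0), IRF200, delays)
        assert c_a[0] < 1e-9 and c_b[0] < 1e-4 and c_c[0] == pytest.approx(1.0, abs=1e-4)

    def test_frozen_intermediate(self):
        delays = np.arange(-500.0, 4000.0, 50.0)
        c_a, c_b, c_c = sequential_profiles(SequentialModel(210.0, 1e9), IRF200, delays)
        assert np.abs(c_c).max() < 1e-5

    def test_degenerate_lifetimes_continuous_limit(self):
        delays = np.arange(-500.0, 3000.0, 25.0)
        exact = sequential_profiles(SequentialModel(300.0, 300.0), IRF200, delays)
        near = sequential_profiles(
            SequentialModel(300.0, 300.0 * (1 + 1e-7)), IRF200, delays
        )
        for e, n in zip(exact, near):
            assert np.abs(e - n).max() < 1e-5

    def test_later_b_maximum_for_slower_tau1(self):
        """With tau2 fixed, increasing tau1 strictly delays the c_B peak."""
        delays = np.arange(-500.0, 6000.0, 1.0)
        peaks = []
        for tau1 in (80.0, 160.0, 320.0, 640.0):
            _, c_b, _ = sequential_profiles(SequentialModel(tau1, 480.0), IRF200, delays)
            peaks.append(delays[np.argmax(c_b)])
        assert all(b > a for a, b in zip(peaks, peaks[1:]))


class TestComposeAndTrace:
    def _fixture(self):
        wl = np.arange(340.0, 640.0, 20.0)
        delays = np.arange(-600.0, 3000.0, 40.0)
        das = DASet(("A", "B", "C"), np.zeros((3, wl.size)))
        das.spectra[0] = 0.5 * np.exp(-((wl - 450) ** 2) / (2 * 120.0**2))
        das.spectra[1] = 2.0 * np.exp(-((wl - 360) ** 2) / (2 * 30.0**2))
        das.spectra[2] = 1.5 * np.exp(-((wl - 520) ** 2) / (2 * 60.0**2))
        profiles = sequential_profiles(SequentialModel(210.0, 480.0), IRF200, delays)
        return wl, delays, das, profiles

    def test_zero_das_gives_zero_map(self):
        wl, delays, das, profiles = self._fixture()
        das.spectra[:] = 0.0
        smap = compose_map(das, profiles, wl, delays)
        assert not smap.amplitudes.any()

    def test_single_component_row_is_scaled_profile(self):
        wl, delays, das, profiles = self._fixture()
        das.spectra[:] = 0.0
        das.spectra[1, 3] = 2.5
        smap = compose_map(das, profiles, wl, delays)
        np.testing.assert_allclose(smap.amplitudes[3], 2.5 * profiles[1], atol=1e-15)
        assert not smap.amplitudes[[i for i in range(wl.size) if i != 3]].any()

    def test_noiseless_roundtrip_through_global_fit(self):
        wl, delays, das, profiles = self._fixture()
        smap = compose_map(das, profiles, wl, delays)
        fit = global_fit(smap, SequentialModel(150.0, 700.0), IRF200)
        model = compose_map(
            fit.das,
            sequential_profiles(fit.model, fit.irf, delays),
            wl,
            delays,
        )
        assert np.abs(model.amplitudes - smap.amplitudes).max() < 1e-6
        assert np.abs(fit.das.spectra - das.spectra).max() < 1e-6

    def test_trace_matches_composed_row_and_offset_profile(self):
        wl, delays, das, profiles = self._fixture()
        das.spectra[:2] = 0.0  # only the offset component C
        smap = compose_map(das, profiles, wl, delays)
        # a fit object holding the exact generating parameters: the
        # residual of the trace must then vanish (exact model class)
        exact = GlobalFitResult(
            model=SequentialModel(210.0, 480.0),
            das=das,
            irf=IRF200,
            residual_rms=0.0,
        )
        observed, fitted = kinetic_trace(smap, 520.0, exact)
        i = np.argmin(np.abs(wl - 520.0))
        corr = np.corrcoef(fitted, profiles[2])[0, 1]
        assert corr == pytest.approx(1.0, abs=1e-6)
        assert np.abs(observed - smap.amplitudes[i]).max() < 1e-12
        assert np.abs(observed - fitted).max() < 1e-9
        # and the fitted parameters land close enough for 1e-6 traces
        fit = global_fit(smap, SequentialModel(180.0, 500.0), IRF200)
        _, fitted2 = kinetic_trace(smap, 520.0, fit)
        assert np.abs(observed - fitted2).max() < 1e-6

    def test_fully_masked_trace_rejected(self):
        wl, delays, das, profiles = self._fixture()
        smap = compose_map(das, profiles, wl, delays)
        smap.mask[5, :] = True
        fit = global_fit(smap, SequentialModel(180.0, 500.0), IRF200)
        with pytest.raises(ValueError):
            kinetic_trace(smap, wl[5], fit)

    def test_dimension_mismatch_rejected(self):
        wl, delays, das, profiles = self._fixture()
        with pytest.raises(ValueError):
            compose_map(das, profiles, wl[:-1], delays)


class TestChirp:
    def _smooth_map(self):
        cfg_delays = np.arange(-800.0, 2500.0, 10.0)
        wl = np.arange(340.0, 640.0, 10.0)
        das = DASet(("A", "B", "C"), np.zeros((3, wl.size)))
        das.spectra[1] = np.exp(-((wl - 380) ** 2) / (2 * 45.0**2))
        das.spectra[2] = np.exp(-((wl - 520) ** 2) / (2 * 70.0**2))
        profiles = sequential_profiles(SequentialModel(210.0, 480.0), IRF200, cfg_delays)
        return compose_map(das, profiles, wl, cfg_delays)

    def test_zero_coefficients_identity(self):
        smap = self._smooth_map()
        out = chirp_correct(smap, [0.0, 0.0])
        np.testing.assert_array_equal(out.amplitudes, smap.amplitudes)
        np.testing.assert_array_equal(out.mask, smap.mask)

    def test_apply_then_correct_roundtrip(self):
        smap = self._smooth_map()
        coeffs = [120.0, -0.25, 0.0002]
        out = chirp_correct(apply_chirp(smap, coeffs), coeffs)
        ok = ~out.mask
        assert ok.sum() > 0.8 * out.mask.size
        assert np.abs(out.amplitudes - smap.amplitudes)[ok].max() < 1e-3

    def test_constant_shift_on_aligned_grid_is_translation(self):
        smap = self._smooth_map()  # uniform 10 fs grid
        out = chirp_correct(smap, [100.0])  # exactly ten grid units
        np.testing.assert_allclose(
            out.amplitudes[:, :-10], smap.amplitudes[:, 10:], atol=1e-12
        )
        assert out.mask[:, -10:].all()


class TestGlobalFit:
    def test_noiseless_synthetic_recovery(self, small_tas_config):
        small_tas_config.noise_sd = 0.0
        small_tas_config.chirp_coeffs = (0.0,)
        smap, truth = generate_tas(small_tas_config)
        fit = global_fit(smap, SequentialModel(120.0, 900.0), IRFModel(200.0))
        assert fit.model.tau1 == pytest.approx(210.0, rel=1e-3)
        assert fit.model.tau2 == pytest.approx(480.0, rel=1e-3)

    def test_noisy_recovery_within_printed_uncertainty(self, small_tas_config):
        smap, truth = generate_tas(small_tas_config)
        corrected = chirp_correct(smap, truth["chirp_coeffs"])
        fit = global_fit(corrected, SequentialModel(150.0, 600.0), IRFModel(200.0))
        assert fit.model.tau1 == pytest.approx(210.0, abs=50.0)
        assert fit.model.tau2 == pytest.approx(480.0, abs=60.0)

    def test_single_component_map_flagged(self):
        wl = np.arange(350.0, 500.0, 25.0)
        delays = np.arange(-500.0, 3000.0, 30.0)
        das = DASet(("A", "B", "C"), np.zeros((3, wl.size)))
        das.spectra[0] = 1.0  # only the fast component
        profiles = sequential_profiles(SequentialModel(210.0, 480.0), IRF200, delays)
        smap = compose_map(das, profiles, wl, delays)
        fit = global_fit(smap, SequentialModel(210.0, 500.0), IRF200)
        assert "tau2_at_bound" in fit.flags or np.abs(fit.das.spectra[1:]).max() < 1e-6

    def test_variable_projection_equals_joint_fit(self):
        """Variable projection must land on the same optimum as a full
        joint nonlinear fit with every DAS entry free."""
        from scipy.optimize import least_squares

        wl = np.arange(350.0, 560.0, 50.0)
        delays = np.arange(-600.0, 3000.0, 30.0)
        das = DASet(("A", "B", "C"), np.zeros((3, wl.size)))
        das.spectra[0] = 0.3 + 0.1 * np.cos(wl / 40.0)
        das.spectra[1] = np.exp(-((wl - 380) ** 2) / (2 * 40.0**2))
        das.spectra[2] = np.exp(-((wl - 500) ** 2) / (2 * 60.0**2))
        profiles = sequential_profiles(SequentialModel(210.0, 480.0), IRF200, delays)
        smap = compose_map(das, profiles, wl, delays)
        rng = np.random.default_rng(4)
        smap.amplitudes += rng.normal(0.0, 0.02, smap.amplitudes.shape)

        fit = global_fit(smap, SequentialModel(150.0, 650.0), IRF200)

        n_wl = wl.size

        def joint_resid(theta):
            tau1, tau2, t0 = theta[:3]
            d = theta[3:].reshape(3, n_wl)
            prof = np.vstack(
                sequential_profiles(
                    SequentialModel(tau1, tau2), IRFModel(200.0, t0), delays
                )
            )
            return (d.T @ prof - smap.amplitudes).ravel()

        x0 = np.concatenate([[150.0, 650.0, 0.0], das.spectra.ravel()])
        joint = least_squares(joint_resid, x0, xtol=1e-14, ftol=1e-14)
        assert fit.model.tau1 == pytest.approx(joint.x[0], rel=1e-6)
        assert fit.model.tau2 == pytest.approx(joint.x[1], rel=1e-6)

    def test_too_few_unmasked_points_rejected(self):
        wl = np.arange(350.0, 500.0, 25.0)
        delays = np.arange(-500.0, 3000.0, 30.0)
        smap = SpectroTemporalMap(
            wl, delays, np.zeros((wl.size, delays.size)),
            np.ones((wl.size, delays.size), dtype=bool),
        )
        with pytest.raises(ValueError):
            global_fit(smap, SequentialModel(210.0, 480.0), IRF200)


class TestMapIO:
    def test_roundtrip_preserves_axes_values_and_mask(self, tmp_path):
        wl = np.arange(340.0, 420.0, 10.0)
        delays = np.arange(-200.0, 600.0, 40.0)
        rng = np.random.default_rng(0)
        amp = rng.normal(size=(wl.size, delays.size))
        mask = rng.random((wl.size, delays.size)) < 0.1
        smap = SpectroTemporalMap(wl, delays, amp, mask)
        path = tmp_path / "map.csv"
        write_map(smap, path)
        back = read_map(path)
        np.testing.assert_allclose(back.wavelengths, wl)
        np.testing.assert_allclose(back.delays, delays)
        np.testing.assert_array_equal(back.mask, mask)
        np.testing.assert_allclose(
            back.amplitudes[~mask], smap.amplitudes[~mask], rtol=1e-9
        )
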