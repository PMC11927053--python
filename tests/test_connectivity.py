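import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from betalink import connectivity as cn
from betalink import synthgen as sg
from betalink.signals import EpochedSignals


def _pair_epochs(maker, n_trials=30, duration=0.5, fs=1000.0):
    trials = []
    for _ in range(n_trials):
        x, y = maker()
        trials.append(np.stack([x, y]))
    return EpochedSignals(data=np.array(trials), fs=fs, t0=0.0)


class TestSectionSpectra:
    def test_55_sections_per_275s_trial(self, rng):
        n = int(2.75 * 1000)
        ep = EpochedSignals(data=rng.standard_normal((4, 2, n)), fs=1000.0, t0=-0.25)
        est = cn.section_spectra(ep, window=(-0.25, 2.5), section_length=0.050)
        assert est.L == 4 * 55

    def test_pooled_count_60_trials_half_second(self, rng):
        ep = EpochedSignals(data=rng.standard_normal((60, 2, 500)), fs=1000.0, t0=0.0)
        est = cn.section_spectra(ep, window=(0.0, 0.5))
        assert est.L == 600

    def test_section_equal_to_window(self, rng):
        ep = EpochedSignals(data=rng.standard_normal((7, 2, 50)), fs=1000.0, t0=0.0)
        est = cn.section_spectra(ep, window=(0.0, 0.05), section_length=0.05)
        assert est.L == 7

    def test_window_shorter_than_section_raises(self, rng):
        ep = EpochedSignals(data=rng.standard_normal((3, 2, 30)), fs=1000.0, t0=0.0)
        with pytest.raises(ValueError, match="section"):
            cn.section_spectra(ep, window=(0.0, 0.03), section_length=0.05)

    def test_padded_grid_is_1hz(self, rng):
        ep = EpochedSignals(data=rng.standard_normal((3, 2, 500)), fs=1000.0, t0=0.0)
        est = cn.section_spectra(ep, window=(0.0, 0.5))
        assert est.freqs[1] - est.freqs[0] == pytest.approx(1.0)
        assert est.native_freqs[1] - est.native_freqs[0] == pytest.approx(20.0)


class TestSmoothing:
    def test_impulse_spreads_with_quarter_weights(self):
        out = cn.smooth_spectrum(np.array([0.0, 0.0, 1.0, 0.0, 0.0]))
        np.testing.assert_allclose(out, [0.0, 0.25, 0.5, 0.25, 0.0])

    def test_endpoint_weights_renormalized(self):
        out = cn.smooth_spectrum(np.array([1.0, 0.0, 0.0]))
        assert out[0] == pytest.approx(0.5 / 0.75)

    def test_constant_unchanged(self):
        out = cn.smooth_spectrum(np.full(11, 3.3))
        np.testing.assert_allclose(out, 3.3)

    @given(a=st.floats(-5, 5), b=st.floats(-5, 5))
    @settings(max_examples=20, deadline=None)
    def test_linear_trend_preserved_in_interior(self, a, b):
        x = a * np.arange(9.0) + b
        out = cn.smooth_spectrum(x)
        np.testing.assert_allclose(out[1:-1], x[1:-1], atol=1e-9)

    def test_short_spectrum_returned_unchanged(self):
        with pytest.warns(UserWarning):
            out = cn.smooth_spectrum(np.array([1.0, 2.0]))
        np.testing.assert_allclose(out, [1.0, 2.0])


class TestCoherence:
    def test_identical_channels_give_unit_coherence(self, rng):
        x = rng.standard_normal((10, 500))
        data = np.stack([x, x], axis=1)
        est = cn.section_spectra(EpochedSignals(data=data, fs=1000.0, t0=0.0),
                                 window=(0.0, 0.5))
        res = cn.coherence(est)
        valid = np.isfinite(res.c12)
        np.testing.assert_allclose(res.c12[valid], 1.0, atol=1e-9)

    def test_independent_noise_near_chance_level(self, rng):
        data = rng.standard_normal((20, 2, 500))
        est = cn.section_spectra(EpochedSignals(data=data, fs=1000.0, t0=0.0),
                                 window=(0.0, 0.5))
        res = cn.coherence(est)
        # chance level for L pooled sections is ~1/L
        assert res.band_mean < 5.0 / est.L

    def test_estimator_bias_approx_inverse_L(self):
        # for independent signals (C = 0) the expected estimate is ~1/L
        rng = np.random.default_rng(7)
        means = []
        for _ in range(8):
            data = rng.standard_normal((10, 2, 500))
            est = cn.section_spectra(
                EpochedSignals(data=data, fs=1000.0, t0=0.0), window=(0.0, 0.5))
            means.append(cn.coherence(est, smooth=False).band_mean)
        bias = np.mean(means)
        assert 0.5 / est.L < bias < 2.0 / est.L

    def test_shared_source_closed_form(self, rng):
        ep = _pair_epochs(
            lambda: sg.gen_shared_source_pair(0.65574, 0.34426, duration=0.5,
                                              fs=1000.0, rng=rng),
            n_trials=60,
        )
        res = cn.coherence(cn.section_spectra(ep, window=(0.0, 0.5)))
        assert res.band_mean == pytest.approx(0.43, abs=0.06)

    def test_scale_and_swap_invariance(self, rng):
        data = rng.standard_normal((10, 2, 500))
        data[:, 1] += 0.5 * data[:, 0]
        ep = EpochedSignals(data=data, fs=1000.0, t0=0.0)
        base = cn.coherence(cn.section_spectra(ep, window=(0.0, 0.5)))
        scaled = ep.copy()
        scaled.data[:, 0] *= 17.0
        res_scaled = cn.coherence(cn.section_spectra(scaled, window=(0.0, 0.5)))
        swapped = ep.copy()
        swapped.data = swapped.data[:, ::-1]
        res_swap = cn.coherence(cn.section_spectra(swapped, window=(0.0, 0.5)))
        np.testing.assert_allclose(base.c12, res_scaled.c12, atol=1e-9)
        np.testing.assert_allclose(base.c12, res_swap.c12, atol=1e-9)
        assert np.nanmin(base.c12) >= 0 and np.nanmax(base.c12) <= 1 + 1e-12


class TestSignificanceThreshold:
    def test_two_sections_alpha_exponent_one(self):
        assert cn.significance_threshold(2, 0.05) == pytest.approx(0.95)

    def test_55_sections(self):
        assert cn.significance_threshold(55, 0.05) == pytest.approx(0.05397, abs=2e-4)

    def test_strictly_decreasing_to_zero(self):
        zs = [cn.significance_threshold(L) for L in (2, 5, 20, 100, 10_000)]
        assert all(a > b for a, b in zip(zs, zs[1:]))
        assert zs[-1] < 0.001

    def test_too_few_sections_rejected(self):
        with pytest.raises(ValueError):
            cn.significance_threshold(1)


class TestMvarFit:
    def test_embedded_univariate_coefficient_recovered(self, rng):
        n = 10_000
        e = rng.standard_normal(n + 100)
        x = np.zeros(n + 100)
        for t in range(1, n + 100):
            x[t] = 0.5 * x[t - 1] + e[t]
        other = rng.standard_normal(n)
        model = cn.fit_mvar(np.stack([x[100:], other]), p=1)
        assert model.coefs[0, 0, 0] == pytest.approx(0.50, abs=0.02)
        assert abs(model.coefs[0, 0, 1]) < 0.05

    def test_white_noise_coefficients_near_zero(self, rng):
        model = cn.fit_mvar(rng.standard_normal((2, 10_000)), p=3)
        assert np.abs(model.coefs).max() < 0.05

    def test_lwr_matches_least_squares(self, rng):
        x, y = sg.gen_ar_coupled_pair(0.6, n_samples=10_000, rng=rng)
        X = np.stack([x, y])
        p = 2
        model = cn.fit_mvar(X, p=p)
        Xd = X - X.mean(axis=1, keepdims=True)
        Y = Xd[:, p:].T
        Z = np.hstack([Xd[:, p - i:-i].T for i in range(1, p + 1)])
        beta = np.linalg.lstsq(Z, Y, rcond=None)[0]
        A_ls = np.stack([beta[2 * (i - 1): 2 * i].T for i in range(1, p + 1)])
        assert np.max(np.abs(model.coefs - A_ls)) < 1e-2

    def test_matches_statsmodels_var(self, rng):
        statsmodels = pytest.importorskip("statsmodels.tsa.api")
        x, y = sg.gen_ar_coupled_pair(0.6, n_samples=20_000, rng=rng)
        model = cn.fit_mvar(np.stack([x, y]), p=2)
        sm_res = statsmodels.VAR(np.stack([x, y]).T).fit(2, trend="n")
        A_sm = np.stack([sm_res.coefs[i] for i in range(2)])
        assert np.max(np.abs(model.coefs - A_sm)) < 1e-2

    def test_stability_flag(self):
        stable = cn.MvarModel(coefs=np.array([[[0.5, 0.0], [0.0, 0.5]]]),
                              sigma=np.eye(2), fs=1000.0)
        unstable = cn.MvarModel(coefs=np.array([[[1.01, 0.0], [0.0, 0.5]]]),
                                sigma=np.eye(2), fs=1000.0)
        assert stable.is_stable() and not unstable.is_stable()

    def test_order_too_large_rejected(self, rng):
        with pytest.raises(ValueError):
            cn.fit_mvar(rng.standard_normal((2, 20)), p=30)


class TestOrderSelection:
    def test_ar2_ground_truth(self, rng):
        n = 10_000
        e = rng.standard_normal((n + 100, 2))
        x = np.zeros((n + 100, 2))
        A1 = np.array([[0.4, 0.1], [0.2, 0.3]])
        A2 = np.array([[-0.3, 0.0], [0.0, -0.35]])
        for t in range(2, n + 100):
            x[t] = A1 @ x[t - 1] + A2 @ x[t - 2] + e[t]
        sel = cn.select_order(x[100:].T, p_max=8)
        assert sel.bic_order == 2

    def test_white_noise_prefers_minimal_order(self, rng):
        sel = cn.select_order(rng.standard_normal((2, 10_000)), p_max=8)
        assert sel.bic_order == 1

    def test_configured_override(self, rng):
        sel = cn.select_order(rng.standard_normal((2, 2_000)), p_max=5,
                              configured=10)
        assert sel.configured_order == 10


class TestTransferFunction:
    def test_no_ar_terms_gives_identity(self):
        model = cn.MvarModel(coefs=np.zeros((0, 2, 2)), sigma=np.eye(2), fs=1000.0)
        H = cn.transfer_function(model, [0.0, 10.0, 20.0])
        for k in range(3):
            np.testing.assert_allclose(H[k], np.eye(2), atol=1e-12)

    def test_univariate_closed_form(self):
        a, fs = 0.5, 1000.0
        model = cn.MvarModel(coefs=np.full((1, 1, 1), a), sigma=np.eye(1), fs=fs)
        freqs = np.array([0.0, 10.0, 100.0, 250.0])
        H = cn.transfer_function(model, freqs)
        expected = 1.0 / np.abs(1 - a * np.exp(-2j * np.pi * freqs / fs)) ** 2
        np.testing.assert_allclose(np.abs(H[:, 0, 0]) ** 2, expected, rtol=1e-12)
        assert np.abs(H[0, 0, 0]) ** 2 == pytest.approx(4.0)  # dc gain 1/(1-a)^2


class TestDirectedCoherence:
    def test_uncoupled_channels_near_zero_cross_terms(self, rng):
        model = cn.fit_mvar(rng.standard_normal((2, 20_000)), p=3)
        res = cn.directed_coherence(model)
        assert res.band_mean(0, 1) < 0.02
        assert res.band_mean(1, 0) < 0.02

    def test_unidirectional_coupling_dominates_at_every_frequency(self, rng):
        x, y = sg.gen_ar_coupled_pair(0.8, n_samples=20_000, rng=rng)
        model = cn.fit_mvar(np.stack([x, y]), p=5)
        res = cn.directed_coherence(model, freqs=np.arange(1.0, 41.0))
        assert np.all(res.dircoh[:, 1, 0] > res.dircoh[:, 0, 1])

    def test_rows_sum_to_one_for_diagonal_innovations(self):
        model = cn.MvarModel(
            coefs=np.array([[[0.5, 0.2], [0.1, 0.4]]]),
            sigma=np.diag([1.0, 2.0]), fs=1000.0,
        )
        res = cn.directed_coherence(model, freqs=np.arange(1.0, 41.0))
        np.testing.assert_allclose(res.dircoh.sum(axis=2), 1.0, atol=1e-12)
        assert res.dircoh.min() >= 0 and res.dircoh.max() <= 1 + 1e-12

    def test_literal_reading_available(self):
        model = cn.MvarModel(
            coefs=np.array([[[0.5, 0.2], [0.1, 0.4]]]),
            sigma=np.eye(2), fs=1000.0,
        )
        res = cn.directed_coherence(model, normalized=False)
        assert res.normalized is False
        assert np.isfinite(res.band_means[0, 1])

    def test_threshold_attached_from_section_count(self):
        model = cn.MvarModel(coefs=np.zeros((0, 2, 2)), sigma=np.eye(2), fs=1000.0)
        res = cn.directed_coherence(model, L=55)
        assert res.z == pytest.approx(cn.significance_threshold(55))
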