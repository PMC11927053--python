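import numpy as np
import pytest

from betalink import ersp, synthgen as sg
from betalink.ersp import (
    ErspFeatures,
    RelativePowerMap,
    Tfr,
    TfrConfig,
    baseline_normalize,
    beta_timecourse,
    compute_tfr,
    extract_ersp_features,
)
from betalink.signals import EpochedSignals


def _epochs_from_signal(x, n_trials=1, fs=1000.0, t0=-0.25):
    data = np.tile(x, (n_trials, 2, 1))
    return EpochedSignals(data=data, fs=fs, t0=t0)


def _flat_tfr(value=1.0, freqs=None, times=None):
    freqs = freqs if freqs is not None else np.arange(10.0, 31.0, 1.0)
    times = times if times is not None else np.arange(-0.25, 2.5, 0.02)
    power = np.full((1, len(freqs), len(times)), float(value))
    return Tfr(power=power, freqs=freqs, times=times, n_trials=1,
               channel_labels=("C3",))


class TestComputeTfr:
    def test_sinusoid_power_concentrates_at_its_frequency(self):
        t = np.arange(2751) / 1000.0 - 0.25
        ep = _epochs_from_signal(np.sin(2 * np.pi * 20 * t), n_trials=3)
        tfr = compute_tfr(ep, TfrConfig(freqs=np.array([10.0, 20.0])))
        mid = len(tfr.times) // 2
        assert tfr.power[0, 1, mid] > 20 * tfr.power[0, 0, mid]

    def test_window_edges_unavailable(self):
        t = np.arange(2751) / 1000.0 - 0.25
        ep = _epochs_from_signal(np.sin(2 * np.pi * 20 * t))
        tfr = compute_tfr(ep, TfrConfig(freqs=np.array([5.0, 20.0])))
        # the 0.6 s window at 5 Hz cannot be centered near the epoch edges
        assert np.isnan(tfr.power[0, 0, 0])
        assert np.isfinite(tfr.power[0, 0, len(tfr.times) // 2])

    def test_epoch_too_short_raises_naming_frequency(self, rng):
        ep = EpochedSignals(data=rng.standard_normal((2, 2, 300)),
                            fs=1000.0, t0=0.0)
        with pytest.raises(ValueError, match="5 Hz"):
            compute_tfr(ep, TfrConfig(freqs=np.array([5.0])))


class TestBaselineNormalize:
    @pytest.mark.parametrize("factor,expected", [
        (1.0, 0.0), (2.0, 100.0), (0.5424, -45.76),
    ])
    def test_relative_power_arithmetic(self, factor, expected):
        tfr = _flat_tfr(1.0)
        post = tfr.times > 0.5
        tfr.power[:, :, post] *= factor
        rpm = baseline_normalize(tfr, (-0.25, 0.0))
        assert np.nanmean(rpm.rp[0, :, post]) == pytest.approx(expected, abs=0.01)
        # baseline neutrality: mean RP over the baseline is 0 per frequency
        bl = (rpm.times >= -0.25) & (rpm.times <= 0)
        assert np.abs(np.nanmean(rpm.rp[0, :, bl])) < 1e-9

    def test_zero_baseline_power_raises(self):
        tfr = _flat_tfr(0.0)
        with pytest.raises(ZeroDivisionError, match="P_rest"):
            baseline_normalize(tfr, (-0.25, 0.0))

    def test_low_frequencies_without_baseline_coverage_are_nan(self, rng):
        ep = EpochedSignals(data=rng.standard_normal((4, 2, 2751)),
                            fs=1000.0, t0=-0.25)
        tfr = compute_tfr(ep, TfrConfig(freqs=np.array([5.0, 20.0])))
        with pytest.warns(RuntimeWarning, match="baseline coverage"):
            rpm = baseline_normalize(tfr, (-0.25, 0.0))
        assert np.isnan(rpm.rp[0, 0]).all()
        assert np.isfinite(rpm.rp[0, 1]).any()


class TestBetaTimecourse:
    def test_constant_map_gives_constant_course(self):
        freqs = np.arange(5.0, 40.25, 0.25)
        times = np.arange(-0.25, 2.5, 0.02)
        rpm = RelativePowerMap(
            rp=np.full((1, len(freqs), len(times)), 7.5), freqs=freqs,
            times=times, channel_labels=("C3",), baseline_window=(-0.25, 0),
        )
        _, tc = beta_timecourse(rpm)
        np.testing.assert_allclose(tc, 7.5)

    def test_linear_in_frequency_rp_averages_to_band_center(self):
        freqs = np.arange(5.0, 40.25, 0.25)
        times = np.arange(0.0, 1.0, 0.02)
        a = 2.0
        rp = np.tile((a * freqs)[None, :, None], (1, 1, len(times)))
        rpm = RelativePowerMap(rp=rp, freqs=freqs, times=times,
                               channel_labels=("C3",), baseline_window=(-0.25, 0))
        _, tc = beta_timecourse(rpm, band=(14.0, 30.0))
        assert tc[0, 0] == pytest.approx(a * 22.0)  # mean of the 14..30 grid

    def test_single_bin_band(self):
        freqs = np.array([19.75, 20.0, 20.25])
        times = np.arange(0.0, 0.2, 0.02)
        rp = np.zeros((1, 3, len(times)))
        rp[0, 1] = 42.0
        rpm = RelativePowerMap(rp=rp, freqs=freqs, times=times,
                               channel_labels=("C3",), baseline_window=(-0.25, 0))
        _, tc = beta_timecourse(rpm, band=(19.9, 20.1))
        np.testing.assert_allclose(tc[0], 42.0)

    def test_empty_band_rejected(self):
        rpm = RelativePowerMap(
            rp=np.zeros((1, 3, 4)), freqs=np.array([5.0, 6.0, 7.0]),
            times=np.arange(4.0), channel_labels=("C3",),
            baseline_window=(-0.25, 0),
        )
        with pytest.raises(ValueError):
            beta_timecourse(rpm, band=(14.0, 30.0))


def _trace(times):
    """0 until 0.10 s, −50 plateau 0.15–0.65 s, +80 plateau 1.0–1.6 s."""
    tc = np.zeros_like(times)
    tc[(times >= 0.15) & (times <= 0.65)] = -50.0
    tc[(times >= 1.0) & (times <= 1.6)] = 80.0
    return tc


class TestExtractFeatures:
    def test_constructed_trace_recovers_both_bursts(self):
        times = np.arange(-0.25, 2.5, 0.02)
        f = extract_ersp_features(times, _trace(times))
        assert f.mrbd_value == pytest.approx(-50.0, abs=3)
        assert f.pmbs_value == pytest.approx(80.0, abs=3)
        assert 1.0 <= f.pmbs_peak_time <= 1.6
        assert f.mrbd_onset == pytest.approx(0.15, abs=0.03)
        assert f.mrbd_end == pytest.approx(0.65, abs=0.05)
        assert f.pmbs_latency == pytest.approx(1.0, abs=0.03)
        assert f.mrbd_onset < f.mrbd_end
        assert f.pmbs_latency < f.pmbs_end

    def test_no_crossing_means_absent(self):
        times = np.arange(-0.25, 2.5, 0.02)
        f = extract_ersp_features(times, np.full_like(times, -5.0))
        assert f.mrbd_value is None and f.mrbd_onset is None
        assert f.pmbs_value is None

    def test_single_sample_crossing_suppressed_by_sustain_rule(self):
        times = np.arange(-0.25, 2.5, 0.02)
        tc = np.zeros_like(times)
        tc[60] = -40.0  # one isolated excursion
        f = extract_ersp_features(times, tc, sustain=3)
        assert f.mrbd_onset is None

    def test_window_clipped_at_epoch_edge(self):
        times = np.arange(-0.25, 2.5, 0.02)
        tc = np.zeros_like(times)
        tc[times >= 2.4] = 80.0  # burst running into the epoch edge
        f = extract_ersp_features(times, tc)
        # the clipped 200 ms window reaches back before the burst, so the
        # value is diluted but still well above threshold
        assert f.pmbs_value is not None and 40 < f.pmbs_value <= 80
        assert f.pmbs_end is None  # burst never returns below threshold
        assert f.pmbs_peak_time >= 2.4


class TestParameterRecovery:
    def test_plateau_factor_recovered_and_monotonic(self):
        values = {}
        for g in (1.15, 1.35388):
            cfg = sg.SynthEegConfig(
                n_trials=60,
                envelope_per_channel=(((1.2, 1.8, g),), ((1.2, 1.8, g),)),
                seed=21,
            )
            ep = sg.gen_bilateral_epochs(cfg)
            tfr = compute_tfr(ep)
            with pytest.warns(RuntimeWarning):
                rpm = baseline_normalize(tfr)
            feats = ersp.extract_all_channels(rpm)
            values[g] = feats[0].pmbs_value
            assert feats[0].pmbs_value == pytest.approx((g**2 - 1) * 100, abs=3)
        assert values[1.35388] > values[1.15]

    def test_baseline_neutrality_without_envelope(self):
        cfg = sg.SynthEegConfig(n_trials=60, seed=33)
        ep = sg.gen_bilateral_epochs(cfg)
        tfr = compute_tfr(ep)
        with pytest.warns(RuntimeWarning):
            rpm = baseline_normalize(tfr)
        _, tc = beta_timecourse(rpm)
        assert np.nanmax(np.abs(tc)) < 3.0
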