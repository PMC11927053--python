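"""Synthetic bilateral EEG, coupled-pair and MEP data with known ground truth.

The generator emulates the statistical structure of a bilateral
sensorimotor EEG/TMS experiment: beta-band (14–30 Hz) oscillations over
a 1/f background, event-locked amplitude envelopes producing a
movement-related beta desynchronization (MRBD) followed by a
post-movement beta synchronization (PMBS), a shared or lagged beta
source producing tunable (directed) interhemispheric coupling, and
motor-evoked-potential trials for single-pulse versus conditioned
stimulation.

Two beta carriers are available.

``"band_noise"``
    Band-limited Gaussian noise, flat in 14–30 Hz.  This is the carrier
    for all coupling work: the magnitude-squared coherence of a
    shared-source pair has the closed form
    ``var_shared**2 / (var_shared + var_noise)**2``.

``"stratified_tones"``
    Constant-amplitude sinusoids with random phase, one frequency per
    trial, the trial frequencies stratified uniformly across the band.
    Because each trial's short-window spectral power then scales
    deterministically with the squared envelope, a plateau with
    amplitude factor ``g`` is recovered by the ERSP pipeline as exactly
    ``(g**2 - 1)*100`` %.  This is the default carrier of the pure-band
    parameter-recovery mode.

Amplitudes are unitless (interpretable as µV); no electrode geometry or
volume conduction is modelled.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .ihi import MepTrial
from .signals import EpochedSignals

__all__ = [
    "SynthEegConfig",
    "SynthMepConfig",
    "gen_beta_oscillation",
    "gen_bilateral_epochs",
    "gen_shared_source_pair",
    "gen_ar_coupled_pair",
    "gen_mep_trials",
    "raised_cosine_envelope",
]


# ---------------------------------------------------------------------------
# configs
# ---------------------------------------------------------------------------

@dataclass
class SynthEegConfig:
    """Parameters of the bilateral epoch generator.

    envelope_per_channel holds, per channel, a list of
    ``(start_s, end_s, amplitude_factor)`` plateaus; the envelope is 1
    elsewhere and enters each plateau through raised-cosine ramps of
    ``ramp_ms`` milliseconds.  A factor below 1 yields an MRBD-like
    power decrease of ``(factor**2 - 1)*100`` %, a factor above 1 a
    PMBS-like rebound.

    ``background`` selects the background mode: ``"none"`` (pure-band,
    the default for parameter recovery), ``"pink"`` (1/f**exponent
    noise over the full spectrum) or ``"pink_notched"`` (1/f noise with
    the beta band excised, keeping the in-band ground truth exact while
    adding broadband realism).  ``beta_to_background_ratio`` is the
    in-band variance ratio of the beta component to the background and
    is ignored when the background is ``"none"`` (and, in-band, when it
    is notched out).
    """

    fs: float = 1000.0
    epoch_window: tuple = (-0.25, 2.5)
    n_trials: int = 60
    beta_band: tuple = (14.0, 30.0)
    background: str = "none"
    background_exponent: float = 1.0
    beta_to_background_ratio: float = 5.0
    envelope_per_channel: tuple = ((), ())
    ramp_ms: float = 50.0
    carrier: str = "stratified_tones"
    coupling_mode: str = "none"
    coupling_params: dict = field(default_factory=dict)
    seed: int | None = None

    def validate(self) -> None:
        lo, hi = self.beta_band
        if not (0 < lo < hi < self.fs / 2):
            raise ValueError(f"beta band {self.beta_band} outside (0, Nyquist)")
        if self.background not in ("none", "pink", "pink_notched"):
            raise ValueError(f"unknown background mode {self.background!r}")
        if self.carrier not in ("stratified_tones", "band_noise"):
            raise ValueError(f"unknown carrier {self.carrier!r}")
        if self.coupling_mode not in ("none", "shared_source", "lagged_ar"):
            raise ValueError(f"unknown coupling mode {self.coupling_mode!r}")
        w0, w1 = self.epoch_window
        for ch, plateaus in enumerate(self.envelope_per_channel):
            prev_end = None
            for (a, b, g) in sorted(plateaus):
                if g <= 0:
                    raise ValueError(f"amplitude factor must be > 0, got {g}")
                if not (w0 <= a < b <= w1):
                    raise ValueError(
                        f"plateau ({a}, {b}) outside epoch window {self.epoch_window}"
                    )
                if prev_end is not None and a < prev_end:
                    raise ValueError(
                        f"overlapping plateaus on channel {ch}"
                    )
                prev_end = b
        if self.coupling_mode == "shared_source":
            vs = self.coupling_params.get("var_shared", 0.5)
            vn = self.coupling_params.get("var_noise", 0.5)
            if vs < 0 or vn < 0:
                raise ValueError("mixing variances must be nonnegative")
            if abs(vs + vn - 1.0) > 1e-9:
                raise ValueError("shared_source mixing variances must sum to 1")


@dataclass
class SynthMepConfig:
    """Parameters of the MEP trial generator.

    Peak-to-peak amplitudes are drawn per trial from normal
    distributions truncated at zero (amplitudes are nonnegative):
    Normal(ts_mean, ts_sd) for single test-stimulus trials and
    Normal(cs_mean, cs_sd) for conditioned trials.  The MEP waveform is
    a biphasic template at ``latency_ms`` after the test stimulus,
    scaled so that its peak-to-peak amplitude equals the draw, over
    Gaussian baseline noise of ``noise_sd`` mV.
    """

    n_trials: int = 30
    ts_mean: float = 1.50
    ts_sd: float = 0.10
    cs_mean: float = 0.78
    cs_sd: float = 0.10
    fs: float = 5000.0
    sweep_s: float = 0.20
    stimulus_time: float = 0.05
    latency_ms: float = 22.0
    duration_ms: float = 15.0
    noise_sd: float = 0.01
    condition: tuple | None = None
    seed: int | None = None

    def validate(self) -> None:
        if self.ts_mean <= 0 or self.cs_mean <= 0:
            raise ValueError("MEP amplitude means must be > 0")
        if self.ts_sd < 0 or self.cs_sd < 0 or self.noise_sd < 0:
            raise ValueError("standard deviations must be >= 0")
        if self.n_trials < 0:
            raise ValueError("n_trials must be >= 0")


# ---------------------------------------------------------------------------
# elementary signals
# ---------------------------------------------------------------------------

def _band_noise(rng, band, n, fs, variance):
    """Band-limited Gaussian noise, sample variance scaled exactly."""
    if variance == 0:
        return np.zeros(n)
    f = np.fft.rfftfreq(n, 1.0 / fs)
    spec = np.fft.rfft(rng.standard_normal(n))
    spec[(f < band[0]) | (f > band[1])] = 0.0
    x = np.fft.irfft(spec, n)
    sd = x.std()
    if sd == 0:  # no FFT bin inside the band
        raise ValueError(f"band {band} contains no resolvable frequency for n={n}")
    return x * (np.sqrt(variance) / sd)


def gen_beta_oscillation(band, duration, fs, variance=1.0, seed=None, rng=None):
    """Band-limited stochastic oscillation of the requested variance.

    Constructed in the frequency domain (white Gaussian spectrum zeroed
    outside ``band``) and scaled so the sample variance equals
    ``variance`` exactly; spectral power outside the band is zero up to
    numerical precision.
    """
    if duration <= 0:
        raise ValueError("duration must be > 0")
    if not (0 < band[0] < band[1] < fs / 2):
        raise ValueError(f"band {band} must lie inside (0, {fs / 2}) Hz")
    if variance < 0:
        raise ValueError("variance must be >= 0")
    rng = rng if rng is not None else np.random.default_rng(seed)
    n = int(round(duration * fs))
    return _band_noise(rng, band, n, fs, variance)


def _stratified_tone_freqs(rng, band, n_trials):
    """One frequency per trial, jittered within equal sub-bands, shuffled."""
    lo, hi = band
    edges = np.linspace(lo, hi, n_trials + 1)
    f0 = edges[:-1] + rng.uniform(0.0, 1.0, n_trials) * (edges[1] - edges[0])
    rng.shuffle(f0)
    return f0


def _tone(rng, f0, n, fs, variance=1.0):
    phase = rng.uniform(0.0, 2.0 * np.pi)
    return np.sqrt(2.0 * variance) * np.cos(
        2.0 * np.pi * f0 * np.arange(n) / fs + phase
    )


def _pink_noise(rng, n, fs, exponent, band_notch=None):
    """1/f**exponent noise, unit variance, optionally with a band excised."""
    f = np.fft.rfftfreq(n, 1.0 / fs)
    spec = np.fft.rfft(rng.standard_normal(n)).astype(complex)
    with np.errstate(divide="ignore"):
        gain = np.where(f > 0, f ** (-exponent / 2.0), 0.0)
    spec *= gain
    if band_notch is not None:
        spec[(f >= band_notch[0]) & (f <= band_notch[1])] = 0.0
    x = np.fft.irfft(spec, n)
    sd = x.std()
    return x / sd if sd > 0 else x


def raised_cosine_envelope(times, plateaus, ramp_s=0.050):
    """Amplitude envelope: 1 everywhere, plateaus entered via cosine ramps.

    ``plateaus`` is a list of ``(start_s, end_s, factor)``; the ramp of
    ``ramp_s`` seconds precedes the start and follows the end, so the
    plateau holds its factor over the full ``[start, end]`` interval.
    """
    env = np.ones_like(times)
    for (a, b, g) in plateaus:
        piece = np.ones_like(times)
        if ramp_s > 0:
            rise = (times >= a - ramp_s) & (times < a)
            piece[rise] = 1 + (g - 1) * 0.5 * (
                1 - np.cos(np.pi * (times[rise] - (a - ramp_s)) / ramp_s)
            )
            fall = (times > b) & (times <= b + ramp_s)
            piece[fall] = g + (1 - g) * 0.5 * (
                1 - np.cos(np.pi * (times[fall] - b) / ramp_s)
            )
        piece[(times >= a) & (times <= b)] = g
        env *= piece
    return env


# ---------------------------------------------------------------------------
# coupled pairs
# ---------------------------------------------------------------------------

def gen_shared_source_pair(var_shared, var_noise, band=(14.0, 30.0),
                           duration=1.0, fs=1000.0, seed=None, rng=None):
    """Common-source pair ``x = s + n1``, ``y = s + n2``.

    ``s``, ``n1``, ``n2`` are independent band-limited Gaussian
    processes with the stated variances, so the theoretical in-band
    magnitude-squared coherence is
    ``var_shared**2 / (var_shared + var_noise)**2``.
    """
    if var_shared < 0 or var_noise < 0:
        raise ValueError("variances must be nonnegative")
    if var_shared + var_noise <= 0:
        raise ValueError("var_shared + var_noise must be > 0")
    rng = rng if rng is not None else np.random.default_rng(seed)
    n = int(round(duration * fs))
    s = _band_noise(rng, band, n, fs, var_shared)
    n1 = _band_noise(rng, band, n, fs, var_noise)
    n2 = _band_noise(rng, band, n, fs, var_noise)
    return s + n1, s + n2


def gen_ar_coupled_pair(coupling, lag=1, n_samples=2000, seed=None, rng=None,
                        ar_self=(0.5, 0.5), noise_sd=(1.0, 1.0), burn_in=500):
    """Unidirectionally coupled bivariate AR pair (x drives y).

    ``x_t = ar_self[0]·x_{t−1} + e1_t`` depends on its own innovations
    only; ``y_t = ar_self[1]·y_{t−1} + coupling·x_{t−lag} + e2_t``.
    Raises if the implied bivariate AR system is unstable.
    """
    if lag < 1 or int(lag) != lag:
        raise ValueError("lag must be a positive integer")
    p = max(int(lag), 1)
    A = np.zeros((p, 2, 2))
    A[0, 0, 0] = ar_self[0]
    A[0, 1, 1] = ar_self[1]
    A[int(lag) - 1, 1, 0] += coupling
    if not _ar_stable(A):
        raise ValueError("AR coefficient set is unstable")
    rng = rng if rng is not None else np.random.default_rng(seed)
    total = n_samples + burn_in
    e = rng.standard_normal((total, 2)) * np.asarray(noise_sd)
    x = np.zeros((total, 2))
    for t in range(total):
        acc = e[t].copy()
        for i in range(1, p + 1):
            if t - i >= 0:
                acc += A[i - 1] @ x[t - i]
        x[t] = acc
    x = x[burn_in:]
    return x[:, 0].copy(), x[:, 1].copy()


def _ar_stable(A) -> bool:
    """Spectral radius of the companion matrix < 1."""
    p, d, _ = A.shape
    comp = np.zeros((p * d, p * d))
    comp[:d] = np.hstack([A[i] for i in range(p)])
    if p > 1:
        comp[d:, :-d] = np.eye(d * (p - 1))
    return np.max(np.abs(np.linalg.eigvals(comp))) < 1.0


# ---------------------------------------------------------------------------
# epoch generator
# ---------------------------------------------------------------------------

def gen_bilateral_epochs(cfg: SynthEegConfig) -> EpochedSignals:
    """Generate ``n_trials x 2 channels x time`` stimulus-locked epochs.

    Each channel's beta component is multiplied by its amplitude
    envelope; the optional 1/f background is stationary.  With
    ``coupling_mode="shared_source"`` the two beta carriers share a
    common band-limited source (mixing variances from
    ``coupling_params``); with ``"lagged_ar"`` they form a
    unidirectionally coupled AR pair (channel 1 driven by channel 0).
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    w0, w1 = cfg.epoch_window
    n = int(round((w1 - w0) * cfg.fs)) + 1
    times = w0 + np.arange(n) / cfg.fs
    plateaus = list(cfg.envelope_per_channel) + [()] * (2 - len(cfg.envelope_per_channel))
    envs = [
        raised_cosine_envelope(times, plateaus[ch], cfg.ramp_ms / 1000.0)
        for ch in range(2)
    ]
    data = np.zeros((cfg.n_trials, 2, n))
    if cfg.n_trials == 0:
        return EpochedSignals(data=data, fs=cfg.fs, t0=w0, meta={"seed": cfg.seed})

    if cfg.coupling_mode == "none" and cfg.carrier == "stratified_tones":
        f0s = [_stratified_tone_freqs(rng, cfg.beta_band, cfg.n_trials)
               for _ in range(2)]
        for k in range(cfg.n_trials):
            for ch in range(2):
                data[k, ch] = _tone(rng, f0s[ch][k], n, cfg.fs) * envs[ch]
    elif cfg.coupling_mode == "none":
        for k in range(cfg.n_trials):
            for ch in range(2):
                data[k, ch] = _band_noise(rng, cfg.beta_band, n, cfg.fs, 1.0) * envs[ch]
    elif cfg.coupling_mode == "shared_source":
        vs = cfg.coupling_params.get("var_shared", 0.5)
        vn = cfg.coupling_params.get("var_noise", 0.5)
        for k in range(cfg.n_trials):
            x, y = gen_shared_source_pair(vs, vn, cfg.beta_band,
                                          duration=n / cfg.fs, fs=cfg.fs, rng=rng)
            data[k, 0] = x[:n] * envs[0]
            data[k, 1] = y[:n] * envs[1]
    else:  # lagged_ar
        cp = cfg.coupling_params
        for k in range(cfg.n_trials):
            x, y = gen_ar_coupled_pair(
                cp.get("coupling", 0.5), lag=cp.get("lag", 1), n_samples=n,
                rng=rng, ar_self=cp.get("ar_self", (0.5, 0.5)),
            )
            data[k, 0] = x * envs[0]
            data[k, 1] = y * envs[1]

    if cfg.background != "none":
        notch = cfg.beta_band if cfg.background == "pink_notched" else None
        bg_var = 1.0 / cfg.beta_to_background_ratio
        for k in range(cfg.n_trials):
            for ch in range(2):
                bg = _pink_noise(rng, n, cfg.fs, cfg.background_exponent, notch)
                if cfg.background == "pink":
                    # scale so the *in-band* background variance is
                    # 1/ratio of the (unit) beta variance
                    inband = _inband_fraction(bg, cfg.fs, cfg.beta_band)
                    scale = np.sqrt(bg_var / max(inband, 1e-12))
                else:
                    scale = np.sqrt(bg_var)
                data[k, ch] += bg * scale

    return EpochedSignals(
        data=data, fs=cfg.fs, t0=w0,
        condition=None,
        meta={"seed": cfg.seed, "coupling_mode": cfg.coupling_mode,
              "carrier": cfg.carrier, "background": cfg.background},
    )


def _inband_fraction(x, fs, band):
    """Fraction of variance of ``x`` inside ``band`` (Welch estimate)."""
    from scipy.signal import welch

    nper = min(len(x), 1024)
    f, p = welch(x, fs=fs, nperseg=nper)
    sel = (f >= band[0]) & (f <= band[1])
    total = np.trapezoid(p, f)
    return float(np.trapezoid(p[sel], f[sel]) / total) if total > 0 else 0.0


# ---------------------------------------------------------------------------
# MEP trials
# ---------------------------------------------------------------------------

def _mep_template(n, fs, stimulus_time, latency_ms, duration_ms):
    """Biphasic unit-peak-to-peak MEP shape at the stated latency."""
    t = np.arange(n) / fs
    on = stimulus_time + latency_ms / 1000.0
    dur = duration_ms / 1000.0
    phase = (t - on) / dur
    w = np.zeros(n)
    m = (phase >= 0) & (phase <= 1)
    w[m] = np.sin(2 * np.pi * phase[m]) * np.sin(np.pi * phase[m]) ** 2
    ptp = w.max() - w.min()
    return w / ptp if ptp > 0 else w


def _trunc_normal(rng, mean, sd, size):
    if sd == 0:
        return np.full(size, float(mean))
    a = (0.0 - mean) / sd
    return stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=size,
                               random_state=rng)


def gen_mep_trials(cfg: SynthMepConfig):
    """Synthetic single-TS and conditioned (CS–TS) MEP trials.

    Returns ``(ts_trials, cs_trials)``, each a list of
    :class:`~betalink.ihi.MepTrial` with ``cfg.n_trials`` entries.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n = int(round(cfg.sweep_s * cfg.fs))
    template = _mep_template(n, cfg.fs, cfg.stimulus_time,
                             cfg.latency_ms, cfg.duration_ms)
    out = {}
    for mode, mean, sd in (("ts", cfg.ts_mean, cfg.ts_sd),
                           ("cs_ts", cfg.cs_mean, cfg.cs_sd)):
        amps = _trunc_normal(rng, mean, sd, cfg.n_trials)
        trials = []
        for a in amps:
            wave = a * template + rng.standard_normal(n) * cfg.noise_sd
            trials.append(
                MepTrial(waveform=wave, fs=cfg.fs,
                         stimulus_time=cfg.stimulus_time, mode=mode,
                         condition=cfg.condition)
            )
        out[mode] = trials
    return out["ts"], out["cs_ts"]
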