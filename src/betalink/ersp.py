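"""Time–frequency power, baseline normalization and MRBD/PMBS features.

The time–frequency representation (TFR) follows the sliding-window FFT
convention of sensorimotor-rhythm studies: at each analysis frequency f
a Hanning-tapered window of three cycles (ΔT = 3/f s) slides in 20 ms
steps; power is the squared magnitude of the complex convolution,
averaged across trials.  Power is then expressed relative to the
pre-stimulus baseline,

    RP(n) = (P_n − P_rest) / P_rest × 100,

with P_rest the mean power over the −0.25–0 s window at that frequency
and channel.  The beta (14–30 Hz) band-mean of RP yields a per-channel
timecourse from which the movement-related beta desynchronization
(MRBD) and the post-movement beta synchronization (PMBS) are located
with the ±10% threshold rules, and quantified as the mean RP over a
200 ms window centered on the trough (MRBD) or peak (PMBS).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import fftconvolve

from .signals import EpochedSignals

__all__ = [
    "TfrConfig",
    "Tfr",
    "RelativePowerMap",
    "ErspFeatures",
    "compute_tfr",
    "baseline_normalize",
    "beta_timecourse",
    "extract_ersp_features",
    "extract_all_channels",
]

logger = logging.getLogger(__name__)


@dataclass
class TfrConfig:
    """Sliding-window TFR parameters.

    freqs: analysis grid, 5–40 Hz in 0.25 Hz steps by default;
    cycles_per_window: adaptive window length ΔT = cycles/f seconds;
    time_step: window advance (20 ms);
    baseline_window: P_rest averaging interval (−0.25–0 s).
    """

    freqs: np.ndarray = field(
        default_factory=lambda: np.arange(5.0, 40.0 + 0.125, 0.25)
    )
    cycles_per_window: float = 3.0
    time_step: float = 0.020
    baseline_window: tuple = (-0.25, 0.0)

    def validate(self) -> None:
        f = np.asarray(self.freqs, dtype=float)
        if f.ndim != 1 or len(f) == 0 or np.any(np.diff(f) <= 0):
            raise ValueError("freqs must be a nonempty ascending 1-D grid")
        if np.any(f <= 0):
            raise ValueError("freqs must be positive")
        if self.time_step <= 0 or self.cycles_per_window <= 0:
            raise ValueError("time_step and cycles_per_window must be > 0")


@dataclass
class Tfr:
    """Trial-averaged power: ``power[channel, freq, time]`` (NaN where
    the analysis window does not fit inside the epoch)."""

    power: np.ndarray
    freqs: np.ndarray
    times: np.ndarray
    n_trials: int
    channel_labels: tuple


@dataclass
class RelativePowerMap:
    """Baseline-normalized power change RP(n) in percent."""

    rp: np.ndarray  # channel x freq x time
    freqs: np.ndarray
    times: np.ndarray
    channel_labels: tuple
    baseline_window: tuple

    def to_dataframe(self) -> pd.DataFrame:
        """Long format: channel, freq, time, rp."""
        ch = np.repeat(self.channel_labels, len(self.freqs) * len(self.times))
        fr = np.tile(np.repeat(self.freqs, len(self.times)), len(self.channel_labels))
        tm = np.tile(self.times, len(self.channel_labels) * len(self.freqs))
        return pd.DataFrame(
            {"channel": ch, "freq": fr, "time": tm, "rp": self.rp.ravel()}
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


@dataclass
class ErspFeatures:
    """MRBD/PMBS values (%) and timing landmarks (s) for one channel.

    Value fields are the mean relative power over a 200 ms window
    centered on the trough (MRBD, ≤ 0) or peak (PMBS, ≥ 0); landmark
    fields are ``None`` when the corresponding ±10% crossing is absent.
    """

    channel: str = ""
    mrbd_value: float | None = None
    mrbd_onset: float | None = None
    mrbd_end: float | None = None
    mrbd_trough_time: float | None = None
    pmbs_value: float | None = None
    pmbs_latency: float | None = None
    pmbs_end: float | None = None
    pmbs_peak_time: float | None = None

    @property
    def mrbd_duration(self) -> float | None:
        if self.mrbd_onset is None or self.mrbd_end is None:
            return None
        return self.mrbd_end - self.mrbd_onset

    @property
    def pmbs_duration(self) -> float | None:
        if self.pmbs_latency is None or self.pmbs_end is None:
            return None
        return self.pmbs_end - self.pmbs_latency

    def to_dict(self) -> dict:
        d = {
            "channel": self.channel,
            "mrbd_value": self.mrbd_value,
            "mrbd_onset": self.mrbd_onset,
            "mrbd_end": self.mrbd_end,
            "mrbd_trough_time": self.mrbd_trough_time,
            "mrbd_duration": self.mrbd_duration,
            "pmbs_value": self.pmbs_value,
            "pmbs_latency": self.pmbs_latency,
            "pmbs_end": self.pmbs_end,
            "pmbs_peak_time": self.pmbs_peak_time,
            "pmbs_duration": self.pmbs_duration,
        }
        return d


# ---------------------------------------------------------------------------
# TFR
# ---------------------------------------------------------------------------

def compute_tfr(epochs: EpochedSignals, cfg: TfrConfig | None = None) -> Tfr:
    """Sliding-window Hanning-taper power, averaged over kept trials.

    At frequency f the window holds ``cfg.cycles_per_window`` cycles;
    power at (f, t) is the squared magnitude of the tapered FFT
    coefficient at f from the window centered at t.  Time points whose
    window would extend beyond the epoch are NaN.  Raises if some
    frequency has no available time point at all.
    """
    cfg = cfg or TfrConfig()
    cfg.validate()
    data = epochs.kept()
    if data.shape[0] == 0:
        raise ValueError("no kept trials to analyze")
    fs = epochs.fs
    t = epochs.times
    freqs = np.asarray(cfg.freqs, dtype=float)

    centers = t[0] + np.arange(0, t[-1] - t[0] + 1e-9, cfg.time_step)
    ci = np.round((centers - t[0]) * fs).astype(int)
    ci = ci[ci < epochs.n_times]
    centers = t[0] + ci / fs

    n_trials, n_ch, n_t = data.shape
    flat = data.reshape(n_trials * n_ch, n_t)
    power = np.full((n_ch, len(freqs), len(ci)), np.nan)

    for k, f in enumerate(freqs):
        L = int(round(cfg.cycles_per_window / f * fs))
        if L % 2 == 0:
            L += 1
        if L > n_t:
            raise ValueError(
                f"epoch too short for the {cfg.cycles_per_window}-cycle window "
                f"at {f:g} Hz (needs {L / fs:.3f} s)"
            )
        taper = np.hanning(L)
        kernel = taper * np.exp(
            -2j * np.pi * f * (np.arange(L) - L // 2) / fs
        )
        conv = fftconvolve(flat, kernel[None, :], mode="same", axes=1)
        pw = (np.abs(conv) ** 2).reshape(n_trials, n_ch, n_t).mean(axis=0)
        half = L // 2
        valid = (ci >= half) & (ci <= n_t - 1 - half)
        power[:, k, valid] = pw[:, ci[valid]]

    return Tfr(
        power=power, freqs=freqs, times=centers,
        n_trials=n_trials, channel_labels=tuple(epochs.channel_labels),
    )


def baseline_normalize(tfr: Tfr, baseline_window=(-0.25, 0.0)) -> RelativePowerMap:
    """Express power as percent change from the pre-stimulus baseline.

    P_rest is the mean over the available baseline time points at each
    frequency and channel.  Frequencies whose analysis window is too
    long to fit a single center inside the baseline get all-NaN rows
    (with a warning); a zero P_rest raises a degenerate-baseline error.
    """
    b0, b1 = baseline_window
    in_bl = (tfr.times >= b0 - 1e-12) & (tfr.times <= b1 + 1e-12)
    if not in_bl.any():
        raise ValueError(f"baseline window {baseline_window} holds no time point")
    rp = np.full_like(tfr.power, np.nan)
    empty = []
    for k, f in enumerate(tfr.freqs):
        avail = in_bl & ~np.isnan(tfr.power[:, k, :]).all(axis=0)
        if not avail.any():
            empty.append(f)
            continue
        prest = np.nanmean(tfr.power[:, k, :][:, avail], axis=1)
        if np.any(prest == 0):
            raise ZeroDivisionError(
                f"degenerate baseline: P_rest = 0 at {f:g} Hz"
            )
        rp[:, k, :] = (tfr.power[:, k, :] - prest[:, None]) / prest[:, None] * 100.0
    if len(empty) == len(tfr.freqs):
        raise ValueError("no frequency has an available baseline time point")
    if empty:
        warnings.warn(
            f"{len(empty)} frequencies below "
            f"{empty[-1]:g} Hz have no baseline coverage; set to NaN",
            RuntimeWarning,
        )
    return RelativePowerMap(
        rp=rp, freqs=tfr.freqs, times=tfr.times,
        channel_labels=tfr.channel_labels, baseline_window=tuple(baseline_window),
    )


def beta_timecourse(rpm: RelativePowerMap, band=(14.0, 30.0)):
    """Unweighted band-mean of RP over 14–30 Hz (inclusive) per channel.

    Returns ``(times, tc)`` with ``tc`` of shape (n_channels, n_times);
    unavailable (NaN) cells are excluded from the mean.
    """
    sel = (rpm.freqs >= band[0] - 1e-12) & (rpm.freqs <= band[1] + 1e-12)
    if not sel.any():
        raise ValueError(f"band {band} contains no analysis frequency")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        tc = np.nanmean(rpm.rp[:, sel, :], axis=1)
    return rpm.times, tc


# ---------------------------------------------------------------------------
# feature extraction
# ---------------------------------------------------------------------------

def _window_mean(times, tc, center, half=0.1):
    sel = (times >= center - half - 1e-12) & (times <= center + half + 1e-12)
    clipped = (center - half < times[0] - 1e-12) or (center + half > times[-1] + 1e-12)
    if clipped:
        logger.warning("200 ms feature window clipped at the epoch edge")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        return float(np.nanmean(tc[sel]))


def _extremum_index(tc, lo, hi, mode, tie_rtol=1e-3):
    """Arg-extremum of tc on [lo, hi]; near-ties resolved to the center.

    On plateau-shaped bursts the extremum is degenerate up to numerical
    ripple; the index returned is the median of the contiguous run of
    points within ``tie_rtol·|extremum|`` of the extremum that contains
    the raw arg-extremum.  On noisy data the tolerance is far below the
    noise level and the raw arg-extremum is returned unchanged.
    """
    seg = tc[lo : hi + 1]
    if mode == "min":
        raw = int(np.nanargmin(seg))
    else:
        raw = int(np.nanargmax(seg))
    ext = seg[raw]
    tol = tie_rtol * max(abs(ext), 1e-9)
    near = np.abs(seg - ext) <= tol
    i0 = raw
    while i0 > 0 and near[i0 - 1]:
        i0 -= 1
    i1 = raw
    while i1 < len(seg) - 1 and near[i1 + 1]:
        i1 += 1
    return lo + (i0 + i1) // 2


def _burst_run(tc, region_start, threshold, mode, sustain):
    """Threshold-crossing run containing the region's global extremum.

    Returns ``(run_start, run_end, extremum_idx)`` index triple or
    ``None`` when the extremum never crosses the threshold or its run
    is shorter than ``sustain`` steps (the sustain rule: isolated blips
    do not count as a burst).
    """
    n = len(tc)
    if region_start >= n:
        return None
    seg = tc[region_start:]
    if not np.isfinite(seg).any():
        return None
    if mode == "min":
        ext = region_start + int(np.nanargmin(seg))
        beyond = tc <= -threshold
    else:
        ext = region_start + int(np.nanargmax(seg))
        beyond = tc >= threshold
    if not beyond[ext]:
        return None
    i0 = ext
    while i0 > region_start and beyond[i0 - 1]:
        i0 -= 1
    i1 = ext
    while i1 < n - 1 and beyond[i1 + 1]:
        i1 += 1
    if i1 - i0 + 1 < sustain:
        return None
    return i0, i1, ext


def extract_ersp_features(times, tc, movement_onset=0.0, threshold=10.0,
                          sustain=3, value_window=0.2, channel="",
                          tie_rtol=1e-3) -> ErspFeatures:
    """Locate and quantify MRBD and PMBS on one band-mean timecourse.

    The MRBD burst is the contiguous run of points at or below
    −``threshold``% that contains the post-onset minimum of the
    timecourse (runs shorter than ``sustain`` steps are ignored); its
    onset is the run's first crossing and its end the first later
    return above the threshold.  The PMBS burst is found analogously
    with the +threshold and the maximum, searched from the MRBD end (or
    the movement onset when no MRBD is detected).  Anchoring each burst
    on the global extremum rather than the first crossing keeps the
    landmarks robust to brief noise excursions.  Values are means over
    ``value_window`` seconds centered on the trough/peak, clipped at
    the epoch edges; an end that never returns across the threshold
    before the epoch ends is reported as ``None`` (open burst).
    """
    times = np.asarray(times, dtype=float)
    tc = np.asarray(tc, dtype=float)
    feats = ErspFeatures(channel=channel)
    start = int(np.searchsorted(times, movement_onset))
    half = value_window / 2.0
    finite = np.where(np.isfinite(tc))[0]
    last = int(finite[-1]) if len(finite) else len(tc) - 1

    # ---- MRBD
    search_from = start
    run = _burst_run(tc, start, threshold, "min", sustain)
    if run is not None:
        i0, i1, _ = run
        trough_i = _extremum_index(tc, i0, i1, "min", tie_rtol)
        feats.mrbd_onset = float(times[i0])
        feats.mrbd_end = float(times[i1 + 1]) if i1 < last else None
        feats.mrbd_trough_time = float(times[trough_i])
        feats.mrbd_value = _window_mean(times, tc, times[trough_i], half)
        search_from = i1 + 1
    # ---- PMBS
    run = _burst_run(tc, search_from, threshold, "max", sustain)
    if run is not None:
        i0, i1, _ = run
        peak_i = _extremum_index(tc, i0, i1, "max", tie_rtol)
        feats.pmbs_latency = float(times[i0])
        feats.pmbs_end = float(times[i1 + 1]) if i1 < last else None
        feats.pmbs_peak_time = float(times[peak_i])
        feats.pmbs_value = _window_mean(times, tc, times[peak_i], half)
    return feats


def extract_all_channels(rpm: RelativePowerMap, band=(14.0, 30.0),
                         movement_onset=0.0, **kwargs):
    """Band-mean timecourse + feature extraction for every channel."""
    times, tc = beta_timecourse(rpm, band)
    return [
        extract_ersp_features(times, tc[ch], movement_onset,
                              channel=rpm.channel_labels[ch], **kwargs)
        for ch in range(tc.shape[0])
    ]
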