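"""Interhemispheric coherence and MVAR-based directed coherence.

Coherence
---------
Each kept trial's analysis window is divided into 50 ms nonoverlapping
sections, pooled across trials.  With F_{i,l}(f) the Hanning-windowed
FFT of channel i over section l (l = 1..L),

    X12(f) = (1/L) Σ_l F_{1,l}(f) F_{2,l}*(f)
    S_i(f) = (1/L) Σ_l |F_{i,l}(f)|²
    C12(f) = |X12(f)|² / (S1(f) S2(f)),

after smoothing X12 and S_i with the 0.25/0.5/0.25 three-point kernel.
A 50 ms section has a native 20 Hz bin spacing, too coarse for a
5–40 Hz analysis grid, so sections are zero-padded to 1 s before the
FFT to yield a 1 Hz display grid; the native-resolution spectra are
retained alongside.

Directed coherence
------------------
A bivariate autoregressive model X(t) = Σ_{i=1..p} A(i) X(t−i) + E(t)
(order p = 10 by default) is fitted from ensemble-averaged lag
covariances by the Levinson–Wiggins–Robinson (Whittle) recursion.  With
H(f) = A(f)^{-1} the transfer function and σ_k² the innovation
variances, the normalized directed coherence is

    DirCoh_{i←j}(f) = |H_ij(f)|² σ_j² / Σ_k |H_ik(f)|² σ_k²,

which lies in [0, 1] and sums to 1 over sources j for diagonal
innovation covariance.  The literal autospectrum-ratio reading
|H_ij|² S_jj / S_ii (not bounded by 1) is available behind a flag.
A value is deemed significant when it exceeds Z = 1 − α^{1/(L−1)}
with L the total number of nonoverlapping sections.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .signals import EpochedSignals

__all__ = [
    "SpectralEstimate",
    "CoherenceResult",
    "MvarModel",
    "DirCohResult",
    "OrderSelection",
    "section_spectra",
    "smooth_spectrum",
    "coherence",
    "select_order",
    "fit_mvar",
    "transfer_function",
    "spectral_matrix",
    "directed_coherence",
    "significance_threshold",
]

BETA_BAND = (14.0, 30.0)


# ---------------------------------------------------------------------------
# sectioned cross-spectra and coherence
# ---------------------------------------------------------------------------

@dataclass
class SpectralEstimate:
    """Pooled section-averaged auto- and cross-spectra.

    ``freqs``/``x12``/``s1``/``s2`` are on the zero-padded display
    grid; the ``native_*`` fields hold the unpadded (section-length
    resolution) estimates.  ``L`` is the pooled section count.
    """

    freqs: np.ndarray
    x12: np.ndarray
    s1: np.ndarray
    s2: np.ndarray
    L: int
    section_length: float
    fs: float
    native_freqs: np.ndarray = field(repr=False, default=None)
    native_x12: np.ndarray = field(repr=False, default=None)
    native_s1: np.ndarray = field(repr=False, default=None)
    native_s2: np.ndarray = field(repr=False, default=None)


@dataclass
class CoherenceResult:
    """Magnitude-squared coherence spectrum and its beta-band mean."""

    freqs: np.ndarray
    c12: np.ndarray
    band: tuple
    band_mean: float
    L: int
    period: str | None = None

    def to_dict(self) -> dict:
        return {
            "period": self.period,
            "band": list(self.band),
            "band_mean": self.band_mean,
            "L": self.L,
        }


def section_spectra(epochs: EpochedSignals, window=None, section_length=0.050,
                    pad_to=1.0, channels=(0, 1)) -> SpectralEstimate:
    """Cut kept trials into nonoverlapping sections and pool their FFTs.

    ``window`` is a (start, stop) interval in epoch seconds (the whole
    epoch when None).  Each section is demeaned and Hanning-windowed
    before the FFT; ``pad_to`` seconds of zero-padding sets the display
    grid (1 Hz for the default 1 s).
    """
    fs = epochs.fs
    nsec = int(round(section_length * fs))
    if nsec < 2:
        raise ValueError("section must span at least 2 samples")
    if window is None:
        window = (epochs.times[0], epochs.times[-1])
    data = epochs.time_slice(*window)
    if data.shape[0] == 0:
        raise ValueError("no kept trials")
    nwin = data.shape[2]
    n_per_trial = nwin // nsec
    if n_per_trial < 1:
        raise ValueError(
            f"analysis window ({nwin / fs:.3f} s) shorter than one "
            f"{section_length:.3f} s section"
        )
    segs = data[:, list(channels), : n_per_trial * nsec]
    segs = segs.reshape(data.shape[0], len(channels), n_per_trial, nsec)
    segs = np.moveaxis(segs, 1, 2).reshape(-1, len(channels), nsec)  # (L, ch, nsec)
    segs = segs - segs.mean(axis=2, keepdims=True)
    taper = np.hanning(nsec)
    segs = segs * taper

    npad = max(int(round(pad_to * fs)), nsec)
    F = np.fft.rfft(segs, n=npad, axis=2)
    Fn = np.fft.rfft(segs, n=nsec, axis=2)
    L = segs.shape[0]

    def _spectra(Fc, n):
        x12 = (Fc[:, 0] * np.conj(Fc[:, 1])).mean(axis=0)
        s1 = (np.abs(Fc[:, 0]) ** 2).mean(axis=0)
        s2 = (np.abs(Fc[:, 1]) ** 2).mean(axis=0)
        return np.fft.rfftfreq(n, 1.0 / fs), x12, s1, s2

    freqs, x12, s1, s2 = _spectra(F, npad)
    nfreqs, nx12, ns1, ns2 = _spectra(Fn, nsec)
    return SpectralEstimate(
        freqs=freqs, x12=x12, s1=s1, s2=s2, L=L,
        section_length=section_length, fs=fs,
        native_freqs=nfreqs, native_x12=nx12, native_s1=ns1, native_s2=ns2,
    )


def smooth_spectrum(spectrum, weights=(0.25, 0.5, 0.25)):
    """Three-point spectral smoothing with 0.25/0.5/0.25 weights.

    Interior points become the weighted sum of themselves and their two
    neighbours; endpoints use the two available weights renormalized to
    sum to one.  Complex input is smoothed componentwise.  Fewer than 3
    points are returned unchanged with a warning.
    """
    x = np.asarray(spectrum)
    if x.shape[-1] < 3:
        warnings.warn("spectrum shorter than 3 points; smoothing skipped")
        return x.copy()
    w_prev, w_mid, w_next = weights
    out = np.empty_like(x)
    out[..., 1:-1] = (
        w_prev * x[..., :-2] + w_mid * x[..., 1:-1] + w_next * x[..., 2:]
    )
    out[..., 0] = (w_mid * x[..., 0] + w_next * x[..., 1]) / (w_mid + w_next)
    out[..., -1] = (w_prev * x[..., -2] + w_mid * x[..., -1]) / (w_prev + w_mid)
    return out


def coherence(est: SpectralEstimate, band=BETA_BAND, smooth=True,
              period=None) -> CoherenceResult:
    """Magnitude-squared coherence from pooled section spectra.

    Smoothing (on X12 and the autospectra) precedes the ratio.  Bins
    with zero autospectral power are reported as NaN (undefined).
    """
    if est.L < 2:
        raise ValueError("need at least 2 pooled sections")
    x12, s1, s2 = est.x12, est.s1, est.s2
    if smooth:
        x12 = smooth_spectrum(x12)
        s1 = smooth_spectrum(s1)
        s2 = smooth_spectrum(s2)
    denom = s1 * s2
    with np.errstate(divide="ignore", invalid="ignore"):
        c12 = np.where(denom > 0, np.abs(x12) ** 2 / denom, np.nan)
    sel = (est.freqs >= band[0] - 1e-12) & (est.freqs <= band[1] + 1e-12)
    band_mean = float(np.nanmean(c12[sel])) if sel.any() else float("nan")
    return CoherenceResult(
        freqs=est.freqs, c12=c12, band=tuple(band),
        band_mean=band_mean, L=est.L, period=period,
    )


def significance_threshold(L, alpha=0.05):
    """Coherence-scale significance level Z = 1 − α^{1/(L−1)}."""
    if L < 2:
        raise ValueError("L must be at least 2")
    return 1.0 - alpha ** (1.0 / (L - 1))


# ---------------------------------------------------------------------------
# MVAR fitting (Levinson–Wiggins–Robinson)
# ---------------------------------------------------------------------------

@dataclass
class MvarModel:
    """Fitted multivariate AR model.

    ``coefs[i-1]`` is the (d x d) matrix A(i) for lag i = 1..p;
    ``sigma`` the innovation covariance of E(t).
    """

    coefs: np.ndarray  # (p, d, d)
    sigma: np.ndarray  # (d, d)
    fs: float
    label: str | None = None

    @property
    def order(self) -> int:
        return self.coefs.shape[0]

    @property
    def n_channels(self) -> int:
        return self.sigma.shape[0]

    def is_stable(self) -> bool:
        p, d, _ = self.coefs.shape
        if p == 0:
            return True
        comp = np.zeros((p * d, p * d))
        comp[:d] = np.hstack(list(self.coefs))
        if p > 1:
            comp[d:, :-d] = np.eye(d * (p - 1))
        return bool(np.max(np.abs(np.linalg.eigvals(comp))) < 1.0)


@dataclass
class OrderSelection:
    """AIC/BIC-optimal model orders and the configured final order."""

    aic_order: int
    bic_order: int
    configured_order: int
    aic: np.ndarray
    bic: np.ndarray


def _lag_covariances(trials, p):
    """Ensemble lag-covariance matrices R(0..p), R(k) = E[x_t x_{t-k}^T].

    ``trials`` is (n_trials, d, n_samples); each trial is demeaned and
    its biased lag covariances averaged across trials.
    """
    trials = np.asarray(trials, dtype=float)
    n_trials, d, n = trials.shape
    if n <= p:
        raise ValueError(f"trials of {n} samples cannot support order {p}")
    X = trials - trials.mean(axis=2, keepdims=True)
    R = np.zeros((p + 1, d, d))
    for k in range(p + 1):
        # R(k) = mean over t of x_t x_{t-k}^T
        a = X[:, :, k:]
        b = X[:, :, : n - k]
        R[k] = np.einsum("mit,mjt->ij", a, b) / (n_trials * (n - k))
    return R


def _lwr(R):
    """Whittle's multichannel Levinson recursion for the Yule–Walker system.

    Given R(0..p) returns (A, Sigma) with A of shape (p, d, d) solving
    R(k) = Σ_i A(i) R(k−i) for k = 1..p and Sigma the forward
    innovation covariance.
    """
    p = len(R) - 1
    d = R[0].shape[0]
    A = np.zeros((0, d, d))
    B = np.zeros((0, d, d))
    sig_f = R[0].copy()
    sig_b = R[0].copy()
    for m in range(1, p + 1):
        delta = R[m].copy()
        for i in range(1, m):
            delta -= A[i - 1] @ R[m - i]
        try:
            k_f = np.linalg.solve(sig_b.T, delta.T).T
            k_b = np.linalg.solve(sig_f.T, delta).T
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                f"singular residual covariance at lag {m}; try a lower order"
            ) from exc
        A_new = np.concatenate([A, k_f[None]], axis=0)
        B_new = np.concatenate([B, k_b[None]], axis=0)
        for i in range(1, m):
            A_new[i - 1] = A[i - 1] - k_f @ B[m - i - 1]
            B_new[i - 1] = B[i - 1] - k_b @ A[m - i - 1]
        sig_f_next = sig_f - k_f @ delta.T
        sig_b_next = sig_b - k_b @ delta
        A, B = A_new, B_new
        sig_f, sig_b = sig_f_next, sig_b_next
    sig_f = 0.5 * (sig_f + sig_f.T)
    return A, sig_f


def fit_mvar(data, window=None, p=10, label=None, ridge=1e-8) -> MvarModel:
    """Fit an MVAR model of order ``p`` by the LWR recursion.

    ``data`` is an :class:`EpochedSignals` (lag covariances are
    estimated per kept trial within ``window`` and averaged — the
    ensemble estimate) or a plain (d, n_samples) array.  ``ridge``
    scales a diagonal loading of R(0) (relative to its trace) that
    keeps the recursion well-posed on nearly deterministic signals; it
    is far below the sampling noise of any stochastic input.  A warning
    is issued when the fitted system is unstable, an error when the
    residual covariance becomes singular.
    """
    if isinstance(data, EpochedSignals):
        trials = data.time_slice(*window) if window is not None else data.kept()
        fs = data.fs
    else:
        arr = np.asarray(data, dtype=float)
        if arr.ndim != 2:
            raise ValueError("array input must be (channels, samples)")
        trials = arr[None]
        fs = 1.0
    n = trials.shape[2]
    if n <= p:
        raise ValueError(f"window of {n} samples cannot support order {p}")
    R = _lag_covariances(trials, p)
    if ridge:
        d = R[0].shape[0]
        R[0] += ridge * np.trace(R[0]) / d * np.eye(d)
    A, sigma = _lwr(R)
    model = MvarModel(coefs=A, sigma=sigma, fs=fs, label=label)
    if not model.is_stable():
        warnings.warn("fitted MVAR model is unstable", RuntimeWarning)
    return model


def select_order(data, p_max=20, configured=10, window=None) -> OrderSelection:
    """AIC/BIC over orders 1..p_max plus the configured final order.

    AIC(p) = ln det Σ_p + 2 p d² / N and BIC(p) = ln det Σ_p +
    p d² ln N / N, with Σ_p the LWR innovation covariance and N the
    effective sample count.
    """
    if isinstance(data, EpochedSignals):
        trials = data.time_slice(*window) if window is not None else data.kept()
    else:
        trials = np.asarray(data, dtype=float)[None]
    n_eff = trials.shape[0] * trials.shape[2]
    d = trials.shape[1]
    if trials.shape[2] <= p_max:
        raise ValueError(f"p_max={p_max} exceeds the per-trial sample budget")
    R = _lag_covariances(trials, p_max)
    aic = np.zeros(p_max)
    bic = np.zeros(p_max)
    for p in range(1, p_max + 1):
        _, sigma = _lwr(R[: p + 1])
        s, logdet = np.linalg.slogdet(sigma)
        if s <= 0:
            logdet = -np.inf
        k = p * d * d
        aic[p - 1] = logdet + 2.0 * k / n_eff
        bic[p - 1] = logdet + k * np.log(n_eff) / n_eff
    return OrderSelection(
        aic_order=int(np.argmin(aic)) + 1,
        bic_order=int(np.argmin(bic)) + 1,
        configured_order=configured,
        aic=aic, bic=bic,
    )


# ---------------------------------------------------------------------------
# transfer function and directed coherence
# ---------------------------------------------------------------------------

def transfer_function(model: MvarModel, freqs) -> np.ndarray:
    """H(f) = A(f)^{-1} with A(f) = I − Σ_i A(i) e^{−i2πf i / fs}.

    Returns an array of shape (n_freqs, d, d); raises naming the
    frequency if A(f) is numerically singular.
    """
    freqs = np.atleast_1d(np.asarray(freqs, dtype=float))
    p, d = model.order, model.n_channels
    lags = np.arange(1, p + 1)
    phase = np.exp(-2j * np.pi * np.outer(freqs, lags) / model.fs)
    Af = np.tile(np.eye(d, dtype=complex), (len(freqs), 1, 1))
    if p:
        Af -= np.einsum("fl,lij->fij", phase, model.coefs.astype(complex))
    H = np.empty_like(Af)
    for k in range(len(freqs)):
        try:
            H[k] = np.linalg.inv(Af[k])
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                f"A(f) singular at f = {freqs[k]:g} Hz"
            ) from exc
    return H


def spectral_matrix(model: MvarModel, freqs) -> np.ndarray:
    """Model spectral matrix S(f) = H(f) Σ H(f)^H (arbitrary scale)."""
    H = transfer_function(model, freqs)
    return H @ model.sigma @ np.conj(np.swapaxes(H, 1, 2))


@dataclass
class DirCohResult:
    """Directed coherence per direction with its significance threshold.

    ``dircoh[f, i, j]`` is the influence j → i at frequency f
    (diagonal entries hold the self terms of the normalization).
    """

    freqs: np.ndarray
    dircoh: np.ndarray  # (n_freqs, d, d)
    band: tuple
    band_means: np.ndarray  # (d, d)
    normalized: bool
    alpha: float = 0.05
    L: int | None = None

    @property
    def z(self) -> float | None:
        if self.L is None:
            return None
        return significance_threshold(self.L, self.alpha)

    def band_mean(self, to_ch: int, from_ch: int) -> float:
        """Band-mean directed coherence ``to_ch ← from_ch``."""
        return float(self.band_means[to_ch, from_ch])

    def significant(self, to_ch: int, from_ch: int) -> bool | None:
        z = self.z
        if z is None:
            return None
        return bool(self.band_mean(to_ch, from_ch) > z)

    def to_dict(self) -> dict:
        d = {
            "band": list(self.band),
            "normalized": self.normalized,
            "alpha": self.alpha,
            "L": self.L,
            "z": self.z,
        }
        n = self.band_means.shape[0]
        for i in range(n):
            for j in range(n):
                if i != j:
                    d[f"band_mean_{i}<-{j}"] = float(self.band_means[i, j])
        return d


def directed_coherence(model: MvarModel, freqs=None, band=BETA_BAND,
                       normalized=True, alpha=0.05, L=None) -> DirCohResult:
    """Frequency-resolved directed coherence from a fitted MVAR model.

    With ``normalized=True`` (default) the classical form bounded in
    [0, 1]: |H_ij|² σ_j² / Σ_k |H_ik|² σ_k², using the innovation
    variances σ_k².  With ``normalized=False`` the literal
    autospectrum-ratio reading |H_ij|² S_jj(f) / S_ii(f).  Band means
    are reported per direction; undefined bins (zero denominator) are
    NaN.
    """
    if freqs is None:
        freqs = np.arange(5.0, 40.0 + 0.5, 1.0)
    freqs = np.atleast_1d(np.asarray(freqs, dtype=float))
    H = transfer_function(model, freqs)
    H2 = np.abs(H) ** 2
    if normalized:
        sig2 = np.diag(model.sigma)
        num = H2 * sig2[None, None, :]
        denom = num.sum(axis=2, keepdims=True)
    else:
        S = spectral_matrix(model, freqs)
        auto = np.real(np.einsum("fii->fi", S))
        num = H2 * auto[:, None, :]
        denom = auto[:, :, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        dc = np.where(denom > 0, num / denom, np.nan)
    sel = (freqs >= band[0] - 1e-12) & (freqs <= band[1] + 1e-12)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        band_means = np.nanmean(dc[sel], axis=0) if sel.any() else \
            np.full(dc.shape[1:], np.nan)
    return DirCohResult(
        freqs=freqs, dircoh=dc, band=tuple(band), band_means=band_means,
        normalized=normalized, alpha=alpha, L=L,
    )
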