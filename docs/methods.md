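# Methods

`betalink` analyses bilateral sensorimotor EEG/TMS experiments in which a
cued index-finger abduction produces a movement-related beta
desynchronization (MRBD) followed by a post-movement beta synchronization
(PMBS), and in which the two primary motor cortices (CM1 contralateral,
IM1 ipsilateral — C3/C4 for right-hand movement) interact through
beta-band coupling and transcallosal inhibition.  This note describes the
models and procedures, the synthetic data they are validated on, and the
numerical choices made where the design was genuinely open.

## Preprocessing

Continuous recordings are zero-phase filtered (4th-order Butterworth
band-pass 0.5–40 Hz plus a 2nd-order 50 Hz IIR notch, both applied
forward–backward) and cut into stimulus-locked epochs from −0.25 s to
2.5 s at 1 kHz.  Zero-phase filtering is used because the ERSP landmark
rules below depend on latencies.

Artifact screening is trial-wise: with M(t) and SD(t) the per-time-point,
per-channel mean and standard deviation across all trials, a trial is
rejected when any of its samples strictly exceeds M ± k·SD (k = 5).  The
boundary is inclusive (|x − M| = k·SD keeps the sample), so degenerate
SD = 0 data survive; the statistics are always computed across all trials
of the container, which makes the operation idempotent.  Screening is per
channel; pooling across channels would be the alternative reading, but
per-channel screening is the stricter and more common convention.
Rejection granularity is the whole trial — no sample interpolation.

## Time–frequency power and ERSP features

Power is computed per frequency f (5–40 Hz, 0.25 Hz steps) with a
Hanning-tapered sliding window of three cycles (ΔT = 3/f s) advanced in
20 ms steps, implemented as complex convolution; power is averaged across
kept trials.  Window positions that would extend beyond the epoch are
marked unavailable (NaN).  Relative power is

    RP(n) = (P_n − P_rest) / P_rest × 100  [%],

with P_rest the mean power over the −0.25–0 s baseline at that frequency
and channel.  Below ≈ 6 Hz the three-cycle window cannot be centered
inside the 0.25 s baseline at all; those frequencies are reported as NaN
rows (with a warning) rather than erroring, mirroring the behaviour of
the standard sliding-window toolboxes.  The beta timecourse is the
unweighted mean of RP over the 14–30 Hz bins (inclusive), skipping
unavailable cells.

MRBD/PMBS landmarks use the ±10% threshold convention.  The implemented
rule is extremum-anchored: the MRBD burst is the contiguous run of
timecourse points at or below −10% that contains the post-onset global
minimum; its first point is the onset, the first later point above the
threshold the end.  PMBS is analogous with +10% and the maximum, searched
from the MRBD end.  Runs shorter than the sustain count (3 time steps =
60 ms, configurable) are ignored.  Anchoring on the extremum rather than
on the first threshold crossing makes the landmarks robust to brief noise
excursions that would otherwise capture the burst; the burst values are
unchanged for clean traces.  The MRBD/PMBS *value* is the mean RP over a
200 ms window centered on the trough/peak, clipped (not dropped) at epoch
edges.  When the extremum is attained over a plateau the arg-extremum is
numerically degenerate; points within a relative tolerance of 10⁻³ of the
extremum are treated as ties and the central index of the tie run is
used.  On noisy data the tolerance is far below the noise level and the
rule reduces to the plain arg-extremum.

The movement-task onset anchoring the landmark search is the imperative
stimulus (t = 0); epochs are stimulus-locked and no EMG-onset detection
is performed.

## Sectioned coherence

For a (start, stop) analysis window, each kept trial's window is divided
into 50 ms nonoverlapping sections pooled across trials (L sections in
total).  Sections are demeaned, Hanning-windowed, zero-padded to 1 s and
Fourier transformed; zero-padding reconciles the 50 ms section length
(native 20 Hz bin spacing) with a 1 Hz display grid, and the
native-resolution spectra are retained alongside.  Cross- and
autospectra are section averages; both are smoothed with the three-point
0.25/0.5/0.25 kernel (endpoints use the two available weights
renormalized to sum to one) before forming

    C12(f) = |X12(f)|² / (S1(f) S2(f)) ∈ [0, 1].

The beta-band summary is the mean over the 14–30 Hz bins.  The
analysis windows for "MRBD period" and "PMBS period" coupling are taken
from the extracted landmarks (onset to end) of the contralateral
channel's trial-averaged timecourse, with fixed fallbacks (0–1 s and
1–2 s) when a burst is absent.

Because a 50 ms Hanning section spans the whole beta band with a single
resolution cell, the band mean has the statistics of roughly one
independent coherence estimate: SD ≈ √(2C/L)·(1−C) (≈ 0.02 at C = 0.43,
L = 600).  The estimator's small-sample bias is ≈ (1−C)/L for weak
coupling, which the test suite verifies at C = 0.

## MVAR directed coherence

A bivariate AR model X(t) = Σᵢ A(i) X(t−i) + E(t) of order p = 10
(default; AIC/BIC-optimal orders are also reported) is fitted by solving
the multivariate Yule–Walker equations with the Levinson–Wiggins–Robinson
(Whittle) recursion.  Lag covariances are estimated per trial (demeaned,
biased normalization) and averaged across trials — an ensemble estimate
suited to epoched data.  A diagonal loading of 10⁻⁸·tr(R(0))/d is added
to R(0); this keeps the recursion well-posed on nearly deterministic
inputs and is orders of magnitude below the sampling noise of any
stochastic signal (the LWR solution agrees with direct least-squares
regression to < 10⁻² on simulated data).  Stability is checked via the
companion-matrix spectral radius; unstable fits warn rather than error,
since short nonstationary burst windows can produce borderline fits whose
transfer function is still evaluable.

With H(f) = A(f)⁻¹, A(f) = I − Σᵢ A(i) e^(−i2πfi/fs), directed coherence
is reported in the classical normalized form

    DirCoh_{i←j}(f) = |H_ij(f)|² σ_j² / Σ_k |H_ik(f)|² σ_k²,

where σ_k² are the innovation variances.  This form is bounded in [0, 1]
and sums to 1 over sources for diagonal innovation covariance, which is
the scale on which the significance threshold operates.  The literal
autospectrum-ratio reading |H_ij|² S_jj(f)/S_ii(f) (unbounded) is
available behind `normalized=False`.  A band-mean value is significant
when it exceeds Z = 1 − α^(1/(L−1)) (α = 0.05), with L the pooled section
count of the same analysis window.

## MEP amplitudes and IHI

MEP trials are 5 kHz EMG sweeps; the amplitude is the peak-to-peak
excursion within a 15–50 ms window after the test stimulus (configurable;
the window spans typical hand-muscle MEP latencies).  Interhemispheric
inhibition is the ratio of condition means,

    IHI = mean(CS-conditioned amplitudes) / mean(single-TS amplitudes),

reported as a fraction (0.52-style) with a percentage field alongside.
The mean-of-amplitudes ratio (rather than a mean of per-trial ratios) is
used because single-pulse and paired-pulse trials are randomly
interleaved and unpaired.  Values below 1 indicate inhibition.

## Synthetic data: what it emulates and what it does not

The generator reproduces the statistical structure the analyses consume:

- **Beta carrier.**  Two modes.  `band_noise` is Gaussian noise flat in
  14–30 Hz with the sample variance scaled exactly to its target — the
  carrier for all coupling work, because the shared-source pair
  x = s + n₁, y = s + n₂ then has the closed-form in-band coherence
  var_s²/(var_s + var_n)².  `stratified_tones` (default) draws one
  constant-amplitude random-phase sinusoid per trial, with trial
  frequencies stratified uniformly across the band.  Because each
  trial's short-window spectral power then scales deterministically with
  the squared envelope, a plateau with amplitude factor g is recovered by
  the ERSP pipeline as (g² − 1)·100 essentially without sampling error.
  With a Gaussian carrier the same 60-trial, 200-ms-window estimator has
  a sampling SD of 6–11 percentage points — the irreducible trial-to-trial
  variability of band-limited noise — so exact parameter-recovery checks
  are only meaningful in the tone mode; this is the purpose of the
  pure-band parameter-recovery mode.
- **Envelopes.**  Plateaus with raised-cosine ramps (50 ms default);
  step edges would leak broadband power across the TFR.
- **Background.**  Optional 1/f^α noise, either full-spectrum (`pink`) or
  with the beta band excised (`pink_notched`, which keeps in-band ground
  truth exact while adding broadband realism).  The in-band
  beta-to-background variance ratio is configurable (default 5).
- **Coupling.**  `shared_source` mixes a common band-limited source into
  both channels; `lagged_ar` generates a unidirectionally coupled AR
  pair (x drives y through a lagged coefficient) with a known causal
  direction, used to validate directed-coherence direction recovery.
- **MEPs.**  Peak-to-peak amplitudes drawn from normal distributions
  truncated at zero (amplitudes are nonnegative), imposed on a biphasic
  waveform template at 22 ms latency over Gaussian baseline noise.

Not modelled: electrode geometry and volume conduction, eye-blink or EMG
artifacts, multi-subject variance components, and physical amplitude
units (amplitudes are unitless, interpretable as µV).  Passing
parameter-recovery tests therefore demonstrates correctness of the
estimators under the generative model, not robustness to the full
artifact structure of human EEG.

## Problem sizes and defaults

Recovery simulations use 60 trials per condition (three 20-trial blocks
is the standard session in this paradigm), 0.5 s coherence windows at
50 ms sections (L = 600 pooled sections), and 30 + 30 MEP trials — the
trial counts of the emulated experiment.  All generators and the
bootstrap are driven by explicit integer seeds; a fixed seed reproduces
every output bit-for-bit.

## Known limitations

- The coherence band mean carries ≈ 0.02 SD at L = 600 because the 50 ms
  section length makes the whole beta band one resolution cell.
- MVAR fits on burst windows treat the windowed data as stationary;
  bursts with strong within-window envelope change can yield borderline
  unstable fits (flagged by a warning).
- The ±10% landmark rules operate on the trial-averaged timecourse;
  single-trial ERSP statistics are out of scope.
- Correlation tooling (Pearson r with a 1000-resample percentile
  bootstrap CI) operates on condition-level summary rows; ANOVA-family
  statistics are deliberately not re-implemented — the exported tidy
  tables are consumable by any statistics package.
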