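"""Motor-evoked-potential amplitudes and interhemispheric inhibition.

In the paired-pulse TMS protocol a conditioning stimulus (CS) over the
ipsilateral motor cortex precedes, by 10 ms, a test stimulus (TS) over
the contralateral motor cortex.  Interhemispheric inhibition (IHI) is
quantified as the ratio of the mean conditioned MEP amplitude to the
mean unconditioned (single-TS) MEP amplitude; values below 1 indicate
inhibition.  Amplitudes are peak-to-peak within a post-stimulus search
window spanning typical hand-muscle MEP latencies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "MepTrial",
    "IhiResult",
    "mep_peak_to_peak",
    "compute_ihi",
    "write_mep_csv",
    "read_mep_csv",
]

#: default peak-to-peak search window, seconds after the test stimulus
DEFAULT_SEARCH_WINDOW = (0.015, 0.050)


@dataclass
class MepTrial:
    """One EMG sweep containing a motor-evoked potential.

    waveform is in mV, sampled at ``fs`` (5 kHz by convention);
    ``stimulus_time`` is the test-stimulus time in seconds from the
    start of the sweep.  ``mode`` is ``"ts"`` (single test stimulus) or
    ``"cs_ts"`` (paired conditioning + test stimulus).
    """

    waveform: np.ndarray
    fs: float = 5000.0
    stimulus_time: float = 0.05
    mode: str = "ts"
    condition: tuple | None = None
    amplitude: float | None = None

    def __post_init__(self):
        self.waveform = np.asarray(self.waveform, dtype=float)
        if self.mode not in ("ts", "cs_ts"):
            raise ValueError(f"mode must be 'ts' or 'cs_ts', got {self.mode!r}")


@dataclass
class IhiResult:
    """Condition-level interhemispheric inhibition."""

    condition: tuple | None
    mean_ts_amplitude: float
    mean_cs_amplitude: float
    ihi: float
    n_ts: int
    n_cs: int
    ts_amplitudes: np.ndarray = field(repr=False, default=None)
    cs_amplitudes: np.ndarray = field(repr=False, default=None)

    @property
    def ihi_percent(self) -> float:
        """IHI expressed as CS·100/TS, the percentage convention."""
        return self.ihi * 100.0

    def to_dict(self) -> dict:
        return {
            "condition": list(self.condition) if self.condition else None,
            "mean_ts_amplitude_mV": self.mean_ts_amplitude,
            "mean_cs_amplitude_mV": self.mean_cs_amplitude,
            "ihi": self.ihi,
            "ihi_percent": self.ihi_percent,
            "n_ts": self.n_ts,
            "n_cs": self.n_cs,
        }


def mep_peak_to_peak(trial: MepTrial, search_window=DEFAULT_SEARCH_WINDOW) -> float:
    """Peak-to-peak amplitude (mV) within the post-TS search window.

    The window is given in seconds after ``trial.stimulus_time`` and
    must lie inside the recorded sweep.
    """
    lo = trial.stimulus_time + search_window[0]
    hi = trial.stimulus_time + search_window[1]
    n = trial.waveform.shape[-1]
    i0 = int(round(lo * trial.fs))
    i1 = int(round(hi * trial.fs))
    if i0 < 0 or i1 > n - 1 or i1 <= i0:
        raise ValueError(
            f"search window [{lo:.4f}, {hi:.4f}] s falls outside the "
            f"{n / trial.fs:.4f} s sweep"
        )
    seg = trial.waveform[i0 : i1 + 1]
    return float(seg.max() - seg.min())


def compute_ihi(ts_trials, cs_trials, search_window=DEFAULT_SEARCH_WINDOW,
                condition=None) -> IhiResult:
    """Mean-of-amplitudes inhibition ratio CS/TS.

    Extracts each trial's peak-to-peak amplitude (stored back on the
    trial), then forms mean(CS amplitudes) / mean(TS amplitudes).  The
    ratio uses condition means rather than per-trial pairing because TS
    and CS trials are interleaved at random and unpaired.
    """
    if len(ts_trials) < 1 or len(cs_trials) < 1:
        raise ValueError("need at least one trial per mode")
    ts_amp = np.array([mep_peak_to_peak(t, search_window) for t in ts_trials])
    cs_amp = np.array([mep_peak_to_peak(t, search_window) for t in cs_trials])
    for t, a in zip(ts_trials, ts_amp):
        t.amplitude = float(a)
    for t, a in zip(cs_trials, cs_amp):
        t.amplitude = float(a)
    mean_ts = float(ts_amp.mean())
    mean_cs = float(cs_amp.mean())
    if mean_ts == 0:
        raise ZeroDivisionError("mean TS amplitude is zero; IHI undefined")
    return IhiResult(
        condition=condition,
        mean_ts_amplitude=mean_ts,
        mean_cs_amplitude=mean_cs,
        ihi=mean_cs / mean_ts,
        n_ts=len(ts_trials),
        n_cs=len(cs_trials),
        ts_amplitudes=ts_amp,
        cs_amplitudes=cs_amp,
    )


def write_mep_csv(trials, path) -> Path:
    """One trial per row: metadata columns then waveform samples."""
    rows = []
    for t in trials:
        row = {
            "mode": t.mode,
            "fs": t.fs,
            "stimulus_time": t.stimulus_time,
            "condition": "/".join(map(str, t.condition)) if t.condition else "",
        }
        row.update({f"s{i}": v for i, v in enumerate(t.waveform)})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
    return Path(path)


def read_mep_csv(path):
    """Inverse of :func:`write_mep_csv`."""
    df = pd.read_csv(path)
    meta_cols = ["mode", "fs", "stimulus_time", "condition"]
    wave_cols = [c for c in df.columns if c not in meta_cols]
    wave_cols.sort(key=lambda c: int(c[1:]))
    trials = []
    for _, row in df.iterrows():
        cond_raw = row["condition"]
        cond = (tuple(str(cond_raw).split("/"))
                if isinstance(cond_raw, str) and cond_raw else None)
        trials.append(
            MepTrial(
                waveform=row[wave_cols].to_numpy(dtype=float),
                fs=float(row["fs"]),
                stimulus_time=float(row["stimulus_time"]),
                mode=str(row["mode"]),
                condition=cond,
            )
        )
    return trials
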