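"""Epoched-signal container and on-disk layout.

The central in-memory object of the pipeline is :class:`EpochedSignals`,
a ``trials x channels x time`` array of stimulus-locked EEG amplitudes
together with its sampling rate and epoch time axis.  For right-hand
movement the two channels are C3 (contralateral motor cortex, CM1) and
C4 (ipsilateral motor cortex, IM1).

On disk, one condition is stored as a ``<name>.npy`` array next to a
``<name>.json`` sidecar holding the sampling rate, epoch start, channel
labels, condition label, kept-trial mask and the generating seed.
Continuous EDF recordings can be read through MNE when it is installed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["EpochedSignals", "save_epochs", "load_epochs", "read_raw_edf",
           "export_edf"]


@dataclass
class EpochedSignals:
    """Stimulus-locked trials for one condition.

    Parameters
    ----------
    data : ndarray, shape (n_trials, n_channels, n_times)
        Amplitudes (interpreted as microvolt for EEG).
    fs : float
        Sampling rate in Hz.
    t0 : float
        Time of the first sample relative to the stimulus, in seconds
        (−0.25 for the standard epoch window).
    channel_labels : tuple of str
        Channel names; ``("C3", "C4")`` maps to (CM1, IM1) for
        right-hand movement.
    condition : str or None
        Condition label, e.g. ``"ballistic"``.
    kept_mask : ndarray of bool, shape (n_trials,)
        Trials surviving artifact screening.  All-true on construction.
    """

    data: np.ndarray
    fs: float
    t0: float = -0.25
    channel_labels: tuple = ("C3", "C4")
    condition: str | None = None
    kept_mask: np.ndarray = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(
                f"data must be trials x channels x time, got shape {self.data.shape}"
            )
        if self.kept_mask is None:
            self.kept_mask = np.ones(self.data.shape[0], dtype=bool)
        else:
            self.kept_mask = np.asarray(self.kept_mask, dtype=bool)
            if self.kept_mask.shape != (self.data.shape[0],):
                raise ValueError("kept_mask must have one entry per trial")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_times(self) -> int:
        return self.data.shape[2]

    @property
    def times(self) -> np.ndarray:
        """Epoch time axis in seconds relative to the stimulus."""
        return self.t0 + np.arange(self.n_times) / self.fs

    def kept(self) -> np.ndarray:
        """Data restricted to trials surviving artifact screening."""
        return self.data[self.kept_mask]

    def copy(self) -> "EpochedSignals":
        return EpochedSignals(
            data=self.data.copy(),
            fs=self.fs,
            t0=self.t0,
            channel_labels=tuple(self.channel_labels),
            condition=self.condition,
            kept_mask=self.kept_mask.copy(),
            meta=dict(self.meta),
        )

    def time_slice(self, start: float, stop: float) -> np.ndarray:
        """Kept-trial data within ``[start, stop]`` seconds (inclusive)."""
        t = self.times
        sel = (t >= start - 1e-12) & (t <= stop + 1e-12)
        return self.kept()[:, :, sel]


def save_epochs(epochs: EpochedSignals, directory, name: str | None = None) -> Path:
    """Write one condition to ``<dir>/<name>.npy`` + ``<name>.json``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    name = name or (epochs.condition or "epochs")
    np.save(directory / f"{name}.npy", epochs.data)
    sidecar = {
        "fs": epochs.fs,
        "t0": epochs.t0,
        "channel_labels": list(epochs.channel_labels),
        "condition": epochs.condition,
        "kept_mask": epochs.kept_mask.astype(int).tolist(),
        "meta": epochs.meta,
    }
    with open(directory / f"{name}.json", "w") as fh:
        json.dump(sidecar, fh, indent=1)
    return directory / f"{name}.npy"


def load_epochs(directory, name: str) -> EpochedSignals:
    """Read one condition written by :func:`save_epochs`."""
    directory = Path(directory)
    data = np.load(directory / f"{name}.npy")
    with open(directory / f"{name}.json") as fh:
        sidecar = json.load(fh)
    return EpochedSignals(
        data=data,
        fs=sidecar["fs"],
        t0=sidecar["t0"],
        channel_labels=tuple(sidecar["channel_labels"]),
        condition=sidecar.get("condition"),
        kept_mask=np.asarray(sidecar["kept_mask"], dtype=bool),
        meta=sidecar.get("meta", {}),
    )


def read_raw_edf(path, channels=("C3", "C4")):
    """Read a continuous EDF recording, returning ``(data, fs)``.

    ``data`` has shape (n_channels, n_samples) restricted to the
    requested channels.  Requires MNE (``pip install betalink[edf]``).
    """
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - environment dependent
        raise ImportError(
            "Reading EDF requires MNE; install the 'edf' extra"
        ) from exc
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    picks = [raw.ch_names.index(ch) for ch in channels]
    return raw.get_data(picks=picks), float(raw.info["sfreq"])


def export_edf(epochs: EpochedSignals, path) -> Path:
    """Export kept trials, concatenated in time, to an EDF file.

    Requires MNE together with an EDF-writer backend (``edfio``); an
    informative ImportError is raised when either is missing.
    """
    try:
        import mne
        import mne.export
    except ImportError as exc:  # pragma: no cover - environment dependent
        raise ImportError(
            "EDF export requires MNE with an EDF writer backend (edfio)"
        ) from exc
    data = epochs.kept()
    cont = data.transpose(1, 0, 2).reshape(epochs.n_channels, -1)
    info = mne.create_info(list(epochs.channel_labels), epochs.fs, "eeg")
    raw = mne.io.RawArray(cont * 1e-6, info, verbose="error")  # µV -> V
    mne.export.export_raw(str(path), raw, fmt="edf", verbose="error")
    return Path(path)
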