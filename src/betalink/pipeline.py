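"""End-to-end orchestration: conditions, reports, and correlations.

``run_condition`` sequences the analysis stages in acquisition order —
artifact screening, time–frequency power with baseline normalization,
MRBD/PMBS feature extraction, sectioned interhemispheric coherence and
MVAR directed coherence over the MRBD and PMBS windows, and (when MEP
data are present) the interhemispheric-inhibition ratio.  The analysis
windows for "MRBD period" and "PMBS period" connectivity are taken
from the extracted landmarks (onset to end of each burst) on the
trial-averaged contralateral timecourse; when a burst is absent its
connectivity block is skipped.

``pearson_bootstrap`` provides the correlation summary used to relate
speed, PMBS, coupling and IHI across condition-level rows: Pearson's r
with a percentile confidence interval from paired bootstrap resamples.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import connectivity as cn
from . import ersp as _ersp
from . import ihi as _ihi
from . import preprocess as pp
from . import synthgen as sg
from .signals import EpochedSignals

__all__ = [
    "RunConfig",
    "ConditionReport",
    "run_condition",
    "pearson_bootstrap",
    "export_report",
    "SCHEMA_VERSION",
]

logger = logging.getLogger(__name__)

SCHEMA_VERSION = "1"

#: fallback connectivity windows (s) when a burst is not detected
FALLBACK_MRBD_WINDOW = (0.0, 1.0)
FALLBACK_PMBS_WINDOW = (1.0, 2.0)


@dataclass
class RunConfig:
    """Everything one end-to-end run needs.

    Exactly one input source is used per condition: a synthetic-EEG
    configuration (``synth``) or a path pair written by
    :func:`betalink.signals.save_epochs` (``data_dir`` + condition
    name).  ``mep`` optionally adds a synthetic MEP configuration or a
    CSV path of recorded trials.
    """

    conditions: tuple = ("ballistic",)
    synth: dict = field(default_factory=dict)        # per-condition SynthEegConfig kwargs
    data_dir: str | None = None
    mep: dict = field(default_factory=dict)          # per-condition SynthMepConfig kwargs / csv path
    artifact_k: float = 5.0
    tfr: dict = field(default_factory=dict)          # TfrConfig kwargs
    beta_band: tuple = (14.0, 30.0)
    section_length: float = 0.050
    mvar_order: int = 10
    out_dir: str = "betalink_out"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "conditions" in raw:
            raw["conditions"] = tuple(raw["conditions"])
        if "beta_band" in raw:
            raw["beta_band"] = tuple(raw["beta_band"])
        return cls(**raw)

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class ConditionReport:
    """All condition-level results plus provenance."""

    condition: str
    n_trials: int
    n_kept: int
    ersp_features: list                      # ErspFeatures per channel
    coherence: dict                          # period -> CoherenceResult
    dircoh: dict                             # period -> DirCohResult
    ihi: _ihi.IhiResult | None
    provenance: dict

    def to_dict(self) -> dict:
        return {
            "schema_version": SCHEMA_VERSION,
            "condition": self.condition,
            "n_trials": self.n_trials,
            "n_kept": self.n_kept,
            "ersp": [f.to_dict() for f in self.ersp_features],
            "coherence": {k: v.to_dict() for k, v in self.coherence.items()},
            "dircoh": {k: v.to_dict() for k, v in self.dircoh.items()},
            "ihi": self.ihi.to_dict() if self.ihi is not None else None,
            "provenance": self.provenance,
        }

    def scalar_rows(self) -> pd.DataFrame:
        """Flat table with one row per exported scalar metric."""
        rows = []

        def add(metric, value, **extra):
            if value is None:
                return
            rows.append({"condition": self.condition, "metric": metric,
                         "value": value, **extra})

        for f in self.ersp_features:
            for key, val in f.to_dict().items():
                if key != "channel" and val is not None:
                    add(f"ersp.{key}", val, channel=f.channel)
        for period, res in self.coherence.items():
            add(f"coherence.band_mean.{period}", res.band_mean, L=res.L)
        for period, res in self.dircoh.items():
            labels = ("CM1", "IM1")
            for i in range(2):
                for j in range(2):
                    if i != j:
                        add(f"dircoh.{labels[i]}<-{labels[j]}.{period}",
                            res.band_mean(i, j), L=res.L)
        if self.ihi is not None:
            add("ihi.ratio", self.ihi.ihi)
            add("ihi.percent", self.ihi.ihi_percent)
        return pd.DataFrame(rows)


def _load_condition_epochs(cfg: RunConfig, condition: str) -> EpochedSignals:
    if condition in cfg.synth or not cfg.data_dir:
        kwargs = dict(cfg.synth.get(condition, {}))
        cond_offset = int(hashlib.sha256(condition.encode()).hexdigest()[:4], 16)
        kwargs.setdefault("seed", (cfg.seed + cond_offset) % (2**31 - 1))
        if "envelope_per_channel" in kwargs:
            kwargs["envelope_per_channel"] = tuple(
                tuple(tuple(p) for p in ch) for ch in kwargs["envelope_per_channel"]
            )
        epochs = sg.gen_bilateral_epochs(sg.SynthEegConfig(**kwargs))
        epochs.condition = condition
        return epochs
    from .signals import load_epochs

    return load_epochs(cfg.data_dir, condition)


def _burst_window(feat: _ersp.ErspFeatures, which: str, times) -> tuple | None:
    if which == "mrbd":
        lo, hi = feat.mrbd_onset, feat.mrbd_end
    else:
        lo, hi = feat.pmbs_latency, feat.pmbs_end
    if lo is None:
        return None
    if hi is None:
        hi = float(times[-1])
    return (lo, hi)


def run_condition(cfg: RunConfig, condition: str) -> ConditionReport:
    """Run preprocess → ersp → connectivity → ihi for one condition."""
    epochs = _load_condition_epochs(cfg, condition)
    stage = "preprocess"
    try:
        epochs = pp.reject_artifacts(epochs, pp.ArtifactParams(cfg.artifact_k))
        stage = "ersp"
        tfr_cfg = _ersp.TfrConfig(**cfg.tfr) if cfg.tfr else _ersp.TfrConfig()
        tfr = _ersp.compute_tfr(epochs, tfr_cfg)
        rpm = _ersp.baseline_normalize(tfr, tfr_cfg.baseline_window)
        feats = _ersp.extract_all_channels(rpm, band=cfg.beta_band)
        times, _ = _ersp.beta_timecourse(rpm, cfg.beta_band)

        stage = "connectivity"
        coh, dc = {}, {}
        cm1 = feats[0]  # contralateral channel drives the window choice
        for period, fallback in (("mrbd", FALLBACK_MRBD_WINDOW),
                                 ("pmbs", FALLBACK_PMBS_WINDOW)):
            win = _burst_window(cm1, period, times) or fallback
            win = (max(win[0], epochs.times[0]), min(win[1], epochs.times[-1]))
            if win[1] - win[0] < cfg.section_length:
                logger.warning("%s window too short for one section; skipped", period)
                continue
            est = cn.section_spectra(epochs, win, cfg.section_length)
            coh[period] = cn.coherence(est, band=cfg.beta_band, period=period)
            n_win = int((win[1] - win[0]) * epochs.fs)
            if n_win > cfg.mvar_order * 10:
                model = cn.fit_mvar(epochs, win, p=cfg.mvar_order, label=period)
                dc[period] = cn.directed_coherence(
                    model, band=cfg.beta_band, L=est.L
                )
            else:
                logger.warning("%s window too short for MVAR order %d; "
                               "directed coherence skipped", period, cfg.mvar_order)

        stage = "ihi"
        ihi_res = None
        mep_src = cfg.mep.get(condition)
        if mep_src is not None:
            if isinstance(mep_src, (str, Path)):
                trials = _ihi.read_mep_csv(mep_src)
                ts = [t for t in trials if t.mode == "ts"]
                cs = [t for t in trials if t.mode == "cs_ts"]
            else:
                mep_cfg = sg.SynthMepConfig(**{"seed": cfg.seed + 101, **mep_src})
                ts, cs = sg.gen_mep_trials(mep_cfg)
            ihi_res = _ihi.compute_ihi(ts, cs, condition=(condition,))
    except Exception as exc:
        raise RuntimeError(f"condition {condition!r} failed at stage "
                           f"{stage}: {exc}") from exc

    provenance = {
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "schema_version": SCHEMA_VERSION,
    }
    return ConditionReport(
        condition=condition,
        n_trials=epochs.n_trials,
        n_kept=int(epochs.kept_mask.sum()),
        ersp_features=feats,
        coherence=coh,
        dircoh=dc,
        ihi=ihi_res,
        provenance=provenance,
    )


def pearson_bootstrap(x, y, n_boot=1000, ci=95.0, seed=None):
    """Pearson r with a percentile bootstrap confidence interval.

    Resampling is paired (rows resampled with replacement); returns
    ``(r, (ci_low, ci_high))``.  Degenerate (zero-variance) input
    raises.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("x and y must be equal-length 1-D arrays of length >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    r = float(np.corrcoef(x, y)[0, 1])
    rng = np.random.default_rng(seed)
    n = len(x)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, n)
        xb, yb = x[idx], y[idx]
        if np.std(xb) == 0 or np.std(yb) == 0:
            boots[b] = np.nan
            continue
        boots[b] = np.corrcoef(xb, yb)[0, 1]
    lo, hi = np.nanpercentile(boots, [(100 - ci) / 2, 100 - (100 - ci) / 2])
    return r, (float(lo), float(hi))


def export_report(report: ConditionReport, out_dir, formats=("json", "csv")):
    """Write the report as JSON (full) and/or CSV (flat scalar table)."""
    supported = ("json", "csv")
    unknown = [f for f in formats if f not in supported]
    if unknown:
        raise ValueError(
            f"unknown format(s) {unknown}; supported: {list(supported)}"
        )
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    if "json" in formats:
        path = out_dir / f"{report.condition}_report.json"
        with open(path, "w") as fh:
            json.dump(report.to_dict(), fh, indent=1, default=_json_default)
        written.append(path)
    if "csv" in formats:
        path = out_dir / f"{report.condition}_metrics.csv"
        report.scalar_rows().to_csv(path, index=False)
        written.append(path)
    return written


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
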