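"""Preprocessing: band-pass filter, imputation + z-scoring, windowing and
baseline correction.

The pipeline order is filter -> impute/z-score -> segment/baseline. Each
trial is cut into consecutive non-overlapping windows; within each window the
first ``baseline_len`` seconds are the resting epoch whose per-channel mean
is subtracted from the entire window (the baseline samples are kept, the
window is merely re-centered on its resting activity).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .synthetic import EEGRecordingSet

logger = logging.getLogger(__name__)

__all__ = [
    "PreprocConfig",
    "SegmentSet",
    "bandpass_filter",
    "impute_and_zscore",
    "segment_and_baseline",
    "preprocess_pipeline",
]

# per-dataset profiles: (window_len s, baseline_len s)
_PROFILES = {"seed": (8.0, 2.0), "deap": (2.0, 1.0)}


@dataclass
class PreprocConfig:
    band: tuple[float, float] = (1.0, 50.0)
    window_len: float = 8.0
    baseline_len: float = 2.0
    filter_order: int = 4
    zscore_eps: float = 1e-8

    def __post_init__(self):
        low, high = self.band
        if not 0 < low < high:
            raise ValueError(f"PreprocConfig.band must satisfy 0 < low < high, got {self.band}")
        if not 0 < self.baseline_len < self.window_len:
            raise ValueError("PreprocConfig requires 0 < baseline_len < window_len")

    @classmethod
    def profile(cls, name: str, **overrides) -> "PreprocConfig":
        """Bundled window/baseline lengths for the 'seed' and 'deap' layouts."""
        try:
            window_len, baseline_len = _PROFILES[name.lower()]
        except KeyError:
            raise ValueError(f"unknown profile {name!r}; available: {sorted(_PROFILES)}") from None
        kwargs = {"window_len": window_len, "baseline_len": baseline_len}
        kwargs.update(overrides)
        return cls(**kwargs)


@dataclass
class SegmentSet:
    """Baseline-corrected fixed-length windows (segment x channel x time)."""

    segments: np.ndarray
    labels: np.ndarray
    subject_ids: np.ndarray
    fs: float
    provenance: list[tuple[int, int]]  # (trial_id, window_index) per segment

    @property
    def n_segments(self) -> int:
        return self.segments.shape[0]

    @property
    def n_channels(self) -> int:
        return self.segments.shape[1]


def bandpass_filter(rec: EEGRecordingSet, cfg: PreprocConfig) -> EEGRecordingSet:
    """Zero-phase Butterworth band-pass of every channel; shapes unchanged."""
    low, high = cfg.band
    if high >= rec.fs / 2:
        raise ValueError(f"band high edge {high} Hz violates Nyquist for fs={rec.fs}")
    sos = butter(cfg.filter_order, [low, high], btype="bandpass", fs=rec.fs, output="sos")
    out = rec.copy()
    out.trials = [sosfiltfilt(sos, t, axis=-1) for t in out.trials]
    return out


def impute_and_zscore(rec: EEGRecordingSet, cfg: PreprocConfig) -> EEGRecordingSet:
    """Per trial, per channel: NaN samples -> within-trial channel mean, then
    standardize the channel to mean 0 / sd 1 (sd below ``zscore_eps`` maps the
    channel to zeros instead of dividing by ~0)."""
    out = rec.copy()
    for ti, trial in enumerate(out.trials):
        missing = np.isnan(trial)
        if missing.any():
            all_missing = missing.all(axis=-1)
            if all_missing.any():
                ch = int(np.flatnonzero(all_missing)[0])
                raise ValueError(f"trial {ti} channel {ch} is entirely missing; cannot impute")
            means = np.nanmean(trial, axis=-1, keepdims=True)
            trial = np.where(missing, means, trial)
        mu = trial.mean(axis=-1, keepdims=True)
        sd = trial.std(axis=-1, keepdims=True)
        z = np.where(sd < cfg.zscore_eps, 0.0, (trial - mu) / np.where(sd < cfg.zscore_eps, 1.0, sd))
        out.trials[ti] = z
    return out


def segment_and_baseline(rec: EEGRecordingSet, cfg: PreprocConfig) -> SegmentSet:
    """Cut trials into non-overlapping windows and baseline-correct each.

    Calibrated window = window - mean(baseline portion), per channel; the
    trailing remainder of a trial shorter than one window is dropped, and a
    trial shorter than one window is skipped with a warning.
    """
    win = int(round(cfg.window_len * rec.fs))
    base = int(round(cfg.baseline_len * rec.fs))
    segments, labels, subjects, provenance = [], [], [], []
    for ti, trial in enumerate(rec.trials):
        n_win = trial.shape[-1] // win
        if n_win == 0:
            logger.warning("trial %d shorter than one window (%d < %d samples); skipped", ti, trial.shape[-1], win)
            continue
        for wi in range(n_win):
            seg = trial[:, wi * win : (wi + 1) * win]
            seg = seg - seg[:, :base].mean(axis=-1, keepdims=True)
            segments.append(seg)
            labels.append(rec.labels[ti])
            subjects.append(rec.subject_ids[ti])
            provenance.append((ti, wi))
    if not segments:
        raise ValueError("no trial was long enough for a single window")
    return SegmentSet(np.stack(segments), np.array(labels), np.array(subjects), rec.fs, provenance)


def preprocess_pipeline(rec: EEGRecordingSet, cfg: PreprocConfig) -> SegmentSet:
    """filter -> impute/z-score -> segment/baseline, in that order."""
    return segment_and_baseline(impute_and_zscore(bandpass_filter(rec, cfg), cfg), cfg)
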