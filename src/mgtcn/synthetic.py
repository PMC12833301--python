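"""Synthetic multichannel EEG with controllable class structure.

Emulates the trial structure of affective-EEG recordings: 62-channel signals
at 200 Hz, per-trial class labels, class-dependent power in the five
canonical frequency bands (delta 1-4, theta 4-8, alpha 8-13, beta 13-20,
gamma 20-30 Hz), additive broadband noise, and a low-amplitude pre-stimulus
baseline epoch at the start of each trial. Class-dependent irregularity
(what the fractal-dimension feature responds to) arises from the band-gain
profile: a class with a larger high-frequency share produces rougher traces.

Band-limited components are band-pass-filtered white noise (4th-order
zero-phase Butterworth), not sinusoids, so nonlinear features remain
non-degenerate. All channels of a trial share a configurable fraction of
each band component's variance (a common source plus private sources),
giving the functional-connectivity graph non-trivial structure.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import butter, sosfiltfilt

__all__ = [
    "BANDS",
    "SynthConfig",
    "EEGRecordingSet",
    "generate_recordings",
    "planted_correlation_features",
    "save_recordings",
    "load_recordings",
]

#: canonical EEG bands as (name, low_Hz, high_Hz)
BANDS: tuple[tuple[str, float, float], ...] = (
    ("delta", 1.0, 4.0),
    ("theta", 4.0, 8.0),
    ("alpha", 8.0, 13.0),
    ("beta", 13.0, 20.0),
    ("gamma", 20.0, 30.0),
)

# default per-class band gains: alpha and beta separate the three classes by
# at least a factor of 2 pairwise; delta/theta/gamma are class-neutral.
_DEFAULT_GAINS = (
    (1.0, 1.0, 0.5, 0.5, 1.0),
    (1.0, 1.0, 1.0, 2.0, 1.0),
    (1.0, 1.0, 2.0, 1.0, 1.0),
)


@dataclass
class SynthConfig:
    """Study conditions for the generator.

    Parameters
    ----------
    n_subjects, n_trials_per_class, n_classes, n_channels : int
        Trial bookkeeping; every (subject, class) pair yields
        ``n_trials_per_class`` trials, so labels are balanced by construction.
    fs : float
        Sampling rate in Hz; must exceed twice the highest band edge.
    trial_len : float
        Trial duration in seconds.
    baseline_len : float
        Length of the low-amplitude epoch at the trial start, in seconds;
        simulated as the same process with all band gains halved.
    band_gain_table : array-like, shape (n_classes, 5)
        Per-class amplitude multiplier for each band component.
    noise_sd : float
        Standard deviation of the additive white noise.
    common_var_frac : float
        Fraction of each band component's variance shared across channels.
    subject_sd : float
        Log-normal sd of the per-subject amplitude factor.
    seed : int
        Seed for the generator's own random stream.
    """

    n_subjects: int = 1
    n_trials_per_class: int = 30
    n_classes: int = 3
    n_channels: int = 62
    fs: float = 200.0
    trial_len: float = 8.0
    baseline_len: float = 2.0
    band_gain_table: np.ndarray = field(default_factory=lambda: np.array(_DEFAULT_GAINS))
    noise_sd: float = 0.5
    common_var_frac: float = 0.3
    subject_sd: float = 0.05
    seed: int = 0

    def __post_init__(self):
        self.band_gain_table = np.asarray(self.band_gain_table, dtype=float)
        self.validate()

    def validate(self) -> None:
        for name in ("n_subjects", "n_trials_per_class", "n_classes", "n_channels"):
            if int(getattr(self, name)) < 1:
                raise ValueError(f"SynthConfig.{name} must be >= 1, got {getattr(self, name)}")
        highest = max(hi for _, _, hi in BANDS)
        if self.fs <= 2 * highest:
            raise ValueError(f"SynthConfig.fs must exceed 2x highest band edge ({2 * highest} Hz), got {self.fs}")
        if self.noise_sd < 0:
            raise ValueError(f"SynthConfig.noise_sd must be >= 0, got {self.noise_sd}")
        if self.band_gain_table.shape != (self.n_classes, len(BANDS)):
            raise ValueError(
                f"SynthConfig.band_gain_table must have shape ({self.n_classes}, {len(BANDS)}), "
                f"got {self.band_gain_table.shape}"
            )
        if not np.all(self.band_gain_table > 0):
            raise ValueError("SynthConfig.band_gain_table entries must be strictly positive")
        if not 0.0 <= self.common_var_frac < 1.0:
            raise ValueError(f"SynthConfig.common_var_frac must be in [0, 1), got {self.common_var_frac}")
        if not 0.0 <= self.baseline_len < self.trial_len:
            raise ValueError("SynthConfig.baseline_len must be in [0, trial_len)")


@dataclass
class EEGRecordingSet:
    """Raw trials: per-trial channel x time matrices plus metadata."""

    trials: list[np.ndarray]
    fs: float
    labels: np.ndarray
    subject_ids: np.ndarray
    channel_names: list[str]

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)
        self.subject_ids = np.asarray(self.subject_ids, dtype=int)
        if self.trials:
            n_ch = self.trials[0].shape[0]
            if any(t.shape[0] != n_ch for t in self.trials):
                raise ValueError("all trials must share the same channel count")
        if len(self.trials) != len(self.labels) or len(self.trials) != len(self.subject_ids):
            raise ValueError("trials, labels and subject_ids must have equal length")

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def n_channels(self) -> int:
        return self.trials[0].shape[0]

    def copy(self) -> "EEGRecordingSet":
        return EEGRecordingSet(
            [t.copy() for t in self.trials],
            self.fs,
            self.labels.copy(),
            self.subject_ids.copy(),
            list(self.channel_names),
        )


def _band_sos(low: float, high: float, fs: float, order: int = 4):
    return butter(order, [low, high], btype="bandpass", fs=fs, output="sos")


def _unit_sd_rows(x: np.ndarray) -> np.ndarray:
    sd = x.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def generate_recordings(cfg: SynthConfig) -> EEGRecordingSet:
    """Generate an :class:`EEGRecordingSet` deterministically from `cfg`.

    Each trial is the sum over bands of a band-limited noise component scaled
    by the trial class's row of ``band_gain_table``, plus white noise of sd
    ``noise_sd``. Band components are normalized to unit sd before scaling so
    that realized band power tracks gain**2. The first ``baseline_len``
    seconds of every trial use all band gains halved (the resting epoch).
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n_samp = int(round(cfg.trial_len * cfg.fs))
    n_base = int(round(cfg.baseline_len * cfg.fs))
    sos_by_band = [_band_sos(lo, hi, cfg.fs) for _, lo, hi in BANDS]

    subject_factor = np.exp(rng.normal(0.0, cfg.subject_sd, size=cfg.n_subjects))

    trials: list[np.ndarray] = []
    labels: list[int] = []
    subject_ids: list[int] = []
    c_frac = cfg.common_var_frac
    for subj in range(cfg.n_subjects):
        for cls in range(cfg.n_classes):
            gains = cfg.band_gain_table[cls]
            for _ in range(cfg.n_trials_per_class):
                sig = np.zeros((cfg.n_channels, n_samp))
                for b, sos in enumerate(sos_by_band):
                    raw = rng.standard_normal((cfg.n_channels + 1, n_samp))
                    comp = _unit_sd_rows(sosfiltfilt(sos, raw, axis=-1))
                    common, private = comp[0], comp[1:]
                    mixed = np.sqrt(c_frac) * common + np.sqrt(1.0 - c_frac) * private
                    # halved gain over the pre-stimulus baseline epoch
                    g = np.full(n_samp, gains[b])
                    g[:n_base] *= 0.5
                    sig += mixed * g
                if cfg.noise_sd > 0:
                    sig += cfg.noise_sd * rng.standard_normal(sig.shape)
                trials.append(sig * subject_factor[subj])
                labels.append(cls)
                subject_ids.append(subj)

    channel_names = [f"CH{i:02d}" for i in range(cfg.n_channels)]
    return EEGRecordingSet(trials, cfg.fs, np.array(labels), np.array(subject_ids), channel_names)


def planted_correlation_features(
    n_per_class: int = 50,
    n_features: int = 32,
    n_classes: int = 3,
    amp: float = 8.0,
    noise_sd: float = 0.8,
    seed: int = 0,
):
    """Feature table whose class signal lives only in the cross-feature
    correlation structure, not in any per-row first-order statistic.

    Each class c has a hidden orthonormal template t_c; row i of class c is
    ``s_i * amp * t_c + noise`` with a symmetric random sign in ``s_i``, so the
    class-conditional mean is zero and a linear classifier on the rows alone
    performs at chance. Rows of the same class are strongly correlated in
    magnitude (|r| ~ amp^2 / (amp^2 + n_features * noise_sd^2)), which only the
    functional-connectivity graph can exploit. Returns a
    :class:`~mgtcn.features.FeatureMatrix`.
    """
    from .features import FeatureMatrix  # deferred: features imports BANDS from here

    rng = np.random.default_rng(seed)
    templates = np.linalg.qr(rng.standard_normal((n_features, n_classes)))[0].T
    X, y = [], []
    for c in range(n_classes):
        s = rng.choice([-1.0, 1.0], size=n_per_class) * rng.uniform(0.8, 1.2, n_per_class)
        X.append(s[:, None] * amp * templates[c] + noise_sd * rng.standard_normal((n_per_class, n_features)))
        y.append(np.full(n_per_class, c))
    return FeatureMatrix(
        np.vstack(X),
        np.concatenate(y),
        np.zeros(n_per_class * n_classes, dtype=int),
        [f"x{i}" for i in range(n_features)],
    )


# ---------------------------------------------------------------------------
# container IO: one .npz of named channel x time arrays + a CSV sidecar
# ---------------------------------------------------------------------------

def save_recordings(rec: EEGRecordingSet, out_dir: str | Path) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    arrays = {f"trial_{i:05d}": t for i, t in enumerate(rec.trials)}
    np.savez(out_dir / "trials.npz", **arrays)
    meta = pd.DataFrame(
        {
            "trial_id": np.arange(rec.n_trials),
            "subject_id": rec.subject_ids,
            "label": rec.labels,
            "fs": rec.fs,
        }
    )
    meta.to_csv(out_dir / "trials.csv", index=False)
    with open(out_dir / "channels.txt", "w") as fh:
        fh.write("\n".join(rec.channel_names) + "\n")
    return out_dir


def load_recordings(in_dir: str | Path) -> EEGRecordingSet:
    in_dir = Path(in_dir)
    meta = pd.read_csv(in_dir / "trials.csv")
    with np.load(in_dir / "trials.npz") as data:
        trials = [data[f"trial_{int(i):05d}"] for i in meta["trial_id"]]
    channel_names = (in_dir / "channels.txt").read_text().strip().split("\n")
    return EEGRecordingSet(
        trials,
        float(meta["fs"].iloc[0]),
        meta["label"].to_numpy(),
        meta["subject_id"].to_numpy(),
        channel_names,
    )
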