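"""Per-segment, per-channel features and the PCA-reduced feature table.

Three feature families per channel and segment:

* Higuchi fractal dimension (HFD): the slope of log L(k) against log(1/k),
  where L(k) is the average curve length of the series sampled at interval k.
  A smooth line gives HFD ~ 1, white noise ~ 2.
* Histogram (Shannon) entropy of the amplitude distribution, in nats, over
  equal-width bins spanning [min, max] of the series.
* Differential entropy per canonical band: DE = log(var(x_band) + eps) of the
  band-pass-filtered series, a log band-power surrogate.

The raw table has channels x 7 columns (HFD, entropy, 5 band DEs, channel
major). PCA (after column standardization) is fitted on training rows only
and applied to all rows, so no test information leaks into the projection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import butter, sosfiltfilt
from sklearn.decomposition import PCA

from .preprocess import SegmentSet
from .synthetic import BANDS

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureConfig",
    "FeatureMatrix",
    "higuchi_fd",
    "histogram_entropy",
    "differential_entropy_band",
    "build_feature_table",
    "reduce_pca",
]


@dataclass
class FeatureConfig:
    hfd_kmax: int = 10
    entropy_bins: int = 100
    bands: tuple = BANDS
    de_eps: float = 1e-10
    pca_dim: int = 64
    pca_var_fraction: float | None = None  # if set, overrides pca_dim
    filter_order: int = 4

    def __post_init__(self):
        if self.hfd_kmax < 2:
            raise ValueError(f"FeatureConfig.hfd_kmax must be >= 2, got {self.hfd_kmax}")
        if self.entropy_bins < 2:
            raise ValueError(f"FeatureConfig.entropy_bins must be >= 2, got {self.entropy_bins}")
        for name, lo, hi in self.bands:
            if not 0 < lo < hi:
                raise ValueError(f"band {name} has non-increasing edges ({lo}, {hi})")
        if self.pca_dim < 1:
            raise ValueError(f"FeatureConfig.pca_dim must be >= 1, got {self.pca_dim}")


@dataclass
class FeatureMatrix:
    """Segments x feature-dimensions table plus label/subject vectors.

    Before reduction ``X`` holds the raw named columns; after
    :func:`reduce_pca` it holds the projected components and ``pca_*`` fields
    record the standardization and loadings for provenance.
    """

    X: np.ndarray
    labels: np.ndarray
    subject_ids: np.ndarray
    feature_names: list[str]
    pca_loadings: np.ndarray | None = None  # (n_components, n_raw_features)
    pca_mean: np.ndarray | None = None
    pca_scale: np.ndarray | None = None
    pca_explained_var_ratio: np.ndarray | None = None
    fs: float | None = None
    bands: tuple = field(default_factory=lambda: BANDS)

    @property
    def n_rows(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def to_dataframe(self) -> pd.DataFrame:
        cols = self.feature_names if self.pca_loadings is None else [f"pc{i:03d}" for i in range(self.n_features)]
        df = pd.DataFrame(self.X, columns=cols)
        df["label"] = self.labels
        df["subject_id"] = self.subject_ids
        return df

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, label_col: str = "label", subject_col: str = "subject_id"):
        feature_cols = [c for c in df.columns if c not in (label_col, subject_col)]
        subjects = df[subject_col].to_numpy() if subject_col in df else np.zeros(len(df), dtype=int)
        return cls(
            df[feature_cols].to_numpy(dtype=float),
            df[label_col].to_numpy(dtype=int),
            subjects,
            feature_cols,
        )


# ---------------------------------------------------------------------------
# individual features
# ---------------------------------------------------------------------------

def _higuchi_batch(X: np.ndarray, kmax: int) -> np.ndarray:
    """HFD for every row of a 2-D array (rows are time series)."""
    n_series, n = X.shape
    if n <= 2 * kmax:
        raise ValueError(f"series length {n} must exceed 2*kmax={2 * kmax}")
    log_lk = np.empty((n_series, kmax))
    for k in range(1, kmax + 1):
        lk = np.zeros(n_series)
        for m in range(k):
            idx = np.arange(m, n, k)
            if idx.size < 2:
                continue
            diffs = np.abs(np.diff(X[:, idx], axis=-1)).sum(axis=-1)
            n_intervals = idx.size - 1
            # Higuchi normalization: rescale to the full record length, then /k
            lk += diffs * (n - 1) / (n_intervals * k) / k
        lk /= k
        log_lk[:, k - 1] = np.log(np.maximum(lk, 1e-300))
    log_inv_k = -np.log(np.arange(1, kmax + 1))
    # least-squares slope of log L(k) on log(1/k), per row
    x = log_inv_k - log_inv_k.mean()
    slopes = (log_lk - log_lk.mean(axis=1, keepdims=True)) @ x / (x @ x)
    # constant rows have zero curve length at every k: defined sentinel 1.0
    const = np.ptp(X, axis=-1) == 0
    if const.any():
        logger.warning("constant signal(s) passed to HFD; returning 1.0 by convention")
        slopes[const] = 1.0
    return slopes


def higuchi_fd(x: np.ndarray, kmax: int = 10) -> float:
    """Higuchi fractal dimension of a 1-D series.

    Computes the average curve length L(k) over the k offset subsequences for
    k = 1..kmax and returns the least-squares slope of log L(k) versus
    log(1/k). Constant input returns 1.0 (the dimension of a flat line).
    """
    return float(_higuchi_batch(np.asarray(x, dtype=float)[None, :], kmax)[0])


def histogram_entropy(x: np.ndarray, bins: int = 100) -> float:
    """Shannon entropy (nats) of the equal-width amplitude histogram.

    Conventional sign: H = -sum p_i log p_i >= 0, with 0 log 0 = 0. A constant
    signal occupies a single bin and returns exactly 0.
    """
    x = np.asarray(x, dtype=float)
    if np.ptp(x) == 0:
        return 0.0
    counts, _ = np.histogram(x, bins=bins)
    p = counts[counts > 0] / x.size
    return float(-(p * np.log(p)).sum())


def _band_sos(lo: float, hi: float, fs: float, order: int):
    return butter(order, [lo, hi], btype="bandpass", fs=fs, output="sos")


def differential_entropy_band(
    x: np.ndarray, band: tuple[float, float], fs: float, de_eps: float = 1e-10, filter_order: int = 4
) -> float:
    """log(var + eps) of the band-pass-filtered signal (natural log)."""
    lo, hi = band
    if hi >= fs / 2:
        raise ValueError(f"band high edge {hi} Hz violates Nyquist for fs={fs}")
    xf = sosfiltfilt(_band_sos(lo, hi, fs, filter_order), np.asarray(x, dtype=float))
    return float(np.log(xf.var() + de_eps))


# ---------------------------------------------------------------------------
# table assembly and reduction
# ---------------------------------------------------------------------------

def build_feature_table(segs: SegmentSet, cfg: FeatureConfig) -> FeatureMatrix:
    """Raw feature table: per channel 1 HFD + 1 entropy + one DE per band,
    channel-major column order (all features of channel 0, then channel 1...).
    """
    S, C, T = segs.segments.shape
    flat = segs.segments.reshape(S * C, T)

    hfd = _higuchi_batch(flat, cfg.hfd_kmax).reshape(S, C)
    ent = np.array([histogram_entropy(row, cfg.entropy_bins) for row in flat]).reshape(S, C)
    de = np.empty((len(cfg.bands), S, C))
    for b, (_, lo, hi) in enumerate(cfg.bands):
        xf = sosfiltfilt(_band_sos(lo, hi, segs.fs, cfg.filter_order), segs.segments, axis=-1)
        de[b] = np.log(xf.var(axis=-1) + cfg.de_eps)

    per_channel = [hfd, ent] + [de[b] for b in range(len(cfg.bands))]
    feat_labels = ["hfd", "entropy"] + [f"de_{name}" for name, _, _ in cfg.bands]
    # (S, C, 7) channel-major flatten
    X = np.stack(per_channel, axis=-1).reshape(S, C * len(per_channel))
    names = [f"ch{c:02d}_{f}" for c in range(C) for f in feat_labels]

    bad = ~np.isfinite(X)
    if bad.any():
        r, col = np.argwhere(bad)[0]
        raise ValueError(f"non-finite feature: segment {r}, column {names[col]}")
    return FeatureMatrix(X, segs.labels.copy(), segs.subject_ids.copy(), names, fs=segs.fs, bands=cfg.bands)


def reduce_pca(F: FeatureMatrix, cfg: FeatureConfig, fit_mask: np.ndarray) -> FeatureMatrix:
    """Standardize columns and project with PCA fitted on ``fit_mask`` rows.

    All rows are transformed; only rows with ``fit_mask`` true contribute to
    the column statistics and the principal directions.
    """
    fit_mask = np.asarray(fit_mask, dtype=bool)
    Xfit = F.X[fit_mask]
    n_comp = cfg.pca_dim if cfg.pca_var_fraction is None else cfg.pca_var_fraction
    max_dim = min(Xfit.shape)
    if cfg.pca_var_fraction is None and cfg.pca_dim > max_dim:
        raise ValueError(
            f"pca_dim={cfg.pca_dim} exceeds min(n_fit_rows, n_features)={max_dim}; choose a smaller dimension"
        )
    mean = Xfit.mean(axis=0)
    scale = Xfit.std(axis=0)
    scale[scale < 1e-12] = 1.0
    Z = (F.X - mean) / scale
    pca = PCA(n_components=n_comp, svd_solver="full", random_state=0)
    pca.fit(Z[fit_mask])
    Xp = pca.transform(Z)
    return FeatureMatrix(
        Xp,
        F.labels.copy(),
        F.subject_ids.copy(),
        list(F.feature_names),
        pca_loadings=pca.components_.copy(),
        pca_mean=mean,
        pca_scale=scale,
        pca_explained_var_ratio=pca.explained_variance_ratio_.copy(),
        fs=F.fs,
        bands=F.bands,
    )
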