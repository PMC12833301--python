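"""Feature closed forms and oracles: HFD, histogram entropy, band DE, PCA."""

import numpy as np
import pytest

from mgtcn.features import (
    FeatureConfig,
    build_feature_table,
    differential_entropy_band,
    higuchi_fd,
    histogram_entropy,
    reduce_pca,
)
from mgtcn.preprocess import SegmentSet

FS = 200.0


def higuchi_reference(x, kmax):
    """Independent textbook implementation: explicit double loop."""
    x = np.asarray(x, float)
    n = len(x)
    lk, invk = [], []
    for k in range(1, kmax + 1):
        lengths = []
        for m in range(k):
            idx = np.arange(m, n, k)
            if len(idx) < 2:
                continue
            dist = np.abs(np.diff(x[idx])).sum()
            norm = (n - 1) / ((len(idx) - 1) * k)
            lengths.append(dist * norm / k)
        lk.append(np.log(np.mean(lengths)))
        invk.append(np.log(1.0 / k))
    return np.polyfit(invk, lk, 1)[0]


class TestHiguchi:
    def test_matches_reference_on_random_signals(self, rng):
        for _ in range(5):
            x = rng.standard_normal(500)
            assert abs(higuchi_fd(x, 10) - higuchi_reference(x, 10)) < 1e-9

    def test_line_has_dimension_one(self):
        assert abs(higuchi_fd(np.arange(1000.0), 10) - 1.0) <= 0.05

    def test_white_noise_near_two(self):
        vals = [higuchi_fd(np.random.default_rng(s).standard_normal(2000), 10) for s in range(20)]
        assert 1.9 <= np.mean(vals) <= 2.05

    def test_scale_invariance(self, rng):
        x = rng.standard_normal(800)
        assert abs(higuchi_fd(x, 10) - higuchi_fd(5 * x, 10)) < 1e-12

    def test_constant_signal_sentinel(self):
        assert higuchi_fd(np.full(500, 3.0), 10) == 1.0

    def test_monotone_in_roughness(self):
        """Mean HFD is non-decreasing as AR(1) smoothing weakens
        (phi 0.95 -> 0.6 -> 0.0), 20 seeds per level."""
        means = []
        for phi in (0.95, 0.6, 0.0):
            vals = []
            for s in range(20):
                rng = np.random.default_rng(s)
                e = rng.standard_normal(2000)
                x = np.empty_like(e)
                x[0] = e[0]
                for i in range(1, len(e)):
                    x[i] = phi * x[i - 1] + e[i]
                vals.append(higuchi_fd(x, 10))
            means.append(np.mean(vals))
        assert means[0] <= means[1] <= means[2]

    def test_too_short_signal_rejected(self):
        with pytest.raises(ValueError, match="kmax"):
            higuchi_fd(np.zeros(15), 10)


class TestHistogramEntropy:
    def test_constant_signal_zero(self):
        assert histogram_entropy(np.full(100, 2.5), 100) == 0.0

    def test_uniform_over_all_bins_is_log_b(self):
        b = 25
        x = np.repeat(np.linspace(0.0, 1.0, b), 4)
        assert histogram_entropy(x, b) == pytest.approx(np.log(b), abs=1e-12)

    def test_bounds(self, rng):
        for _ in range(10):
            h = histogram_entropy(rng.standard_normal(300), 50)
            assert 0.0 <= h <= np.log(50)


class TestDifferentialEntropy:
    def test_unit_variance_band_limited_near_zero(self, rng):
        from scipy.signal import butter, sosfiltfilt

        sos = butter(4, [8, 13], btype="bandpass", fs=FS, output="sos")
        x = sosfiltfilt(sos, rng.standard_normal(4000))
        x /= x.std()
        assert abs(differential_entropy_band(x, (8, 13), FS)) < 0.1

    def test_scaling_shifts_by_two_log_c(self, rng):
        x = rng.standard_normal(2000)
        c = 3.7
        d1 = differential_entropy_band(x, (8, 13), FS)
        d2 = differential_entropy_band(c * x, (8, 13), FS)
        assert d2 - d1 == pytest.approx(2 * np.log(c), abs=1e-6)

    def test_zero_signal_hits_eps_floor(self):
        assert differential_entropy_band(np.zeros(1000), (8, 13), FS) == pytest.approx(np.log(1e-10))

    def test_nyquist_violation_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            differential_entropy_band(np.zeros(1000), (8, 120), FS)

    def test_additivity_under_concatenation(self, rng):
        """DE of two concatenated independent equal-variance signals equals
        DE of either within 0.05 nats at n >= 2000."""
        a = rng.standard_normal(4000)
        b = rng.standard_normal(4000)
        d_a = differential_entropy_band(a, (8, 13), FS)
        d_cat = differential_entropy_band(np.concatenate([a, b]), (8, 13), FS)
        assert abs(d_cat - d_a) < 0.05


def make_segs(rng, n_seg=2, n_ch=8, n_t=800, labels=None):
    labels = np.zeros(n_seg, int) if labels is None else np.asarray(labels)
    return SegmentSet(
        rng.standard_normal((n_seg, n_ch, n_t)),
        labels,
        np.zeros(n_seg, int),
        FS,
        [(i, 0) for i in range(n_seg)],
    )


class TestFeatureTable:
    def test_raw_dimension_is_channels_times_seven(self, rng):
        segs = make_segs(rng, n_ch=62, n_t=400)
        F = build_feature_table(segs, FeatureConfig())
        assert F.X.shape == (2, 62 * 7)

    def test_rows_and_labels_preserved(self, rng):
        segs = make_segs(rng, labels=[1, 2])
        F = build_feature_table(segs, FeatureConfig())
        assert F.n_rows == 2
        assert list(F.labels) == [1, 2]

    def test_channel_permutation_permutes_column_blocks(self, rng):
        segs = make_segs(rng, n_ch=4)
        F = build_feature_table(segs, FeatureConfig())
        perm = [2, 0, 3, 1]
        segs_p = SegmentSet(segs.segments[:, perm], segs.labels, segs.subject_ids, FS, segs.provenance)
        Fp = build_feature_table(segs_p, FeatureConfig())
        blocks = F.X.reshape(2, 4, 7)
        assert np.allclose(Fp.X.reshape(2, 4, 7), blocks[:, perm])

    def test_determinism(self, rng):
        segs = make_segs(rng)
        a = build_feature_table(segs, FeatureConfig())
        b = build_feature_table(segs, FeatureConfig())
        assert np.array_equal(a.X, b.X)


class TestPCA:
    def test_full_dimension_is_lossless_rotation(self, rng):
        X = rng.standard_normal((30, 6))
        from mgtcn.features import FeatureMatrix

        F = FeatureMatrix(X, np.zeros(30, int), np.zeros(30, int), [f"x{i}" for i in range(6)])
        F2 = reduce_pca(F, FeatureConfig(pca_dim=6), np.ones(30, bool))
        # project back: reconstruction of the standardized data is exact
        Z = (X - F2.pca_mean) / F2.pca_scale
        recon = F2.X @ F2.pca_loadings + Z[np.ones(30, bool)].mean(axis=0)
        assert np.allclose(recon, Z, atol=1e-10)

    def test_rank3_data_explained_by_three_components(self, rng):
        from mgtcn.features import FeatureMatrix

        basis = rng.standard_normal((3, 12))
        X = rng.standard_normal((50, 3)) @ basis
        F = FeatureMatrix(X, np.zeros(50, int), np.zeros(50, int), [f"x{i}" for i in range(12)])
        F2 = reduce_pca(F, FeatureConfig(pca_dim=3), np.ones(50, bool))
        assert F2.pca_explained_var_ratio.sum() >= 0.999
        # oracle: eigendecomposition of the standardized covariance
        Z = (X - X.mean(0)) / X.std(0)
        evals = np.linalg.eigvalsh(np.cov(Z.T))[::-1]
        assert evals[:3].sum() / evals.sum() >= 0.999

    def test_fit_rows_have_centered_components(self, rng):
        from mgtcn.features import FeatureMatrix

        X = rng.standard_normal((40, 8))
        F = FeatureMatrix(X, np.zeros(40, int), np.zeros(40, int), [f"x{i}" for i in range(8)])
        mask = np.zeros(40, bool)
        mask[:25] = True
        F2 = reduce_pca(F, FeatureConfig(pca_dim=4), mask)
        assert np.all(np.abs(F2.X[mask].mean(axis=0)) < 1e-10)

    def test_loadings_ignore_test_rows(self, rng):
        from mgtcn.features import FeatureMatrix

        X = rng.standard_normal((40, 8))
        mask = np.zeros(40, bool)
        mask[:25] = True
        F = FeatureMatrix(X, np.zeros(40, int), np.zeros(40, int), [f"x{i}" for i in range(8)])
        F2 = reduce_pca(F, FeatureConfig(pca_dim=4), mask)
        X_perturbed = X.copy()
        X_perturbed[~mask] += 100.0
        Fp = FeatureMatrix(X_perturbed, F.labels, F.subject_ids, F.feature_names)
        F2p = reduce_pca(Fp, FeatureConfig(pca_dim=4), mask)
        assert np.array_equal(F2.pca_loadings, F2p.pca_loadings)
        assert np.array_equal(F2.X[mask], F2p.X[mask])

    def test_oversized_dim_rejected(self, rng):
        from mgtcn.features import FeatureMatrix

        F = FeatureMatrix(rng.standard_normal((10, 5)), np.zeros(10, int), np.zeros(10, int), list("abcde"))
        with pytest.raises(ValueError, match="smaller"):
            reduce_pca(F, FeatureConfig(pca_dim=8), np.ones(10, bool))
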