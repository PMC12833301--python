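"""Model / Results front end.

:class:`MultilayerGTCN` is the user-facing model object, built from a feature
matrix (or straight from recordings via :meth:`MultilayerGTCN.from_recordings`).
Its :meth:`~MultilayerGTCN.fit` runs stratified k-fold cross-validated
training of the dual-graph transformer/GCN network and returns a
:class:`GTCNResults` carrying per-fold accuracy, precision/recall/F1, the
pooled confusion matrix, training curves and a ``summary()`` table.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .features import FeatureConfig, FeatureMatrix, build_feature_table
from .graphs import GraphConfig
from .network import ModelConfig
from .preprocess import PreprocConfig, preprocess_pipeline
from .synthetic import EEGRecordingSet
from .train_eval import (
    EvalReport,
    TrainConfig,
    cross_validate,
    run_ablation,
    stratified_kfold,
)

__all__ = ["MultilayerGTCN", "GTCNResults"]


class MultilayerGTCN:
    """Dual-graph transformer/GCN emotion classifier over a feature table.

    Parameters
    ----------
    features : FeatureMatrix or ndarray
        Pre-PCA feature table (segments x raw features). If an ndarray is
        given, `labels` must be provided.
    labels : ndarray, optional
        Per-row class indices (ignored when `features` is a FeatureMatrix).
    model_cfg, train_cfg, graph_cfg, feature_cfg
        Architecture, optimization, graph-construction and feature/PCA
        configuration; all have the published defaults.
    """

    def __init__(
        self,
        features: FeatureMatrix | np.ndarray,
        labels: np.ndarray | None = None,
        *,
        model_cfg: ModelConfig | None = None,
        train_cfg: TrainConfig | None = None,
        graph_cfg: GraphConfig | None = None,
        feature_cfg: FeatureConfig | None = None,
    ):
        if isinstance(features, FeatureMatrix):
            self.features = features
        else:
            features = np.asarray(features, dtype=float)
            if labels is None:
                raise ValueError("labels are required when features is a plain array")
            self.features = FeatureMatrix(
                features,
                np.asarray(labels, dtype=int),
                np.zeros(len(features), dtype=int),
                [f"x{i}" for i in range(features.shape[1])],
            )
        n_classes = int(self.features.labels.max()) + 1
        self.model_cfg = model_cfg or ModelConfig(n_classes=n_classes)
        self.train_cfg = train_cfg or TrainConfig()
        self.graph_cfg = graph_cfg or GraphConfig()
        self.feature_cfg = feature_cfg or FeatureConfig(
            pca_dim=min(64, self.features.n_features, max(2, self.features.n_rows - 1))
        )

    # -- constructors --------------------------------------------------------
    @classmethod
    def from_recordings(
        cls,
        rec: EEGRecordingSet,
        preproc_cfg: PreprocConfig | None = None,
        feature_cfg: FeatureConfig | None = None,
        **kwargs,
    ) -> "MultilayerGTCN":
        """Run preprocessing + feature extraction, then build the model."""
        preproc_cfg = preproc_cfg or PreprocConfig()
        feature_cfg = feature_cfg or FeatureConfig()
        segs = preprocess_pipeline(rec, preproc_cfg)
        F = build_feature_table(segs, feature_cfg)
        return cls(F, feature_cfg=feature_cfg, **kwargs)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, label_col: str = "label", **kwargs) -> "MultilayerGTCN":
        return cls(FeatureMatrix.from_dataframe(df, label_col=label_col), **kwargs)

    # -- fitting ---------------------------------------------------------------
    def fit(self, folds=None) -> "GTCNResults":
        """Cross-validated training; returns a :class:`GTCNResults`."""
        report = cross_validate(
            self.features, self.model_cfg, self.train_cfg, self.graph_cfg, self.feature_cfg, folds=folds
        )
        return GTCNResults(self, report)

    def folds(self) -> list[tuple[np.ndarray, np.ndarray]]:
        return stratified_kfold(self.features.labels, self.train_cfg.folds, self.train_cfg.seed)

    def ablation(self, variants: list[str] | None = None) -> pd.DataFrame:
        """CV accuracy/F1 per ablation variant on identical folds."""
        return run_ablation(
            self.features, self.model_cfg, self.train_cfg, self.graph_cfg, self.feature_cfg, variants=variants
        )


class GTCNResults:
    """Cross-validation results: metrics, confusion matrix, curves."""

    def __init__(self, model: MultilayerGTCN, report: EvalReport):
        self.model = model
        self.report = report

    # convenience passthroughs
    @property
    def accuracy_mean(self) -> float:
        return self.report.accuracy_mean

    @property
    def accuracy_sd(self) -> float:
        return self.report.accuracy_sd

    @property
    def macro_f1_mean(self) -> float:
        return self.report.macro_f1_mean

    @property
    def macro_f1_sd(self) -> float:
        return self.report.macro_f1_sd

    @property
    def confusion(self) -> np.ndarray:
        return self.report.confusion

    @property
    def confusion_percent(self) -> np.ndarray:
        return self.report.confusion_percent

    @property
    def fold_frame(self) -> pd.DataFrame:
        return self.report.to_frame()

    def summary(self) -> str:
        lines = [
            "Multilayer graph transformer/GCN cross-validation results",
            "=" * 58,
            f"segments: {self.model.features.n_rows}   classes: {self.model.model_cfg.n_classes}   "
            f"folds: {self.model.train_cfg.folds}",
            f"accuracy : {100 * self.accuracy_mean:6.2f} +/- {100 * self.accuracy_sd:.2f} %",
            f"macro F1 : {100 * self.macro_f1_mean:6.2f} +/- {100 * self.macro_f1_sd:.2f} %",
            "",
            "per-fold metrics:",
            self.fold_frame.to_string(index=False, float_format=lambda v: f"{v:.4f}"),
            "",
            "pooled confusion matrix (rows = true class, counts):",
            pd.DataFrame(self.confusion).to_string(),
        ]
        return "\n".join(lines)

    def save(self, out_dir: str | Path) -> Path:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        metrics = {
            "accuracy_mean": self.accuracy_mean,
            "accuracy_sd": self.accuracy_sd,
            "macro_f1_mean": self.macro_f1_mean,
            "macro_f1_sd": self.macro_f1_sd,
            "per_fold": self.fold_frame.to_dict(orient="records"),
        }
        (out_dir / "metrics.json").write_text(json.dumps(metrics, indent=2))
        pd.DataFrame(self.confusion).to_csv(out_dir / "confusion_counts.csv", index=False)
        pd.DataFrame(self.confusion_percent).to_csv(out_dir / "confusion_percent.csv", index=False)
        curves = []
        for fr in self.report.fold_reports:
            for epoch in range(len(fr.curves.get("train_loss", []))):
                curves.append({"fold": fr.fold, "epoch": epoch, **{k: v[epoch] for k, v in fr.curves.items()}})
        if curves:
            pd.DataFrame(curves).to_csv(out_dir / "curves.csv", index=False)
        return out_dir

    def export_embeddings(self, path: str | Path) -> Path:
        """Pooled test-node fused embeddings (one row per held-out segment)
        with true/predicted labels, for external visualization (e.g. t-SNE)."""
        rows = []
        for fr in self.report.fold_reports:
            if fr.embedding is None:
                continue
            df = pd.DataFrame(fr.embedding, columns=[f"e{i:03d}" for i in range(fr.embedding.shape[1])])
            df.insert(0, "fold", fr.fold)
            df["label"] = fr.y_true
            df["predicted"] = fr.y_pred
            rows.append(df)
        out = pd.concat(rows, ignore_index=True)
        path = Path(path)
        out.to_csv(path, index=False)
        return path

    def plot_confusion(self, path: str | Path | None = None):
        """Row-normalized confusion-matrix heatmap (requires matplotlib)."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(4, 4))
        pct = self.confusion_percent
        im = ax.imshow(pct, cmap="Blues", vmin=0, vmax=100)
        for i in range(pct.shape[0]):
            for j in range(pct.shape[1]):
                ax.text(j, i, f"{self.confusion[i, j]}\n{pct[i, j]:.1f}%", ha="center", va="center", fontsize=8)
        ax.set_xlabel("predicted")
        ax.set_ylabel("true")
        fig.colorbar(im, ax=ax, shrink=0.8)
        fig.tight_layout()
        if path is not None:
            fig.savefig(path, dpi=120)
            plt.close(fig)
        return fig
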