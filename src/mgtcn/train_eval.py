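"""Training loop, stratified cross-validation, metrics and the ablation driver.

Per fold: PCA (column standardization + projection) and the functional
adjacency are fitted on training rows only; a stratified validation subset of
the training rows drives early stopping on validation loss; the held-out fold
is evaluated transductively on its own split graph using the train-fitted
batch-norm statistics. Accuracy, per-class precision/recall/F1 (with their
closed forms from the confusion matrix) and macro/micro aggregates are
reported per fold and as mean +/- sd (ddof=1) across folds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold, train_test_split

from .features import FeatureConfig, FeatureMatrix, reduce_pca
from .graphs import DualGraph, GraphConfig, assemble_dual_graph
from .network import GraphTensors, ModelConfig, ModelParams, forward, nll_loss
from .optim import Adam, PlateauScheduler, cosine_lr

logger = logging.getLogger(__name__)

__all__ = [
    "TrainConfig",
    "EvalReport",
    "FoldReport",
    "stratified_kfold",
    "train_fold",
    "evaluate",
    "cross_validate",
    "run_ablation",
    "confusion_matrix",
    "metrics_from_confusion",
]

ABLATION_VARIANTS = {
    "full": {},
    "no_transformer": {"use_transformer": False},
    "no_gcn": {"use_gcn": False},
    "no_physical": {"use_physical": False},
    "no_functional": {"use_functional": False},
}


@dataclass
class TrainConfig:
    lr: float = 1e-4
    weight_decay: float = 5e-4
    max_epochs: int = 300
    patience: int = 10
    scheduler: str = "cosine"  # or "plateau"
    folds: int = 5
    val_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.folds < 2:
            raise ValueError(f"TrainConfig.folds must be >= 2, got {self.folds}")
        if not 0 < self.val_fraction < 0.5:
            raise ValueError(f"TrainConfig.val_fraction must be in (0, 0.5), got {self.val_fraction}")
        if self.scheduler not in ("cosine", "plateau"):
            raise ValueError(f"unknown scheduler {self.scheduler!r}")


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def confusion_matrix(y_true: np.ndarray, y_pred: np.ndarray, n_classes: int) -> np.ndarray:
    cm = np.zeros((n_classes, n_classes), dtype=int)
    np.add.at(cm, (np.asarray(y_true, int), np.asarray(y_pred, int)), 1)
    return cm


def metrics_from_confusion(cm: np.ndarray) -> dict:
    """Accuracy and per-class precision/recall/F1 from a confusion matrix.

    Rows are true classes, columns predicted. Classes with zero support are
    excluded from the macro averages (flagged in ``undefined_classes``).
    """
    cm = np.asarray(cm, dtype=float)
    total = cm.sum()
    tp = np.diag(cm)
    fp = cm.sum(axis=0) - tp
    fn = cm.sum(axis=1) - tp
    support = cm.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(tp + fp > 0, tp / (tp + fp), 0.0)
        recall = np.where(tp + fn > 0, tp / (tp + fn), 0.0)
        denom = precision + recall
        f1 = np.where(denom > 0, 2 * precision * recall / np.where(denom > 0, denom, 1.0), 0.0)
    defined = support > 0
    undefined = np.flatnonzero(~defined)
    if undefined.size:
        logger.warning("classes %s have no support in this split; excluded from macro averages", undefined.tolist())
    micro_f1 = tp.sum() / total if total else 0.0  # single-label: micro-F1 == accuracy
    return {
        "accuracy": float(tp.sum() / total) if total else 0.0,
        "precision": precision,
        "recall": recall,
        "f1": f1,
        "support": support.astype(int),
        "macro_f1": float(f1[defined].mean()) if defined.any() else 0.0,
        "macro_precision": float(precision[defined].mean()) if defined.any() else 0.0,
        "macro_recall": float(recall[defined].mean()) if defined.any() else 0.0,
        "micro_f1": float(micro_f1),
        "undefined_classes": undefined.tolist(),
    }


@dataclass
class FoldReport:
    fold: int
    confusion: np.ndarray
    metrics: dict
    curves: dict
    y_true: np.ndarray
    y_pred: np.ndarray
    embedding: np.ndarray | None = None  # fused pre-classifier test-node embedding


@dataclass
class EvalReport:
    """Cross-validation summary: per-fold metrics and pooled confusion."""

    fold_reports: list[FoldReport]
    n_classes: int

    def _per_fold(self, key: str) -> np.ndarray:
        return np.array([fr.metrics[key] for fr in self.fold_reports])

    @property
    def accuracy_mean(self) -> float:
        return float(self._per_fold("accuracy").mean())

    @property
    def accuracy_sd(self) -> float:
        vals = self._per_fold("accuracy")
        return float(vals.std(ddof=1)) if len(vals) > 1 else 0.0

    @property
    def macro_f1_mean(self) -> float:
        return float(self._per_fold("macro_f1").mean())

    @property
    def macro_f1_sd(self) -> float:
        vals = self._per_fold("macro_f1")
        return float(vals.std(ddof=1)) if len(vals) > 1 else 0.0

    @property
    def confusion(self) -> np.ndarray:
        """Pooled confusion matrix (counts) over all folds."""
        return np.sum([fr.confusion for fr in self.fold_reports], axis=0)

    @property
    def confusion_percent(self) -> np.ndarray:
        cm = self.confusion.astype(float)
        rows = cm.sum(axis=1, keepdims=True)
        return 100.0 * cm / np.where(rows > 0, rows, 1.0)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"fold": fr.fold, "accuracy": fr.metrics["accuracy"], "macro_f1": fr.metrics["macro_f1"],
             "macro_precision": fr.metrics["macro_precision"], "macro_recall": fr.metrics["macro_recall"]}
            for fr in self.fold_reports
        ]
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# folds and training
# ---------------------------------------------------------------------------

def stratified_kfold(labels: np.ndarray, k: int, seed: int) -> list[tuple[np.ndarray, np.ndarray]]:
    """Disjoint covering folds with per-fold class proportions within one
    member of the global proportions; deterministic given `seed`."""
    labels = np.asarray(labels, dtype=int)
    counts = np.bincount(labels)
    small = np.flatnonzero((counts > 0) & (counts < k))
    if small.size:
        raise ValueError(f"class(es) {small.tolist()} have fewer than k={k} members")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [(tr, te) for tr, te in skf.split(np.zeros(len(labels)), labels)]


def _prepare_fold(F, fold, graph_cfg, feature_cfg, train_cfg):
    """PCA on train rows, split graphs, and the internal train/val masks."""
    train_idx, test_idx = fold
    n = F.n_rows
    train_mask = np.zeros(n, dtype=bool)
    train_mask[train_idx] = True
    F2 = reduce_pca(F, feature_cfg, fit_mask=train_mask) if F.pca_loadings is None else F
    g_train, g_test = assemble_dual_graph(F2, train_mask, graph_cfg)
    # stratified validation subset (local indices within the train graph)
    local = np.arange(len(train_idx))
    y_tr = F2.labels[train_idx]
    n_classes = len(np.unique(y_tr))
    # stratification needs at least one validation row per class
    n_val = max(n_classes, int(np.ceil(train_cfg.val_fraction * len(train_idx))))
    tr_loc, val_loc = train_test_split(
        local,
        test_size=n_val,
        stratify=y_tr,
        random_state=train_cfg.seed,
    )
    fit_mask_local = np.zeros(len(train_idx), dtype=bool)
    fit_mask_local[tr_loc] = True
    g_train.masks = {"train": fit_mask_local, "val": ~fit_mask_local}
    return F2, g_train, g_test


def train_fold(
    F: FeatureMatrix,
    fold: tuple[np.ndarray, np.ndarray],
    model_cfg: ModelConfig,
    train_cfg: TrainConfig,
    graph_cfg: GraphConfig | None = None,
    feature_cfg: FeatureConfig | None = None,
) -> tuple[ModelParams, dict]:
    """Train on one fold's train graph with early stopping on validation loss.

    Returns the best-validation parameters and the per-epoch curves
    (train/val loss and accuracy, learning rate).
    """
    graph_cfg = graph_cfg or GraphConfig()
    feature_cfg = feature_cfg or FeatureConfig()
    F2, g_train, _ = _prepare_fold(F, fold, graph_cfg, feature_cfg, train_cfg)

    params = ModelParams(model_cfg, F2.n_features)
    opt = Adam(params.tensors(), lr=train_cfg.lr, weight_decay=train_cfg.weight_decay)
    plateau = PlateauScheduler(train_cfg.lr) if train_cfg.scheduler == "plateau" else None
    rng = np.random.default_rng(train_cfg.seed + 1)
    gt = GraphTensors.from_graph(g_train, graph_cfg.self_loops_gcn)
    tr_mask, val_mask = g_train.masks["train"], g_train.masks["val"]
    y = g_train.labels

    curves = {"train_loss": [], "val_loss": [], "train_acc": [], "val_acc": [], "lr": []}
    best_val = np.inf
    best_state = params.state_dict()
    stale = 0
    for epoch in range(train_cfg.max_epochs):
        if train_cfg.scheduler == "cosine":
            opt.lr = cosine_lr(train_cfg.lr, epoch, train_cfg.max_epochs)
        log_probs, _ = forward(g_train, params, model_cfg, training=True, rng=rng, gt=gt)
        loss = nll_loss(_rows(log_probs, tr_mask), y[tr_mask])
        opt.zero_grad()
        loss.backward()
        opt.step()
        if not params.all_finite() or not np.isfinite(loss.data):
            raise RuntimeError(f"training diverged at epoch {epoch} (non-finite loss or parameters)")

        eval_lp, _ = forward(g_train, params, model_cfg, training=False, gt=gt)
        val_loss = float(nll_loss(_rows(eval_lp, val_mask), y[val_mask]).data)
        pred = eval_lp.data.argmax(axis=1)
        curves["train_loss"].append(float(loss.data))
        curves["val_loss"].append(val_loss)
        curves["train_acc"].append(float((pred[tr_mask] == y[tr_mask]).mean()))
        curves["val_acc"].append(float((pred[val_mask] == y[val_mask]).mean()))
        curves["lr"].append(opt.lr)
        if plateau is not None:
            opt.lr = plateau.step(val_loss)

        if val_loss < best_val - 1e-9:
            best_val = val_loss
            best_state = params.state_dict()
            stale = 0
        else:
            stale += 1
            if stale >= train_cfg.patience:
                logger.info("early stop at epoch %d (no val improvement for %d epochs)", epoch, stale)
                break
    params.load_state_dict(best_state)
    return params, curves


def _rows(t, mask):
    # row-select on a Tensor via a constant selection matrix (keeps gradients)
    sel = np.zeros((int(mask.sum()), t.shape[0]))
    sel[np.arange(int(mask.sum())), np.flatnonzero(mask)] = 1.0
    from .autodiff import Tensor

    return Tensor(sel) @ t


def evaluate(
    params: ModelParams,
    F: FeatureMatrix,
    fold: tuple[np.ndarray, np.ndarray],
    model_cfg: ModelConfig,
    train_cfg: TrainConfig,
    graph_cfg: GraphConfig | None = None,
    feature_cfg: FeatureConfig | None = None,
    curves: dict | None = None,
    fold_id: int = 0,
) -> FoldReport:
    """Build the test-split graph, run the trained model in evaluation mode
    and compute the fold's confusion matrix and metrics."""
    graph_cfg = graph_cfg or GraphConfig()
    feature_cfg = feature_cfg or FeatureConfig()
    _, _, g_test = _prepare_fold(F, fold, graph_cfg, feature_cfg, train_cfg)
    gt = GraphTensors.from_graph(g_test, graph_cfg.self_loops_gcn)
    log_probs, emb = forward(g_test, params, model_cfg, training=False, gt=gt)
    y_pred = log_probs.data.argmax(axis=1)
    y_true = g_test.labels
    cm = confusion_matrix(y_true, y_pred, model_cfg.n_classes)
    return FoldReport(fold_id, cm, metrics_from_confusion(cm), curves or {}, y_true, y_pred, emb.data.copy())


def cross_validate(
    F: FeatureMatrix,
    model_cfg: ModelConfig,
    train_cfg: TrainConfig,
    graph_cfg: GraphConfig | None = None,
    feature_cfg: FeatureConfig | None = None,
    folds: list[tuple[np.ndarray, np.ndarray]] | None = None,
) -> EvalReport:
    """Stratified k-fold cross-validation of the full train/evaluate cycle."""
    folds = folds if folds is not None else stratified_kfold(F.labels, train_cfg.folds, train_cfg.seed)
    reports = []
    for i, fold in enumerate(folds):
        params, curves = train_fold(F, fold, model_cfg, train_cfg, graph_cfg, feature_cfg)
        reports.append(evaluate(params, F, fold, model_cfg, train_cfg, graph_cfg, feature_cfg, curves, fold_id=i))
        logger.info("fold %d: accuracy %.4f macro-F1 %.4f", i, reports[-1].metrics["accuracy"], reports[-1].metrics["macro_f1"])
    return EvalReport(reports, model_cfg.n_classes)


def run_ablation(
    F: FeatureMatrix,
    model_cfg: ModelConfig,
    train_cfg: TrainConfig,
    graph_cfg: GraphConfig | None = None,
    feature_cfg: FeatureConfig | None = None,
    variants: list[str] | None = None,
) -> pd.DataFrame:
    """Run the full CV once per ablation variant on identical folds/seeds.

    Variants are drawn from: full, no_transformer, no_gcn, no_physical,
    no_functional. Returns a table of variant -> mean +/- sd accuracy / F1.
    """
    variants = variants or list(ABLATION_VARIANTS)
    unknown = set(variants) - set(ABLATION_VARIANTS)
    if unknown:
        raise ValueError(f"unknown ablation variant(s): {sorted(unknown)}")
    folds = stratified_kfold(F.labels, train_cfg.folds, train_cfg.seed)
    rows = []
    for name in variants:
        overrides = ABLATION_VARIANTS[name]
        cfg_v = ModelConfig(**{**model_cfg.__dict__, **overrides})
        rep = cross_validate(F, cfg_v, train_cfg, graph_cfg, feature_cfg, folds=folds)
        rows.append(
            {
                "variant": name,
                "accuracy_mean": rep.accuracy_mean,
                "accuracy_sd": rep.accuracy_sd,
                "macro_f1_mean": rep.macro_f1_mean,
                "macro_f1_sd": rep.macro_f1_sd,
            }
        )
    return pd.DataFrame(rows)
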