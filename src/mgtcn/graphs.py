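"""Dual-layer graph construction.

Two edge layers over the same node set:

* physical proximity — a complete topology: every ordered pair of distinct
  nodes is connected with unit weight (a uniform structural prior, not
  electrode geometry);
* functional connectivity — Pearson correlation between node feature vectors,
  thresholded by the mean off-diagonal magnitude and converted to an edge
  list (ties at the threshold are kept).

Nodes default to segments (samples); correlations and the PCA upstream are
computed within a train or test split only, and edge indices are local to the
split, so no edge ever connects a train node to a test node.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .features import FeatureMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "GraphConfig",
    "DualGraph",
    "physical_adjacency",
    "functional_adjacency",
    "threshold_and_edges",
    "assemble_dual_graph",
]


@dataclass
class GraphConfig:
    threshold_mode: str = "abs_mean"  # or "signed_mean"
    node_semantics: str = "segments_as_nodes"  # or "features_as_nodes" (experimental)
    self_loops_gcn: bool = True

    def __post_init__(self):
        if self.threshold_mode not in ("abs_mean", "signed_mean"):
            raise ValueError(f"unknown threshold_mode {self.threshold_mode!r}")
        if self.node_semantics not in ("segments_as_nodes", "features_as_nodes"):
            raise ValueError(f"unknown node_semantics {self.node_semantics!r}")


@dataclass
class DualGraph:
    """Node features plus the two edge layers, indices local to the split."""

    X: np.ndarray  # (N, D)
    edges_physical: np.ndarray  # (2, Ep) ordered pairs (src, dst)
    edges_functional: np.ndarray  # (2, Ef)
    func_weights: np.ndarray  # correlation per functional edge
    labels: np.ndarray
    masks: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return self.X.shape[0]


def physical_adjacency(n: int) -> np.ndarray:
    """Complete-topology binary adjacency: ones off-diagonal, zero diagonal."""
    if n < 2:
        raise ValueError(f"physical adjacency needs n >= 2 nodes, got {n}")
    return np.ones((n, n)) - np.eye(n)


def functional_adjacency(X: np.ndarray) -> np.ndarray:
    """Pearson correlation between node feature vectors; zero diagonal.

    Zero-variance node vectors get all-zero correlations (with a warning)
    rather than NaNs.
    """
    X = np.asarray(X, dtype=float)
    sd = X.std(axis=1)
    zero_var = sd == 0
    if zero_var.any():
        logger.warning("%d zero-variance node(s); their correlations are set to 0", int(zero_var.sum()))
    with np.errstate(invalid="ignore", divide="ignore"):
        A = np.corrcoef(X)
    A[zero_var, :] = 0.0
    A[:, zero_var] = 0.0
    np.fill_diagonal(A, 0.0)
    return A


def threshold_and_edges(A: np.ndarray, mode: str = "abs_mean") -> tuple[np.ndarray, np.ndarray]:
    """Keep entries at or above the mean off-diagonal level; return the edge
    index (2, E) and the carried weights.

    ``abs_mean`` compares |A_ij| against the mean off-diagonal |A| (so strong
    anticorrelations survive); ``signed_mean`` compares A_ij against the mean
    off-diagonal A. The diagonal never enters the mean or the edges. Ties at
    the threshold are kept (>= rule).
    """
    A = np.asarray(A, dtype=float)
    n = A.shape[0]
    off = ~np.eye(n, dtype=bool)
    if not np.any(A[off]):
        logger.warning("all-zero adjacency: empty functional edge list")
        return np.zeros((2, 0), dtype=int), np.zeros(0)
    if mode == "abs_mean":
        keep = off & (np.abs(A) >= np.abs(A[off]).mean())
    elif mode == "signed_mean":
        keep = off & (A >= A[off].mean())
    else:
        raise ValueError(f"unknown threshold mode {mode!r}")
    src, dst = np.nonzero(keep)
    return np.vstack([src, dst]), A[src, dst]


def _graph_for_rows(X: np.ndarray, labels: np.ndarray, cfg: GraphConfig) -> DualGraph:
    n = X.shape[0]
    ap = physical_adjacency(n)
    ep_src, ep_dst = np.nonzero(ap)
    af = functional_adjacency(X)
    ef, wf = threshold_and_edges(af, cfg.threshold_mode)
    return DualGraph(X, np.vstack([ep_src, ep_dst]), ef, wf, labels)


def assemble_dual_graph(
    F: FeatureMatrix, train_mask: np.ndarray, cfg: GraphConfig | None = None
) -> tuple[DualGraph, DualGraph]:
    """Build the train-split and test-split dual graphs from a feature matrix.

    Under the default ``segments_as_nodes``, nodes are the rows of each split;
    the functional adjacency is computed strictly within the split and both
    layers are reindexed to the split's local node numbering, so perturbing
    test rows cannot change the train graph.

    The secondary ``features_as_nodes`` mode (experimental) treats feature
    columns as nodes with the transposed train-row values as node features.
    """
    cfg = cfg or GraphConfig()
    train_mask = np.asarray(train_mask, dtype=bool)
    test_mask = ~train_mask
    if cfg.node_semantics == "features_as_nodes":
        Xt = F.X[train_mask].T  # nodes = feature columns
        if Xt.shape[0] < 3:
            raise ValueError("features_as_nodes needs at least 3 feature columns")
        col_labels = np.zeros(Xt.shape[0], dtype=int)
        g = _graph_for_rows(Xt, col_labels, cfg)
        return g, g
    for name, mask in (("train", train_mask), ("test", test_mask)):
        if mask.sum() < 3:
            raise ValueError(f"{name} split has {int(mask.sum())} rows; need at least 3 nodes")
    g_train = _graph_for_rows(F.X[train_mask], F.labels[train_mask], cfg)
    g_test = _graph_for_rows(F.X[test_mask], F.labels[test_mask], cfg)
    return g_train, g_test
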