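"""The dual-graph transformer/GCN network.

A single weight-shared encoder (two graph-transformer layers followed by one
GCN layer) is applied to both edge layers of a :class:`~mgtcn.graphs.DualGraph`;
the two per-node embeddings are concatenated and a fully connected classifier
with one hidden stage maps the fused representation to log class
probabilities.

Message passing is computed densely: attention logits are materialized as an
N x N matrix and masked to the graph's edges, which is exact and fast at the
node counts this package targets (hundreds of nodes per split graph).

Layer semantics:

* transformer layer — per head, scaled dot-product logits
  e_ij = (q_i . k_j) / sqrt(d_k) over in-neighbors j of i, softmax-normalized
  attention alpha_ij, output the alpha-weighted sum of projected neighbor
  features; heads are concatenated and passed through ELU. In ``qkv`` mode
  query/key/value use separate projections; in ``shared_w`` mode a single W
  serves as query, key and value projection (the literal single-matrix form).
  Dropout is applied to alpha during training only. A node with no incoming
  edges aggregates to zeros.
* GCN layer — symmetric degree normalization with optional self-loops,
  h_i' = ELU(BN(sum_j Ahat_ij W h_j)) with Ahat = D^-1/2 (A + I) D^-1/2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor, concat
from .graphs import DualGraph

__all__ = [
    "ModelConfig",
    "ModelParams",
    "edges_to_mask",
    "normalized_adjacency",
    "transformer_layer",
    "gcn_layer",
    "forward",
    "nll_loss",
    "log_softmax",
]


@dataclass
class ModelConfig:
    hidden_dim: int = 128
    heads: int = 8
    dropout: float = 0.5
    fc_hidden: int = 256
    n_classes: int = 3
    n_transformer_layers: int = 2
    attention_mode: str = "qkv"  # or "shared_w"
    use_transformer: bool = True
    use_gcn: bool = True
    use_physical: bool = True
    use_functional: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.hidden_dim % self.heads != 0:
            raise ValueError(f"hidden_dim {self.hidden_dim} must be divisible by heads {self.heads}")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError(f"dropout must be in [0, 1), got {self.dropout}")
        if self.attention_mode not in ("qkv", "shared_w"):
            raise ValueError(f"unknown attention_mode {self.attention_mode!r}")
        if not (self.use_physical or self.use_functional):
            raise ValueError("ablation disables both graph layers; at least one must remain")
        if not (self.use_transformer or self.use_gcn):
            raise ValueError("ablation disables both layer types; at least one must remain")

    @property
    def d_k(self) -> int:
        return self.hidden_dim // self.heads

    @property
    def n_branches(self) -> int:
        return int(self.use_physical) + int(self.use_functional)

    def encoder_out_dim(self, in_dim: int) -> int:
        return self.hidden_dim if (self.use_transformer or self.use_gcn) else in_dim

    def embedding_dim(self, in_dim: int) -> int:
        return self.encoder_out_dim(in_dim) * self.n_branches


class BatchNorm:
    """1-D batch normalization with learnable affine and running statistics.

    Inference is transductive: every forward pass processes an entire split
    graph at once, so normalization always uses the statistics of the current
    batch (the split being processed). This keeps evaluation deterministic and
    correctly scaled even though the train and test split graphs differ in
    size — attention over a complete topology averages over all nodes of the
    split, so activation variance depends on the split's node count. The
    affine parameters (gamma, beta) are shared across all callers, as the
    weight-shared encoder requires; running statistics are still tracked per
    *stream* (physical / functional branch) during training as fitted
    artifacts and diagnostics.
    """

    def __init__(self, dim: int, momentum: float = 0.1, eps: float = 1e-5, n_streams: int = 1):
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)
        self.running_mean = np.zeros((n_streams, dim))
        self.running_var = np.ones((n_streams, dim))
        self.momentum = momentum
        self.eps = eps

    def __call__(self, x: Tensor, training: bool, stream: int = 0) -> Tensor:
        mu = x.mean(axis=0)
        var = ((x - mu) ** 2).mean(axis=0)
        if training:
            self.running_mean[stream] = (1 - self.momentum) * self.running_mean[stream] + self.momentum * mu.data
            self.running_var[stream] = (1 - self.momentum) * self.running_var[stream] + self.momentum * var.data
        norm = (x - mu) / ((var + self.eps) ** 0.5)
        return norm * self.gamma + self.beta

    def tensors(self) -> list[Tensor]:
        return [self.gamma, self.beta]


def _uniform(rng: np.random.Generator, fan_in: int, shape) -> Tensor:
    bound = 1.0 / np.sqrt(fan_in)
    return Tensor(rng.uniform(-bound, bound, size=shape), requires_grad=True)


@dataclass
class TransformerLayerParams:
    """Per-head projection matrices for one transformer layer."""

    Wq: list[Tensor]
    Wk: list[Tensor]
    Wv: list[Tensor]
    shared: bool = False  # shared_w mode: Wq is the single W, Wk/Wv alias it


class ModelParams:
    """All trainable tensors plus batch-norm running statistics."""

    def __init__(self, cfg: ModelConfig, in_dim: int):
        rng = np.random.default_rng(cfg.seed)
        self.cfg = cfg
        self.in_dim = in_dim
        self.tf_layers: list[TransformerLayerParams] = []
        if cfg.use_transformer:
            d = in_dim
            for _ in range(cfg.n_transformer_layers):
                if cfg.attention_mode == "shared_w":
                    W = [_uniform(rng, d, (d, cfg.d_k)) for _ in range(cfg.heads)]
                    self.tf_layers.append(TransformerLayerParams(W, W, W, shared=True))
                else:
                    self.tf_layers.append(
                        TransformerLayerParams(
                            [_uniform(rng, d, (d, cfg.d_k)) for _ in range(cfg.heads)],
                            [_uniform(rng, d, (d, cfg.d_k)) for _ in range(cfg.heads)],
                            [_uniform(rng, d, (d, cfg.d_k)) for _ in range(cfg.heads)],
                        )
                    )
                d = cfg.hidden_dim
        gcn_in = cfg.hidden_dim if cfg.use_transformer else in_dim
        if cfg.use_gcn:
            self.gcn_W = _uniform(rng, gcn_in, (gcn_in, cfg.hidden_dim))
            self.gcn_bn = BatchNorm(cfg.hidden_dim, n_streams=2)
        emb = cfg.embedding_dim(in_dim)
        self.fc1_W = _uniform(rng, emb, (emb, cfg.fc_hidden))
        self.fc1_b = Tensor(np.zeros(cfg.fc_hidden), requires_grad=True)
        self.fc_bn = BatchNorm(cfg.fc_hidden)
        self.fc2_W = _uniform(rng, cfg.fc_hidden, (cfg.fc_hidden, cfg.n_classes))
        self.fc2_b = Tensor(np.zeros(cfg.n_classes), requires_grad=True)

    def tensors(self) -> list[Tensor]:
        out: list[Tensor] = []
        for layer in self.tf_layers:
            out.extend(layer.Wq)
            if not layer.shared:
                out.extend(layer.Wk)
                out.extend(layer.Wv)
        if self.cfg.use_gcn:
            out.append(self.gcn_W)
            out.extend(self.gcn_bn.tensors())
        out.extend([self.fc1_W, self.fc1_b, *self.fc_bn.tensors(), self.fc2_W, self.fc2_b])
        return out

    # snapshot/restore for early stopping ---------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {f"t{i}": t.data.copy() for i, t in enumerate(self.tensors())}
        if self.cfg.use_gcn:
            state["gcn_bn_mean"] = self.gcn_bn.running_mean.copy()
            state["gcn_bn_var"] = self.gcn_bn.running_var.copy()
        state["fc_bn_mean"] = self.fc_bn.running_mean.copy()
        state["fc_bn_var"] = self.fc_bn.running_var.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for i, t in enumerate(self.tensors()):
            t.data = state[f"t{i}"].copy()
        if self.cfg.use_gcn:
            self.gcn_bn.running_mean = state["gcn_bn_mean"].copy()
            self.gcn_bn.running_var = state["gcn_bn_var"].copy()
        self.fc_bn.running_mean = state["fc_bn_mean"].copy()
        self.fc_bn.running_var = state["fc_bn_var"].copy()

    def all_finite(self) -> bool:
        return all(np.isfinite(t.data).all() for t in self.tensors())


# ---------------------------------------------------------------------------
# graph preparation
# ---------------------------------------------------------------------------

def edges_to_mask(edge_index: np.ndarray, n: int) -> np.ndarray:
    """Dense attention mask: mask[i, j] = 1 iff edge j -> i exists (j in N(i))."""
    mask = np.zeros((n, n))
    if edge_index.size:
        src, dst = edge_index
        mask[dst, src] = 1.0
    return mask


def normalized_adjacency(edge_index: np.ndarray, n: int, self_loops: bool = True) -> np.ndarray:
    """Dense D^-1/2 (A + I) D^-1/2 (or without I) built from an edge list."""
    A = np.zeros((n, n))
    if edge_index.size:
        src, dst = edge_index
        A[dst, src] = 1.0
    if self_loops:
        A = A + np.eye(n)
    deg = A.sum(axis=1)
    inv_sqrt = np.where(deg > 0, 1.0 / np.sqrt(np.maximum(deg, 1e-12)), 0.0)
    return inv_sqrt[:, None] * A * inv_sqrt[None, :]


def _dropout(x: Tensor, p: float, training: bool, rng: np.random.Generator | None) -> Tensor:
    if not training or p <= 0.0:
        return x
    keep = (rng.random(x.shape) >= p) / (1.0 - p)
    return x * keep


def _masked_softmax(logits: Tensor, mask: np.ndarray) -> Tensor:
    """Row-wise softmax restricted to mask==1 entries; all-masked rows -> 0."""
    shift = logits - logits.data.max(axis=1, keepdims=True)  # constant shift
    e = shift.exp() * mask
    denom = e.sum(axis=1, keepdims=True) + 1e-30
    return e / denom


def transformer_layer(
    X: Tensor | np.ndarray,
    edges: np.ndarray,
    params: TransformerLayerParams,
    cfg: ModelConfig,
    training: bool = False,
    rng: np.random.Generator | None = None,
    mask: np.ndarray | None = None,
    return_alpha: bool = False,
):
    """One multi-head graph-transformer layer (dense masked attention)."""
    if not isinstance(X, Tensor):
        X = Tensor(X)
    if mask is None:
        mask = edges_to_mask(edges, X.shape[0])
    scale = 1.0 / np.sqrt(cfg.d_k)
    heads_out, alphas = [], []
    for h in range(cfg.heads):
        q = X @ params.Wq[h]
        k = q if params.shared else X @ params.Wk[h]
        v = q if params.shared else X @ params.Wv[h]
        alpha = _masked_softmax((q @ k.T) * scale, mask)
        if return_alpha:
            alphas.append(alpha.data.copy())
        alpha = _dropout(alpha, cfg.dropout, training, rng)
        heads_out.append(alpha @ v)
    out = concat(heads_out, axis=1).elu()
    if return_alpha:
        return out, alphas
    return out


def gcn_layer(
    X: Tensor | np.ndarray,
    edges: np.ndarray,
    params: ModelParams,
    cfg: ModelConfig,
    training: bool = False,
    ahat: np.ndarray | None = None,
    self_loops: bool = True,
    apply_bn: bool = True,
) -> Tensor:
    """One GCN layer: symmetric-normalized aggregation, batch-norm, ELU.

    ``apply_bn=False`` bypasses batch normalization (useful for inspecting the
    raw degree-normalized aggregation)."""
    if not isinstance(X, Tensor):
        X = Tensor(X)
    if ahat is None:
        ahat = normalized_adjacency(edges, X.shape[0], self_loops=self_loops)
    agg = Tensor(ahat) @ (X @ params.gcn_W)
    if apply_bn:
        agg = params.gcn_bn(agg, training)
    return agg.elu()


def log_softmax(z: Tensor) -> Tensor:
    shift = z - z.data.max(axis=1, keepdims=True)
    lse = shift.exp().sum(axis=1, keepdims=True).log()
    return shift - lse


def nll_loss(log_probs: Tensor, labels: np.ndarray) -> Tensor:
    """Mean negative log-likelihood of the true classes."""
    labels = np.asarray(labels, dtype=int)
    n, c = log_probs.shape
    onehot = np.zeros((n, c))
    onehot[np.arange(n), labels] = 1.0
    return -(log_probs * onehot).sum() * (1.0 / n)


# ---------------------------------------------------------------------------
# full forward pass
# ---------------------------------------------------------------------------

@dataclass
class GraphTensors:
    """Pre-built dense operators for one DualGraph (cacheable per split)."""

    mask_phys: np.ndarray
    ahat_phys: np.ndarray
    mask_func: np.ndarray
    ahat_func: np.ndarray

    @classmethod
    def from_graph(cls, g: DualGraph, self_loops: bool = True) -> "GraphTensors":
        n = g.n_nodes
        return cls(
            edges_to_mask(g.edges_physical, n),
            normalized_adjacency(g.edges_physical, n, self_loops),
            edges_to_mask(g.edges_functional, n),
            normalized_adjacency(g.edges_functional, n, self_loops),
        )


def _encode(X: Tensor, mask: np.ndarray, ahat: np.ndarray, params: ModelParams, cfg: ModelConfig, training, rng, stream: int = 0) -> Tensor:
    h = X
    if cfg.use_transformer:
        for layer in params.tf_layers:
            h = transformer_layer(h, None, layer, cfg, training, rng, mask=mask)
    if cfg.use_gcn:
        agg = Tensor(ahat) @ (h @ params.gcn_W)
        h = params.gcn_bn(agg, training, stream=stream).elu()
    return h


def forward(
    graph: DualGraph,
    params: ModelParams,
    cfg: ModelConfig,
    training: bool = False,
    rng: np.random.Generator | None = None,
    gt: GraphTensors | None = None,
    self_loops: bool = True,
) -> tuple[Tensor, Tensor]:
    """Run the shared encoder on both graph layers and classify.

    Returns ``(log_probs, embedding)`` where ``embedding`` is the fused
    pre-classifier representation (2 x hidden_dim with both branches active).
    The identical :class:`ModelParams` object serves both branches, so
    gradients from the physical and functional views accumulate into the same
    weights.
    """
    if gt is None:
        gt = GraphTensors.from_graph(graph, self_loops)
    X = Tensor(graph.X)
    branches = []
    if cfg.use_physical:
        branches.append(_encode(X, gt.mask_phys, gt.ahat_phys, params, cfg, training, rng, stream=0))
    if cfg.use_functional:
        branches.append(_encode(X, gt.mask_func, gt.ahat_func, params, cfg, training, rng, stream=1))
    emb = branches[0] if len(branches) == 1 else concat(branches, axis=1)
    h = _dropout(emb, cfg.dropout, training, rng)
    h = h @ params.fc1_W + params.fc1_b
    h = params.fc_bn(h, training).elu()
    logits = h @ params.fc2_W + params.fc2_b
    return log_softmax(logits), emb
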