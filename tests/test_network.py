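"""Message-passing oracles, forward-pass contracts, ablation switches."""

import numpy as np
import pytest

from mgtcn.autodiff import Tensor
from mgtcn.graphs import DualGraph
from mgtcn.network import (
    GraphTensors,
    ModelConfig,
    ModelParams,
    edges_to_mask,
    forward,
    gcn_layer,
    log_softmax,
    nll_loss,
    normalized_adjacency,
    transformer_layer,
)


def elu(x):
    return np.where(x > 0, x, np.expm1(x))


def random_graph(rng, n, p=0.5, symmetric=True):
    A = rng.random((n, n)) < p
    np.fill_diagonal(A, False)
    if symmetric:
        A = A | A.T
    src, dst = np.nonzero(A)
    return np.vstack([src, dst])


def attention_oracle(X, edges, layer, cfg):
    """Dense per-node reference: explicit logits, softmax, weighted sum."""
    n = X.shape[0]
    neigh = {i: [] for i in range(n)}
    for s, d in zip(*edges):
        neigh[d].append(s)
    heads = []
    for h in range(cfg.heads):
        Wq, Wk, Wv = layer.Wq[h].data, layer.Wk[h].data, layer.Wv[h].data
        out = np.zeros((n, cfg.d_k))
        for i in range(n):
            js = neigh[i]
            if not js:
                continue
            q = X[i] @ Wq
            e = np.array([q @ (X[j] @ Wk) for j in js]) / np.sqrt(cfg.d_k)
            a = np.exp(e - e.max())
            a = a / a.sum()
            out[i] = sum(ak * (X[j] @ Wv) for ak, j in zip(a, js))
        heads.append(out)
    return elu(np.concatenate(heads, axis=1))


def gcn_oracle(X, edges, W, self_loops=True):
    """Per-node reference: sum_j W h_j / sqrt(deg_i deg_j)."""
    n = X.shape[0]
    A = np.zeros((n, n))
    for s, d in zip(*edges):
        A[d, s] = 1.0
    if self_loops:
        A += np.eye(n)
    deg = A.sum(axis=1)
    out = np.zeros((n, W.shape[1]))
    for i in range(n):
        for j in range(n):
            if A[i, j] and deg[i] > 0 and deg[j] > 0:
                out[i] += (X[j] @ W) / np.sqrt(deg[i] * deg[j])
    return out


def small_cfg(**kw):
    defaults = dict(hidden_dim=8, heads=2, dropout=0.0, fc_hidden=16, n_classes=3, seed=0)
    defaults.update(kw)
    return ModelConfig(**defaults)


class TestTransformerLayer:
    @pytest.mark.parametrize("mode", ["qkv", "shared_w"])
    def test_matches_dense_oracle(self, mode, rng):
        cfg = small_cfg(attention_mode=mode)
        for _ in range(10):
            n = int(rng.integers(3, 13))
            X = rng.standard_normal((n, 5))
            edges = random_graph(rng, n)
            params = ModelParams(cfg, 5)
            out = transformer_layer(X, edges, params.tf_layers[0], cfg)
            ref = attention_oracle(X, edges, params.tf_layers[0], cfg)
            assert np.abs(out.data - ref).max() < 1e-5

    def test_attention_rows_sum_to_one(self, rng):
        cfg = small_cfg()
        n = 8
        X = rng.standard_normal((n, 5))
        edges = random_graph(rng, n)
        params = ModelParams(cfg, 5)
        _, alphas = transformer_layer(X, edges, params.tf_layers[0], cfg, return_alpha=True)
        has_neigh = edges_to_mask(edges, n).sum(axis=1) > 0
        for alpha in alphas:
            assert np.allclose(alpha[has_neigh].sum(axis=1), 1.0, atol=1e-9)

    def test_single_neighbor_gets_full_attention(self, rng):
        cfg = small_cfg()
        X = rng.standard_normal((3, 5))
        edges = np.array([[1], [0]])  # only 1 -> 0
        params = ModelParams(cfg, 5)
        _, alphas = transformer_layer(X, edges, params.tf_layers[0], cfg, return_alpha=True)
        for alpha in alphas:
            assert alpha[0, 1] == pytest.approx(1.0)

    def test_identical_neighbors_split_attention_equally(self, rng):
        cfg = small_cfg()
        X = rng.standard_normal((3, 5))
        X[2] = X[1]  # neighbors 1 and 2 have identical features
        edges = np.array([[1, 2], [0, 0]])
        params = ModelParams(cfg, 5)
        _, alphas = transformer_layer(X, edges, params.tf_layers[0], cfg, return_alpha=True)
        for alpha in alphas:
            assert alpha[0, 1] == pytest.approx(0.5)
            assert alpha[0, 2] == pytest.approx(0.5)

    def test_isolated_node_aggregates_to_zero(self, rng):
        cfg = small_cfg()
        X = rng.standard_normal((3, 5))
        edges = np.array([[1, 2], [2, 1]])  # node 0 isolated
        params = ModelParams(cfg, 5)
        out = transformer_layer(X, edges, params.tf_layers[0], cfg)
        assert np.allclose(out.data[0], 0.0)  # ELU(0) = 0


class TestGCNLayer:
    def test_matches_dense_oracle(self, rng):
        cfg = small_cfg()
        for _ in range(10):
            n = int(rng.integers(2, 13))
            X = rng.standard_normal((n, cfg.hidden_dim))
            edges = random_graph(rng, n)
            params = ModelParams(cfg, cfg.hidden_dim)
            out = gcn_layer(X, edges, params, cfg, apply_bn=False)
            ref = elu(gcn_oracle(X, edges, params.gcn_W.data))
            assert np.abs(out.data - ref).max() < 1e-5

    def test_single_node_self_loop_identity(self):
        cfg = small_cfg()
        params = ModelParams(cfg, cfg.hidden_dim)
        params.gcn_W.data = np.eye(cfg.hidden_dim)
        h = np.linspace(-1, 1, cfg.hidden_dim)[None, :]
        out = gcn_layer(h, np.zeros((2, 0), int), params, cfg, apply_bn=False)
        assert np.allclose(out.data, elu(h))

    def test_two_node_path_hand_computed(self):
        cfg = small_cfg()
        params = ModelParams(cfg, cfg.hidden_dim)
        params.gcn_W.data = np.eye(cfg.hidden_dim)
        X = np.vstack([np.ones(cfg.hidden_dim), 3 * np.ones(cfg.hidden_dim)])
        edges = np.array([[0, 1], [1, 0]])
        # with self-loops both degrees are 2; c = 2 for every pair
        out = gcn_layer(X, edges, params, cfg, apply_bn=False)
        assert np.allclose(out.data[0], elu((1 + 3) / 2 * np.ones(cfg.hidden_dim)))
        assert np.allclose(out.data[1], elu((1 + 3) / 2 * np.ones(cfg.hidden_dim)))

    def test_normalized_adjacency_row_construction(self, rng):
        n = 6
        edges = random_graph(rng, n)
        ahat = normalized_adjacency(edges, n, self_loops=True)
        A = np.zeros((n, n))
        A[edges[1], edges[0]] = 1
        A += np.eye(n)
        d = A.sum(1)
        assert np.allclose(ahat, A / np.sqrt(np.outer(d, d)))


def make_dual_graph(rng, n=10, d=6):
    X = rng.standard_normal((n, d))
    phys = np.vstack(np.nonzero(np.ones((n, n)) - np.eye(n)))
    func = random_graph(rng, n)
    labels = rng.integers(0, 3, n)
    return DualGraph(X, phys, func, np.ones(func.shape[1]), labels)


class TestForward:
    def test_log_probabilities_normalize(self, rng):
        g = make_dual_graph(rng)
        cfg = small_cfg()
        params = ModelParams(cfg, 6)
        lp, emb = forward(g, params, cfg)
        assert np.allclose(np.exp(lp.data).sum(axis=1), 1.0, atol=1e-6)
        assert emb.shape == (10, 2 * cfg.hidden_dim)

    def test_disabling_functional_halves_embedding(self, rng):
        g = make_dual_graph(rng)
        cfg = small_cfg(use_functional=False)
        params = ModelParams(cfg, 6)
        _, emb = forward(g, params, cfg)
        assert emb.shape == (10, cfg.hidden_dim)

    def test_branches_share_parameter_objects(self, rng):
        """The encoder serving both graphs is one parameter set: the same
        tensor objects are updated by gradients from both branches."""
        g = make_dual_graph(rng)
        cfg = small_cfg()
        params = ModelParams(cfg, 6)
        ids = [id(t) for t in params.tensors()]
        assert len(ids) == len(set(ids))  # each tensor listed once
        lp, _ = forward(g, params, cfg, training=True, rng=np.random.default_rng(0))
        nll_loss(lp, g.labels).backward()
        grads1 = {id(t): t.grad.copy() for t in params.tensors() if t.grad is not None}
        # changing only the functional edges changes encoder gradients
        g2 = DualGraph(g.X, g.edges_physical, g.edges_physical.copy(), None, g.labels)
        for t in params.tensors():
            t.grad = None
        lp2, _ = forward(g2, params, cfg, training=True, rng=np.random.default_rng(0))
        nll_loss(lp2, g.labels).backward()
        Wq0 = params.tf_layers[0].Wq[0]
        assert not np.allclose(grads1[id(Wq0)], Wq0.grad)

    def test_permutation_equivariance(self, rng):
        g = make_dual_graph(rng, n=8)
        cfg = small_cfg()
        params = ModelParams(cfg, 6)
        lp, _ = forward(g, params, cfg)
        perm = rng.permutation(8)
        inv = np.argsort(perm)
        gp = DualGraph(
            g.X[perm],
            np.vstack([inv[g.edges_physical[0]], inv[g.edges_physical[1]]]),
            np.vstack([inv[g.edges_functional[0]], inv[g.edges_functional[1]]]),
            g.func_weights,
            g.labels[perm],
        )
        lpp, _ = forward(gp, params, cfg)
        assert np.allclose(lpp.data, lp.data[perm], atol=1e-8)

    @pytest.mark.parametrize("lr", [1e-2, 1e-3])
    def test_one_optimizer_step_decreases_loss(self, lr, rng):
        from mgtcn.optim import Adam

        g = make_dual_graph(rng, n=12)
        cfg = small_cfg()
        params = ModelParams(cfg, 6)
        opt = Adam(params.tensors(), lr=lr)
        lp, _ = forward(g, params, cfg, training=True, rng=np.random.default_rng(0))
        loss0 = nll_loss(lp, g.labels)
        loss0.backward()
        opt.step()
        lp1, _ = forward(g, params, cfg, training=True, rng=np.random.default_rng(0))
        loss1 = nll_loss(lp1, g.labels)
        assert float(loss1.data) < float(loss0.data)

    def test_fixed_seed_gives_identical_initialization(self):
        a = ModelParams(small_cfg(seed=5), 6)
        b = ModelParams(small_cfg(seed=5), 6)
        assert all(np.array_equal(x.data, y.data) for x, y in zip(a.tensors(), b.tensors()))


class TestConfigAndLoss:
    def test_ablation_conflicts_rejected(self):
        with pytest.raises(ValueError, match="graph"):
            small_cfg(use_physical=False, use_functional=False)
        with pytest.raises(ValueError, match="layer"):
            small_cfg(use_transformer=False, use_gcn=False)
        with pytest.raises(ValueError, match="divisible"):
            ModelConfig(hidden_dim=10, heads=4)

    def test_nll_perfect_prediction_is_zero(self):
        lp = Tensor(np.log(np.array([[1.0 - 2e-16, 1e-16, 1e-16]])))
        assert float(nll_loss(lp, [0]).data) == pytest.approx(0.0, abs=1e-12)

    def test_nll_uniform_prediction_is_log_c(self):
        for c in (2, 3, 5):
            lp = Tensor(np.full((4, c), -np.log(c)))
            assert float(nll_loss(lp, [0] * 4).data) == pytest.approx(np.log(c), abs=1e-12)

    def test_nll_mean_reduction(self, rng):
        lp = log_softmax(Tensor(rng.standard_normal((2, 3))))
        y = [0, 2]
        a = -lp.data[0, 0]
        b = -lp.data[1, 2]
        assert float(nll_loss(lp, y).data) == pytest.approx((a + b) / 2)
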