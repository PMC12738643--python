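"""Layer correctness against dense/loop brute-force oracles."""

import numpy as np
import pytest

from hdti.gnn_core import (
    GATLayerParams,
    GATv2Layer,
    GCNLayer,
    GCNLayerParams,
    gat_forward,
    gatv2_attention,
    gcn_forward,
    glorot_uniform,
)

from conftest import random_symmetric_graph


# -- oracles ----------------------------------------------------------------

def dense_gcn_oracle(H, edge_index, W, B, f=lambda x: x):
    """out = f(D^-1 A H W + H B) with A the 0/1 incoming-adjacency."""
    n = H.shape[0]
    A = np.zeros((n, n))
    for u, v in edge_index.T:
        A[v, u] = 1.0
    deg = A.sum(axis=1)
    Dinv = np.diag(np.where(deg > 0, 1.0 / np.maximum(deg, 1), 0.0))
    return f(Dinv @ A @ H @ W + H @ B)


def loop_gatv2_oracle(H, edge_index, params: GATLayerParams):
    """Explicit per-node loops: logits, softmax, weighted aggregation."""
    n, heads = H.shape[0], params.heads
    d_head = params.a.shape[1]
    Wh = (H @ params.W).reshape(n, heads, d_head)
    edges = [(int(u), int(v)) for u, v in edge_index.T]
    edges += [(v, v) for v in range(n)]  # self-loops
    alpha = np.zeros((len(edges), heads))
    out = np.zeros((n, heads, d_head))
    slope = params.leaky_slope
    for v in range(n):
        incoming = [i for i, (s, d) in enumerate(edges) if d == v]
        for h in range(heads):
            logits = []
            for i in incoming:
                s = Wh[edges[i][0], h] + Wh[v, h]
                ls = np.where(s > 0, s, slope * s)
                logits.append(float(params.a[h] @ ls))
            logits = np.asarray(logits)
            ex = np.exp(logits - logits.max())
            a = ex / ex.sum()
            for i, w in zip(incoming, a):
                alpha[i, h] = w
                out[v, h] += w * Wh[edges[i][0], h]
    return np.asarray(edges).T, alpha, out


def _rand_gcn_params(rng, d_in, d_out):
    return GCNLayerParams(W=rng.normal(size=(d_in, d_out)),
                          B=rng.normal(size=(d_in, d_out)))


def _rand_gat_params(rng, d_in, heads, d_head):
    return GATLayerParams(W=rng.normal(size=(d_in, heads * d_head)),
                          a=rng.normal(size=(heads, d_head)), heads=heads)


# -- GCN --------------------------------------------------------------------

class TestGCN:
    def test_isolated_node_self_term_only(self):
        H = np.array([[2.0, -1.0]])
        params = GCNLayerParams(W=np.eye(2), B=np.eye(2))
        out = gcn_forward(H, np.empty((2, 0), dtype=int), params, "identity")
        assert np.allclose(out, H)

    def test_path_graph_neighbor_mean(self):
        # a-b-c with all features [1]: middle node averages two ones
        H = np.ones((3, 1))
        ei = np.array([[0, 1, 1, 2], [1, 0, 2, 1]])
        params = GCNLayerParams(W=np.array([[1.0]]), B=np.array([[0.0]]))
        out = gcn_forward(H, ei, params, "identity")
        assert np.allclose(out, np.ones((3, 1)))

    @pytest.mark.parametrize("activation", ["identity", "relu"])
    def test_matches_dense_oracle_random(self, rng, activation):
        from hdti.gnn_core import _ACTIVATIONS
        f = _ACTIVATIONS[activation][0]
        for _ in range(100):
            H, ei = random_symmetric_graph(rng)
            params = _rand_gcn_params(rng, H.shape[1], 4)
            out = gcn_forward(H, ei, params, activation)
            expected = dense_gcn_oracle(H, ei, params.W, params.B, f)
            assert np.allclose(out, expected, atol=1e-6)

    def test_homogeneity_identity_activation(self, rng):
        H, ei = random_symmetric_graph(rng)
        params = GCNLayerParams(W=rng.normal(size=(5, 3)),
                                B=np.zeros((5, 3)))
        out1 = gcn_forward(H, ei, params, "identity")
        out2 = gcn_forward(3.7 * H, ei, params, "identity")
        assert np.allclose(out2, 3.7 * out1, atol=1e-8)

    def test_permutation_equivariance(self, rng):
        H, ei = random_symmetric_graph(rng)
        n = H.shape[0]
        perm = rng.permutation(n)
        params = _rand_gcn_params(rng, H.shape[1], 3)
        out = gcn_forward(H, ei, params, "relu")
        inv = np.argsort(perm)
        out_p = gcn_forward(H[inv], perm[ei], params, "relu")
        assert np.allclose(out_p, out[inv], atol=1e-8)


# -- GATv2 ------------------------------------------------------------------

class TestGATv2Attention:
    def test_single_node_self_loop_alpha_one(self, rng):
        H = rng.normal(size=(1, 4))
        params = _rand_gat_params(rng, 4, 2, 3)
        _, alpha = gatv2_attention(H, np.empty((2, 0), dtype=int), params)
        assert np.allclose(alpha, 1.0)

    def test_equal_features_uniform_alpha(self, rng):
        n = 5
        H = np.tile(rng.normal(size=(1, 4)), (n, 1))
        # complete graph
        pairs = [(u, v) for u in range(n) for v in range(n) if u != v]
        ei = np.asarray(list(zip(*pairs)))
        params = _rand_gat_params(rng, 4, 1, 6)
        _, alpha = gatv2_attention(H, ei, params)
        assert np.allclose(alpha, 1.0 / n, atol=1e-12)

    def test_softmax_normalization_random(self, rng):
        for _ in range(20):
            H, ei = random_symmetric_graph(rng)
            params = _rand_gat_params(rng, H.shape[1], 2, 3)
            ei_sl, alpha = gatv2_attention(H, ei, params)
            dst = ei_sl[1]
            sums = np.zeros((H.shape[0], params.heads))
            np.add.at(sums, dst, alpha)
            assert np.allclose(sums, 1.0, atol=1e-12)

    def test_matches_loop_oracle(self, rng):
        for _ in range(100):
            H, ei = random_symmetric_graph(rng, max_nodes=6)
            params = _rand_gat_params(rng, H.shape[1], 2, 3)
            ei_sl, alpha = gatv2_attention(H, ei, params)
            ei_o, alpha_o, _ = loop_gatv2_oracle(H, ei, params)
            assert np.array_equal(ei_sl, ei_o)
            assert np.allclose(alpha, alpha_o, atol=1e-6)


class TestGATForward:
    def test_single_node_identity(self, rng):
        H = rng.normal(size=(1, 3))
        params = GATLayerParams(W=np.eye(3), a=rng.normal(size=(1, 3)),
                                heads=1)
        out = gat_forward(H, np.empty((2, 0), dtype=int), params,
                          "identity", mode="concat")
        assert np.allclose(out, H)

    def test_uniform_alpha_reduces_to_mean(self, rng):
        n = 4
        H = np.tile(rng.normal(size=(1, 3)), (n, 1))
        pairs = [(u, v) for u in range(n) for v in range(n) if u != v]
        ei = np.asarray(list(zip(*pairs)))
        params = _rand_gat_params(rng, 3, 1, 5)
        out = gat_forward(H, ei, params, "identity", mode="concat")
        Wh = H @ params.W
        assert np.allclose(out, Wh, atol=1e-10)  # mean of equal rows

    @pytest.mark.parametrize("mode", ["concat", "average"])
    def test_matches_loop_oracle(self, rng, mode):
        for _ in range(100):
            H, ei = random_symmetric_graph(rng, max_nodes=6)
            params = _rand_gat_params(rng, H.shape[1], 2, 3)
            out = gat_forward(H, ei, params, "identity", mode=mode)
            _, _, out_o = loop_gatv2_oracle(H, ei, params)
            n = H.shape[0]
            expected = (out_o.reshape(n, -1) if mode == "concat"
                        else out_o.mean(axis=1))
            assert np.allclose(out, expected, atol=1e-6)

    def test_invalid_mode(self, rng):
        H, ei = random_symmetric_graph(rng)
        params = _rand_gat_params(rng, H.shape[1], 1, 4)
        with pytest.raises(ValueError, match="mode"):
            gat_forward(H, ei, params, "relu", mode="sum")

    def test_permutation_equivariance(self, rng):
        H, ei = random_symmetric_graph(rng)
        n = H.shape[0]
        perm = rng.permutation(n)
        params = _rand_gat_params(rng, H.shape[1], 2, 3)
        out = gat_forward(H, ei, params, "relu")
        inv = np.argsort(perm)
        out_p = gat_forward(H[inv], perm[ei], params, "relu")
        assert np.allclose(out_p, out[inv], atol=1e-8)


# -- gradients ---------------------------------------------------------------

class TestBackward:
    """Backward passes agree with central finite differences."""

    def _numeric_grad(self, layer, H, ei, param_key, loss_fn, eps=1e-6):
        arr = layer.param_dict[param_key]
        num = np.zeros_like(arr)
        it = np.nditer(arr, flags=["multi_index"])
        while not it.finished:
            ix = it.multi_index
            old = arr[ix]
            arr[ix] = old + eps
            lp = loss_fn(layer.forward(H, ei))
            arr[ix] = old - eps
            lm = loss_fn(layer.forward(H, ei))
            arr[ix] = old
            num[ix] = (lp - lm) / (2 * eps)
            it.iternext()
        return num

    @pytest.mark.parametrize("kind", ["gcn", "gat"])
    def test_parameter_gradients(self, rng, kind):
        H, ei = random_symmetric_graph(rng, max_nodes=5)
        d = H.shape[1]
        if kind == "gcn":
            layer = GCNLayer(d, 3, rng, activation="identity")
        else:
            layer = GATv2Layer(d, 4, rng, heads=2, activation="identity")
        target = rng.normal(size=layer.forward(H, ei).shape)

        def loss_fn(out):
            return 0.5 * float(np.sum((out - target) ** 2))

        out = layer.forward(H, ei)
        layer.backward(out - target)
        for key in layer.param_dict:
            num = self._numeric_grad(layer, H, ei, key, loss_fn)
            assert np.allclose(layer.grads[key], num, atol=1e-5), key

    @pytest.mark.parametrize("kind", ["gcn", "gat"])
    def test_input_gradients(self, rng, kind):
        H, ei = random_symmetric_graph(rng, max_nodes=5)
        d = H.shape[1]
        layer = (GCNLayer(d, 3, rng, activation="identity") if kind == "gcn"
                 else GATv2Layer(d, 4, rng, heads=2, activation="identity"))
        target = rng.normal(size=layer.forward(H, ei).shape)
        out = layer.forward(H, ei)
        dH = layer.backward(out - target)
        eps = 1e-6
        num = np.zeros_like(H)
        for i in range(H.shape[0]):
            for j in range(H.shape[1]):
                old = H[i, j]
                H[i, j] = old + eps
                lp = 0.5 * np.sum((layer.forward(H, ei) - target) ** 2)
                H[i, j] = old - eps
                lm = 0.5 * np.sum((layer.forward(H, ei) - target) ** 2)
                H[i, j] = old
                num[i, j] = (lp - lm) / (2 * eps)
        assert np.allclose(dH, num, atol=1e-5)


def test_glorot_bounds_and_determinism():
    a = glorot_uniform(np.random.default_rng(3), (10, 20))
    b = glorot_uniform(np.random.default_rng(3), (10, 20))
    assert np.array_equal(a, b)
    limit = np.sqrt(6.0 / 30)
    assert np.all(np.abs(a) <= limit)
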