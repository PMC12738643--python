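"""Network assembly, pooling, forward invariances, parameter counting."""

import numpy as np
import pytest

from hdti.chem_graph import D_ATOM, smiles_to_graph
from hdti.gnn_core import GATv2Layer, GCNLayer
from hdti.model import (
    GraphBatch,
    HybridGNN,
    ModelConfig,
    build_model,
    count_parameters,
    global_pool,
)


class TestBuild:
    def test_default_head_width_is_128(self):
        model = build_model(ModelConfig(), D_ATOM)
        assert model.head_input_width == 128

    def test_embedding_8_head_width_16(self):
        model = build_model(ModelConfig(embedding_size=8), D_ATOM)
        assert model.head_input_width == 16

    def test_default_layout_two_gcn_three_gat(self):
        model = build_model(ModelConfig(), D_ATOM)
        kinds = [type(l).__name__ for l in model.hidden_layers]
        assert kinds == ["GCNLayer", "GCNLayer",
                         "GATv2Layer", "GATv2Layer", "GATv2Layer"]
        assert isinstance(model.input_layer, GCNLayer)

    def test_custom_layout_length(self):
        model = build_model(
            ModelConfig(hidden_layout=("gcn", "gat", "gcn")), D_ATOM)
        assert len(model.hidden_layers) == 3

    def test_invalid_layout_entry(self):
        with pytest.raises(ValueError, match="gcn"):
            ModelConfig(hidden_layout=("gcn", "sage"))

    def test_hidden_widths_all_embedding_size(self):
        model = build_model(ModelConfig(embedding_size=32), D_ATOM)
        for layer in model.hidden_layers:
            W = layer.param_dict["W"]
            assert W.shape == (32, 32)


class TestGlobalPool:
    def test_single_graph_max_mean(self):
        H = np.array([[1.0, 2.0], [3.0, 0.0]])
        out = global_pool(H, np.array([0, 0]))
        assert np.allclose(out, [[3.0, 2.0, 2.0, 1.0]])

    def test_single_node_max_equals_mean(self, rng):
        h = rng.normal(size=(1, 4))
        out = global_pool(h, np.array([0]))
        assert np.allclose(out, np.concatenate([h, h], axis=1))

    def test_batch_matches_per_graph_loop(self, rng):
        sizes = [3, 1, 5]
        H = rng.normal(size=(sum(sizes), 6))
        member = np.repeat(np.arange(3), sizes)
        out = global_pool(H, member, 3)
        start = 0
        for g, size in enumerate(sizes):
            block = H[start:start + size]
            assert np.allclose(out[g, :6], block.max(axis=0))
            assert np.allclose(out[g, 6:], block.mean(axis=0))
            start += size

    def test_pooled_width_always_2d(self, rng):
        for d in (1, 4, 17):
            H = rng.normal(size=(5, d))
            out = global_pool(H, np.zeros(5, dtype=int))
            assert out.shape == (1, 2 * d)


class TestForward:
    @pytest.fixture(scope="class")
    def setup(self):
        graphs = [smiles_to_graph(s)
                  for s in ["CCO", "c1ccccc1O", "CC(=O)NC"]]
        model = build_model(
            ModelConfig(embedding_size=16, dropout=0.0), D_ATOM, rng=5)
        return model, graphs

    def test_one_prediction_per_graph(self, setup):
        model, graphs = setup
        batch = GraphBatch.from_graphs(graphs, np.zeros(3))
        pred = model.forward(batch)
        assert pred.shape == (3,)
        assert np.all(np.isfinite(pred))

    def test_zero_head_weights_predict_bias(self, setup):
        model, graphs = setup
        saved = model.head.W.copy()
        model.head.W[...] = 0.0
        model.head.b[...] = -1.25
        batch = GraphBatch.from_graphs(graphs, np.zeros(3))
        assert np.allclose(model.forward(batch), -1.25)
        model.head.W[...] = saved

    def test_node_permutation_invariance(self, setup, rng):
        model, graphs = setup
        g = graphs[1]
        perm = rng.permutation(g.num_nodes)
        inv = np.argsort(perm)
        import dataclasses
        g2 = dataclasses.replace(
            g, node_features=g.node_features[inv],
            edge_index=perm[g.edge_index])
        p1 = model.forward(GraphBatch.from_graphs([g], [0.0]))
        p2 = model.forward(GraphBatch.from_graphs([g2], [0.0]))
        assert np.allclose(p1, p2, atol=1e-5)

    def test_batch_independence_and_duplication(self, setup):
        model, graphs = setup
        singles = [model.forward(GraphBatch.from_graphs([g], [0.0]))[0]
                   for g in graphs]
        batch = GraphBatch.from_graphs(graphs + [graphs[0]], np.zeros(4))
        pred = model.forward(batch)
        assert np.allclose(pred[:3], singles, atol=1e-10)
        assert pred[3] == pred[0]

    def test_d_atom_mismatch_raises(self, setup):
        model, graphs = setup
        batch = GraphBatch.from_graphs(graphs, np.zeros(3))
        batch.node_features = batch.node_features[:, :5]
        with pytest.raises(ValueError, match="d_atom"):
            model.forward(batch)

    def test_dropout_only_in_training_mode(self, rng):
        graphs = [smiles_to_graph("CCOCC")]
        model = build_model(
            ModelConfig(embedding_size=8, dropout=0.5), D_ATOM, rng=2)
        batch = GraphBatch.from_graphs(graphs, [0.0])
        a = model.forward(batch, training=False)
        b = model.forward(batch, training=False)
        assert np.array_equal(a, b)
        c = model.forward(batch, training=True, rng=rng)
        d = model.forward(batch, training=True, rng=rng)
        assert not np.array_equal(c, d)  # different masks


class TestCountParameters:
    def test_head_parameter_count(self):
        model = build_model(ModelConfig(), D_ATOM)
        head = model.head
        assert head.W.size + head.b.size == 129

    def test_monotone_in_embedding_size(self):
        small = count_parameters(build_model(ModelConfig(embedding_size=32),
                                             D_ATOM))
        large = count_parameters(build_model(ModelConfig(embedding_size=64),
                                             D_ATOM))
        assert large > small

    def test_stable_across_rebuilds_and_matches_recount(self):
        model = build_model(ModelConfig(), D_ATOM, rng=0)
        model2 = build_model(ModelConfig(), D_ATOM, rng=99)
        assert count_parameters(model) == count_parameters(model2)
        manual = sum(arr.size for _, arr in model.named_parameters())
        assert count_parameters(model) == manual


class TestCheckpoint:
    def test_save_load_round_trip(self, tmp_path, rng):
        graphs = [smiles_to_graph("CCN"), smiles_to_graph("c1ccoc1")]
        model = build_model(
            ModelConfig(embedding_size=12, heads=2, dropout=0.3),
            D_ATOM, rng=7)
        batch = GraphBatch.from_graphs(graphs, np.zeros(2))
        pred = model.forward(batch)
        path = tmp_path / "ckpt.npz"
        model.save(path)
        model2 = HybridGNN.load(path)
        assert model2.config == model.config
        assert np.allclose(model2.forward(batch), pred)
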