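"""The hybrid GCN/GATv2 network for graph-level pIC50 regression.

Architecture: an initial graph convolution mapping the raw atom features
to the embedding width, five hidden layers (two GCN then three GATv2,
each embedding -> embedding with ReLU and dropout), a dual global
readout concatenating per-graph max pooling (GMP) and average pooling
(GAP), and a single affine head mapping the pooled 2*embedding vector
to one real prediction per graph.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .chem_graph import MolecularGraph
from .gnn_core import GCNLayer, GATv2Layer, glorot_uniform

__all__ = [
    "ModelConfig",
    "GraphBatch",
    "HybridGNN",
    "build_model",
    "global_pool",
    "count_parameters",
]

DEFAULT_LAYOUT = ("gcn", "gcn", "gat", "gat", "gat")


@dataclass
class ModelConfig:
    """Architecture hyperparameters of the hybrid network."""

    embedding_size: int = 64
    hidden_layout: tuple[str, ...] = DEFAULT_LAYOUT
    dropout: float = 0.2
    heads: int = 1
    activation: str = "relu"

    def __post_init__(self):
        if self.embedding_size <= 0:
            raise ValueError("embedding_size must be positive")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        layout = tuple(str(k).lower() for k in self.hidden_layout)
        bad = [k for k in layout if k not in ("gcn", "gat")]
        if bad:
            raise ValueError(f"hidden_layout entries must be 'gcn' or 'gat': {bad}")
        self.hidden_layout = layout


@dataclass
class GraphBatch:
    """A batch of molecular graphs stacked into one disjoint union."""

    node_features: np.ndarray  # [total_nodes, d_atom]
    edge_index: np.ndarray  # [2, total_edges], node ids offset per graph
    membership: np.ndarray  # [total_nodes] graph id of each node
    targets: np.ndarray  # [num_graphs]
    num_graphs: int

    @classmethod
    def from_graphs(cls, graphs: list[MolecularGraph], targets) -> "GraphBatch":
        if not graphs:
            raise ValueError("cannot batch zero graphs")
        xs, eis, member = [], [], []
        offset = 0
        for gid, g in enumerate(graphs):
            if g.num_nodes == 0:
                raise ValueError(f"graph {gid} has no nodes")
            xs.append(g.node_features)
            eis.append(g.edge_index + offset)
            member.append(np.full(g.num_nodes, gid, dtype=np.int64))
            offset += g.num_nodes
        return cls(
            node_features=np.concatenate(xs, axis=0),
            edge_index=np.concatenate(eis, axis=1),
            membership=np.concatenate(member),
            targets=np.asarray(targets, dtype=np.float64),
            num_graphs=len(graphs),
        )


def global_pool(H: np.ndarray, membership: np.ndarray,
                num_graphs: int | None = None) -> np.ndarray:
    """Concat(GMP, GAP): per-graph feature-wise max then mean, width 2d."""
    H = np.asarray(H, dtype=float)
    membership = np.asarray(membership, dtype=np.int64)
    if num_graphs is None:
        num_graphs = int(membership.max()) + 1 if membership.size else 0
    counts = np.bincount(membership, minlength=num_graphs)
    if np.any(counts == 0):
        raise ValueError("every graph in a batch must have at least one node")
    d = H.shape[1]
    mx = np.full((num_graphs, d), -np.inf)
    np.maximum.at(mx, membership, H)
    mean = np.zeros((num_graphs, d))
    np.add.at(mean, membership, H)
    mean /= counts[:, None]
    return np.concatenate([mx, mean], axis=1)


class _LinearHead:
    def __init__(self, d_in: int, rng: np.random.Generator):
        self.W = glorot_uniform(rng, (d_in, 1))
        self.b = np.zeros(1)
        self.grads = {"W": np.zeros_like(self.W), "b": np.zeros_like(self.b)}
        self._cache = None

    @property
    def param_dict(self):
        return {"W": self.W, "b": self.b}

    def forward(self, X):
        self._cache = X
        return (X @ self.W + self.b).ravel()

    def backward(self, dy):
        X = self._cache
        dy = dy[:, None]
        self.grads["W"] += X.T @ dy
        self.grads["b"] += dy.sum(axis=0)
        return dy @ self.W.T


class HybridGNN:
    """Initial GCN + configurable GCN/GAT hidden stack + GMP||GAP + linear head.

    Dropout (inverted) regularizes the pooled graph representation before
    the linear head and is active only during training-mode forward
    passes. Masking node embeddings ahead of the max-pooling readout
    would inflate the training-time max statistics by 1/(1-p) and
    miscalibrate the head at evaluation, so the mask is applied after
    the readout, where the linear head keeps the expectation exact.
    """

    def __init__(self, config: ModelConfig, d_atom: int,
                 rng: np.random.Generator | int | None = 0):
        if not isinstance(rng, np.random.Generator):
            rng = np.random.default_rng(rng)
        self.config = config
        self.d_atom = d_atom
        d = config.embedding_size
        act = config.activation
        self.input_layer = GCNLayer(d_atom, d, rng, activation=act)
        self.hidden_layers = []
        for kind in config.hidden_layout:
            if kind == "gcn":
                self.hidden_layers.append(GCNLayer(d, d, rng, activation=act))
            else:
                self.hidden_layers.append(
                    GATv2Layer(d, d, rng, heads=config.heads,
                               activation=act, mode="concat")
                )
        self.head = _LinearHead(2 * d, rng)
        self._drop_mask = None

    # -- introspection ------------------------------------------------------

    @property
    def head_input_width(self) -> int:
        """Input width of the final linear layer (2 x embedding size)."""
        return self.head.W.shape[0]

    @property
    def gat_layer_indices(self) -> list[int]:
        return [i for i, l in enumerate(self.hidden_layers)
                if isinstance(l, GATv2Layer)]

    def named_parameters(self):
        yield from ((f"input.{k}", v) for k, v in self.input_layer.param_dict.items())
        for i, layer in enumerate(self.hidden_layers):
            yield from ((f"hidden{i}.{k}", v) for k, v in layer.param_dict.items())
        yield from ((f"head.{k}", v) for k, v in self.head.param_dict.items())

    def _layers(self):
        return [self.input_layer, *self.hidden_layers, self.head]

    def zero_grad(self):
        for layer in self._layers():
            for g in layer.grads.values():
                g[...] = 0.0

    # -- forward / backward --------------------------------------------------

    def forward(self, batch: GraphBatch, training: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        if batch.node_features.shape[1] != self.d_atom:
            raise ValueError(
                f"batch has d_atom={batch.node_features.shape[1]}, "
                f"model built for {self.d_atom}"
            )
        p = self.config.dropout
        use_dropout = training and p > 0.0
        if use_dropout and rng is None:
            raise ValueError("training-mode forward with dropout needs an rng")
        H = self.input_layer.forward(batch.node_features, batch.edge_index)
        for layer in self.hidden_layers:
            H = layer.forward(H, batch.edge_index)
        self._pool_in = H
        self._batch = batch
        pooled = global_pool(H, batch.membership, batch.num_graphs)
        self._pooled = pooled
        if use_dropout:
            self._drop_mask = (rng.random(pooled.shape) >= p) / (1.0 - p)
            pooled = pooled * self._drop_mask
        else:
            self._drop_mask = None
        return self.head.forward(pooled)

    def backward(self, dpred: np.ndarray) -> None:
        """Accumulate parameter gradients for the most recent forward pass."""
        dpooled = self.head.backward(dpred)
        if self._drop_mask is not None:
            dpooled = dpooled * self._drop_mask
        batch, H = self._batch, self._pool_in
        d = H.shape[1]
        member = batch.membership
        counts = np.bincount(member, minlength=batch.num_graphs).astype(float)
        # max-pool gradient routes to the argmax node of each (graph, feature)
        dH = np.zeros_like(H)
        mx = self._pooled[:, :d]
        is_max = H == mx[member]
        # split ties evenly so the gradient check stays exact
        tie_count = np.zeros((batch.num_graphs, d))
        np.add.at(tie_count, member, is_max.astype(float))
        dH += is_max * (dpooled[:, :d] / tie_count)[member]
        dH += (dpooled[:, d:] / counts[:, None])[member]
        for i in range(len(self.hidden_layers) - 1, -1, -1):
            dH = self.hidden_layers[i].backward(dH)
        self.input_layer.backward(dH)

    # -- persistence ----------------------------------------------------------

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: arr.copy() for name, arr in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for name, arr in self.named_parameters():
            if name not in state:
                raise KeyError(f"missing parameter {name}")
            if state[name].shape != arr.shape:
                raise ValueError(f"shape mismatch for {name}")
            arr[...] = state[name]

    def save(self, path) -> None:
        meta = {
            "embedding_size": self.config.embedding_size,
            "dropout": self.config.dropout,
            "heads": self.config.heads,
            "d_atom": self.d_atom,
        }
        np.savez(
            path,
            __layout__=np.asarray(self.config.hidden_layout, dtype=np.str_),
            __activation__=np.asarray(self.config.activation, dtype=np.str_),
            __meta__=np.asarray(
                [meta["embedding_size"], meta["heads"], meta["d_atom"]],
                dtype=np.int64,
            ),
            __dropout__=np.asarray(self.config.dropout),
            **dict(self.named_parameters()),
        )

    @classmethod
    def load(cls, path) -> "HybridGNN":
        with np.load(path) as data:
            emb, heads, d_atom = (int(v) for v in data["__meta__"])
            config = ModelConfig(
                embedding_size=emb,
                hidden_layout=tuple(str(s) for s in data["__layout__"]),
                dropout=float(data["__dropout__"]),
                heads=heads,
                activation=str(data["__activation__"]),
            )
            model = cls(config, d_atom, rng=0)
            model.load_state_dict({k: data[k] for k in data.files
                                   if not k.startswith("__")})
        return model


def build_model(config: ModelConfig, d_atom: int,
                rng: np.random.Generator | int | None = 0) -> HybridGNN:
    """Construct the hybrid network for atom-feature width ``d_atom``."""
    return HybridGNN(config, d_atom, rng=rng)


def count_parameters(model: HybridGNN) -> int:
    """Total number of trainable scalars in the model."""
    return int(sum(arr.size for _, arr in model.named_parameters()))
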