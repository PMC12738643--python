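"""scikit-learn style estimators over the hybrid graph network.

`HybridGraphRegressor` is the primary user-facing surface: fit on a
list of SMILES strings (or pre-built molecular graphs) and a pIC50
vector, predict on new molecules, and compose with sklearn model
selection. `MolecularGraphFeaturizer` turns SMILES into featurized
graphs; `GraphDescriptorRegressor` wraps the light descriptor-space
baselines (ordinary least squares, k-NN).
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin, TransformerMixin

from .chem_graph import MolecularGraph, smiles_to_graph
from .evaluation import baseline_predict
from .model import DEFAULT_LAYOUT, HybridGNN, ModelConfig, build_model
from .training import TrainConfig, predict as _predict, train as _train

__all__ = [
    "MolecularGraphFeaturizer",
    "HybridGraphRegressor",
    "GraphDescriptorRegressor",
]


def _as_graphs(X) -> list[MolecularGraph]:
    graphs = []
    for item in X:
        if isinstance(item, MolecularGraph):
            graphs.append(item)
        else:
            graphs.append(smiles_to_graph(str(item)))
    return graphs


class MolecularGraphFeaturizer(TransformerMixin, BaseEstimator):
    """Stateless transformer: SMILES strings -> MolecularGraph objects."""

    def fit(self, X, y=None):
        self.n_features_in_ = 1
        return self

    def transform(self, X) -> list[MolecularGraph]:
        return _as_graphs(X)


class HybridGraphRegressor(RegressorMixin, BaseEstimator):
    """Hybrid GCN/GATv2 graph regressor for pIC50 prediction.

    Parameters mirror the network and optimizer hyperparameters: an
    initial graph convolution, a five-layer hidden stack (two GCN then
    three GATv2 by default) at `embedding_size` width, dual max+mean
    global pooling and a linear head, trained with Adam on the MSE loss.

    Attributes set by :meth:`fit`: ``model_`` (the trained network),
    ``history_`` (per-epoch losses), ``d_atom_``.
    """

    def __init__(self, embedding_size: int = 64,
                 hidden_layout: tuple = DEFAULT_LAYOUT,
                 dropout: float = 0.2, heads: int = 1,
                 activation: str = "relu",
                 learning_rate: float = 0.005, epochs: int = 300,
                 batch_size: int = 512, weight_decay: float = 1e-4,
                 random_state: int = 0):
        self.embedding_size = embedding_size
        self.hidden_layout = hidden_layout
        self.dropout = dropout
        self.heads = heads
        self.activation = activation
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.batch_size = batch_size
        self.weight_decay = weight_decay
        self.random_state = random_state

    def _model_config(self) -> ModelConfig:
        return ModelConfig(
            embedding_size=self.embedding_size,
            hidden_layout=tuple(self.hidden_layout),
            dropout=self.dropout,
            heads=self.heads,
            activation=self.activation,
        )

    def _train_config(self) -> TrainConfig:
        return TrainConfig(
            learning_rate=self.learning_rate,
            epochs=self.epochs,
            batch_size=self.batch_size,
            weight_decay=self.weight_decay,
            seed=self.random_state,
        )

    def fit(self, X, y, X_val=None, y_val=None):
        graphs = _as_graphs(X)
        y = np.asarray(y, dtype=float).ravel()
        if len(graphs) != y.size:
            raise ValueError("X and y have inconsistent lengths")
        self.d_atom_ = graphs[0].node_features.shape[1]
        model = build_model(self._model_config(), self.d_atom_,
                            rng=np.random.default_rng(self.random_state))
        val_graphs = _as_graphs(X_val) if X_val is not None else None
        self.model_, self.history_ = _train(
            model, graphs, y, val_graphs, y_val, config=self._train_config())
        return self

    def predict(self, X) -> np.ndarray:
        if not hasattr(self, "model_"):
            raise AttributeError("estimator is not fitted; call fit first")
        return _predict(self.model_, _as_graphs(X), self.batch_size)


class GraphDescriptorRegressor(RegressorMixin, BaseEstimator):
    """Light baseline on fixed graph summary descriptors.

    ``method`` is "linear" (ordinary least squares) or "knn"
    (k-nearest neighbours, Euclidean, default k=5).
    """

    def __init__(self, method: str = "linear", k: int = 5):
        self.method = method
        self.k = k

    def fit(self, X, y):
        self.train_graphs_ = _as_graphs(X)
        self.train_targets_ = np.asarray(y, dtype=float).ravel()
        return self

    def predict(self, X) -> np.ndarray:
        if not hasattr(self, "train_graphs_"):
            raise AttributeError("estimator is not fitted; call fit first")
        return baseline_predict(self.method, self.train_graphs_,
                                self.train_targets_, _as_graphs(X), k=self.k)
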