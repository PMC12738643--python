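"""Training loop (Adam + MSE), cross-validation driver, inference timing.

Training is deterministic given the seed on a single thread: parameter
initialization, batch shuffling and dropout masks all derive from one
seeded generator. No early stopping — models train for the configured
number of epochs, with train/validation loss recorded every epoch for
overfitting monitoring.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np

from .data_pipeline import kfold_split, make_batches
from .evaluation import MetricsReport, compute_metrics
from .model import GraphBatch, HybridGNN, ModelConfig, build_model

__all__ = [
    "TrainConfig",
    "TrainHistory",
    "AdamOptimizer",
    "train",
    "predict",
    "run_cross_validation",
    "measure_inference_time",
]


@dataclass
class TrainConfig:
    """Optimizer hyperparameters. The grid explored in tuning spans
    learning rates {0.01, 0.005, 0.0005} and epoch counts
    {100, 200, 300, 500, 700, 1000}."""

    learning_rate: float = 0.005
    epochs: int = 300
    batch_size: int = 512
    seed: int = 0
    loss: str = "mse"
    optimizer: str = "adam"
    weight_decay: float = 1e-4

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.weight_decay < 0:
            raise ValueError("weight_decay must be >= 0")
        if self.loss != "mse":
            raise ValueError("only the MSE loss is supported")
        if self.optimizer != "adam":
            raise ValueError("only the Adam optimizer is supported")


@dataclass
class TrainHistory:
    """Per-epoch training/validation loss and wall-clock time."""

    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    epoch_seconds: list[float] = field(default_factory=list)


class AdamOptimizer:
    """Adam with the standard moment coefficients (0.9, 0.999).

    ``weight_decay`` adds classic L2 regularization (decay * param) to
    the gradient before the moment updates.
    """

    def __init__(self, model: HybridGNN, lr: float,
                 betas=(0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.model = model
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self._m = {}
        self._v = {}
        for layer in model._layers():
            for key, g in layer.grads.items():
                self._m[(id(layer), key)] = np.zeros_like(g)
                self._v[(id(layer), key)] = np.zeros_like(g)

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for layer in self.model._layers():
            params = layer.param_dict
            for key, g in layer.grads.items():
                if self.weight_decay:
                    g = g + self.weight_decay * params[key]
                m = self._m[(id(layer), key)]
                v = self._v[(id(layer), key)]
                m *= self.b1
                m += (1.0 - self.b1) * g
                v *= self.b2
                v += (1.0 - self.b2) * g * g
                params[key] -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def _mse_and_grad(pred, target):
    resid = pred - target
    return float(np.mean(resid ** 2)), 2.0 * resid / resid.size


def _eval_loss(model, batches):
    total, n = 0.0, 0
    for b in batches:
        pred = model.forward(b, training=False)
        total += float(np.sum((pred - b.targets) ** 2))
        n += b.num_graphs
    return total / n


def train(model: HybridGNN, train_graphs, train_targets,
          val_graphs=None, val_targets=None,
          config: TrainConfig | None = None
          ) -> tuple[HybridGNN, TrainHistory]:
    """Train in place; returns the model and its loss history.

    Aborts with a diagnostic if the loss becomes non-finite (learning
    rate too high).
    """
    config = config or TrainConfig()
    rng = np.random.default_rng(config.seed)
    opt = AdamOptimizer(model, lr=config.learning_rate,
                        weight_decay=config.weight_decay)
    history = TrainHistory()
    val_batches = (make_batches(val_graphs, val_targets, config.batch_size)
                   if val_graphs is not None else None)
    for epoch in range(config.epochs):
        tic = time.perf_counter()
        batches = make_batches(train_graphs, train_targets,
                               config.batch_size, shuffle=True, rng=rng)
        sse, n = 0.0, 0
        for b in batches:
            model.zero_grad()
            pred = model.forward(b, training=True, rng=rng)
            loss, dpred = _mse_and_grad(pred, b.targets)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch}; "
                    "the learning rate is likely too high"
                )
            model.backward(dpred)
            opt.step()
            sse += loss * b.num_graphs
            n += b.num_graphs
        history.train_loss.append(sse / n)
        history.val_loss.append(
            _eval_loss(model, val_batches) if val_batches is not None
            else float("nan"))
        history.epoch_seconds.append(time.perf_counter() - tic)
    return model, history


def predict(model: HybridGNN, graphs, batch_size: int = 512) -> np.ndarray:
    """Eval-mode predictions for a list of graphs."""
    out = []
    for b in make_batches(graphs, np.zeros(len(graphs)), batch_size):
        out.append(model.forward(b, training=False))
    return np.concatenate(out)


def run_cross_validation(graphs, targets, k: int = 5,
                         model_config: ModelConfig | None = None,
                         train_config: TrainConfig | None = None,
                         split_seed: int = 42,
                         ) -> tuple[list[MetricsReport], list[TrainHistory]]:
    """k-fold cross-validation: k independently initialized models, each
    trained on k-1 folds and scored on the held-out fold."""
    model_config = model_config or ModelConfig()
    train_config = train_config or TrainConfig()
    targets = np.asarray(targets, dtype=float)
    folds = kfold_split(len(graphs), k=k, seed=split_seed)
    d_atom = graphs[0].node_features.shape[1]
    reports, histories = [], []
    for fold in range(k):
        tr, va = folds.fold_indices(fold)
        model = build_model(model_config, d_atom,
                            rng=np.random.default_rng(train_config.seed + fold))
        try:
            model, hist = train(
                model,
                [graphs[i] for i in tr], targets[tr],
                [graphs[i] for i in va], targets[va],
                config=train_config,
            )
        except Exception as exc:
            raise RuntimeError(f"training failed in fold {fold}") from exc
        pred = predict(model, [graphs[i] for i in va])
        reports.append(compute_metrics(targets[va], pred))
        histories.append(hist)
    return reports, histories


def measure_inference_time(model: HybridGNN, batch: GraphBatch,
                           n_runs: int = 10) -> tuple[float, list[float]]:
    """Average wall-clock seconds of an eval-mode forward pass.

    Returns (mean, per-run durations); no gradients are computed.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    durations = []
    for _ in range(n_runs):
        tic = time.perf_counter()
        model.forward(batch, training=False)
        durations.append(time.perf_counter() - tic)
    return float(np.mean(durations)), durations
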