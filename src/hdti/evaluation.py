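"""Regression metrics, cross-validation aggregation and light baselines.

Metrics follow the conventions of the drug-sensitivity literature:
RMSE, MAE, R^2 = 1 - RMSE^2 / Var(y_obs) with Var the population
(1/n-normalized) variance — so that predicting the observed mean scores
exactly 0 — and Harrell's concordance index for continuous outcomes
(pairwise concordance over pairs with distinct observed values,
prediction ties counted 1/2).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.linear_model import LinearRegression
from sklearn.neighbors import KNeighborsRegressor

from .chem_graph import MolecularGraph

__all__ = [
    "MetricsReport",
    "CVSummary",
    "rmse",
    "mae",
    "r2",
    "concordance_index",
    "compute_metrics",
    "aggregate_cv",
    "graph_descriptors",
    "baseline_predict",
]


def _check_pair(y_obs, y_pred):
    y_obs = np.asarray(y_obs, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if y_obs.size == 0:
        raise ValueError("empty input")
    if y_obs.shape != y_pred.shape:
        raise ValueError(f"length mismatch: {y_obs.size} vs {y_pred.size}")
    return y_obs, y_pred


def rmse(y_obs, y_pred) -> float:
    """Root mean squared error."""
    y_obs, y_pred = _check_pair(y_obs, y_pred)
    return float(np.sqrt(np.mean((y_obs - y_pred) ** 2)))


def mae(y_obs, y_pred) -> float:
    """Mean absolute error."""
    y_obs, y_pred = _check_pair(y_obs, y_pred)
    return float(np.mean(np.abs(y_obs - y_pred)))


def r2(y_obs, y_pred) -> float:
    """Coefficient of determination, 1 - RMSE^2 / Var(y_obs)."""
    y_obs, y_pred = _check_pair(y_obs, y_pred)
    var = float(np.mean((y_obs - y_obs.mean()) ** 2))
    if var == 0.0:
        raise ValueError("R^2 undefined: observed values are constant")
    return float(1.0 - np.mean((y_obs - y_pred) ** 2) / var)


def concordance_index(y_obs, y_pred) -> float:
    """Harrell's C for continuous outcomes.

    Fraction of comparable pairs (distinct observed values) whose
    predictions are ranked concordantly; prediction ties count 1/2.
    """
    y_obs, y_pred = _check_pair(y_obs, y_pred)
    if y_obs.size < 2:
        raise ValueError("concordance needs at least two samples")
    do = y_obs[:, None] - y_obs[None, :]
    dp = y_pred[:, None] - y_pred[None, :]
    iu = np.triu_indices(y_obs.size, k=1)
    do, dp = do[iu], dp[iu]
    comparable = do != 0
    n_comp = int(comparable.sum())
    if n_comp == 0:
        raise ValueError("concordance undefined: all observed values equal")
    s = do[comparable] * dp[comparable]
    return float((np.sum(s > 0) + 0.5 * np.sum(s == 0)) / n_comp)


@dataclass
class MetricsReport:
    """MAE/RMSE/R^2/concordance for one evaluation on n samples."""

    mae: float
    rmse: float
    r2: float
    ci: float
    n: int

    def as_dict(self) -> dict:
        return {"mae": self.mae, "rmse": self.rmse, "r2": self.r2,
                "ci": self.ci, "n": self.n}


def compute_metrics(y_obs, y_pred) -> MetricsReport:
    """All four metrics in one report."""
    y_obs, y_pred = _check_pair(y_obs, y_pred)
    return MetricsReport(
        mae=mae(y_obs, y_pred),
        rmse=rmse(y_obs, y_pred),
        r2=r2(y_obs, y_pred),
        ci=concordance_index(y_obs, y_pred),
        n=int(y_obs.size),
    )


@dataclass
class CVSummary:
    """Per-metric mean, sample SD and t-based 95% CI over folds."""

    metric_names: tuple[str, ...]
    per_fold: dict[str, np.ndarray]
    mean: dict[str, float]
    sd: dict[str, float]
    ci_half_width: dict[str, float]
    confidence: float = 0.95

    def as_dict(self) -> dict:
        return {
            name: {
                "per_fold": list(map(float, self.per_fold[name])),
                "mean": self.mean[name],
                "sd": self.sd[name],
                "ci95_half_width": self.ci_half_width[name],
            }
            for name in self.metric_names
        }


def aggregate_cv(reports: list[MetricsReport],
                 confidence: float = 0.95) -> CVSummary:
    """Aggregate per-fold reports: mean, sample SD (n-1), t-interval.

    Half-width = t_{(1+c)/2, k-1} * SD / sqrt(k).
    """
    k = len(reports)
    if k < 2:
        raise ValueError("need at least two folds to aggregate")
    names = ("mae", "rmse", "r2", "ci")
    per_fold = {n: np.asarray([getattr(r, n) for r in reports]) for n in names}
    tcrit = float(stats.t.ppf(0.5 + confidence / 2.0, df=k - 1))
    mean = {n: float(v.mean()) for n, v in per_fold.items()}
    sd = {n: float(v.std(ddof=1)) for n, v in per_fold.items()}
    half = {n: tcrit * sd[n] / np.sqrt(k) for n in names}
    return CVSummary(metric_names=names, per_fold=per_fold, mean=mean,
                     sd=sd, ci_half_width=half, confidence=confidence)


# -- descriptor-space baselines ---------------------------------------------

_BOND_CODES = (1.0, 1.5, 2.0, 3.0)


def graph_descriptors(graph: MolecularGraph) -> np.ndarray:
    """Fixed-length graph summary: node count, mean atom features,
    bond-type histogram. Used as the feature vector of the light
    baseline regressors."""
    mean_feats = graph.node_features.mean(axis=0)
    if graph.num_edges:
        codes = graph.edge_features[:, 0]
        hist = np.asarray([(codes == c).sum() for c in _BOND_CODES],
                          dtype=float) / 2.0  # directed pairs -> bonds
    else:
        hist = np.zeros(len(_BOND_CODES))
    return np.concatenate([[float(graph.num_nodes)], mean_feats, hist])


def baseline_predict(method: str, train_graphs, train_targets,
                     test_graphs, k: int = 5) -> np.ndarray:
    """Light comparator models on graph summary descriptors.

    method="linear": ordinary least squares; method="knn": k-nearest
    neighbours (Euclidean, default k=5).
    """
    Xtr = np.stack([graph_descriptors(g) for g in train_graphs])
    Xte = np.stack([graph_descriptors(g) for g in test_graphs])
    y = np.asarray(train_targets, dtype=float)
    if method == "linear":
        # lstsq-backed fit handles singular designs via the pseudo-inverse
        if np.linalg.matrix_rank(np.column_stack([Xtr, np.ones(len(Xtr))])) \
                < Xtr.shape[1] + 1:
            warnings.warn("singular design matrix; least-squares fit uses "
                          "the pseudo-inverse solution", stacklevel=2)
        est = LinearRegression()
    elif method == "knn":
        est = KNeighborsRegressor(n_neighbors=min(k, len(Xtr)))
    else:
        raise ValueError(f"unknown baseline method {method!r}")
    est.fit(Xtr, y)
    return np.asarray(est.predict(Xte), dtype=float)
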