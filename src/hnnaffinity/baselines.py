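"""Classical descriptor-only regressors and the consensus predictor.

Random forest, gradient boosting, and AdaBoost-over-decision-trees are
fitted on the K x D interaction-descriptor matrix alone (these methods
cannot consume SMILES/sequence strings).  The consensus prediction is
the element-wise mean of the three tree-model predictions; the hybrid
neural network is never part of the consensus.

Hyperparameter defaults here are this package's choices, exposed for
override: 500 trees (RF), 500 boosting stages at learning rate 0.05
(GB), and 200 AdaBoost rounds over depth-4 trees (DT).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import (
    AdaBoostRegressor,
    GradientBoostingRegressor,
    RandomForestRegressor,
)
from sklearn.tree import DecisionTreeRegressor

ALGORITHMS = ("random_forest", "gradient_boosting", "adaboost_decision_tree")

DEFAULT_HYPERPARAMETERS: dict[str, dict] = {
    "random_forest": {"n_estimators": 500, "n_jobs": 1},
    "gradient_boosting": {"n_estimators": 500, "learning_rate": 0.05},
    "adaboost_decision_tree": {"n_estimators": 200, "max_depth": 4},
}


@dataclass
class BaselineModel:
    algorithm: str
    fitted: object
    seed: int
    hyperparameters: dict = field(default_factory=dict)
    n_features: int = 0


def _make_estimator(algorithm: str, seed: int, hyperparameters: dict):
    hp = {**DEFAULT_HYPERPARAMETERS[algorithm], **hyperparameters}
    if algorithm == "random_forest":
        return RandomForestRegressor(random_state=seed, **hp), hp
    if algorithm == "gradient_boosting":
        return GradientBoostingRegressor(random_state=seed, **hp), hp
    if algorithm == "adaboost_decision_tree":
        depth = hp.pop("max_depth")
        est = AdaBoostRegressor(
            estimator=DecisionTreeRegressor(max_depth=depth, random_state=seed),
            random_state=seed,
            **hp,
        )
        hp["max_depth"] = depth
        return est, hp
    raise ValueError(f"unknown algorithm {algorithm!r}; expected one of {ALGORITHMS}")


def train_baseline(
    algorithm: str,
    descriptors: np.ndarray,
    labels: np.ndarray,
    seed: int = 0,
    hyperparameters: dict | None = None,
) -> BaselineModel:
    """Fit one tree-ensemble regressor on descriptors; deterministic given seed."""
    X = np.asarray(descriptors, dtype=np.float64)
    y = np.asarray(labels, dtype=np.float64)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError(f"descriptors {X.shape} and labels {y.shape} misaligned")
    if X.shape[0] < 2:
        raise ValueError("need at least 2 training samples")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values in descriptors or labels")
    est, hp = _make_estimator(algorithm, seed, hyperparameters or {})
    est.fit(X, y)
    return BaselineModel(algorithm=algorithm, fitted=est, seed=seed,
                         hyperparameters=hp, n_features=X.shape[1])


def predict_baseline(model: BaselineModel, descriptors: np.ndarray) -> np.ndarray:
    X = np.asarray(descriptors, dtype=np.float64)
    if X.ndim != 2 or X.shape[1] != model.n_features:
        raise ValueError(
            f"descriptor width {X.shape[1] if X.ndim == 2 else '?'} does not "
            f"match the fitted width {model.n_features}"
        )
    if X.shape[0] == 0:
        return np.zeros(0)
    return np.asarray(model.fitted.predict(X), dtype=np.float64)


def consensus(predictions: list[np.ndarray]) -> np.ndarray:
    """Element-wise mean of >= 2 aligned prediction vectors."""
    if len(predictions) < 2:
        raise ValueError("consensus needs at least two prediction vectors")
    arrays = [np.asarray(p, dtype=np.float64) for p in predictions]
    lengths = {a.shape for a in arrays}
    if len(lengths) != 1:
        raise ValueError(f"prediction vectors have mismatched shapes: {lengths}")
    return np.mean(arrays, axis=0)
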