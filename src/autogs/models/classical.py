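"""Classical regressors behind the shared fit/predict contract.

All five operate on the (n, L) dosage matrix.  Feature/target scaling is
built into the estimators that need it (SVM, MLP).  The extreme-gradient
slot is backed by scikit-learn's histogram gradient booster, which carries
the same design (regularized second-order boosting over decision trees).
"""

from __future__ import annotations

import pickle

import numpy as np
from sklearn.compose import TransformedTargetRegressor
from sklearn.ensemble import (
    GradientBoostingRegressor,
    HistGradientBoostingRegressor,
    RandomForestRegressor,
)
from sklearn.neural_network import MLPRegressor
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR


def _scaled(est) -> TransformedTargetRegressor:
    return TransformedTargetRegressor(
        regressor=Pipeline([("scale", StandardScaler()), ("est", est)]),
        transformer=StandardScaler(),
    )


def _make_estimator(name: str, seed: int, hp: dict):
    if name == "SVM":
        defaults = dict(kernel="rbf", C=10.0, epsilon=0.1, gamma="scale")
        return _scaled(SVR(**{**defaults, **hp}))
    if name == "XGBoost":
        defaults = dict(
            max_iter=300, learning_rate=0.1, l2_regularization=1.0,
            early_stopping=False, random_state=seed,
        )
        return HistGradientBoostingRegressor(**{**defaults, **hp})
    if name == "GBDT":
        defaults = dict(
            n_estimators=300, learning_rate=0.05, max_depth=3,
            subsample=0.8, random_state=seed,
        )
        return GradientBoostingRegressor(**{**defaults, **hp})
    if name == "MLP":
        # wide tanh layer + strong L2, solved with lbfgs: stable and accurate
        # on n ~ 1e3 marker panels where SGD underfits
        defaults = dict(
            hidden_layer_sizes=(256,), activation="tanh", solver="lbfgs",
            alpha=10.0, max_iter=2000, random_state=seed,
        )
        return _scaled(MLPRegressor(**{**defaults, **hp}))
    if name == "RF":
        defaults = dict(
            n_estimators=300, max_features=0.33, min_samples_leaf=2,
            n_jobs=1, random_state=seed,
        )
        return RandomForestRegressor(**{**defaults, **hp})
    raise ValueError(f"unknown classical model {name!r}")


class SkRegressor:
    """Thin wrapper giving scikit-learn estimators the pool contract."""

    def __init__(self, name: str, seed: int = 0, hyperparams: dict | None = None):
        self.name = name
        self.seed = seed
        self.est = _make_estimator(name, seed, dict(hyperparams or {}))

    def fit(self, x, y, x_val=None, y_val=None, config=None) -> "SkRegressor":
        self.est.fit(np.asarray(x, dtype=np.float64), np.asarray(y, dtype=np.float64))
        return self

    def predict(self, x) -> np.ndarray:
        return np.asarray(self.est.predict(np.asarray(x, dtype=np.float64)), dtype=np.float64)

    def get_state(self) -> dict:
        return {"pickle": pickle.dumps(self.est, protocol=4)}

    def set_state(self, state: dict, input_shape=None) -> None:
        self.est = pickle.loads(state["pickle"])
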