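"""Random-forest regression on the four resonance-derived parameters.

An ensemble of 400 regression trees, grown on bootstrap resamples (sampling
with replacement), with half of the four variables (2) considered at each
decision split and a minimum of 3 observations per tree leaf. Rows with an
undefined bandwidth are the caller's responsibility to exclude before
fitting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.ensemble import RandomForestRegressor

from ..errors import ConfigurationError, ModelStateError

__all__ = ["RfConfig", "RfRegressor", "train_rf", "predict_rf"]


@dataclass(frozen=True)
class RfConfig:
    """Hyperparameters of the random-forest regressor."""

    n_trees: int = 400
    features_per_split: int = 2
    min_samples_leaf: int = 3
    bootstrap: bool = True
    seed: int = 0


class RfRegressor:
    """Thin wrapper holding the config and the fitted forest."""

    def __init__(self, cfg: RfConfig | None = None):
        self.cfg = cfg or RfConfig()
        self.forest: RandomForestRegressor | None = None

    def fit(self, features: np.ndarray, targets: np.ndarray) -> "RfRegressor":
        x = np.asarray(features, dtype=float)
        y = np.asarray(targets, dtype=float)
        if x.ndim != 2 or x.shape[0] != y.shape[0]:
            raise ConfigurationError(f"feature matrix {x.shape} does not match targets {y.shape}")
        if not np.all(np.isfinite(x)):
            raise ConfigurationError("feature matrix contains non-finite values; "
                                     "exclude undefined-bandwidth rows before fitting")
        if x.shape[0] < 2 * self.cfg.min_samples_leaf:
            raise ConfigurationError(
                f"need at least {2 * self.cfg.min_samples_leaf} rows, got {x.shape[0]}"
            )
        if np.all(y == y[0]):
            warnings.warn("all targets identical; forest will be a constant predictor",
                          stacklevel=2)
        self.forest = RandomForestRegressor(
            n_estimators=self.cfg.n_trees,
            max_features=self.cfg.features_per_split,
            min_samples_leaf=self.cfg.min_samples_leaf,
            bootstrap=self.cfg.bootstrap,
            random_state=self.cfg.seed,
            n_jobs=1,
        )
        self.forest.fit(x, y)
        return self

    def predict(self, features: np.ndarray) -> np.ndarray:
        if self.forest is None:
            raise ModelStateError("forest has not been trained")
        return self.forest.predict(np.asarray(features, dtype=float))


def train_rf(features: np.ndarray, targets: np.ndarray, cfg: RfConfig | None = None
             ) -> RfRegressor:
    """Fit the forest on (n, 4) feature rows and RWC targets."""
    return RfRegressor(cfg).fit(features, targets)


def predict_rf(model: RfRegressor, features: np.ndarray) -> np.ndarray:
    return model.predict(features)
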