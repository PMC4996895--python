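"""Random-forest regression and its two-pass bias correction (RFBC).

The primary model is a bagged regression-tree ensemble whose prediction
is the unweighted tree average.  Because that average shrinks toward the
sample mean, tall canopies are underestimated and short ones
overestimated.  The correction reflects each training row's out-of-bag
(OOB) residual through the observation:

    MCH_new = yhat_oob - (y - yhat_oob) = 2 * yhat_oob - y

a target biased by the same amount as the primary model but in the
opposite direction.  A second ensemble is fit on (X, MCH_new), and the
corrected prediction is

    yhat_BC(x) = yhat(x) - (yhat_new(x) - yhat(x)) = 2 * yhat(x) - yhat_new(x).

Forests are scikit-learn ``RandomForestRegressor`` ensembles; OOB
predictions are averaged explicitly over the trees whose bootstrap
excluded each row.  Rows that every bootstrap happened to include
(probability ~(1 - 1/n)^J per tree count J) receive the full-ensemble
prediction instead and are flagged, preserving the row alignment of the
reflection step.  The bias ensemble uses the same configuration but an
independent seed substream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestRegressor
from sklearn.ensemble._forest import _generate_unsampled_indices

from .errors import ConfigurationError, InvalidInputError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RFConfig:
    """Forest configuration (common regression-forest defaults).

    ``max_features`` is the number (int) or fraction (float) of
    predictors considered per split; the default third of the predictors
    is standard regression practice.
    """

    n_trees: int = 500
    max_features: float = 1.0 / 3.0
    min_leaf: int = 5
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ConfigurationError(f"n_trees must be >= 1, got {self.n_trees}")
        if isinstance(self.max_features, float):
            if not (0.0 < self.max_features <= 1.0):
                raise ConfigurationError(
                    f"fractional max_features must be in (0, 1], "
                    f"got {self.max_features}")
        elif self.max_features < 1:
            raise ConfigurationError(
                f"max_features must be >= 1, got {self.max_features}")
        if self.min_leaf < 1:
            raise ConfigurationError(f"min_leaf must be >= 1, got {self.min_leaf}")


@dataclass
class RFFit:
    """A fitted ensemble plus per-training-row OOB predictions."""

    model: RandomForestRegressor
    oob_prediction: np.ndarray
    never_oob: np.ndarray  # rows whose OOB average fell back to the ensemble

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.model.n_features_in_:
            raise InvalidInputError(
                f"X must be (n, {self.model.n_features_in_}), got {X.shape}")
        return self.model.predict(X)


def _make_forest(config: RFConfig, seed) -> RandomForestRegressor:
    return RandomForestRegressor(
        n_estimators=config.n_trees,
        max_features=config.max_features,
        min_samples_leaf=config.min_leaf,
        bootstrap=True,
        random_state=seed,
        n_jobs=1,
    )


def _oob_predictions(forest: RandomForestRegressor, X: np.ndarray
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Average each row over the trees whose bootstrap excluded it."""
    n = X.shape[0]
    ms = forest.max_samples
    if ms is None:
        n_boot = n
    elif isinstance(ms, float):
        n_boot = max(round(n * ms), 1)
    else:
        n_boot = int(ms)
    sums = np.zeros(n)
    counts = np.zeros(n, dtype=int)
    for tree in forest.estimators_:
        idx = _generate_unsampled_indices(tree.random_state, n, n_boot, None)
        if idx.size:
            sums[idx] += tree.predict(X[idx])
            counts[idx] += 1
    never = counts == 0
    oob = np.empty(n)
    oob[~never] = sums[~never] / counts[~never]
    if never.any():
        logger.info("%d training rows were never out-of-bag; using the "
                    "full-ensemble prediction for them", int(never.sum()))
        oob[never] = forest.predict(X[never])
    return oob, never


def fit_rf(X, y, config: RFConfig = RFConfig()) -> RFFit:
    """Fit a bagged forest and return it with OOB predictions."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or y.shape != (X.shape[0],):
        raise InvalidInputError(
            f"X must be (n, p) with matching y, got {X.shape} / {y.shape}")
    if X.shape[0] < 2:
        raise InvalidInputError("need at least two training rows")
    forest = _make_forest(config, config.seed).fit(X, y)
    oob, never = _oob_predictions(forest, X)
    return RFFit(forest, oob, never)


@dataclass
class RFBCModel:
    """Primary ensemble plus the reflected-residual bias ensemble."""

    primary: RFFit
    bias: RFFit
    config: RFConfig


def reflected_targets(oob_prediction, y) -> np.ndarray:
    """Reflect the OOB residual through the observation: 2*oob - y.

    The result is biased by the same amount as the primary model but in
    the opposite direction; it is the training target of the bias stage.
    """
    return 2.0 * np.asarray(oob_prediction, float) - np.asarray(y, float)


def fit_rfbc(X, y, config: RFConfig = RFConfig()) -> RFBCModel:
    """Two-pass fit: primary forest, then a forest on 2*oob - y."""
    seeds = np.random.SeedSequence(config.seed).spawn(2)
    s1, s2 = (int(s.generate_state(1)[0] % (2**31)) for s in seeds)
    primary = fit_rf(X, y, RFConfig(config.n_trees, config.max_features,
                                    config.min_leaf, s1))
    y_new = reflected_targets(primary.oob_prediction, y)
    bias = fit_rf(X, y_new, RFConfig(config.n_trees, config.max_features,
                                     config.min_leaf, s2))
    return RFBCModel(primary, bias, config)


def predict_rfbc(model: RFBCModel, X) -> np.ndarray:
    """Bias-corrected prediction 2 * primary(X) - bias(X)."""
    return 2.0 * model.primary.predict(X) - model.bias.predict(X)


class RandomForestModel:
    """Estimator-style wrapper around :func:`fit_rf`."""

    def __init__(self, config: RFConfig = RFConfig()):
        self.config = config
        self.fit_: RFFit | None = None

    def fit(self, X, y) -> "RandomForestModel":
        self.fit_ = fit_rf(X, y, self.config)
        return self

    def predict(self, X) -> np.ndarray:
        if self.fit_ is None:
            raise InvalidInputError("fit before predict")
        return self.fit_.predict(X)


class BiasCorrectedForest:
    """Estimator-style wrapper around :func:`fit_rfbc`."""

    def __init__(self, config: RFConfig = RFConfig()):
        self.config = config
        self.model_: RFBCModel | None = None

    def fit(self, X, y) -> "BiasCorrectedForest":
        self.model_ = fit_rfbc(X, y, self.config)
        return self

    def predict(self, X) -> np.ndarray:
        if self.model_ is None:
            raise InvalidInputError("fit before predict")
        return predict_rfbc(self.model_, X)
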