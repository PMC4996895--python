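"""Maximum-entropy class-probability regression for continuous MCH.

The response is discretized into height classes; for each class k a
Gibbs density ``q_k(x) proportional to exp(lambda_k . f(x))`` is fit
over a background sample of the prediction domain, which is the
entropy-maximal density whose (regularized) feature expectations match
the class sample's empirical feature means.  The "raw" output is the
density ratio against the uniform background density,
``p_k_raw(x) = q_k(x) / p(x)``, and class priors are the empirical
training proportions ``p0(A_k) = N_k / N_total``.  Prediction is the
posterior expectation of the class nominal heights:

    <MCH_i> = sum_k [p_k_raw(X_i)]^m p0(A_k) MCHbar_k
              / sum_k [p_k_raw(X_i)]^m p0(A_k)

``m = 1`` is the plain expectation; raising ``m`` concentrates weight
on the most probable classes and pulls predictions at the distribution
tails toward their class centers.  ``m = 3`` is the bias-corrected
variant (MEBC).

Feature expansion: background-standardized layer values plus their
squares (linear + quadratic constraints); each per-class fit is an
L2-regularized convex problem solved with L-BFGS-B (budget 500
iterations, gradient tolerance 1e-6).  All raw outputs are handled in
log space, normalized per pixel by the maximum before exponentiation,
so underflow cannot zero the expectation denominator.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp

from .errors import (
    ConvergenceError,
    DegenerateProbabilityError,
    InvalidInputError,
    InvalidParameterError,
)
from .raster_io import SampleSet

DEFAULT_POWER_M = 3.0   # best-performing power weight for MEBC
DEFAULT_BIN_WIDTH = 2.0  # metres


@dataclass
class ClassBinning:
    """Uniform response bins with empty classes dropped.

    ``edges`` are the uniform bin boundaries; a response y belongs to
    bin j when ``edges[j] < y <= edges[j+1]``.  Only non-empty bins are
    kept as classes; ``bin_of_class[k]`` maps class k back to its bin,
    ``centers[k]`` is the mean training response in the class (bin
    midpoint as fallback) and ``counts[k]`` its sample count.
    """

    edges: np.ndarray
    bin_of_class: np.ndarray
    centers: np.ndarray
    counts: np.ndarray

    @property
    def n_classes(self) -> int:
        return len(self.centers)

    def assign(self, y) -> np.ndarray:
        """Class index per response; -1 for responses in dropped bins."""
        y = np.asarray(y, dtype=float)
        b = np.digitize(y, self.edges, right=True) - 1
        b = np.clip(b, 0, len(self.edges) - 2)
        lut = np.full(len(self.edges) - 1, -1, dtype=int)
        lut[self.bin_of_class] = np.arange(self.n_classes)
        return lut[b]


def make_binning(responses, bin_width: float = DEFAULT_BIN_WIDTH
                 ) -> ClassBinning:
    """Bin responses into uniform classes of ``bin_width`` metres.

    Bins span ``(0, max(responses)]`` (extended below zero only if a
    response demands it); empty bins are dropped and centers are the
    per-class response means.
    """
    y = np.asarray(responses, dtype=float)
    if y.size == 0:
        raise InvalidInputError("responses must be non-empty")
    if bin_width <= 0:
        raise InvalidParameterError(f"bin_width must be > 0, got {bin_width}")
    lo = min(0.0, np.floor(y.min() / bin_width - 1) * bin_width)
    n_bins = int(np.ceil((y.max() - lo) / bin_width))
    n_bins = max(n_bins, 1)
    edges = lo + bin_width * np.arange(n_bins + 1)
    b = np.clip(np.digitize(y, edges, right=True) - 1, 0, n_bins - 1)
    kept = np.flatnonzero(np.bincount(b, minlength=n_bins))
    centers = np.array([y[b == j].mean() for j in kept])
    counts = np.array([(b == j).sum() for j in kept])
    return ClassBinning(edges, kept, centers, counts)


@dataclass
class MEModel:
    """Fitted maximum-entropy class model."""

    binning: ClassBinning
    class_weights: np.ndarray      # (K, F) Gibbs coefficients lambda_k
    log_normalizers: np.ndarray    # (K,) log mean_bg exp(lambda_k . f)
    priors: np.ndarray             # (K,) empirical N_k / N_total
    feature_mean: np.ndarray       # (p,) background means for standardization
    feature_sd: np.ndarray         # (p,) background sds
    power_m: float = DEFAULT_POWER_M
    regularization: float = 0.01

    def features(self, X) -> np.ndarray:
        """Standardized values and their squares."""
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.feature_mean.size:
            raise InvalidInputError(
                f"X must be (n, {self.feature_mean.size}), got {X.shape}")
        z = (X - self.feature_mean) / self.feature_sd
        return np.hstack([z, z**2])

    def log_raw(self, X) -> np.ndarray:
        """(n, K) log density ratios log p_k_raw(x)."""
        return self.features(X) @ self.class_weights.T - self.log_normalizers

    def to_json(self) -> str:
        b = self.binning
        return json.dumps({
            "edges": b.edges.tolist(), "bin_of_class": b.bin_of_class.tolist(),
            "centers": b.centers.tolist(), "counts": b.counts.tolist(),
            "class_weights": self.class_weights.tolist(),
            "log_normalizers": self.log_normalizers.tolist(),
            "priors": self.priors.tolist(),
            "feature_mean": self.feature_mean.tolist(),
            "feature_sd": self.feature_sd.tolist(),
            "power_m": self.power_m, "regularization": self.regularization,
        })

    @classmethod
    def from_json(cls, doc: str) -> "MEModel":
        d = json.loads(doc)
        binning = ClassBinning(np.array(d["edges"]),
                               np.array(d["bin_of_class"], dtype=int),
                               np.array(d["centers"]),
                               np.array(d["counts"], dtype=int))
        return cls(binning, np.array(d["class_weights"]),
                   np.array(d["log_normalizers"]), np.array(d["priors"]),
                   np.array(d["feature_mean"]), np.array(d["feature_sd"]),
                   d["power_m"], d["regularization"])


def _fit_class(f_bar: np.ndarray, F_bg: np.ndarray, reg: float,
               max_iter: int, tol: float, class_id: int) -> np.ndarray:
    """Maximize the regularized Gibbs likelihood of one class."""
    log_n = np.log(F_bg.shape[0])

    def objective(lam):
        eta = F_bg @ lam
        lz = logsumexp(eta) - log_n
        p = np.exp(eta - lz - log_n)
        obj = -f_bar @ lam + lz + reg * lam @ lam
        grad = -f_bar + p @ F_bg + 2.0 * reg * lam
        return obj, grad

    res = minimize(objective, np.zeros(F_bg.shape[1]), jac=True,
                   method="L-BFGS-B",
                   options={"maxiter": max_iter, "gtol": tol,
                            "ftol": 1e-12})
    gnorm = float(np.max(np.abs(res.jac)))
    if not res.success and gnorm > 1e-4:
        raise ConvergenceError(
            f"class {class_id}: optimizer stopped ({res.message}) with "
            f"gradient norm {gnorm:.3e}", class_id=class_id,
            gradient_norm=gnorm)
    return res.x


def fit_me(train: SampleSet, background: np.ndarray,
           binning: ClassBinning | None = None,
           bin_width: float = DEFAULT_BIN_WIDTH,
           regularization: float = 0.01,
           power_m: float = DEFAULT_POWER_M,
           max_iter: int = 500, tol: float = 1e-6) -> MEModel:
    """Fit per-class Gibbs density ratios over a background sample.

    ``background`` should cover the prediction domain (all valid pixels
    or a large uniform subsample).  Classes come from ``binning`` or a
    fresh uniform binning of the training responses; classes without
    training members are dropped (prior 0).
    """
    if train.y is None:
        raise InvalidInputError("training SampleSet needs responses")
    bg = np.asarray(background, dtype=float)
    if bg.ndim != 2 or bg.shape[1] != train.X.shape[1]:
        raise InvalidInputError(
            "background must be (n_bg, n_predictors) matching the train set")
    if binning is None:
        binning = make_binning(train.y, bin_width)
    mu = bg.mean(axis=0)
    sd = bg.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)

    labels = binning.assign(train.y)
    keep = np.flatnonzero(np.bincount(labels[labels >= 0],
                                      minlength=binning.n_classes))
    if keep.size < binning.n_classes:
        binning = ClassBinning(binning.edges, binning.bin_of_class[keep],
                               binning.centers[keep], binning.counts[keep])
        labels = binning.assign(train.y)

    z_bg = (bg - mu) / sd
    F_bg = np.hstack([z_bg, z_bg**2])
    z_tr = (train.X - mu) / sd
    F_tr = np.hstack([z_tr, z_tr**2])

    K = binning.n_classes
    weights = np.empty((K, F_bg.shape[1]))
    log_norm = np.empty(K)
    priors = np.empty(K)
    log_n = np.log(F_bg.shape[0])
    for k in range(K):
        members = labels == k
        priors[k] = members.mean()
        weights[k] = _fit_class(F_tr[members].mean(axis=0), F_bg,
                                regularization, max_iter, tol, k)
        log_norm[k] = logsumexp(F_bg @ weights[k]) - log_n
    priors /= priors.sum()
    return MEModel(binning, weights, log_norm, priors, mu, sd,
                   power_m, regularization)


def power_expectation(raw, priors, centers, m: float = 1.0) -> np.ndarray:
    """Posterior expectation of class centers from raw density ratios.

    Evaluates ``sum_k raw_k^m prior_k center_k / sum_k raw_k^m prior_k``
    per row; ``m = 1`` is the plain Bayes expectation, larger ``m``
    up-weights the most probable classes.
    """
    raw = np.atleast_2d(np.asarray(raw, dtype=float))
    with np.errstate(divide="ignore"):
        log_raw = np.log(raw)
    return _expectation_from_log_raw(log_raw, np.asarray(priors, float),
                                     np.asarray(centers, float), m)


def _expectation_from_log_raw(log_raw, priors, centers, m) -> np.ndarray:
    if m < 1:
        raise InvalidParameterError(f"power m must be >= 1, got {m}")
    with np.errstate(divide="ignore"):
        logw = m * log_raw + np.log(priors)
    peak = logw.max(axis=1, keepdims=True)
    if not np.all(np.isfinite(peak)):
        raise DegenerateProbabilityError(
            "all class weights vanished for at least one row")
    w = np.exp(logw - peak)
    return (w @ centers) / w.sum(axis=1)


def posterior_probabilities(model: MEModel, X) -> np.ndarray:
    """(n, K) posterior class probabilities (non-negative, rows sum to 1)."""
    logw = model.log_raw(X) + np.log(model.priors)
    logw -= logw.max(axis=1, keepdims=True)
    w = np.exp(logw)
    return w / w.sum(axis=1, keepdims=True)


def predict_me(model: MEModel, X, m: float | None = None) -> np.ndarray:
    """Predict MCH as the (power-weighted) expectation of class centers.

    ``m = 1`` is the plain expectation; ``m`` defaulting to the model's
    ``power_m`` (3) gives the bias-corrected MEBC prediction.
    """
    if m is None:
        m = model.power_m
    return _expectation_from_log_raw(model.log_raw(X), model.priors,
                                     model.binning.centers, m)


class MaxEntRegressor:
    """Estimator-style wrapper: fit on (X, y), predict heights.

    ``power_m=1`` is the plain ME regressor; ``power_m=3`` the
    bias-corrected MEBC.  ``background`` defaults to the training
    predictors; pass the full valid-pixel matrix of a scene when
    available (capped at ``background_cap`` by seeded subsampling).
    """

    def __init__(self, bin_width: float = DEFAULT_BIN_WIDTH,
                 power_m: float = 1.0, regularization: float = 0.01,
                 background: np.ndarray | None = None,
                 background_cap: int = 100_000,
                 seed: int | None = None,
                 max_iter: int = 500, tol: float = 1e-6):
        self.bin_width = bin_width
        self.power_m = power_m
        self.regularization = regularization
        self.background = background
        self.background_cap = background_cap
        self.seed = seed
        self.max_iter = max_iter
        self.tol = tol
        self.model_: MEModel | None = None

    def fit(self, X, y) -> "MaxEntRegressor":
        X = np.asarray(X, dtype=float)
        bg = X if self.background is None else np.asarray(self.background,
                                                         dtype=float)
        if bg.shape[0] > self.background_cap:
            rng = np.random.default_rng(self.seed)
            bg = bg[rng.choice(bg.shape[0], self.background_cap,
                               replace=False)]
        self.model_ = fit_me(SampleSet(X, y), bg,
                             bin_width=self.bin_width,
                             regularization=self.regularization,
                             power_m=self.power_m,
                             max_iter=self.max_iter, tol=self.tol)
        return self

    def predict(self, X) -> np.ndarray:
        if self.model_ is None:
            raise InvalidInputError("fit before predict")
        return predict_me(self.model_, X, self.power_m)
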