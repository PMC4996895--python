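"""Accuracy/bias statistics, Monte Carlo cross-validation, variograms.

Metrics
-------
RMSE, R^2 and the mean signed deviation MSD = mean(predicted - measured),
plus two tail-bias diagnostics: MSD1, the MSD over pairs whose
predicted + measured sum is below a low threshold (default 20 m — small
trees), and MSD2, over pairs whose sum exceeds a high threshold (default
60 m — large trees).  Underestimation of tall canopies therefore shows
up as negative MSD2.  Sums equal to a threshold fall in neither subset;
a metric over an empty subset is reported as NaN, never as zero.

Cross-validation is Monte Carlo CV (repeated random subsampling): each
repetition draws a fresh disjoint train/test split, fits a model from a
factory, and scores on the held-out rows; per-metric mean and standard
deviation across repetitions are reported.

The semi-variogram is the classical estimator
``gamma(h) = (1 / (2 N(h))) * sum over pairs at lag in bin h of
(z_i - z_j)^2`` with pairs binned by Euclidean distance between pixel
centers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.spatial.distance import pdist

from .errors import ConfigurationError, InvalidInputError, InvalidParameterError
from .raster_io import Raster, SampleSet

#: Metric names carried through CV aggregation.
METRICS = ("rmse", "r2", "msd", "msd1", "msd2")


@dataclass
class EvalReport:
    """Point metrics for one prediction/measurement pair of vectors."""

    rmse: float
    r2: float
    msd: float
    msd1: float
    msd2: float
    n_test: int
    n_msd1: int
    n_msd2: int

    def as_dict(self) -> dict[str, float]:
        return {m: getattr(self, m) for m in METRICS}


@dataclass
class CVReport:
    """Per-metric (mean, sd) across Monte Carlo CV repetitions."""

    mean: dict[str, float]
    sd: dict[str, float]
    n_reps: int
    n_train: int
    n_test: int
    reps: list[EvalReport] = field(default_factory=list)

    def formatted(self, metric: str, digits: int = 2) -> str:
        return (f"{self.mean[metric]:.{digits}f} ± "
                f"{self.sd[metric]:.{digits}f}")


def compute_metrics(predicted, measured,
                    low_sum_threshold: float = 20.0,
                    high_sum_threshold: float = 60.0) -> EvalReport:
    """RMSE, R^2, MSD and the tail diagnostics MSD1/MSD2.

    The tail subsets use strict inequalities on predicted + measured:
    sum < ``low_sum_threshold`` for MSD1, sum > ``high_sum_threshold``
    for MSD2.
    """
    p = np.asarray(predicted, dtype=float)
    m = np.asarray(measured, dtype=float)
    if p.shape != m.shape or p.ndim != 1:
        raise InvalidInputError(
            f"predicted/measured must be equal-length vectors, "
            f"got shapes {p.shape} and {m.shape}")
    if p.size == 0:
        raise InvalidInputError("empty metric input")
    err = p - m
    rmse = float(np.sqrt(np.mean(err**2)))
    msd = float(np.mean(err))
    if p.size >= 2 and np.var(m) > 0:
        r2 = float(1.0 - np.sum(err**2) / np.sum((m - m.mean())**2))
    else:
        r2 = math.nan
    s = p + m
    lo = s < low_sum_threshold
    hi = s > high_sum_threshold
    msd1 = float(np.mean(err[lo])) if lo.any() else math.nan
    msd2 = float(np.mean(err[hi])) if hi.any() else math.nan
    return EvalReport(rmse, r2, msd, msd1, msd2,
                      p.size, int(lo.sum()), int(hi.sum()))


def monte_carlo_cv(data: SampleSet, n_train: int, n_test,
                   n_reps: int, model_factory: Callable[[int], object],
                   seed: int | None = None,
                   low_sum_threshold: float = 20.0,
                   high_sum_threshold: float = 60.0) -> CVReport:
    """Repeated random subsampling CV.

    Per repetition: a fresh disjoint train/test split of ``data``
    (``n_test`` may be the string ``"rest"``), a model built by
    ``model_factory(rep_seed)`` and fit on the training rows, then scored
    on the test rows.  Metric means and standard deviations (ddof=1, NaN
    aware for the tail subsets) are aggregated across repetitions.
    """
    n = len(data)
    if data.y is None:
        raise InvalidInputError("monte_carlo_cv needs a response vector")
    if n_train < 1 or n_reps < 1:
        raise ConfigurationError("n_train and n_reps must be >= 1")
    rest = n_test == "rest"
    n_test_num = n - n_train if rest else int(n_test)
    if n_train + n_test_num > n or n_test_num < 1:
        raise ConfigurationError(
            f"infeasible split: n_train={n_train}, n_test={n_test_num}, "
            f"available={n}")
    root = np.random.SeedSequence(seed)
    reps: list[EvalReport] = []
    for rep, ss in enumerate(root.spawn(n_reps)):
        rng = np.random.default_rng(ss)
        perm = rng.permutation(n)
        tr = data.subset(perm[:n_train])
        te = data.subset(perm[n_train:n_train + n_test_num])
        model = model_factory(int(ss.generate_state(1)[0] % (2**31)))
        model.fit(tr.X, tr.y)
        pred = np.asarray(model.predict(te.X), dtype=float)
        reps.append(compute_metrics(pred, te.y,
                                    low_sum_threshold, high_sum_threshold))
    mean = {}
    sd = {}
    for met in METRICS:
        vals = np.array([getattr(r, met) for r in reps], dtype=float)
        ok = np.isfinite(vals)
        mean[met] = float(vals[ok].mean()) if ok.any() else math.nan
        sd[met] = (float(vals[ok].std(ddof=1)) if ok.sum() > 1
                   else (0.0 if ok.any() else math.nan))
    return CVReport(mean, sd, n_reps, n_train, n_test_num, reps)


# ---------------------------------------------------------------------------
# Semi-variograms
# ---------------------------------------------------------------------------

@dataclass
class VariogramResult:
    """Binned empirical semi-variogram."""

    lag_centers: np.ndarray
    semivariance: np.ndarray
    pair_counts: np.ndarray
    max_lag: float

    def initial_slope(self, n_bins: int = 3) -> float:
        """Least-squares slope of gamma vs lag over the first populated bins."""
        ok = np.flatnonzero(self.pair_counts > 0)[:n_bins]
        if ok.size < 2:
            return math.nan
        A = np.column_stack([self.lag_centers[ok], np.ones(ok.size)])
        coef, *_ = np.linalg.lstsq(A, self.semivariance[ok], rcond=None)
        return float(coef[0])


def semivariogram(coords, values, max_lag: float,
                  n_bins: int = 30) -> VariogramResult:
    """Empirical semi-variogram of scattered points.

    ``coords`` is (n, 2) in metres.  Pairs farther apart than ``max_lag``
    are excluded; a bin with no pairs gets NaN semivariance (never zero).
    """
    c = np.asarray(coords, dtype=float)
    v = np.asarray(values, dtype=float)
    if c.ndim != 2 or c.shape[1] != 2 or v.shape != (c.shape[0],):
        raise InvalidInputError("coords must be (n, 2) and values length n")
    if c.shape[0] < 2:
        raise InvalidInputError("need at least two points")
    if max_lag <= 0:
        raise InvalidParameterError(f"max_lag must be > 0, got {max_lag}")
    d = pdist(c)
    sq = pdist(v[:, None], metric="sqeuclidean")
    edges = np.linspace(0.0, max_lag, n_bins + 1)
    keep = d <= max_lag
    idx = np.clip(np.digitize(d[keep], edges) - 1, 0, n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins).astype(int)
    sums = np.bincount(idx, weights=sq[keep], minlength=n_bins)
    with np.errstate(invalid="ignore", divide="ignore"):
        gamma = np.where(counts > 0, sums / (2.0 * np.maximum(counts, 1)),
                         np.nan)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return VariogramResult(centers, gamma, counts, max_lag)


def raster_semivariogram(raster: Raster, max_lag: float | None = None,
                         n_bins: int = 30, sample: int = 3000,
                         seed: int | None = None) -> VariogramResult:
    """Variogram of a raster's valid pixels (subsampled for tractability).

    Default ``max_lag`` is half the scene diagonal; pixel-center
    coordinates come from the raster transform.
    """
    rows, cols = np.nonzero(raster.valid_mask)
    if rows.size < 2:
        raise InvalidInputError("raster has fewer than two valid pixels")
    if rows.size > sample:
        rng = np.random.default_rng(seed)
        pick = rng.choice(rows.size, size=sample, replace=False)
        rows, cols = rows[pick], cols[pick]
    coords = raster.transform.pixel_centers(rows, cols)
    if max_lag is None:
        s = raster.transform.pixel_size
        nr, nc = raster.shape
        max_lag = 0.5 * math.hypot(nr * s, nc * s)
    return semivariogram(coords, raster.values[rows, cols], max_lag, n_bins)
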