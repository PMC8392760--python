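"""Gaussian-process input-function prediction (MLIF).

Each scan contributes an input vector x_n — the three carotid IDIF
curves, peak-normalized per channel over the training cohort and
concatenated (length 3*T, T = 361 one-second samples over 0-6 min) —
and an output y_n, the measured arterial input function (length T,
kBq/mL).  A single Matern-5/2 kernel over the 3T-dimensional inputs is
shared by all T output time points, so prediction is the standard GP
conditional in matrix form,

    E[y*] = k_*^T (K + sigma_eps^2 I)^-1 Y
    V[y*] = k(x*, x*) - k_*^T (K + sigma_eps^2 I)^-1 k_*,

with Y the N x T matrix of training AIF residuals about the training
mean curve (the GP mean function is the empirical cohort-mean AIF; a
zero mean on strictly positive curves drives the marginal-likelihood
optimum to a degenerate flat kernel that predicts the same curve for
every subject).  Hyperparameters
(lengthscale, signal variance, noise variance) maximize the log
marginal likelihood summed over output dimensions; linear algebra goes
through a cached Cholesky factor of K + sigma_eps^2 I.

Only the inputs are normalized: the output scale carries the absolute
calibration, which is how a predicted MLIF needs no blood sample.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve, cholesky
from scipy.optimize import minimize
from scipy.spatial.distance import cdist

from .carotid_segmentation import IdifSet
from .curves import TimeActivityCurve

__all__ = [
    "NormalizationConstants",
    "TrainingSet",
    "GpMlifModel",
    "MlifPrediction",
    "matern52",
    "fit_normalization",
    "normalize",
    "build_training_set",
    "train",
    "predict",
    "loo_cross_validate",
]

_JITTER = 1e-10


@dataclass(frozen=True)
class NormalizationConstants:
    """Per-channel cohort-maximum peaks used to scale IDIF inputs."""

    peak10: float
    peak100: float
    peak1000: float

    def __post_init__(self) -> None:
        if min(self.peak10, self.peak100, self.peak1000) <= 0:
            raise ValueError("normalization peaks must be positive")

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.peak10, self.peak100, self.peak1000)


@dataclass(frozen=True)
class TrainingSet:
    """Paired normalized inputs X (N x 3T) and AIF outputs Y (N x T)."""

    X: np.ndarray
    Y: np.ndarray
    norm: NormalizationConstants

    def __post_init__(self) -> None:
        X = np.atleast_2d(np.asarray(self.X, dtype=float))
        Y = np.atleast_2d(np.asarray(self.Y, dtype=float))
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "Y", Y)
        if X.shape[0] != Y.shape[0]:
            raise ValueError("inputs and outputs must pair up")

    @property
    def n_subjects(self) -> int:
        return self.X.shape[0]


def matern52(A: np.ndarray, B: np.ndarray, lengthscale: float, signal_var: float) -> np.ndarray:
    """Matern covariance with smoothness nu = 5/2 between row vectors."""
    r = cdist(np.atleast_2d(A), np.atleast_2d(B)) / lengthscale
    s5r = np.sqrt(5.0) * r
    return signal_var * (1.0 + s5r + 5.0 * r**2 / 3.0) * np.exp(-s5r)


def fit_normalization(train_idifs: list[IdifSet]) -> NormalizationConstants:
    """Highest peak per IDIF channel across the training cohort."""
    if not train_idifs:
        raise ValueError("empty training cohort")
    peaks = [
        max(s.channels()[c].peak for s in train_idifs) for c in range(3)
    ]
    if min(peaks) <= 0:
        raise ValueError("an IDIF channel is non-positive across the whole cohort")
    return NormalizationConstants(*peaks)


def normalize(idifs: IdifSet, norm: NormalizationConstants) -> np.ndarray:
    """Concatenate the three IDIF curves, each divided by its channel's
    cohort-maximum peak.  Training vectors land in [0, 1]; test vectors
    may exceed 1 (relative amplitudes between subjects are preserved)."""
    parts = [c.value / p for c, p in zip(idifs.channels(), norm.as_tuple())]
    return np.concatenate(parts)


def build_training_set(cohort: list[tuple[IdifSet, TimeActivityCurve]]) -> TrainingSet:
    """Assemble (X, Y) from per-scan (IdifSet, measured AIF) pairs."""
    norm = fit_normalization([idifs for idifs, _ in cohort])
    X = np.stack([normalize(idifs, norm) for idifs, _ in cohort])
    Y = np.stack([aif.value for _, aif in cohort])
    return TrainingSet(X, Y, norm)


@dataclass(frozen=True)
class GpMlifModel:
    """A trained MLIF model: kernel hyperparameters, training matrices
    and the cached Cholesky factor of K + sigma_eps^2 I."""

    lengthscale: float
    signal_var: float
    noise_var: float
    norm: NormalizationConstants
    train_X: np.ndarray
    train_Y: np.ndarray
    y_mean: np.ndarray  # empirical mean AIF of the training cohort
    cho: tuple  # scipy (c, lower) pair
    alpha: np.ndarray  # (K + sigma^2 I)^-1 (Y - y_mean), cached
    t_grid: np.ndarray
    log_marginal_likelihood: float


@dataclass(frozen=True)
class MlifPrediction:
    """Predicted input function with its (shared) pointwise variance."""

    mean: TimeActivityCurve
    variance: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.variance) < 0):
            raise ValueError("predictive variance must be non-negative")


def _lml(theta: np.ndarray, X: np.ndarray, Y: np.ndarray) -> float:
    """Log marginal likelihood of mean-centred outputs, summed over the
    T output dimensions; theta = log(lengthscale, signal_var, noise_var)."""
    ell, sf2, sn2 = np.exp(theta)
    Y = Y - Y.mean(axis=0)
    N, T = Y.shape
    K = matern52(X, X, ell, sf2) + (sn2 + _JITTER) * np.eye(N)
    try:
        L = cholesky(K, lower=True)
    except np.linalg.LinAlgError:
        return -np.inf
    alpha = cho_solve((L, True), Y)
    logdet = 2.0 * np.sum(np.log(np.diag(L)))
    return float(
        -0.5 * np.sum(Y * alpha) - 0.5 * T * logdet - 0.5 * N * T * np.log(2.0 * np.pi)
    )


def _finalize(theta: np.ndarray, ts: TrainingSet, t_grid: np.ndarray) -> GpMlifModel:
    ell, sf2, sn2 = np.exp(theta)
    N = ts.n_subjects
    K = matern52(ts.X, ts.X, ell, sf2) + (sn2 + _JITTER) * np.eye(N)
    cho = cho_factor(K, lower=True)
    y_mean = ts.Y.mean(axis=0)
    alpha = cho_solve(cho, ts.Y - y_mean)
    return GpMlifModel(
        lengthscale=float(ell),
        signal_var=float(sf2),
        noise_var=float(sn2),
        norm=ts.norm,
        train_X=ts.X,
        train_Y=ts.Y,
        y_mean=y_mean,
        cho=cho,
        alpha=alpha,
        t_grid=np.asarray(t_grid, dtype=float),
        log_marginal_likelihood=_lml(theta, ts.X, ts.Y),
    )


def _default_inits(ts: TrainingSet) -> list[tuple[float, float, float]]:
    """Deterministic data-scaled starting points for the optimizer.

    The lengthscale starts at the median pairwise input distance and the
    variances at the centred-output variance: marginal-likelihood
    surfaces for curve-valued outputs are multimodal, and starting on
    the data scale (plus a small fixed multi-start) keeps quasi-Newton
    ascent out of the degenerate flat- and diagonal-kernel modes.
    """
    d = cdist(ts.X, ts.X)
    med = float(np.median(d[np.triu_indices_from(d, k=1)])) or 1.0
    var = float(np.mean((ts.Y - ts.Y.mean(axis=0)) ** 2)) or 1.0
    return [
        (med, var, 0.01 * var),
        (med / 3.0, var, 0.1 * var),
        (3.0 * med, var, 0.1 * var),
    ]


def train(
    ts: TrainingSet,
    t_grid: np.ndarray | None = None,
    init: tuple[float, float, float] | None = None,
    optimize: bool = True,
    maxiter: int = 1000,
) -> GpMlifModel:
    """Fit hyperparameters by maximizing the log marginal likelihood.

    Quasi-Newton (L-BFGS-B) over log-hyperparameters.  By default a
    small fixed set of data-scaled starting points is tried and the
    solution with the highest marginal likelihood kept; everything is
    deterministic given the training set.  Pass ``init`` to use a single
    explicit start, or ``optimize=False`` to condition on ``init`` as-is.
    """
    if ts.n_subjects < 2 and optimize:
        raise ValueError("need at least two training subjects to optimize hyperparameters")
    if t_grid is None:
        t_grid = np.arange(ts.Y.shape[1], dtype=float)
    if not optimize:
        if init is None:
            raise ValueError("optimize=False requires explicit hyperparameters")
        return _finalize(np.log(np.asarray(init, dtype=float)), ts, t_grid)
    inits = [init] if init is not None else _default_inits(ts)
    bounds = [(np.log(1e-3), np.log(1e4))] * 2 + [(np.log(1e-8), np.log(1e4))]
    best_theta, best_val = None, np.inf
    for start in inits:
        theta0 = np.log(np.asarray(start, dtype=float))
        res = minimize(
            lambda th: -_lml(th, ts.X, ts.Y),
            theta0,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": maxiter, "gtol": 1e-6},
        )
        if np.isfinite(res.fun) and res.fun < best_val:
            best_theta, best_val = res.x, float(res.fun)
    if best_theta is None:
        best_theta = np.log(np.asarray(inits[0], dtype=float))
    return _finalize(best_theta, ts, t_grid)


def predict(model: GpMlifModel, idifs: IdifSet) -> MlifPrediction:
    """GP conditional mean and variance for one scan's IDIF set.

    The test input is normalized with the *training* constants (no test
    blood data enters).  The variance is the single-kernel value shared
    by all output time points.
    """
    x_star = normalize(idifs, model.norm)[None, :]
    if x_star.shape[1] != model.train_X.shape[1]:
        raise ValueError("test IDIF grid does not match the training grid")
    k_star = matern52(model.train_X, x_star, model.lengthscale, model.signal_var)  # (N, 1)
    mean = model.y_mean + (k_star.T @ model.alpha).ravel()
    v = cho_solve(model.cho, k_star)
    var = float(model.signal_var - (k_star.T @ v).item())
    var = max(var, 0.0)
    curve = TimeActivityCurve(model.t_grid, mean, grid_kind="uniform-1s")
    return MlifPrediction(mean=curve, variance=np.full(mean.shape, var))


def loo_cross_validate(
    cohort: list[tuple[IdifSet, TimeActivityCurve]], **train_kwargs
) -> list[MlifPrediction]:
    """Leave-one-out protocol: for each scan, refit the normalization and
    retrain on the other N-1 scans, then predict the held-out scan.

    The held-out subject's AIF never enters its own training fold, and
    its IDIFs are normalized with training-fold constants only.
    """
    if len(cohort) < 3:
        raise ValueError("leave-one-out needs a cohort of at least 3")
    t_grid = cohort[0][1].t
    out = []
    for i in range(len(cohort)):
        rest = cohort[:i] + cohort[i + 1 :]
        model = train(build_training_set(rest), t_grid=t_grid, **train_kwargs)
        out.append(predict(model, cohort[i][0]))
    return out
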