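"""Nested cross-validated epsilon-SVR with grid search and model averaging.

The estimator is an epsilon-SVR with RBF kernel ``exp(-gamma * ||u - v||^2)``,
epsilon fixed at 0.1.  Hyperparameters C and gamma are selected in an inner
5-fold CV by minimizing the mean absolute error over a log2 grid
(C = 2^-5 ... 2^15, gamma = 2^-15 ... 2^5 by default); the winner is refit on
the whole outer training set and evaluated on the held-out outer fold, so each
patient is predicted exactly once per repetition.  The whole procedure is
repeated with different sample randomizations (substream per repetition,
identical across model versions) and the per-patient predictions averaged;
the coefficient of determination of the averaged predictions is the final
model fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Union

import numpy as np
from sklearn.svm import SVR

from .streams import CV, RandomStream


class CvError(ValueError):
    pass


def log2_grid(lo: int, hi: int) -> np.ndarray:
    """2^lo, 2^(lo+1), ..., 2^hi."""
    return 2.0 ** np.arange(lo, hi + 1)


@dataclass
class CvConfig:
    outer_k: int = 10
    inner_k: int = 5
    epsilon: float = 0.1
    C_grid: np.ndarray = field(default_factory=lambda: log2_grid(-5, 15))
    gamma_grid: np.ndarray = field(default_factory=lambda: log2_grid(-15, 5))
    n_repetitions: int = 10

    def __post_init__(self) -> None:
        if self.outer_k < 2 or self.inner_k < 2:
            raise CvError("outer_k and inner_k must be >= 2")
        self.C_grid = np.sort(np.asarray(self.C_grid, dtype=float))
        self.gamma_grid = np.sort(np.asarray(self.gamma_grid, dtype=float))
        if self.C_grid.size == 0 or self.gamma_grid.size == 0:
            raise CvError("hyperparameter grids must be non-empty")
        if self.n_repetitions < 1:
            raise CvError("n_repetitions must be >= 1")

    @classmethod
    def reduced(cls, n_repetitions: int = 3) -> "CvConfig":
        """Desk-scale 5x5 grid spanning the same log2 range more coarsely."""
        return cls(
            C_grid=2.0 ** np.array([-3.0, 0.0, 3.0, 6.0, 9.0]),
            gamma_grid=2.0 ** np.array([-9.0, -6.0, -3.0, 0.0, 3.0]),
            n_repetitions=n_repetitions,
        )


FeaturesLike = Union[np.ndarray, Callable[[np.ndarray, np.ndarray], tuple[np.ndarray, np.ndarray]]]


@dataclass
class FitResult:
    predictions: np.ndarray          # (n_repetitions, n) out-of-fold predictions
    averaged_predictions: np.ndarray  # (n,)
    r2_per_repetition: np.ndarray    # (n_repetitions,)
    r2_averaged: float
    mae_per_repetition: np.ndarray
    chosen_params: list[list[tuple[float, float]]]  # [rep][outer fold] -> (C, gamma)
    fold_assignments: np.ndarray     # (n_repetitions, n) outer-fold index per patient


def make_folds(n: int, k: int, rng: np.random.Generator) -> np.ndarray:
    """Fold index per row: shuffle, then cut into k nearly equal contiguous
    blocks (sizes differ by at most 1)."""
    if n < k:
        raise CvError(f"cannot make {k} folds from {n} rows")
    order = rng.permutation(n)
    folds = np.empty(n, dtype=int)
    for j, chunk in enumerate(np.array_split(order, k)):
        folds[chunk] = j
    return folds


def mae(pred: np.ndarray, true: np.ndarray) -> float:
    pred = np.asarray(pred, dtype=float)
    true = np.asarray(true, dtype=float)
    if pred.shape != true.shape or pred.size == 0:
        raise CvError("pred and true must be equal-length non-empty vectors")
    return float(np.abs(pred - true).mean())


def r_squared(pred: np.ndarray, true: np.ndarray) -> float:
    """1 - SS_res / SS_tot; may be negative for models worse than the mean."""
    pred = np.asarray(pred, dtype=float)
    true = np.asarray(true, dtype=float)
    if pred.shape != true.shape or pred.size < 2:
        raise CvError("pred and true must be equal-length vectors of size >= 2")
    ss_tot = float(((true - true.mean()) ** 2).sum())
    if ss_tot == 0.0:
        raise CvError("true values are constant; R^2 undefined")
    ss_res = float(((true - pred) ** 2).sum())
    return 1.0 - ss_res / ss_tot


def fit_svr(X: np.ndarray, y: np.ndarray, C: float, gamma: float, epsilon: float = 0.1) -> SVR:
    model = SVR(kernel="rbf", C=C, gamma=gamma, epsilon=epsilon, cache_size=64)
    model.fit(X, y)
    return model


def inner_cv_select(
    X: np.ndarray, y: np.ndarray, config: CvConfig, rng: np.random.Generator
) -> tuple[float, float]:
    """Grid search by inner k-fold CV, minimizing mean MAE.

    Ties break to the smallest C, then the smallest gamma.  Constant training
    targets make the search degenerate; the grid minimum is returned.
    """
    n = len(y)
    if n < config.inner_k:
        raise CvError("training set smaller than inner_k")
    if np.ptp(y) == 0.0:
        return float(config.C_grid[0]), float(config.gamma_grid[0])
    folds = make_folds(n, config.inner_k, rng)
    best: Optional[tuple[float, float]] = None
    best_mae = np.inf
    # iterate C then gamma in ascending order: the first strict minimum
    # realises the tie rule automatically
    splits = [(folds != j, folds == j) for j in range(config.inner_k)]
    for C in config.C_grid:
        for gamma in config.gamma_grid:
            errs = []
            for train, val in splits:
                model = fit_svr(X[train], y[train], C, gamma, config.epsilon)
                errs.append(mae(model.predict(X[val]), y[val]))
            mean_mae = float(np.mean(errs))
            if mean_mae < best_mae - 1e-15:
                best_mae = mean_mae
                best = (float(C), float(gamma))
    assert best is not None
    return best


def nested_cv_predict(
    features: FeaturesLike,
    targets: np.ndarray,
    config: CvConfig,
    stream: RandomStream,
    repetition: int = 0,
) -> tuple[np.ndarray, list[tuple[float, float]], np.ndarray]:
    """One repetition of the nested CV; returns (out-of-fold predictions,
    chosen (C, gamma) per outer fold, outer-fold assignment per patient).

    ``features`` is either the (n, p) design matrix, or a callable
    ``builder(train_idx, test_idx) -> (X_train, X_test)`` for fold-safe
    feature construction.  The sample randomization depends only on the
    stream and repetition index, hence is identical across model versions.
    """
    y = np.asarray(targets, dtype=float)
    n = len(y)
    if n < config.outer_k:
        raise CvError("fewer rows than outer_k")
    rng_outer = stream.substream(CV, repetition, 0)
    folds = make_folds(n, config.outer_k, rng_outer)
    preds = np.empty(n)
    chosen: list[tuple[float, float]] = []
    for j in range(config.outer_k):
        train_idx = np.flatnonzero(folds != j)
        test_idx = np.flatnonzero(folds == j)
        if callable(features):
            X_train, X_test = features(train_idx, test_idx)
        else:
            X_train = features[train_idx]
            X_test = features[test_idx]
        rng_inner = stream.substream(CV, repetition, 1 + j)
        C, gamma = inner_cv_select(X_train, y[train_idx], config, rng_inner)
        model = fit_svr(X_train, y[train_idx], C, gamma, config.epsilon)
        preds[test_idx] = model.predict(X_test)
        chosen.append((C, gamma))
    return preds, chosen, folds


def run_repetitions(
    features: FeaturesLike,
    targets: np.ndarray,
    config: CvConfig,
    stream: RandomStream,
) -> FitResult:
    """Run all repetitions and average the per-patient predictions."""
    y = np.asarray(targets, dtype=float)
    n = len(y)
    preds = np.empty((config.n_repetitions, n))
    folds = np.empty((config.n_repetitions, n), dtype=int)
    chosen: list[list[tuple[float, float]]] = []
    for r in range(config.n_repetitions):
        preds[r], params, folds[r] = nested_cv_predict(features, y, config, stream, repetition=r)
        chosen.append(params)
    averaged = preds.mean(axis=0)
    return FitResult(
        predictions=preds,
        averaged_predictions=averaged,
        r2_per_repetition=np.array([r_squared(p, y) for p in preds]),
        r2_averaged=r_squared(averaged, y),
        mae_per_repetition=np.array([mae(p, y) for p in preds]),
        chosen_params=chosen,
        fold_assignments=folds,
    )
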