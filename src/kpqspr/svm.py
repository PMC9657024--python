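"""RBF support-vector-regression counterpart to the linear QSPR model.

The SVR is tuned by a γ/C grid search over log-spaced axes spanning
10⁻²–10⁴, scored by mean cross-validated RMSE over seeded folds that are
stratified by compound class. Both the descriptors and the response are
standardized to training mean and SD before fitting, following the
convention of R's standard SVR implementation (the ε-insensitive tube
then applies on the standardized response scale); predictions are mapped
back to natural units before scoring. Descriptor scaling is essential —
polarizability (~10²) and surface potential (~10⁻²) otherwise differ by
four orders of magnitude and the kernel would see only one of them.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.svm import SVR

from .dataset import QsprDataset
from .validation import MetricsReport, ValidationError, regression_metrics

__all__ = ["SvmConfig", "GridSearchResult", "grid_search_svr", "fit_evaluate_svr"]

#: Default grid axes: integer powers of ten from 1e-2 to 1e4.
DEFAULT_AXIS = tuple(10.0 ** k for k in range(-2, 5))


@dataclass(frozen=True)
class SvmConfig:
    """Hyperparameters of one RBF-SVR model."""

    gamma: float
    c: float
    epsilon: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.gamma > 0:
            raise ValueError(f"gamma must be positive, got {self.gamma}")
        if not self.c > 0:
            raise ValueError(f"C must be positive, got {self.c}")
        if self.epsilon < 0:
            raise ValueError(f"epsilon must be non-negative, got {self.epsilon}")


@dataclass(frozen=True)
class GridSearchResult:
    """Cross-validated γ/C grid with the selected configuration.

    ``grid`` has columns gamma, c, log10_gamma, log10_c, cv_rmse — one
    row per grid cell, contour-ready.
    """

    grid: pd.DataFrame
    best: SvmConfig
    cv_rmse_best: float

    def top_fraction(self, config: SvmConfig, fraction: float = 0.1) -> bool:
        """Is ``config``'s cell within the best ``fraction`` of cells by CV error?"""
        ranked = self.grid.sort_values("cv_rmse", kind="stable").reset_index(drop=True)
        cutoff = max(1, int(np.ceil(fraction * len(ranked))))
        head = ranked.iloc[:cutoff]
        return bool(
            ((head.gamma == config.gamma) & (head.c == config.c)).any()
        )


class _Scaler:
    """Training-set standardization (mean 0, SD 1; sample SD as in R)."""

    def __init__(self, X: np.ndarray):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        self.mean = X.mean(axis=0)
        self.sd = X.std(axis=0, ddof=1)
        if np.any(self.sd == 0):
            raise ValidationError("degenerate descriptor with zero variance")

    def __call__(self, X: np.ndarray) -> np.ndarray:
        return (X - self.mean) / self.sd

    def undo(self, Z: np.ndarray) -> np.ndarray:
        return Z * self.sd + self.mean


def _fit_predict(
    gamma: float, c: float, epsilon: float,
    X_fit: np.ndarray, y_fit: np.ndarray, X_new: np.ndarray,
) -> np.ndarray:
    """Fit an RBF SVR with X and y standardized to the fitting data."""
    xsc = _Scaler(X_fit)
    ysc = _Scaler(y_fit.reshape(-1, 1))
    svr = SVR(kernel="rbf", gamma=gamma, C=c, epsilon=epsilon)
    svr.fit(xsc(X_fit), ysc(y_fit.reshape(-1, 1)).ravel())
    return ysc.undo(svr.predict(xsc(X_new)).reshape(-1, 1)).ravel()


def _design(ds: QsprDataset, descriptors: Sequence[str]) -> np.ndarray:
    return np.asarray(ds.descriptor_matrix(descriptors), dtype=float)


def _stratified_folds(
    classes: Sequence[str], folds: int, seed: int
) -> list[np.ndarray]:
    """Seeded class-stratified fold assignment (round-robin after shuffle)."""
    rng = np.random.default_rng(seed)
    assignment = np.empty(len(classes), dtype=int)
    next_fold = 0
    for cls in sorted(set(classes)):
        idx = np.flatnonzero(np.asarray(classes) == cls)
        rng.shuffle(idx)
        for i in idx:
            assignment[i] = next_fold % folds
            next_fold += 1
    return [np.flatnonzero(assignment == f) for f in range(folds)]


def grid_search_svr(
    train: QsprDataset,
    descriptors: Sequence[str] = ("alpha", "vsmin"),
    response: str = "log_kp_exp",
    gamma_axis: Sequence[float] = DEFAULT_AXIS,
    c_axis: Sequence[float] = DEFAULT_AXIS,
    folds: int = 10,
    seed: int = 0,
    epsilon: float = 0.1,
) -> GridSearchResult:
    """Grid search over (γ, C) scored by mean k-fold CV RMSE.

    Folds are assigned once per call by a seeded, class-stratified
    shuffle, so every grid cell is scored on identical folds and the
    whole grid is bit-reproducible under a fixed seed. Ties are broken
    toward smaller C, then smaller γ.
    """
    if folds < 2:
        raise ValidationError(f"need at least 2 folds, got {folds}")
    if len(train) < folds:
        raise ValidationError(f"training size {len(train)} < folds {folds}")
    X = _design(train, descriptors)
    y = np.asarray(train.responses(response), dtype=float)
    if np.any(X.std(axis=0) == 0):
        raise ValidationError("degenerate descriptor with zero variance")
    classes = [r.compound_class for r in train.records]
    fold_idx = _stratified_folds(classes, folds, seed)

    rows = []
    for gamma in gamma_axis:
        for c in c_axis:
            sq_errs: list[np.ndarray] = []
            for test in fold_idx:
                if test.size == 0:
                    continue
                mask = np.ones(len(y), dtype=bool)
                mask[test] = False
                pred = _fit_predict(gamma, c, epsilon, X[mask], y[mask], X[test])
                sq_errs.append((pred - y[test]) ** 2)
            cv_rmse = float(np.sqrt(np.mean(np.concatenate(sq_errs))))
            rows.append((gamma, c, np.log10(gamma), np.log10(c), cv_rmse))
    grid = pd.DataFrame(
        rows, columns=["gamma", "c", "log10_gamma", "log10_c", "cv_rmse"]
    )
    # argmin with ties toward smaller C then smaller gamma
    ordered = grid.sort_values(["cv_rmse", "c", "gamma"], kind="stable")
    best_row = ordered.iloc[0]
    best = SvmConfig(
        gamma=float(best_row.gamma), c=float(best_row.c), epsilon=epsilon, seed=seed
    )
    return GridSearchResult(grid=grid, best=best, cv_rmse_best=float(best_row.cv_rmse))


def fit_evaluate_svr(
    config: SvmConfig,
    train: QsprDataset,
    validation: QsprDataset,
    descriptors: Sequence[str] = ("alpha", "vsmin"),
    response: str = "log_kp_exp",
    ddof: int = 1,
) -> tuple[MetricsReport, MetricsReport]:
    """Fit an RBF SVR on the training set and score both split halves.

    Metrics follow the package conventions (error = predicted − observed;
    validation Q² referenced to the training mean).
    """
    X_tr = _design(train, descriptors)
    X_va = _design(validation, descriptors)
    y_tr = np.asarray(train.responses(response), dtype=float)
    y_va = np.asarray(validation.responses(response), dtype=float)
    pred_tr = _fit_predict(config.gamma, config.c, config.epsilon, X_tr, y_tr, X_tr)
    pred_va = _fit_predict(config.gamma, config.c, config.epsilon, X_tr, y_tr, X_va)
    train_metrics = regression_metrics(y_tr, pred_tr, ddof=ddof)
    validation_metrics = regression_metrics(
        y_va, pred_va, reference_mean=float(y_tr.mean()), ddof=ddof
    )
    return train_metrics, validation_metrics
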