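"""Leverage-based applicability domain and Williams-plot data.

A query compound is inside the leverage domain when its hat value
h = x₀ᵀ(XᵀX)⁻¹x₀ (X the training design with intercept) does not exceed
the conventional threshold h* = 3p/n, p counting all fitted parameters
including the intercept. A compound is "well predicted" when its
standardized residual |e/s| < 3. The Williams plot is the scatter of
standardized residual against leverage; :func:`williams_report` emits its
data as a table together with the training descriptor ranges, which serve
as a simpler range-based domain screen.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .dataset import QsprDataset
from .linear import LinearFit, ModelError

__all__ = [
    "WilliamsPoint",
    "AdReport",
    "leverage_values",
    "leverage_threshold",
    "standardized_residuals",
    "williams_report",
]


@dataclass(frozen=True)
class WilliamsPoint:
    """One compound's coordinates and verdicts on the Williams plot."""

    abbreviation: str
    leverage: float
    std_residual: float
    in_leverage_domain: bool
    well_predicted: bool


@dataclass(frozen=True)
class AdReport:
    """Applicability-domain summary for a fitted model.

    ``alpha_range`` and ``vsmin_range`` are the closed descriptor
    intervals spanned by the data the model was fitted to (only present
    when the fit uses those descriptors).
    """

    points: tuple[WilliamsPoint, ...]
    h_star: float
    descriptor_ranges: dict[str, tuple[float, float]]

    @property
    def alpha_range(self) -> tuple[float, float] | None:
        return self.descriptor_ranges.get("alpha")

    @property
    def vsmin_range(self) -> tuple[float, float] | None:
        return self.descriptor_ranges.get("vsmin")

    def in_descriptor_ranges(self, record) -> bool:
        """Range-based screen: every model descriptor inside its interval."""
        for name, (lo, hi) in self.descriptor_ranges.items():
            if not lo <= record.descriptor(name) <= hi:
                return False
        return True


def leverage_values(design: np.ndarray, queries: np.ndarray) -> np.ndarray:
    """Hat values h = x₀ᵀ(XᵀX)⁻¹x₀ for query rows against a training design.

    Both arrays must already carry the intercept column. Raises
    :class:`~kpqspr.linear.ModelError` if the training design is rank
    deficient.
    """
    X = np.asarray(design, dtype=float)
    Q = np.atleast_2d(np.asarray(queries, dtype=float))
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ModelError("collinear design: cannot invert XᵀX")
    xtx_inv = np.linalg.inv(X.T @ X)
    return np.einsum("ij,jk,ik->i", Q, xtx_inv, Q)


def leverage_threshold(p_params: int, n: int) -> float:
    """Leverage cutoff h* = 3 × p / n, p counting all fitted parameters."""
    if p_params < 1:
        raise ValueError(f"p_params must be ≥ 1, got {p_params}")
    if n <= p_params:
        raise ValueError(f"need n > p_params, got n={n}, p={p_params}")
    return 3.0 * p_params / n


def standardized_residuals(
    fit: LinearFit,
    observed,
    predicted,
    studentized: bool = False,
) -> np.ndarray:
    """Residuals (predicted − observed) scaled by the fit's residual SD.

    With ``studentized=True`` each residual is additionally divided by
    sqrt(1−h) using the training hat values (internally studentized
    form); this only applies when scoring the fit's own training set.
    """
    if fit.residual_sd <= 1e-12:  # numerically perfect fit
        raise ModelError("standardized residuals undefined for a perfect fit")
    e = np.asarray(predicted, dtype=float) - np.asarray(observed, dtype=float)
    if studentized:
        design = np.hstack([np.ones((fit.n, 1)), fit.model.exog])
        h = leverage_values(design, design)
        if e.shape != h.shape:
            raise ModelError("studentized residuals require the training set itself")
        return e / (fit.residual_sd * np.sqrt(1.0 - h))
    return e / fit.residual_sd


def williams_report(ds: QsprDataset, fit: LinearFit) -> AdReport:
    """Williams-plot data and domain verdicts for every record in ``ds``.

    ``fit`` must have been computed on ``ds`` (the hat values and h* are
    defined by that design); the descriptor ranges are the training
    extremes for each model descriptor.
    """
    names = fit.descriptor_names
    X = np.hstack([np.ones((fit.n, 1)), fit.model.exog])
    queries = np.hstack(
        [np.ones((len(ds), 1)), np.asarray(ds.descriptor_matrix(names), dtype=float)]
    )
    h = leverage_values(X, queries)
    h_star = leverage_threshold(fit.n_params, fit.n)
    y = np.asarray(ds.responses(fit.model.response))
    stdr = standardized_residuals(fit, y, fit.predict(ds))
    points = tuple(
        WilliamsPoint(
            abbreviation=rec.abbreviation,
            leverage=float(hi),
            std_residual=float(ri),
            in_leverage_domain=bool(hi <= h_star),
            well_predicted=bool(abs(ri) < 3.0),
        )
        for rec, hi, ri in zip(ds.records, h, stdr)
    )
    ranges = {
        name: (float(np.min(col)), float(np.max(col)))
        for name, col in zip(names, fit.model.exog.T)
    }
    return AdReport(points=points, h_star=h_star, descriptor_ranges=ranges)


def plot_williams(report: AdReport, ax=None):
    """Render the Williams plot (optional; imports matplotlib lazily)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    h = [p.leverage for p in report.points]
    r = [p.std_residual for p in report.points]
    ax.scatter(h, r, s=18)
    ax.axvline(report.h_star, ls="--", c="k", lw=1, label=f"h* = {report.h_star:.3f}")
    for yline in (-3, 3):
        ax.axhline(yline, ls=":", c="grey", lw=1)
    ax.set_xlabel("leverage h")
    ax.set_ylabel("standardized residual")
    ax.legend()
    return ax
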