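"""Ordinary-least-squares QSPR models with full inferential diagnostics.

The modelling surface follows the Model/Results idiom: build a
:class:`KpLinearModel` from a dataset (or DataFrame), call :meth:`fit` and
work with the returned :class:`LinearFit`, which carries coefficient
estimates with standard errors, t and p values, collinearity diagnostics
(VIF), the residual scale and R², and offers prediction with confidence
or prediction intervals.

Two canonical model forms are provided as conveniences:

* :func:`fit_koa_model` — the single-descriptor regression of log K_P on
  log K_OA, the traditional partitioning surrogate.
* :func:`fit_ols` with descriptors ``("alpha", "vsmin")`` — the
  two-descriptor model in which polarizability captures dispersion
  interactions with the particle phase and the most negative surface
  potential captures hydrogen-bond acceptance.

Coefficients are reported on natural descriptor scales (no
standardization), so they are directly interpretable as log-unit change
per descriptor unit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .dataset import CompoundRecord, QsprDataset

__all__ = [
    "KpLinearModel",
    "LinearFit",
    "PredictionInterval",
    "fit_ols",
    "fit_koa_model",
    "ModelError",
]


class ModelError(ValueError):
    """Raised for unfittable designs or invalid prediction requests."""


@dataclass(frozen=True)
class PredictionInterval:
    """A point prediction with interval bounds at a stated confidence level."""

    point: float
    lower: float
    upper: float
    level: float

    def __post_init__(self) -> None:
        if not (self.lower <= self.point <= self.upper):
            raise ModelError("interval bounds must bracket the point prediction")


def _records_to_frame(records) -> pd.DataFrame:
    if isinstance(records, QsprDataset):
        frame = records.to_dataframe()
    elif isinstance(records, pd.DataFrame):
        frame = records.copy()
    elif isinstance(records, CompoundRecord):
        frame = QsprDataset.from_records([records]).to_dataframe()
    else:  # iterable of records
        frame = QsprDataset.from_records(list(records)).to_dataframe()
    return frame


class KpLinearModel:
    """OLS model of a response on named molecular descriptors.

    Parameters
    ----------
    data
        A :class:`~kpqspr.dataset.QsprDataset` or a DataFrame with one
        column per descriptor and one for the response.
    descriptors
        Ordered descriptor names (k ≥ 1).
    response
        Response column, by default the experimental log K_P.
    """

    def __init__(
        self,
        data: QsprDataset | pd.DataFrame,
        descriptors: Sequence[str] = ("alpha", "vsmin"),
        response: str = "log_kp_exp",
    ) -> None:
        if not descriptors:
            raise ModelError("at least one descriptor is required")
        self.descriptors = tuple(descriptors)
        self.response = response
        frame = _records_to_frame(data)
        missing = [c for c in (*self.descriptors, response) if c not in frame.columns]
        if missing:
            raise ModelError(f"data lacks required columns: {missing}")
        self._frame = frame
        self.endog = frame[response].to_numpy(dtype=float)
        self.exog = frame[list(self.descriptors)].to_numpy(dtype=float)
        self.nobs = len(frame)

    @classmethod
    def from_dataframe(
        cls,
        frame: pd.DataFrame,
        descriptors: Sequence[str] = ("alpha", "vsmin"),
        response: str = "log_kp_exp",
    ) -> "KpLinearModel":
        return cls(frame, descriptors=descriptors, response=response)

    def fit(self) -> "LinearFit":
        """Fit by OLS and return a results object.

        Raises
        ------
        ModelError
            If n ≤ k+1 or the design (with intercept) is rank deficient.
        """
        n, k = self.exog.shape
        p = k + 1
        if n <= p:
            raise ModelError(f"need more observations than parameters (n={n}, p={p})")
        design = sm.add_constant(self.exog, has_constant="add")
        if np.linalg.matrix_rank(design) < p:
            raise ModelError("collinear design: descriptor matrix is rank deficient")
        res = sm.OLS(self.endog, design).fit()
        vif = self._vif()
        return LinearFit(model=self, _sm_results=res, vif=vif)

    def _vif(self) -> tuple[float, ...]:
        """Variance inflation factors, VIF_j = 1/(1 − R²_j)."""
        k = self.exog.shape[1]
        if k == 1:
            return (1.0,)
        out = []
        for j in range(k):
            others = np.delete(self.exog, j, axis=1)
            aux = sm.OLS(
                self.exog[:, j], sm.add_constant(others, has_constant="add")
            ).fit()
            out.append(float(1.0 / (1.0 - aux.rsquared)))
        return tuple(out)


class LinearFit:
    """Results of a :class:`KpLinearModel` fit.

    Attributes
    ----------
    coefficients : ndarray
        Per-descriptor slopes, in the model's descriptor order.
    intercept : float
    standard_errors : ndarray
        For (intercept, *slopes*), from s²(XᵀX)⁻¹.
    t_values, p_values : ndarray
        Wald t statistics and two-sided p values on n−p degrees of freedom.
    vif : tuple of float
        Variance inflation factor per descriptor (1.0 for k=1).
    residual_sd : float
        s = sqrt(SSE/(n−p)).
    r2 : float
        Coefficient of determination on the fitting set.
    """

    def __init__(self, model: KpLinearModel, _sm_results, vif: tuple[float, ...]):
        self.model = model
        self._res = _sm_results
        self.descriptor_names = model.descriptors
        params = np.asarray(_sm_results.params, dtype=float)
        self.intercept = float(params[0])
        self.coefficients = params[1:]
        self.standard_errors = np.asarray(_sm_results.bse, dtype=float)
        self.t_values = np.asarray(_sm_results.tvalues, dtype=float)
        self.p_values = np.asarray(_sm_results.pvalues, dtype=float)
        self.vif = vif
        self.n = int(_sm_results.nobs)
        self.df_resid = int(_sm_results.df_resid)
        self.n_params = self.n - self.df_resid
        self.residual_sd = float(np.sqrt(_sm_results.scale))
        self.r2 = float(_sm_results.rsquared)
        self.training_mean = float(np.mean(model.endog))
        self.fitted_values = np.asarray(_sm_results.fittedvalues, dtype=float)
        self.residuals = self.fitted_values - model.endog  # predicted − observed

    # -- prediction ---------------------------------------------------------

    def _design_for(self, records) -> np.ndarray:
        frame = _records_to_frame(records)
        missing = [c for c in self.descriptor_names if c not in frame.columns]
        if missing:
            raise ModelError(f"records lack descriptor(s): {missing}")
        x = frame[list(self.descriptor_names)].to_numpy(dtype=float)
        return np.hstack([np.ones((len(frame), 1)), x])

    def predict(self, records) -> np.ndarray:
        """Point predictions, intercept + Σ coefficient × descriptor."""
        design = self._design_for(records)
        return design @ np.concatenate([[self.intercept], self.coefficients])

    def predict_interval(
        self,
        records,
        level: float = 0.95,
        kind: str = "mean",
    ) -> list[PredictionInterval]:
        """Predictions with t-based intervals.

        Parameters
        ----------
        level
            Confidence level in (0, 1).
        kind
            ``"mean"`` for the mean-response (confidence) interval,
            half-width t·s·sqrt(x₀ᵀ(XᵀX)⁻¹x₀); ``"observation"`` for a
            new-observation prediction interval, which adds the unit
            residual variance under the square root.
        """
        if not 0.0 < level < 1.0:
            raise ModelError(f"confidence level must be in (0,1), got {level}")
        if kind not in ("mean", "observation"):
            raise ModelError(f"kind must be 'mean' or 'observation', got {kind!r}")
        from scipy import stats

        design = self._design_for(records)
        xtx_inv = np.asarray(self._res.normalized_cov_params, dtype=float)
        lev = np.einsum("ij,jk,ik->i", design, xtx_inv, design)
        if kind == "observation":
            lev = lev + 1.0
        tcrit = stats.t.ppf(1.0 - (1.0 - level) / 2.0, self.df_resid)
        points = design @ np.concatenate([[self.intercept], self.coefficients])
        half = tcrit * self.residual_sd * np.sqrt(lev)
        return [
            PredictionInterval(point=float(pt), lower=float(pt - h),
                               upper=float(pt + h), level=level)
            for pt, h in zip(points, half)
        ]

    # -- presentation -------------------------------------------------------

    def params_dict(self) -> dict[str, float]:
        out = {"intercept": self.intercept}
        out.update(dict(zip(self.descriptor_names, map(float, self.coefficients))))
        return out

    def summary(self) -> str:
        """Human-readable coefficient table with diagnostics."""
        lines = [
            f"OLS fit of {self.model.response} on "
            + ", ".join(self.descriptor_names),
            f"n = {self.n}, parameters = {self.n_params}, "
            f"R² = {self.r2:.3f}, residual SD = {self.residual_sd:.3f}",
            "",
            f"{'term':<12}{'coef':>12}{'SE':>10}{'t':>10}{'p':>12}{'VIF':>8}",
        ]
        names = ("intercept", *self.descriptor_names)
        vifs = (float("nan"), *self.vif)
        params = np.concatenate([[self.intercept], self.coefficients])
        for name, b, se, t, pval, v in zip(
            names, params, self.standard_errors, self.t_values, self.p_values, vifs
        ):
            vif_s = f"{v:8.3f}" if np.isfinite(v) else " " * 8
            lines.append(f"{name:<12}{b:>12.4f}{se:>10.4f}{t:>10.3f}{pval:>12.3g}{vif_s}")
        return "\n".join(lines)

    def to_json_dict(self) -> dict:
        """Plain serializable document of named coefficients and diagnostics."""
        return {
            "response": self.model.response,
            "descriptors": list(self.descriptor_names),
            "coefficients": self.params_dict(),
            "standard_errors": dict(
                zip(("intercept", *self.descriptor_names),
                    map(float, self.standard_errors))
            ),
            "t_values": dict(
                zip(("intercept", *self.descriptor_names), map(float, self.t_values))
            ),
            "vif": dict(zip(self.descriptor_names, map(float, self.vif))),
            "n": self.n,
            "r2": self.r2,
            "residual_sd": self.residual_sd,
        }


def fit_ols(
    ds: QsprDataset | pd.DataFrame,
    descriptors: Sequence[str] = ("alpha", "vsmin"),
    response: str = "log_kp_exp",
) -> LinearFit:
    """Fit an OLS model of ``response`` on ``descriptors`` with intercept."""
    return KpLinearModel(ds, descriptors=descriptors, response=response).fit()


def fit_koa_model(ds: QsprDataset | pd.DataFrame) -> LinearFit:
    """Fit the single-descriptor log K_OA surrogate model for log K_P."""
    return fit_ols(ds, descriptors=("log_koa",))
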