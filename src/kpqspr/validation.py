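"""Model validation machinery: metric bundles, external validation,
leave-one-out cross-validation, and the error-based predictive-ability
criteria of Roy and co-workers.

Conventions
-----------
* Prediction error is ``predicted − observed`` throughout.
* The headline RMSE uses the Bessel-style denominator n−1,
  sqrt(SSE/(n−1)), which is the convention of the reference statistics
  this package reproduces; pass ``ddof=0`` for the plain root mean
  square sqrt(SSE/n).
* Q² = 1 − Σ(y−ŷ)²/Σ(y−ȳ_ref)². For an external set the reference mean
  ȳ_ref is the *training-set* mean; for a model evaluated on its own
  fitting set it is that set's mean (in which case Q² coincides with R²
  computed as 1 − SSE/SST).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .dataset import QsprDataset, split_by_flag
from .linear import LinearFit, fit_ols

__all__ = [
    "MetricsReport",
    "ExternalValidationResult",
    "LooReport",
    "RoyReport",
    "regression_metrics",
    "external_validation",
    "loo_cv",
    "roy_error_criteria",
    "pearson_r",
    "ValidationError",
]


class ValidationError(ValueError):
    """Raised on malformed metric inputs."""


@dataclass(frozen=True)
class MetricsReport:
    """The statistic bundle for one (observed, predicted) pair of vectors.

    Attributes
    ----------
    r2 : float
        Squared Pearson correlation of observed vs predicted.
    q2 : float
        Predictive squared correlation, 1 − Σe²/Σ(y−ȳ_ref)².
    rmse : float
        sqrt(SSE/(n−ddof)) with the report's ``ddof``.
    mae : float
        Mean absolute error.
    mpe, mne : float
        Maximum positive and maximum (most) negative signed error.
    bias : float
        Mean signed error (systematic error).
    """

    n: int
    r2: float
    q2: float
    rmse: float
    mae: float
    mpe: float
    mne: float
    bias: float
    ddof: int = 1

    def as_dict(self) -> dict[str, float]:
        return {
            "n": self.n, "r2": self.r2, "q2": self.q2, "rmse": self.rmse,
            "mae": self.mae, "mpe": self.mpe, "mne": self.mne, "bias": self.bias,
        }


def _check_pair(observed, predicted) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(observed, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if y.shape != p.shape:
        raise ValidationError(
            f"length mismatch: observed {y.shape} vs predicted {p.shape}"
        )
    if y.size < 2:
        raise ValidationError(f"need at least 2 points, got {y.size}")
    return y, p


def pearson_r(x, y) -> float:
    """Product-moment correlation coefficient.

    Raises
    ------
    ValidationError
        On length mismatch, n < 2 or zero variance in either input.
    """
    xv, yv = _check_pair(x, y)
    if np.std(xv) == 0 or np.std(yv) == 0:
        raise ValidationError("correlation undefined for zero-variance input")
    return float(stats.pearsonr(xv, yv).statistic)


def regression_metrics(
    observed,
    predicted,
    reference_mean: float | None = None,
    ddof: int = 1,
) -> MetricsReport:
    """Compute the seven-statistic bundle for observed vs predicted values.

    Parameters
    ----------
    reference_mean
        The mean ȳ_ref in the Q² denominator. Defaults to the mean of
        ``observed`` (self-evaluation convention); pass the training-set
        mean when scoring an external set.
    ddof
        Denominator correction for RMSE: the default 1 gives
        sqrt(SSE/(n−1)); 0 gives the plain root mean square error.
    """
    y, p = _check_pair(observed, predicted)
    e = p - y
    n = y.size
    ref = float(np.mean(y)) if reference_mean is None else float(reference_mean)
    sse = float(e @ e)
    sst = float(np.sum((y - ref) ** 2))
    if np.std(y) == 0 or np.std(p) == 0:
        r2 = float("nan")  # correlation-based R² undefined on flat vectors
    else:
        r2 = float(stats.pearsonr(y, p).statistic ** 2)
    return MetricsReport(
        n=n,
        r2=r2,
        q2=1.0 - sse / sst if sst > 0 else float("nan"),
        rmse=float(np.sqrt(sse / (n - ddof))),
        mae=float(np.mean(np.abs(e))),
        mpe=float(np.max(e)),
        mne=float(np.min(e)),
        bias=float(np.mean(e)),
        ddof=ddof,
    )


@dataclass(frozen=True)
class ExternalValidationResult:
    """Training-set fit plus metric bundles for both split halves."""

    fit: LinearFit
    train_metrics: MetricsReport
    validation_metrics: MetricsReport
    validation_predictions: tuple[float, ...]


def external_validation(
    ds: QsprDataset,
    descriptors: Sequence[str] = ("alpha", "vsmin"),
    response: str = "log_kp_exp",
    ddof: int = 1,
) -> ExternalValidationResult:
    """Fixed-split external validation using the dataset's record flags.

    Fits OLS on the records not flagged as validation, predicts the
    flagged ones, and scores both parts. The validation Q² uses the
    training mean as its reference; training metrics use the training
    mean (so training Q² = R² computed from SSE/SST).
    """
    train, valid = split_by_flag(ds)
    fit = fit_ols(train, descriptors=descriptors, response=response)
    y_tr = np.asarray(train.responses(response))
    y_va = np.asarray(valid.responses(response))
    pred_va = fit.predict(valid)
    train_metrics = regression_metrics(y_tr, fit.fitted_values, ddof=ddof)
    validation_metrics = regression_metrics(
        y_va, pred_va, reference_mean=float(np.mean(y_tr)), ddof=ddof
    )
    return ExternalValidationResult(
        fit=fit,
        train_metrics=train_metrics,
        validation_metrics=validation_metrics,
        validation_predictions=tuple(map(float, pred_va)),
    )


@dataclass(frozen=True)
class LooReport:
    """Leave-one-out cross-validation summary.

    ``q2_cv`` = 1 − PRESS/SST with SST about the full-set mean;
    ``rmse_cv`` = sqrt(PRESS/n). ``per_record_errors`` are the LOO
    residuals (predicted − observed) in dataset order.
    """

    q2_cv: float
    rmse_cv: float
    per_record_errors: tuple[float, ...]


def loo_cv(
    ds: QsprDataset,
    descriptors: Sequence[str] = ("alpha", "vsmin"),
    response: str = "log_kp_exp",
) -> LooReport:
    """Leave-one-out cross-validation by explicit refitting.

    Each record is predicted by a model fitted to the other n−1 records.
    For OLS this equals the PRESS identity e_loo = e/(1−h), which the
    test suite uses as an independent check.
    """
    n = len(ds)
    k = len(descriptors)
    if n <= k + 2:
        raise ValidationError(f"LOO needs n > k+2 (n={n}, k={k})")
    y = np.asarray(ds.responses(response))
    errors = []
    records = list(ds.records)
    for i in range(n):
        rest = QsprDataset.from_records(records[:i] + records[i + 1:])
        fit_i = fit_ols(rest, descriptors=descriptors, response=response)
        pred_i = float(fit_i.predict(records[i])[0])
        errors.append(pred_i - y[i])
    e = np.asarray(errors)
    press = float(e @ e)
    sst = float(np.sum((y - y.mean()) ** 2))
    return LooReport(
        q2_cv=1.0 - press / sst,
        rmse_cv=float(np.sqrt(press / n)),
        per_record_errors=tuple(map(float, e)),
    )


@dataclass(frozen=True)
class RoyReport:
    """Error-based predictive-ability criteria for an external set.

    All errors are ``predicted − observed``, ordered as the validation
    records appear in the dataset. Trimming removes exactly the two
    records with the largest absolute error.

    Attributes
    ----------
    npe, nne : int
        Counts of positive and negative errors.
    npe_nne_ratio : float or None
        NPE/NNE; None when NNE = 0 (criterion skipped).
    abs_mean_pe_over_mean_ne : float or None
        |mean positive error / mean negative error|.
    trimmed_mae : float
        MAE of the n−2 errors left after trimming.
    sigma_abs : float
        Sample SD of the absolute errors after trimming.
    training_range : float
        max − min of the training responses.
    resid_autocorr_r2 : float
        Squared Pearson correlation of (e_i, e_{i−1}).
    resid_vs_y_r2 : float
        Squared Pearson correlation of observed values with errors.
    verdicts : mapping
        Criterion name → "pass"/"fail"/"skipped (NNE=0)".
    """

    npe: int
    nne: int
    npe_nne_ratio: float | None
    abs_mean_pe_over_mean_ne: float | None
    mae_val: float
    abs_bias_val: float
    trimmed_mae: float
    sigma_abs: float
    training_range: float
    resid_autocorr_r2: float
    resid_vs_y_r2: float
    verdicts: Mapping[str, str] = field(default_factory=dict)


def roy_error_criteria(
    training_responses,
    validation_observed,
    validation_predicted,
) -> RoyReport:
    """Apply the error-distribution criteria for systematic error and
    predictive ability to an external validation set.

    The checks, on errors e = predicted − observed:

    1. NPE/NNE ≤ 5 (no gross sign imbalance);
    2. |mean positive error / mean negative error| < 2;
    3. MAE − |BIAS| > 0.5 × MAE (errors not dominated by a shift);
    4. R² of consecutive errors (e_i vs e_{i−1}) < 0.5;
    5. R² of observed values vs errors < 0.5;
    6. trimmed MAE < 0.1 × training response range;
    7. trimmed MAE + 3σ(|e|, trimmed) ≤ 0.2 × training response range.

    When every error shares one sign the ratio criteria are undefined and
    reported as skipped rather than failed.
    """
    y_tr = np.asarray(training_responses, dtype=float)
    y, p = _check_pair(validation_observed, validation_predicted)
    if y.size < 5:
        raise ValidationError(f"need at least 5 validation points, got {y.size}")
    e = p - y
    abs_e = np.abs(e)

    npe = int(np.sum(e > 0))
    nne = int(np.sum(e < 0))
    if nne > 0 and npe > 0:
        ratio = npe / nne
        mean_ratio = abs(float(np.mean(e[e > 0]) / np.mean(e[e < 0])))
    else:
        ratio = None
        mean_ratio = None

    mae = float(np.mean(abs_e))
    abs_bias = abs(float(np.mean(e)))

    drop = np.argsort(-abs_e, kind="stable")[:2]
    trimmed = np.delete(abs_e, drop)
    assert trimmed.size == y.size - 2
    trimmed_mae = float(np.mean(trimmed))
    sigma_abs = float(np.std(trimmed, ddof=1))

    rng = float(np.max(y_tr) - np.min(y_tr))

    def _r2_or_nan(a: np.ndarray, b: np.ndarray) -> float:
        if np.std(a) == 0 or np.std(b) == 0:
            return float("nan")  # degenerate (constant) error vector
        return float(stats.pearsonr(a, b).statistic ** 2)

    autocorr_r2 = _r2_or_nan(e[1:], e[:-1])
    y_vs_e_r2 = _r2_or_nan(y, e)

    def _verdict(ok: bool) -> str:
        return "pass" if ok else "fail"

    skipped = "skipped (NNE=0 or NPE=0)"
    verdicts = {
        "npe_nne_ratio_le_5": _verdict(ratio <= 5) if ratio is not None else skipped,
        "abs_mean_pe_over_mean_ne_lt_2": (
            _verdict(mean_ratio < 2) if mean_ratio is not None else skipped
        ),
        "mae_minus_abs_bias_gt_half_mae": _verdict(mae - abs_bias > 0.5 * mae),
        "resid_autocorr_r2_lt_0.5": (
            _verdict(autocorr_r2 < 0.5) if np.isfinite(autocorr_r2)
            else "skipped (constant errors)"
        ),
        "resid_vs_y_r2_lt_0.5": (
            _verdict(y_vs_e_r2 < 0.5) if np.isfinite(y_vs_e_r2)
            else "skipped (constant errors)"
        ),
        "trimmed_mae_lt_0.1_range": _verdict(trimmed_mae < 0.1 * rng),
        "trimmed_mae_plus_3sigma_le_0.2_range": _verdict(
            trimmed_mae + 3 * sigma_abs <= 0.2 * rng
        ),
    }
    return RoyReport(
        npe=npe,
        nne=nne,
        npe_nne_ratio=ratio,
        abs_mean_pe_over_mean_ne=mean_ratio,
        mae_val=mae,
        abs_bias_val=abs_bias,
        trimmed_mae=trimmed_mae,
        sigma_abs=sigma_abs,
        training_range=rng,
        resid_autocorr_r2=autocorr_r2,
        resid_vs_y_r2=y_vs_e_r2,
        verdicts=verdicts,
    )
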