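"""Metric bundle, external validation, LOO CV, Roy criteria, correlation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kpqspr import (
    QsprDataset,
    SyntheticSpec,
    ValidationError,
    external_validation,
    fit_ols,
    generate_dataset,
    loo_cv,
    pearson_r,
    regression_metrics,
    roy_error_criteria,
    split_by_flag,
)


class TestRegressionMetrics:
    def test_three_point_toy_hand_arithmetic(self):
        """obs (0,1,2) vs pred (0,1,4): every statistic by hand."""
        m = regression_metrics([0, 1, 2], [0, 1, 4], ddof=0)
        assert m.rmse == pytest.approx(np.sqrt(4 / 3))
        assert m.mae == pytest.approx(2 / 3)
        assert m.mpe == pytest.approx(2.0)
        assert m.mne == pytest.approx(0.0)
        assert m.bias == pytest.approx(2 / 3)

    def test_perfect_prediction(self):
        m = regression_metrics([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert m.r2 == pytest.approx(1.0)
        assert m.q2 == pytest.approx(1.0)
        assert m.rmse == m.mae == m.bias == 0.0

    def test_full_set_fixture_metrics(self, full_fit, table1):
        m = regression_metrics(table1.responses(), full_fit.fitted_values)
        assert m.r2 == pytest.approx(0.847, abs=5e-4)
        assert m.q2 == pytest.approx(0.847, abs=5e-4)
        assert m.rmse == pytest.approx(0.584, abs=1e-3)
        assert m.mae == pytest.approx(0.491, abs=1e-3)
        assert m.bias == pytest.approx(0.000, abs=1e-9)
        assert m.mpe == pytest.approx(1.119, abs=2e-3)
        assert m.mne == pytest.approx(-1.197, abs=2e-3)

    def test_length_mismatch_and_short_input_error(self):
        with pytest.raises(ValidationError):
            regression_metrics([1, 2], [1, 2, 3])
        with pytest.raises(ValidationError):
            regression_metrics([1.0], [1.0])

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_bias_variance_decomposition(self, seed):
        """rmse² (ddof=0) = bias² + population variance of errors."""
        rng = np.random.default_rng(seed)
        y = rng.normal(size=12)
        p = y + rng.normal(size=12)
        m = regression_metrics(y, p, ddof=0)
        e = p - y
        assert m.rmse**2 == pytest.approx(m.bias**2 + np.var(e), abs=1e-10)

    def test_q2_equals_r2_for_self_fit(self, full_fit, table1):
        """With the evaluation-set mean as reference, Q² = 1−SSE/SST = R²."""
        m = regression_metrics(table1.responses(), full_fit.fitted_values)
        assert m.q2 == pytest.approx(full_fit.r2, abs=1e-10)


class TestPearson:
    def test_fixture_alpha_correlation(self, table1):
        r = pearson_r([rec.alpha for rec in table1], table1.responses())
        assert r == pytest.approx(0.839, abs=5e-4)

    def test_identity_and_sign_flip(self):
        x = [1.0, 2.0, 4.0]
        assert pearson_r(x, x) == pytest.approx(1.0)
        assert pearson_r(x, [-v for v in x]) == pytest.approx(-1.0)

    def test_zero_variance_errors(self):
        with pytest.raises(ValidationError):
            pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestExternalValidation:
    def test_canonical_split_statistics(self, ext_result):
        fit = ext_result.fit
        assert fit.coefficients[0] == pytest.approx(0.031, abs=5e-4)
        assert fit.coefficients[1] == pytest.approx(-27.835, abs=0.05)
        tm, vm = ext_result.train_metrics, ext_result.validation_metrics
        assert tm.r2 == pytest.approx(0.842, abs=1e-3)
        assert tm.rmse == pytest.approx(0.618, abs=1e-3)
        assert vm.r2 == pytest.approx(0.854, abs=2e-3)
        assert vm.rmse == pytest.approx(0.535, abs=3e-3)
        assert vm.mae == pytest.approx(0.438, abs=3e-3)
        # external Q² referenced to the training mean differs from R²
        assert vm.q2 == pytest.approx(0.847, abs=5e-3)

    def test_validation_copy_of_training_matches_training_metrics(self):
        spec = SyntheticSpec(n=20, noise_sd=0.3, seed=3)
        base = generate_dataset(spec)
        from dataclasses import replace as drep

        train_recs = [drep(r, is_validation=False) for r in base.records]
        val_recs = [
            drep(r, abbreviation=r.abbreviation + "v", is_validation=True)
            for r in base.records
        ]
        ds = QsprDataset.from_records(train_recs + val_recs)
        res = external_validation(ds)
        assert res.validation_metrics.r2 == pytest.approx(res.train_metrics.r2)
        assert res.validation_metrics.rmse == pytest.approx(res.train_metrics.rmse)
        assert res.validation_metrics.mae == pytest.approx(res.train_metrics.mae)

    def test_noiseless_validation_is_perfect(self):
        ds = generate_dataset(SyntheticSpec(n=24, noise_sd=0.0, seed=5))
        res = external_validation(ds)
        assert res.validation_metrics.r2 == pytest.approx(1.0, abs=1e-9)


class TestLooCv:
    def test_leverage_identity_on_fixture(self, table1, full_fit):
        """Explicit-refit LOO residuals equal e/(1−h) from the full fit."""
        rep = loo_cv(table1)
        X = np.hstack([np.ones((50, 1)), full_fit.model.exog])
        h = np.diag(X @ np.linalg.inv(X.T @ X) @ X.T)
        expected = full_fit.residuals / (1 - h)
        assert np.asarray(rep.per_record_errors) == pytest.approx(expected, abs=1e-8)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=10, deadline=None, derandomize=True)
    def test_leverage_identity_random_data(self, seed):
        ds = generate_dataset(SyntheticSpec(n=15, noise_sd=0.5, seed=seed % 2**31))
        rep = loo_cv(ds)
        fit = fit_ols(ds)
        X = np.hstack([np.ones((15, 1)), fit.model.exog])
        h = np.diag(X @ np.linalg.inv(X.T @ X) @ X.T)
        assert np.asarray(rep.per_record_errors) == pytest.approx(
            fit.residuals / (1 - h), abs=1e-8
        )

    def test_noiseless_q2_is_one(self):
        ds = generate_dataset(SyntheticSpec(n=20, noise_sd=0.0, seed=1))
        assert loo_cv(ds).q2_cv == pytest.approx(1.0, abs=1e-9)

    def test_fixture_q2_shows_robustness(self, table1):
        rep = loo_cv(table1)
        assert rep.q2_cv > 0.8
        assert len(rep.per_record_errors) == 50

    def test_too_small_dataset_errors(self):
        ds = generate_dataset(SyntheticSpec(n=4, noise_sd=0.1, seed=2))
        with pytest.raises(ValidationError):
            loo_cv(ds)


class TestRoyCriteria:
    def test_canonical_validation_set(self, table1, ext_result):
        train, valid = split_by_flag(table1)
        roy = roy_error_criteria(
            train.responses(), valid.responses(), ext_result.validation_predictions
        )
        assert (roy.npe, roy.nne) == (8, 7)
        assert roy.npe_nne_ratio == pytest.approx(1.143, abs=5e-4)
        assert roy.mae_val == pytest.approx(0.438, abs=3e-3)
        assert roy.trimmed_mae == pytest.approx(0.370, abs=2e-3)
        assert roy.sigma_abs == pytest.approx(0.234, abs=2e-3)
        assert roy.training_range == pytest.approx(5.21, abs=5e-3)
        assert roy.resid_vs_y_r2 == pytest.approx(0.029, abs=5e-3)
        # threshold checks the published analysis reports as satisfied
        assert roy.verdicts["npe_nne_ratio_le_5"] == "pass"
        assert roy.verdicts["abs_mean_pe_over_mean_ne_lt_2"] == "pass"
        assert roy.verdicts["mae_minus_abs_bias_gt_half_mae"] == "pass"
        assert roy.verdicts["resid_autocorr_r2_lt_0.5"] == "pass"
        assert roy.verdicts["resid_vs_y_r2_lt_0.5"] == "pass"
        assert roy.verdicts["trimmed_mae_lt_0.1_range"] == "pass"

    def test_hand_computed_five_residuals(self):
        """errors (+0.1, −0.2, +0.3, −0.4, +0.5) against zero observations."""
        obs = np.zeros(5)
        pred = np.array([0.1, -0.2, 0.3, -0.4, 0.5])
        roy = roy_error_criteria(np.linspace(-5, 0, 10), obs, pred)
        assert (roy.npe, roy.nne) == (3, 2)
        assert roy.npe_nne_ratio == pytest.approx(1.5)
        assert roy.abs_mean_pe_over_mean_ne == pytest.approx(0.3 / 0.3)
        assert roy.mae_val == pytest.approx(0.3)
        assert roy.trimmed_mae == pytest.approx(0.2)  # drop 0.5 and 0.4
        assert roy.sigma_abs == pytest.approx(0.1)

    def test_all_positive_errors_skips_ratio(self):
        obs = np.zeros(6)
        pred = np.full(6, 0.5)
        roy = roy_error_criteria(np.linspace(0, 5, 8), obs, pred)
        assert roy.nne == 0
        assert roy.npe_nne_ratio is None
        assert "skipped" in roy.verdicts["npe_nne_ratio_le_5"]

    def test_trimming_removes_exactly_two(self):
        obs = np.zeros(7)
        pred = np.array([0.1, -0.1, 0.2, -0.2, 0.3, -3.0, 3.0])
        roy = roy_error_criteria(np.linspace(0, 5, 8), obs, pred)
        assert roy.trimmed_mae == pytest.approx(np.mean([0.1, 0.1, 0.2, 0.2, 0.3]))

    def test_too_few_validation_points_error(self):
        with pytest.raises(ValidationError):
            roy_error_criteria([0, 5], np.zeros(4), np.ones(4))
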