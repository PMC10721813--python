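"""Additive hybridization, the BDS gate, and the 14-model study."""

import dataclasses
import warnings

import numpy as np
import pytest

from hybridts.evaluation import accuracy_table, rmse
from hybridts.hybrid_pipeline import (
    STUDY_MODELS,
    HybridSpec,
    StudyConfig,
    fit_hybrid,
    forecast_hybrid,
    run_study,
)
from hybridts.linear_arimax import (
    ArimaOrder,
    LinearModelSpec,
    fit_linear,
    forecast_linear,
    residual_series,
)
from hybridts.nonlinear_learners import (
    FittedLearner,
    NLSVRSpec,
    TDNNSpec,
    TrainingConfig,
    recursive_forecast,
)
from hybridts.series_io import split_holdout
from hybridts.synthetic_data import generate, nonlinear_residual_config

LIN = LinearModelSpec(order=ArimaOrder(0, 1, 1), exogenous=True)


@pytest.fixture(scope="module")
def nl_case():
    """Nonlinear-residual scenario: dataset, split, and a fitted hybrid."""
    ds = generate(nonlinear_residual_config(seed=0)).dataset
    split = split_holdout(ds, 7)
    spec = HybridSpec(linear=LIN,
                      residual_learner=NLSVRSpec(lags=4, C=100.0, gamma=1.0,
                                                 epsilon=0.02),
                      bds_gate="advisory")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = fit_hybrid(ds, split, spec, TrainingConfig(seed=0))
    return ds, split, fit


class TestFitHybrid:
    def test_linear_stage_unchanged_by_hybridization(self, nl_case):
        ds, split, hfit = nl_case
        standalone = fit_linear(split.train, LIN)
        np.testing.assert_array_equal(hfit.linear_fit.phi, standalone.phi)
        np.testing.assert_array_equal(hfit.linear_fit.theta, standalone.theta)
        assert hfit.linear_fit.mu == standalone.mu
        assert hfit.linear_fit.beta == standalone.beta

    def test_learner_trained_on_linear_residuals(self, nl_case):
        _, split, hfit = nl_case
        np.testing.assert_array_equal(
            hfit.residuals, residual_series(hfit.linear_fit)
        )

    def test_bds_report_populated(self, nl_case):
        _, _, hfit = nl_case
        assert len(hfit.bds_report) == 8
        assert min(c.p_value for c in hfit.bds_report) < 0.05

    def test_provenance_records_seed(self, nl_case):
        _, _, hfit = nl_case
        assert hfit.provenance["seed"] == 0
        assert len(hfit.provenance["config_hash"]) == 16

    def test_infeasible_learner_lags(self, nl_case):
        ds, split, _ = nl_case
        bad = HybridSpec(linear=LIN,
                         residual_learner=NLSVRSpec(lags=split.train.n))
        with pytest.raises(ValueError, match="lags"):
            fit_hybrid(ds, split, bad, TrainingConfig(seed=0))

    def test_hard_gate_raises_when_bds_cannot_reject(self):
        # a purely linear draw whose residual BDS grid has min p >= 0.05
        cfg = dataclasses.replace(nonlinear_residual_config(seed=1),
                                  nonlinearity_strength=0.0, noise_sd=25.0)
        ds = generate(cfg).dataset
        split = split_holdout(ds, 7)
        spec = HybridSpec(linear=LIN, residual_learner=NLSVRSpec(lags=2),
                          bds_gate="hard")
        with pytest.raises(ValueError, match="not detectably non-linear"):
            fit_hybrid(ds, split, spec, TrainingConfig(seed=0))

    def test_advisory_gate_warns_not_raises(self):
        cfg = dataclasses.replace(nonlinear_residual_config(seed=1),
                                  nonlinearity_strength=0.0, noise_sd=25.0)
        ds = generate(cfg).dataset
        split = split_holdout(ds, 7)
        spec = HybridSpec(linear=LIN, residual_learner=NLSVRSpec(lags=2),
                          bds_gate="advisory")
        with pytest.warns(UserWarning, match="not detectably non-linear"):
            fit_hybrid(ds, split, spec, TrainingConfig(seed=0))

    def test_gate_off_runs_silently(self):
        cfg = dataclasses.replace(nonlinear_residual_config(seed=1),
                                  nonlinearity_strength=0.0, noise_sd=25.0)
        ds = generate(cfg).dataset
        split = split_holdout(ds, 7)
        spec = HybridSpec(linear=LIN, residual_learner=NLSVRSpec(lags=2),
                          bds_gate="off")
        fit = fit_hybrid(ds, split, spec, TrainingConfig(seed=0))
        assert fit.bds_report == []


class _ZeroModel:
    def predict(self, X):
        return np.full(X.shape[0], 0.5)  # scaled midpoint of a symmetric scaler


class TestForecastHybrid:
    def test_zero_residual_learner_reduces_to_linear(self, nl_case):
        ds, split, hfit = nl_case
        from hybridts.nonlinear_learners import _MinMaxScaler

        # a learner that always predicts 0 in original units
        zero = FittedLearner(spec=TDNNSpec(lags=2, hidden=1),
                             scaler=_MinMaxScaler(lo=-1.0, hi=1.0),
                             model=_ZeroModel(), config=None)
        hybrid0 = dataclasses.replace(hfit, residual_fit=zero)
        yhat = forecast_hybrid(hybrid0, 7, future_exog=split.test.x)
        linear = forecast_linear(hfit.linear_fit, 7, future_exog=split.test.x)
        np.testing.assert_allclose(yhat, linear.values, rtol=0, atol=1e-12)

    def test_additivity_exact(self, nl_case):
        _, split, hfit = nl_case
        yhat, lhat, nhat = forecast_hybrid(hfit, 7, future_exog=split.test.x,
                                           return_components=True)
        np.testing.assert_allclose(yhat, lhat + nhat, rtol=0, atol=1e-10)

    def test_composes_from_separately_invoked_stages(self, nl_case):
        _, split, hfit = nl_case
        yhat = forecast_hybrid(hfit, 7, future_exog=split.test.x)
        lin = forecast_linear(hfit.linear_fit, 7, future_exog=split.test.x).values
        p = hfit.residual_fit.p
        res = recursive_forecast(hfit.residual_fit, hfit.residuals[-p:], 7)
        np.testing.assert_allclose(yhat, lin + res, rtol=0, atol=1e-10)


class TestOverfittingGuard:
    def test_hybrid_not_much_worse_on_purely_linear_data(self):
        # no nonlinear component: the hybrid may not beat the linear model,
        # but on average it must not degrade it by more than 10%
        base = dataclasses.replace(nonlinear_residual_config(),
                                   nonlinearity_strength=0.0, noise_sd=25.0)
        spec = HybridSpec(linear=LIN, residual_learner=NLSVRSpec(lags=3),
                          bds_gate="off")
        ratios = []
        for s in range(20):
            ds = generate(dataclasses.replace(base, seed=s)).dataset
            split = split_holdout(ds, 7)
            lfit = fit_linear(split.train, LIN)
            lfc = forecast_linear(lfit, 7, future_exog=split.test.x).values
            hfit = fit_hybrid(ds, split, spec, TrainingConfig(seed=s))
            hfc = forecast_hybrid(hfit, 7, future_exog=split.test.x)
            ratios.append(rmse(split.test.y, hfc) / rmse(split.test.y, lfc))
        assert np.mean(ratios) <= 1.10


@pytest.fixture(scope="module")
def zoo(wheat_ds):
    cfg = StudyConfig(seed=0, training=TrainingConfig(seed=0, epochs=60))
    return run_study(wheat_ds, cfg)


class TestRunStudy:
    def test_all_fourteen_models_present(self, zoo):
        assert set(zoo.forecasts) == set(STUDY_MODELS)
        assert zoo.failures == {}
        for fc in zoo.forecasts.values():
            assert np.asarray(fc).shape == (7,)

    def test_deterministic_given_seed(self, wheat_ds, zoo):
        cfg = StudyConfig(seed=0, training=TrainingConfig(seed=0, epochs=60))
        again = run_study(wheat_ds, cfg)
        for name in STUDY_MODELS:
            np.testing.assert_array_equal(zoo.forecasts[name],
                                          again.forecasts[name])

    def test_accuracy_table_contract(self, zoo):
        report = accuracy_table(zoo)
        assert len(report.table) == 14
        # metrics agree with direct metric calls on the stored vectors
        y = zoo.split.test.y
        row = report.lookup("ARIMA", zoo.series_name)
        assert row[0] == pytest.approx(rmse(y, zoo.forecasts["ARIMA"]))

    def test_requires_exog(self, wheat_ds):
        from conftest import make_dataset

        bare = make_dataset(wheat_ds.y)
        with pytest.raises(ValueError, match="exogenous"):
            run_study(bare, StudyConfig())
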