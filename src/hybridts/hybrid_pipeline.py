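"""Additive hybridization and the 14-model comparison protocol.

The hybrid assumes the response decomposes additively,
y_t = L_t + N_t: a linear ARIMA/ARIMAX stage captures L_t, its one-step
residuals e_t = y_t - Lhat_t are screened for non-linearity with the BDS
test and handed to a nonlinear learner, and forecasts are summed,
yhat = Lhat + Nhat, at every horizon — exactly, by construction.

``run_study`` fits the canonical 14-model zoo on a shared chronological
holdout: ARIMA, ARIMAX, the six standalone learners on the level series,
and the six ARIMAX-residual hybrids.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings as _warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .diagnostics import BDSResult, bds_test
from .linear_arimax import (
    FittedLinearModel,
    LinearModelSpec,
    fit_linear,
    forecast_linear,
    residual_series,
    select_order,
)
from .nonlinear_learners import (
    CNNSpec,
    FittedLearner,
    LSTMSpec,
    LearnerSpec,
    NLSVRSpec,
    RNNSpec,
    TDNNSpec,
    TrainingConfig,
    WNNSpec,
    fit_learner,
    embed_lags,
    fit_series_learner,
    recursive_forecast,
)
from .series_io import AnnualDataset, HoldoutSplit, split_holdout

__all__ = [
    "HybridSpec",
    "HybridFit",
    "StudyConfig",
    "ModelZooResult",
    "fit_hybrid",
    "forecast_hybrid",
    "run_study",
    "STUDY_MODELS",
]

logger = logging.getLogger("hybridts")

_GATE_MODES = {"advisory", "hard", "off"}


@dataclass(frozen=True)
class HybridSpec:
    linear: LinearModelSpec
    residual_learner: LearnerSpec
    bds_gate: str = "advisory"
    bds_alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.bds_gate not in _GATE_MODES:
            raise ValueError(f"bds_gate must be one of {sorted(_GATE_MODES)}")


@dataclass(frozen=True)
class HybridFit:
    """Linear stage + residual learner + the evidence that joined them."""

    spec: HybridSpec
    linear_fit: FittedLinearModel
    residual_fit: FittedLearner
    bds_report: list[BDSResult]
    provenance: dict

    @property
    def residuals(self) -> np.ndarray:
        return self.linear_fit.residuals


def _config_hash(payload: dict) -> str:
    return hashlib.sha256(json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()[:16]


def fit_hybrid(
    ds: AnnualDataset,
    split: HoldoutSplit,
    spec: HybridSpec,
    config: Optional[TrainingConfig] = None,
) -> HybridFit:
    """Fit linear stage on the training prefix, learner on its residuals.

    BDS gate behavior on the residual series: ``advisory`` warns when no
    (epsilon, m) cell rejects i.i.d. at ``bds_alpha``; ``hard`` raises;
    ``off`` skips the test entirely.
    """
    config = config or TrainingConfig()
    linear_fit = fit_linear(split.train, spec.linear)
    resid = residual_series(linear_fit)
    if spec.residual_learner.lags >= resid.size:
        raise ValueError(
            f"learner lags {spec.residual_learner.lags} infeasible on "
            f"{resid.size} residuals"
        )
    bds_report: list[BDSResult] = []
    if spec.bds_gate != "off":
        try:
            bds_report = bds_test(resid)
        except ValueError as exc:
            if spec.bds_gate == "hard":
                raise
            _warnings.warn(f"BDS test skipped on residuals: {exc}", stacklevel=2)
        if bds_report:
            rejected = any(r.p_value < spec.bds_alpha for r in bds_report)
            if not rejected:
                msg = (
                    "residuals not detectably non-linear: no BDS cell rejects "
                    f"i.i.d. at alpha={spec.bds_alpha}"
                )
                if spec.bds_gate == "hard":
                    raise ValueError(msg)
                _warnings.warn(msg, stacklevel=2)
    residual_fit = fit_learner(
        spec.residual_learner, embed_lags(resid, spec.residual_learner.lags), config
    )
    provenance = {
        "seed": config.seed,
        "config_hash": _config_hash(
            {
                "linear": spec.linear.label,
                "learner": repr(spec.residual_learner),
                "gate": spec.bds_gate,
                "train_years": [int(split.train.years[0]), int(split.train.years[-1])],
                "training": repr(config),
            }
        ),
    }
    return HybridFit(
        spec=spec,
        linear_fit=linear_fit,
        residual_fit=residual_fit,
        bds_report=bds_report,
        provenance=provenance,
    )


def forecast_hybrid(
    fit: HybridFit,
    h: int,
    future_exog: Optional[Sequence[float]] = None,
    extrapolate_exog: bool = False,
    return_components: bool = False,
):
    """yhat = Lhat + Nhat: linear forecast plus recursive residual forecast."""
    linear = forecast_linear(
        fit.linear_fit, h, future_exog=future_exog, extrapolate_exog=extrapolate_exog
    )
    p = fit.residual_fit.p
    nhat = recursive_forecast(fit.residual_fit, fit.residuals[-p:], h)
    yhat = linear.values + nhat
    if return_components:
        return yhat, linear.values, nhat
    return yhat


# --------------------------------------------------------------------------
# the 14-model study

STUDY_MODELS = (
    "ARIMA", "ARIMAX",
    "TDNN", "NLSVR", "WNN", "CNN", "RNN", "LSTM",
    "ARIMAX-TDNN", "ARIMAX-NLSVR", "ARIMAX-WNN", "ARIMAX-CNN",
    "ARIMAX-RNN", "ARIMAX-LSTM",
)


def _default_learner_specs() -> dict[str, LearnerSpec]:
    # compact architectures within the study's search ranges; the NLSVR
    # kernel width / tube defaults follow the published reference values
    return {
        "TDNN": TDNNSpec(lags=3, hidden=6),
        "NLSVR": NLSVRSpec(lags=3, C=10.0, gamma=0.25, epsilon=0.10),
        "WNN": WNNSpec(lags=3, wavelons=6),
        "CNN": CNNSpec(lags=3, filters=6, kernel_size=2, pool_size=1),
        "RNN": RNNSpec(lags=2, hidden=5),
        "LSTM": LSTMSpec(lags=2, hidden=4),
    }


@dataclass(frozen=True)
class StudyConfig:
    """Run-level knobs for the 14-model comparison."""

    k: int = 7
    d: Optional[int] = None          # differencing; None = choose via ADF
    p_max: int = 2
    q_max: int = 2
    criterion: str = "aic"
    seed: int = 0
    training: TrainingConfig = field(default_factory=TrainingConfig)
    learner_specs: dict = field(default_factory=_default_learner_specs)
    residual_learner_specs: Optional[dict] = None  # None = same as learner_specs
    bds_gate: str = "advisory"


@dataclass(frozen=True)
class ModelZooResult:
    """Fits and holdout forecasts for the 14 canonical models."""

    series_name: str
    split: HoldoutSplit
    forecasts: dict            # model name -> np.ndarray of k holdout forecasts
    fits: dict                 # model name -> fitted object
    failures: dict             # model name -> error message
    config: StudyConfig


def run_study(ds: AnnualDataset, config: Optional[StudyConfig] = None) -> ModelZooResult:
    """Fit all 14 models on a shared holdout split; failures are recorded.

    Requires an exogenous series (the ARIMAX family needs it).  Holdout
    exogenous values are the observed ones; all stochastic learners derive
    their seeds deterministically from ``config.seed``.
    """
    config = config or StudyConfig()
    if not ds.has_exog:
        raise ValueError("run_study needs a dataset with an exogenous series")
    split = split_holdout(ds, k=config.k)
    train, test = split.train, split.test
    d = config.d
    if d is None:
        from .diagnostics import select_differencing

        d = select_differencing(train)
    logger.info("study on %s: n=%d, k=%d, d=%d, seed=%d",
                ds.name, ds.n, config.k, d, config.seed)

    forecasts: dict[str, np.ndarray] = {}
    fits: dict[str, object] = {}
    failures: dict[str, str] = {}

    def attempt(name, fn):
        try:
            fits[name], forecasts[name] = fn()
            logger.info("model %-13s fitted (seed offset applied)", name)
        except Exception as exc:  # noqa: BLE001 - per-model failures are recorded
            failures[name] = f"{type(exc).__name__}: {exc}"
            logger.warning("model %s failed: %s", name, failures[name])

    # --- linear family
    def fit_arima():
        spec = select_order(train, d=d, p_max=config.p_max, q_max=config.q_max,
                            criterion=config.criterion, exogenous=False)
        fit = fit_linear(train, spec)
        return fit, forecast_linear(fit, config.k).values

    def fit_arimax():
        spec = select_order(train, d=d, p_max=config.p_max, q_max=config.q_max,
                            criterion=config.criterion, exogenous=True)
        fit = fit_linear(train, spec)
        return fit, forecast_linear(fit, config.k, future_exog=test.x).values

    attempt("ARIMA", fit_arima)
    attempt("ARIMAX", fit_arimax)

    # --- standalone learners on the level series
    learner_specs = config.learner_specs
    residual_specs = config.residual_learner_specs or learner_specs
    for i, name in enumerate(("TDNN", "NLSVR", "WNN", "CNN", "RNN", "LSTM")):
        spec = learner_specs[name]

        def fit_standalone(spec=spec, offset=i):
            tc = replace(config.training, seed=config.seed + offset)
            fitted = fit_series_learner(spec, train.y, tc)
            fc = recursive_forecast(fitted, train.y[-spec.lags:], config.k)
            return fitted, fc

        attempt(name, fit_standalone)

    # --- ARIMAX-residual hybrids (shared ARIMAX linear stage)
    if "ARIMAX" in fits:
        arimax_fit: FittedLinearModel = fits["ARIMAX"]
        for i, name in enumerate(("TDNN", "NLSVR", "WNN", "CNN", "RNN", "LSTM")):
            spec = residual_specs[name]

            def fit_h(spec=spec, offset=i):
                tc = replace(config.training, seed=config.seed + 100 + offset)
                hspec = HybridSpec(
                    linear=arimax_fit.spec, residual_learner=spec,
                    bds_gate=config.bds_gate,
                )
                with _warnings.catch_warnings():
                    _warnings.simplefilter("ignore")
                    hfit = fit_hybrid(ds, split, hspec, tc)
                fc = forecast_hybrid(hfit, config.k, future_exog=test.x)
                return hfit, fc

            attempt(f"ARIMAX-{name}", fit_h)
    else:
        for name in ("TDNN", "NLSVR", "WNN", "CNN", "RNN", "LSTM"):
            failures[f"ARIMAX-{name}"] = "linear ARIMAX stage failed"

    return ModelZooResult(
        series_name=ds.name,
        split=split,
        forecasts=forecasts,
        fits=fits,
        failures=failures,
        config=config,
    )
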