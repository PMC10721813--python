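"""ARIMA(p,d,q) and ARIMAX fitting, order selection and linear forecasting.

The model, written on the differenced scale with backshift operator B,

    phi_p(B) (1-B)^d y_t = mu + beta * x_t + theta_q(B) eps_t

is estimated by differencing the response d times and fitting an
ARMA(p, q) (+ constant, + exogenous-in-levels regression) to the result
with statsmodels' state-space machinery (exact ML, stationarity and
invertibility enforced by parameter transformation).  Forecasts of the
differenced series are iterated minimum-MSE predictions, integrated back
to the original scale.

Parameterization note: writing w for the d-th difference, the backend
estimates  w_t = beta * x_t + u_t  with
phi_p(B) u_t = mu + theta_q(B) eps_t: the constant sits inside the ARMA
recursion — exactly the equation-form mu above — while the exogenous
term is a contemporaneous regression, so w_t - beta * x_t follows the
ARMA.  Without exogenous terms this is literally the model equation;
with both AR terms and an exogenous variable, rewriting the regression
form into the single-equation form would give the exogenous term an
implied AR lag polynomial.  Coefficients are reported as estimated.

Sign conventions
----------------
AR: both this package and statsmodels write phi(B) = 1 - sum phi_i B^i,
so AR coefficients need no mapping.  MA: this package reports
theta(B) = 1 - sum theta_j B^j (the subtraction convention of the model
statement above), whereas statsmodels estimates 1 + sum theta_j B^j;
the mapping theta_here = -theta_statsmodels is applied at the boundary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import product
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from statsmodels.tsa.statespace.sarimax import SARIMAX

from .evaluation import mape as _mape
from .evaluation import rmse as _rmse
from .series_io import AnnualDataset, difference, split_holdout, undifference

__all__ = [
    "ArimaOrder",
    "LinearModelSpec",
    "FittedLinearModel",
    "LinearForecast",
    "fit_linear",
    "select_order",
    "forecast_linear",
    "residual_series",
]

MAX_ORDER = 5


@dataclass(frozen=True)
class ArimaOrder:
    p: int
    d: int
    q: int

    def __post_init__(self) -> None:
        if min(self.p, self.d, self.q) < 0:
            raise ValueError("orders must be non-negative")
        if self.p > MAX_ORDER or self.q > MAX_ORDER:
            raise ValueError(f"p and q are capped at {MAX_ORDER}")

    @property
    def n_arma_params(self) -> int:
        return self.p + self.q


@dataclass(frozen=True)
class LinearModelSpec:
    """What to fit: the order, the constant, and the exogenous term."""

    order: ArimaOrder
    include_constant: bool = True
    exogenous: bool = False
    difference_exog: bool = False  # Eq-as-written default: x enters in levels

    def __post_init__(self) -> None:
        if self.order.n_arma_params == 0 and not self.include_constant and not self.exogenous:
            raise ValueError("empty model: need AR/MA terms, a constant, or an exogenous term")

    @property
    def label(self) -> str:
        o = self.order
        base = f"ARIMAX({o.p},{o.d},{o.q})" if self.exogenous else f"ARIMA({o.p},{o.d},{o.q})"
        return base


@dataclass(frozen=True)
class FittedLinearModel:
    """Estimated linear stage: coefficients, residuals, fit criteria.

    Coefficients are stored in the package's (subtraction) MA convention;
    ``theta_statsmodels_convention`` gives the opposite-sign mapping.
    Residuals are one-step-ahead in-sample innovations in original units,
    aligned to training years d onwards (length n - d).
    """

    spec: LinearModelSpec
    mu: Optional[float]
    phi: np.ndarray
    theta: np.ndarray
    beta: Optional[float]
    standard_errors: dict
    p_values: dict
    residuals: np.ndarray
    residual_years: np.ndarray
    fitted_values: np.ndarray  # one-step predictions on the original scale
    sigma2: float
    aic: float
    bic: float
    loglik: float
    train_years: np.ndarray
    train_y: np.ndarray
    train_x: Optional[np.ndarray]
    _results: object = field(repr=False, compare=False)

    @property
    def theta_statsmodels_convention(self) -> np.ndarray:
        return -self.theta

    def coefficients(self) -> dict:
        out: dict[str, float] = {}
        if self.mu is not None:
            out["mu"] = self.mu
        for i, v in enumerate(self.phi, 1):
            out[f"phi{i}"] = float(v)
        for j, v in enumerate(self.theta, 1):
            out[f"theta{j}"] = float(v)
        if self.beta is not None:
            out["beta1"] = self.beta
        out["sigma2"] = self.sigma2
        return out


@dataclass(frozen=True)
class LinearForecast:
    years: np.ndarray
    values: np.ndarray
    future_exog: Optional[np.ndarray] = None
    exog_extrapolated: bool = False

    @property
    def h(self) -> int:
        return int(self.values.size)


def _design(train: AnnualDataset, spec: LinearModelSpec):
    """Differenced endog and aligned exog for the ARMA stage."""
    d = spec.order.d
    w = difference(train.y, d)
    exog = None
    if spec.exogenous:
        if train.x is None:
            raise ValueError("spec requires an exogenous series but the dataset has none")
        if np.std(train.x) == 0.0:
            raise ValueError("singular exogenous column (constant)")
        exog = difference(train.x, d) if spec.difference_exog else train.x[d:]
        exog = exog.reshape(-1, 1)
    return w, exog


def fit_linear(train: AnnualDataset, spec: LinearModelSpec) -> FittedLinearModel:
    """Exact-ML fit of the linear stage on the training prefix."""
    o = spec.order
    if train.n <= 10 + o.p + o.q + o.d:
        raise ValueError(
            f"training length {train.n} too short for order ({o.p},{o.d},{o.q}); "
            f"need > {10 + o.p + o.q + o.d}"
        )
    w, exog = _design(train, spec)
    model = SARIMAX(
        w,
        exog=exog,
        order=(o.p, 0, o.q),
        trend="c" if spec.include_constant else "n",
        enforce_stationarity=True,
        enforce_invertibility=True,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(disp=False, maxiter=200)
    if not np.all(np.isfinite(res.params)):
        raise ValueError("estimation failed: non-finite parameter estimates")

    names = list(res.param_names)
    params = dict(zip(names, np.asarray(res.params, dtype=float)))
    bse = dict(zip(names, np.asarray(res.bse, dtype=float)))
    pvals = dict(zip(names, np.asarray(res.pvalues, dtype=float)))

    phi = np.array([params[f"ar.L{i}"] for i in range(1, o.p + 1)], dtype=float)
    # map statsmodels' addition convention to the subtraction convention
    theta = np.array([-params[f"ma.L{j}"] for j in range(1, o.q + 1)], dtype=float)
    mu = float(params["intercept"]) if spec.include_constant else None
    beta = float(params["x1"]) if spec.exogenous else None

    def _remap(d_: dict) -> dict:
        out = {}
        for key, val in d_.items():
            if key == "intercept":
                out["mu"] = float(val)
            elif key == "x1":
                out["beta1"] = float(val)
            elif key.startswith("ar.L"):
                out["phi" + key[4:]] = float(val)
            elif key.startswith("ma.L"):
                out["theta" + key[4:]] = float(val)
            else:
                out[key] = float(val)
        return out

    resid = np.asarray(res.resid, dtype=float)  # innovations of the differenced series,
    # which equal original-scale one-step innovations (differencing is a known shift)
    fitted_diff = w - resid
    fitted_levels = _one_step_levels(train.y, fitted_diff, o.d)

    return FittedLinearModel(
        spec=spec,
        mu=mu,
        phi=phi,
        theta=theta,
        beta=beta,
        standard_errors=_remap(bse),
        p_values=_remap(pvals),
        residuals=resid,
        residual_years=train.years[o.d :],
        fitted_values=np.asarray(fitted_levels, dtype=float),
        sigma2=float(params["sigma2"]),
        aic=float(res.aic),
        bic=float(res.bic),
        loglik=float(res.llf),
        train_years=train.years.copy(),
        train_y=train.y.copy(),
        train_x=None if train.x is None else train.x.copy(),
        _results=res,
    )


def _one_step_levels(y: np.ndarray, fitted_diff: np.ndarray, d: int) -> np.ndarray:
    """One-step level predictions from predictions of the d-th difference.

    yhat_t = predicted d-th difference + the known lag terms of (1-B)^d y_t.
    """
    if d == 0:
        return fitted_diff
    # (1-B)^d y_t = sum_{i=0}^{d} (-1)^i C(d,i) y_{t-i}; solve for y_t
    from math import comb

    n = y.size
    out = np.empty(n - d, dtype=float)
    for idx, t in enumerate(range(d, n)):
        known = 0.0
        for i in range(1, d + 1):
            known += ((-1) ** i) * comb(d, i) * y[t - i]
        out[idx] = fitted_diff[idx] - known
    return out


def residual_series(model: FittedLinearModel) -> np.ndarray:
    """Training one-step innovations e_t = y_t - Lhat_t (length n - d)."""
    return model.residuals.copy()


def _extrapolate_exog(model: FittedLinearModel, h: int) -> np.ndarray:
    """Univariate drift forecast of x for beyond-sample horizons (flagged)."""
    x = model.train_x
    spec = LinearModelSpec(order=ArimaOrder(1, 1, 0), include_constant=True, exogenous=False)
    xds = AnnualDataset(name="exog", years=model.train_years, y=x)
    fit = fit_linear(xds, spec)
    vals = forecast_linear(fit, h).values
    return np.clip(vals, 0.0, 100.0)


def forecast_linear(
    model: FittedLinearModel,
    h: int,
    future_exog: Optional[Sequence[float]] = None,
    extrapolate_exog: bool = False,
) -> LinearForecast:
    """Iterated minimum-MSE point forecasts on the original scale."""
    if h < 1:
        raise ValueError("horizon h must be >= 1")
    o = model.spec.order
    exog_used = None
    extrapolated = False
    if model.spec.exogenous:
        if future_exog is None:
            if not extrapolate_exog:
                raise ValueError(
                    "exogenous model needs h future exogenous values; supply future_exog "
                    "or pass extrapolate_exog=True to auto-extrapolate (flagged in output)"
                )
            exog_used = _extrapolate_exog(model, h)
            extrapolated = True
        else:
            exog_used = np.asarray(future_exog, dtype=float)
            if exog_used.size != h:
                raise ValueError(f"need {h} future exogenous values, got {exog_used.size}")
        if model.spec.difference_exog:
            anchors_x = model.train_x[-o.d :] if o.d else np.array([])
            exog_fc = difference(np.concatenate([anchors_x, exog_used]), o.d) if o.d else exog_used
        else:
            exog_fc = exog_used
        diff_fc = model._results.forecast(steps=h, exog=exog_fc.reshape(-1, 1))
    else:
        diff_fc = model._results.forecast(steps=h)
    diff_fc = np.asarray(diff_fc, dtype=float)
    if o.d == 0:
        values = diff_fc
    else:
        values = undifference(diff_fc, o.d, model.train_y[-o.d :])
    years = model.train_years[-1] + 1 + np.arange(h)
    return LinearForecast(
        years=years, values=values, future_exog=exog_used, exog_extrapolated=extrapolated
    )


@dataclass(frozen=True)
class OrderSelection:
    best: LinearModelSpec
    scores: pd.DataFrame  # one row per candidate with the criterion value
    criterion: str


def select_order(
    train: AnnualDataset,
    d: int,
    p_max: int = MAX_ORDER,
    q_max: int = MAX_ORDER,
    criterion: str = "aic",
    exogenous: bool = False,
    include_constant: bool = True,
    validation_k: int = 7,
    spec_space: Optional[Sequence[LinearModelSpec]] = None,
    return_table: bool = False,
):
    """Grid-search (p, q) at fixed d by information criterion or holdout error.

    Candidates are all (p, q) with 0 <= p <= p_max, 0 <= q <= q_max
    (the (0,0) cell is the constant-only model and requires a constant).
    Ties are broken by fewer parameters, then lower q, then lower p.
    For criterion ``holdout_rmse``/``holdout_mape`` a validation tail of
    ``validation_k`` points is carved from the end of the training data.
    """
    if criterion not in {"aic", "bic", "holdout_rmse", "holdout_mape"}:
        raise ValueError(f"unknown criterion {criterion!r}")
    if spec_space is None:
        spec_space = []
        for p, q in product(range(p_max + 1), range(q_max + 1)):
            if p == 0 and q == 0 and not include_constant and not exogenous:
                continue
            spec_space.append(
                LinearModelSpec(
                    order=ArimaOrder(p, d, q),
                    include_constant=include_constant,
                    exogenous=exogenous,
                )
            )
    if not spec_space:
        raise ValueError("empty specification grid")

    inner = None
    if criterion.startswith("holdout"):
        inner = split_holdout(train, k=validation_k)

    rows, failures = [], []
    for spec in spec_space:
        try:
            if criterion in {"aic", "bic"}:
                fit = fit_linear(train, spec)
                score = fit.aic if criterion == "aic" else fit.bic
            else:
                fit = fit_linear(inner.train, spec)
                fc = forecast_linear(
                    fit,
                    inner.k,
                    future_exog=inner.test.x if spec.exogenous else None,
                )
                metric = _rmse if criterion == "holdout_rmse" else _mape
                score = metric(inner.test.y, fc.values)
        except Exception as exc:  # noqa: BLE001 - candidate failures are data
            failures.append((spec.label, str(exc)))
            continue
        n_params = (
            spec.order.n_arma_params
            + int(spec.include_constant)
            + int(spec.exogenous)
        )
        rows.append(
            {
                "p": spec.order.p,
                "q": spec.order.q,
                "spec": spec,
                "score": float(score),
                "n_params": n_params,
            }
        )
    if not rows:
        lines = "; ".join(f"{lbl}: {msg}" for lbl, msg in failures)
        raise ValueError(f"all candidate fits failed — {lines}")
    table = pd.DataFrame(rows)
    table = table.sort_values(
        by=["score", "n_params", "q", "p"], kind="mergesort"
    ).reset_index(drop=True)
    best = table["spec"].iloc[0]
    if return_table:
        return OrderSelection(best=best, scores=table, criterion=criterion)
    return best
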