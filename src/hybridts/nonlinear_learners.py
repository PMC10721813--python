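"""Lag embedding and the six nonlinear learners.

A univariate series is turned into supervised rows
(y_{t-1}, ..., y_{t-p}) -> y_t and handed to one of:

* TDNN  — single-hidden-layer perceptron with ReLU hidden units,
* NLSVR — epsilon-insensitive support vector regression, RBF kernel,
* WNN   — the same perceptron with Morlet wavelons exp(-y^2)cos(5y),
* CNN   — one conv block (filters/kernel/pool) with a linear head,
* RNN   — vanilla tanh recurrence over the lags as a length-p sequence,
* LSTM  — gated recurrence over the same sequence.

Every learner sees the series min-max scaled to [0, 1] (scaler fitted on
the training rows only, inverted before anything is reported), trains
deterministically from a seed, and forecasts multiple steps recursively
by feeding predictions back as inputs.

``count_parameters`` gives the exact trainable-weight count of each
network (the single-output head included); RNN/LSTM consume the p lags
one value per time step, which is why their counts do not depend on p.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Callable, Optional, Sequence, Union

import numpy as np
import pandas as pd
from sklearn.svm import SVR

from ._nets import CNNNet, LSTMNet, MLPNet, RNNNet, TrainingDivergence, morlet, relu
from .evaluation import mape as _mape
from .evaluation import rmse as _rmse

__all__ = [
    "LagEmbedding",
    "TDNNSpec",
    "NLSVRSpec",
    "WNNSpec",
    "CNNSpec",
    "RNNSpec",
    "LSTMSpec",
    "LearnerSpec",
    "TrainingConfig",
    "FittedLearner",
    "GridSearchResult",
    "embed_lags",
    "count_parameters",
    "morlet",
    "relu",
    "fit_learner",
    "fit_series_learner",
    "recursive_forecast",
    "grid_search",
]


@dataclass(frozen=True)
class LagEmbedding:
    """Supervised lag matrix: row i is (y_{t-1},...,y_{t-p}) for target y_t."""

    X: np.ndarray
    targets: np.ndarray
    p: int

    def __post_init__(self) -> None:
        if self.X.shape != (self.targets.size, self.p):
            raise ValueError("embedding shape mismatch")


def embed_lags(series: Sequence[float], p: int) -> LagEmbedding:
    """Lag-embed a series; rows are most-recent-lag-first, order preserved."""
    arr = np.asarray(series, dtype=float)
    if p < 1:
        raise ValueError("need at least one lag")
    if p >= arr.size:
        raise ValueError(f"p={p} must be smaller than the series length {arr.size}")
    windows = np.lib.stride_tricks.sliding_window_view(arr, p)[:-1]
    return LagEmbedding(X=windows[:, ::-1].copy(), targets=arr[p:].copy(), p=p)


# --------------------------------------------------------------------------
# learner specifications


@dataclass(frozen=True)
class TDNNSpec:
    lags: int
    hidden: int

    def __post_init__(self) -> None:
        if not (1 <= self.lags <= 6 and 1 <= self.hidden <= 10):
            raise ValueError("TDNN search range: lags 1-6, hidden 1-10")


@dataclass(frozen=True)
class NLSVRSpec:
    lags: int
    C: float = 10.0
    gamma: float = 0.25
    epsilon: float = 0.10

    def __post_init__(self) -> None:
        if self.lags < 1 or self.C <= 0 or self.gamma <= 0 or self.epsilon < 0:
            raise ValueError("require lags >= 1, C > 0, gamma > 0, epsilon >= 0")


@dataclass(frozen=True)
class WNNSpec:
    lags: int
    wavelons: int

    def __post_init__(self) -> None:
        if not (1 <= self.lags <= 6 and 1 <= self.wavelons <= 10):
            raise ValueError("WNN search range: lags 1-6, wavelons 1-10")


@dataclass(frozen=True)
class CNNSpec:
    lags: int
    filters: int
    kernel_size: int = 2
    pool_size: int = 1
    activation: str = "relu"  # 'tanh' optionally
    pooling: str = "max"

    def __post_init__(self) -> None:
        if self.lags - self.kernel_size + 1 < 1:
            raise ValueError("kernel does not fit in the lag window")
        if (self.lags - self.kernel_size + 1) // self.pool_size < 1:
            raise ValueError("pool size larger than the convolution output")


@dataclass(frozen=True)
class RNNSpec:
    lags: int
    hidden: int

    def __post_init__(self) -> None:
        if self.lags < 1 or self.hidden < 1:
            raise ValueError("lags and hidden must be >= 1")


@dataclass(frozen=True)
class LSTMSpec:
    lags: int
    hidden: int

    def __post_init__(self) -> None:
        if self.lags < 1 or self.hidden < 1:
            raise ValueError("lags and hidden must be >= 1")


LearnerSpec = Union[TDNNSpec, NLSVRSpec, WNNSpec, CNNSpec, RNNSpec, LSTMSpec]


def count_parameters(spec: LearnerSpec) -> int:
    """Exact trainable parameter count, single-output dense head included."""
    if isinstance(spec, (TDNNSpec, WNNSpec)):
        q = spec.hidden if isinstance(spec, TDNNSpec) else spec.wavelons
        return q * (spec.lags + 1) + (q + 1)
    if isinstance(spec, CNNSpec):
        m = (spec.lags - spec.kernel_size + 1) // spec.pool_size
        return spec.filters * (spec.kernel_size + 1) + spec.filters * m + 1
    if isinstance(spec, RNNSpec):
        n = spec.hidden
        return n * n + 3 * n + 1
    if isinstance(spec, LSTMSpec):
        n = spec.hidden
        return 4 * (n * (n + 1) + n) + (n + 1)
    if isinstance(spec, NLSVRSpec):
        raise ValueError("NLSVR is a kernel method without a fixed parameter count")
    raise TypeError(f"unknown learner spec {type(spec).__name__}")


@dataclass(frozen=True)
class TrainingConfig:
    """Optimization settings shared by all network learners.

    Adam with minibatches of ``batch_size`` (default 1) for ``epochs``
    epochs (default 300); the seed fully determines initialization and the
    shuffling order.  ``patience`` (epochs without improvement) enables
    early stopping; None disables it.  Min-max scaling to [0, 1] is fitted
    on the training rows only.
    """

    epochs: int = 300
    batch_size: int = 1
    learning_rate: float = 0.01
    seed: int = 0
    patience: Optional[int] = None
    optimizer: str = "adam"

    def __post_init__(self) -> None:
        if self.optimizer != "adam":
            raise ValueError("only the Adam optimizer is implemented")
        if self.epochs < 1 or self.batch_size < 1 or self.learning_rate <= 0:
            raise ValueError("invalid training configuration")


@dataclass(frozen=True)
class _MinMaxScaler:
    lo: float
    hi: float

    @classmethod
    def fit(cls, values: np.ndarray) -> "_MinMaxScaler":
        lo, hi = float(np.min(values)), float(np.max(values))
        if hi - lo == 0.0:
            raise ValueError("degenerate scaler: constant training values")
        return cls(lo=lo, hi=hi)

    def transform(self, v):
        return (np.asarray(v, dtype=float) - self.lo) / (self.hi - self.lo)

    def inverse(self, v):
        return np.asarray(v, dtype=float) * (self.hi - self.lo) + self.lo


def _build_net(spec: LearnerSpec):
    if isinstance(spec, TDNNSpec):
        return MLPNet(spec.lags, spec.hidden, activation="relu")
    if isinstance(spec, WNNSpec):
        return MLPNet(spec.lags, spec.wavelons, activation="morlet")
    if isinstance(spec, CNNSpec):
        return CNNNet(
            spec.lags, spec.filters, spec.kernel_size, spec.pool_size,
            activation=spec.activation, pooling=spec.pooling,
        )
    if isinstance(spec, RNNSpec):
        return RNNNet(spec.lags, spec.hidden)
    if isinstance(spec, LSTMSpec):
        return LSTMNet(spec.lags, spec.hidden)
    raise TypeError(f"no network for spec {type(spec).__name__}")


@dataclass
class FittedLearner:
    """A trained learner plus its scaler; predicts in original units."""

    spec: LearnerSpec
    scaler: _MinMaxScaler
    model: object
    config: Optional[TrainingConfig]
    loss_history: list = field(default_factory=list)

    @property
    def p(self) -> int:
        return self.spec.lags

    def predict(self, X: np.ndarray) -> np.ndarray:
        """One-step predictions for lag rows given in original units."""
        Xs = self.scaler.transform(np.atleast_2d(X))
        if isinstance(self.model, SVR):
            out = self.model.predict(Xs)
        else:
            out = self.model.predict(Xs)
        return self.scaler.inverse(out)


def fit_learner(
    spec: LearnerSpec,
    embedding: LagEmbedding,
    config: Optional[TrainingConfig] = None,
) -> FittedLearner:
    """Train a learner on a lag embedding (scaler fitted on these rows only)."""
    config = config or TrainingConfig()
    if embedding.targets.size == 0:
        raise ValueError("empty embedding")
    if embedding.p != spec.lags:
        raise ValueError(
            f"embedding has p={embedding.p} lags but the spec wants {spec.lags}"
        )
    all_values = np.concatenate([embedding.X.ravel(), embedding.targets])
    scaler = _MinMaxScaler.fit(all_values)
    Xs = scaler.transform(embedding.X)
    ys = scaler.transform(embedding.targets)
    if isinstance(spec, NLSVRSpec):
        svr = SVR(kernel="rbf", C=spec.C, gamma=spec.gamma, epsilon=spec.epsilon)
        svr.fit(Xs, ys)
        return FittedLearner(spec=spec, scaler=scaler, model=svr, config=config)
    net = _build_net(spec)
    net.fit(
        Xs, ys,
        epochs=config.epochs,
        batch_size=config.batch_size,
        lr=config.learning_rate,
        seed=config.seed,
        patience=config.patience,
    )
    return FittedLearner(
        spec=spec, scaler=scaler, model=net, config=config,
        loss_history=list(net.loss_history),
    )


def fit_series_learner(
    spec: LearnerSpec,
    series: Sequence[float],
    config: Optional[TrainingConfig] = None,
) -> FittedLearner:
    """Convenience: embed a series with the spec's lags, then fit."""
    return fit_learner(spec, embed_lags(series, spec.lags), config)


def recursive_forecast(
    fitted: FittedLearner,
    history: Sequence[float],
    h: int,
) -> np.ndarray:
    """Iterated multi-step forecast feeding predictions back as inputs.

    ``history`` is the last p observed values in chronological order
    (original units); the result is h steps ahead, original units.
    """
    if h < 1:
        raise ValueError("horizon h must be >= 1")
    hist = np.asarray(history, dtype=float)
    p = fitted.p
    if hist.size != p:
        raise ValueError(f"history must supply exactly p={p} values, got {hist.size}")
    buf = list(hist)
    out = np.empty(h, dtype=float)
    for step in range(h):
        row = np.array(buf[-p:][::-1])  # most recent first
        out[step] = float(fitted.predict(row[None, :])[0])
        buf.append(out[step])
    return out


@dataclass(frozen=True)
class GridSearchResult:
    best: LearnerSpec
    scores: pd.DataFrame  # one row per candidate: spec fields, score, n_params


def grid_search(
    spec_family: Callable[[int, int], LearnerSpec],
    train: Sequence[float],
    validation: Sequence[float],
    metric: str = "rmse",
    lags_range: Sequence[int] = range(1, 7),
    hidden_range: Sequence[int] = range(1, 11),
    config: Optional[TrainingConfig] = None,
) -> GridSearchResult:
    """Exhaustive (lags x hidden) search scored on a validation tail.

    ``spec_family`` maps (lags, hidden) to a spec.  The learner is trained
    on ``train`` and scored by recursively forecasting the ``validation``
    block that chronologically follows it.  Ties break toward fewer
    parameters, then fewer lags.  The full score table is retained.
    """
    if metric not in {"rmse", "mape"}:
        raise ValueError("metric must be 'rmse' or 'mape'")
    train = np.asarray(train, dtype=float)
    validation = np.asarray(validation, dtype=float)
    candidates = list(product(lags_range, hidden_range))
    if not candidates:
        raise ValueError("empty search grid")
    score_fn = _rmse if metric == "rmse" else _mape
    rows, failures = [], []
    for lags, hidden in candidates:
        try:
            spec = spec_family(lags, hidden)
            fitted = fit_series_learner(spec, train, config)
            fc = recursive_forecast(fitted, train[-lags:], validation.size)
            score = score_fn(validation, fc)
            try:
                n_params = count_parameters(spec)
            except ValueError:
                n_params = 0
        except (ValueError, TrainingDivergence) as exc:
            failures.append((lags, hidden, str(exc)))
            continue
        rows.append(
            {"lags": lags, "hidden": hidden, "spec": spec,
             "score": float(score), "n_params": n_params}
        )
    if not rows:
        detail = "; ".join(f"({p},{q}): {m}" for p, q, m in failures)
        raise ValueError(f"all grid candidates failed — {detail}")
    table = pd.DataFrame(rows).sort_values(
        by=["score", "n_params", "lags"], kind="mergesort"
    ).reset_index(drop=True)
    return GridSearchResult(best=table["spec"].iloc[0], scores=table)
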