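"""Pre-modeling diagnostics: descriptives, correlation, ADF, and the BDS test.

The workflow gates implemented here mirror standard hybrid-forecasting
practice: descriptive statistics and Pearson correlation justify the
exogenous covariate, the augmented Dickey–Fuller (ADF) test fixes the
differencing order d, and the Broock–Dechert–Scheinkman (BDS) test checks
for departures from i.i.d. (interpreted as residual non-linearity) before
a nonlinear learner is fitted.

The BDS statistic is computed from first principles via correlation
integrals C_m(eps) — the fraction of pairs of m-histories within
sup-norm distance eps — with the Brock–Dechert–Scheinkman–LeBaron
asymptotic variance estimator:

    W_m(eps) = sqrt(n_m) * (C_m - C_1^m) / sigma_m(eps),   n_m = n - m + 1

which is asymptotically standard normal under i.i.d.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.tsa.stattools import adfuller

from .series_io import AnnualDataset, difference

__all__ = [
    "DescriptiveStats",
    "ADFResult",
    "BDSResult",
    "describe",
    "pearson_correlation",
    "adf_test",
    "select_differencing",
    "correlation_integral",
    "bds_statistic",
    "bds_test",
]


@dataclass(frozen=True)
class DescriptiveStats:
    """Summary statistics in the layout of a standard descriptives table."""

    mean: float
    minimum: float
    maximum: float
    standard_deviation: float  # sample sd, ddof=1
    cv_percent: float  # 100 * sd / mean
    skewness: float  # bias-corrected sample skewness
    kurtosis: float  # bias-corrected excess kurtosis


@dataclass(frozen=True)
class ADFResult:
    statistic: float
    p_value: float
    lags_used: int
    regression_kind: str  # "constant" or "constant+trend"
    alpha: float
    reject_unit_root: bool


@dataclass(frozen=True)
class BDSResult:
    epsilon: float
    embedding_dimension: int
    statistic: float
    p_value: float


def describe(series: Sequence[float]) -> DescriptiveStats:
    """Mean, min, max, sample sd, CV%, skewness and excess kurtosis.

    Skewness and kurtosis use the bias-corrected (small-sample adjusted)
    estimators, i.e. ``scipy.stats.skew/kurtosis`` with ``bias=False``;
    kurtosis is reported in excess form (normal = 0).
    """
    arr = np.asarray(series, dtype=float)
    if arr.size < 4:
        raise ValueError("need at least 4 observations for skewness/kurtosis")
    sd = float(np.std(arr, ddof=1))
    if sd == 0.0:
        raise ValueError("zero variance: series is constant")
    mean = float(np.mean(arr))
    return DescriptiveStats(
        mean=mean,
        minimum=float(arr.min()),
        maximum=float(arr.max()),
        standard_deviation=sd,
        cv_percent=100.0 * sd / mean if mean != 0.0 else float("nan"),
        skewness=float(sps.skew(arr, bias=False)),
        kurtosis=float(sps.kurtosis(arr, fisher=True, bias=False)),
    )


def pearson_correlation(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Pearson r with the two-sided p-value from the t-transform (n-2 df)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size != b.size:
        raise ValueError("series must have equal lengths")
    if a.size < 3:
        raise ValueError("need at least 3 paired observations")
    if np.std(a) == 0.0 or np.std(b) == 0.0:
        raise ValueError("zero variance: cannot correlate a constant series")
    res = sps.pearsonr(a, b)
    return float(res.statistic), float(res.pvalue)


_REGRESSION_CODES = {"constant": "c", "constant+trend": "ct"}


def adf_test(
    series: Sequence[float],
    regression_kind: str = "constant+trend",
    max_lag: Optional[int] = None,
    alpha: float = 0.05,
) -> ADFResult:
    """Augmented Dickey–Fuller unit-root test.

    The ADF regression is run on first differences with the lagged level
    and ``k`` lagged differences; ``k`` is chosen by AIC up to ``max_lag``
    (default ``floor((n-1)^(1/3))``).  P-values come from MacKinnon
    response-surface interpolation.  Rejection means stationarity.
    """
    arr = np.asarray(series, dtype=float)
    if arr.size < 15:
        raise ValueError("series too short for the ADF test (need n >= 15)")
    if regression_kind not in _REGRESSION_CODES:
        raise ValueError(f"regression_kind must be one of {sorted(_REGRESSION_CODES)}")
    if max_lag is None:
        max_lag = int(np.floor((arr.size - 1) ** (1.0 / 3.0)))
    stat, pval, usedlag, _, _, _ = adfuller(
        arr, maxlag=max_lag, regression=_REGRESSION_CODES[regression_kind], autolag="AIC"
    )
    return ADFResult(
        statistic=float(stat),
        p_value=float(pval),
        lags_used=int(usedlag),
        regression_kind=regression_kind,
        alpha=alpha,
        reject_unit_root=bool(pval < alpha),
    )


def select_differencing(
    ds: AnnualDataset | Sequence[float],
    alpha: float = 0.05,
    max_d: int = 2,
) -> int:
    """Smallest d in {0..max_d} whose d-th difference rejects a unit root.

    The level series is tested with constant+trend deterministics (annual
    yields trend strongly); differenced series with constant only.
    """
    y = ds.y if isinstance(ds, AnnualDataset) else np.asarray(ds, dtype=float)
    for d in range(max_d + 1):
        kind = "constant+trend" if d == 0 else "constant"
        res = adf_test(difference(y, d), regression_kind=kind, alpha=alpha)
        if res.reject_unit_root:
            return d
    raise ValueError(
        f"series still non-stationary after d={max_d} differences at alpha={alpha}; "
        "inspect the series and override the differencing order manually"
    )


def _indicator_matrix(series: np.ndarray, epsilon: float) -> np.ndarray:
    """Pairwise closeness indicators |x_s - x_t| <= eps (diagonal True)."""
    return np.abs(series[:, None] - series[None, :]) <= epsilon


def _joint_indicators(ind: np.ndarray, m: int) -> np.ndarray:
    """Indicator matrix of sup-norm closeness between m-histories.

    Built by the standard recursion: histories (x_t..x_{t+m-1}) are close
    iff all coordinate pairs are, so the joint matrix is the elementwise
    product of m shifted copies of the 1-d indicator matrix.
    """
    joint = ind
    for _ in range(m - 1):
        joint = joint[1:, 1:] & ind[: joint.shape[0] - 1, : joint.shape[0] - 1]
    return joint


def _pair_fraction(ind: np.ndarray) -> float:
    n = ind.shape[0]
    if n < 2:
        raise ValueError("need at least 2 embedded vectors")
    iu = np.triu_indices(n, 1)
    return float(np.mean(ind[iu]))


def correlation_integral(series: Sequence[float], epsilon: float, m: int) -> float:
    """C_m(eps): fraction of pairs of m-histories within sup-norm eps.

    Computed over all unordered pairs of the n - m + 1 embedded vectors.
    """
    arr = np.asarray(series, dtype=float)
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    if m < 1:
        raise ValueError("embedding dimension must be >= 1")
    if arr.size - m + 1 < 2:
        raise ValueError("series too short for this embedding dimension")
    return _pair_fraction(_joint_indicators(_indicator_matrix(arr, epsilon), m))


def bds_statistic(series: Sequence[float], epsilon: float, m: int) -> BDSResult:
    """The BDS statistic W_m(eps) with its two-sided normal p-value.

    Uses the BDSL asymptotic variance
        sigma_m^2 = 4 * [ k^m + 2*sum_{j=1}^{m-1} k^(m-j) C^(2j)
                          + (m-1)^2 C^(2m) - m^2 k C^(2m-2) ]
    with C = C_1(eps) and k the triple-closeness fraction, both estimated
    on the full sample; the effect C_m - C_1^m conditions on the first
    m - 1 values (C_1 re-estimated on the last n - m + 1 observations).
    """
    arr = np.asarray(series, dtype=float)
    if m < 2:
        raise ValueError("embedding dimension must be >= 2 for the BDS statistic")
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    n_full = arr.size
    if n_full - m + 1 < 3:
        raise ValueError("series too short for the BDS statistic")
    ind = _indicator_matrix(arr, epsilon)

    c1_full = _pair_fraction(ind)
    if not (0.0 < c1_full < 1.0):
        raise ValueError(
            f"degenerate correlation integral C_1({epsilon:g}) = {c1_full:g}; "
            "BDS statistic undefined for this (epsilon, m) cell"
        )
    # triple-closeness fraction k = P(|x_s-x_t|<=eps and |x_t-x_r|<=eps)
    ind_f = ind.astype(float)
    row = ind_f.sum(axis=1)  # includes the diagonal
    k = float(((row**2).sum() - 3.0 * ind_f.sum() + 2.0 * n_full) / (
        n_full * (n_full - 1) * (n_full - 2)
    ))

    c_m = _pair_fraction(_joint_indicators(ind, m))
    n_m = n_full - m + 1
    c1_trunc = _pair_fraction(ind[m - 1 :, m - 1 :])

    acc = 0.0
    for j in range(1, m):
        acc += (k ** (m - j)) * (c1_full ** (2 * j))
    sigma2 = 4.0 * (
        k**m
        + 2.0 * acc
        + ((m - 1) ** 2) * (c1_full ** (2 * m))
        - (m**2) * k * (c1_full ** (2 * m - 2))
    )
    if sigma2 <= 0:
        raise ValueError("non-positive BDS variance estimate; epsilon unsuitable")
    w = math.sqrt(n_m) * (c_m - c1_trunc**m) / math.sqrt(sigma2)
    return BDSResult(
        epsilon=float(epsilon),
        embedding_dimension=int(m),
        statistic=float(w),
        p_value=float(2.0 * sps.norm.sf(abs(w))),
    )


def bds_test(
    series: Sequence[float],
    epsilon_multipliers: Sequence[float] = (0.5, 1.0, 1.5, 2.0),
    dims: Sequence[int] = (2, 3),
    epsilons: Optional[Sequence[float]] = None,
) -> list[BDSResult]:
    """BDS test over a grid of epsilons and embedding dimensions.

    By default the epsilons are multiples of the sample standard deviation
    of the series actually passed in; explicit ``epsilons`` override the
    multiplier grid.
    """
    arr = np.asarray(series, dtype=float)
    sd = float(np.std(arr, ddof=1))
    if sd == 0.0:
        raise ValueError("zero variance: series is constant")
    if epsilons is None:
        epsilons = [mult * sd for mult in epsilon_multipliers]
    return [bds_statistic(arr, eps, m) for eps in epsilons for m in dims]
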