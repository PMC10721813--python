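"""Forecast-accuracy metrics and model comparison summaries.

RMSE and MAPE are the two holdout criteria:

    RMSE = sqrt( (1/n) * sum (y_t - yhat_t)^2 )          [response units]
    MAPE = (100/n) * sum |(y_t - yhat_t) / y_t|          [percent]

``improvement_summary`` computes percentage improvements of a reference
model over a baseline set, averaged (unweighted) over all
(baseline model, series) pairs — the convention that reproduces the
published headline percentages from the reference accuracy table shipped
with the package.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AccuracyReport",
    "ImprovementSummary",
    "rmse",
    "mape",
    "accuracy_table",
    "improvement_summary",
    "load_reference_accuracy",
]


def _paired(y: Sequence[float], yhat: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape or y.ndim != 1:
        raise ValueError(f"y and yhat must be aligned 1-d arrays (got {y.shape} vs {yhat.shape})")
    if y.size == 0:
        raise ValueError("need at least one observation")
    return y, yhat


def rmse(y: Sequence[float], yhat: Sequence[float]) -> float:
    """Root mean squared error, in the units of the response."""
    y, yhat = _paired(y, yhat)
    return float(np.sqrt(np.mean((y - yhat) ** 2)))


def mape(y: Sequence[float], yhat: Sequence[float]) -> float:
    """Mean absolute percentage error, in percent; undefined if any y = 0."""
    y, yhat = _paired(y, yhat)
    if np.any(y == 0.0):
        raise ValueError("MAPE undefined: actual value of zero in the series")
    return float(100.0 * np.mean(np.abs((y - yhat) / y)))


@dataclass(frozen=True)
class AccuracyReport:
    """Per-(model, series) RMSE and MAPE rows."""

    table: pd.DataFrame  # columns: model, series, rmse, mape

    def __post_init__(self) -> None:
        required = {"model", "series", "rmse", "mape"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"accuracy table must have columns {sorted(required)}")
        if self.table.duplicated(["model", "series"]).any():
            raise ValueError("duplicate (model, series) row in accuracy report")
        if (self.table["rmse"] < 0).any() or (self.table["mape"] < 0).any():
            raise ValueError("negative error metric in accuracy report")

    @property
    def models(self) -> list[str]:
        return list(dict.fromkeys(self.table["model"]))

    @property
    def series(self) -> list[str]:
        return list(dict.fromkeys(self.table["series"]))

    def lookup(self, model: str, series: str) -> tuple[float, float]:
        row = self.table[(self.table["model"] == model) & (self.table["series"] == series)]
        if row.empty:
            raise KeyError(f"no accuracy row for model={model!r}, series={series!r}")
        return float(row["rmse"].iloc[0]), float(row["mape"].iloc[0])

    @staticmethod
    def concat(reports: Iterable["AccuracyReport"]) -> "AccuracyReport":
        return AccuracyReport(pd.concat([r.table for r in reports], ignore_index=True))


@dataclass(frozen=True)
class ImprovementSummary:
    """Percent improvements of a reference model over a baseline set.

    ``per_pair`` has one row per (baseline, series) with columns
    rmse_improvement / mape_improvement (percent, positive iff the
    reference beats that baseline); ``average_*`` are their unweighted
    means over all pairs.
    """

    reference: str
    baselines: tuple[str, ...]
    per_pair: pd.DataFrame
    average_rmse_improvement: float
    average_mape_improvement: float


def accuracy_table(zoo, split=None) -> AccuracyReport:
    """Build the accuracy report for a fitted model zoo on its holdout.

    ``zoo`` is a :class:`hybridts.hybrid_pipeline.ModelZooResult`; the split
    defaults to the one stored in the zoo.  Metrics are computed on the k
    holdout points in original units, and failed models are excluded (they
    remain listed in ``zoo.failures``).
    """
    split = split or zoo.split
    y_test = split.test.y
    rows = []
    for model_name, forecast in zoo.forecasts.items():
        fc = np.asarray(forecast, dtype=float)
        if fc.shape != y_test.shape:
            raise ValueError(
                f"model {model_name!r} forecast does not cover the holdout "
                f"({fc.size} points vs k={y_test.size})"
            )
        rows.append(
            {
                "model": model_name,
                "series": zoo.series_name,
                "rmse": rmse(y_test, fc),
                "mape": mape(y_test, fc),
            }
        )
    return AccuracyReport(pd.DataFrame(rows))


def improvement_summary(
    report: AccuracyReport,
    reference: str,
    baselines: Sequence[str],
) -> ImprovementSummary:
    """Average percent improvement of ``reference`` over each baseline.

    For each (baseline b, series s) and metric M:
        improvement = 100 * (M[b, s] - M[reference, s]) / M[b, s]
    and the summary averages these unweighted over all pairs.
    """
    baselines = tuple(baselines)
    if reference in baselines:
        raise ValueError("reference model must not be in the baseline set")
    if not baselines:
        raise ValueError("baseline set is empty")
    rows = []
    for b in baselines:
        for s in report.series:
            ref_rmse, ref_mape = report.lookup(reference, s)
            base_rmse, base_mape = report.lookup(b, s)
            rows.append(
                {
                    "baseline": b,
                    "series": s,
                    "rmse_improvement": 100.0 * (base_rmse - ref_rmse) / base_rmse,
                    "mape_improvement": 100.0 * (base_mape - ref_mape) / base_mape,
                }
            )
    per_pair = pd.DataFrame(rows)
    return ImprovementSummary(
        reference=reference,
        baselines=baselines,
        per_pair=per_pair,
        average_rmse_improvement=float(per_pair["rmse_improvement"].mean()),
        average_mape_improvement=float(per_pair["mape_improvement"].mean()),
    )


def load_reference_accuracy() -> AccuracyReport:
    """The published 14-model x 3-crop accuracy table shipped as a fixture.

    Used by tests and the ``reproduce-abstract`` command only; never as a
    silent default anywhere in the pipeline.
    """
    with resources.files("hybridts.data").joinpath("reference_accuracy.csv").open() as fh:
        return AccuracyReport(pd.read_csv(fh))
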