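"""Annual time-series data model, CSV I/O, differencing and holdout splitting.

The universal input object is :class:`AnnualDataset`: a response series
(e.g. crop yield in kg/hectare) indexed by consecutive calendar years,
optionally paired with a single exogenous covariate (e.g. area under
irrigation, in percent).  All downstream stages — diagnostics, linear
ARIMA/ARIMAX fitting, nonlinear learners, hybrids — consume this type.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AnnualDataset",
    "HoldoutSplit",
    "InputFormatError",
    "read_dataset",
    "write_dataset",
    "split_holdout",
    "difference",
    "undifference",
]


class InputFormatError(ValueError):
    """Raised when an input table violates the expected CSV contract."""


def _as_float_array(values: Sequence[float], what: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{what} must be one-dimensional")
    if arr.size and not np.all(np.isfinite(arr)):
        bad = int(np.flatnonzero(~np.isfinite(arr))[0])
        raise InputFormatError(f"{what} contains a missing/non-finite value at position {bad}")
    return arr


@dataclass(frozen=True)
class AnnualDataset:
    """A year-indexed response series with an optional exogenous series.

    Invariants enforced at construction: years strictly increasing with
    step 1; no missing values; the exogenous series, when present, is a
    percentage in [0, 100] aligned one-to-one with the response.
    """

    name: str
    years: np.ndarray
    y: np.ndarray
    x: Optional[np.ndarray] = None
    response_name: str = "y"
    exog_name: Optional[str] = None

    def __post_init__(self) -> None:
        years = np.asarray(self.years, dtype=int)
        y = _as_float_array(self.y, "response series")
        if years.ndim != 1 or years.size != y.size:
            raise ValueError("years and response must be aligned 1-d arrays")
        if years.size == 0:
            raise ValueError("dataset must contain at least one observation")
        steps = np.diff(years)
        if steps.size and not np.all(steps == 1):
            gap = int(np.flatnonzero(steps != 1)[0])
            raise InputFormatError(
                f"non-contiguous years: {years[gap]} is followed by {years[gap + 1]}"
            )
        object.__setattr__(self, "years", years)
        object.__setattr__(self, "y", y)
        if self.x is not None:
            x = _as_float_array(self.x, "exogenous series")
            if x.size != y.size:
                raise ValueError("exogenous series must have the same length as the response")
            if x.size and (x.min() < 0.0 or x.max() > 100.0):
                raise InputFormatError("exogenous percentages must lie in [0, 100]")
            object.__setattr__(self, "x", x)

    @property
    def n(self) -> int:
        return int(self.y.size)

    @property
    def has_exog(self) -> bool:
        return self.x is not None

    def slice(self, start: int, stop: int, suffix: str = "") -> "AnnualDataset":
        """Positional sub-series (keeps year alignment and metadata)."""
        return AnnualDataset(
            name=self.name + suffix,
            years=self.years[start:stop],
            y=self.y[start:stop],
            x=None if self.x is None else self.x[start:stop],
            response_name=self.response_name,
            exog_name=self.exog_name,
        )

    def to_frame(self) -> pd.DataFrame:
        data = {"year": self.years, self.response_name: self.y}
        if self.x is not None:
            data[self.exog_name or "x"] = self.x
        return pd.DataFrame(data)


@dataclass(frozen=True)
class HoldoutSplit:
    """Chronological train/test partition; test is the final ``k`` years."""

    train: AnnualDataset
    test: AnnualDataset
    k: int = field(default=7)

    def __post_init__(self) -> None:
        if self.test.n != self.k:
            raise ValueError("test length must equal k")
        if self.test.years[0] != self.train.years[-1] + 1:
            raise ValueError("train and test must be chronologically contiguous")


def read_dataset(
    path: str | Path,
    response_column: str,
    exog_column: Optional[str] = None,
    name: Optional[str] = None,
) -> AnnualDataset:
    """Read and validate an annual dataset from a header CSV.

    The file must contain a ``year`` column plus the named value columns.
    Rows are sorted by year before validation, so on-disk order is
    irrelevant.  Non-numeric cells and year gaps raise
    :class:`InputFormatError` naming the offending row.
    """
    path = Path(path)
    df = pd.read_csv(path)
    for col in ["year", response_column] + ([exog_column] if exog_column else []):
        if col not in df.columns:
            raise InputFormatError(f"missing column {col!r} in {path.name}")
    df = df.sort_values("year").reset_index(drop=True)
    for col in ["year", response_column] + ([exog_column] if exog_column else []):
        coerced = pd.to_numeric(df[col], errors="coerce")
        if coerced.isna().any():
            row = int(coerced.isna().idxmax())
            raise InputFormatError(
                f"non-numeric or missing value in column {col!r} at row {row} "
                f"(year {df['year'].iloc[row]!r})"
            )
        df[col] = coerced
    return AnnualDataset(
        name=name or path.stem,
        years=df["year"].to_numpy(dtype=int),
        y=df[response_column].to_numpy(dtype=float),
        x=df[exog_column].to_numpy(dtype=float) if exog_column else None,
        response_name=response_column,
        exog_name=exog_column,
    )


def write_dataset(ds: AnnualDataset, path: str | Path) -> None:
    """Write the dataset back in the same CSV dialect ``read_dataset`` accepts."""
    ds.to_frame().to_csv(path, index=False)


def split_holdout(
    ds: AnnualDataset,
    k: int = 7,
    allow_empty_test: bool = False,
    allow_tiny_train: bool = False,
) -> HoldoutSplit:
    """Chronological split retaining the last ``k`` observations for testing.

    ``k=0`` is rejected unless ``allow_empty_test`` (degenerate full-train
    split); a training prefix shorter than 10 points is rejected unless
    ``allow_tiny_train``.
    """
    if k < 0 or k >= ds.n:
        raise ValueError(f"holdout length k={k} must satisfy 0 <= k < n={ds.n}")
    if k == 0 and not allow_empty_test:
        raise ValueError("k=0 produces an empty test set; pass allow_empty_test=True")
    if ds.n - k < 10 and not allow_tiny_train:
        raise ValueError(
            f"training prefix of length {ds.n - k} is very short; pass allow_tiny_train=True"
        )
    if k == 0:
        # degenerate: empty-test HoldoutSplit cannot satisfy contiguity; represent
        # with k formally 0 and an empty suffix dataset is invalid, so refuse.
        raise ValueError("degenerate k=0 split is not representable; use the dataset directly")
    return HoldoutSplit(
        train=ds.slice(0, ds.n - k),
        test=ds.slice(ds.n - k, ds.n),
        k=k,
    )


def difference(series: Sequence[float], d: int) -> np.ndarray:
    """Apply the differencing operator (1 - B)^d; output length n - d."""
    arr = np.asarray(series, dtype=float)
    if d < 0:
        raise ValueError("d must be non-negative")
    if d >= arr.size:
        raise ValueError(f"cannot take d={d} differences of a length-{arr.size} series")
    return np.diff(arr, n=d) if d > 0 else arr.copy()


def undifference(diffs: Sequence[float], d: int, anchors: Sequence[float]) -> np.ndarray:
    """Invert ``difference``: reconstruct the continuation of the original series.

    ``anchors`` are the last ``d`` values of the *original* (undifferenced)
    series immediately preceding the block that ``diffs`` continues.  The
    round-trip ``difference(concat(anchors, out), d) == diffs`` is exact.
    """
    z = np.asarray(diffs, dtype=float)
    a = np.asarray(anchors, dtype=float)
    if d < 0:
        raise ValueError("d must be non-negative")
    if a.size != d:
        raise ValueError(f"expected {d} anchor value(s), got {a.size}")
    if d == 0:
        return z.copy()
    if z.size == 0:
        return np.array([], dtype=float)
    # reduce the d initial level values to initial conditions at every
    # differencing depth, then integrate back up one level at a time
    out = z
    for level in range(d, 0, -1):
        last = np.diff(a, n=level - 1)[-1]
        out = last + np.cumsum(out)
    return out
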