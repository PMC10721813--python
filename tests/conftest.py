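"""Shared fixtures: synthetic datasets and warning hygiene.

All data used by the suite is generated programmatically at test time
from seeded configurations; nothing is read from disk except the
packaged reference accuracy table.
"""

import warnings

import numpy as np
import pytest

from hybridts.series_io import AnnualDataset
from hybridts.synthetic_data import default_crop_profiles, generate


@pytest.fixture(autouse=True)
def _quiet_statsmodels():
    # state-space fits on short annual series legitimately warn about
    # convergence and starting values; tests assert on results instead
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", module="statsmodels")
        warnings.filterwarnings("ignore", message=".*Maximum Likelihood.*")
        yield


@pytest.fixture(scope="session")
def wheat_like():
    """One fixed draw of the wheat-like profile (n=70, seed 0)."""
    return generate(default_crop_profiles()["wheat-like"])


@pytest.fixture(scope="session")
def wheat_ds(wheat_like):
    return wheat_like.dataset


def make_dataset(y, x=None, start_year=1900, name="test"):
    y = np.asarray(y, dtype=float)
    return AnnualDataset(
        name=name, years=start_year + np.arange(y.size), y=y,
        x=None if x is None else np.asarray(x, dtype=float),
    )
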