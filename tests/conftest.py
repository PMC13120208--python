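import numpy as np
import pandas as pd
import pytest

from nanorisk import BinnedConcentrationSeries, MATERIALS, SizeBinGrid


def make_series(values, grid=None, kind="emission"):
    """Build a small session from a (timestamps x bins) value matrix."""
    values = np.atleast_2d(np.asarray(values, dtype=float))
    if grid is None:
        n_bins = values.shape[1]
        edges = np.geomspace(10.0, 420.0, n_bins + 1)
        grid = SizeBinGrid("custom", edges)
    ts = pd.date_range("2025-01-01", periods=values.shape[0], freq="min")
    return BinnedConcentrationSeries(grid, ts, values, session_kind=kind)


@pytest.fixture
def silver():
    return MATERIALS["silver"]


@pytest.fixture
def gold():
    return MATERIALS["gold"]
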