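"""Shared fixtures: the published silica-monitoring reference table.

``silica_reference_table.csv`` holds the published per-subgroup charting
statistics, control limits and signal flags for the silica-in-iron-ore
monitoring illustration (m = 520 reference values, 78 test subgroups of
size n = 5; HWMA/DHWMA with lambda = 0.5, HHWMA with lambda1 = 0.75,
lambda2 = 0.5).  The raw process measurements are not public; the rank
sums are recovered from the HWMA column by inverting the smoothing
recursion (W_t = (H_t - (1-lambda) Wbar_{t-1}) / lambda, snapped to the
half-integer grid that midranked rank sums live on).
"""

from pathlib import Path

import numpy as np
import pandas as pd
import pytest

DATA = Path(__file__).parent / "data"

MU_W = 1315.0  # n(m+n+1)/2 for m=520, n=5
LAMBDA = 0.5


@pytest.fixture(scope="session")
def silica_table() -> pd.DataFrame:
    df = pd.read_csv(DATA / "silica_reference_table.csv")
    assert len(df) == 78
    return df


@pytest.fixture(scope="session")
def silica_w(silica_table) -> np.ndarray:
    """Rank sums recovered from the published HWMA statistics."""
    w = []
    csum = 0.0
    for t, h in enumerate(silica_table["hwma_stat"], start=1):
        wbar = MU_W if t == 1 else csum / (t - 1)
        raw = (h - (1 - LAMBDA) * wbar) / LAMBDA
        w.append(round(raw * 2) / 2)
        csum += w[-1]
    return np.array(w)
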