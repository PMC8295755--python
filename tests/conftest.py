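"""Shared fixtures: tiny hand-checkable datasets and simulated collections."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from droughtgen.response import RESPONSE_COLUMNS, ResponseTable
from droughtgen.ringio import RingWidthSeries, TreeCollection

settings.register_profile(
    "suite", deadline=None, derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow, HealthCheck.function_scoped_fixture],
)
settings.load_profile("suite")


def make_response_table(prov_values: dict, events: list[int], trait: str = "Res",
                        site_id: str = "S") -> ResponseTable:
    """Build a ResponseTable from provenance -> list of per-tree event profiles.

    ``prov_values[pid]`` is a list of trees, each a list of values aligned
    with ``events``.
    """
    rows = []
    for pid, trees in prov_values.items():
        for t, profile in enumerate(trees):
            tid = f"{pid}_T{t + 1}"
            for ev, val in zip(events, profile):
                res = val if trait == "Res" else math.nan
                rec = val if trait == "Rec" else math.nan
                rows.append((site_id, pid, tid, int(ev),
                             math.nan, math.nan, math.nan, res, rec, ()))
    return ResponseTable(pd.DataFrame(rows, columns=RESPONSE_COLUMNS), sorted(events))


@pytest.fixture
def flat_series() -> RingWidthSeries:
    return RingWidthSeries("T1", "P1", "S", 1980, np.full(30, 1.7))


@pytest.fixture
def step_series() -> RingWidthSeries:
    """2.0 mm everywhere except 1.0 mm in 2000 (the drought year)."""
    widths = np.full(30, 2.0)
    widths[2000 - 1980] = 1.0
    return RingWidthSeries("T1", "P1", "S", 1980, widths)


@pytest.fixture
def small_collection(flat_series) -> TreeCollection:
    widths = np.full(30, 2.0)
    widths[2000 - 1980] = 1.0
    other = RingWidthSeries("T2", "P2", "S", 1980, widths)
    return TreeCollection.from_series([flat_series, other], site_id="S")
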