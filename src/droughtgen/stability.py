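"""Phenotypic stability of provenances across drought events.

Finlay-Wilkinson joint regression: each provenance's event mean is regressed
on the environmental index (the unweighted mean of provenance means per
event).  A slope b near 1 is average stability, b > 1 marks provenances
whose response swings more than the trial mean (unstable), b < 1 less
(stable).  Because the index is the mean of the regressands, the slopes of a
complete provenance-by-event table average to exactly 1 — a useful internal
check.  Rank stability between event pairs is summarised by Spearman
correlations of provenance means.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .response import ResponseTable

log = logging.getLogger(__name__)

__all__ = [
    "StabilityResult",
    "provenance_event_means",
    "environmental_index",
    "fw_regression",
    "stability_summary",
    "rank_stability",
]


@dataclass
class StabilityResult:
    """Finlay-Wilkinson slopes per provenance plus species-level summaries."""

    trait: str
    slopes: pd.DataFrame  # provenance_id, b, intercept, n_events, flagged
    b_dev: float
    b_ist: float
    ist_definition: str = "deviation"


def provenance_event_means(table: ResponseTable, trait: str) -> pd.DataFrame:
    """Provenance x event matrix of mean responses over defined tree records."""
    d = table.defined(trait)
    return d.pivot_table(index="provenance_id", columns="event_year", values=trait, aggfunc="mean")


def environmental_index(table: ResponseTable, trait: str) -> pd.Series:
    """Per-event baseline: the unweighted mean over provenance means.

    Each provenance first contributes the mean over its trees' defined
    values, so unbalanced tree counts do not tilt the index.
    """
    means = provenance_event_means(table, trait)
    empty = [int(ev) for ev in table.events if ev not in means.columns or means[ev].isna().all()]
    if empty:
        raise ValueError(f"no defined {trait} data for event(s) {empty}")
    return means.mean(axis=0, skipna=True)


def fw_regression(table: ResponseTable, trait: str) -> pd.DataFrame:
    """Per-provenance OLS slope and intercept on the environmental index."""
    means = provenance_event_means(table, trait)
    index = environmental_index(table, trait)
    if float(np.var(index.to_numpy())) == 0:
        raise ValueError("environmental index has zero variance; slopes undefined")
    rows = []
    for pid, row in means.iterrows():
        joint = pd.concat([row.rename("m"), index.rename("x")], axis=1).dropna()
        n = len(joint)
        flagged = n < len(index)
        if n < 2:
            rows.append((pid, math.nan, math.nan, n, True))
            continue
        if n < 4:
            log.warning("provenance %s: Finlay-Wilkinson slope from only %d events", pid, n)
        b, intercept = np.polyfit(joint["x"].to_numpy(), joint["m"].to_numpy(), 1)
        rows.append((pid, float(b), float(intercept), n, flagged))
    return pd.DataFrame(rows, columns=["provenance_id", "b", "intercept", "n_events", "flagged"])


def stability_summary(slopes, definition: str = "deviation") -> tuple[float, float]:
    """Species summaries (b_dev, b_ist) from per-provenance slopes.

    ``b_dev`` is the mean absolute deviation of the slopes from 1 over all
    provenances.  ``b_ist`` summarises the unstable provenances (b > 1):
    with ``definition="deviation"`` it is the mean of |1 - b| over them;
    with ``definition="mean_b"`` the mean of b itself.  With no unstable
    provenance b_ist is NaN.
    """
    b = np.asarray(pd.Series(slopes).dropna(), dtype=float)
    if b.size == 0:
        raise ValueError("no slopes given")
    b_dev = float(np.mean(np.abs(1.0 - b)))
    unstable = b[b > 1]
    if unstable.size == 0:
        return b_dev, math.nan
    if definition == "deviation":
        b_ist = float(np.mean(np.abs(1.0 - unstable)))
    elif definition == "mean_b":
        b_ist = float(np.mean(unstable))
    else:
        raise ValueError(f"unknown b_ist definition {definition!r}")
    return b_dev, b_ist


def finlay_wilkinson(table: ResponseTable, trait: str, ist_definition: str = "deviation") -> StabilityResult:
    """Full stability analysis for one trait."""
    slopes = fw_regression(table, trait)
    b_dev, b_ist = stability_summary(slopes["b"], definition=ist_definition)
    return StabilityResult(trait, slopes, b_dev, b_ist, ist_definition)


def rank_stability(table: ResponseTable, trait: str) -> pd.DataFrame:
    """Pairwise Spearman rank correlations of provenance means between events.

    Ties get average ranks (scipy convention).  Pairs with fewer than three
    provenances jointly defined are flagged low-power.
    """
    means = provenance_event_means(table, trait)
    rows = []
    for ev_a, ev_b in itertools.combinations(sorted(means.columns), 2):
        joint = means[[ev_a, ev_b]].dropna()
        n = len(joint)
        if n < 2:
            rows.append((int(ev_a), int(ev_b), math.nan, n, True))
            continue
        rs = float(spearmanr(joint[ev_a], joint[ev_b]).statistic)
        rows.append((int(ev_a), int(ev_b), rs, n, n < 3))
    return pd.DataFrame(rows, columns=["event_a", "event_b", "Rs", "n_provenances", "low_power"])


__all__.append("finlay_wilkinson")
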