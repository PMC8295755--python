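"""Per-tree drought-response indices (Lloret resistance and recovery).

Resistance is the ratio of the drought-year ring width to the mean width of
a 9-year window centred on the drought year; recovery is the ratio of the
mean width of the two post-drought years to the drought-year width.  Both
are computed on raw, untransformed widths: within the short event window the
age-related growth trend is negligible, and dimensional transforms (e.g.
basal-area increment) would distort the trait variances used downstream.

Consecutive events are allowed to have overlapping windows; every
(tree, event) record is an independent computation.  Records whose
post-drought window contains another configured event are flagged
``biased_recovery`` but still computed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .ringio import RingWidthSeries, TreeCollection

__all__ = [
    "LloretResult",
    "DroughtResponseRecord",
    "ResponseTable",
    "resistance",
    "recovery",
    "compute_response_table",
]

RESPONSE_COLUMNS = [
    "site_id", "provenance_id", "tree_id", "event_year",
    "I_dr", "I_9yr", "I_postdr", "Res", "Rec", "flags",
]


@dataclass(frozen=True)
class LloretResult:
    """One index value with its parts; NaN value carries a reason."""

    value: float
    i_dr: float = math.nan
    i_ref: float = math.nan  # window mean (Res) or post-drought mean (Rec)
    reason: str | None = None
    degenerate: bool = False

    @property
    def defined(self) -> bool:
        return np.isfinite(self.value)


@dataclass(frozen=True)
class DroughtResponseRecord:
    tree_id: str
    provenance_id: str
    site_id: str
    event_year: int
    i_dr: float
    i_9yr: float
    i_postdr: float
    res: float
    rec: float
    flags: tuple[str, ...] = ()


@dataclass
class ResponseTable:
    """Tidy per-(tree, event) response records plus a completeness report."""

    df: pd.DataFrame
    events: list[int]
    completeness: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = set(RESPONSE_COLUMNS) - set(self.df.columns)
        if missing:
            raise ValueError(f"response table missing columns: {sorted(missing)}")
        dup = self.df.duplicated(subset=["site_id", "tree_id", "event_year"])
        if dup.any():
            raise ValueError("duplicate (tree, event) records")

    def defined(self, trait: str) -> pd.DataFrame:
        """Records where ``trait`` ('Res' or 'Rec') is defined."""
        return self.df[np.isfinite(self.df[trait])]

    def to_csv(self, path_or_buf) -> None:
        out = self.df.copy()
        out["flags"] = out["flags"].map(lambda f: ";".join(f) if f else "")
        out.to_csv(path_or_buf, index=False)

    @classmethod
    def from_csv(cls, path_or_buf) -> "ResponseTable":
        df = pd.read_csv(path_or_buf)
        df["flags"] = df["flags"].fillna("").map(lambda s: tuple(s.split(";")) if s else ())
        events = sorted(df["event_year"].unique().tolist())
        return cls(df, events)


def _window_widths(series: RingWidthSeries, years: Sequence[int]) -> np.ndarray | None:
    vals = np.array([series.width_at(y) for y in years])
    if not np.all(np.isfinite(vals)):
        return None
    return vals


def resistance(
    series: RingWidthSeries,
    event_year: int,
    window: int = 9,
    include_event: bool = True,
) -> LloretResult:
    """Resistance Res = I_dr / I_window for a centred odd-length window.

    The window mean includes the drought year itself by default (the centred
    window places the event in the middle year); ``include_event=False``
    averages only the surrounding years.
    """
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be an odd integer >= 3")
    half = window // 2
    years = list(range(event_year - half, event_year + half + 1))
    vals = _window_widths(series, years)
    if vals is None:
        return LloretResult(math.nan, reason="incomplete window")
    i_dr = float(vals[half])
    ref_vals = vals if include_event else np.delete(vals, half)
    i_ref = float(ref_vals.mean())
    if i_ref == 0:
        return LloretResult(math.nan, i_dr=i_dr, i_ref=i_ref, reason="zero window mean", degenerate=True)
    return LloretResult(i_dr / i_ref, i_dr=i_dr, i_ref=i_ref)


def recovery(series: RingWidthSeries, event_year: int, post_window: int = 2) -> LloretResult:
    """Recovery Rec = I_postdr / I_dr over the ``post_window`` years after the event."""
    if post_window < 1:
        raise ValueError("post_window must be >= 1")
    vals = _window_widths(series, [event_year])
    if vals is None:
        return LloretResult(math.nan, reason="incomplete window")
    i_dr = float(vals[0])
    post = _window_widths(series, list(range(event_year + 1, event_year + post_window + 1)))
    if post is None:
        return LloretResult(math.nan, i_dr=i_dr, reason="incomplete post window")
    i_post = float(post.mean())
    if i_dr == 0:
        return LloretResult(math.nan, i_dr=i_dr, i_ref=i_post, reason="zero drought-year width",
                            degenerate=True)
    return LloretResult(i_post / i_dr, i_dr=i_dr, i_ref=i_post)


def compute_response_table(
    collection: TreeCollection,
    events: Sequence[int] | Mapping[str, Sequence[int]],
    window: int = 9,
    post_window: int = 2,
    include_event: bool = True,
) -> ResponseTable:
    """One response record attempted per tree x event.

    ``events`` is either a flat list of event years or a mapping
    ``site_id -> years`` (species-specific event choices, e.g. a site whose
    drought hit one year earlier than the others).  Missingness reasons are
    tallied in the returned table's ``completeness`` dict.
    """
    if isinstance(events, Mapping):
        site_events = list(events.get(collection.site_id, []))
    else:
        site_events = list(events)
    if not site_events:
        raise ValueError(f"no event years configured for site {collection.site_id!r}")
    rows = []
    completeness: dict[str, int] = {"complete": 0}
    for tree_id in sorted(collection.trees):
        s = collection.trees[tree_id]
        for ev in site_events:
            res = resistance(s, ev, window=window, include_event=include_event)
            rec = recovery(s, ev, post_window=post_window)
            flags: list[str] = []
            if res.degenerate or rec.degenerate:
                flags.append("degenerate")
            if any(o != ev and ev < o <= ev + post_window for o in site_events):
                flags.append("biased_recovery")
            for r in (res, rec):
                if r.reason:
                    completeness[r.reason] = completeness.get(r.reason, 0) + 1
            if res.defined and rec.defined:
                completeness["complete"] += 1
            rows.append(
                (s.site_id, s.provenance_id, s.tree_id, int(ev),
                 res.i_dr, res.i_ref, rec.i_ref, res.value, rec.value, tuple(flags))
            )
    df = pd.DataFrame(rows, columns=RESPONSE_COLUMNS)
    return ResponseTable(df, sorted(set(site_events)), completeness)
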