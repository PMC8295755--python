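"""Reading, validation and aggregation of increment-core ring-width data.

Increment cores arrive either in the Tucson ("rwl") decadal exchange format
used throughout dendrochronology, or as long-form CSV.  Two cores per tree
are averaged into a single-tree series; site-level chronologies (detrended,
dimensionless ring-width indices averaged over trees) are built for
visualising common growth signals such as drought years.

Widths are always held in millimetres.  Missing rings measured as zero are
kept as ``0.0`` (biologically meaningful — a locally absent ring); years a
core simply does not cover are ``NaN``.
"""

from __future__ import annotations

import io
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

log = logging.getLogger(__name__)

__all__ = [
    "CoreSeries",
    "RingWidthSeries",
    "TreeCollection",
    "Chronology",
    "RwlParseError",
    "read_rwl",
    "write_rwl",
    "read_long_csv",
    "write_long_csv",
    "average_cores",
    "collection_from_cores",
    "build_chronology",
    "tukey_biweight_mean",
]

Dialect = Literal["0.01mm", "0.001mm", "auto"]

# Tucson terminator tokens: 999 marks end-of-series in the 0.01 mm
# convention, -9999 in the 0.001 mm convention.
_TERMINATORS = {"999": "0.01mm", "-9999": "0.001mm"}
_SCALE = {"0.01mm": 0.01, "0.001mm": 0.001}


class RwlParseError(ValueError):
    """Raised when a Tucson-format stream cannot be parsed."""


def _validate_widths(widths: np.ndarray) -> None:
    if widths.size < 1:
        raise ValueError("a ring-width series needs at least one ring")
    finite = widths[np.isfinite(widths)]
    if np.any(finite < 0):
        raise ValueError("ring widths must be nonnegative")


@dataclass(frozen=True)
class CoreSeries:
    """One increment core: annual ring widths from ``first_year`` onward."""

    core_id: str
    tree_id: str
    provenance_id: str
    site_id: str
    first_year: int
    widths: np.ndarray  # mm/year, NaN = not covered

    def __post_init__(self) -> None:
        object.__setattr__(self, "widths", np.asarray(self.widths, dtype=float))
        _validate_widths(self.widths)

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.first_year, self.first_year + len(self.widths))

    @property
    def last_year(self) -> int:
        return self.first_year + len(self.widths) - 1


@dataclass(frozen=True)
class RingWidthSeries:
    """Single-tree annual ring-width series (cores already averaged)."""

    tree_id: str
    provenance_id: str
    site_id: str
    first_year: int
    widths: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "widths", np.asarray(self.widths, dtype=float))
        _validate_widths(self.widths)

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.first_year, self.first_year + len(self.widths))

    @property
    def last_year(self) -> int:
        return self.first_year + len(self.widths) - 1

    def width_at(self, year: int) -> float:
        """Width in ``year`` (mm); NaN outside the covered span."""
        if year < self.first_year or year > self.last_year:
            return math.nan
        return float(self.widths[year - self.first_year])


@dataclass
class TreeCollection:
    """All single-tree series of one trial site, indexed by tree id."""

    site_id: str
    trees: dict[str, RingWidthSeries] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for tid, s in self.trees.items():
            if s.tree_id != tid:
                raise ValueError(f"key {tid!r} does not match series tree_id {s.tree_id!r}")

    @classmethod
    def from_series(cls, series: Iterable[RingWidthSeries], site_id: str | None = None) -> "TreeCollection":
        series = list(series)
        if not series:
            raise ValueError("no series given")
        sid = site_id if site_id is not None else series[0].site_id
        trees: dict[str, RingWidthSeries] = {}
        for s in series:
            if s.tree_id in trees:
                raise ValueError(f"duplicate tree_id {s.tree_id!r}")
            trees[s.tree_id] = s
        return cls(site_id=sid, trees=trees)

    @property
    def provenance_index(self) -> dict[str, list[str]]:
        idx: dict[str, list[str]] = {}
        for tid, s in self.trees.items():
            idx.setdefault(s.provenance_id, []).append(tid)
        return idx

    def __len__(self) -> int:
        return len(self.trees)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.trees.values():
            for year, w in zip(s.years, s.widths):
                if np.isfinite(w):
                    rows.append((s.site_id, s.provenance_id, s.tree_id, int(year), float(w)))
        return pd.DataFrame(rows, columns=["site_id", "provenance_id", "tree_id", "year", "width_mm"])

    @classmethod
    def from_frame(cls, df: pd.DataFrame, site_id: str | None = None) -> "TreeCollection":
        series = []
        for (sid, pid, tid), grp in df.groupby(["site_id", "provenance_id", "tree_id"], sort=True):
            grp = grp.sort_values("year")
            years = grp["year"].to_numpy(dtype=int)
            first, last = int(years[0]), int(years[-1])
            widths = np.full(last - first + 1, np.nan)
            widths[years - first] = grp["width_mm"].to_numpy(dtype=float)
            series.append(RingWidthSeries(str(tid), str(pid), str(sid), first, widths))
        return cls.from_series(series, site_id=site_id)


@dataclass(frozen=True)
class Chronology:
    """Site chronology: dimensionless ring-width index with sample depth."""

    site_id: str
    first_year: int
    index: np.ndarray        # dimensionless, NaN where no tree contributes
    sample_depth: np.ndarray  # trees contributing per year
    detrend: str = "series_mean"
    robust_mean: bool = False

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.first_year, self.first_year + len(self.index))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"year": self.years, "index": self.index, "sample_depth": self.sample_depth}
        )


# ---------------------------------------------------------------------------
# Tucson (rwl) reading and writing
# ---------------------------------------------------------------------------

def read_rwl(
    source,
    dialect: Dialect = "auto",
    metadata: Mapping[str, tuple[str, str, str]] | None = None,
) -> list[CoreSeries]:
    """Parse a Tucson/rwl stream into :class:`CoreSeries`.

    Parameters
    ----------
    source:
        Text stream or string containing decadal Tucson rows: an 8-character
        series id, a year, then up to 10 integer values; the series ends at
        the terminator token (``999`` for the 0.01 mm dialect, ``-9999`` for
        the 0.001 mm dialect).
    dialect:
        ``"auto"`` infers units from the terminator of each series.
    metadata:
        Optional ``core_id -> (tree_id, provenance_id, site_id)`` map; cores
        absent from the map get their ``core_id`` as tree id and empty
        provenance/site labels.
    """
    if isinstance(source, str):
        source = io.StringIO(source)
    cores: list[CoreSeries] = []
    cur_id: str | None = None
    cur_first: int | None = None
    cur_vals: list[float] = []
    cur_dialect: str | None = None

    def flush() -> None:
        nonlocal cur_id, cur_first, cur_vals, cur_dialect
        if cur_id is None:
            return
        d = cur_dialect or (dialect if dialect != "auto" else None)
        if d is None:
            raise RwlParseError(f"series {cur_id!r} has no terminator and dialect is 'auto'")
        widths = np.asarray(cur_vals, dtype=float) * _SCALE[d]
        tid, pid, sid = (metadata or {}).get(cur_id, (cur_id, "", ""))
        cores.append(CoreSeries(cur_id, tid, pid, sid, cur_first, widths))
        cur_id, cur_first, cur_vals, cur_dialect = None, None, [], None

    for lineno, raw in enumerate(source, start=1):
        if not raw.strip():
            continue
        sid = raw[:8].strip()
        rest = raw[8:].split()
        if not sid or not rest:
            raise RwlParseError(f"line {lineno}: missing series id or decade header")
        try:
            year = int(rest[0])
        except ValueError as exc:
            raise RwlParseError(f"line {lineno}: malformed decade header {rest[0]!r}") from exc
        if sid != cur_id:
            flush()
            cur_id, cur_first = sid, year
        else:
            expected = cur_first + len(cur_vals)
            if year != expected:
                raise ValueError(
                    f"line {lineno}: non-monotone years in core {sid!r}: "
                    f"header {year}, expected {expected}"
                )
        for tok in rest[1:]:
            if tok in _TERMINATORS:
                term_dialect = _TERMINATORS[tok]
                cur_dialect = dialect if dialect != "auto" else term_dialect
                flush()
                break
            try:
                cur_vals.append(float(int(tok)))
            except ValueError as exc:
                raise RwlParseError(f"line {lineno}: malformed value token {tok!r}") from exc
    flush()
    return cores


def write_rwl(cores: Sequence[CoreSeries], dialect: Literal["0.01mm", "0.001mm"] = "0.01mm") -> str:
    """Serialize cores to Tucson text in the requested unit dialect."""
    scale = _SCALE[dialect]
    terminator = {v: k for k, v in _TERMINATORS.items()}[dialect]
    out: list[str] = []
    for core in cores:
        vals = [int(round(w / scale)) for w in core.widths]
        tokens = [str(v) for v in vals] + [terminator]
        year = core.first_year
        pos = 0
        while pos < len(tokens):
            # rows hold the remainder of the current decade (10-year blocks)
            n_in_row = 10 - (year % 10) if pos else 10 - (core.first_year % 10)
            row_year = core.first_year if pos == 0 else year
            chunk = tokens[pos : pos + n_in_row]
            out.append(f"{core.core_id:<8}{row_year:>4}" + "".join(f"{t:>6}" for t in chunk))
            pos += len(chunk)
            year = row_year + len(chunk)
    return "\n".join(out) + "\n"


# ---------------------------------------------------------------------------
# Long-form CSV
# ---------------------------------------------------------------------------

_LONG_COLS = ["site_id", "provenance_id", "tree_id", "core_id", "year", "width_mm"]


def read_long_csv(path_or_buf) -> list[CoreSeries]:
    """Read long-form core data (site_id, provenance_id, tree_id, core_id, year, width_mm)."""
    df = pd.read_csv(path_or_buf)
    missing = set(_LONG_COLS) - set(df.columns)
    if missing:
        raise ValueError(f"long-form CSV missing columns: {sorted(missing)}")
    cores = []
    for (sid, pid, tid, cid), grp in df.groupby(
        ["site_id", "provenance_id", "tree_id", "core_id"], sort=True
    ):
        grp = grp.sort_values("year")
        years = grp["year"].to_numpy(dtype=int)
        first, last = int(years[0]), int(years[-1])
        widths = np.full(last - first + 1, np.nan)
        widths[years - first] = grp["width_mm"].to_numpy(dtype=float)
        cores.append(CoreSeries(str(cid), str(tid), str(pid), str(sid), first, widths))
    return cores


def write_long_csv(cores: Sequence[CoreSeries], path_or_buf) -> None:
    rows = []
    for c in cores:
        for year, w in zip(c.years, c.widths):
            if np.isfinite(w):
                rows.append((c.site_id, c.provenance_id, c.tree_id, c.core_id, int(year), float(w)))
    pd.DataFrame(rows, columns=_LONG_COLS).to_csv(path_or_buf, index=False)


# ---------------------------------------------------------------------------
# Aggregation
# ---------------------------------------------------------------------------

def average_cores(cores: Sequence[CoreSeries]) -> RingWidthSeries:
    """Average the cores of one tree into a single-tree series.

    Per year, the arithmetic mean over cores with a measured value; years no
    core covers stay NaN.  All cores must agree on tree, provenance and site.
    """
    if not cores:
        raise ValueError("average_cores needs at least one core")
    tree_ids = {c.tree_id for c in cores}
    if len(tree_ids) != 1:
        raise ValueError(f"cores belong to different trees: {sorted(tree_ids)}")
    for attr in ("provenance_id", "site_id"):
        labels = {getattr(c, attr) for c in cores}
        if len(labels) != 1:
            raise ValueError(f"conflicting {attr} labels for tree {cores[0].tree_id!r}: {sorted(labels)}")
    first = min(c.first_year for c in cores)
    last = max(c.last_year for c in cores)
    n = last - first + 1
    total = np.zeros(n)
    count = np.zeros(n)
    for c in cores:
        sl = slice(c.first_year - first, c.first_year - first + len(c.widths))
        mask = np.isfinite(c.widths)
        total[sl][mask] += c.widths[mask]
        count[sl][mask] += 1
    widths = np.where(count > 0, total / np.maximum(count, 1), np.nan)
    c0 = cores[0]
    return RingWidthSeries(c0.tree_id, c0.provenance_id, c0.site_id, first, widths)


def collection_from_cores(cores: Sequence[CoreSeries], site_id: str | None = None) -> TreeCollection:
    """Group cores by tree, average, and assemble a :class:`TreeCollection`."""
    by_tree: dict[str, list[CoreSeries]] = {}
    for c in cores:
        by_tree.setdefault(c.tree_id, []).append(c)
    series = [average_cores(cs) for cs in by_tree.values()]
    return TreeCollection.from_series(series, site_id=site_id)


# ---------------------------------------------------------------------------
# Chronology building
# ---------------------------------------------------------------------------

def tukey_biweight_mean(x: np.ndarray, c: float = 9.0) -> float:
    """One-step Tukey biweight robust mean (median/MAD scaled)."""
    x = np.asarray(x, dtype=float)
    x = x[np.isfinite(x)]
    if x.size == 0:
        return math.nan
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    if mad <= 0:
        return float(med)
    u = (x - med) / (c * mad)
    w = np.where(np.abs(u) < 1, (1 - u**2) ** 2, 0.0)
    if w.sum() == 0:
        return float(med)
    return float(np.sum(w * x) / w.sum())


def _neg_exp(t, a, b, k):
    return a * np.exp(-b * t) + k


def _fit_trend(widths: np.ndarray, method: str) -> np.ndarray:
    """Fitted deterministic growth trend for one series (NaN-free input)."""
    t = np.arange(len(widths), dtype=float)
    if method == "none":
        return np.ones_like(widths)
    if method == "series_mean":
        return np.full_like(widths, widths.mean())
    if method == "neg_exp_or_linear":
        # modified negative exponential, falling back to a straight line,
        # falling back to the series mean — the community cascade
        try:
            span = widths.max() - widths.min()
            p0 = (max(span, 1e-3), 0.05, max(widths.min(), 1e-3))
            popt, _ = curve_fit(
                _neg_exp, t, widths, p0=p0,
                bounds=([0.0, 1e-6, 0.0], [np.inf, 10.0, np.inf]), maxfev=2000,
            )
            fit = _neg_exp(t, *popt)
            if np.all(fit > 0):
                return fit
        except Exception:  # noqa: BLE001 - any fit failure cascades
            pass
        slope, intercept = np.polyfit(t, widths, 1)
        fit = slope * t + intercept
        if slope < 0 and np.all(fit > 0):
            log.warning("negative-exponential fit failed; using linear trend")
            return fit
        log.warning("trend fit failed; falling back to series-mean detrending")
        return np.full_like(widths, widths.mean())
    raise ValueError(f"unknown detrend method {method!r}")


def build_chronology(
    collection: TreeCollection,
    detrend: Literal["neg_exp_or_linear", "series_mean", "none"] = "neg_exp_or_linear",
    robust_mean: bool = True,
) -> Chronology:
    """Detrend every tree to a dimensionless index and average per year.

    Each tree series is divided by its fitted deterministic age trend (or its
    own mean); the per-year average over trees uses the Tukey biweight robust
    mean when ``robust_mean`` is set, the arithmetic mean otherwise.
    """
    if len(collection) < 1:
        raise ValueError("chronology needs at least one tree series")
    first = min(s.first_year for s in collection.trees.values())
    last = max(s.last_year for s in collection.trees.values())
    n = last - first + 1
    indices = np.full((len(collection), n), np.nan)
    for i, s in enumerate(collection.trees.values()):
        mask = np.isfinite(s.widths)
        if mask.sum() < 2:
            continue
        vals = s.widths[mask]
        trend = _fit_trend(vals, detrend)
        idx = np.full(len(s.widths), np.nan)
        idx[mask] = vals / trend
        indices[i, s.first_year - first : s.first_year - first + len(idx)] = idx
    depth = np.isfinite(indices).sum(axis=0)
    out = np.full(n, np.nan)
    for j in range(n):
        col = indices[:, j]
        col = col[np.isfinite(col)]
        if col.size:
            out[j] = tukey_biweight_mean(col) if robust_mean else col.mean()
    return Chronology(collection.site_id, first, out, depth, detrend=detrend, robust_mean=robust_mean)
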