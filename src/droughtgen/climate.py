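"""Site precipitation, the standardized precipitation index (SPI), and
drought-event identification.

Monthly precipitation from nearby weather stations is interpolated to the
trial-site coordinates by inverse-distance weighting on great-circle
distances.  The SPI follows the McKee construction: backward-looking k-month
precipitation sums are fitted, per calendar month, with a gamma distribution
(zero sums handled as a point mass), and the fitted cumulative probability is
mapped through the standard-normal quantile function.  Negative SPI values
indicate drought; severity classes use the conventional thresholds
moderate (< -1), severe (< -1.5) and extreme (< -2).

Candidate drought years can be detected from SPI exceedances, but trials are
usually analysed with a curated event list (growth decline is what matters),
so an explicit event list always takes precedence over detection.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammainc, ndtri
from scipy.stats import pearsonr

log = logging.getLogger(__name__)

__all__ = [
    "StationSeries",
    "SitePrecipSeries",
    "SPISeries",
    "DroughtEvent",
    "read_station_csv",
    "write_station_csv",
    "great_circle_km",
    "idw_interpolate",
    "thom_gamma_fit",
    "spi",
    "classify_severity",
    "detect_drought_years",
    "spi_site_correlation",
]

EARTH_RADIUS_KM = 6371.0
SEVERITY_THRESHOLDS = {"moderate": -1.0, "severe": -1.5, "extreme": -2.0}
_H_EPS = 1e-10  # clip for the normal quantile at probability 0/1


def _monthly_index(values: pd.Series) -> pd.Series:
    """Coerce to a PeriodIndex[M] series on a contiguous grid."""
    if not isinstance(values.index, pd.PeriodIndex):
        raise TypeError("monthly series must be indexed by a pandas PeriodIndex (freq='M')")
    if values.index.has_duplicates:
        raise ValueError("duplicate (year, month) entries in monthly grid")
    values = values.sort_index()
    full = pd.period_range(values.index[0], values.index[-1], freq="M")
    return values.reindex(full)


def monthly_series(years: Sequence[int], months: Sequence[int], values: Sequence[float]) -> pd.Series:
    """Build a monthly series from parallel year/month/value columns."""
    idx = pd.PeriodIndex(
        [pd.Period(year=int(y), month=int(m), freq="M") for y, m in zip(years, months)], freq="M"
    )
    return _monthly_index(pd.Series(np.asarray(values, dtype=float), index=idx))


@dataclass
class StationSeries:
    """Monthly precipitation (mm) observed at one weather station."""

    station_id: str
    latitude: float
    longitude: float
    precip: pd.Series  # mm/month, PeriodIndex[M]

    def __post_init__(self) -> None:
        self.precip = _monthly_index(self.precip)
        vals = self.precip.to_numpy()
        if np.any(vals[np.isfinite(vals)] < 0):
            raise ValueError(f"station {self.station_id!r}: negative precipitation")


@dataclass
class SitePrecipSeries:
    """Monthly precipitation interpolated to a trial site."""

    site_id: str
    latitude: float
    longitude: float
    precip: pd.Series

    def __post_init__(self) -> None:
        self.precip = _monthly_index(self.precip)


@dataclass
class SPISeries:
    """SPI values at one aggregation scale for one site.

    ``values`` is NaN for the first ``scale_k - 1`` months and wherever the
    k-month window contains missing precipitation.  ``fit_params`` records,
    per calendar month, the fitted gamma shape/scale, the zero-sum mixture
    probability ``q`` and the calibration sample size.
    """

    site_id: str
    scale_k: int
    values: pd.Series
    calibration: tuple[int, int] | None = None
    fit_params: dict[int, dict[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.scale_k < 1:
            raise ValueError("scale_k must be >= 1")
        self.values = self.values.sort_index()


@dataclass(frozen=True)
class DroughtEvent:
    """One drought year at a site, with the SPI evidence that triggered it."""

    site_id: str
    event_year: int
    severity: str | None = None  # moderate | severe | extreme | None (curated)
    min_spi: float = math.nan
    triggers: tuple = ()  # (scale, Period) pairs below threshold
    curated: bool = False


def read_station_csv(path_or_buf) -> list[StationSeries]:
    """Station CSV: station_id, latitude, longitude, year, month, precip_mm."""
    df = pd.read_csv(path_or_buf)
    required = {"station_id", "latitude", "longitude", "year", "month", "precip_mm"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"station CSV missing columns: {sorted(missing)}")
    out = []
    for sid, grp in df.groupby("station_id", sort=True):
        series = monthly_series(grp["year"], grp["month"], grp["precip_mm"])
        out.append(
            StationSeries(str(sid), float(grp["latitude"].iloc[0]), float(grp["longitude"].iloc[0]), series)
        )
    return out


def write_station_csv(stations: Sequence[StationSeries], path_or_buf) -> None:
    rows = []
    for s in stations:
        for per, v in s.precip.items():
            if np.isfinite(v):
                rows.append((s.station_id, s.latitude, s.longitude, per.year, per.month, float(v)))
    pd.DataFrame(rows, columns=["station_id", "latitude", "longitude", "year", "month", "precip_mm"]
                 ).to_csv(path_or_buf, index=False)


def great_circle_km(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    """Haversine great-circle distance in kilometres."""
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dphi = p2 - p1
    dlam = math.radians(lon2 - lon1)
    a = math.sin(dphi / 2) ** 2 + math.cos(p1) * math.cos(p2) * math.sin(dlam / 2) ** 2
    return 2 * EARTH_RADIUS_KM * math.asin(min(1.0, math.sqrt(a)))


def idw_interpolate(
    stations: Sequence[StationSeries],
    site_id: str,
    latitude: float,
    longitude: float,
    power: float = 2.0,
    zero_tol_km: float = 0.001,
) -> SitePrecipSeries:
    """Inverse-distance-weighted monthly precipitation at the site.

    Weights are ``distance**-power`` on great-circle distances; a station
    within ``zero_tol_km`` of the site is returned verbatim.  Months no
    station reports stay missing.
    """
    if not stations:
        raise ValueError("idw_interpolate needs at least one station")
    if power <= 0:
        raise ValueError("power must be positive")
    dists = np.array([great_circle_km(latitude, longitude, s.latitude, s.longitude) for s in stations])
    start = min(s.precip.index[0] for s in stations)
    end = max(s.precip.index[-1] for s in stations)
    grid = pd.period_range(start, end, freq="M")
    nearest = int(np.argmin(dists))
    if dists[nearest] < zero_tol_km:
        return SitePrecipSeries(site_id, latitude, longitude, stations[nearest].precip.reindex(grid))
    mat = np.vstack([s.precip.reindex(grid).to_numpy() for s in stations])
    w = dists ** (-power)
    mask = np.isfinite(mat)
    wsum = (mask * w[:, None]).sum(axis=0)
    num = np.nansum(np.where(mask, mat, 0.0) * w[:, None], axis=0)
    vals = np.where(wsum > 0, num / np.maximum(wsum, 1e-300), np.nan)
    return SitePrecipSeries(site_id, latitude, longitude, pd.Series(vals, index=grid))


def thom_gamma_fit(positive_sums: np.ndarray) -> tuple[float, float]:
    """Gamma shape/scale by Thom's closed-form maximum-likelihood approximation.

    ``A = ln(mean) - mean(ln x)``; ``shape = (1 + sqrt(1 + 4A/3)) / (4A)``;
    falls back to method of moments when A is numerically nonpositive.
    """
    x = np.asarray(positive_sums, dtype=float)
    mean = x.mean()
    a = math.log(mean) - np.mean(np.log(x))
    if a <= 0:
        var = x.var(ddof=1) if x.size > 1 else 0.0
        if var <= 0:
            return math.inf, 0.0  # degenerate; caller handles
        shape = mean**2 / var
    else:
        shape = (1.0 + math.sqrt(1.0 + 4.0 * a / 3.0)) / (4.0 * a)
    return shape, mean / shape


def spi(
    site: SitePrecipSeries,
    scale_k: int,
    calibration: tuple[int, int] | None = None,
    min_per_month: int = 20,
    var_tol: float = 1e-12,
) -> SPISeries:
    """Standardized precipitation index at aggregation scale ``scale_k``.

    Backward-looking k-month sums are formed on the contiguous monthly grid;
    for each calendar month a gamma distribution is fitted to the positive
    sums within the calibration window (default: the full series), with the
    zero-sum probability handled as the mixture ``H(x) = q + (1-q) G(x)``
    and ``q = n_zero / (n + 1)``.  ``SPI = ndtri(H)``.  Calendar months with
    fewer than ``min_per_month`` calibration values, or the first ``k - 1``
    months, are missing.  Degenerate months (all sums equal within
    ``var_tol``) get SPI 0.
    """
    precip = site.precip
    sums = precip.rolling(scale_k, min_periods=scale_k).sum()
    years = sums.index.year
    months = sums.index.month
    out = np.full(len(sums), np.nan)
    if calibration is None:
        calib_mask = np.ones(len(sums), dtype=bool)
    else:
        calib_mask = (years >= calibration[0]) & (years <= calibration[1])
    fit_params: dict[int, dict[str, float]] = {}
    svals = sums.to_numpy()
    for m in range(1, 13):
        msel = months == m
        cal = svals[msel & calib_mask]
        cal = cal[np.isfinite(cal)]
        n = cal.size
        if n < min_per_month:
            log.warning("SPI scale %d month %d: only %d calibration values (< %d); left missing",
                        scale_k, m, n, min_per_month)
            continue
        tgt_idx = np.where(msel & np.isfinite(svals))[0]
        x = svals[tgt_idx]
        if np.var(cal) < var_tol:
            # no spread: every sum sits at the distribution median
            out[tgt_idx] = 0.0
            fit_params[m] = {"shape": math.nan, "scale": math.nan, "q": 0.0, "n": n, "degenerate": 1.0}
            continue
        nz = int(np.sum(cal <= 0))
        q = nz / (n + 1)
        pos = cal[cal > 0]
        shape, scl = thom_gamma_fit(pos)
        g = np.where(x > 0, gammainc(shape, np.maximum(x, 0) / scl), 0.0)
        h = np.clip(q + (1 - q) * g, _H_EPS, 1 - _H_EPS)
        out[tgt_idx] = ndtri(h)
        fit_params[m] = {"shape": shape, "scale": scl, "q": q, "n": n, "degenerate": 0.0}
    values = pd.Series(out, index=sums.index)
    return SPISeries(site.site_id, scale_k, values, calibration, fit_params)


def classify_severity(spi_value: float) -> str | None:
    """Severity class of a single SPI value (strict thresholds)."""
    if spi_value is None or not np.isfinite(spi_value):
        return None
    if spi_value < SEVERITY_THRESHOLDS["extreme"]:
        return "extreme"
    if spi_value < SEVERITY_THRESHOLDS["severe"]:
        return "severe"
    if spi_value < SEVERITY_THRESHOLDS["moderate"]:
        return "moderate"
    return "none"


def detect_drought_years(
    spi_by_scale: Mapping[int, SPISeries],
    threshold: float = -1.5,
    scales: Iterable[int] = (1, 3),
    month_window: tuple[int, int] = (4, 9),
    override: Sequence[int] | Sequence[DroughtEvent] | None = None,
) -> list[DroughtEvent]:
    """Flag calendar years whose growing-season SPI falls below ``threshold``.

    A year is flagged when any month within ``month_window`` (inclusive
    calendar-month bounds) at any requested scale is below the threshold;
    severity is the class of the yearly minimum SPI over the triggers.  When
    ``override`` is given (curated event years or ready events) it is
    returned verbatim, with severities filled from the SPI where possible.
    """
    scales = list(scales)
    if not scales:
        raise ValueError("empty scales set")
    missing = [k for k in scales if k not in spi_by_scale]
    if missing:
        raise KeyError(f"requested scales not available: {missing}")
    site_id = spi_by_scale[scales[0]].site_id
    lo, hi = month_window

    def year_min(year: int) -> tuple[float, tuple]:
        vmin, triggers = math.inf, []
        for k in scales:
            s = spi_by_scale[k].values
            sel = s[(s.index.year == year) & (s.index.month >= lo) & (s.index.month <= hi)]
            for per, v in sel.items():
                if np.isfinite(v):
                    vmin = min(vmin, v)
                    if v < threshold:
                        triggers.append((k, per))
        return vmin, tuple(triggers)

    if override is not None:
        events = []
        for item in override:
            if isinstance(item, DroughtEvent):
                events.append(item)
            else:
                vmin, trig = year_min(int(item))
                sev = classify_severity(vmin) if np.isfinite(vmin) else None
                events.append(DroughtEvent(site_id, int(item), sev, vmin if np.isfinite(vmin) else math.nan,
                                           trig, curated=True))
        return events

    years = sorted({int(y) for k in scales for y in spi_by_scale[k].values.index.year})
    events = []
    for year in years:
        vmin, trig = year_min(year)
        if trig:
            events.append(DroughtEvent(site_id, year, classify_severity(vmin), vmin, trig))
    return events


def spi_site_correlation(a: SPISeries, b: SPISeries) -> float:
    """Pearson correlation of two same-scale SPI series over joint months."""
    if a.scale_k != b.scale_k:
        raise ValueError(f"scale mismatch: {a.scale_k} vs {b.scale_k}")
    joined = pd.concat([a.values.rename("a"), b.values.rename("b")], axis=1, join="inner").dropna()
    if len(joined) < 3:
        raise ValueError("fewer than 3 jointly defined months")
    if joined["a"].std(ddof=0) == 0 or joined["b"].std(ddof=0) == 0:
        return math.nan
    return float(pearsonr(joined["a"], joined["b"]).statistic)
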