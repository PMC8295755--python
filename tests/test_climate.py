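"""IDW interpolation, SPI transform and drought-event identification."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.special import gammainc, ndtri

from droughtgen.climate import (
    SPISeries,
    SitePrecipSeries,
    StationSeries,
    classify_severity,
    detect_drought_years,
    great_circle_km,
    idw_interpolate,
    monthly_series,
    read_station_csv,
    spi,
    spi_site_correlation,
    write_station_csv,
)


def make_station(sid, lat, lon, values, start="1970-01"):
    idx = pd.period_range(start, periods=len(values), freq="M")
    return StationSeries(sid, lat, lon, pd.Series(np.asarray(values, float), index=idx))


# ---------------------------------------------------------------------------
# Independent brute-force SPI oracle: explicit loops, Thom formula coded
# from its published definition, scipy gamma CDF / normal quantile.
# ---------------------------------------------------------------------------

def spi_oracle(precip: pd.Series, k: int) -> pd.Series:
    vals = precip.to_numpy()
    n = len(vals)
    sums = np.full(n, np.nan)
    for i in range(k - 1, n):
        window = vals[i - k + 1 : i + 1]
        if np.all(np.isfinite(window)):
            sums[i] = window.sum()
    out = np.full(n, np.nan)
    months = precip.index.month
    for m in range(1, 13):
        idx = [i for i in range(n) if months[i] == m and np.isfinite(sums[i])]
        cal = [sums[i] for i in idx]
        if len(cal) < 20:
            continue
        if np.var(cal) < 1e-12:
            for i in idx:
                out[i] = 0.0
            continue
        nz = sum(1 for c in cal if c <= 0)
        q = nz / (len(cal) + 1)
        pos = [c for c in cal if c > 0]
        mean = sum(pos) / len(pos)
        a = math.log(mean) - sum(math.log(c) for c in pos) / len(pos)
        alpha = (1 + math.sqrt(1 + 4 * a / 3)) / (4 * a)
        beta = mean / alpha
        for i in idx:
            g = gammainc(alpha, sums[i] / beta) if sums[i] > 0 else 0.0
            h = min(max(q + (1 - q) * g, 1e-10), 1 - 1e-10)
            out[i] = ndtri(h)
    return pd.Series(out, index=precip.index)


def gamma_precip(seed=20, years=40):
    rng = np.random.default_rng(seed)
    idx = pd.period_range("1970-01", periods=12 * years, freq="M")
    means = np.array([30, 28, 38, 45, 60, 72, 70, 60, 48, 40, 38, 32], dtype=float)
    vals = rng.gamma(1.7, means[idx.month - 1] / 1.7)
    return SitePrecipSeries("S", 48.0, 16.0, pd.Series(vals, index=idx))


class TestIdw:
    def test_target_at_station_returns_station(self):
        a = make_station("A", 48.0, 16.0, [10, 20, 30])
        b = make_station("B", 49.0, 17.0, [100, 200, 300])
        out = idw_interpolate([a, b], "S", 48.0, 16.0)
        np.testing.assert_allclose(out.precip.to_numpy(), [10, 20, 30])

    def test_equal_values_pass_through(self):
        a = make_station("A", 48.0, 16.0, [5.0] * 3)
        b = make_station("B", 48.5, 16.5, [5.0] * 3)
        out = idw_interpolate([a, b], "S", 48.2, 16.2)
        np.testing.assert_allclose(out.precip.to_numpy(), 5.0)

    def test_distance_weighted_hand_example(self):
        # along the equator distances are proportional to longitude offsets,
        # so stations at 1 and 2 degrees east sit at distance ratio 1:2
        a = make_station("A", 0.0, 1.0, [10.0])
        b = make_station("B", 0.0, 2.0, [40.0])
        out = idw_interpolate([a, b], "S", 0.0, 0.0, power=2.0)
        d1 = great_circle_km(0, 0, 0, 1)
        w1, w2 = d1 ** -2, (2 * d1) ** -2
        assert out.precip.iloc[0] == pytest.approx((10 * w1 + 40 * w2) / (w1 + w2))
        assert out.precip.iloc[0] == pytest.approx(16.0)

    def test_bounded_by_station_range(self):
        rng = np.random.default_rng(0)
        stations = [make_station(f"S{i}", 48 + 0.1 * i, 16 - 0.1 * i, rng.uniform(0, 100, 24))
                    for i in range(4)]
        out = idw_interpolate(stations, "S", 48.15, 16.05)
        mat = np.vstack([s.precip.to_numpy() for s in stations])
        assert np.all(out.precip.to_numpy() >= mat.min(axis=0) - 1e-12)
        assert np.all(out.precip.to_numpy() <= mat.max(axis=0) + 1e-12)

    def test_missing_month_left_missing(self):
        vals = [1.0, np.nan, 3.0]
        a = make_station("A", 48.0, 16.0, vals)
        b = make_station("B", 48.5, 16.5, vals)
        out = idw_interpolate([a, b], "S", 48.2, 16.2)
        assert np.isnan(out.precip.iloc[1])


class TestSpi:
    def test_degenerate_constant_month_gives_zero(self):
        idx = pd.period_range("1980-01", periods=12 * 30, freq="M")
        site = SitePrecipSeries("S", 48, 16, pd.Series(50.0, index=idx))
        s = spi(site, 1)
        np.testing.assert_allclose(s.values.to_numpy(), 0.0)

    @pytest.mark.parametrize("k", [1, 3, 12])
    def test_matches_independent_oracle(self, k):
        site = gamma_precip()
        ours = spi(site, k).values
        theirs = spi_oracle(site.precip, k)
        both = np.isfinite(ours.to_numpy()) & np.isfinite(theirs.to_numpy())
        assert both.sum() > 400
        np.testing.assert_allclose(ours.to_numpy()[both], theirs.to_numpy()[both], atol=1e-6)

    def test_normalization_per_calendar_month(self):
        # the per-month median of a single 40-year series carries Monte-Carlo
        # noise of ~0.12-0.2 SD, so the statistic is averaged over replicate
        # series of the same length before checking the normalization bounds
        meds = np.zeros((12, 12))
        sds = np.zeros((12, 12))
        for r in range(12):
            s = spi(gamma_precip(seed=100 + r), 3).values
            for m in range(1, 13):
                vals = s[s.index.month == m].dropna()
                meds[r, m - 1] = vals.median()
                sds[r, m - 1] = vals.std(ddof=1)
        assert np.abs(meds.mean(axis=0)).max() <= 0.15
        assert np.all((sds.mean(axis=0) >= 0.8) & (sds.mean(axis=0) <= 1.2))

    def test_first_k_minus_1_months_missing(self):
        site = gamma_precip()
        s = spi(site, 6).values
        assert s.iloc[:5].isna().all()
        assert np.isfinite(s.iloc[5])

    def test_monotone_in_aggregated_sum(self):
        site = gamma_precip()
        k = 3
        s = spi(site, k).values
        sums = site.precip.rolling(k, min_periods=k).sum()
        for m in range(1, 13):
            sel = (s.index.month == m) & np.isfinite(s.to_numpy())
            order = np.argsort(sums[sel].to_numpy())
            assert np.all(np.diff(s[sel].to_numpy()[order]) >= -1e-12)

    def test_insufficient_calibration_left_missing(self):
        idx = pd.period_range("2000-01", periods=60, freq="M")
        site = SitePrecipSeries("S", 48, 16, pd.Series(50.0, index=idx))
        s = spi(site, 1, min_per_month=20)
        assert s.values.isna().all()

    def test_configured_scales_yield_one_series_each(self):
        site = gamma_precip(years=41)
        scales = [1, 3, 6, 12, 24, 48]
        out = {k: spi(site, k) for k in scales}
        assert sorted(out) == scales
        assert all(isinstance(v, SPISeries) and v.scale_k == k for k, v in out.items())


class TestSeverity:
    @pytest.mark.parametrize("value,expected", [
        (-1.2, "moderate"), (-1.7, "severe"), (-2.3, "extreme"),
        (0.0, "none"), (-1.5, "moderate"), (-2.0, "severe"), (-1.0, "none"),
    ])
    def test_thresholds_strict(self, value, expected):
        assert classify_severity(value) == expected

    def test_missing_input_gives_missing_class(self):
        assert classify_severity(float("nan")) is None


def constructed_spi(values_by_period, site_id="S", k=3):
    periods = pd.PeriodIndex(list(values_by_period), freq="M")
    return SPISeries(site_id, k, pd.Series(list(values_by_period.values()), index=periods))


class TestDetect:
    def test_single_low_month_flags_year(self):
        s = constructed_spi({pd.Period("2000-06", "M"): -1.8, pd.Period("2000-07", "M"): 0.2,
                             pd.Period("2001-06", "M"): 0.5})
        events = detect_drought_years({3: s}, scales=[3])
        assert [(e.event_year, e.severity) for e in events] == [(2000, "severe")]

    def test_all_nonnegative_gives_empty(self):
        s = constructed_spi({pd.Period("2000-06", "M"): 0.0, pd.Period("2001-06", "M"): 1.2})
        assert detect_drought_years({3: s}, scales=[3]) == []

    def test_override_passthrough(self):
        s = constructed_spi({pd.Period("2000-06", "M"): 2.0})
        events = detect_drought_years({3: s}, scales=[3], override=[1993, 2000, 2003])
        assert [e.event_year for e in events] == [1993, 2000, 2003]
        assert all(e.curated for e in events)

    def test_empty_scales_error(self):
        s = constructed_spi({pd.Period("2000-06", "M"): 0.0})
        with pytest.raises(ValueError):
            detect_drought_years({3: s}, scales=[])


class TestCorrelation:
    def test_identical_series(self):
        s = constructed_spi({pd.Period(f"2000-{m:02d}", "M"): v
                             for m, v in zip(range(1, 6), [0.1, -0.5, 1.2, 0.3, -1.0])})
        assert spi_site_correlation(s, s) == pytest.approx(1.0)

    def test_sign_flip(self):
        vals = {pd.Period(f"2000-{m:02d}", "M"): v
                for m, v in zip(range(1, 6), [0.1, -0.5, 1.2, 0.3, -1.0])}
        a = constructed_spi(vals)
        b = constructed_spi({k: -v for k, v in vals.items()})
        assert spi_site_correlation(a, b) == pytest.approx(-1.0)

    def test_hand_computed_pearson(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([2.0, 1.0, 4.0, 3.0, 5.0])
        a = constructed_spi({pd.Period(f"2000-{m:02d}", "M"): v for m, v in zip(range(1, 6), x)})
        b = constructed_spi({pd.Period(f"2000-{m:02d}", "M"): v for m, v in zip(range(1, 6), y)})
        hand = np.sum((x - x.mean()) * (y - y.mean())) / math.sqrt(
            np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2))
        assert spi_site_correlation(a, b) == pytest.approx(hand)

    def test_scale_mismatch_rejected(self):
        a = constructed_spi({pd.Period("2000-01", "M"): 0.0}, k=1)
        b = constructed_spi({pd.Period("2000-01", "M"): 0.0}, k=3)
        with pytest.raises(ValueError):
            spi_site_correlation(a, b)


def test_station_csv_round_trip(tmp_path):
    st = make_station("A", 48.1, 16.2, [10.0, 20.0, 30.0])
    path = tmp_path / "stations.csv"
    write_station_csv([st], path)
    again = read_station_csv(path)
    assert again[0].station_id == "A"
    np.testing.assert_allclose(again[0].precip.to_numpy(), st.precip.to_numpy())
    assert again[0].latitude == pytest.approx(48.1)


def test_monthly_series_rejects_duplicates():
    with pytest.raises(ValueError):
        monthly_series([2000, 2000], [1, 1], [1.0, 2.0])
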