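"""Core estimator: block averaging, flux, budgets, and a brute-force oracle."""

import numpy as np
import pandas as pd
import pytest

from dielmetab import metabolism as mb
from dielmetab.solar import MetabolicDay


def _series(start, n, **cols):
    idx = pd.date_range(start, periods=n, freq="30min", tz="UTC") \
        + pd.Timedelta(minutes=15)
    return pd.DataFrame(cols, index=idx)


class TestBlockAverage:
    def test_mean_within_block(self):
        t = pd.to_datetime(["2021-05-01 00:00", "2021-05-01 00:10",
                            "2021-05-01 00:20"]).tz_localize("UTC")
        df = pd.DataFrame({"timestamp": t, "oxygen": [100.0, 110.0, 120.0]})
        out = mb.block_average(df)
        assert len(out) == 1
        assert out["oxygen"].iloc[0] == 110.0
        assert out.index[0] == pd.Timestamp("2021-05-01 00:15+00:00")

    def test_no_observation_gives_nan_block(self):
        t = pd.to_datetime(["2021-05-01 00:10", "2021-05-01 01:10"]
                           ).tz_localize("UTC")
        df = pd.DataFrame({"timestamp": t, "oxygen": [100.0, 120.0]})
        out = mb.block_average(df)
        assert len(out) == 3
        assert np.isnan(out["oxygen"].iloc[1])

    def test_constant_series_unchanged(self):
        t = pd.date_range("2021-05-01", periods=18, freq="10min", tz="UTC")
        df = pd.DataFrame({"timestamp": t, "oxygen": 200.0})
        out = mb.block_average(df)
        assert (out["oxygen"] == 200.0).all()

    def test_observations_never_cross_block_boundary(self):
        # 00:29:59 belongs to the first block, 00:30:00 to the second
        t = pd.to_datetime(["2021-05-01 00:29:59", "2021-05-01 00:30:00"]
                           ).tz_localize("UTC")
        df = pd.DataFrame({"timestamp": t, "oxygen": [100.0, 200.0]})
        out = mb.block_average(df)
        assert list(out["oxygen"]) == [100.0, 200.0]


class TestCorrectDepth:
    def test_offset_added(self):
        assert mb.correct_depth(2.70, 0.30) == pytest.approx(3.00)

    def test_zero_offset_identity(self):
        assert mb.correct_depth(1.23, 0.0) == 1.23

    def test_shallow_reading_still_valid(self):
        assert mb.correct_depth(0.10, 0.30) == pytest.approx(0.40)

    def test_nonpositive_result_flagged(self):
        assert np.isnan(mb.correct_depth(-0.50, 0.30))


class TestAirseaFlux:
    def test_equilibrium_zero(self):
        assert mb.airsea_flux(0.5, 250.0, 250.0) == 0.0

    def test_direct_product(self):
        assert mb.airsea_flux(0.5, 270.0, 250.0) == pytest.approx(10.0)

    def test_supersaturation_outgasses(self):
        assert mb.airsea_flux(0.5, 250.0, 270.0) < 0


class TestInstantaneousNep:
    def test_constant_oxygen_zero_rate(self):
        s = _series("2021-05-01", 10, oxygen=200.0, depth=3.0, flux=0.0)
        r = mb.instantaneous_nep(s)
        assert np.allclose(r.iloc[1:], 0.0)

    def test_hand_value(self):
        # +10 mmol/m3 over half an hour at H = 3 m, F = 0:
        # 3 * 10 / (0.5/24) = 1440 mmol m-2 d-1
        s = _series("2021-05-01", 2, oxygen=[200.0, 210.0], depth=3.0, flux=0.0)
        r = mb.instantaneous_nep(s)
        assert r.iloc[1] == pytest.approx(1440.0)

    def test_long_gap_breaks_chain(self):
        idx = pd.DatetimeIndex(
            list(pd.date_range("2021-05-01 00:15", periods=3, freq="30min",
                               tz="UTC"))
            + list(pd.date_range("2021-05-01 02:45", periods=3, freq="30min",
                                 tz="UTC")))
        s = pd.DataFrame({"oxygen": 200.0, "depth": 3.0, "flux": 0.0}, index=idx)
        r = mb.instantaneous_nep(s)
        assert np.isnan(r.iloc[3])  # 2-block gap: no rate across it
        assert np.isfinite(r.iloc[4])

    def test_single_missing_block_bridged(self):
        idx = pd.DatetimeIndex(
            list(pd.date_range("2021-05-01 00:15", periods=2, freq="30min",
                               tz="UTC"))
            + [pd.Timestamp("2021-05-01 01:45+00:00")])
        s = pd.DataFrame({"oxygen": [200.0, 205.0, 215.0], "depth": 3.0,
                          "flux": 0.0}, index=idx)
        r = mb.instantaneous_nep(s)
        # 10 mmol/m3 over 1 h at 3 m
        assert r.iloc[2] == pytest.approx(3.0 * 10.0 / (1.0 / 24.0))


def _toy_day(daylight_h=12.0, n_day=24, n_night=24):
    start = pd.Timestamp("2021-05-01 11:00+00:00")
    sunset = start + pd.Timedelta(hours=daylight_h)
    end = start + pd.Timedelta(hours=24)
    return MetabolicDay(index=0, start=start, sunset=sunset, end=end,
                        day_intervals=np.arange(n_day),
                        night_intervals=np.arange(n_day, n_day + n_night))


class TestDailyRates:
    def test_formula_arithmetic(self):
        # mean day rate +200, mean night rate -150, 12 h daylight:
        # ER = 150, GPP = (200 + 150) * 0.5 = 175, NEP = 25
        day = _toy_day()
        rates = pd.Series([200.0] * 24 + [-150.0] * 24)
        out = mb.daily_rates(day, rates)
        assert out["er"] == pytest.approx(150.0)
        assert out["gpp"] == pytest.approx(175.0)
        assert out["nep"] == pytest.approx(25.0)
        assert not out["anomalous_gpp"] and not out["anomalous_er"]

    def test_rising_night_oxygen_flags_anomalous_er(self):
        day = _toy_day()
        rates = pd.Series([200.0] * 24 + [50.0] * 24)  # O2 rising at night
        out = mb.daily_rates(day, rates)
        assert out["er"] < 0 and out["anomalous_er"]

    def test_no_night_data_no_rates(self):
        day = _toy_day()
        rates = pd.Series([200.0] * 24 + [np.nan] * 24)
        assert mb.daily_rates(day, rates) is None

    def test_nep_identity_exact(self, clean_fit):
        d = clean_fit.daily
        np.testing.assert_array_equal(d["nep"].to_numpy(),
                                      (d["gpp"] - d["er"]).to_numpy())


class TestBruteForceOracle:
    """Two metabolic days of irregular hand-generated numbers: the whole
    difference/budget pipeline must equal an explicit loop re-computation."""

    def test_daily_rates_match_spreadsheet_arithmetic(self):
        rng = np.random.default_rng(42)
        n = 96  # 48 h of 30-min blocks
        idx = pd.date_range("2021-05-01 11:15", periods=n, freq="30min",
                            tz="UTC")
        o2 = 220.0 + np.cumsum(rng.normal(0, 3.0, n))
        h = 3.0 + 0.4 * np.sin(np.arange(n) / 5.0)
        fl = rng.normal(0, 15.0, n)
        s = pd.DataFrame({"oxygen": o2, "depth": h, "flux": fl}, index=idx)

        inst = mb.instantaneous_nep(s)

        # independent spreadsheet-style recomputation
        expect = [np.nan]
        for i in range(1, n):
            dt_d = (idx[i] - idx[i - 1]).total_seconds() / 86400.0
            expect.append(0.5 * (h[i] + h[i - 1]) * (o2[i] - o2[i - 1]) / dt_d
                          - 0.5 * (fl[i] + fl[i - 1]))
        np.testing.assert_allclose(inst.iloc[1:], expect[1:], rtol=1e-9)

        # two 24-h metabolic days, 13 h of daylight
        for d0 in (0, 48):
            day = MetabolicDay(
                index=d0 // 48,
                start=idx[d0] - pd.Timedelta(minutes=15),
                sunset=idx[d0] - pd.Timedelta(minutes=15) + pd.Timedelta(hours=13),
                end=idx[d0] - pd.Timedelta(minutes=15) + pd.Timedelta(hours=24),
                day_intervals=np.arange(d0, d0 + 26),
                night_intervals=np.arange(d0 + 26, d0 + 48))
            got = mb.daily_rates(day, inst)

            night_vals = [expect[i] for i in range(d0 + 26, d0 + 48)
                          if not np.isnan(expect[i])]
            day_vals = [expect[i] for i in range(d0, d0 + 26)
                        if not np.isnan(expect[i])]
            er = -sum(night_vals) / len(night_vals)
            gpp = (sum(day_vals) / len(day_vals) + er) * (13.0 / 24.0)
            assert got["er"] == pytest.approx(er, rel=1e-9)
            assert got["gpp"] == pytest.approx(gpp, rel=1e-9)
            assert got["nep"] == pytest.approx(gpp - er, rel=1e-9)


class TestGasExchangeNeutrality:
    def test_doubling_kw_at_saturation_changes_nothing(self):
        n = 96
        idx = pd.date_range("2021-05-01 11:15", periods=n, freq="30min",
                            tz="UTC")
        o2 = 215.0 + 20 * np.sin(np.arange(n) / 7.0)
        kw = np.full(n, 1.5)
        s1 = pd.DataFrame({"oxygen": o2, "depth": 3.0,
                           "flux": mb.airsea_flux(kw, o2, o2)}, index=idx)
        s2 = pd.DataFrame({"oxygen": o2, "depth": 3.0,
                           "flux": mb.airsea_flux(2 * kw, o2, o2)}, index=idx)
        r1, r2 = mb.instantaneous_nep(s1), mb.instantaneous_nep(s2)
        np.testing.assert_array_equal(r1.to_numpy(), r2.to_numpy())


class TestFromRecordsDerivations:
    def _sonde(self, **cols):
        t = pd.date_range("2021-05-01 05:00", periods=288, freq="10min",
                          tz="UTC")
        base = dict(timestamp=t, temperature=15.0, oxygen=280.0)
        return pd.DataFrame({**base, **cols})

    def _met(self):
        t = pd.date_range("2021-05-01 05:00", periods=288, freq="10min",
                          tz="UTC")
        return pd.DataFrame({"timestamp": t, "wind_speed": 5.0,
                             "baro_pressure": 1013.25})

    def test_salinity_derived_from_conductivity(self, station):
        # conductivity ratio 1 at 15 degC defines S = 35
        m = mb.OpenWaterMetabolism.from_records(
            self._sonde(conductivity=42.914, depth=2.7), self._met(), station)
        assert np.allclose(m.series["salinity"].dropna(), 35.0, atol=1e-6)
        # sensor offset applied to depth
        assert np.allclose(m.series["depth"].dropna(), 3.0)

    def test_depth_derived_from_pressure(self, station):
        from dielmetab.seawater import surface_density
        m = mb.OpenWaterMetabolism.from_records(
            self._sonde(salinity=35.0, pressure=10.10 + 2.0),
            self._met(), station)
        expect = 2.0 * 1e4 / (surface_density(35.0, 15.0) * 9.81) + 0.30
        assert np.allclose(m.series["depth"].dropna(), expect)

    def test_missing_salinity_blocks_metabolism(self, station):
        with pytest.raises(ValueError, match="blocked"):
            mb.OpenWaterMetabolism.from_records(
                self._sonde(depth=2.7), self._met(), station)


class TestStratification:
    def test_uniform_profile_zero(self):
        assert mb.stratification_check([180.0, 180.0, 180.0]) == 0.0

    def test_hand_arithmetic(self):
        assert mb.stratification_check([100.0, 104.0, 108.0]) == pytest.approx(4.0)

    def test_single_point_absent(self):
        assert mb.stratification_check([200.0]) is None
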