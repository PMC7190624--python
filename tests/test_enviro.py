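"""Raster annotation, day length, wind decomposition, and the lag table."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from snowtrack import enviro, geo
from snowtrack.enviro import EnvRasterSeries, annotate, day_length, lag_extract, wind_decompose


def constant_series(value=1.0, name="snow", ndates=5):
    dates = np.arange(np.datetime64("2016-04-01"), np.datetime64("2016-04-01") + np.timedelta64(ndates, "D"))
    lats = np.arange(60.0, 62.01, 0.5)
    lons = np.arange(20.0, 22.01, 0.5)
    vals = np.full((ndates, lats.size, lons.size), value)
    return EnvRasterSeries.from_arrays(name, dates, lats, lons, vals)


class TestRasterSeries:
    def test_validates_axes(self):
        with pytest.raises(ValueError, match="increasing"):
            EnvRasterSeries.from_arrays("x", ["2016-04-01"], [61.0, 60.0], [20.0], np.zeros((1, 2, 1)))
        with pytest.raises(ValueError, match="daily"):
            EnvRasterSeries.from_arrays("x", ["2016-04-01", "2016-04-03"], [60.0], [20.0],
                                        np.zeros((2, 1, 1)))

    def test_annotate_constant_grid_and_missing(self, caplog):
        s = constant_series(3.5, name="temperature")
        pts = pd.DataFrame({"lon": [20.7, 50.0, 21.0], "lat": [61.1, 61.0, 60.0],
                            "date": pd.to_datetime(["2016-04-02", "2016-04-02", "2019-01-01"])})
        out = annotate(pts, s)
        assert out["temperature"].iloc[0] == 3.5           # any in-bounds point
        assert np.isnan(out["temperature"].iloc[1])        # off grid
        assert np.isnan(out["temperature"].iloc[2])        # off date range

    def test_equidistant_tie_breaks_to_lower_index(self):
        s = constant_series(0.0)
        s.data.values[:, :, 0] = 9.0  # lon cell 20.0 differs from lon cell 20.5
        v = s.value_at(20.25, 60.0, "2016-04-01")  # exactly between cells
        assert v[0] == 9.0

    def test_netcdf_roundtrip(self, tmp_path):
        s = constant_series(1.0)
        s.data.values[2, 1, 1] = 0.0
        p = tmp_path / "snow.nc"
        s.to_netcdf(p)
        s2 = EnvRasterSeries.from_netcdf(p)
        assert s2.name == "snow"
        np.testing.assert_array_equal(s.data.values, s2.data.values)
        np.testing.assert_array_equal(s.dates, s2.dates)


class TestDayLength:
    def test_polar_day_and_equinox(self):
        assert day_length(70.0, "2016-06-21") == 24.0
        assert day_length(0.0, "2016-03-20") == pytest.approx(12.0, abs=0.2)

    def test_matches_independent_declination_formula(self):
        # Spencer (1971) Fourier declination + the standard hour-angle formula
        def oracle(lat, J):
            g = 2 * np.pi * (J - 1) / 365.0
            decl = (0.006918 - 0.399912 * np.cos(g) + 0.070257 * np.sin(g)
                    - 0.006758 * np.cos(2 * g) + 0.000907 * np.sin(2 * g)
                    - 0.002697 * np.cos(3 * g) + 0.00148 * np.sin(3 * g))
            x = -np.tan(np.radians(lat)) * np.tan(decl)
            return 24.0 / np.pi * np.arccos(np.clip(x, -1, 1))

        for lat, doy in [(45.0, 80), (60.0, 120), (70.0, 60), (-45.0, 300)]:
            assert day_length(lat, doy) == pytest.approx(oracle(lat, doy), abs=0.1)

    @given(lat=hst.floats(-60, 60), doy=hst.integers(1, 365))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_hemispheric_complement(self, lat, doy):
        # away from polar thresholds day lengths at +/-lat sum to ~24 h
        assert day_length(lat, doy) + day_length(-lat, doy) == pytest.approx(24.0, abs=0.3)

    def test_rejects_bad_latitude(self):
        with pytest.raises(ValueError):
            day_length(95.0, 100)


class TestWindDecompose:
    @pytest.mark.parametrize("u,v,h,support,cross", [
        (10.0, 0.0, 90.0, 10.0, 0.0),     # pure tailwind flying due east
        (0.0, 5.0, 180.0, -5.0, 0.0),     # headwind flying due south
        (3.0, 4.0, 30.0, 4.9641, 0.5981),  # rotation-matrix projection by hand
    ])
    def test_examples(self, u, v, h, support, cross):
        ws, cw = wind_decompose(u, v, h)
        assert ws == pytest.approx(support, abs=1e-3)
        assert abs(cw) == pytest.approx(abs(cross), abs=1e-3)

    @given(u=hst.floats(-30, 30), v=hst.floats(-30, 30), h=hst.floats(0, 360))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_energy_identity(self, u, v, h):
        ws, cw = wind_decompose(u, v, h)
        assert ws**2 + cw**2 == pytest.approx(u**2 + v**2, rel=1e-12, abs=1e-12)

    def test_nan_heading_gives_nan(self):
        ws, cw = wind_decompose(1.0, 2.0, np.nan)
        assert np.isnan(ws) and np.isnan(cw)


class TestLagExtract:
    def points(self):
        return pd.DataFrame({"individual": ["a", "a"], "year": 2016,
                             "lon": [20.5, 21.0], "lat": [60.5, 61.0],
                             "date": pd.to_datetime(["2016-04-02", "2016-04-03"])})

    def test_static_series_constant_across_lags(self):
        s = constant_series(0.42, name="ndvi", ndates=30)
        tab = lag_extract(self.points(), {"ndvi": s}, lags=range(-3, 4), include_day_length=False)
        ok = tab[~tab["missing"]]
        assert ok["value"].nunique() == 1
        assert ok["value"].iloc[0] == 0.42

    def test_lag_zero_equals_plain_annotation(self):
        s = constant_series(1.0, ndates=10)
        s.data.values[:] = np.random.default_rng(0).random(s.data.shape)
        pts = self.points()
        tab = lag_extract(pts, {"snow": s}, lags=(0,), include_day_length=False)
        direct = annotate(pts, s)["snow"].to_numpy()
        np.testing.assert_allclose(tab[tab["variable"] == "snow"]["value"].to_numpy(), direct)

    def test_out_of_range_lags_flagged_missing(self):
        s = constant_series(1.0, ndates=3)  # 2016-04-01..03
        tab = lag_extract(self.points(), {"snow": s}, lags=range(-10, 11), include_day_length=False)
        assert tab["missing"].any()
        assert not tab[tab["lag"] == 0]["missing"].any()

    def test_day_length_recomputed_at_shifted_date(self):
        tab = lag_extract(self.points(), {}, lags=(-10, 10), include_day_length=True)
        d = tab[tab["variable"] == "day_length"]
        # spring at 60N: day length increases with the shifted date
        assert (d[d["lag"] == 10]["value"].to_numpy() > d[d["lag"] == -10]["value"].to_numpy()).all()


class TestGeo:
    def test_haversine_known_step(self):
        # one degree due north
        assert geo.haversine_km(20.0, 70.0, 20.0, 71.0) == pytest.approx(111.19, abs=0.1)
        assert geo.initial_bearing_deg(20.0, 70.0, 20.0, 71.0) == pytest.approx(0.0, abs=1e-9)

    def test_haversine_vs_vincenty_oracle(self):
        # WGS84 Vincenty inverse as the independent geodesic oracle
        def vincenty_km(lon1, lat1, lon2, lat2):
            a, f = 6378.137, 1 / 298.257223563
            b = (1 - f) * a
            L = np.radians(lon2 - lon1)
            U1, U2 = np.arctan((1 - f) * np.tan(np.radians([lat1, lat2])))
            lam = L
            for _ in range(200):
                sin_s = np.sqrt((np.cos(U2) * np.sin(lam)) ** 2
                                + (np.cos(U1) * np.sin(U2) - np.sin(U1) * np.cos(U2) * np.cos(lam)) ** 2)
                cos_s = np.sin(U1) * np.sin(U2) + np.cos(U1) * np.cos(U2) * np.cos(lam)
                sig = np.arctan2(sin_s, cos_s)
                sin_a = np.cos(U1) * np.cos(U2) * np.sin(lam) / sin_s
                cos2a = 1 - sin_a**2
                cos2sm = cos_s - 2 * np.sin(U1) * np.sin(U2) / cos2a if cos2a else 0.0
                C = f / 16 * cos2a * (4 + f * (4 - 3 * cos2a))
                lam_new = L + (1 - C) * f * sin_a * (
                    sig + C * sin_s * (cos2sm + C * cos_s * (-1 + 2 * cos2sm**2)))
                if abs(lam_new - lam) < 1e-12:
                    lam = lam_new
                    break
                lam = lam_new
            u2 = cos2a * (a**2 - b**2) / b**2
            A = 1 + u2 / 16384 * (4096 + u2 * (-768 + u2 * (320 - 175 * u2)))
            B = u2 / 1024 * (256 + u2 * (-128 + u2 * (74 - 47 * u2)))
            dsig = B * sin_s * (cos2sm + B / 4 * (cos_s * (-1 + 2 * cos2sm**2)
                                                  - B / 6 * cos2sm * (-3 + 4 * sin_s**2) * (-3 + 4 * cos2sm**2)))
            return b * A * (sig - dsig)

        cases = [(20.0, 60.0, 22.0, 61.5), (30.0, 70.0, 31.0, 70.9),
                 (25.0, 65.0, 28.0, 67.0), (20.0, 55.0, 24.0, 57.0)]
        for lon1, lat1, lon2, lat2 in cases:
            hav = geo.haversine_km(lon1, lat1, lon2, lat2)
            ref = vincenty_km(lon1, lat1, lon2, lat2)
            assert ref < 500.0
            assert abs(hav - ref) / ref < 0.005

    def test_destination_inverts_bearing_and_distance(self):
        lon, lat = geo.destination(25.0, 62.0, 37.0, 180.0)
        assert geo.haversine_km(25.0, 62.0, lon, lat) == pytest.approx(180.0, rel=1e-9)
        assert geo.initial_bearing_deg(25.0, 62.0, lon, lat) == pytest.approx(37.0, abs=1e-9)

    def test_turn_angle_conventions(self):
        assert geo.turn_angle_deg(10.0, 10.0) == 0.0
        assert geo.turn_angle_deg(0.0, 180.0) == 180.0   # back-track is +180
        assert geo.turn_angle_deg(350.0, 10.0) == 20.0   # wraps through north
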