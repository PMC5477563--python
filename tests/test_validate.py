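from datetime import date

import numpy as np
import pandas as pd
import pytest

from humidclim import (
    GridSpec,
    StationSeries,
    SynthParams,
    annual_bioclim,
    buffer_zones,
    build_year_climatology,
    collocate,
    gen_climate_cube,
    gen_station_series,
    iqr_outliers,
    raster_compare,
    series_stats,
    station_bioclim,
)
from humidclim.validate import BUFFER_AREA_DEG2


@pytest.fixture
def grid():
    return GridSpec(n_rows=4, n_cols=5, lat_step=2.0, lon_step=2.0,
                    lat_origin=-60.0, lon_origin=-70.0)


@pytest.fixture
def month_cube(grid):
    return gen_climate_cube(grid, date(2001, 1, 1), date(2001, 1, 31),
                            SynthParams(noise_sd=1.0, seed=8))


class TestCollocate:
    def test_station_at_cell_center_pairs_full_series(self, grid, month_cube):
        lat, lon = grid.lat_centers[1], grid.lon_centers[2]
        stn = StationSeries("S", lat, lon, month_cube.times,
                            month_cube.temperature[:, 1, 2] - 273.15)
        pairs = collocate(month_cube, stn)
        assert len(pairs) == len(month_cube)
        np.testing.assert_allclose(pairs["grid"], pairs["station"], atol=1e-12)

    def test_six_hourly_station_intersection_count(self, grid):
        cube = gen_climate_cube(grid, date(2001, 1, 1), date(2001, 1, 31),
                                SynthParams(noise_sd=0))
        times = pd.date_range("2001-01-01", periods=30 * 4, freq="6h")
        stn = StationSeries("S", grid.lat_centers[0], grid.lon_centers[0],
                            times, np.zeros(len(times)), step_hours=6)
        pairs = collocate(cube, stn)
        assert len(pairs) == 120

    def test_cell_edge_station_resolves_to_lowest_row_and_column(self, grid, month_cube):
        # exactly between rows 0/1 and columns 1/2
        lat = (grid.lat_centers[0] + grid.lat_centers[1]) / 2
        lon = (grid.lon_centers[1] + grid.lon_centers[2]) / 2
        stn = StationSeries("edge", lat, lon, month_cube.times,
                            month_cube.temperature[:, 0, 1] - 273.15)
        pairs = collocate(month_cube, stn)
        np.testing.assert_allclose(pairs["grid"], pairs["station"], atol=1e-12)

    def test_station_outside_extent_rejected(self, grid, month_cube):
        stn = StationSeries("far", 40.0, 0.0, month_cube.times[:5],
                            np.zeros(5))
        with pytest.raises(ValueError, match="outside"):
            collocate(month_cube, stn)


class TestSeriesStats:
    def test_noiseless_line_recovers_exact_parameters(self):
        x = np.linspace(-30.0, 5.0, 500)
        pairs = pd.DataFrame({"station": x, "grid": 0.86 * x - 1.57})
        s = series_stats(pairs)
        assert s.pearson_r == pytest.approx(1.0)
        assert s.slope == pytest.approx(0.86)
        assert s.intercept == pytest.approx(-1.57)
        assert s.residual_iqr == pytest.approx(0.0, abs=1e-12)

    def test_planted_parameters_recovered_from_noisy_station(self):
        idx = pd.date_range("1995-01-01", periods=12_000, freq="h")
        hours = np.arange(12_000)
        truth = pd.Series(
            -25 + 20 * np.cos(hours * 2 * np.pi / 8766) + 9 * np.cos(hours * 2 * np.pi / 24),
            index=idx,
        )
        stn = gen_station_series(truth, slope=0.73, intercept=-8.9, noise_sd=3.0, seed=21)
        pairs = pd.DataFrame({"station": stn.temperature, "grid": truth.to_numpy()},
                             index=idx)
        s = series_stats(pairs)
        assert s.slope == pytest.approx(0.73, abs=0.02)
        assert s.intercept == pytest.approx(-8.9, abs=0.3)

    def test_residual_quartiles_by_hand_enumeration(self):
        # residuals {-2,-1,0,1,2}: q1 = -1, q3 = 1 by linear interpolation
        x = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
        # this residual pattern is zero-sum and orthogonal to x, so the OLS
        # fit is y = x and the residual multiset is exactly {-2,-1,0,1,2}
        y = x + np.array([1.0, -2.0, 0.0, 2.0, -1.0])
        s = series_stats(pd.DataFrame({"station": x, "grid": y}))
        assert s.residual_q1 == pytest.approx(-1.0)
        assert s.residual_q3 == pytest.approx(1.0)
        assert s.residual_iqr == pytest.approx(2.0)

    def test_pair_order_invariance_and_scale_invariance_of_r(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=300)
        y = 0.7 * x + rng.normal(scale=0.3, size=300)
        pairs = pd.DataFrame({"station": x, "grid": y})
        s1 = series_stats(pairs)
        s2 = series_stats(pairs.sample(frac=1.0, random_state=0))
        assert s1.pearson_r == pytest.approx(s2.pearson_r, rel=1e-12)
        assert s1.slope == pytest.approx(s2.slope, rel=1e-12)
        s3 = series_stats(pairs * 4.0)
        assert s3.pearson_r == pytest.approx(s1.pearson_r, rel=1e-12)
        assert s3.r_squared == pytest.approx(s1.r_squared, rel=1e-12)

    def test_r_squared_equals_squared_correlation(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=500)
        y = 1.2 * x + rng.normal(size=500)
        s = series_stats(pd.DataFrame({"station": x, "grid": y}))
        assert abs(s.r_squared - s.pearson_r**2) < 1e-12

    def test_zero_variance_predictor_rejected(self):
        pairs = pd.DataFrame({"station": np.ones(10), "grid": np.arange(10.0)})
        with pytest.raises(ValueError, match="variance"):
            series_stats(pairs)

    def test_per_month_summaries_present_with_datetime_index(self):
        idx = pd.date_range("2001-01-01", periods=24 * 365, freq="h")
        rng = np.random.default_rng(5)
        x = rng.normal(size=len(idx))
        pairs = pd.DataFrame({"station": x, "grid": x + rng.normal(size=len(idx))},
                             index=idx)
        s = series_stats(pairs)
        assert sorted(s.per_month) == list(range(1, 13))
        for summary in s.per_month.values():
            assert summary["q1"] <= summary["median"] <= summary["q3"]


class TestStationBioclim:
    def test_constant_station_closed_form(self):
        times = pd.date_range("2001-01-01", "2002-01-01", freq="h", inclusive="left")
        stn = StationSeries("C", -60.0, 0.0, times, np.full(len(times), 10.0))
        out = station_bioclim(stn, 2001)
        assert out["BIO1"] == pytest.approx(10.0)
        assert out["BIO2"] == 0.0 and out["BIO4"] == 0.0 and out["BIO7"] == 0.0

    def test_annual_range_closure(self):
        times = pd.date_range("2001-01-01", "2002-01-01", freq="h", inclusive="left")
        rng = np.random.default_rng(6)
        temps = -20 + 15 * np.cos(np.arange(len(times)) * 2 * np.pi / 8766) \
            + rng.normal(0, 2, len(times))
        stn = StationSeries("R", -75.0, 100.0, times, temps)
        out = station_bioclim(stn, 2001)
        assert out["BIO7"] == pytest.approx(out["BIO5"] - out["BIO6"], abs=1e-12)

    def test_agrees_with_cube_pipeline_on_shared_cell(self, grid):
        cube = gen_climate_cube(grid, date(2001, 1, 1), date(2002, 1, 1),
                                SynthParams(noise_sd=1.0, seed=12))
        r, c = 2, 3
        truth = cube.cell_series(r, c)["temperature_K"] - 273.15
        stn = gen_station_series(truth, slope=1.0, intercept=0.0, noise_sd=0.0,
                                 lat=float(grid.lat_centers[r]),
                                 lon=float(grid.lon_centers[c]))
        from_station = station_bioclim(stn, 2001)
        clim = build_year_climatology(cube, 2001)
        from_cube = annual_bioclim(clim, version="mean")
        for name, value in from_station.items():
            assert value == pytest.approx(from_cube[name][r, c], rel=1e-12), name

    def test_insufficient_coverage_names_failing_months(self):
        times = pd.date_range("2001-01-01", "2001-11-01", freq="h", inclusive="left")
        stn = StationSeries("P", -64.0, -64.0, times, np.zeros(len(times)) + 1.0)
        with pytest.raises(ValueError, match="2001-11.*2001-12"):
            station_bioclim(stn, 2001)


class TestBufferZones:
    def test_single_buffer_geometry(self):
        bufs = buffer_zones([(10.0, 20.0)])
        assert bufs.union_area == pytest.approx(BUFFER_AREA_DEG2, abs=1e-9)
        minx, miny, maxx, maxy = bufs.union.bounds
        assert maxx - minx == pytest.approx(np.sqrt(1 / 3), abs=1e-9)

    def test_coincident_stations_not_double_counted(self):
        bufs = buffer_zones([(0.0, 0.0), (0.0, 0.0)])
        assert bufs.union_area == pytest.approx(BUFFER_AREA_DEG2, abs=1e-9)

    def test_high_latitude_buffer_clipped_at_pole(self):
        bufs = buffer_zones([(89.9, 0.0)])
        assert bufs.union_area < BUFFER_AREA_DEG2
        assert bufs.union.bounds[3] == pytest.approx(90.0)
        # the 82 N case from real station networks is not clipped
        assert buffer_zones([(82.0, 0.0)]).union_area == pytest.approx(BUFFER_AREA_DEG2)


class TestIqrOutliers:
    def test_all_equal_residuals_flag_nothing(self):
        assert not iqr_outliers(np.full(50, 3.3)).any()

    def test_hand_enumerated_fence(self):
        # sorted {1,2,3,4,100}: Q1=2, Q3=4, IQR=2, fences [-1, 7]
        mask = iqr_outliers(np.array([1.0, 2.0, 3.0, 4.0, 100.0]))
        np.testing.assert_array_equal(mask, [False, False, False, False, True])

    def test_normal_sample_flag_rate_matches_theory(self):
        rng = np.random.default_rng(7)
        flagged = iqr_outliers(rng.standard_normal(100_000)).mean()
        assert flagged == pytest.approx(0.007, abs=0.002)

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError, match="at least 4"):
            iqr_outliers(np.array([1.0, 2.0, 3.0]))


class TestRasterCompare:
    @pytest.fixture
    def scene(self):
        grid = GridSpec(n_rows=60, n_cols=80, lat_step=0.25, lon_step=0.25,
                        lat_origin=10.0, lon_origin=0.0)
        rng = np.random.default_rng(9)
        a = 15.0 + rng.normal(0, 3.0, grid.shape)
        stations = [(7.5 - 2.5 * i, 2.5 + 2.0 * j) for i in range(3) for j in range(4)]
        return grid, a, buffer_zones(stations)

    def test_identity_comparison(self, scene):
        grid, a, bufs = scene
        s, mask, frac = raster_compare(a, a, grid, bufs)
        assert s.pearson_r == pytest.approx(1.0)
        assert s.slope == pytest.approx(1.0)
        assert s.intercept == pytest.approx(0.0, abs=1e-9)
        assert not mask.any() and frac == 0.0

    def test_constant_shift_moves_intercept(self, scene):
        grid, a, bufs = scene
        s, mask, frac = raster_compare(a, a + 5.0, grid, bufs)
        assert s.slope == pytest.approx(1.0)
        assert s.intercept == pytest.approx(-5.0)
        assert not mask.any()

    def test_planted_outliers_recovered(self, scene):
        # outliers go into the response raster: predictor-side shifts of
        # this size are high-leverage points that bend the fit instead
        grid, b, bufs = scene
        rng = np.random.default_rng(10)
        a = b + rng.normal(0.0, 0.5, grid.shape)
        lat, lon = grid.cell_centers()
        import shapely
        inside = shapely.contains_xy(bufs.union, lon.ravel(), lat.ravel()).reshape(grid.shape)
        idx = np.argwhere(inside)
        n_plant = int(round(0.03 * len(idx)))
        chosen = idx[rng.choice(len(idx), n_plant, replace=False)]
        resid_iqr = np.subtract(*np.percentile((a - b)[inside], [75, 25])) * -1
        for r, c in chosen:
            a[r, c] += 10.0 * resid_iqr
        s, mask, frac = raster_compare(a, b, grid, bufs)
        flagged = {tuple(int(v) for v in rc) for rc in np.argwhere(mask)}
        planted = {tuple(int(v) for v in rc) for rc in chosen}
        assert planted <= flagged
        assert frac == pytest.approx(0.03, abs=0.02)

    def test_empty_buffers_rejected(self, scene):
        grid, a, _ = scene
        far = buffer_zones([(-80.0, 100.0)])
        with pytest.raises(ValueError, match="buffer"):
            raster_compare(a, a, grid, far)
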