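import numpy as np
import pytest

from humidclim import (
    MonthlyClimatology,
    annual_bioclim,
    apply_ecological_rescale,
    cyclic_windows,
    decadal_mean,
    gen_monthly_climatology,
    select_window,
)
from humidclim.bioclim import TEMPERATURE_VARIABLES, VARIABLE_NAMES

from conftest import random_climatologies
from oracles import bioclim_oracle


class TestCyclicWindows:
    def test_all_ones_sum_to_three(self):
        np.testing.assert_array_equal(cyclic_windows(np.ones(12)), np.full(12, 3.0))

    def test_single_impulse_wraps(self):
        v = np.zeros(12)
        v[0] = 1.0  # January
        w = cyclic_windows(v)
        # windows starting in Nov, Dec and Jan contain January
        np.testing.assert_array_equal(np.nonzero(w)[0] + 1, [1, 11, 12])
        assert w[[0, 10, 11]].tolist() == [1.0, 1.0, 1.0]

    def test_matches_modular_index_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            v = rng.normal(size=12)
            w = cyclic_windows(v)
            expected = [v[i] + v[(i + 1) % 12] + v[(i + 2) % 12] for i in range(12)]
            np.testing.assert_allclose(w, expected, rtol=1e-14)

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError, match="12"):
            cyclic_windows(np.ones(11))


class TestSelectWindow:
    def test_increasing_values_select_last(self):
        assert select_window(np.arange(1.0, 13.0), "max") == 12
        assert select_window(np.arange(1.0, 13.0), "min") == 1

    def test_tie_breaks_to_earliest_start(self):
        assert select_window(np.ones(12), "max") == 1
        assert select_window(np.ones(12), "min") == 1

    def test_matches_linear_scan_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            v = rng.integers(0, 5, 12).astype(float)  # ties likely
            for mode, cmp in (("max", lambda a, b: a > b), ("min", lambda a, b: a < b)):
                best = 0
                for i in range(1, 12):
                    if cmp(v[i], v[best]):
                        best = i
                assert select_window(v, mode) == best + 1


class TestAnnualBioclim:
    def test_constant_climatology_closed_forms(self, constant_clim):
        raw = annual_bioclim(constant_clim, version="mean", cv_offset=0.0)
        get = lambda n: raw[n][0, 0]
        assert get("BIO1") == 10.0
        assert get("BIO2") == 0.0
        assert get("BIO4") == 0.0
        assert get("BIO5") == 10.0 and get("BIO6") == 10.0 and get("BIO7") == 0.0
        assert np.isnan(get("BIO3"))
        assert get("BIO12") == pytest.approx(0.06)  # pre-rescale 12-month sum
        assert get("BIO13") == 0.005 and get("BIO14") == 0.005
        assert get("BIO15") == pytest.approx(0.0, abs=1e-9)
        rescaled = apply_ecological_rescale(raw)
        assert rescaled["BIO12"][0, 0] == pytest.approx(0.005)
        assert rescaled["BIO16"][0, 0] == pytest.approx(0.005)

    def test_annual_range_closure(self, toy_seasonal):
        bset = annual_bioclim(toy_seasonal, version="mean")
        np.testing.assert_allclose(bset["BIO7"], bset["BIO5"] - bset["BIO6"], rtol=0)

    def test_toy_seasonal_matches_independent_oracle(self, toy_seasonal):
        for version in ("min", "mean", "max"):
            bset = apply_ecological_rescale(annual_bioclim(toy_seasonal, version=version))
            expected = bioclim_oracle(
                toy_seasonal.tmin[:, 0, 0].tolist(),
                toy_seasonal.tmax[:, 0, 0].tolist(),
                toy_seasonal.moisture(version)[:, 0, 0].tolist(),
                rescaled=True,
            )
            for name in VARIABLE_NAMES:
                assert bset[name][0, 0] == pytest.approx(expected[name], rel=1e-12), name

    def test_missing_month_blanks_all_outputs(self, toy_seasonal):
        clim = MonthlyClimatology(
            grid=toy_seasonal.grid, year=0,
            tmin=toy_seasonal.tmin.copy(), tmax=toy_seasonal.tmax.copy(),
            hmin=toy_seasonal.hmin, hmean=toy_seasonal.hmean, hmax=toy_seasonal.hmax,
        )
        clim.tmin[4, 0, 0] = np.nan
        bset = annual_bioclim(clim, version="mean")
        assert all(np.isnan(bset[name][0, 0]) for name in VARIABLE_NAMES)

    def test_version_identity_of_temperature_variables(self):
        clim = random_climatologies(np.random.default_rng(2), 200)
        sets = {v: annual_bioclim(clim, version=v) for v in ("min", "mean", "max")}
        for name in TEMPERATURE_VARIABLES:
            np.testing.assert_array_equal(sets["min"][name], sets["mean"][name])
            np.testing.assert_array_equal(sets["mean"][name], sets["max"][name])

    def test_version_monotonicity_of_moisture_variables(self):
        clim = random_climatologies(np.random.default_rng(3), 200)
        sets = {v: apply_ecological_rescale(annual_bioclim(clim, version=v))
                for v in ("min", "mean", "max")}
        for name in ("BIO12", "BIO13", "BIO14", "BIO16", "BIO17", "BIO18", "BIO19"):
            assert np.all(sets["min"][name] <= sets["mean"][name] + 1e-15), name
            assert np.all(sets["mean"][name] <= sets["max"][name] + 1e-15), name

    def test_ordering_invariants_hold_on_random_cells(self):
        clim = random_climatologies(np.random.default_rng(4), 1000)
        bset = apply_ecological_rescale(annual_bioclim(clim, version="mean"))
        assert np.all(bset["BIO6"] <= bset["BIO1"])
        assert np.all(bset["BIO1"] <= bset["BIO5"])
        assert np.all(bset["BIO11"] <= bset["BIO1"] + 1e-12)
        assert np.all(bset["BIO1"] <= bset["BIO10"] + 1e-12)
        assert np.all(bset["BIO14"] <= bset["BIO12"] + 1e-15)
        assert np.all(bset["BIO12"] <= bset["BIO13"] + 1e-15)
        assert np.all(bset["BIO17"] <= bset["BIO12"] + 1e-15)
        assert np.all(bset["BIO12"] <= bset["BIO16"] + 1e-15)
        bio3 = bset["BIO3"]
        defined = np.isfinite(bio3)
        assert np.all(bio3[defined] >= 0) and np.all(bio3[defined] <= 100 + 1e-9)

    def test_month_rotation_covariance(self, toy_seasonal):
        """Rotating the month axis leaves the rotation-invariant variables
        unchanged and shifts selected window starts consistently."""
        base = apply_ecological_rescale(annual_bioclim(toy_seasonal, version="mean"))
        for shift in (1, 5, 11):
            rolled = MonthlyClimatology(
                grid=toy_seasonal.grid, year=0,
                **{f: np.roll(getattr(toy_seasonal, f), shift, axis=0)
                   for f in ("tmin", "tmax", "hmin", "hmean", "hmax")},
            )
            rot = apply_ecological_rescale(annual_bioclim(rolled, version="mean"))
            for name in [f"BIO{i}" for i in list(range(1, 8)) + list(range(10, 18))]:
                assert rot[name][0, 0] == pytest.approx(base[name][0, 0], rel=1e-12), name
            # window starts rotate with the months
            tavg = (rolled.tmin + rolled.tmax)[:, 0, 0] / 2
            base_tavg = (toy_seasonal.tmin + toy_seasonal.tmax)[:, 0, 0] / 2
            w_rot = select_window(cyclic_windows(tavg), "max")
            w_base = select_window(cyclic_windows(base_tavg), "max")
            assert (w_rot - 1) % 12 == (w_base - 1 + shift) % 12


class TestRescaleAndDecadalMean:
    def test_double_rescale_rejected(self, toy_seasonal):
        bset = apply_ecological_rescale(annual_bioclim(toy_seasonal, version="mean"))
        with pytest.raises(ValueError, match="already"):
            apply_ecological_rescale(bset)

    def test_mean_of_identical_sets_is_identity(self, toy_seasonal):
        bset = apply_ecological_rescale(annual_bioclim(toy_seasonal, version="mean"))
        dec = decadal_mean([bset] * 10, period="80s")
        for name in VARIABLE_NAMES:
            np.testing.assert_allclose(dec[name], bset[name], rtol=1e-15)
        assert dec.period == "80s"

    def test_mean_of_two_sets(self):
        a = apply_ecological_rescale(
            annual_bioclim(gen_monthly_climatology("constant", c=0.0, h=0.004), "mean"))
        b = apply_ecological_rescale(
            annual_bioclim(gen_monthly_climatology("constant", c=10.0, h=0.004), "mean"))
        dec = decadal_mean([a, b])
        assert dec["BIO1"][0, 0] == pytest.approx(5.0)

    def test_mean_commutes_with_annual_range_difference(self):
        rng = np.random.default_rng(5)
        sets = [annual_bioclim(random_climatologies(rng, 40), "mean") for _ in range(4)]
        dec = decadal_mean(sets)
        np.testing.assert_allclose(
            dec["BIO7"], dec["BIO5"] - dec["BIO6"], rtol=0, atol=1e-12
        )

    def test_mixed_versions_rejected(self, toy_seasonal):
        a = annual_bioclim(toy_seasonal, version="min")
        b = annual_bioclim(toy_seasonal, version="max")
        with pytest.raises(ValueError, match="version"):
            decadal_mean([a, b])
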