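"""Holdridge parameter computations and warming-level interpolation."""

import numpy as np
import pytest
import xarray as xr
from hypothesis import given, settings
from hypothesis import strategies as st

import cropscs as c
from cropscs.climate import _check_aligned

from conftest import const_monthly, monthly_from_values


class TestMonthlyMean:
    @pytest.mark.parametrize(
        "tmin, tmax, expected", [(10, 20, 15), (-5, 5, 0), (7, 7, 7)]
    )
    def test_midpoint(self, tmin, tmax, expected):
        result = c.monthly_mean_estimate(const_monthly(tmin), const_monthly(tmax))
        assert float(result.min()) == float(result.max()) == expected

    def test_misaligned_grids_rejected(self):
        with pytest.raises(ValueError, match="misaligned"):
            c.monthly_mean_estimate(
                const_monthly(0, shape=(2, 2)), const_monthly(1, shape=(3, 3))
            )


class TestBiasCorrection:
    def test_zero_bias_is_identity(self):
        est = const_monthly(12.0)
        ref_min, ref_max = const_monthly(5.0), const_monthly(15.0)
        ref_mean = const_monthly(10.0)  # exactly the midpoint -> zero bias
        out = c.bias_correct_tmean(est, ref_mean, ref_min, ref_max)
        assert np.allclose(out.values, est.values)

    def test_monthly_bias_added_per_month(self):
        est = const_monthly(12.0, shape=(1, 1))
        ref_min, ref_max = const_monthly(5.0, (1, 1)), const_monthly(15.0, (1, 1))
        ref_mean_vals = np.full(12, 10.0)
        ref_mean_vals[2] = 10.7  # month 3 runs 0.7 degC warm of the midpoint
        ref_mean = monthly_from_values(ref_mean_vals)
        out = c.bias_correct_tmean(est, ref_mean, ref_min, ref_max)
        assert out.values[2, 0, 0] == pytest.approx(12.7)
        assert np.allclose(np.delete(out.values, 2, axis=0), 12.0)

    def test_not_idempotent(self):
        est = const_monthly(12.0)
        ref_min, ref_max = const_monthly(5.0), const_monthly(15.0)
        ref_mean = const_monthly(10.5)  # bias +0.5
        once = c.bias_correct_tmean(est, ref_mean, ref_min, ref_max)
        twice = c.bias_correct_tmean(once, ref_mean, ref_min, ref_max)
        assert np.allclose(once.values, 12.5)
        assert np.allclose(twice.values, 13.0)


class TestAnnualPrecip:
    def test_constant_months(self):
        assert float(c.annual_precipitation(const_monthly(100.0)).max()) == 1200.0

    def test_zero(self):
        assert float(c.annual_precipitation(const_monthly(0.0)).max()) == 0.0

    def test_arithmetic_series(self):
        precip = monthly_from_values(np.arange(1, 13))
        assert float(c.annual_precipitation(precip).item()) == 78.0

    def test_negative_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            c.annual_precipitation(const_monthly(-1.0))


class TestBiotemperature:
    def test_constant_warm(self):
        assert float(c.biotemperature(const_monthly(20.0)).max()) == 20.0

    def test_subzero_months_clamped_divide_by_12(self):
        tmean = monthly_from_values([10.0] * 6 + [-10.0] * 6)
        assert float(c.biotemperature(tmean).item()) == pytest.approx(5.0)

    def test_all_subzero_is_zero(self):
        assert float(c.biotemperature(const_monthly(-3.0)).max()) == 0.0

    def test_optional_cap(self):
        assert float(c.biotemperature(const_monthly(35.0), cap=30.0).max()) == 30.0

    def test_monotone_under_warming(self, rng):
        tmean = c.monthly_climatology(rng.normal(5, 10, (12, 6, 6)))
        warmer = tmean + np.abs(rng.normal(0, 2, (12, 6, 6)))
        assert (c.biotemperature(warmer) >= c.biotemperature(tmean)).all()
        assert (c.annual_pet(warmer) >= c.annual_pet(tmean)).all()


class TestPET:
    def test_constant_twenty(self):
        assert float(c.annual_pet(const_monthly(20.0)).max()) == pytest.approx(1178.6)

    def test_all_subzero_is_zero(self):
        assert float(c.annual_pet(const_monthly(-5.0)).max()) == 0.0

    def test_ratio_is_holdridge_constant(self, rng):
        tmean = c.monthly_climatology(rng.normal(10, 12, (12, 8, 8)))
        pet = c.annual_pet(tmean)
        bt = c.biotemperature(tmean)
        positive = bt.values > 0
        ratio = pet.values[positive] / bt.values[positive]
        assert np.allclose(ratio, c.PET_PER_BIOTEMP, rtol=1e-9)


class TestAridity:
    def _field(self, value):
        return xr.DataArray(np.full((1, 1), float(value)), dims=("y", "x"))

    def test_ratio(self):
        assert float(c.aridity(self._field(1000), self._field(500)).item()) == 2.0

    def test_zero_pet(self):
        assert float(c.aridity(self._field(0), self._field(100)).item()) == 0.0

    def test_dry_limit_cap(self):
        out = c.aridity(self._field(500), self._field(0))
        assert float(out.item()) == 2.0**8

    def test_both_zero(self):
        assert float(c.aridity(self._field(0), self._field(0)).item()) == 0.0

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            c.aridity(self._field(-1), self._field(10))


class TestFrost:
    def test_all_above_zero(self):
        assert bool(c.frost_indicator(const_monthly(2.0)).all())

    def test_one_subzero_month(self):
        tmin = monthly_from_values([2.0] * 11 + [-0.1])
        assert not bool(c.frost_indicator(tmin).item())

    def test_exactly_zero_counts_as_frost(self):
        tmin = monthly_from_values([2.0] * 11 + [0.0])
        assert not bool(c.frost_indicator(tmin).item())


class TestWarmingInterpolation:
    def _spec(self, x, x0=2031, x1=2051):
        return c.WarmingLevelSpec(1.5, "SSP1-2.6", x, x0, x1)

    def test_endpoint_exact(self, rng):
        y0 = xr.DataArray(rng.normal(size=(4, 4)), dims=("y", "x"))
        y1 = xr.DataArray(rng.normal(size=(4, 4)), dims=("y", "x"))
        out = c.interpolate_warming_level(y0, y1, self._spec(x=2031))
        assert np.array_equal(out.values, y0.values)

    def test_midpoint_is_mean(self):
        y0 = xr.DataArray(np.full((2, 2), 4.0), dims=("y", "x"))
        y1 = xr.DataArray(np.full((2, 2), 8.0), dims=("y", "x"))
        out = c.interpolate_warming_level(y0, y1, self._spec(x=2041))
        assert np.allclose(out.values, 6.0)

    def test_published_crossing_year_example(self):
        # 1.5 degC level: centre years 2031/2051, crossing year 2033
        y0 = xr.DataArray(np.full((1, 1), 10.0), dims=("y", "x"))
        y1 = xr.DataArray(np.full((1, 1), 20.0), dims=("y", "x"))
        out = c.interpolate_warming_level(y0, y1, self._spec(x=2033))
        assert float(out.item()) == pytest.approx(11.0)

    def test_degenerate_years_rejected(self):
        with pytest.raises(ValueError):
            c.WarmingLevelSpec(2.0, "SSP2-4.5", 2053, 2051, 2051)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(x=st.floats(min_value=2031, max_value=2051))
    def test_matches_two_point_line(self, x):
        spec = self._spec(x=x)
        y0 = xr.DataArray(np.array([[3.0]]), dims=("y", "x"))
        y1 = xr.DataArray(np.array([[9.0]]), dims=("y", "x"))
        expected = np.interp(x, [2031, 2051], [3.0, 9.0])
        out = float(c.interpolate_warming_level(y0, y1, spec).item())
        assert out == pytest.approx(expected, abs=1e-12)


class TestComposedParams:
    def test_pet_identity_and_polar_zeros(self, world):
        params = world.baseline_params
        positive = params["biotemperature"].values > 0
        ratio = params["pet"].values[positive] / params["biotemperature"].values[positive]
        assert np.allclose(ratio, c.PET_PER_BIOTEMP, rtol=1e-9)
        frozen = ~positive
        assert np.all(params["pet"].values[frozen] == 0.0)
        assert np.all(params["aridity"].values[frozen] == 0.0)

    def test_equatorial_cells_are_humid(self, world):
        # the generator's wet-equator band keeps aridity below 1 there
        rows = world.config.grid_rows
        eq = slice(rows // 2 - 2, rows // 2 + 2)
        aridity = world.baseline_params["aridity"].values[eq, :]
        assert np.median(aridity) < 1.0


class TestHLZClassification:
    def _params(self, bt, precip, frost):
        bt = np.atleast_2d(bt).astype(float)
        return xr.Dataset(
            {
                "biotemperature": (("y", "x"), bt),
                "annual_precip": (("y", "x"), np.atleast_2d(precip).astype(float)),
                "pet": (("y", "x"), bt * c.PET_PER_BIOTEMP),
                "aridity": (
                    ("y", "x"),
                    bt * c.PET_PER_BIOTEMP / np.maximum(np.atleast_2d(precip), 1e-9),
                ),
                "frost_free": (("y", "x"), np.atleast_2d(frost).astype(bool)),
            }
        )

    def test_exactly_38_zones_over_dense_sweep(self):
        bt = np.concatenate([[0.1], np.geomspace(0.5, 40, 60)])
        pr = np.concatenate([[10.0], np.geomspace(50, 20000, 60)])
        btg, prg = np.meshgrid(bt, pr)
        labels = set()
        for frost in (False, True):
            zones = c.hlz_classify(
                self._params(btg, prg, np.full(btg.shape, frost))
            ).values
            labels |= set(np.unique(zones).tolist())
        assert labels == set(range(1, 39))

    def test_identical_params_identical_zone(self):
        zones = c.hlz_classify(self._params([[10.0, 10.0]], [[600, 600]], [[0, 0]]))
        assert zones.values[0, 0] == zones.values[0, 1]

    def test_half_open_boundaries(self):
        # a biotemperature exactly on a class edge belongs to the upper class
        below = c.hlz_classify(self._params([[2.999]], [[300]], [[0]])).values[0, 0]
        on_edge = c.hlz_classify(self._params([[3.0]], [[300]], [[0]])).values[0, 0]
        assert below == 4  # subpolar wet tundra
        assert on_edge == 8  # boreal moist forest
        pr_edge = c.hlz_classify(self._params([[10.0]], [[250.0]], [[0]])).values[0, 0]
        pr_below = c.hlz_classify(self._params([[10.0]], [[249.9]], [[0]])).values[0, 0]
        assert pr_below == 12 and pr_edge == 13

    def test_frost_separates_temperate_from_subtropical(self):
        frosty = c.hlz_classify(self._params([[18.0]], [[1500]], [[0]])).values[0, 0]
        frost_free = c.hlz_classify(self._params([[18.0]], [[1500]], [[1]])).values[0, 0]
        assert frosty == 21   # warm temperate moist forest
        assert frost_free == 28  # subtropical moist forest

    def test_nonfinite_unclassified(self):
        zones = c.hlz_classify(self._params([[np.nan]], [[500]], [[0]]))
        assert zones.values[0, 0] == 0


def test_default_warming_level_table():
    levels = c.default_warming_levels()
    assert [s.level for s in levels] == [1.5, 2, 3, 4]
    first = levels[0]
    assert (first.x0, first.x, first.x1) == (2031, 2033, 2051)
    for spec in levels:
        assert spec.x0 < spec.x1 and spec.x0 <= spec.x <= spec.x1


def test_alignment_checker_rejects_shifted_coords():
    a = xr.DataArray(np.zeros((2, 2)), dims=("y", "x"), coords={"y": [0, 1], "x": [0, 1]})
    b = xr.DataArray(np.zeros((2, 2)), dims=("y", "x"), coords={"y": [0, 1], "x": [1, 2]})
    with pytest.raises(ValueError, match="misaligned"):
        _check_aligned(a, b)
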