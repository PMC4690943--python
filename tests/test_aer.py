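"""Leakage-area and infiltration model: hand-calculation oracles, monotonicity."""

import numpy as np
import pandas as pd
import pytest

import airtier as at
from airtier.aer import (
    DENSITY_CUTOFFS,
    LeakageCoefficients,
    T_IN_DEFAULT,
    assign_stories,
    building_height,
    house_volume_liters,
)


class TestHousingFilter:
    def test_all_below_threshold_unchanged(self):
        houses = pd.DataFrame({"a_floor_m2": [100.0, 200.0, 600.0]})
        out = at.filter_housing_stock(houses, max_floor_area=650.3)
        assert len(out) == 3

    def test_exact_threshold_retained(self):
        houses = pd.DataFrame({"a_floor_m2": [650.3, 650.30001]})
        out = at.filter_housing_stock(houses, max_floor_area=650.3)
        assert list(out["a_floor_m2"]) == [650.3]

    def test_mixed_toy_set(self):
        areas = [100, 200, 300, 400, 500, 600, 640, 700, 800, 900.0]
        out = at.filter_housing_stock(pd.DataFrame({"a_floor_m2": areas}),
                                      max_floor_area=650.3)
        assert len(out) == 7


class TestStoriesAndGeometry:
    def test_one_story_below_threshold(self):
        assert assign_stories(150.0) == 1
        assert building_height(1) == pytest.approx(3.0)

    def test_two_stories_at_or_above(self):
        assert assign_stories(1000.0) == 2
        assert assign_stories(1200.0) == 2
        assert building_height(2) == pytest.approx(5.5)

    def test_threshold_configurable(self):
        assert assign_stories(300.0, area_threshold=250.0) == 2
        assert assign_stories(300.0, area_threshold=350.0) == 1

    def test_volume(self):
        assert house_volume_liters(150.0, 1) == pytest.approx(375_000.0)


class TestNormalizedLeakage:
    def test_hand_value_conventional_home(self):
        # exp(20.7 - 0.0107*2000 - 0.00220*150)
        nl = at.normalized_leakage(2000, 150.0, income_low=False)
        assert nl == pytest.approx(np.exp(20.7 - 0.0107 * 2000 - 0.0022 * 150), rel=1e-12)
        assert nl == pytest.approx(0.357, abs=5e-4)

    def test_newer_homes_are_tighter(self):
        older = at.normalized_leakage(1900, 150.0, False)
        newer = at.normalized_leakage(2000, 150.0, False)
        assert newer < older

    def test_income_class_switches_coefficients(self):
        low = at.normalized_leakage(1980, 120.0, True)
        conv = at.normalized_leakage(1980, 120.0, False)
        assert low != conv


class TestLeakageArea:
    def test_reference_height_simplification(self):
        # at H = 2.5 m the height factor is 1: A_inf = 10 * NL * A_floor cm^2
        assert at.leakage_area(0.5, 100.0, 2.5) == pytest.approx(500.0, rel=1e-12)

    def test_hand_value_two_story(self):
        # unit-tracked: 0.357 * 150 m^2 / (1000*(5.5/2.5)^0.3) -> m^2 -> cm^2
        a = at.leakage_area(0.357, 150.0, 5.5)
        expected_m2 = 0.357 * 150.0 / (1000.0 * (5.5 / 2.5) ** 0.3)
        assert a == pytest.approx(expected_m2 * 1e4, rel=1e-12)
        assert a == pytest.approx(422.6, abs=0.5)

    def test_height_exponent_recovered_by_regression(self):
        h = np.linspace(2.5, 9.0, 40)
        a = at.leakage_area(0.4, 150.0, h)
        slope = np.polyfit(np.log(h), np.log(a), 1)[0]
        assert slope == pytest.approx(-0.3, abs=1e-6)

    def test_nonpositive_height_rejected(self):
        with pytest.raises(ValueError):
            at.leakage_area(0.4, 150.0, 0.0)


class TestInfiltrationFlow:
    def test_no_drivers_no_flow(self):
        assert at.infiltration_flow(500.0, 1.45e-4, 1.04e-4, 20.0, 20.0, 0.0) == 0.0

    def test_hand_value(self):
        # 500 cm^2, |dT| = 10 K, U = 3 m/s
        q = at.infiltration_flow(500.0, 1.45e-4, 1.04e-4, 20.0, 10.0, 3.0)
        assert q == pytest.approx(500 * np.sqrt(1.45e-3 + 9.36e-4), rel=1e-12)
        assert q == pytest.approx(24.4, abs=0.05)

    def test_linear_in_leakage_area(self):
        q1 = at.infiltration_flow(250.0, 1.45e-4, 1.04e-4, 23.6, 10.0, 3.0)
        q2 = at.infiltration_flow(500.0, 1.45e-4, 1.04e-4, 23.6, 10.0, 3.0)
        assert q2 == pytest.approx(2 * q1, rel=1e-12)

    @pytest.mark.parametrize("driver", ["wind", "stack"])
    def test_monotone_in_drivers(self, driver):
        base = at.infiltration_flow(500.0, 1.45e-4, 1.04e-4, 23.6, 15.0, 2.0)
        if driver == "wind":
            more = at.infiltration_flow(500.0, 1.45e-4, 1.04e-4, 23.6, 15.0, 4.0)
        else:
            more = at.infiltration_flow(500.0, 1.45e-4, 1.04e-4, 23.6, 5.0, 2.0)
        assert more > base


class TestAirExchangeRate:
    def test_zero_flow(self):
        assert at.air_exchange_rate(0.0, 375_000.0) == 0.0

    def test_hand_value(self):
        # 24.4 L/s into a 150 m^2 single-story house (375 m^3)
        assert at.air_exchange_rate(24.4, 375_000.0) == pytest.approx(0.234, abs=5e-4)

    def test_halves_with_double_volume(self):
        a1 = at.air_exchange_rate(24.4, 375_000.0)
        a2 = at.air_exchange_rate(24.4, 750_000.0)
        assert a2 == pytest.approx(a1 / 2, rel=1e-12)

    def test_nonpositive_volume_rejected(self):
        with pytest.raises(ValueError):
            at.air_exchange_rate(10.0, 0.0)


class TestShelterClass:
    def test_below_first_cutoff_most_exposed(self):
        assert at.shelter_class_from_density(10.0) == 1

    def test_cutoff_boundary_goes_to_higher_class(self):
        assert at.shelter_class_from_density(DENSITY_CUTOFFS[0]) == 2

    def test_three_cutoffs_give_four_reachable_classes(self):
        cutoffs = (100.0, 500.0, 1500.0)
        classes = {at.shelter_class_from_density(d, cutoffs)
                   for d in np.linspace(0, 3000, 400)}
        assert classes == {1, 2, 3, 4}

    def test_nonincreasing_cutoffs_rejected(self):
        with pytest.raises(ValueError):
            at.shelter_class_from_density(10.0, (100.0, 100.0))


class TestBlockAer:
    def _setup(self, n_houses, same=True, seed=0):
        hours = pd.date_range("2012-01-01", periods=24, freq="h")
        rng = np.random.default_rng(seed)
        houses = pd.DataFrame({
            "house_id": [f"h{i}" for i in range(n_houses)],
            "block_id": "b0",
            "a_floor_m2": 150.0 if same else rng.uniform(80, 400, n_houses),
            "y_built": 1980 if same else rng.integers(1900, 2015, n_houses),
            "stories": 1,
            "income_low": False,
        })
        blocks = pd.DataFrame({"block_id": ["b0"], "x_km": [0.0], "y_km": [0.0],
                               "house_density": [300.0]})
        met = pd.DataFrame({
            "station_id": "m0", "x_km": 0.0, "y_km": 0.0, "hour": hours,
            "wind_speed": rng.uniform(1, 6, 24), "wind_dir": 0.0,
            "t_out": rng.uniform(0, 15, 24), "stability": "D",
        })
        return houses, blocks, met, hours

    def test_identical_houses_equal_single_house_aer(self):
        houses, blocks, met, hours = self._setup(25, same=True)
        full = at.block_aer(houses, blocks, met, hours, seed=1)
        single = at.block_aer(houses.iloc[:1], blocks, met, hours, seed=1)
        np.testing.assert_allclose(full["aer_per_h"], single["aer_per_h"], rtol=1e-12)
        assert (full["n_houses"] == 10).all()

    def test_sampling_once_per_block_and_deterministic(self):
        houses, blocks, met, hours = self._setup(25, same=False)
        a = at.block_aer(houses, blocks, met, hours, seed=5)
        b = at.block_aer(houses, blocks, met, hours, seed=5)
        pd.testing.assert_frame_equal(a, b)
        # one fixed 10-house subset: the hourly series is a smooth function of
        # met only, so the house-mean leakage term is constant across hours
        aer = a["aer_per_h"].to_numpy()
        m = met.set_index("hour").loc[hours]
        drivers = np.sqrt(
            1.45e-4 * np.abs(T_IN_DEFAULT - m["t_out"].to_numpy())
            + at.LeakageCoefficients().k_w(1, 3) * m["wind_speed"].to_numpy() ** 2
        )
        ratio = aer / drivers
        assert np.ptp(ratio) / ratio.mean() < 1e-9

    def test_aer_nonnegative_and_wind_monotone(self):
        houses, blocks, met, hours = self._setup(10, same=True)
        met = met.assign(t_out=T_IN_DEFAULT)  # isolate wind driver
        calm = at.block_aer(houses, blocks, met.assign(wind_speed=1.0), hours, seed=0)
        windy = at.block_aer(houses, blocks, met.assign(wind_speed=5.0), hours, seed=0)
        assert (calm["aer_per_h"] >= 0).all()
        assert (windy["aer_per_h"] > calm["aer_per_h"]).all()

    def test_newer_stock_has_lower_aer(self):
        houses, blocks, met, hours = self._setup(10, same=True)
        new = at.block_aer(houses.assign(y_built=2010), blocks, met, hours, seed=0)
        old = at.block_aer(houses.assign(y_built=1940), blocks, met, hours, seed=0)
        assert (new["aer_per_h"] < old["aer_per_h"]).all()

    def test_empty_block_falls_back_to_default_house(self):
        houses, blocks, met, hours = self._setup(5)
        empty = houses.iloc[0:0]
        out = at.block_aer(empty, blocks, met, hours, seed=0)
        assert len(out) == len(hours)
        assert (out["aer_per_h"] > 0).any()
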