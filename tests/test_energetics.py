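"""Energetics: coefficient table, event costing, daily aggregation."""

from datetime import datetime

import numpy as np
import pytest

from sealteb.energetics import (
    DEFAULT_COEFFICIENTS,
    EnergyCoefficients,
    budgets_to_frame,
    coefficient,
    daily_budgets,
    effective_behaviour,
    event_energy,
    litres_to_mj,
)
from sealteb.segmentation import BehaviourEvent


def brute_force_dee_l_o2(events, mass_kg, coeffs=DEFAULT_COEFFICIENTS):
    """Second-by-second integration oracle: rate/60 litres per second."""
    total = 0.0
    for ev in events:
        rate = coefficient(
            effective_behaviour(ev), ev.location, ev.season,
            ev.water_temp_c, coeffs,
        )
        for _ in range(int(round(ev.end_s - ev.start_s))):
            total += rate / 60.0 * mass_kg
    return total


class TestCoefficientTable:
    def test_rest_land_rates_from_their_construction(self):
        c = EnergyCoefficients()
        assert c.rest_land["winter"] == pytest.approx(0.7 * 0.007)
        assert c.rest_land["winter"] == pytest.approx(0.0049)
        assert c.rest_land["summer"] == pytest.approx(0.7 * 0.009)
        assert c.rest_land["summer"] == pytest.approx(0.0063)

    def test_grooming_rates_from_their_construction(self):
        c = EnergyCoefficients()
        assert c.groom_water["winter"] == pytest.approx(2 * 0.007)
        assert c.groom_water["winter"] == pytest.approx(0.014)
        assert c.groom_water["summer"] == pytest.approx(2 * 0.009)
        assert c.groom_water["summer"] == pytest.approx(0.018)
        assert c.groom_land == {"winter": 0.007, "summer": 0.009}

    def test_land_activity_doubles_water_activity(self):
        c = EnergyCoefficients()
        assert c.active_land == pytest.approx(2 * 0.0303)
        assert c.active_land == pytest.approx(0.0606)

    def test_resting_in_water_temperature_rule(self):
        # full-precision coefficients, not the rounded display values
        assert coefficient("resting", "water", "winter", 15.0) == pytest.approx(
            1.6 * (0.00195 + 0.00029 * 15.0)
        )
        assert coefficient("resting", "water", "winter", 15.0) == pytest.approx(0.01008)

    def test_lookup_rules(self):
        assert coefficient("resting", "land", "winter") == pytest.approx(0.0049)
        assert coefficient("foraging", "land", "winter") == pytest.approx(0.0606)
        assert coefficient("travelling", "land", "summer") == pytest.approx(0.0606)
        # surface and underwater share water rates
        assert coefficient("grooming", "surface", "winter") == pytest.approx(0.014)
        assert coefficient("grooming", "underwater", "winter") == pytest.approx(0.014)
        # no season effect on activity in water
        assert coefficient("travelling", "water", "winter") == coefficient(
            "travelling", "water", "summer"
        )

    def test_rejections(self):
        with pytest.raises(ValueError, match="water_temp_c"):
            coefficient("resting", "water", "winter")
        with pytest.raises(ValueError, match="behaviour"):
            coefficient("sleeping", "land", "winter")
        with pytest.raises(ValueError, match="location"):
            coefficient("resting", "sky", "winter")
        with pytest.raises(ValueError, match="season"):
            coefficient("resting", "land", "spring")

    def test_out_of_range_temperature_warns_not_errors(self):
        with pytest.warns(UserWarning, match="extrapolating"):
            coefficient("resting", "water", "winter", 30.0)

    def test_nonpositive_coefficients_rejected(self):
        with pytest.raises(ValueError):
            EnergyCoefficients(active_water=0.0)

    def test_season_ordering_on_land(self):
        c = EnergyCoefficients()
        assert c.rest_land["summer"] > c.rest_land["winter"]


class TestEventEnergy:
    def test_resting_on_land_arithmetic(self):
        ev = BehaviourEvent("resting", "land", 0, 100 * 60, season="winter")
        assert event_energy(ev, 50.0) == pytest.approx(0.0049 * 100 * 50)
        assert event_energy(ev, 50.0) == pytest.approx(24.5)

    def test_foraging_on_land_costed_as_travelling(self):
        ev = BehaviourEvent("foraging", "land", 0, 600, season="winter")
        assert effective_behaviour(ev) == "travelling"
        assert event_energy(ev, 50.0) == pytest.approx(0.0606 * 10 * 50)
        assert event_energy(ev, 50.0) == pytest.approx(30.3)

    def test_linearity_in_mass_and_duration(self):
        ev1 = BehaviourEvent("grooming", "surface", 0, 600, "summer", 18.0)
        ev2 = BehaviourEvent("grooming", "surface", 0, 1200, "summer", 18.0)
        assert event_energy(ev1, 60.0) == pytest.approx(2 * event_energy(ev1, 30.0))
        assert event_energy(ev2, 30.0) == pytest.approx(2 * event_energy(ev1, 30.0))

    def test_nonpositive_mass_rejected(self):
        ev = BehaviourEvent("resting", "land", 0, 60, season="winter")
        with pytest.raises(ValueError):
            event_energy(ev, 0.0)


class TestUnitConversion:
    def test_zero(self):
        assert litres_to_mj(0.0) == 0.0

    def test_one_litre(self):
        assert litres_to_mj(1.0) == pytest.approx(0.02093)

    def test_full_day_resting_land_winter_chain(self):
        # 50 kg for 1440 min at 0.0049 -> 352.8 l -> 7.384 MJ
        litres = 0.0049 * 1440 * 50
        assert litres == pytest.approx(352.8)
        assert litres_to_mj(litres) == pytest.approx(7.384, abs=5e-4)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            litres_to_mj(-1.0)


class TestDailyBudgets:
    def test_event_straddling_midnight_is_prorated(self):
        start = datetime(2014, 7, 1, 23, 50, 0)
        ev = BehaviourEvent("resting", "land", 0, 1200, season="winter")
        budgets = daily_budgets([ev], 50.0, start=start)
        assert len(budgets) == 2
        m0 = sum(budgets[0].minutes.values())
        m1 = sum(budgets[1].minutes.values())
        assert m0 == pytest.approx(10.0)
        assert m1 == pytest.approx(10.0)
        assert budgets[0].date == "2014-07-01"
        assert budgets[1].date == "2014-07-02"

    def test_known_composition_closed_form(self):
        # 720 min resting-land-winter + 720 min active-water at 50 kg
        events = [
            BehaviourEvent("resting", "land", 0, 720 * 60, season="winter"),
            BehaviourEvent("travelling", "surface", 720 * 60, 1440 * 60,
                           season="winter", water_temp_c=14.0),
        ]
        (b,) = daily_budgets(events, 50.0)
        expected_l = (0.0049 * 720 + 0.0303 * 720) * 50
        assert b.dee_l_o2 == pytest.approx(expected_l)
        assert b.dee_l_o2 == pytest.approx(1267.2)
        assert b.dee_mj == pytest.approx(26.52, abs=0.01)
        assert b.complete

    def test_decomposition_conserves_totals(self, rng):
        events = _random_events(rng, 6 * 3600)
        budgets = daily_budgets(events, 40.0)
        for b in budgets:
            assert sum(b.litres.values()) == pytest.approx(b.dee_l_o2, abs=1e-9)
            assert b.mass_specific_dee_mj_per_kg == pytest.approx(b.dee_mj / 40.0)

    def test_overlapping_events_rejected(self):
        events = [
            BehaviourEvent("resting", "land", 0, 100, season="winter"),
            BehaviourEvent("grooming", "land", 50, 150, season="winter"),
        ]
        with pytest.raises(ValueError, match="overlap"):
            daily_budgets(events, 50.0)

    def test_incomplete_day_flagged(self):
        ev = BehaviourEvent("resting", "land", 0, 3600, season="winter")
        (b,) = daily_budgets([ev], 50.0)
        assert not b.complete

    def test_matches_per_second_integration_oracle(self, rng):
        for _ in range(20):
            events = _random_events(rng, int(rng.integers(3600, 48 * 3600)))
            budgets = daily_budgets(events, 35.0)
            total = sum(b.dee_l_o2 for b in budgets)
            oracle = brute_force_dee_l_o2(events, 35.0)
            assert total == pytest.approx(oracle, rel=1e-6)

    def test_budget_frame_columns(self, rng):
        events = _random_events(rng, 7200)
        frame = budgets_to_frame(daily_budgets(events, 50.0))
        assert "dee_mj" in frame.columns
        assert "min_active_surface" in frame.columns
        # frame decomposition also conserves
        mj_cols = [c for c in frame.columns if c.startswith("mj_")]
        np.testing.assert_allclose(
            frame[mj_cols].sum(axis=1), frame["dee_mj"], atol=1e-9
        )


def _random_events(rng, total_s):
    """Random contiguous event sequence covering [0, total_s]."""
    behaviours = ["foraging", "travelling", "grooming", "resting"]
    locations = ["land", "surface", "underwater"]
    events = []
    t = 0
    while t < total_s:
        dur = int(rng.integers(60, 7200))
        dur = min(dur, total_s - t)
        loc = str(rng.choice(locations))
        events.append(
            BehaviourEvent(
                behaviour=str(rng.choice(behaviours)),
                location=loc,
                start_s=t, end_s=t + dur, season="winter",
                water_temp_c=float(rng.uniform(8, 20)) if loc != "land" else None,
            )
        )
        t += dur
    return events


def test_dee_monotone_in_activity_fraction():
    """For a fixed day, shifting time from resting to activity never
    lowers DEE (active > grooming > resting rates below 26 degC)."""
    mass = 50.0
    prev = -1.0
    for active_min in (0, 240, 480, 720, 960, 1200, 1440):
        rest_min = 1440 - active_min
        events = []
        if active_min:
            events.append(
                BehaviourEvent("travelling", "surface", 0, active_min * 60,
                               season="winter", water_temp_c=14.0)
            )
        if rest_min:
            events.append(
                BehaviourEvent("resting", "surface", active_min * 60, 86400,
                               season="winter", water_temp_c=14.0)
            )
        (b,) = daily_budgets(events, mass)
        assert b.dee_mj > prev
        prev = b.dee_mj
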