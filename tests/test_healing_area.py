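"""Healing trajectories and closed-form time-averaged exposure areas.

The closed forms are cross-checked against dense numeric quadrature of the
instantaneous areas (the independent oracle for the time averages).
"""

import dataclasses
import math

import numpy as np
import pytest

from fissureflux.catalog_io import EarthquakeEvent
from fissureflux.fissure_scaling import FissureGeometry, geometry_for_event
from fissureflux.healing_area import (
    AreaBudget,
    catalog_area_budget,
    instantaneous_areas,
    length_at_age,
    time_averaged_areas,
    width_at_age,
)
from fissureflux.model_config import ModelConstants

T_REC = 942 / 0.49  # default per-fissure recovery time, a


def make_geometry(l0=615126.0, w0=1.5):
    return FissureGeometry(
        initial_total_length_m=l0,
        initial_width_m=w0,
        rupture_length_km=48.06,
        recovery_time_a=T_REC,
    )


def quadrature_areas(geometry, elapsed, constants, n_steps=100_000):
    """Independent oracle: trapezoid quadrature of the instantaneous areas."""
    t = np.linspace(0.0, elapsed, n_steps + 1)
    sidewall = np.empty_like(t)
    bottom = np.empty_like(t)
    for i, ti in enumerate(t):
        sidewall[i], bottom[i] = instantaneous_areas(geometry, float(ti), constants)
    return (
        float(np.trapezoid(sidewall, t) / elapsed),
        float(np.trapezoid(bottom, t) / elapsed),
    )


class TestTrajectories:
    def test_length_initial_and_fully_healed(self, constants):
        geometry = make_geometry()
        assert length_at_age(geometry, 0.0, constants) == 615126.0
        assert length_at_age(geometry, T_REC, constants) == 0.0
        assert length_at_age(geometry, 2 * T_REC, constants) == 0.0

    def test_length_linear_midpoint(self, constants):
        geometry = make_geometry()
        assert length_at_age(geometry, T_REC / 2, constants) == pytest.approx(
            307563, abs=1
        )

    def test_width_widens_then_vanishes_at_recovery(self, constants):
        geometry = make_geometry(w0=1.304)
        assert width_at_age(geometry, 0.0, constants) == 1.304
        assert width_at_age(geometry, 10.0, constants) == pytest.approx(1.804)
        assert width_at_age(geometry, T_REC, constants) == 0.0

    def test_total_length_mode_recovery_scales_with_event(self, constants):
        geometry = make_geometry(l0=1000.0)
        # total-length reading: the whole 1000 m heals at 0.49 m/a
        t_rec_total = 1000.0 / 0.49
        assert length_at_age(
            geometry, t_rec_total, constants, mode="total_length"
        ) == pytest.approx(0.0, abs=1e-9)
        assert length_at_age(
            geometry, 100.0, constants, mode="total_length"
        ) == pytest.approx(1000.0 - 0.49 * 100.0)

    def test_zero_healing_rates_freeze_geometry(self):
        constants = ModelConstants(length_heal_rate_rL=0.0, width_widen_rate_rW=0.0)
        geometry = make_geometry()
        assert length_at_age(geometry, 1e6, constants) == 615126.0
        assert width_at_age(geometry, 1e6, constants) == 1.5


class TestInstantaneousAreas:
    def test_sidewall_is_both_walls_times_depth(self, constants):
        geometry = make_geometry()
        sidewall, _ = instantaneous_areas(geometry, 0.0, constants)
        assert sidewall == pytest.approx(2 * 3.0 * 615126)  # 3,690,756 m^2

    def test_unit_case(self, constants):
        geometry = FissureGeometry(1.0, 2.0, 1.0, T_REC)
        assert instantaneous_areas(geometry, 0.0, constants) == (6.0, 2.0)

    def test_after_recovery_both_zero(self, constants):
        geometry = make_geometry()
        assert instantaneous_areas(geometry, T_REC + 1, constants) == (0.0, 0.0)


class TestTimeAveragedAreas:
    def test_constant_geometry_limit(self):
        constants = ModelConstants(length_heal_rate_rL=0.0, width_widen_rate_rW=0.0)
        geometry = make_geometry(w0=1.304)
        budget = time_averaged_areas(geometry, 5000.0, constants)
        assert budget.sidewall_area_m2 == pytest.approx(2 * 3.0 * 615126)
        assert budget.bottom_area_m2 == pytest.approx(615126 * 1.304)

    def test_short_elapsed_time_approaches_initial_area(self, constants):
        geometry = make_geometry()
        budget = time_averaged_areas(geometry, 1e-6, constants)
        assert budget.sidewall_area_m2 == pytest.approx(
            2 * 3.0 * 615126, rel=1e-4
        )

    def test_full_recovery_window_averages_half_initial_sidewall(self, constants):
        geometry = make_geometry()
        budget = time_averaged_areas(geometry, T_REC, constants)
        assert budget.sidewall_area_m2 == pytest.approx(3.0 * 615126, rel=1e-12)

    def test_nonpositive_elapsed_rejected(self, constants):
        with pytest.raises(ValueError):
            time_averaged_areas(make_geometry(), 0.0, constants)

    @pytest.mark.parametrize("seed", [0, 1])
    def test_matches_numeric_quadrature(self, constants, seed):
        rng = np.random.default_rng(seed)
        for _ in range(10):
            geometry = make_geometry(
                l0=float(rng.uniform(1e3, 1e6)), w0=float(rng.uniform(0.1, 5.0))
            )
            elapsed = float(rng.uniform(1.0, 3000.0))
            budget = time_averaged_areas(geometry, elapsed, constants)
            sw_q, sb_q = quadrature_areas(geometry, elapsed, constants, n_steps=20_000)
            assert budget.sidewall_area_m2 == pytest.approx(sw_q, rel=1e-6)
            assert budget.bottom_area_m2 == pytest.approx(sb_q, rel=1e-6)

    def test_sidewall_average_nonincreasing_in_elapsed_time(self, constants):
        geometry = make_geometry()
        times = np.linspace(1.0, 4000.0, 50)
        values = [
            time_averaged_areas(geometry, float(t), constants).sidewall_area_m2
            for t in times
        ]
        assert all(a >= b - 1e-9 for a, b in zip(values, values[1:]))

    def test_areas_stay_positive_for_finite_elapsed(self, constants):
        geometry = make_geometry()
        budget = time_averaged_areas(geometry, 10 * T_REC, constants)
        assert budget.sidewall_area_m2 > 0
        assert budget.bottom_area_m2 > 0


class TestAreaBudgetInvariants:
    def test_total_must_be_component_sum(self):
        with pytest.raises(ValueError):
            AreaBudget(1.0, 1.0, 3.0, 1.0)

    def test_negative_area_rejected(self):
        with pytest.raises(ValueError):
            AreaBudget(-1.0, 1.0, 0.0, 1.0)


class TestCatalogAreaBudget:
    def test_empty_catalog_all_zero(self, constants):
        total, per_event = catalog_area_budget([], constants)
        assert total.sidewall_area_m2 == 0.0
        assert total.bottom_area_m2 == 0.0
        assert per_event == []

    def test_duplicate_event_doubles_totals(self, constants):
        event = EarthquakeEvent("a", 2000, 7.0)
        single, _ = catalog_area_budget([event], constants)
        double, _ = catalog_area_budget([event, event], constants)
        assert double.sidewall_area_m2 == pytest.approx(2 * single.sidewall_area_m2)
        assert double.bottom_area_m2 == pytest.approx(2 * single.bottom_area_m2)

    def test_totals_are_sums_of_single_event_budgets(self, constants):
        events = [
            EarthquakeEvent("a", 2000, 7.0),
            EarthquakeEvent("b", 1900, 7.5),
        ]
        total, per_event = catalog_area_budget(events, constants)
        singles = [catalog_area_budget([e], constants)[0] for e in events]
        assert total.sidewall_area_m2 == pytest.approx(
            sum(s.sidewall_area_m2 for s in singles)
        )
        assert total.bottom_area_m2 == pytest.approx(
            sum(s.bottom_area_m2 for s in singles)
        )
        assert [b.elapsed_a for _, b in per_event] == [22.0, 122.0]

    def test_permutation_invariance(self, constants):
        events = [
            EarthquakeEvent("a", 2000, 7.0),
            EarthquakeEvent("b", 1900, 7.5),
            EarthquakeEvent("c", -325, 8.0),
        ]
        forward, _ = catalog_area_budget(events, constants)
        backward, _ = catalog_area_budget(list(reversed(events)), constants)
        assert forward.sidewall_area_m2 == pytest.approx(backward.sidewall_area_m2)
        assert forward.bottom_area_m2 == pytest.approx(backward.bottom_area_m2)

    def test_event_after_reference_year_rejected(self, constants):
        future = EarthquakeEvent("f", 2030, 7.0)
        with pytest.raises(ValueError, match="reference year"):
            catalog_area_budget([future], constants)

    def test_reference_year_event_contributes_initial_areas(self, constants):
        event = EarthquakeEvent("now", 2022, 7.0)
        total, per_event = catalog_area_budget([event], constants)
        geometry = geometry_for_event(event, constants)
        sw0, sb0 = instantaneous_areas(geometry, 0.0, constants)
        assert total.sidewall_area_m2 == pytest.approx(sw0)
        assert total.bottom_area_m2 == pytest.approx(sb0)
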