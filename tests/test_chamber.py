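"""Forward-model tests: TEF kernel, activity term, fasting decline, chamber ODE."""
import numpy as np
import pytest

from calorpart.chamber import (
    ChamberSpec,
    FastingDayParameters,
    FedDayParameters,
    ManualEvent,
    SimulationError,
    activity_gas_rate,
    fasting_decline,
    simulate_chamber_day,
    steady_state_fractions,
    tef_response,
)
from calorpart.traces import SignalTrace

from conftest import DT, N, impulse_feed


class TestTefResponse:
    def test_zero_feed_gives_zero_response(self, zero_trace):
        out = tef_response(zero_trace, 0.1, 2.0)
        assert np.all(out.values == 0.0)

    def test_impulse_meal_mass_balance(self, impulse_meal):
        # kernel has unit mass: integrated gas volume = O2TEF x meal size
        out = tef_response(impulse_meal, 0.12, 1.5)
        # 22+ h after the meal the Erlang-2 tail is < 1e-9 of the mass
        assert out.integral() == pytest.approx(0.12 * 500.0, rel=1e-6)

    def test_impulse_response_matches_erlang2_closed_form(self, impulse_meal):
        ttef = 2.0
        out = tef_response(impulse_meal, 1.0, ttef)
        t_meal = impulse_meal.times[1000]
        t = (out.times - t_meal) / 3600.0  # h since meal
        k = 2.0 / ttef
        expected = np.where(t >= 0, 500.0 * k * k * t * np.exp(-k * t), 0.0)
        # exact per-tick updates vs the continuous kernel: one-tick smearing
        assert np.max(np.abs(out.values - expected)) < 500.0 * k * DT / 3600.0

    def test_peak_at_half_ttef_and_mean_lag_ttef(self, impulse_meal):
        ttef = 2.0
        out = tef_response(impulse_meal, 1.0, ttef)
        t_meal = impulse_meal.times[1000]
        t_h = (out.times - t_meal) / 3600.0
        t_peak = t_h[np.argmax(out.values)]
        assert t_peak == pytest.approx(ttef / 2.0, abs=2 * DT / 3600.0)
        mean_lag = np.sum(t_h * out.values) / np.sum(out.values)
        assert mean_lag == pytest.approx(ttef, rel=1e-3)

    def test_nonpositive_ttef_rejected(self, impulse_meal):
        with pytest.raises(ValueError, match="TTEF"):
            tef_response(impulse_meal, 0.1, 0.0)

    def test_decreasing_cumulative_trace_rejected(self):
        bad = SignalTrace(0.0, DT, np.linspace(100, 0, N))
        with pytest.raises(ValueError, match="non-decreasing"):
            tef_response(bad, 0.1, 2.0)


class TestActivityGasRate:
    def test_zero_voltage_zero_rate(self, zero_trace):
        assert np.all(activity_gas_rate(zero_trace, 2.0).values == 0.0)

    def test_constant_voltage_hand_arithmetic(self):
        # 2 mV for 1 h at 0.5 L/(mV h) -> 1.0 L
        force = SignalTrace(0.0, DT, np.full(360, 2.0))
        out = activity_gas_rate(force, 0.5)
        assert out.integral() == pytest.approx(1.0)

    def test_linearity_in_trace(self, zero_trace):
        rng = np.random.default_rng(0)
        force = SignalTrace(0.0, DT, rng.uniform(0, 5, N))
        doubled = force.with_values(2 * force.values)
        assert activity_gas_rate(doubled, 1.3).integral() == pytest.approx(
            2 * activity_gas_rate(force, 1.3).integral()
        )

    def test_negative_voltage_rejected(self):
        force = SignalTrace(0.0, DT, np.full(10, -0.1))
        with pytest.raises(ValueError, match="voltage"):
            activity_gas_rate(force, 1.0)


class TestFastingDecline:
    def test_boundary_values(self):
        assert fasting_decline(0.0, 14.0, 10.0, 5.0) == pytest.approx(14.0)
        assert fasting_decline(1e6, 14.0, 10.0, 5.0) == pytest.approx(10.0)

    def test_hand_evaluated_point(self):
        # one time constant in: 10 + 4/e
        assert fasting_decline(5.0, 14.0, 10.0, 5.0) == pytest.approx(
            10.0 + 4.0 / np.e, rel=1e-12
        )

    def test_monotone_nonincreasing(self):
        t = np.linspace(0, 30, 200)
        y = fasting_decline(t, 14.0, 10.0, 5.0)
        assert np.all(np.diff(y) <= 0)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            fasting_decline(-1.0, 14.0, 10.0, 5.0)


class TestSimulateChamberDay:
    def test_no_exchange_stays_at_ingoing(self, zero_trace):
        spec = ChamberSpec(physical_volume=12000.0, outflow=8000.0)
        p = FedDayParameters(0, 0, 0, 0, 0, 0, 2.0)
        res = simulate_chamber_day(spec, p, zero_trace, zero_trace)
        assert np.allclose(res.o2_fraction.values, spec.ingoing_air_fractions[0])
        assert np.allclose(res.co2_fraction.values, spec.ingoing_air_fractions[1])

    def test_unit_rq_steady_state(self, zero_trace):
        # VO2 = VCO2 = 250 L/h, outflow 20 000 L/h: O2 drops by 250/20000
        spec = ChamberSpec(physical_volume=12000.0, outflow=20000.0)
        p = FedDayParameters(250, 250, 0, 0, 0, 0, 2.0)
        res = simulate_chamber_day(spec, p, zero_trace, zero_trace)
        assert res.o2_fraction.values[-1] == pytest.approx(0.1970, abs=1e-12)

    @pytest.mark.parametrize("draw", range(20))
    def test_steady_state_matches_mass_balance_oracle(self, zero_trace, draw):
        rng = np.random.default_rng(draw)
        vo2 = rng.uniform(10, 60)
        vco2 = vo2 * rng.uniform(0.7, 1.3)
        flow = rng.uniform(4000, 20000)
        vol = rng.uniform(5000, 20000)
        spec = ChamberSpec(physical_volume=vol, outflow=flow)
        p = FedDayParameters(vo2, vco2, 0, 0, 0, 0, 2.0)
        res = simulate_chamber_day(spec, p, zero_trace, zero_trace)
        xo, xc = steady_state_fractions(spec, vo2, vco2, flow)
        assert abs(res.o2_fraction.values[-1] - xo) < 1e-6
        assert abs(res.co2_fraction.values[-1] - xc) < 1e-6

    def test_gas_conservation_per_step(self, zero_trace):
        spec = ChamberSpec(physical_volume=12000.0, outflow=7500.0)
        p = FedDayParameters(33, 36, 0, 0, 0, 0, 2.0)
        res = simulate_chamber_day(spec, p, zero_trace, zero_trace)
        # inflow keeps the total inventory constant
        total = res.inventories.sum(axis=1)
        assert np.ptp(total) < 1e-8 * spec.physical_volume

    def test_superposition_of_meals(self, zero_trace, default_spec):
        p = FedDayParameters(33, 36, 0, 0, 0.08, 0.1, 2.0)
        feed_a = impulse_feed(300.0, 1000)
        feed_b = impulse_feed(400.0, 4000)
        both = feed_a.with_values(feed_a.values + feed_b.values)
        base = simulate_chamber_day(
            default_spec, p, impulse_feed(0.0), zero_trace
        ).o2_fraction.values
        ra = simulate_chamber_day(default_spec, p, feed_a, zero_trace).o2_fraction.values
        rb = simulate_chamber_day(default_spec, p, feed_b, zero_trace).o2_fraction.values
        rab = simulate_chamber_day(default_spec, p, both, zero_trace).o2_fraction.values
        assert np.max(np.abs(rab - (ra + rb - base))) < 1e-12

    def test_step_halving_changes_volumes_below_tolerance(self, default_spec):
        rng = np.random.default_rng(1)
        force = SignalTrace(0.0, DT, rng.uniform(0, 4, N))
        feed = impulse_feed(2500.0, 3000)
        p = FedDayParameters(33, 36, 2.5, 2.7, 0.08, 0.1, 2.0)
        res10 = simulate_chamber_day(default_spec, p, feed, force)
        # same drivers on a 5-s grid
        force5 = SignalTrace(0.0, 5.0, np.repeat(force.values, 2))
        feed5 = SignalTrace(0.0, 5.0, np.repeat(feed.values, 2))
        spec5 = ChamberSpec(physical_volume=12000.0, outflow=7500.0)
        res5 = simulate_chamber_day(spec5, p, feed5, force5)
        for key in ("total_o2_L", "total_co2_L"):
            assert res5.components[key] == pytest.approx(
                res10.components[key], rel=1e-3
            )

    def test_exact_and_rk4_routes_agree(self, default_spec, zero_trace):
        rng = np.random.default_rng(2)
        force = SignalTrace(0.0, DT, rng.uniform(0, 4, N))
        feed = impulse_feed(2000.0, 2500)
        p = FedDayParameters(33, 36, 2.5, 2.7, 0.08, 0.1, 2.0)
        a = simulate_chamber_day(default_spec, p, feed, force, method="exact")
        b = simulate_chamber_day(default_spec, p, feed, force, method="rk4")
        assert np.max(np.abs(a.o2_fraction.values - b.o2_fraction.values)) < 1e-10

    def test_excess_consumption_raises(self, zero_trace):
        spec = ChamberSpec(physical_volume=1000.0, outflow=100.0)
        p = FedDayParameters(500.0, 10.0, 0, 0, 0, 0, 2.0)
        with pytest.raises(SimulationError, match="t="):
            simulate_chamber_day(spec, p, zero_trace, zero_trace)

    def test_manual_event_adds_its_volume(self, zero_trace, default_spec):
        p = FedDayParameters(33, 36, 0, 0, 0, 0, 2.0)
        ev = ManualEvent(start=36000.0, duration=1800.0, extra_vo2=4.0)
        res = simulate_chamber_day(
            default_spec, p, impulse_feed(0.0), zero_trace, events=[ev]
        )
        assert res.components["events_o2_L"] == pytest.approx(4.0 * 0.5)
        # contribution is small relative to the day, as annotated events must be
        assert res.components["events_o2_L"] < 0.005 * res.components["total_o2_L"]

    def test_fasting_day_declines_toward_asymptote(self, zero_trace, default_spec):
        p = FastingDayParameters(33, 36, 0, 0, 25, 27, 3.0, 3.0)
        res = simulate_chamber_day(default_spec, p, None, zero_trace)
        assert res.animal_vo2[0] == pytest.approx(33.0, rel=1e-3)
        assert res.animal_vo2[-1] == pytest.approx(25.0, rel=1e-2)


class TestParameterValidation:
    def test_fed_rejects_negative(self):
        with pytest.raises(ValueError):
            FedDayParameters(-1, 36, 0, 0, 0, 0, 2.0)

    def test_fasting_rejects_vofast_above_vofed(self):
        with pytest.raises(ValueError, match="VOFAST"):
            FastingDayParameters(30, 33, 0, 0, 31, 20, 3.0, 3.0)

    def test_chamber_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            ChamberSpec(physical_volume=1000.0, ingoing_air_fractions=(0.2, 0.1, 0.6))
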