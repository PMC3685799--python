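"""Preprocessing tests: drift, lag, STP, Haldane volumes, smoothing."""
import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from calorpart.chamber import ChamberSpec, FedDayParameters, simulate_chamber_day
from calorpart.preprocess import (
    AnalyzerCalibration,
    align_lag,
    correct_drift,
    gas_volumes,
    smooth_inputs,
    standardize_24h,
)
from calorpart.traces import SignalTrace

from conftest import DT, N


class TestDriftCorrection:
    def _cal(self, drift=0.0):
        # O2 analyzer: baseline = ingoing air, span = standard gas
        return AnalyzerCalibration(
            baseline_true=0.2095, span_true=0.1900,
            baseline_start=0.2095, baseline_end=0.2095 + drift,
            span_start=0.1900, span_end=0.1900 + drift,
        )

    def test_identical_calibrations_leave_trace_unchanged(self):
        tr = SignalTrace(0.0, DT, np.full(N, 0.2000))
        out = correct_drift(tr, self._cal(0.0))
        assert np.allclose(out.values, tr.values)

    def test_linear_offset_drift_interpolated_to_midpoint(self):
        # +0.05 %-points offset drift over the day: a midpoint reading of
        # 20.00% is corrected by half the drift, to 19.975%
        tr = SignalTrace(0.0, DT, np.full(N, 0.2000))
        out = correct_drift(tr, self._cal(0.0005))
        mid = N // 2
        assert out.values[mid] == pytest.approx(0.19975, abs=1e-6)

    def test_order_independent_with_lag_on_constant_trace(self):
        tr = SignalTrace(0.0, DT, np.full(N, 0.2000))
        cal = self._cal(0.0003)
        a = align_lag(correct_drift(tr, cal), 70.0)
        b = correct_drift(align_lag(tr, 70.0), cal)
        # constant traces: the operations commute except for the drift
        # ramp sampled 70 s apart at the filled edge
        assert np.allclose(a.values[:-7], b.values[:-7], atol=1e-8)

    def test_missing_end_calibration_requires_explicit_policy(self):
        cal = AnalyzerCalibration(0.2095, 0.19, 0.2095, None, 0.19, None)
        tr = SignalTrace(0.0, DT, np.full(N, 0.2))
        with pytest.raises(ValueError, match="carry_forward"):
            correct_drift(tr, cal)
        out = correct_drift(tr, cal, allow_carry_forward=True)
        assert np.allclose(out.values, 0.2)


class TestLagAlignment:
    def test_zero_lag_is_identity(self):
        tr = SignalTrace(0.0, DT, np.arange(N, dtype=float))
        assert np.array_equal(align_lag(tr, 0.0).values, tr.values)

    def test_step_moves_seven_ticks_earlier(self):
        v = np.zeros(N)
        v[1000:] = 1.0
        out = align_lag(SignalTrace(0.0, DT, v), 70.0)
        assert out.values[993] == 1.0
        assert out.values[992] == 0.0

    def test_round_trip_restores_interior(self):
        rng = np.random.default_rng(0)
        tr = SignalTrace(0.0, DT, rng.normal(size=N))
        fwd = align_lag(tr, 70.0)
        # shift back by prepending: interior samples must be intact
        assert np.array_equal(fwd.values[:-7], tr.values[7:])

    def test_lag_longer_than_trace_rejected(self):
        tr = SignalTrace(0.0, DT, np.zeros(5))
        with pytest.raises(ValueError, match="longer"):
            align_lag(tr, 100.0)

    def test_non_grid_lag_rejected(self):
        tr = SignalTrace(0.0, DT, np.zeros(N))
        with pytest.raises(ValueError, match="multiple"):
            align_lag(tr, 73.0)


class TestStandardize24h:
    def test_partial_day_scales_proportionally(self):
        assert standardize_24h(440.0, 22.0) == pytest.approx(480.0)

    def test_full_day_unchanged_and_zero_maps_to_zero(self):
        assert standardize_24h(523.0, 24.0) == pytest.approx(523.0)
        assert standardize_24h(0.0, 17.3) == 0.0

    def test_duration_over_24h_rejected(self):
        with pytest.raises(ValueError):
            standardize_24h(100.0, 25.0)

    @given(
        v=st.floats(0, 1e4),
        d=st.floats(0.5, 24.0),
        k=st.floats(0.1, 10.0),
    )
    def test_scale_equivariance(self, v, d, k):
        assert standardize_24h(k * v, d) == pytest.approx(
            k * standardize_24h(v, d), rel=1e-12
        )


class TestSmoothing:
    def test_constant_trace_unchanged(self):
        tr = SignalTrace(0.0, DT, np.full(N, 3.3))
        assert np.allclose(smooth_inputs(tr).values, 3.3)

    def test_integral_preserved_on_spiky_traces(self):
        rng = np.random.default_rng(3)
        spiky = rng.exponential(1.0, N) * (rng.uniform(size=N) < 0.05)
        tr = SignalTrace(0.0, DT, spiky)
        out = smooth_inputs(tr, window=6)
        assert out.integral() == pytest.approx(tr.integral(), rel=1e-3)

    def test_single_missing_tick_interpolated(self):
        v = np.linspace(0, 1, N)
        v[500] = np.nan
        out = smooth_inputs(SignalTrace(0.0, DT, v), method="interpolate")
        assert out.values[500] == pytest.approx((v[499] + v[501]) / 2)

    def test_window_below_one_rejected(self):
        with pytest.raises(ValueError):
            smooth_inputs(SignalTrace(0.0, DT, np.zeros(N)), window=0)


class TestGasVolumes:
    def _spec(self, flow=7500.0):
        return ChamberSpec(physical_volume=12000.0, outflow=flow)

    def test_no_concentration_difference_gives_zero_volumes(self, zero_trace):
        spec = self._spec()
        cin = spec.ingoing_air_fractions
        o2 = SignalTrace(0.0, DT, np.full(N, cin[0]))
        co2 = SignalTrace(0.0, DT, np.full(N, cin[1]))
        ch4 = SignalTrace(0.0, DT, np.zeros(N))
        flow = SignalTrace(0.0, DT, np.full(N, 7500.0))
        v = gas_volumes(o2, co2, ch4, flow, spec)
        assert v.vo2 == pytest.approx(0.0, abs=1e-9)
        assert v.vco2 == pytest.approx(0.0, abs=1e-9)
        assert v.vch4 == pytest.approx(0.0, abs=1e-9)

    def test_simulator_round_trip_within_half_percent(self, zero_trace):
        rng = np.random.default_rng(7)
        force = SignalTrace(0.0, DT, rng.uniform(0, 4, N))
        cum = np.cumsum(rng.uniform(size=N) < 0.01) * 25.0
        feed = SignalTrace(0.0, DT, cum.astype(float))
        p = FedDayParameters(33, 36, 2.5, 2.7, 0.08, 0.1, 2.0)
        spec = self._spec()
        sim = simulate_chamber_day(spec, p, feed, force, ch4_rate=1.2)
        flow = SignalTrace(0.0, DT, np.full(N, 7500.0))
        v = gas_volumes(sim.o2_fraction, sim.co2_fraction, sim.ch4_fraction, flow, spec)
        h = DT / 3600.0
        true_vo2 = sim.animal_vo2.sum() * h
        true_vco2 = sim.animal_vco2.sum() * h
        assert v.vo2 == pytest.approx(true_vo2, rel=5e-3)
        assert v.vco2 == pytest.approx(true_vco2, rel=5e-3)
        assert v.vch4 == pytest.approx(1.2 * 24.0, rel=5e-3)

    def test_unit_rq_reduces_to_flow_times_concentration_difference(self):
        # with VCO2 = VO2 the inflow equals the outflow and the inert-gas
        # formula collapses to outflow x (cin - cout)
        spec = self._spec(flow=20000.0)
        p = FedDayParameters(250, 250, 0, 0, 0, 0, 2.0)
        zero = SignalTrace(0.0, DT, np.zeros(N))
        sim = simulate_chamber_day(spec, p, zero, zero)
        flow = SignalTrace(0.0, DT, np.full(N, 20000.0))
        v = gas_volumes(
            sim.o2_fraction, sim.co2_fraction,
            SignalTrace(0.0, DT, np.zeros(N)), flow, spec,
        )
        cin = spec.ingoing_air_fractions[0]
        naive = 20000.0 * np.mean(cin - sim.o2_fraction.values) * v.duration_h
        assert v.vo2 == pytest.approx(naive, rel=1e-6)
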