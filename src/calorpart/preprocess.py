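"""From raw chamber recordings to clean traces and daily gas volumes.

The raw material is what the acquisition system writes: analyzer gas
fractions of the outgoing air, outflow at measured conditions,
temperature / pressure / humidity, force-sensor voltage, cumulative feed
dispensed, and the daily calibration records.  Preprocessing applies,
in order:

1. two-point analyzer drift correction, linear in time over the day;
2. lag alignment (analyzers see the chamber ~70 s late);
3. conversion of the outflow to STP (dry air, ideal-gas law);
4. excision of interruption windows (morning care/calibration break);
5. inert-gas (Haldane-type) back-calculation of O2 consumption and CO2
   and CH4 production per 10-s tick, with a chamber storage term, and
   cumulation into daily volumes;
6. proportional standardization of daily volumes to 24 h.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .chamber import ChamberSpec
from .constants import DEFAULT_LAG_S, STP_TEMPERATURE_K
from .traces import SignalTrace

__all__ = [
    "AnalyzerCalibration",
    "RawDayRecording",
    "DayVolumes",
    "PreprocessedDay",
    "correct_drift",
    "align_lag",
    "to_stp_flow",
    "saturation_vapor_pressure_atm",
    "exchange_rates",
    "gas_volumes",
    "standardize_24h",
    "smooth_inputs",
    "interruption_mask",
    "preprocess_day",
]


# ----------------------------------------------------------------------
# calibration / drift
# ----------------------------------------------------------------------

@dataclass
class AnalyzerCalibration:
    """Start- and end-of-day two-point calibration of one gas analyzer.

    The baseline is ingoing air, the span a standard gas of known
    composition.  Readings are analyzer output (fractions); true values
    are the certified fractions.  Drift between the two calibrations is
    taken to be linear in time.
    """

    baseline_true: float
    span_true: float
    baseline_start: float
    baseline_end: Optional[float]
    span_start: float
    span_end: Optional[float]

    def __post_init__(self) -> None:
        for name in ("baseline_true", "span_true", "baseline_start", "span_start"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} outside the physical gas-fraction range: {v}")
        if abs(self.span_true - self.baseline_true) < 1e-12:
            raise ValueError("span and baseline true values must differ")


def correct_drift(
    trace: SignalTrace,
    cal: AnalyzerCalibration,
    *,
    day_span_s: float = 86400.0,
    allow_carry_forward: bool = False,
) -> SignalTrace:
    """Apply a time-linear two-point calibration correction.

    At each tick the baseline and span readings are interpolated between
    their start- and end-of-day values and the analyzer output is mapped
    through the resulting linear (offset + gain) correction.
    """
    if cal.baseline_end is None or cal.span_end is None:
        if not allow_carry_forward:
            raise ValueError(
                "missing end-of-day calibration; pass allow_carry_forward=True "
                "to reuse the start-of-day readings"
            )
        cal = AnalyzerCalibration(
            cal.baseline_true,
            cal.span_true,
            cal.baseline_start,
            cal.baseline_start,
            cal.span_start,
            cal.span_start,
        )
    w = np.clip(trace.times / day_span_s, 0.0, 1.0)
    base_read = cal.baseline_start + w * (cal.baseline_end - cal.baseline_start)
    span_read = cal.span_start + w * (cal.span_end - cal.span_start)
    gain = (cal.span_true - cal.baseline_true) / (span_read - base_read)
    corrected = cal.baseline_true + (trace.values - base_read) * gain
    return trace.with_values(corrected, drift_corrected=True)


def align_lag(trace: SignalTrace, lag_s: float = DEFAULT_LAG_S) -> SignalTrace:
    """Shift an analyzer trace earlier by the transport lag.

    The analyzers sample air that left the chamber ``lag_s`` earlier, so
    the reading at tick ``k`` describes the chamber at ``k - lag``;
    alignment moves it back.  The trailing edge is filled with the last
    observed value and flagged.
    """
    if lag_s < 0:
        raise ValueError("lag must be >= 0")
    shift = int(round(lag_s / trace.dt))
    if abs(shift * trace.dt - lag_s) > 1e-6:
        raise ValueError("lag must be a multiple of the grid resolution")
    if shift == 0:
        return trace
    if shift >= trace.n:
        raise ValueError("lag longer than the trace")
    values = np.empty_like(trace.values)
    values[:-shift] = trace.values[shift:]
    values[-shift:] = trace.values[-1]
    return trace.with_values(values, lag_aligned_s=lag_s, edge_filled_ticks=shift)


# ----------------------------------------------------------------------
# unit conversion
# ----------------------------------------------------------------------

def saturation_vapor_pressure_atm(temp_c: np.ndarray) -> np.ndarray:
    """Saturation water-vapor pressure (atm), Tetens approximation."""
    temp_c = np.asarray(temp_c, dtype=float)
    kpa = 0.61078 * np.exp(17.27 * temp_c / (temp_c + 237.3))
    return kpa / 101.325


def to_stp_flow(
    flow: SignalTrace,
    temperature: SignalTrace,
    pressure: SignalTrace,
    humidity: Optional[SignalTrace] = None,
    *,
    vapor_correction: bool = True,
) -> SignalTrace:
    """Convert a measured-condition flow (L/h) to dry STP (0 degC, 1 atm).

    The water-vapor partial pressure is removed first (dry-air
    assumption), then the ideal-gas law rescales to 0 degC and 1 atm.
    """
    p = pressure.values.copy()
    if vapor_correction and humidity is not None:
        p = p - humidity.values / 100.0 * saturation_vapor_pressure_atm(
            temperature.values
        )
    factor = (STP_TEMPERATURE_K / (STP_TEMPERATURE_K + temperature.values)) * p
    return flow.with_values(flow.values * factor, stp=True)


# ----------------------------------------------------------------------
# recordings
# ----------------------------------------------------------------------

@dataclass
class RawDayRecording:
    """One animal-day of raw aligned 10-s traces."""

    o2: SignalTrace            # outgoing O2 fraction (analyzer units)
    co2: SignalTrace           # outgoing CO2 fraction
    ch4: SignalTrace           # outgoing CH4 fraction
    outflow: SignalTrace       # L/h at measured conditions
    temperature: SignalTrace   # degC
    pressure: SignalTrace      # atm
    humidity: SignalTrace      # %RH
    force: SignalTrace         # mV
    feed: SignalTrace          # g cumulative dispensed
    standing: Optional[SignalTrace] = None   # 0/1 infrared beam
    interruptions: Sequence[tuple] = ()      # [(start_s, end_s), ...]
    calibrations: dict = field(default_factory=dict)  # gas -> AnalyzerCalibration
    animal_id: Optional[str] = None
    day: Optional[int] = None
    fasted: bool = False

    def __post_init__(self) -> None:
        ref = self.o2
        for name in ("co2", "ch4", "outflow", "temperature", "pressure",
                     "humidity", "force", "feed"):
            tr = getattr(self, name)
            if not tr.same_grid(ref):
                raise ValueError(f"trace {name!r} is not on the common grid")
        spans = sorted(self.interruptions)
        for (a0, a1), (b0, b1) in zip(spans, spans[1:]):
            if b0 < a1:
                raise ValueError("interruption windows overlap")


@dataclass
class DayVolumes:
    """Daily gas-exchange volumes of one animal-day (L STP)."""

    vo2: float
    vco2: float
    vch4: float
    duration_h: float
    vo2_24h: float
    vco2_24h: float
    vch4_24h: float
    flags: dict = field(default_factory=dict)

    @property
    def rq(self) -> float:
        return self.vco2 / self.vo2


@dataclass
class PreprocessedDay:
    """Clean traces ready for model fitting, plus daily volumes."""

    o2: SignalTrace
    co2: SignalTrace
    ch4: SignalTrace
    outflow_stp: SignalTrace
    force: SignalTrace
    feed: SignalTrace
    valid: np.ndarray          # bool per tick; False inside interruptions
    volumes: DayVolumes
    animal_id: Optional[str] = None
    day: Optional[int] = None
    fasted: bool = False


def interruption_mask(trace: SignalTrace, interruptions: Sequence[tuple]) -> np.ndarray:
    """Boolean mask, True where the tick lies outside every interruption."""
    valid = np.ones(trace.n, dtype=bool)
    t = trace.times
    for start, end in interruptions:
        valid &= ~((t + trace.dt > start) & (t < end))
    return valid


# ----------------------------------------------------------------------
# volume computation
# ----------------------------------------------------------------------

def exchange_rates(
    o2: SignalTrace,
    co2: SignalTrace,
    ch4: SignalTrace,
    outflow_stp: SignalTrace,
    spec: ChamberSpec,
) -> dict:
    """Per-tick gas-exchange rates (L STP/h) by inert-gas balance.

    The inflow is never measured; because N2 is neither consumed nor
    produced, each tick's inflow follows from the nitrogen balance
    (Haldane-type transformation).  This captures the effect of a
    respiratory quotient different from 1 on the inflow-outflow
    difference.  A chamber storage term (physical volume times the
    concentration derivative) makes the balance exact over transients.
    Rates refer to the intervals between consecutive samples (length
    n - 1).
    """
    cin_o2, cin_co2, cin_n2 = spec.ingoing_air_fractions
    v = spec.physical_volume
    h = o2.dt / 3600.0

    x_o2, x_co2, x_ch4 = o2.values, co2.values, ch4.values
    x_n2 = 1.0 - x_o2 - x_co2 - x_ch4
    flow = outflow_stp.values

    # tick-average concentrations and storage rates (per tick j, between
    # samples j and j+1)
    def tick(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        xbar = 0.5 * (x[:-1] + x[1:])
        storage = v * np.diff(x) / h    # L/h
        return xbar, storage

    n2_bar, n2_sto = tick(x_n2)
    o2_bar, o2_sto = tick(x_o2)
    co2_bar, co2_sto = tick(x_co2)
    ch4_bar, ch4_sto = tick(x_ch4)
    fbar = 0.5 * (flow[:-1] + flow[1:])

    fin = (fbar * n2_bar + n2_sto) / cin_n2
    return {
        "vo2": fin * cin_o2 - fbar * o2_bar - o2_sto,
        "vco2": fbar * co2_bar + co2_sto - fin * cin_co2,
        "vch4": fbar * ch4_bar + ch4_sto,
        "inflow": fin,
    }


def gas_volumes(
    o2: SignalTrace,
    co2: SignalTrace,
    ch4: SignalTrace,
    outflow_stp: SignalTrace,
    spec: ChamberSpec,
    valid: Optional[np.ndarray] = None,
) -> DayVolumes:
    """Daily VO2 / VCO2 / VCH4 (L STP) cumulated from the tick rates.

    Ticks inside interruption windows are excised before cumulation and
    the totals are reported both as measured and standardized to 24 h
    assuming proportionality.
    """
    h = o2.dt / 3600.0
    rates = exchange_rates(o2, co2, ch4, outflow_stp, spec)
    vo2_rate, vco2_rate, vch4_rate = rates["vo2"], rates["vco2"], rates["vch4"]

    if valid is None:
        keep = np.ones(vo2_rate.size, dtype=bool)
    else:
        keep = valid[:-1] & valid[1:]

    if _sustained_negative(vo2_rate[keep]):
        raise ValueError(
            "computed O2 consumption negative over a sustained window; "
            "check calibration and trace alignment"
        )

    duration = float(keep.sum()) * h
    vo2_total = float(vo2_rate[keep].sum() * h)
    vco2_total = float(vco2_rate[keep].sum() * h)
    vch4_total = float(vch4_rate[keep].sum() * h)
    return DayVolumes(
        vo2=vo2_total,
        vco2=vco2_total,
        vch4=vch4_total,
        duration_h=duration,
        vo2_24h=standardize_24h(vo2_total, duration),
        vco2_24h=standardize_24h(vco2_total, duration),
        vch4_24h=standardize_24h(vch4_total, duration),
    )


def _sustained_negative(rate: np.ndarray, window: int = 60) -> bool:
    """True if the rate stays negative over a full window of ticks."""
    if rate.size < window:
        return bool(rate.size and np.all(rate < 0))
    roll = pd.Series(rate).rolling(window).max()
    return bool((roll < 0).any())


def standardize_24h(volume: float, measured_duration_h: float) -> float:
    """Scale a partial-day volume to 24 h assuming proportionality."""
    if not 0.0 < measured_duration_h <= 24.0 + 1e-9:
        raise ValueError(
            f"measured duration must lie in (0, 24] h, got {measured_duration_h}"
        )
    return volume * 24.0 / measured_duration_h


# ----------------------------------------------------------------------
# smoothing
# ----------------------------------------------------------------------

def smooth_inputs(
    trace: SignalTrace, method: str = "moving_average", window: int = 6
) -> SignalTrace:
    """Make a driver trace continuous enough for the ODE model.

    Missing samples are linearly interpolated first; then a centered
    moving average of ``window`` ticks is applied ("moving_average") or
    the interpolated trace is returned as-is ("interpolate").  The
    moving average preserves the daily integral (edges are padded with
    the edge value).
    """
    if window < 1:
        raise ValueError("window must be >= 1 tick")
    s = pd.Series(trace.values)
    s = s.interpolate(method="linear", limit_direction="both")
    values = s.to_numpy()
    if method == "interpolate" or window == 1:
        return trace.with_values(values, smoothed=method)
    if method != "moving_average":
        raise ValueError(f"unknown smoothing method {method!r}")
    pad = window // 2
    padded = np.concatenate(
        (np.full(pad, values[0]), values, np.full(window - 1 - pad, values[-1]))
    )
    kernel = np.ones(window) / window
    smooth = np.convolve(padded, kernel, mode="valid")
    return trace.with_values(smooth, smoothed=f"moving_average({window})")


# ----------------------------------------------------------------------
# orchestration
# ----------------------------------------------------------------------

def preprocess_day(
    rec: RawDayRecording,
    spec: ChamberSpec,
    *,
    lag_s: float = DEFAULT_LAG_S,
    smoothing_window: int = 6,
    vapor_correction: bool = True,
) -> PreprocessedDay:
    """Run the full preprocessing chain on one raw animal-day."""
    gases = {}
    for name, tr in (("o2", rec.o2), ("co2", rec.co2), ("ch4", rec.ch4)):
        cal = rec.calibrations.get(name)
        clean = correct_drift(tr, cal) if cal is not None else tr
        clean = smooth_inputs(clean, method="interpolate")
        gases[name] = align_lag(clean, lag_s)

    outflow_stp = to_stp_flow(
        smooth_inputs(rec.outflow, window=smoothing_window),
        smooth_inputs(rec.temperature, window=smoothing_window),
        smooth_inputs(rec.pressure, window=smoothing_window),
        smooth_inputs(rec.humidity, window=smoothing_window),
        vapor_correction=vapor_correction,
    )
    force = smooth_inputs(rec.force, window=smoothing_window)
    feed = smooth_inputs(rec.feed, method="interpolate")

    valid = interruption_mask(rec.o2, rec.interruptions)
    volumes = gas_volumes(
        gases["o2"], gases["co2"], gases["ch4"], outflow_stp, spec, valid
    )
    return PreprocessedDay(
        o2=gases["o2"],
        co2=gases["co2"],
        ch4=gases["ch4"],
        outflow_stp=outflow_stp,
        force=force,
        feed=feed,
        valid=valid,
        volumes=volumes,
        animal_id=rec.animal_id,
        day=rec.day,
        fasted=rec.fasted,
    )
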