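"""Forward model of an open-circuit respiration chamber.

Two coupled sub-models describe how the O2 and CO2 concentrations of the
outgoing air respond to what the animal does:

* the **animal** sub-model turns feeding and physical-activity signals
  into instantaneous O2 consumption and CO2 production (L STP/h): a
  constant resting term, a term proportional to the force-sensor voltage
  and a meal-locked term that follows an Erlang-2 (gamma, shape 2)
  kernel produced by a two-compartment cascade with fractional emptying
  rate ``2/TTEF`` in each compartment;
* the **chamber** sub-model books the STP inventories of O2, CO2 and N2
  inside the chamber.  Only the outflow is measured; the inflow is
  defined as the flow required to keep the chamber's STP volume constant
  given the outflow and the net respiratory exchange, so with a
  respiratory quotient different from 1 the inflow differs from the
  outflow.  The concentration of each gas is its inventory divided by
  the summed inventory.

Because the inflow closes the volume balance exactly, each inventory
obeys a scalar linear ODE with known time-varying coefficients.  The
default integrator exploits this: per 10-s tick all drivers are held
constant and the inventory is advanced with the exact exponential
update.  A classical fixed-step RK4 integrator over the full coupled
system is available as ``method="rk4"`` and serves as an independent
numerical route.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Union

import numpy as np
from scipy.signal import lfilter

from .constants import INGOING_CO2, INGOING_N2, INGOING_O2
from .traces import SignalTrace

__all__ = [
    "ChamberSpec",
    "FedDayParameters",
    "FastingDayParameters",
    "ManualEvent",
    "SimulationError",
    "SimulationResult",
    "tef_response",
    "tef_compartments",
    "activity_gas_rate",
    "fasting_decline",
    "animal_gas_rates",
    "simulate_chamber_day",
    "steady_state_fractions",
]


class SimulationError(RuntimeError):
    """Raised when the forward simulation becomes unphysical."""


# ----------------------------------------------------------------------
# domain types
# ----------------------------------------------------------------------

@dataclass
class ChamberSpec:
    """Physical description of the chamber and its ventilation.

    Parameters
    ----------
    physical_volume : float
        Chamber gas volume in L at STP (0 degC, 1 atm).
    ingoing_air_fractions : tuple
        (O2, CO2, N2) volumetric fractions of the ingoing air; must sum
        to 1.
    outflow : float or SignalTrace
        Outgoing air flow in L/h at STP; a scalar is interpreted as a
        constant flow.
    temperature, pressure, humidity : SignalTrace, optional
        Measured-condition traces (degC, atm, %RH) kept for unit
        conversion; the simulator itself works entirely at STP.
    """

    physical_volume: float
    ingoing_air_fractions: tuple = (INGOING_O2, INGOING_CO2, INGOING_N2)
    outflow: Union[float, SignalTrace] = 0.0
    temperature: Optional[SignalTrace] = None
    pressure: Optional[SignalTrace] = None
    humidity: Optional[SignalTrace] = None

    def __post_init__(self) -> None:
        if self.physical_volume <= 0:
            raise ValueError("chamber volume must be positive")
        f = np.asarray(self.ingoing_air_fractions, dtype=float)
        if f.size != 3 or np.any(f < 0) or np.any(f > 1):
            raise ValueError("ingoing air fractions must be three values in [0, 1]")
        if abs(f.sum() - 1.0) > 1e-9:
            raise ValueError(f"ingoing air fractions must sum to 1, got {f.sum()!r}")
        self.ingoing_air_fractions = tuple(f)

    def outflow_values(self, n: int) -> np.ndarray:
        """Outflow (L/h STP) on an n-tick grid."""
        if isinstance(self.outflow, SignalTrace):
            if self.outflow.n != n:
                raise ValueError("outflow trace does not match the simulation grid")
            out = self.outflow.values
        else:
            out = np.full(n, float(self.outflow))
        if np.any(out < 0):
            raise ValueError("outflow must be non-negative")
        return out


def _require_nonneg(name: str, value: float) -> None:
    if value < 0:
        raise ValueError(f"{name} must be >= 0, got {value}")


@dataclass
class FedDayParameters:
    """Estimable parameters of a fed day (all gas volumes L STP).

    VOFED/VCFED: resting O2 consumption / CO2 production, L/h.
    VOFOR/VCFOR: gas exchange per unit force-sensor signal, L/(mV h).
    O2TEF/CO2TEF: gas exchange per g of feed ingested, L/g.
    TTEF: mean time between feed intake and its gas response, h.
    """

    VOFED: float
    VCFED: float
    VOFOR: float
    VCFOR: float
    O2TEF: float
    CO2TEF: float
    TTEF: float

    names = ("VOFED", "VCFED", "VOFOR", "VCFOR", "O2TEF", "CO2TEF", "TTEF")

    def __post_init__(self) -> None:
        for name in self.names:
            _require_nonneg(name, getattr(self, name))
        if self.TTEF <= 0:
            raise ValueError("TTEF must be strictly positive")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, k) for k in self.names], dtype=float)

    @classmethod
    def from_array(cls, x: Sequence[float]) -> "FedDayParameters":
        return cls(*[float(v) for v in x])


@dataclass
class FastingDayParameters:
    """Estimable parameters of the fasting day.

    Resting exchange declines first-order from the fed level (VOFED,
    VCFED) toward the fasting asymptote (VOFAST, VCFAST) with time
    constants TOADAP and TCADAP (hours); activity terms stay active.
    """

    VOFED: float
    VCFED: float
    VOFOR: float
    VCFOR: float
    VOFAST: float
    VCFAST: float
    TOADAP: float
    TCADAP: float

    names = ("VOFED", "VCFED", "VOFOR", "VCFOR", "VOFAST", "VCFAST", "TOADAP", "TCADAP")

    def __post_init__(self) -> None:
        for name in self.names:
            _require_nonneg(name, getattr(self, name))
        if self.TOADAP <= 0 or self.TCADAP <= 0:
            raise ValueError("adaptation time constants must be strictly positive")
        if self.VOFAST > self.VOFED:
            raise ValueError("VOFAST must not exceed VOFED")
        if self.VCFAST > self.VCFED:
            raise ValueError("VCFAST must not exceed VCFED")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, k) for k in self.names], dtype=float)

    @classmethod
    def from_array(cls, x: Sequence[float]) -> "FastingDayParameters":
        return cls(*[float(v) for v in x])


@dataclass
class ManualEvent:
    """A short, manually annotated burst of extra gas exchange.

    Occasional excursions of chamber concentrations unrelated to feeding
    or activity (door seals, care interventions) are modeled as
    rectangular pulses so they do not bias parameter estimates.  Their
    contribution must stay below 0.5% of the daily exchange.
    """

    start: float          # s from midnight
    duration: float       # s
    extra_vo2: float = 0.0    # L/h during the pulse
    extra_vco2: float = 0.0   # L/h during the pulse

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("event duration must be positive")


# ----------------------------------------------------------------------
# animal sub-model
# ----------------------------------------------------------------------

def _intake_rate(feed_trace: SignalTrace) -> np.ndarray:
    """Feed ingestion rate (g/h) per tick from a cumulative trace."""
    cum = feed_trace.values
    if np.any(np.diff(cum) < -1e-9):
        raise ValueError("cumulative feed trace must be non-decreasing")
    d = np.diff(cum, append=cum[-1])
    return d / (feed_trace.dt / 3600.0)


def tef_compartments(feed_trace: SignalTrace, ttef: float) -> tuple[np.ndarray, np.ndarray]:
    """Contents (g) of the two thermic-effect compartments at tick starts.

    dC1/dt = intake_rate - (2/TTEF) C1 ; dC2/dt = (2/TTEF) (C1 - C2).
    Advanced with the exact solution for intake held constant over each
    tick, so feed mass is conserved to machine precision.
    """
    if ttef <= 0:
        raise ValueError("TTEF must be strictly positive")
    r = _intake_rate(feed_trace)
    h = feed_trace.dt / 3600.0
    k = 2.0 / ttef
    e = np.exp(-k * h)
    a1 = (1.0 - e) / k
    b2 = k * h * e
    c0 = (1.0 - e - b2) / k
    # exact per-tick updates of the linear cascade are constant-coefficient
    # IIR recursions; run them through lfilter
    c1 = np.concatenate(([0.0], lfilter([a1], [1.0, -e], r)))
    u = b2 * c1[:-1] + c0 * r
    c2 = np.concatenate(([0.0], lfilter([1.0], [1.0, -e], u)))
    return c1, c2


def tef_response(feed_trace: SignalTrace, gas_per_g: float, ttef: float) -> SignalTrace:
    """Meal-locked gas-exchange rate (L/h) from the cumulative feed trace.

    The response to an impulse meal is the Erlang-2 kernel
    ``(2/TTEF)^2 t exp(-2 t/TTEF)`` (unit mass, peak at TTEF/2, mean lag
    TTEF) scaled by ``gas_per_g`` per gram ingested.
    """
    _, c2 = tef_compartments(feed_trace, ttef)
    k = 2.0 / ttef
    return feed_trace.with_values(gas_per_g * k * c2[:-1])


def _tef_release_rate(feed_trace: SignalTrace, ttef: float) -> np.ndarray:
    """Tick-averaged feed-mass release rate (g/h) out of compartment 2.

    Computed from the mass balance of the cascade, so the day's released
    plus stored mass equals the ingested mass to machine precision.
    """
    c1, c2 = tef_compartments(feed_trace, ttef)
    r = _intake_rate(feed_trace)
    h = feed_trace.dt / 3600.0
    stored = c1 + c2
    released = r * h - np.diff(stored)   # g leaving compartment 2 per tick
    return released / h


def activity_gas_rate(force_trace: SignalTrace, gas_per_mv: float) -> SignalTrace:
    """Gas-exchange rate (L/h) proportional to the force-sensor voltage."""
    if np.any(force_trace.values < 0):
        raise ValueError(
            "negative force-sensor voltage: check sensor baseline before modeling"
        )
    if gas_per_mv < 0:
        raise ValueError("activity coefficient must be >= 0")
    return force_trace.with_values(gas_per_mv * force_trace.values)


def fasting_decline(
    t: Union[float, np.ndarray], fed_level: float, fast_level: float, tau: float
) -> Union[float, np.ndarray]:
    """Resting exchange (L/h) t hours after the start of the fast.

    First-order decline fast_level + (fed_level - fast_level) exp(-t/tau).
    """
    if tau <= 0:
        raise ValueError("tau must be strictly positive")
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time since fast start must be >= 0")
    out = fast_level + (fed_level - fast_level) * np.exp(-t / tau)
    return float(out) if out.ndim == 0 else out


def _event_rates(
    events: Iterable[ManualEvent], times: np.ndarray, dt: float
) -> tuple[np.ndarray, np.ndarray]:
    vo2 = np.zeros_like(times)
    vco2 = np.zeros_like(times)
    for ev in events:
        mask = (times + dt > ev.start) & (times < ev.start + ev.duration)
        vo2[mask] += ev.extra_vo2
        vco2[mask] += ev.extra_vco2
    return vo2, vco2


def animal_gas_rates(
    params: Union[FedDayParameters, FastingDayParameters],
    feed_trace: Optional[SignalTrace],
    force_trace: SignalTrace,
    events: Sequence[ManualEvent] = (),
    fast_start_s: float = 0.0,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Per-tick animal O2 consumption and CO2 production (L/h).

    Returns (vo2, vco2, components) where ``components`` holds the daily
    per-component volumes (L) of each gas.
    """
    times = force_trace.times
    dt = force_trace.dt
    h = dt / 3600.0
    n = force_trace.n

    act_o2 = activity_gas_rate(force_trace, params.VOFOR).values
    act_co2 = activity_gas_rate(force_trace, params.VCFOR).values
    ev_o2, ev_co2 = _event_rates(events, times, dt)

    if isinstance(params, FedDayParameters):
        rest_o2 = np.full(n, params.VOFED)
        rest_co2 = np.full(n, params.VCFED)
        if feed_trace is None:
            raise ValueError("fed-day simulation requires a feed trace")
        if not feed_trace.same_grid(force_trace):
            raise ValueError("feed and force traces must share the grid")
        release = _tef_release_rate(feed_trace, params.TTEF)
        tef_o2 = params.O2TEF * release
        tef_co2 = params.CO2TEF * release
    else:
        t_fast = np.clip((times + dt / 2.0 - fast_start_s) / 3600.0, 0.0, None)
        rest_o2 = fasting_decline(t_fast, params.VOFED, params.VOFAST, params.TOADAP)
        rest_co2 = fasting_decline(t_fast, params.VCFED, params.VCFAST, params.TCADAP)
        tef_o2 = np.zeros(n)
        tef_co2 = np.zeros(n)

    vo2 = rest_o2 + act_o2 + tef_o2 + ev_o2
    vco2 = rest_co2 + act_co2 + tef_co2 + ev_co2
    components = {
        "resting_o2_L": float(rest_o2.sum() * h),
        "resting_co2_L": float(rest_co2.sum() * h),
        "activity_o2_L": float(act_o2.sum() * h),
        "activity_co2_L": float(act_co2.sum() * h),
        "tef_o2_L": float(tef_o2.sum() * h),
        "tef_co2_L": float(tef_co2.sum() * h),
        "events_o2_L": float(ev_o2.sum() * h),
        "events_co2_L": float(ev_co2.sum() * h),
        "total_o2_L": float(vo2.sum() * h),
        "total_co2_L": float(vco2.sum() * h),
    }
    return vo2, vco2, components


# ----------------------------------------------------------------------
# chamber sub-model
# ----------------------------------------------------------------------

def steady_state_fractions(
    spec: ChamberSpec, vo2: float, vco2: float, outflow: float
) -> tuple[float, float]:
    """Closed-form steady-state outgoing (O2, CO2) fractions.

    At steady state the inflow equals ``outflow + vo2 - vco2`` (volume
    constancy) and each gas balance gives
    ``x_g = (inflow * c_in_g -/+ exchange_g) / outflow``.
    """
    cin_o2, cin_co2, _ = spec.ingoing_air_fractions
    fin = outflow + vo2 - vco2
    x_o2 = (fin * cin_o2 - vo2) / outflow
    x_co2 = (fin * cin_co2 + vco2) / outflow
    return x_o2, x_co2


def _scan_linear(a_coef: np.ndarray, b_coef: np.ndarray, i0: float,
                 chunk: int = 1024) -> np.ndarray:
    """Solve I[j+1] = a[j] I[j] + b[j]; returns I[0..n] (length n+1).

    Vectorized per chunk with renormalization at chunk boundaries to
    avoid overflow of the cumulative products.
    """
    n = a_coef.size
    out = np.empty(n + 1)
    out[0] = i0
    i = i0
    for s in range(0, n, chunk):
        e = min(s + chunk, n)
        p = np.cumprod(a_coef[s:e])
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = b_coef[s:e] / p
        seg = p * (i + np.cumsum(terms))
        out[s + 1 : e + 1] = seg
        i = seg[-1]
    return out


@dataclass
class SimulationResult:
    """Output of :func:`simulate_chamber_day`."""

    o2_fraction: SignalTrace
    co2_fraction: SignalTrace
    inflow: np.ndarray                 # L/h STP per tick
    inventories: np.ndarray            # (n+1, 3) L STP: O2, CO2, N2
    animal_vo2: np.ndarray             # L/h per tick
    animal_vco2: np.ndarray
    components: dict = field(default_factory=dict)
    ch4_fraction: Optional[SignalTrace] = None


def simulate_chamber_day(
    spec: ChamberSpec,
    params: Union[FedDayParameters, FastingDayParameters],
    feed_trace: Optional[SignalTrace],
    force_trace: SignalTrace,
    events: Sequence[ManualEvent] = (),
    *,
    initial_fractions: Optional[tuple] = None,
    fast_start_s: float = 0.0,
    method: str = "exact",
    step: Optional[float] = None,
    ch4_rate: float = 0.0,
) -> SimulationResult:
    """Simulate outgoing O2 and CO2 fractions for one animal-day.

    Parameters
    ----------
    initial_fractions : (O2, CO2) or None
        Chamber composition at the first tick; defaults to the
        steady-state composition under the initial animal rates (a
        chamber that has held the animal for a while).
    method : "exact" or "rk4"
        "exact" advances the (conditionally linear) inventories with
        per-tick exponential updates; "rk4" integrates the full coupled
        system with a fixed-step classical Runge-Kutta scheme (kept as
        an independent numerical route; non-stiff at realistic
        ventilation rates).
    step : float, optional
        Internal sub-step in seconds for "rk4" (default: the trace
        resolution).
    ch4_rate : float
        Constant enteric CH4 production, L STP/h.  CH4 dynamics are not
        part of the inventory ODEs; the rate enters the inflow balance
        and yields a quasi-steady outgoing CH4 fraction
        ``ch4_rate / outflow`` so that downstream inert-gas volume
        calculations close.
    """
    n = force_trace.n
    dt = force_trace.dt
    h = dt / 3600.0
    v = spec.physical_volume
    cin = np.asarray(spec.ingoing_air_fractions)
    outflow = spec.outflow_values(n)

    vo2, vco2, components = animal_gas_rates(
        params, feed_trace, force_trace, events, fast_start_s
    )

    with np.errstate(divide="ignore"):
        x_ch4 = np.where(outflow > 0, ch4_rate / np.where(outflow > 0, outflow, 1.0), 0.0)

    if initial_fractions is None:
        # quasi-steady four-gas start: inflow closes the volume balance
        fin0 = outflow[0] + vo2[0] - vco2[0] - ch4_rate
        x0_o2 = (fin0 * cin[0] - vo2[0]) / outflow[0]
        x0_co2 = (fin0 * cin[1] + vco2[0]) / outflow[0]
    else:
        x0_o2, x0_co2 = initial_fractions
    x0 = np.array([x0_o2, x0_co2, 1.0 - x0_o2 - x0_co2 - x_ch4[0]])

    inflow = outflow + vo2 - vco2 - ch4_rate
    source = np.stack(
        [inflow * cin[0] - vo2, inflow * cin[1] + vco2, inflow * cin[2]], axis=1
    )

    if method == "exact":
        lam = outflow / v                              # 1/h
        lh = lam * h
        decay = np.exp(-lh)
        inv = np.empty((n + 1, 3))
        small = lh < 1e-12
        for g in range(3):
            b = np.where(
                small, source[:, g] * h, source[:, g] / np.where(small, 1.0, lam) * (1.0 - decay)
            )
            inv[:, g] = _scan_linear(decay, b, x0[g] * v)
    elif method == "rk4":
        inv = _rk4_inventories(v, outflow, source, x0 * v, h, dt, step)
    else:
        raise ValueError(f"unknown integration method {method!r}")

    if np.any(inv <= 0):
        bad = np.argwhere(inv <= 0)[0]
        t_bad = force_trace.t0 + dt * (bad[0])
        raise SimulationError(
            f"gas inventory driven non-positive at t={t_bad:.0f} s "
            "(consumption exceeds supply)"
        )

    ch4_inv = v * np.concatenate((x_ch4[:1], x_ch4))
    total = inv.sum(axis=1) + ch4_inv
    frac = inv / total[:, None]
    o2 = force_trace.with_values(frac[:n, 0])
    co2 = force_trace.with_values(frac[:n, 1])
    ch4 = force_trace.with_values(ch4_inv[:n] / total[:n])
    return SimulationResult(
        o2_fraction=o2,
        co2_fraction=co2,
        inflow=inflow,
        inventories=inv,
        animal_vo2=vo2,
        animal_vco2=vco2,
        components=components,
        ch4_fraction=ch4,
    )


def _rk4_inventories(
    v: float,
    outflow: np.ndarray,
    source: np.ndarray,
    inv0: np.ndarray,
    h: float,
    dt: float,
    step: Optional[float],
) -> np.ndarray:
    """Fixed-step RK4 over dI/dt = source - outflow * I / sum(I)."""
    n = outflow.size
    sub = 1 if step is None else max(1, int(round(dt / step)))
    hs = h / sub
    inv = np.empty((n + 1, 3))
    inv[0] = inv0
    state = inv0.astype(float).copy()

    def deriv(y: np.ndarray, f_out: float, src: np.ndarray) -> np.ndarray:
        return src - f_out * y / y.sum()

    for j in range(n):
        f_out = outflow[j]
        src = source[j]
        for _ in range(sub):
            k1 = deriv(state, f_out, src)
            k2 = deriv(state + 0.5 * hs * k1, f_out, src)
            k3 = deriv(state + 0.5 * hs * k2, f_out, src)
            k4 = deriv(state + hs * k3, f_out, src)
            state = state + (hs / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        inv[j + 1] = state
    return inv
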