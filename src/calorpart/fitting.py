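"""Inverse estimation of the day model from observed gas concentrations.

Parameters are estimated per animal-day by minimizing the sum of
squared differences between predicted and measured O2 / CO2 fractions
of the outgoing air, with the derivative-free Nelder-Mead simplex.
Estimation is staged:

1. parameters directly tied to O2 consumption (VOFED, VOFOR, O2TEF and
   the shared TTEF) on the O2 residuals alone;
2. parameters tied to CO2 production (VCFED, VCFOR, CO2TEF) on the CO2
   residuals, with TTEF carried over from step 1;
3. a joint refinement of all parameters on the combined residuals.

Strictly positive parameters are optimized in log space, which keeps
the simplex unconstrained without penalty terms.  Days without feed or
without activity leave the corresponding coefficients unidentifiable;
they are frozen at their initial values and flagged.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Union

import numpy as np
from scipy.optimize import minimize

from .chamber import (
    ChamberSpec,
    FastingDayParameters,
    FedDayParameters,
    ManualEvent,
    simulate_chamber_day,
)
from .preprocess import PreprocessedDay

__all__ = ["FitOptions", "FitResult", "objective_sse", "fit_fed_day", "fit_fasting_day"]


@dataclass
class FitOptions:
    """Nelder-Mead settings shared by all fitting steps."""

    max_evals_per_step: int = 5000
    rel_sse_tol: float = 1e-8
    xatol: float = 1e-6            # log-parameter space
    restarts_on_stagnation: int = 1
    co2_weight: float = 1.0        # weight of CO2 SSE in the joint step


@dataclass
class FitResult:
    """Outcome of a day fit."""

    parameters: Union[FedDayParameters, FastingDayParameters]
    sse_o2: float
    sse_co2: float
    r2_o2: float
    r2_co2: float
    n_evals: int
    converged: bool
    step_log: list = field(default_factory=list)
    flags: dict = field(default_factory=dict)


def _unchecked(cls, values: dict):
    """Build a parameter object bypassing invariant checks (optimizer use)."""
    obj = object.__new__(cls)
    for k, v in values.items():
        setattr(obj, k, v)
    return obj


class _DayProblem:
    """Caches everything constant across objective evaluations of a day."""

    def __init__(
        self,
        day: PreprocessedDay,
        spec: ChamberSpec,
        events: Sequence[ManualEvent] = (),
        fast_start_s: float = 0.0,
    ):
        self.day = day
        self.spec = replace(spec, outflow=day.outflow_stp)
        self.events = tuple(events)
        self.fast_start_s = fast_start_s
        mask = day.valid.copy()
        edge = day.o2.flags.get("edge_filled_ticks", 0)
        if edge:
            mask[-edge:] = False
        self.mask = mask
        self.obs_o2 = day.o2.values
        self.obs_co2 = day.co2.values
        self.x0 = (self.obs_o2[0], self.obs_co2[0])
        # constant CH4 rate treated as known from the measured volumes
        self.ch4_rate = day.volumes.vch4 / day.volumes.duration_h if (
            day.volumes.duration_h > 0
        ) else 0.0
        m = self.mask
        self.tss_o2 = float(np.sum((self.obs_o2[m] - self.obs_o2[m].mean()) ** 2))
        self.tss_co2 = float(np.sum((self.obs_co2[m] - self.obs_co2[m].mean()) ** 2))
        self.n_evals = 0

    def predict(self, params):
        feed = None if isinstance(params, FastingDayParameters) else self.day.feed
        return simulate_chamber_day(
            self.spec,
            params,
            feed,
            self.day.force,
            self.events,
            initial_fractions=self.x0,
            fast_start_s=self.fast_start_s,
            ch4_rate=self.ch4_rate,
        )

    def sse(self, params, which: str = "both") -> float:
        self.n_evals += 1
        try:
            res = self.predict(params)
        except Exception:
            return np.inf
        m = self.mask
        s = 0.0
        if which in ("O2", "both"):
            s += float(np.sum((res.o2_fraction.values[m] - self.obs_o2[m]) ** 2))
        if which in ("CO2", "both"):
            s += float(np.sum((res.co2_fraction.values[m] - self.obs_co2[m]) ** 2))
        return s


def objective_sse(
    params: Union[FedDayParameters, FastingDayParameters],
    day: PreprocessedDay,
    spec: ChamberSpec,
    which: str = "both",
    events: Sequence[ManualEvent] = (),
    fast_start_s: float = 0.0,
) -> float:
    """Sum of squared concentration residuals (fraction^2) for one day."""
    if which not in ("O2", "CO2", "both"):
        raise ValueError("which must be 'O2', 'CO2' or 'both'")
    return _DayProblem(day, spec, events, fast_start_s).sse(params, which)


def _nelder_mead(fun, x0: np.ndarray, opts: FitOptions) -> tuple[np.ndarray, float, int, bool]:
    f0 = fun(x0)
    fatol = max(opts.rel_sse_tol * max(f0, 1e-300), 1e-300)
    best_x, best_f = x0, f0
    evals = 0
    converged = False
    start = x0
    for attempt in range(opts.restarts_on_stagnation + 1):
        res = minimize(
            fun,
            start,
            method="Nelder-Mead",
            options=dict(
                maxfev=opts.max_evals_per_step,
                fatol=fatol,
                xatol=opts.xatol,
                adaptive=len(x0) > 5,
            ),
        )
        evals += res.nfev
        if res.fun < best_f:
            best_x, best_f = res.x, res.fun
        if res.success:
            converged = True
            break
        # restart from a slightly perturbed best point
        start = best_x + 0.05 * np.random.default_rng(attempt).standard_normal(len(x0))
    return np.asarray(best_x), best_f, evals, converged


def _default_fed_init(day: PreprocessedDay, spec: ChamberSpec) -> dict:
    """Data-driven starting values.

    Resting levels from the quiet-night tick rates (activity in the
    lowest quartile before 06:00), activity coefficients from the
    regression of tick rate on force voltage, and the feeding
    coefficients from whatever daily exchange the other two terms leave
    unexplained.
    """
    from .preprocess import exchange_rates

    rates = exchange_rates(day.o2, day.co2, day.ch4, day.outflow_stp, spec)
    keep = day.valid[:-1] & day.valid[1:]
    force = day.force.values[:-1]
    vo2, vco2 = rates["vo2"], rates["vco2"]

    night = (day.force.times[:-1] < 6 * 3600.0) & keep
    if night.any():
        quiet = night & (force <= np.quantile(force[night], 0.25))
        quiet = quiet if quiet.any() else night
    else:
        quiet = keep
    vofed0 = max(float(np.median(vo2[quiet])), 1e-3)
    vcfed0 = max(float(np.median(vco2[quiet])), 1e-3)

    var_f = float(np.var(force[keep]))
    if var_f > 0:
        vofor0 = float(np.cov(vo2[keep], force[keep])[0, 1] / var_f)
        vcfor0 = float(np.cov(vco2[keep], force[keep])[0, 1] / var_f)
    else:
        vofor0 = vcfor0 = 1.0
    vofor0 = min(max(vofor0, 0.1), 50.0)
    vcfor0 = min(max(vcfor0, 0.1), 50.0)

    h = day.o2.dt / 3600.0
    feed_total = float(day.feed.values[-1] - day.feed.values[0])
    duration = float(keep.sum()) * h
    force_int = float(np.sum(force[keep]) * h)
    o2tef0 = co2tef0 = 0.05
    if feed_total > 0:
        resid_o2 = float(np.sum(vo2[keep]) * h) - vofed0 * duration - vofor0 * force_int
        resid_co2 = float(np.sum(vco2[keep]) * h) - vcfed0 * duration - vcfor0 * force_int
        o2tef0 = min(max(resid_o2 / feed_total, 0.005), 0.5)
        co2tef0 = min(max(resid_co2 / feed_total, 0.005), 0.5)

    return dict(
        VOFED=vofed0, VCFED=vcfed0,
        VOFOR=vofor0, VCFOR=vcfor0,
        O2TEF=o2tef0, CO2TEF=co2tef0,
        TTEF=2.0,
    )


def _fit_staged(
    problem: _DayProblem,
    cls,
    init: dict,
    steps: list,
    frozen: dict,
    opts: FitOptions,
) -> FitResult:
    """Generic staged Nelder-Mead driver over log-transformed subsets."""
    current = dict(init)
    step_log = []
    total_evals = 0
    all_converged = True

    for which, names in steps:
        free = [k for k in names if k not in frozen]
        if not free:
            continue

        def fun(logx, free=free, which=which):
            trial = dict(current)
            for k, v in zip(free, logx):
                trial[k] = np.exp(v)
            return problem.sse(_unchecked(cls, trial), which)

        x0 = np.log([max(current[k], 1e-12) for k in free])
        x, f, ne, conv = _nelder_mead(fun, x0, opts)
        for k, v in zip(free, x):
            current[k] = float(np.exp(v))
        total_evals += ne
        all_converged &= conv
        step_log.append({"which": which, "free": free, "sse": f,
                         "n_evals": ne, "converged": conv,
                         "params": dict(current)})

    flags = {}
    if cls is FastingDayParameters:
        for fast, fed in (("VOFAST", "VOFED"), ("VCFAST", "VCFED")):
            if current[fast] > current[fed]:
                warnings.warn(
                    f"{fast} estimated above {fed}; clipping to the fed level",
                    stacklevel=2,
                )
                current[fast] = current[fed]
                flags[f"{fast.lower()}_clipped"] = True
    params = cls(**{k: current[k] for k in cls.names})

    sse_o2 = problem.sse(params, "O2")
    sse_co2 = problem.sse(params, "CO2")
    return FitResult(
        parameters=params,
        sse_o2=sse_o2,
        sse_co2=sse_co2,
        r2_o2=1.0 - sse_o2 / problem.tss_o2 if problem.tss_o2 > 0 else np.nan,
        r2_co2=1.0 - sse_co2 / problem.tss_co2 if problem.tss_co2 > 0 else np.nan,
        n_evals=total_evals,
        converged=all_converged,
        step_log=step_log,
        flags=flags,
    )


def fit_fed_day(
    day: PreprocessedDay,
    spec: ChamberSpec,
    init: Optional[dict] = None,
    options: Optional[FitOptions] = None,
    events: Sequence[ManualEvent] = (),
) -> FitResult:
    """Estimate the seven fed-day parameters from one preprocessed day."""
    opts = options or FitOptions()
    problem = _DayProblem(day, spec, events)
    start = _default_fed_init(day, spec)
    if init:
        start.update(init)

    frozen = {}
    feed_total = float(day.feed.values[-1] - day.feed.values[0])
    if feed_total <= 0:
        frozen.update(O2TEF=True, CO2TEF=True, TTEF=True)
        start["O2TEF"] = start["CO2TEF"] = 0.0
    if day.force.integral() <= 0:
        frozen.update(VOFOR=True, VCFOR=True)
        start["VOFOR"] = start["VCFOR"] = 0.0

    steps = [
        ("O2", ["VOFED", "VOFOR", "O2TEF", "TTEF"]),
        ("CO2", ["VCFED", "VCFOR", "CO2TEF"]),
        ("both", list(FedDayParameters.names)),
    ]
    result = _fit_staged(problem, FedDayParameters, start, steps, frozen, opts)
    if frozen:
        result.flags["unidentifiable"] = sorted(frozen)
    return result


def fit_fasting_day(
    day: PreprocessedDay,
    spec: ChamberSpec,
    fed_params: FedDayParameters,
    init: Optional[dict] = None,
    options: Optional[FitOptions] = None,
    events: Sequence[ManualEvent] = (),
    *,
    fast_start_s: float = 0.0,
    reestimate_fed_levels: bool = False,
) -> FitResult:
    """Estimate the fasting-day parameters.

    The fed-state levels (VOFED, VCFED) anchor the top of the
    first-order decline; by default they are fixed at the values fitted
    on the fed days (``reestimate_fed_levels=True`` frees them).
    """
    opts = options or FitOptions()
    problem = _DayProblem(day, spec, events, fast_start_s)
    start = dict(
        VOFED=fed_params.VOFED,
        VCFED=fed_params.VCFED,
        VOFOR=fed_params.VOFOR,
        VCFOR=fed_params.VCFOR,
        VOFAST=0.7 * fed_params.VOFED,
        VCFAST=0.7 * fed_params.VCFED,
        TOADAP=4.0,
        TCADAP=4.0,
    )
    if init:
        start.update(init)

    frozen = {}
    if not reestimate_fed_levels:
        frozen.update(VOFED=True, VCFED=True)
    if day.force.integral() <= 0:
        frozen.update(VOFOR=True, VCFOR=True)
        start["VOFOR"] = start["VCFOR"] = 0.0

    steps = [
        ("O2", ["VOFED", "VOFAST", "TOADAP", "VOFOR"]),
        ("CO2", ["VCFED", "VCFAST", "TCADAP", "VCFOR"]),
        ("both", list(FastingDayParameters.names)),
    ]
    result = _fit_staged(problem, FastingDayParameters, start, steps, frozen, opts)
    if frozen:
        result.flags["fixed"] = sorted(frozen)
    return result
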