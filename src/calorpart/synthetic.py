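"""Synthetic respiration-chamber cohorts with known ground truth.

No individual-animal chamber recordings from this kind of experiment
are publicly deposited, so every downstream module is exercised against
synthetic data whose generating parameters are known exactly.  The
generator emulates the full measurement chain of a growing-pig energy
balance study:

* a cohort of groups x three sex classes (entire male EM, surgically
  castrated SC, immunocastrated IC), body weight ~115 kg, each animal
  measured 6 fed days and 1 fasting day;
* ad-libitum feeding bouts (marked point process: exponential gaps,
  lognormal sizes) with the feeder locked 06:00-09:00;
* rectangular activity bouts with lognormal amplitudes over a low
  baseline, diurnally modulated, amplitude independent of duration;
* chamber gas traces from the forward model, then the instrument layer:
  linear analyzer drift, 70-s transport lag, analyzer noise, a 15-min
  morning interruption, outflow recorded at chamber conditions;
* a per-period laboratory table (feed, N streams, assayed energies)
  energetically consistent with the gas traces.

Default magnitudes are calibrated to published LS-means for this animal
model: ME 2400-2900 kJ/kg BW^0.60/day, FHP 730-860 kJ/kg BW^0.60/day,
AHP/ME around 8.6%.  Everything is deterministic given the scenario
seed; each animal-day is realized from an independent child seed so
days can be regenerated lazily and in any order.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import constants as C
from .chamber import (
    ChamberSpec,
    FastingDayParameters,
    FedDayParameters,
    simulate_chamber_day,
)
from .preprocess import AnalyzerCalibration, RawDayRecording
from .traces import SignalTrace, full_day_grid

__all__ = [
    "ClassTargets",
    "CohortScenario",
    "AnimalTruth",
    "SyntheticCohort",
    "generate_feeding_bouts",
    "generate_activity_trace",
    "draw_animal",
    "generate_chamber_day",
    "generate_cohort",
]

N_TICKS = 8640


@dataclass
class ClassTargets:
    """Energetic magnitudes of one sex class (per kg BW^0.60 per day)."""

    bw_mean: float               # kg
    me_per_msize: float          # kJ/kg^0.60/day
    fhp_per_msize: float         # kJ/kg^0.60/day
    tef_fraction_of_me: float    # total TEF as fraction of ME
    pd_g_per_day: float          # protein deposition
    rq_rest_fed: float           # resting fed respiratory quotient
    me_content_kj_g_dm: float    # dietary ME density


DEFAULT_CLASS_TARGETS = {
    "EM": ClassTargets(114.0, 2396.0, 856.0, 0.130, 261.0, 1.08, 15.41),
    "SC": ClassTargets(111.0, 2632.0, 735.0, 0.175, 196.0, 1.14, 15.37),
    "IC": ClassTargets(120.1, 2864.0, 783.0, 0.169, 246.0, 1.15, 15.13),
}


@dataclass
class CohortScenario:
    """Everything needed to generate a cohort deterministically."""

    seed: int = 0
    n_groups: int = 6
    classes: tuple = ("EM", "SC", "IC")
    class_targets: dict = field(default_factory=lambda: dict(DEFAULT_CLASS_TARGETS))
    n_fed_days: int = 6

    # between-animal variation
    bw_sd: float = 6.0                   # kg
    me_sd_per_msize: float = 110.0       # kJ/kg^0.60/day
    fhp_sd_per_msize: float = 36.0
    ahp_me_ratio_mean: float = 0.086
    ahp_me_ratio_sd: float = 0.015
    tef_fraction_sd: float = 0.012
    tef_short_fraction: float = 0.60     # share of TEF that is meal-locked
    ttef_mean_h: float = 2.0
    ttef_sd_h: float = 0.3
    rq_fasting: float = 0.85
    rq_tef_short: float = 1.10
    rq_activity: float = 1.00
    toadap_range_h: tuple = (2.5, 5.0)
    urinary_n_fasting_g: float = 20.0
    gross_energy_kj_g_dm: float = 18.61
    crude_protein_fraction_dm: float = 0.2011
    fecal_n_fraction: float = 0.12
    ammonia_n_g_per_day: float = 1.5
    urine_energy_kj_per_g_n: float = 48.0
    ch4_l_per_day_fed: float = 30.0
    ch4_l_per_day_fasting: float = 7.0
    dm_fraction_as_fed: float = 0.88
    bw_gain_kg_per_day: float = 1.27

    # meal pattern
    meal_rate_per_open_hour: float = 0.55
    meal_size_cv: float = 0.45
    eating_rate_g_per_min: float = 110.0
    lockout_window_h: tuple = (6.0, 9.0)
    daily_intake_cv: float = 0.05

    # activity pattern
    force_mean_mv_range: tuple = (1.6, 4.0)
    activity_bout_rate_per_day: float = 60.0
    activity_bout_duration_min: float = 4.0
    activity_amplitude_cv: float = 0.8
    force_baseline_mv: float = 0.12
    fasting_activity_factor: float = 0.7
    standing_threshold_mv: float = 2.0

    # chamber and instruments
    chamber_volume_l: float = 12000.0
    outflow_mean_l_h: float = 7500.0
    outflow_diurnal_amp: float = 150.0
    temperature_c: float = 24.0
    humidity_pct: float = 70.0
    pressure_atm: float = 1.0
    analyzer_noise_sd: float = 2e-5      # fraction (0.002 %-points)
    analyzer_drift_sd: float = 5e-5      # fraction per day, linear
    force_noise_sd_mv: float = 0.05
    outflow_noise_sd: float = 5.0        # L/h
    lag_s: float = C.DEFAULT_LAG_S
    interruption: tuple = (8 * 3600.0, 8 * 3600.0 + 15 * 60.0)
    span_gas = {"o2": 0.190, "co2": 0.012, "ch4": 0.001}

    @property
    def n_animals(self) -> int:
        return self.n_groups * len(self.classes)

    # -- determinism ----------------------------------------------------
    def rng(self, *key: int) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence((self.seed, *key)))

    # -- serialization --------------------------------------------------
    def to_yaml(self) -> str:
        d = dataclasses.asdict(self)
        d["class_targets"] = {
            k: dataclasses.asdict(v) for k, v in self.class_targets.items()
        }
        return yaml.safe_dump(d)

    @classmethod
    def from_yaml(cls, text: str) -> "CohortScenario":
        d = yaml.safe_load(text)
        d["class_targets"] = {
            k: ClassTargets(**v) for k, v in d.get("class_targets", {}).items()
        }
        for key in ("classes", "toadap_range_h", "lockout_window_h",
                    "force_mean_mv_range", "interruption"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class AnimalTruth:
    """Generating ground truth of one animal."""

    animal_id: str
    group: int
    sex_class: str
    bw: float
    bw_start: float
    bw_end: float
    fed_params: FedDayParameters
    fasting_params: FastingDayParameters
    dm_intake_g_per_day: float
    force_mean_mv: float
    ahp_me_ratio: float
    urinary_n_fasting: float
    ch4_rate_fed: float
    ch4_rate_fasting: float

    @property
    def metabolic_size(self) -> float:
        return self.bw ** C.METABOLIC_EXPONENT


# ----------------------------------------------------------------------
# behavioral signal generators
# ----------------------------------------------------------------------

def generate_feeding_bouts(
    scenario: CohortScenario, rng: np.random.Generator, total_g: float
) -> SignalTrace:
    """Cumulative as-fed feed trace (g) for one day.

    Bout start times follow a homogeneous point process over the hours
    the feeder is open; bout sizes are lognormal and rescaled so the day
    totals ``total_g`` exactly; each bout is ingested at a constant
    eating rate.
    """
    t = full_day_grid()
    n = t.size
    cum = np.zeros(n)
    if total_g <= 0:
        return SignalTrace(0.0, C.TICK_S, cum)

    lock0, lock1 = (h * 3600.0 for h in scenario.lockout_window_h)
    open_hours = 24.0 - (lock1 - lock0) / 3600.0
    n_bouts = max(1, rng.poisson(scenario.meal_rate_per_open_hour * open_hours))
    starts = rng.uniform(0.0, 86400.0, size=n_bouts * 4)
    starts = starts[(starts < lock0) | (starts >= lock1)][:n_bouts]
    if starts.size == 0:
        starts = np.array([lock1 + 600.0])
    sigma = np.sqrt(np.log(1.0 + scenario.meal_size_cv ** 2))
    sizes = rng.lognormal(mean=-0.5 * sigma ** 2, sigma=sigma, size=starts.size)
    sizes *= total_g / sizes.sum()

    rate_per_tick = scenario.eating_rate_g_per_min / 6.0   # g per 10 s
    intake = np.zeros(n)
    for s, m in zip(np.sort(starts), sizes):
        k = int(s // C.TICK_S)
        remaining = m
        while remaining > 0 and k < n:
            tk = k * C.TICK_S
            if lock0 <= tk < lock1:     # bout truncated by lockout
                break
            bite = min(rate_per_tick, remaining)
            intake[k] += bite
            remaining -= bite
            k += 1
    np.cumsum(intake, out=cum)
    return SignalTrace(0.0, C.TICK_S, cum)


def generate_activity_trace(
    scenario: CohortScenario,
    rng: np.random.Generator,
    mean_mv: float,
) -> SignalTrace:
    """Force-sensor voltage trace (mV): rectangular bouts over baseline.

    Bout amplitude is drawn independently of duration, so time spent
    active is a poor predictor of the mechanical work — mirroring the
    weak standing-time/AHP association seen with infrared barriers.
    """
    t = full_day_grid()
    n = t.size
    base = np.abs(rng.normal(scenario.force_baseline_mv, scenario.force_baseline_mv / 3, n))
    n_bouts = rng.poisson(scenario.activity_bout_rate_per_day)
    # diurnal modulation: more activity in daytime
    hours = rng.uniform(0, 24, size=max(n_bouts, 1) * 3)
    weight = 1.0 + 0.8 * np.sin((hours - 6.0) / 24.0 * 2 * np.pi - np.pi / 2) ** 2
    keep = rng.uniform(0, weight.max(), size=hours.size) < weight
    hours = hours[keep][:n_bouts]
    signal = base.copy()
    sigma = np.sqrt(np.log(1.0 + scenario.activity_amplitude_cv ** 2))
    for h0 in hours:
        dur_ticks = max(1, int(rng.exponential(scenario.activity_bout_duration_min) * 6))
        amp = rng.lognormal(np.log(4.0) - 0.5 * sigma ** 2, sigma)
        k = int(h0 * 360.0)
        signal[k : k + dur_ticks] += amp
    current = signal.mean()
    if current > 0:
        signal *= mean_mv / current
    return SignalTrace(0.0, C.TICK_S, signal)


# ----------------------------------------------------------------------
# animal-level truth
# ----------------------------------------------------------------------

def _energy_to_o2(kj: float, rq: float) -> float:
    """L O2 carrying ``kj`` of Brouwer heat at respiratory quotient rq."""
    return kj / (C.BROUWER_O2 + C.BROUWER_CO2 * rq)


def draw_animal(scenario: CohortScenario, group: int, sex_class: str) -> AnimalTruth:
    """Draw one animal's ground-truth parameters from the class targets."""
    rng = scenario.rng(1, group, scenario.classes.index(sex_class))
    tgt = scenario.class_targets[sex_class]

    bw = max(60.0, rng.normal(tgt.bw_mean, scenario.bw_sd))
    msize = bw ** C.METABOLIC_EXPONENT
    me_total = max(1200.0, rng.normal(tgt.me_per_msize, scenario.me_sd_per_msize)) * msize
    fhp_total = max(400.0, rng.normal(tgt.fhp_per_msize, scenario.fhp_sd_per_msize)) * msize
    ratio = float(np.clip(
        rng.normal(scenario.ahp_me_ratio_mean, scenario.ahp_me_ratio_sd), 0.03, 0.16
    ))
    tef_frac = float(np.clip(
        rng.normal(tgt.tef_fraction_of_me, scenario.tef_fraction_sd), 0.05, 0.30
    ))
    ttef = float(np.clip(rng.normal(scenario.ttef_mean_h, scenario.ttef_sd_h), 0.8, 4.0))

    # fasting asymptote from FHP at the fasting RQ
    vofast = (fhp_total + C.BROUWER_N * scenario.urinary_n_fasting_g) / (
        24.0 * (C.BROUWER_O2 + C.BROUWER_CO2 * scenario.rq_fasting)
    )
    vcfast = scenario.rq_fasting * vofast

    # fed resting level: fasting + long-term TEF, at the fed resting RQ
    tef_l_kj = (1.0 - scenario.tef_short_fraction) * tef_frac * me_total
    vofed = vofast + tef_l_kj / 24.0 / (
        C.BROUWER_O2 + C.BROUWER_CO2 * tgt.rq_rest_fed
    )
    vcfed = tgt.rq_rest_fed * vofed

    # short-term TEF coefficients per g of as-fed feed
    dm_intake = me_total / tgt.me_content_kj_g_dm
    as_fed_intake = dm_intake / scenario.dm_fraction_as_fed
    tef_s_kj = scenario.tef_short_fraction * tef_frac * me_total
    o2tef = _energy_to_o2(tef_s_kj, scenario.rq_tef_short) / as_fed_intake
    co2tef = scenario.rq_tef_short * o2tef

    # activity coefficients from the AHP target and the force pattern
    force_mean = rng.uniform(*scenario.force_mean_mv_range)
    ahp_kj = ratio * me_total
    ahp_o2 = _energy_to_o2(ahp_kj, scenario.rq_activity)
    vofor = ahp_o2 / (force_mean * 24.0)
    vcfor = scenario.rq_activity * vofor

    toadap = rng.uniform(*scenario.toadap_range_h)
    tcadap = float(np.clip(toadap * rng.normal(1.0, 0.1), *scenario.toadap_range_h))

    fed = FedDayParameters(vofed, vcfed, vofor, vcfor, o2tef, co2tef, ttef)
    fasting = FastingDayParameters(
        vofed, vcfed, vofor, vcfor, vofast, vcfast, toadap, tcadap
    )
    half_span = scenario.bw_gain_kg_per_day * scenario.n_fed_days / 2.0
    return AnimalTruth(
        animal_id=f"{sex_class}{group + 1}",
        group=group,
        sex_class=sex_class,
        bw=bw,
        bw_start=bw - half_span,
        bw_end=bw + half_span,
        fed_params=fed,
        fasting_params=fasting,
        dm_intake_g_per_day=dm_intake,
        force_mean_mv=force_mean,
        ahp_me_ratio=ratio,
        urinary_n_fasting=scenario.urinary_n_fasting_g,
        ch4_rate_fed=scenario.ch4_l_per_day_fed / 24.0,
        ch4_rate_fasting=scenario.ch4_l_per_day_fasting / 24.0,
    )


# ----------------------------------------------------------------------
# one chamber day
# ----------------------------------------------------------------------

def generate_chamber_day(
    scenario: CohortScenario,
    animal: AnimalTruth,
    day: int,
    fasted: bool = False,
) -> tuple[RawDayRecording, dict]:
    """Realize one animal-day: raw recording plus generating truth.

    The truth dict carries the exact parameters, the noise-free daily
    exchange volumes, and the per-component volumes of the animal
    sub-model.
    """
    rng = scenario.rng(2, animal.group, scenario.classes.index(animal.sex_class), day)
    t = full_day_grid()
    n = t.size

    force_mean = animal.force_mean_mv * (
        scenario.fasting_activity_factor if fasted else rng.normal(1.0, 0.08)
    )
    force_true = generate_activity_trace(scenario, rng, max(force_mean, 0.2))

    if fasted:
        feed_true = SignalTrace(0.0, C.TICK_S, np.zeros(n))
        params = animal.fasting_params
        ch4_rate = animal.ch4_rate_fasting
    else:
        total = animal.dm_intake_g_per_day / scenario.dm_fraction_as_fed
        total *= max(0.5, rng.normal(1.0, scenario.daily_intake_cv))
        feed_true = generate_feeding_bouts(scenario, rng, total)
        params = animal.fed_params
        ch4_rate = animal.ch4_rate_fed

    outflow_stp = (
        scenario.outflow_mean_l_h
        + scenario.outflow_diurnal_amp * np.sin(2 * np.pi * (t / 86400.0 - 0.3))
    )
    spec = ChamberSpec(
        physical_volume=scenario.chamber_volume_l,
        outflow=SignalTrace(0.0, C.TICK_S, outflow_stp),
    )
    sim = simulate_chamber_day(
        spec, params, None if fasted else feed_true, force_true,
        ch4_rate=ch4_rate,
    )

    # ---- instrument layer --------------------------------------------
    lag_ticks = int(round(scenario.lag_s / C.TICK_S))
    drift = {g: rng.normal(0.0, scenario.analyzer_drift_sd) for g in ("o2", "co2", "ch4")}
    w = t / 86400.0

    def record_gas(name: str, true_values: np.ndarray) -> SignalTrace:
        lagged = np.empty(n)
        lagged[lag_ticks:] = true_values[: n - lag_ticks]
        lagged[:lag_ticks] = true_values[0]
        noisy = lagged + drift[name] * w + rng.normal(0.0, scenario.analyzer_noise_sd, n)
        return SignalTrace(0.0, C.TICK_S, noisy)

    o2_rec = record_gas("o2", sim.o2_fraction.values)
    co2_rec = record_gas("co2", sim.co2_fraction.values)
    ch4_rec = record_gas("ch4", sim.ch4_fraction.values)

    cin = spec.ingoing_air_fractions
    base_true = {"o2": cin[0], "co2": cin[1], "ch4": 0.0}
    calibrations = {
        g: AnalyzerCalibration(
            baseline_true=base_true[g],
            span_true=scenario.span_gas[g],
            baseline_start=base_true[g],
            baseline_end=base_true[g] + drift[g],
            span_start=scenario.span_gas[g],
            span_end=scenario.span_gas[g] + drift[g],
        )
        for g in ("o2", "co2", "ch4")
    }

    temperature = SignalTrace(0.0, C.TICK_S, scenario.temperature_c
                              + 0.3 * np.sin(2 * np.pi * w) + rng.normal(0, 0.05, n))
    pressure = SignalTrace(0.0, C.TICK_S, scenario.pressure_atm
                           + 0.001 * np.sin(2 * np.pi * (w - 0.2))
                           + rng.normal(0, 5e-5, n))
    humidity = SignalTrace(0.0, C.TICK_S, np.clip(
        scenario.humidity_pct + rng.normal(0, 0.5, n), 0, 100))

    from .preprocess import saturation_vapor_pressure_atm  # local import, no cycle

    p_dry = pressure.values - humidity.values / 100.0 * saturation_vapor_pressure_atm(
        temperature.values
    )
    stp_factor = (C.STP_TEMPERATURE_K / (C.STP_TEMPERATURE_K + temperature.values)) * p_dry
    outflow_rec = SignalTrace(
        0.0, C.TICK_S,
        outflow_stp / stp_factor + rng.normal(0, scenario.outflow_noise_sd, n),
    )

    force_rec = force_true.with_values(
        np.clip(force_true.values + rng.normal(0, scenario.force_noise_sd_mv, n), 0, None)
    )
    feed_rec = feed_true
    standing = force_true.with_values(
        (force_true.values > scenario.standing_threshold_mv).astype(float)
    )

    # blank the analyzers during the care/calibration interruption
    i0, i1 = scenario.interruption
    gap = (t + C.TICK_S > i0) & (t < i1)
    for tr in (o2_rec, co2_rec, ch4_rec):
        tr.values[gap] = np.nan

    rec = RawDayRecording(
        o2=o2_rec, co2=co2_rec, ch4=ch4_rec,
        outflow=outflow_rec,
        temperature=temperature, pressure=pressure, humidity=humidity,
        force=force_rec, feed=feed_rec, standing=standing,
        interruptions=[scenario.interruption],
        calibrations=calibrations,
        animal_id=animal.animal_id, day=day, fasted=fasted,
    )
    h = C.TICK_S / 3600.0
    truth = {
        "animal_id": animal.animal_id,
        "day": day,
        "fasted": fasted,
        "params": params,
        "vo2_L": float(sim.animal_vo2.sum() * h),
        "vco2_L": float(sim.animal_vco2.sum() * h),
        "vch4_L": ch4_rate * 24.0,
        "components": sim.components,
        "feed_g": float(feed_true.values[-1]),
        "force_integral_mv_h": force_true.integral(),
        "o2_true": sim.o2_fraction,
        "co2_true": sim.co2_fraction,
    }
    return rec, truth


# ----------------------------------------------------------------------
# cohort
# ----------------------------------------------------------------------

@dataclass
class SyntheticCohort:
    """Lazy handle on a generated cohort.

    Days are realized on demand (deterministically) to keep memory
    bounded; the per-animal truth and the laboratory assay table are
    materialized eagerly.
    """

    scenario: CohortScenario
    animals: list

    def chamber_spec(self) -> ChamberSpec:
        return ChamberSpec(physical_volume=self.scenario.chamber_volume_l)

    def day_index(self) -> list:
        out = []
        for a in self.animals:
            for d in range(self.scenario.n_fed_days):
                out.append((a.animal_id, d, False))
            out.append((a.animal_id, self.scenario.n_fed_days, True))
        return out

    def animal(self, animal_id: str) -> AnimalTruth:
        for a in self.animals:
            if a.animal_id == animal_id:
                return a
        raise KeyError(animal_id)

    def realize_day(self, animal_id: str, day: int):
        a = self.animal(animal_id)
        fasted = day >= self.scenario.n_fed_days
        return generate_chamber_day(self.scenario, a, day, fasted)

    def truth_table(self) -> pd.DataFrame:
        rows = []
        for a in self.animals:
            fp = a.fed_params
            gp = a.fasting_params
            rows.append({
                "animal_id": a.animal_id, "group": a.group,
                "sex_class": a.sex_class, "bw": a.bw,
                "metabolic_size": a.metabolic_size,
                "ahp_me_ratio": a.ahp_me_ratio,
                **{k: getattr(fp, k) for k in fp.names},
                "VOFAST": gp.VOFAST, "VCFAST": gp.VCFAST,
                "TOADAP": gp.TOADAP, "TCADAP": gp.TCADAP,
            })
        return pd.DataFrame(rows)

    def assay_table(self) -> pd.DataFrame:
        """Per-animal period laboratory table (6 fed days pooled)."""
        sc = self.scenario
        rows = []
        for a in self.animals:
            days = sc.n_fed_days
            rng = sc.rng(3, a.group, sc.classes.index(a.sex_class))
            dm = a.dm_intake_g_per_day * days
            ge = sc.gross_energy_kj_g_dm * dm
            tgt = sc.class_targets[a.sex_class]
            me = tgt.me_content_kj_g_dm * dm
            n_in = sc.crude_protein_fraction_dm / C.PROTEIN_PER_G_N * dm
            pd_day = max(80.0, rng.normal(tgt.pd_g_per_day, 20.0))
            n_ret = pd_day / C.PROTEIN_PER_G_N * days
            n_fecal = sc.fecal_n_fraction * n_in
            n_ammonia = sc.ammonia_n_g_per_day * days
            n_urinary = n_in - n_fecal - n_ret - n_ammonia
            if n_urinary < 0:
                raise ValueError("scenario implies negative urinary N")
            urine_e = sc.urine_energy_kj_per_g_n * (n_urinary + n_ammonia)
            ch4 = sc.ch4_l_per_day_fed * days
            fecal_e = ge - me - urine_e - C.CH4_ENERGY_KJ_PER_L * ch4
            offered = dm / sc.dm_fraction_as_fed * 1.04
            intake_as_fed = dm / sc.dm_fraction_as_fed
            rows.append({
                "animal_id": a.animal_id, "sex_class": a.sex_class,
                "group": a.group,
                "bw_start": a.bw_start, "bw_end": a.bw_end, "days": days,
                "feed_offered_g": offered, "refusals_g": offered - intake_as_fed,
                "spillage_g": 0.0, "feed_dm_g": dm,
                "ge_intake_kj": ge, "fecal_e_kj": fecal_e, "urine_e_kj": urine_e,
                "ch4_l": ch4,
                "n_intake_g": n_in, "n_fecal_g": n_fecal,
                "n_urinary_g": n_urinary, "n_ammonia_g": n_ammonia,
                "urinary_n_fasting_g": a.urinary_n_fasting,
            })
        return pd.DataFrame(rows)


def truth_energy_summary(cohort: SyntheticCohort) -> pd.DataFrame:
    """Per-animal energy components implied by the generating truth.

    Applies the same partition and standardization algebra the pipeline
    uses, but with the exact generating parameters and noise-free
    volumes — the oracle for end-to-end recovery checks.  Energy traits
    are kJ/kg BW^0.60/day.
    """
    from .balance import BalancePeriod, energy_balance
    from .partition import brouwer_hp
    from .standardize import activity_ratio, correct_activity

    assay = cohort.assay_table().set_index("animal_id")
    rows = []
    for a in cohort.animals:
        row = assay.loc[a.animal_id]
        days = int(row["days"])
        n_day = (row["n_urinary_g"] + row["n_ammonia_g"]) / days
        gp = a.fasting_params
        fhp = brouwer_hp(24 * gp.VOFAST, 24 * gp.VCFAST, 0.0, a.urinary_n_fasting)
        hp = ahp = tef_s = 0.0
        for d in range(days):
            _, truth = cohort.realize_day(a.animal_id, d)
            comp = truth["components"]
            hp += brouwer_hp(truth["vo2_L"], truth["vco2_L"], truth["vch4_L"], n_day)
            ahp += brouwer_hp(comp["activity_o2_L"], comp["activity_co2_L"])
            tef_s += brouwer_hp(comp["tef_o2_L"], comp["tef_co2_L"])
        hp, ahp, tef_s = hp / days, ahp / days, tef_s / days
        tef = tef_s + (hp - ahp - tef_s - fhp)
        period = BalancePeriod(
            animal_id=a.animal_id, sex_class=a.sex_class,
            bw_start=row["bw_start"], bw_end=row["bw_end"], days=days,
            feed_offered=row["feed_offered_g"], refusals=row["refusals_g"],
            spillage=row["spillage_g"],
            ge_intake=row["ge_intake_kj"], fecal_e=row["fecal_e_kj"],
            urine_e=row["urine_e_kj"], ch4=row["ch4_l"],
            n_intake=row["n_intake_g"], n_fecal=row["n_fecal_g"],
            n_urinary=row["n_urinary_g"], n_ammonia=row["n_ammonia_g"],
            hp=hp * days,
        )
        eb = energy_balance(period)
        ms = eb.metabolic_size
        rows.append({
            "animal_id": a.animal_id, "sex_class": a.sex_class,
            "metabolic_size": ms,
            "me": eb.me / ms, "fhp": fhp / ms, "ahp": ahp / ms,
            "tef": tef / ms, "hp": hp / ms, "re": eb.re / ms,
        })
    df = pd.DataFrame(rows).set_index("animal_id")
    ratio = activity_ratio(df["ahp"], df["me"])
    hi = []
    for aid, r in df.iterrows():
        cb = correct_activity(
            r["me"], r["fhp"], r["ahp"], r["tef"], r["re"], ratio, animal_id=aid
        )
        hi.append(cb.HI)
    df["hi"] = hi
    df.attrs["ahp_me_ratio"] = ratio
    return df


def generate_cohort(scenario: Optional[CohortScenario] = None) -> SyntheticCohort:
    """Draw the full cohort (animals only; days realize lazily)."""
    sc = scenario or CohortScenario()
    animals = [
        draw_animal(sc, g, cls)
        for g in range(sc.n_groups)
        for cls in sc.classes
    ]
    return SyntheticCohort(scenario=sc, animals=animals)
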