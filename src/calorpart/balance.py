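"""Nitrogen and energy balance over a measurement period.

A balance period pools several consecutive fed days of one animal:
feed offered minus refusals and spillage, the nitrogen streams (feces,
urine, ammonia recovered from condensate and outgoing air), the assayed
energies, methane, and the heat production from calorimetry.  Derived
per-day quantities:

* ME  = (GE - fecal E - urinary E - 39.5 kJ/L x CH4) / days
* N retention -> protein deposition PD = 6.25 x N_ret
* RE = ME - HP;  FD = (RE - 23.6 PD) / 39.7
* metabolic body size = BW ** 0.60
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

from . import constants as C

__all__ = [
    "BalancePeriod",
    "EnergyBalance",
    "nitrogen_balance",
    "me_intake",
    "retained_energy",
    "fat_deposition",
    "metabolic_size",
    "energy_balance",
]


@dataclass
class BalancePeriod:
    """Pooled laboratory and calorimetry results of one animal-period."""

    animal_id: str
    sex_class: str               # EM | SC | IC
    bw_start: float              # kg
    bw_end: float                # kg
    days: int
    feed_offered: float          # g DM
    refusals: float              # g DM
    spillage: float              # g DM
    ge_intake: float             # kJ over the period
    fecal_e: float               # kJ
    urine_e: float               # kJ
    ch4: float                   # L STP over the period
    n_intake: float              # g
    n_fecal: float               # g
    n_urinary: float             # g
    n_ammonia: float             # g
    hp: float                    # kJ over the period

    def __post_init__(self) -> None:
        if self.days < 1:
            raise ValueError("period must span at least one day")
        for name in ("feed_offered", "refusals", "spillage", "ge_intake",
                     "fecal_e", "urine_e", "ch4", "n_intake", "n_fecal",
                     "n_urinary", "n_ammonia", "hp"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.refusals + self.spillage > self.feed_offered:
            raise ValueError("refusals + spillage exceed offered feed")

    @property
    def feed_intake(self) -> float:
        """g DM ingested over the period."""
        return self.feed_offered - self.refusals - self.spillage

    @property
    def urinary_n_total(self) -> float:
        """Urinary N including recovered ammonia, g over the period."""
        return self.n_urinary + self.n_ammonia


@dataclass
class EnergyBalance:
    """Per-day energy balance derived from a :class:`BalancePeriod`."""

    me: float                    # kJ/day
    re: float                    # kJ/day
    pd: float                    # g/day
    fd: float                    # g/day
    rq: Optional[float]          # unitless
    metabolic_size: float        # kg^0.60
    flags: dict = field(default_factory=dict)


def nitrogen_balance(period: BalancePeriod) -> tuple[float, float]:
    """(N retained g/day, protein deposition g/day)."""
    n_ret = (
        period.n_intake - period.n_fecal - period.n_urinary - period.n_ammonia
    ) / period.days
    if n_ret < 0:
        warnings.warn(
            f"negative N retention ({n_ret:.1f} g/day) for {period.animal_id}",
            stacklevel=2,
        )
    return n_ret, C.PROTEIN_PER_G_N * n_ret


def me_intake(period: BalancePeriod) -> float:
    """Metabolizable energy intake, kJ/day."""
    me = (
        period.ge_intake
        - period.fecal_e
        - period.urine_e
        - C.CH4_ENERGY_KJ_PER_L * period.ch4
    ) / period.days
    if me > period.ge_intake / period.days:
        raise ValueError("ME cannot exceed gross energy intake")
    return me


def retained_energy(period: BalancePeriod, me: Optional[float] = None) -> float:
    """Retained energy RE = ME - HP, kJ/day."""
    if me is None:
        me = me_intake(period)
    return me - period.hp / period.days


def fat_deposition(re: float, pd: float) -> float:
    """Fat deposition g/day from RE (kJ/day) and PD (g/day)."""
    return (re - C.ENERGY_PER_G_PROTEIN * pd) / C.ENERGY_PER_G_FAT


def metabolic_size(bw: float, exponent: float = C.METABOLIC_EXPONENT) -> float:
    """Metabolic body size, kg ** exponent (default 0.60)."""
    if bw <= 0:
        raise ValueError("body weight must be positive")
    return bw ** exponent


def energy_balance(
    period: BalancePeriod,
    *,
    vo2: Optional[float] = None,
    vco2: Optional[float] = None,
    exponent: float = C.METABOLIC_EXPONENT,
) -> EnergyBalance:
    """Full per-day energy balance of one period.

    Metabolic size uses the mean of start and end BW.  If the period's
    daily gas volumes are supplied, the respiratory quotient is
    reported.
    """
    me = me_intake(period)
    re = retained_energy(period, me)
    _, pd = nitrogen_balance(period)
    fd = fat_deposition(re, pd)
    flags = {}
    if fd < 0:
        flags["negative_fd"] = True
        warnings.warn(
            f"negative fat deposition ({fd:.1f} g/day) for {period.animal_id}",
            stacklevel=2,
        )
    rq = (vco2 / vo2) if (vo2 and vco2) else None
    bw_mean = 0.5 * (period.bw_start + period.bw_end)
    return EnergyBalance(
        me=me,
        re=re,
        pd=pd,
        fd=fd,
        rq=rq,
        metabolic_size=metabolic_size(bw_mean, exponent),
        flags=flags,
    )
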