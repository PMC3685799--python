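"""Activity standardization of heat production and derived efficiencies.

Between-animal differences in physical activity bias the heat increment
and every quantity derived from it.  The standardization fixes the
activity heat of every animal at the cohort-mean fraction of its ME
intake (AHP_c = ratio x ME); the energy freed (or added) by the
correction is split between the thermic effect of feeding and retained
energy in proportion to the fed-state partition:

    dTEF  = (AHP - AHP_c) * TEF / (ME - FHP - AHP)
    TEF_c = TEF + dTEF
    RE_c  = RE + (AHP - AHP_c) - dTEF

so that FHP + AHP_c + TEF_c + RE_c = ME remains exact.  Downstream:

    HI = AHP_c + TEF_c            heat increment
    k_mg = (1 - HI/ME) x 100      efficiency of ME for maintenance+growth
    ME_m = FHP x 100 / k_mg       maintenance ME requirement
    NE = ME - HI                  net energy

Protein deposition is held fixed under the correction; only fat
deposition absorbs the RE adjustment.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .balance import fat_deposition

__all__ = [
    "CorrectedBalance",
    "EfficiencySummary",
    "activity_ratio",
    "correct_activity",
    "efficiency",
    "net_energy",
    "impute_missing_fhp",
    "cohort_summary",
]


@dataclass
class CorrectedBalance:
    """Activity-standardized energy components, kJ/kg BW^0.60/day."""

    AHP_c: float
    TEF_c: float
    RE_c: float
    HP_c: float
    HI: float
    FD_c: Optional[float]        # g/day (whole-animal scale)
    ratio_used: float

    def __post_init__(self) -> None:
        if self.AHP_c < 0:
            raise ValueError("corrected activity heat must be >= 0")


@dataclass
class EfficiencySummary:
    """Efficiency of ME use and dietary energy values."""

    k_mg: float                  # %
    me_m: float                  # kJ/kg BW^0.60/day
    ne_intake: Optional[float] = None    # MJ/day
    me_content: Optional[float] = None   # MJ/kg DM
    ne_content: Optional[float] = None   # MJ/kg DM


def activity_ratio(ahp: Sequence[float], me: Sequence[float]) -> float:
    """Cohort-mean AHP/ME ratio (mean of per-animal ratios, unitless)."""
    ahp = np.asarray(ahp, dtype=float)
    me = np.asarray(me, dtype=float)
    if ahp.size == 0 or ahp.size != me.size:
        raise ValueError("need matching, non-empty AHP and ME vectors")
    if np.any(me <= 0):
        raise ValueError("ME intake must be positive for every animal")
    return float(np.mean(ahp / me))


def correct_activity(
    me: float,
    fhp: float,
    ahp: float,
    tef: float,
    re: float,
    ratio: float,
    *,
    pd: Optional[float] = None,
    metabolic_size: Optional[float] = None,
    animal_id: str = "?",
) -> CorrectedBalance:
    """Standardize one animal's activity heat to ``ratio x ME``.

    All energy arguments are per kg BW^0.60 per day.  If ``pd`` (g/day)
    and ``metabolic_size`` are given, corrected fat deposition is
    recomputed from the corrected RE at fixed protein deposition.
    """
    denom = me - fhp - ahp
    if denom <= 0:
        raise ValueError(
            f"ME must exceed FHP + AHP for animal {animal_id}: "
            f"ME={me:.1f}, FHP={fhp:.1f}, AHP={ahp:.1f}"
        )
    ahp_c = ratio * me
    d_tef = (ahp - ahp_c) * tef / denom
    tef_c = tef + d_tef
    re_c = re + (ahp - ahp_c) - d_tef
    hi = ahp_c + tef_c
    hp_c = fhp + hi
    fd_c = None
    if pd is not None and metabolic_size is not None:
        fd_c = fat_deposition(re_c * metabolic_size, pd)
    return CorrectedBalance(
        AHP_c=ahp_c, TEF_c=tef_c, RE_c=re_c, HP_c=hp_c, HI=hi,
        FD_c=fd_c, ratio_used=ratio,
    )


def efficiency(fhp: float, hi: float, me: float) -> EfficiencySummary:
    """k_mg (%) and maintenance ME requirement from FHP, HI and ME."""
    if not 0 <= hi < me:
        raise ValueError(f"need 0 <= HI < ME, got HI={hi}, ME={me}")
    k_mg = (1.0 - hi / me) * 100.0
    me_m = fhp * 100.0 / k_mg
    return EfficiencySummary(k_mg=k_mg, me_m=me_m)


def net_energy(
    me_intake_mj: float, hi_mj: float, feed_intake_kg_dm: float
) -> tuple[float, float, float]:
    """(NE intake MJ/day, ME content MJ/kg DM, NE content MJ/kg DM)."""
    if feed_intake_kg_dm <= 0:
        raise ValueError("feed intake must be positive")
    ne = me_intake_mj - hi_mj
    return ne, me_intake_mj / feed_intake_kg_dm, ne / feed_intake_kg_dm


def impute_missing_fhp(
    cohort: pd.DataFrame,
    target_class: str,
    *,
    class_col: str = "sex_class",
    fhp_col: str = "fhp",
) -> float:
    """Impute a missing FHP as the mean of same-class animals.

    Values are on the kJ/kg BW^0.60/day scale, so the class mean
    transfers across body weights.
    """
    same = cohort.loc[
        (cohort[class_col] == target_class) & cohort[fhp_col].notna(), fhp_col
    ]
    if same.empty:
        raise ValueError(f"no non-missing FHP values for class {target_class!r}")
    return float(same.mean())


def cohort_summary(
    results: pd.DataFrame,
    grouping: str = "sex_class",
    *,
    columns: Optional[Iterable[str]] = None,
) -> pd.DataFrame:
    """Arithmetic group means of the energy traits, one row per group."""
    if results.empty:
        raise ValueError("empty cohort")
    num = results.select_dtypes("number") if columns is None else results[list(columns)]
    return num.groupby(results[grouping]).mean()
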