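"""End-to-end orchestration: configuration, file formats, pipeline, tables.

The pipeline composes the other modules over a whole cohort:

    preprocess -> fit (6 fed + 1 fasting day per animal) -> partition
    -> balance -> standardize -> group summaries

and is a pure function of (inputs, configuration, seed).  A
worked-example mode feeds published group LS-means through the same
balance and standardization algebra to reproduce the derived cells
(HI, RE_c, ME_m, FD_c, cross-class averages) without any
individual-animal data.
"""
from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import constants as C
from .balance import BalancePeriod, energy_balance, fat_deposition, metabolic_size
from .datasets import example_gain_lsmeans, example_lsmeans
from .fitting import FitOptions, fit_fasting_day, fit_fed_day
from .partition import brouwer_hp, partition_fed_day
from .preprocess import AnalyzerCalibration, RawDayRecording, preprocess_day
from .standardize import (
    activity_ratio,
    cohort_summary,
    correct_activity,
    efficiency,
    impute_missing_fhp,
    net_energy,
)
from .synthetic import CohortScenario, SyntheticCohort, generate_cohort
from .traces import SignalTrace

__all__ = [
    "RunConfig",
    "PipelineResult",
    "run_cohort",
    "run_pipeline",
    "report_tables",
    "worked_example",
    "write_cohort",
    "read_day_dir",
]


@dataclass
class RunConfig:
    """Validated run configuration; persisted alongside every output."""

    metabolic_exponent: float = C.METABOLIC_EXPONENT
    brouwer_coefficients: tuple = (C.BROUWER_O2, C.BROUWER_CO2, C.BROUWER_CH4, C.BROUWER_N)
    ratio_override: Optional[float] = None     # AHP_c/ME; None = cohort mean
    lag_s: float = C.DEFAULT_LAG_S
    smoothing_window: int = 6
    max_evals_per_step: int = 5000
    rel_sse_tol: float = 1e-8
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not 0 < self.metabolic_exponent <= 1:
            raise ValueError("metabolic exponent must lie in (0, 1]")
        if len(tuple(self.brouwer_coefficients)) != 4:
            raise ValueError("need four heat-equation coefficients")
        if self.ratio_override is not None and not 0 < self.ratio_override < 1:
            raise ValueError("ratio override must be a fraction in (0, 1)")

    def fit_options(self) -> FitOptions:
        return FitOptions(
            max_evals_per_step=self.max_evals_per_step,
            rel_sse_tol=self.rel_sse_tol,
        )

    def to_yaml(self) -> str:
        return yaml.safe_dump(dataclasses.asdict(self))

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        d = yaml.safe_load(text) or {}
        if "brouwer_coefficients" in d:
            d["brouwer_coefficients"] = tuple(d["brouwer_coefficients"])
        return cls(**d)

    def hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:12]


@dataclass
class PipelineResult:
    """Bundle of per-animal results and group summaries."""

    per_animal: pd.DataFrame
    group_means: pd.DataFrame
    ratio_used: float
    config: RunConfig
    fit_diagnostics: pd.DataFrame
    provenance: dict = field(default_factory=dict)


def run_cohort(
    cohort: SyntheticCohort,
    config: Optional[RunConfig] = None,
    *,
    exclude_days: frozenset = frozenset(),
    progress: bool = False,
) -> PipelineResult:
    """Run the full analysis on a cohort of chamber recordings.

    ``exclude_days`` is a set of ``(animal_id, day)`` pairs to drop
    (e.g. a lost fasting day, which triggers FHP imputation from the
    same sex class).
    """
    cfg = config or RunConfig()
    spec = cohort.chamber_spec()
    assay = cohort.assay_table().set_index("animal_id")
    opts = cfg.fit_options()
    coeff = tuple(cfg.brouwer_coefficients)

    records = []
    diagnostics = []
    for animal in cohort.animals:
        aid = animal.animal_id
        row = assay.loc[aid]
        days = int(row["days"])
        urinary_n_day = (row["n_urinary_g"] + row["n_ammonia_g"]) / days

        fed_days = []
        for d in range(days):
            if (aid, d) in exclude_days:
                continue
            rec, _ = cohort.realize_day(aid, d)
            day = preprocess_day(
                rec, spec, lag_s=cfg.lag_s, smoothing_window=cfg.smoothing_window
            )
            fit = fit_fed_day(day, spec, options=opts)
            fed_days.append((day, fit))
            diagnostics.append({
                "animal_id": aid, "day": d, "fasted": False,
                "r2_o2": fit.r2_o2, "r2_co2": fit.r2_co2,
                "n_evals": fit.n_evals, "converged": fit.converged,
            })
            if progress:
                print(f"  fitted {aid} day {d}: R2 {fit.r2_o2:.4f}/{fit.r2_co2:.4f}")
        if not fed_days:
            raise ValueError(f"animal {aid} has no usable fed days")

        # fed-state anchor for the fasting fit: mean fitted levels
        mean_fed = fed_days[0][1].parameters
        mean_fed = dataclasses.replace(
            mean_fed,
            **{
                k: float(np.mean([getattr(f.parameters, k) for _, f in fed_days]))
                for k in mean_fed.names
            },
        )

        fast_day_no = days
        fhp = None
        fhp_imputed = False
        if (aid, fast_day_no) not in exclude_days:
            rec, _ = cohort.realize_day(aid, fast_day_no)
            day = preprocess_day(
                rec, spec, lag_s=cfg.lag_s, smoothing_window=cfg.smoothing_window
            )
            fit = fit_fasting_day(day, spec, mean_fed, options=opts)
            diagnostics.append({
                "animal_id": aid, "day": fast_day_no, "fasted": True,
                "r2_o2": fit.r2_o2, "r2_co2": fit.r2_co2,
                "n_evals": fit.n_evals, "converged": fit.converged,
            })
            fp = fit.parameters
            fhp = brouwer_hp(
                24.0 * fp.VOFAST, 24.0 * fp.VCFAST, 0.0,
                row["urinary_n_fasting_g"], coefficients=coeff,
            )

        records.append({
            "animal_id": aid, "sex_class": animal.sex_class,
            "group": animal.group,
            "fed_days": fed_days, "fhp": fhp, "fhp_imputed": fhp_imputed,
            "urinary_n_day": urinary_n_day, "assay": row,
        })

    # ---- FHP imputation pass -----------------------------------------
    msizes = {
        r["animal_id"]: metabolic_size(
            0.5 * (r["assay"]["bw_start"] + r["assay"]["bw_end"]),
            cfg.metabolic_exponent,
        )
        for r in records
    }
    fhp_frame = pd.DataFrame({
        "animal_id": [r["animal_id"] for r in records],
        "sex_class": [r["sex_class"] for r in records],
        "fhp": [
            (r["fhp"] / msizes[r["animal_id"]]) if r["fhp"] is not None else np.nan
            for r in records
        ],
    })
    for r in records:
        if r["fhp"] is None:
            per_msize = impute_missing_fhp(fhp_frame, r["sex_class"])
            r["fhp"] = per_msize * msizes[r["animal_id"]]
            r["fhp_imputed"] = True

    # ---- partition + balance per animal ------------------------------
    rows = []
    for r in records:
        aid = r["animal_id"]
        row = r["assay"]
        days = int(row["days"])
        comps = []
        vo2_sum = vco2_sum = 0.0
        for day, fit in r["fed_days"]:
            v = day.volumes
            comp = partition_fed_day(
                fit.parameters, day.feed, day.force,
                v.vo2_24h, v.vco2_24h, v.vch4_24h,
                r["urinary_n_day"], r["fhp"], coefficients=coeff,
            )
            comps.append(comp)
            vo2_sum += v.vo2_24h
            vco2_sum += v.vco2_24h
        n_used = len(comps)
        hp_day = float(np.mean([c.HP_total for c in comps]))
        ahp_day = float(np.mean([c.AHP for c in comps]))
        tef_s_day = float(np.mean([c.TEF_s for c in comps]))
        tef_l_day = float(np.mean([c.TEF_l for c in comps]))

        period = BalancePeriod(
            animal_id=aid, sex_class=r["sex_class"],
            bw_start=row["bw_start"], bw_end=row["bw_end"], days=days,
            feed_offered=row["feed_offered_g"], refusals=row["refusals_g"],
            spillage=row["spillage_g"],
            ge_intake=row["ge_intake_kj"], fecal_e=row["fecal_e_kj"],
            urine_e=row["urine_e_kj"], ch4=row["ch4_l"],
            n_intake=row["n_intake_g"], n_fecal=row["n_fecal_g"],
            n_urinary=row["n_urinary_g"], n_ammonia=row["n_ammonia_g"],
            hp=hp_day * days,
        )
        eb = energy_balance(
            period, vo2=vo2_sum / n_used, vco2=vco2_sum / n_used,
            exponent=cfg.metabolic_exponent,
        )
        ms = eb.metabolic_size
        rows.append({
            "animal_id": aid, "sex_class": r["sex_class"], "group": r["group"],
            "bw": 0.5 * (row["bw_start"] + row["bw_end"]),
            "metabolic_size": ms,
            "me": eb.me / ms, "fhp": r["fhp"] / ms,
            "ahp": ahp_day / ms, "tef_s": tef_s_day / ms,
            "tef_l": tef_l_day / ms, "tef": (tef_s_day + tef_l_day) / ms,
            "hp": hp_day / ms, "re": eb.re / ms,
            "pd_g": eb.pd, "fd_g": eb.fd, "rq": eb.rq,
            "feed_dm_kg_day": row["feed_dm_g"] / days / 1000.0,
            "fhp_imputed": r["fhp_imputed"],
        })

    per_animal = pd.DataFrame(rows).set_index("animal_id")

    # ---- activity standardization ------------------------------------
    ratio = (
        cfg.ratio_override
        if cfg.ratio_override is not None
        else activity_ratio(per_animal["ahp"], per_animal["me"])
    )
    corrected = []
    for aid, row in per_animal.iterrows():
        cb = correct_activity(
            row["me"], row["fhp"], row["ahp"], row["tef"], row["re"], ratio,
            pd=row["pd_g"], metabolic_size=row["metabolic_size"], animal_id=aid,
        )
        eff = efficiency(row["fhp"], cb.HI, row["me"])
        me_mj = row["me"] * row["metabolic_size"] / 1000.0
        hi_mj = cb.HI * row["metabolic_size"] / 1000.0
        ne_mj, me_content, ne_content = net_energy(
            me_mj, hi_mj, row["feed_dm_kg_day"]
        )
        corrected.append({
            "animal_id": aid,
            "ahp_c": cb.AHP_c, "tef_c": cb.TEF_c, "re_c": cb.RE_c,
            "hp_c": cb.HP_c, "hi": cb.HI, "fd_c_g": cb.FD_c,
            "k_mg": eff.k_mg, "me_m": eff.me_m,
            "hi_pct_me": 100.0 * cb.HI / row["me"],
            "ne_intake_mj": ne_mj,
            "me_content_mj_kg_dm": me_content,
            "ne_content_mj_kg_dm": ne_content,
        })
    per_animal = per_animal.join(pd.DataFrame(corrected).set_index("animal_id"))

    groups = cohort_summary(per_animal.drop(columns=["fhp_imputed"]), "sex_class")
    return PipelineResult(
        per_animal=per_animal,
        group_means=groups,
        ratio_used=ratio,
        config=cfg,
        fit_diagnostics=pd.DataFrame(diagnostics),
        provenance={"config_hash": cfg.hash(), "seed": cohort.scenario.seed,
                    "n_animals": len(cohort.animals)},
    )


def run_pipeline(
    config: Optional[RunConfig] = None,
    *,
    scenario: Optional[CohortScenario] = None,
    data_dir: Optional[Path] = None,
    progress: bool = False,
) -> PipelineResult:
    """Top-level entry: generate (or load) a cohort and analyze it."""
    cfg = config or RunConfig()
    if data_dir is not None:
        scenario = CohortScenario.from_yaml(
            (Path(data_dir) / "scenario.yaml").read_text()
        )
    if scenario is None:
        scenario = CohortScenario(seed=cfg.seed)
    cohort = generate_cohort(scenario)
    return run_cohort(cohort, cfg, progress=progress)


# ----------------------------------------------------------------------
# report tables
# ----------------------------------------------------------------------

_TABLE3_ROWS = [
    ("BW (kg)", "bw"),
    ("ME intake (kJ/kg BW^0.60/d)", "me"),
    ("FHP", "fhp"),
    ("AHP", "ahp"),
    ("AHP_c", "ahp_c"),
    ("TEF_c", "tef_c"),
    ("HI", "hi"),
    ("HP_c", "hp_c"),
    ("RE_c", "re_c"),
    ("HI (% of ME)", "hi_pct_me"),
    ("ME_m (kJ/kg BW^0.60/d)", "me_m"),
    ("k_mg (%)", "k_mg"),
    ("RQ", "rq"),
    ("ME content (MJ/kg DM)", "me_content_mj_kg_dm"),
    ("NE content (MJ/kg DM)", "ne_content_mj_kg_dm"),
]

_TABLE4_ROWS = [
    ("PD (g/d)", "pd_g"),
    ("FD_c (g/d)", "fd_c_g"),
]


def report_tables(result: PipelineResult) -> dict:
    """Group-mean summary tables in the classical row layout."""
    if result.per_animal.empty:
        raise ValueError("empty cohort")
    g = result.group_means
    order = [c for c in ("EM", "SC", "IC") if c in g.index]
    t3 = pd.DataFrame(
        {label: g.loc[order, col] for label, col in _TABLE3_ROWS if col in g}
    ).T[order]
    t4 = pd.DataFrame(
        {label: g.loc[order, col] for label, col in _TABLE4_ROWS if col in g}
    ).T[order]
    return {"energy_balance": t3, "deposition": t4}


# ----------------------------------------------------------------------
# worked example on published LS-means
# ----------------------------------------------------------------------

def worked_example(exponent: float = C.METABOLIC_EXPONENT) -> dict:
    """Derived cells of the published worked example.

    Feeds the group LS-means through the same algebra the pipeline
    applies to individual animals: HI as the sum of corrected activity
    and feeding heat, RE_c as ME minus HP_c, the maintenance requirement
    from FHP and the heat-increment share of ME, corrected fat
    deposition from RE_c at fixed PD, and the castrated-class and
    three-class averages.
    """
    ls = example_lsmeans()
    gain = example_gain_lsmeans()
    classes = list(ls.columns)

    hi = ls.loc["ahp_c"] + ls.loc["tef_c"]
    re_c = ls.loc["me"] - ls.loc["hp_c"]
    me_m = pd.Series({
        cls: efficiency(
            ls.loc["fhp", cls],
            ls.loc["hi_c_pct_me", cls] / 100.0 * ls.loc["me", cls],
            ls.loc["me", cls],
        ).me_m
        for cls in classes
    })
    fd_c = pd.Series({
        cls: fat_deposition(
            re_c[cls] * metabolic_size(ls.loc["bw_kg", cls], exponent),
            gain.loc["pd_g_per_day", cls],
        )
        for cls in classes
    })
    castrated = [c for c in classes if c != "EM"]
    return {
        "hi": hi,
        "re_c": re_c,
        "me_m": me_m,
        "fd_c": fd_c,
        "tef_c_castrated_mean": float(ls.loc["tef_c", castrated].mean()),
        "ne_castrated_mean": float(ls.loc["ne_content_mj_kg_dm", castrated].mean()),
        "hi_castrated_mean": float(hi[castrated].mean()),
        "pd_mean": float(gain.loc["pd_g_per_day"].mean()),
        "bw_mean": float(ls.loc["bw_kg"].mean()),
    }


# ----------------------------------------------------------------------
# cohort file I/O (plain-text, one folder per animal-day)
# ----------------------------------------------------------------------

_TRACE_COLUMNS = [
    "o2", "co2", "ch4", "outflow", "temperature", "pressure",
    "humidity", "force", "feed", "standing",
]


def write_day_dir(rec: RawDayRecording, path: Path) -> None:
    """Write one raw animal-day: traces.csv + meta.yaml."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame({"time_s": rec.o2.times})
    for col in _TRACE_COLUMNS:
        tr = getattr(rec, col)
        df[col] = tr.values if tr is not None else np.nan
    df.to_csv(path / "traces.csv", index=False)
    meta = {
        "animal_id": rec.animal_id,
        "day": rec.day,
        "fasted": rec.fasted,
        "interruptions": [list(map(float, w)) for w in rec.interruptions],
        "calibrations": {
            g: {k: (None if v is None else float(v)) for k, v in
                dataclasses.asdict(c).items()}
            for g, c in rec.calibrations.items()
        },
    }
    (path / "meta.yaml").write_text(yaml.safe_dump(meta))


def read_day_dir(path: Path) -> RawDayRecording:
    """Read one raw animal-day written by :func:`write_day_dir`."""
    path = Path(path)
    df = pd.read_csv(path / "traces.csv")
    meta = yaml.safe_load((path / "meta.yaml").read_text())
    t0 = float(df["time_s"].iloc[0])
    dt = float(df["time_s"].iloc[1] - df["time_s"].iloc[0])

    def tr(col: str) -> SignalTrace:
        return SignalTrace(t0, dt, df[col].to_numpy(dtype=float))

    return RawDayRecording(
        o2=tr("o2"), co2=tr("co2"), ch4=tr("ch4"), outflow=tr("outflow"),
        temperature=tr("temperature"), pressure=tr("pressure"),
        humidity=tr("humidity"), force=tr("force"), feed=tr("feed"),
        standing=tr("standing"),
        interruptions=[tuple(w) for w in meta.get("interruptions", [])],
        calibrations={
            g: AnalyzerCalibration(**c)
            for g, c in meta.get("calibrations", {}).items()
        },
        animal_id=meta.get("animal_id"),
        day=meta.get("day"),
        fasted=bool(meta.get("fasted", False)),
    )


def write_cohort(cohort: SyntheticCohort, outdir: Path) -> None:
    """Materialize a synthetic cohort to disk (scenario, truth, days)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "scenario.yaml").write_text(cohort.scenario.to_yaml())
    cohort.truth_table().to_csv(outdir / "truth_animals.csv", index=False)
    cohort.assay_table().to_csv(outdir / "assay.csv", index=False)
    for aid, day, fasted in cohort.day_index():
        rec, _ = cohort.realize_day(aid, day)
        write_day_dir(rec, outdir / aid / f"day{day}")
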