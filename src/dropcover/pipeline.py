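"""End-to-end orchestration: simulate/load -> cohorts -> endpoints -> tables.

This is the engine behind the command-line interface.  ``run_all`` executes
the full analysis with one :class:`RunConfig`, writes publication-shaped
delimited tables (baseline characteristics, adherence summaries, risk
factors, Kaplan-Meier tables and plot), the exclusion ledger, and a run log
recording the seed and every policy flag for provenance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from datetime import date
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import claims_model as cm
from .adherence_metrics import (
    AdherenceResult,
    adherence_frame,
    compute_pdc,
    summarize_adherence,
)
from .cohort_builder import CohortAssignment, build_cohorts
from .exposure_engine import patient_coverage
from .persistence_analysis import (
    KMEstimate,
    PersistenceResult,
    build_episode,
    km_fit,
    logrank,
)
from .risk_factor_analysis import (
    compare_groups,
    risk_factor_table,
    stepwise_multivariate,
    univariate_screen,
)
from .switching_patterns import classify_trajectory, pattern_table
from .synthetic_claims import SyntheticConfig, SyntheticTables, generate

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Inputs plus every analysis policy flag (documented defaults)."""

    # either a simulation config or paths to the four input tables
    simulate: SyntheticConfig | None = None
    claims_path: str | None = None
    diagnoses_path: str | None = None
    procedures_path: str | None = None
    covariates_path: str | None = None

    window: tuple[date, date] = cm.STUDY_WINDOW
    both_eyes_policy: str = "halve"       # halve | none
    unfixed_day_rule: str = "both"        # both | either
    pdc_count_grace: bool = False
    gap_anchor: str = "supply_end"        # supply_end | dispense
    persistence_mode: str = "class"       # class | subset
    ttest_equal_var: bool = False         # Welch by default
    stepwise_entry_p: float = 0.05
    stepwise_stay_p: float = 0.05
    seed: int = 0
    outdir: str | None = None


@dataclass
class RunResult:
    assignments: list[CohortAssignment]
    ledger: dict[str, int]
    adherence: list[AdherenceResult]
    persistence: list[PersistenceResult]
    km: dict[str, KMEstimate]
    logrank_stat: float
    logrank_p: float
    adherence_summary: pd.DataFrame
    switching: pd.DataFrame
    risk_factors: pd.DataFrame
    analysis_frame: pd.DataFrame
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)


def load_inputs(config: RunConfig, dictionary=None):
    dictionary = dictionary or cm.DrugDictionary.default()
    if config.simulate is not None:
        sim = config.simulate
        tables = generate(sim)
        claims = _claims_from_frame(tables.claims)
        diagnoses = [
            cm.DiagnosisRecord(str(r.patient_id), date.fromisoformat(r.date),
                               cm.DiagnosisRecord.normalize_code(r.icd10_code))
            for r in tables.diagnoses.itertuples(index=False)
        ]
        procedures = [
            cm.ProcedureRecord(str(r.patient_id), date.fromisoformat(r.date),
                               bool(r.is_glaucoma_surgery_or_laser))
            for r in tables.procedures.itertuples(index=False)
        ]
        covariates = tables.covariates.set_index("patient_id")
        return claims, diagnoses, procedures, covariates, tables
    claims = cm.load_claims(config.claims_path, dictionary)
    diagnoses = cm.load_diagnoses(config.diagnoses_path)
    procedures = cm.load_procedures(config.procedures_path)
    covariates = (
        cm.load_covariates(config.covariates_path) if config.covariates_path else pd.DataFrame()
    )
    return claims, diagnoses, procedures, covariates, None


def _claims_from_frame(frame: pd.DataFrame) -> list[cm.PharmacyClaim]:
    return [
        cm.PharmacyClaim(
            str(r.patient_id),
            date.fromisoformat(r.dispense_date),
            str(r.generic_name),
            float(r.dosage_quantity),
            int(r.period_field),
        )
        for r in frame.sort_values(["patient_id", "dispense_date"]).itertuples(index=False)
    ]


def analyze_patients(claims, assignments, dictionary, config: RunConfig):
    """Per-patient coverage, PDC, persistence episode and trajectory."""
    by_patient: dict[str, list[cm.PharmacyClaim]] = {}
    for c in claims:
        by_patient.setdefault(c.patient_id, []).append(c)
    adherence, persistence, patterns = [], [], []
    for a in assignments:
        pclaims = sorted(by_patient.get(a.patient_id, []), key=lambda c: c.dispense_date)
        coverage = patient_coverage(pclaims, dictionary, both_eyes_policy=config.both_eyes_policy)
        adherence.append(
            compute_pdc(
                coverage, a, dictionary,
                unfixed_day_rule=config.unfixed_day_rule,
                pdc_count_grace=config.pdc_count_grace,
            )
        )
        persistence.append(
            build_episode(
                coverage, pclaims, a, dictionary,
                mode=config.persistence_mode, gap_anchor=config.gap_anchor,
            )
        )
        patterns.append(classify_trajectory(pclaims, coverage, a, dictionary))
    return adherence, persistence, patterns


def assemble_analysis_frame(
    assignments, adherence, covariates: pd.DataFrame
) -> pd.DataFrame:
    """Per-patient frame for the risk-factor screen.

    ``fixed_combination`` is coded 1 for the fixed cohort (the protective
    exposure), and ``nonadherent`` is the outcome (PDC < 80%).
    """
    adf = adherence_frame(adherence)
    frame = pd.DataFrame(
        {
            "patient_id": [a.patient_id for a in assignments],
            "fixed_combination": [int(a.cohort == "fixed") for a in assignments],
        }
    ).set_index("patient_id")
    frame = frame.join(adf[["pdc_percent", "adherent"]])
    frame["nonadherent"] = (~frame["adherent"].astype(bool)).astype(int)
    if covariates is not None and len(covariates):
        cov = covariates.loc[:, [c for c in covariates.columns if not c.startswith("_")]]
        frame = frame.join(cov, how="left")
    return frame


RISK_FACTOR_VARIABLES = [
    "fixed_combination", "sex", "age", "body_mass_index", "smoking",
    "hba1c_percent", "hypertension", "diabetes", "hyperlipidemia", "cancer",
    "region_category",
]


def run_all(config: RunConfig, dictionary=None) -> RunResult:
    """Execute the full pipeline; any stage error aborts with the stage named."""
    dictionary = dictionary or cm.DrugDictionary.default()
    stage = "load"
    try:
        claims, diagnoses, procedures, covariates, sim_tables = load_inputs(config, dictionary)
        stage = "cohort"
        assignments, ledger = build_cohorts(
            claims, diagnoses, procedures, dictionary, config.window,
            both_eyes_policy=config.both_eyes_policy,
        )
        stage = "endpoints"
        adherence, persistence, patterns = analyze_patients(
            claims, assignments, dictionary, config
        )
        stage = "summaries"
        summary = summarize_adherence(adherence)
        switching = pattern_table(patterns)
        km: dict[str, KMEstimate] = {}
        for cohort in ("fixed", "unfixed"):
            group = [r for r in persistence if r.cohort == cohort]
            if group:
                km[cohort] = km_fit(group)
        fixed = [r for r in persistence if r.cohort == "fixed"]
        unfixed = [r for r in persistence if r.cohort == "unfixed"]
        if fixed and unfixed:
            lr_stat, lr_p = logrank(fixed, unfixed)
        else:
            lr_stat, lr_p = float("nan"), float("nan")
        stage = "risk_factors"
        frame = assemble_analysis_frame(assignments, adherence, covariates)
        variables = [v for v in RISK_FACTOR_VARIABLES if v in frame.columns]
        risk = pd.DataFrame()
        if frame["nonadherent"].nunique() == 2:
            uni, candidates = univariate_screen(frame[variables], frame["nonadherent"])
            multi = (
                stepwise_multivariate(
                    frame[variables], frame["nonadherent"], candidates,
                    entry_p=config.stepwise_entry_p, stay_p=config.stepwise_stay_p,
                )
                if candidates
                else []
            )
            risk = risk_factor_table(uni, multi)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    result = RunResult(
        assignments=assignments,
        ledger=ledger,
        adherence=adherence,
        persistence=persistence,
        km=km,
        logrank_stat=lr_stat,
        logrank_p=lr_p,
        adherence_summary=summary,
        switching=switching,
        risk_factors=risk,
        analysis_frame=frame,
    )
    if config.outdir:
        write_outputs(result, config, covariates, sim_tables)
    return result


def baseline_table(frame: pd.DataFrame) -> pd.DataFrame:
    """Baseline characteristics by cohort: n plus mean +/- SD or n (%)."""
    rows = []
    groups = {"fixed": frame[frame["fixed_combination"] == 1],
              "unfixed": frame[frame["fixed_combination"] == 0]}
    skip = {"fixed_combination", "pdc_percent", "adherent", "nonadherent"}
    for var in frame.columns:
        if var in skip:
            continue
        for gname, g in groups.items():
            col = g[var].dropna()
            if pd.api.types.is_numeric_dtype(col) and col.nunique() > 2:
                rows.append({"variable": var, "cohort": gname, "n": len(col),
                             "summary": f"{col.mean():.1f} +/- {col.std(ddof=1):.1f}"})
            else:
                for level, cnt in col.value_counts().items():
                    rows.append({"variable": f"{var}={level}", "cohort": gname, "n": int(cnt),
                                 "summary": f"{100 * cnt / max(len(col), 1):.1f}%"})
    return pd.DataFrame(rows)


def km_table(est: KMEstimate) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "time_days": est.timeline,
            "at_risk": est.at_risk,
            "persistence_rate_pct": 100.0 * est.survival,
            "ci_lower_pct": 100.0 * est.ci_lower,
            "ci_upper_pct": 100.0 * est.ci_upper,
        }
    )


def write_outputs(result: RunResult, config: RunConfig, covariates, sim_tables) -> None:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if sim_tables is not None:
        sim_tables.write(outdir / "inputs")

    pd.DataFrame(
        [
            {
                "patient_id": a.patient_id, "cohort": a.cohort,
                "index_date": a.index_date.isoformat(), "index_regimen": a.index_regimen,
                "pre_index_monotherapy_days": a.pre_index_monotherapy_days,
                "index_products": "|".join(a.index_products), "withdrawn": int(a.withdrawn),
            }
            for a in result.assignments
        ]
    ).to_csv(outdir / "assignments.csv", index=False)
    pd.Series(result.ledger, name="count").rename_axis("rule").to_csv(outdir / "exclusion_ledger.csv")
    result.adherence_summary.to_csv(outdir / "table2_adherence.csv")
    adherence_frame(result.adherence).to_csv(outdir / "adherence.csv")
    baseline_table(result.analysis_frame).to_csv(outdir / "table1_baseline.csv", index=False)
    pd.DataFrame(
        [
            {"patient_id": r.patient_id, "cohort": r.cohort, "duration_days": r.duration_days,
             "event": int(r.event), "reason": r.reason}
            for r in result.persistence
        ]
    ).to_csv(outdir / "persistence.csv", index=False)
    for cohort, est in result.km.items():
        km_table(est).to_csv(outdir / f"km_{cohort}.csv", index=False)
    result.switching.to_csv(outdir / "switching.csv", index=False)
    if len(result.risk_factors):
        result.risk_factors.to_csv(outdir / "table5_risk_factors.csv")
    _plot_km(result, outdir / "km_curves.png")

    run_log = {
        "seed": config.seed,
        "window": [d.isoformat() for d in config.window],
        "policy": {
            "both_eyes_policy": config.both_eyes_policy,
            "unfixed_day_rule": config.unfixed_day_rule,
            "pdc_count_grace": config.pdc_count_grace,
            "gap_anchor": config.gap_anchor,
            "persistence_mode": config.persistence_mode,
            "ttest_equal_var": config.ttest_equal_var,
            "stepwise_entry_p": config.stepwise_entry_p,
            "stepwise_stay_p": config.stepwise_stay_p,
        },
        "logrank": {"statistic": result.logrank_stat, "p_value": result.logrank_p},
        "simulate": asdict(config.simulate) if config.simulate is not None else None,
    }
    with open(outdir / "run_log.yaml", "w") as fh:
        yaml.safe_dump(run_log, fh, sort_keys=True)


def _plot_km(result: RunResult, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for cohort, est in result.km.items():
        est.fitter.plot_survival_function(ax=ax, label=f"{cohort} combination")
    ax.set_xlabel("days since index")
    ax.set_ylabel("persistence (proportion)")
    ax.set_ylim(0, 1.02)
    ax.set_title("Treatment persistence")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
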