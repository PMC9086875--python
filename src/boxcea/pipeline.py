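"""End-to-end analysis runs: simulate -> mITT filter -> cost -> impute ->
QALY -> incremental CEA -> report files.

Every run writes a self-contained bundle of CSV outputs plus a JSON
manifest (seed, configuration hash, package versions, file hashes) so a
run is fully reproducible from its directory.  Amounts are reported in
2020 euros, optionally with US dollars alongside at the study's fixed
exchange rate.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .cea import (DEFAULT_WTP_GRID, CEDraws, IncrementalResult, bootstrap_ce,
                  ceac, icer, incremental_from_completed, mean_diff_ttest)
from .costing import (PatientCostParams, PriceTable,
                      default_price_table, eur_to_usd,
                      patient_related_box_cost, patient_related_visit_cost,
                      total_costs)
from .qaly import ImputationSpec, impute_utilities, qaly_auc_frame
from .synthetic_data import (ARMS, CONTROL, INTERVENTION, PatientRecord,
                             TrialConfig, apply_mitt_filter, default_config,
                             frame_to_records, generate_trial,
                             records_to_frame)

logger = logging.getLogger("boxcea")

REQUIRED_COLUMNS = ("patient_id", "arm", "dropout_flag", "age", "sex",
                    "index_event", "troponin", "u1", "u6", "u12")


class SchemaError(ValueError):
    """Input table does not match the patient-level CSV contract."""


@dataclass(frozen=True)
class RunConfig:
    """Everything one analysis run needs."""

    trial_config: TrialConfig = field(default_factory=default_config)
    input_path: Optional[Path] = None      # None => simulate
    perspective: str = "department"
    B: int = 1000
    m: int = 20
    wtp_grid: np.ndarray = field(default_factory=lambda: DEFAULT_WTP_GRID)
    seed: int = 0
    out_dir: Path = Path("boxcea_run")
    currency: str = "EUR"                  # EUR | USD | both

    def __post_init__(self) -> None:
        if self.B < 1 or self.m < 1:
            raise ValueError("B and m must be >= 1")
        if self.perspective not in ("department", "combined"):
            raise ValueError(f"unknown perspective {self.perspective!r}")
        if self.currency not in ("EUR", "USD", "both"):
            raise ValueError(f"unknown currency {self.currency!r}")


@dataclass
class RunResult:
    """In-memory summary of a completed run."""

    records: list[PatientRecord]
    cost_table: pd.DataFrame
    qaly_summary: pd.DataFrame
    incremental: IncrementalResult
    draws: CEDraws
    ceac_curve: pd.DataFrame
    patient_related: Optional[pd.DataFrame] = None
    out_dir: Optional[Path] = None


def validate_patient_frame(frame: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    cost_cols = [c for c in frame.columns if c.startswith("cost_")]
    if missing or not cost_cols:
        problems = []
        if missing:
            problems.append(f"missing columns: {missing}")
        if not cost_cols:
            problems.append("no cost_* item columns")
        raise SchemaError("; ".join(problems))


def _load_or_simulate(config: RunConfig) -> list[PatientRecord]:
    if config.input_path is not None:
        frame = pd.read_csv(config.input_path)
        validate_patient_frame(frame)
        logger.info("loaded %d patient records from %s", len(frame),
                    config.input_path)
        return frame_to_records(frame)
    records = generate_trial(config.trial_config, seed=config.seed)
    logger.info("simulated %d patient records (seed %d)", len(records),
                config.seed)
    return records


def _table2_style(records: Sequence[PatientRecord], totals: pd.DataFrame,
                  perspective: str = "department") -> pd.DataFrame:
    """Cost report: per-item per-arm mean +/- SD with the between-arm
    difference (control − intervention, matching the published layout),
    pooled-t CI and p-value.  Under the combined perspective two extra rows
    carry the patient-related component and the combined total."""
    per_arm = {}
    for arm in ARMS:
        sub = [r for r in records if r.arm == arm]
        costs = pd.DataFrame([r.item_costs for r in sub])
        counts = pd.DataFrame([r.item_counts for r in sub])
        per_arm[arm] = (costs, counts)
    items = list(per_arm[INTERVENTION][0].columns)
    rows = []
    for item in items + ["total"]:
        row = {"item": item}
        series = {}
        for arm in ARMS:
            costs, counts = per_arm[arm]
            vals = costs.sum(axis=1) if item == "total" else costs[item]
            series[arm] = vals
            key = "intervention" if arm == INTERVENTION else "control"
            row[f"{key}_n_events"] = int(counts.values.sum() if item == "total"
                                         else counts[item].sum())
            row[f"{key}_mean"] = float(vals.mean())
            row[f"{key}_sd"] = float(vals.std(ddof=1))
        diff, ci, p = mean_diff_ttest(series[CONTROL], series[INTERVENTION])
        row.update({"difference": diff, "ci_low": ci[0], "ci_high": ci[1],
                    "p_value": p})
        rows.append(row)
    if perspective == "combined":
        arm_series = totals.set_index("patient_id")
        for label, col in (("patient_related", "total_patient_related"),
                           ("total_combined", "total_cost")):
            row = {"item": label}
            series = {}
            for arm in ARMS:
                vals = arm_series.loc[arm_series["arm"] == arm, col]
                series[arm] = vals
                key = "intervention" if arm == INTERVENTION else "control"
                row[f"{key}_n_events"] = 0
                row[f"{key}_mean"] = float(vals.mean())
                row[f"{key}_sd"] = float(vals.std(ddof=1))
            diff, ci, p = mean_diff_ttest(series[CONTROL], series[INTERVENTION])
            row.update({"difference": diff, "ci_low": ci[0],
                        "ci_high": ci[1], "p_value": p})
            rows.append(row)
    return pd.DataFrame(rows)


def _patient_related_table(records: Sequence[PatientRecord],
                           params: PatientCostParams) -> pd.DataFrame:
    """Per-arm mean +/- SD of patient-related costs and their components."""
    visit_office = patient_related_visit_cost(params, "in_office")
    visit_e = patient_related_visit_cost(params, "e_visit")
    box_cost = patient_related_box_cost(params)
    rows = []
    for arm in ARMS:
        sub = [r for r in records if r.arm == arm]
        office = np.array([r.item_counts.get("in_office", 0) for r in sub])
        evisit = np.array([r.item_counts.get("e_visit", 0) for r in sub])
        per_patient = office * visit_office + evisit * visit_e
        if arm == INTERVENTION:
            per_patient = per_patient + box_cost
        rows.append({
            "arm": arm,
            "mean_in_office_component": float((office * visit_office).mean()),
            "mean_e_visit_component": float((evisit * visit_e).mean()),
            "box_time_component": box_cost if arm == INTERVENTION else 0.0,
            "mean": float(per_patient.mean()),
            "sd": float(per_patient.std(ddof=1)),
        })
    return pd.DataFrame(rows)


def _with_usd(frame: pd.DataFrame, currency: str,
              euro_cols: Sequence[str]) -> pd.DataFrame:
    if currency == "EUR":
        return frame
    out = frame.copy()
    for col in euro_cols:
        if col in out.columns:
            out[f"{col}_usd"] = eur_to_usd(out[col].astype(float))
    if currency == "USD":
        out = out.drop(columns=[c for c in euro_cols if c in out.columns])
    return out


def _file_sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_analysis(config: RunConfig,
                 prices: Optional[PriceTable] = None,
                 patient_params: Optional[PatientCostParams] = None,
                 write: bool = True) -> RunResult:
    """Execute the full pipeline under the configured perspective.

    ``perspective="department"`` is the base case; ``"combined"`` adds
    patient-related costs (the sensitivity analysis).
    """
    prices = prices or default_price_table()
    patient_params = patient_params or PatientCostParams()
    records = apply_mitt_filter(_load_or_simulate(config))
    for arm in ARMS:
        n = sum(r.arm == arm for r in records)
        logger.info("analysis population: %s n=%d", arm, n)
        if n == 0:
            raise ValueError(f"no analysable patients in arm {arm!r}")

    totals = total_costs(records, prices, patient_params,
                         perspective=config.perspective)
    cost_table = _table2_style(records, totals, config.perspective)

    # Imputation and per-patient QALYs; completed frames carry cost + qaly.
    frame = records_to_frame(records)
    spec = ImputationSpec(m=config.m, seed=config.seed)
    completed = impute_utilities(frame, spec)
    for comp in completed:
        comp["total_cost"] = totals["total_cost"].to_numpy()
        comp["qaly"] = qaly_auc_frame(comp).to_numpy()

    incremental = incremental_from_completed(completed)
    draws = bootstrap_ce(completed, B=config.B, seed=config.seed)
    curve = ceac(draws, config.wtp_grid)

    from .qaly import pooled_arm_qalys
    pooled = pooled_arm_qalys(completed)
    qaly_summary = pd.DataFrame([
        {"arm": arm, "mean_qaly": pooled.mean[arm],
         "se": float(np.sqrt(pooled.variance[arm]))}
        for arm in ARMS
    ])

    patient_related = None
    if config.perspective == "combined":
        patient_related = _patient_related_table(records, patient_params)

    result = RunResult(records=records, cost_table=cost_table,
                       qaly_summary=qaly_summary, incremental=incremental,
                       draws=draws, ceac_curve=curve.to_frame(),
                       patient_related=patient_related)
    if write:
        result.out_dir = _write_bundle(config, result)
    return result


def run_base_case(config: RunConfig, **kwargs) -> RunResult:
    """Base-case analysis: department-of-cardiology perspective."""
    if config.perspective != "department":
        raise ValueError("base case requires the department perspective")
    return run_analysis(config, **kwargs)


def run_sensitivity(config: RunConfig, **kwargs) -> RunResult:
    """Sensitivity analysis: combined perspective including patient-related
    travel, parking and lost-time costs."""
    if config.perspective != "combined":
        config = dataclasses.replace(config, perspective="combined")
    return run_analysis(config, **kwargs)


def extrapolate_national(delta_cost_per_patient: float,
                         n_patients: int = 34_000) -> float:
    """Annual national savings if the per-patient cost difference held for
    every AMI patient in the Netherlands (~34,000/year); a cost increase
    yields zero savings."""
    if n_patients < 0:
        raise ValueError("n_patients must be nonnegative")
    if delta_cost_per_patient > 0:
        logger.warning("intervention increases costs by %.0f EUR/patient; "
                       "no national savings", delta_cost_per_patient)
    return n_patients * max(0.0, -delta_cost_per_patient)


def _write_bundle(config: RunConfig, result: RunResult) -> Path:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    euro_summary_cols = ["intervention_mean", "intervention_sd",
                         "control_mean", "control_sd", "difference",
                         "ci_low", "ci_high"]
    files = {
        "records.csv": records_to_frame(result.records),
        "cost_summary.csv": _with_usd(result.cost_table, config.currency,
                                      euro_summary_cols),
        "qaly_summary.csv": result.qaly_summary,
        "ce_draws.csv": result.draws.to_frame(),
        "ceac.csv": result.ceac_curve,
    }
    if result.patient_related is not None:
        files["patient_related.csv"] = _with_usd(
            result.patient_related, config.currency,
            ["mean", "sd", "mean_in_office_component",
             "mean_e_visit_component", "box_time_component"])
    inc = result.incremental
    ratio, label = icer(inc.delta_cost, inc.delta_qaly)
    files["incremental.csv"] = pd.DataFrame([{
        "delta_cost": inc.delta_cost,
        "delta_cost_ci_low": inc.ci_cost[0],
        "delta_cost_ci_high": inc.ci_cost[1],
        "p_cost": inc.p_cost,
        "delta_qaly": inc.delta_qaly,
        "delta_qaly_ci_low": inc.ci_qaly[0],
        "delta_qaly_ci_high": inc.ci_qaly[1],
        "p_qaly": inc.p_qaly,
        "icer": np.nan if ratio is None else ratio,
        "icer_label": label,
        "national_annual_savings": extrapolate_national(inc.delta_cost),
    }])
    for name, frame in files.items():
        frame.to_csv(out / name, index=False)
    manifest = {
        "package": "boxcea",
        "version": __version__,
        "python": sys.version.split()[0],
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "seed": config.seed,
        "perspective": config.perspective,
        "B": config.B,
        "m": config.m,
        "currency": config.currency,
        "config_sha256": hashlib.sha256(
            repr(config.trial_config).encode()).hexdigest(),
        "files": {name: _file_sha256(out / name) for name in files},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  sort_keys=True) + "\n")
    logger.info("run bundle written to %s", out)
    return out
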