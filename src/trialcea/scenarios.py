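"""The 2x2 scenario matrix: {multiply imputed, complete case} x
{unadjusted, adjusted}.

The base case imputes missing resource use, utilities and covariates by
chained equations, computes per-patient total costs and 30-day QALYs on
each completed dataset, and quantifies uncertainty by bootstrapping
within each completed dataset and pooling the replicate clouds (the
point estimate is the mean of the per-dataset increments; the BCa bias
constant comes from the pooled cloud and the acceleration is the mean of
the per-dataset jackknife accelerations).  The complete case restricts
to patients with no missing resource use, no missing QALY input (both
utility assessments, or a death), and no missing adjustment covariate.
Adjusted cells fit identity-link GLMs (gamma for cost, normal for QALY)
and, in the base case, pool the arm coefficient by Rubin's rules.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import costing, utility_qaly
from .adjustment import AdjustmentSpec, fit_adjusted, fit_adjusted_pooled
from .ceac import CEACCurve, ceac_from_replicates
from .imputation import ImputationSpec, impute
from .incremental import (IncrementalResult, bca_interval,
                          bootstrap_increments, classify)

logger = logging.getLogger(__name__)

__all__ = ["AnalysisConfig", "ScenarioResult", "ScenariosOutput",
           "build_analysis_frame", "compute_cost_qaly",
           "complete_case_mask", "run_scenarios", "SCENARIO_LABELS"]

SCENARIO_LABELS = ("base_case_unadjusted", "base_case_adjusted",
                   "complete_case_unadjusted", "complete_case_adjusted")

RESOURCE_FIELDS = ["inpatient_days", "itu_days", "hdu_days", "gp_visits",
                   "practice_nurse_visits", "district_nurse_visits",
                   "outpatient_visits"]
COVARIATE_FIELDS = ["stoma_planned", "viscus_planned", "emergency_surgery",
                    "age", "bmi", "diabetes", "smoker", "ssi"]


@dataclass
class AnalysisConfig:
    """Knobs of the full analysis pipeline."""

    B: int = 1000                # bootstrap replicates per completed dataset
    m: int = 20                  # imputations
    n_iterations: int = 10       # chained-equation sweeps
    k_pmm: int = 5
    seed: int = 0
    intervention_label: str = "intervention"
    device_arm: str = "intervention"
    min_complete_n: int = 50     # abort floor for the complete-case cells
    days_per_year: float = 365.25
    death_rule: str = "linear_to_zero"
    wtp_grid: object = None
    impute_by_arm: bool = False


@dataclass
class ScenarioResult:
    label: str
    delta_cost: float
    ci_cost: tuple
    delta_qaly: float
    ci_qaly: tuple
    icer_or_label: object
    n_used: int
    seed: int
    note: str = ""


@dataclass
class ScenariosOutput:
    results: list
    ceacs: dict = field(default_factory=dict)        # label -> CEACCurve
    replicates: dict = field(default_factory=dict)   # label -> replicate frame
    complete_case_n: int = 0
    n_total: int = 0

    def to_table(self) -> pd.DataFrame:
        rows = []
        for r in self.results:
            icer = r.icer_or_label
            rows.append({
                "scenario": r.label,
                "delta_cost": r.delta_cost,
                "cost_ci_low": r.ci_cost[0], "cost_ci_high": r.ci_cost[1],
                "delta_qaly": r.delta_qaly,
                "qaly_ci_low": r.ci_qaly[0], "qaly_ci_high": r.ci_qaly[1],
                "icer": icer if isinstance(icer, float) else np.nan,
                "label": icer if isinstance(icer, str) else "",
                "n_used": r.n_used, "seed": r.seed, "note": r.note,
            })
        return pd.DataFrame(rows)


def _score_series(col) -> pd.Series:
    out = []
    for v in col:
        if v is None or (isinstance(v, float) and np.isnan(v)) or pd.isna(v):
            out.append(np.nan)
        else:
            out.append(utility_qaly.score_profile_string(v))
    return pd.Series(out, index=col.index, dtype=float)


def build_analysis_frame(trial: pd.DataFrame) -> pd.DataFrame:
    """Numeric analysis frame: covariates, resource use, scored utilities.

    EQ-5D profile strings become tariff indices (baseline_utility,
    mid_utility, day30_utility); a 0/1 ``treat`` column mirrors the arm so
    the imputation models can condition on it.
    """
    frame = trial[["patient_id", "arm"] + COVARIATE_FIELDS
                  + RESOURCE_FIELDS + ["medication_cost", "death_day"]].copy()
    frame["baseline_utility"] = _score_series(trial["eq5d_baseline"])
    frame["mid_utility"] = _score_series(trial["eq5d_mid"])
    frame["day30_utility"] = _score_series(trial["eq5d_30d"])
    labels = pd.unique(trial["arm"])
    if len(labels) != 2:
        raise ValueError(f"exactly two arms required, got {list(labels)}")
    return frame


def compute_cost_qaly(frame: pd.DataFrame, unit_costs,
                      cfg: AnalysisConfig) -> pd.DataFrame:
    """Attach per-patient total_cost and qaly columns to an analysis frame."""
    out = frame.copy()
    breakdown = costing.cost_table(frame, unit_costs, cfg.device_arm)
    out["total_cost"] = breakdown["total"].to_numpy()
    out["qaly"] = [
        q if (q := utility_qaly.qaly_30d(
            u0, u30, dd,
            days_per_year=cfg.days_per_year,
            death_rule=cfg.death_rule)) is not None else np.nan
        for u0, u30, dd in zip(frame["baseline_utility"],
                               frame["day30_utility"],
                               frame["death_day"].where(frame["death_day"].notna(),
                                                        None))
    ]
    return out


def complete_case_mask(frame: pd.DataFrame) -> pd.Series:
    """Patients usable in both complete-case cells: full resource use,
    full QALY inputs (baseline utility plus 30-day utility or a death),
    and every adjustment covariate observed."""
    has_resources = frame[RESOURCE_FIELDS + ["medication_cost"]].notna().all(axis=1)
    has_qaly = frame["baseline_utility"].notna() & (
        frame["day30_utility"].notna() | frame["death_day"].notna())
    has_covs = frame[COVARIATE_FIELDS].notna().all(axis=1)
    return has_resources & has_qaly & has_covs


def _pooled_unadjusted(completed, unit_costs, cfg) -> tuple[ScenarioResult, pd.DataFrame]:
    per: list[IncrementalResult] = []
    for j, comp in enumerate(completed):
        cq = compute_cost_qaly(comp, unit_costs, cfg)
        per.append(bootstrap_increments(
            cq, B=cfg.B, seed=int(np.random.SeedSequence(
                entropy=cfg.seed, spawn_key=(101, j)).generate_state(1)[0] % 2**31),
            intervention_label=cfg.intervention_label))
    dc = float(np.mean([r.delta_cost for r in per]))
    de = float(np.mean([r.delta_effect for r in per]))
    cloud = pd.concat([r.replicates for r in per], ignore_index=True)
    a_c = float(np.mean([r.accel_cost for r in per]))
    a_e = float(np.mean([r.accel_effect for r in per]))
    res = ScenarioResult(
        label="base_case_unadjusted",
        delta_cost=dc,
        ci_cost=bca_interval(cloud["delta_cost"], dc, acceleration=a_c),
        delta_qaly=de,
        ci_qaly=bca_interval(cloud["delta_effect"], de, acceleration=a_e),
        icer_or_label=classify(dc, de),
        n_used=len(completed[0]),
        seed=cfg.seed,
    )
    return res, cloud


def run_scenarios(trial: pd.DataFrame, unit_costs,
                  cfg: AnalysisConfig | None = None) -> ScenariosOutput:
    """Run all four scenario cells on a patient table.

    Complete-case cells are aborted (logged, values NaN) when fewer than
    ``cfg.min_complete_n`` patients satisfy the complete-case predicate.
    Deterministic given ``cfg.seed``.
    """
    cfg = cfg or AnalysisConfig()
    frame = build_analysis_frame(trial)
    n_total = len(frame)
    out = ScenariosOutput(results=[], n_total=n_total)

    targets = [c for c in frame.select_dtypes(include=[np.number]).columns
               if c != "death_day" and frame[c].isna().any()]
    any_missing = bool(targets)
    if any_missing:
        spec = ImputationSpec(m=cfg.m, n_iterations=cfg.n_iterations,
                              k_pmm=cfg.k_pmm, seed=cfg.seed,
                              by_arm=cfg.impute_by_arm)
        completed = impute(frame, spec, variables=targets)
    else:
        completed = [frame]

    # -- base case, unadjusted ---------------------------------------
    base_unadj, cloud = _pooled_unadjusted(completed, unit_costs, cfg)
    out.results.append(base_unadj)
    out.replicates["base_case_unadjusted"] = cloud
    out.ceacs["base_case_unadjusted"] = ceac_from_replicates(cloud, cfg.wtp_grid)

    # -- base case, adjusted -----------------------------------------
    cqs = [compute_cost_qaly(c, unit_costs, cfg) for c in completed]
    if len(cqs) > 1:
        pooled_c, _ = fit_adjusted_pooled(
            cqs, AdjustmentSpec.cost_default(),
            intervention_label=cfg.intervention_label)
        pooled_q, _ = fit_adjusted_pooled(
            cqs, AdjustmentSpec.qaly_default(),
            intervention_label=cfg.intervention_label)
        dc, de = pooled_c.estimate, pooled_q.estimate
        ci_c, ci_q = pooled_c.conf_int(), pooled_q.conf_int()
    else:
        rc = fit_adjusted(cqs[0], AdjustmentSpec.cost_default(),
                          intervention_label=cfg.intervention_label)
        rq = fit_adjusted(cqs[0], AdjustmentSpec.qaly_default(),
                          intervention_label=cfg.intervention_label)
        dc, de = rc.adjusted_increment, rq.adjusted_increment
        ci_c, ci_q = (rc.ci_low, rc.ci_high), (rq.ci_low, rq.ci_high)
    out.results.append(ScenarioResult(
        label="base_case_adjusted", delta_cost=float(dc), ci_cost=tuple(ci_c),
        delta_qaly=float(de), ci_qaly=tuple(ci_q),
        icer_or_label=classify(dc, de), n_used=n_total, seed=cfg.seed))

    # -- complete case ------------------------------------------------
    cc_mask = complete_case_mask(frame)
    out.complete_case_n = int(cc_mask.sum())
    cc = compute_cost_qaly(frame.loc[cc_mask], unit_costs, cfg)
    if out.complete_case_n < cfg.min_complete_n:
        logger.warning("complete-case cells aborted: n=%d below floor %d",
                       out.complete_case_n, cfg.min_complete_n)
        for lab in ("complete_case_unadjusted", "complete_case_adjusted"):
            out.results.append(ScenarioResult(
                label=lab, delta_cost=float("nan"), ci_cost=(np.nan, np.nan),
                delta_qaly=float("nan"), ci_qaly=(np.nan, np.nan),
                icer_or_label="", n_used=out.complete_case_n, seed=cfg.seed,
                note="aborted: complete-case n below floor"))
        return out

    cc_seed = int(np.random.SeedSequence(entropy=cfg.seed,
                                         spawn_key=(202,)).generate_state(1)[0]
                  % 2**31)
    cc_unadj = bootstrap_increments(cc, B=cfg.B, seed=cc_seed,
                                    intervention_label=cfg.intervention_label)
    out.results.append(ScenarioResult(
        label="complete_case_unadjusted",
        delta_cost=cc_unadj.delta_cost, ci_cost=cc_unadj.ci_cost,
        delta_qaly=cc_unadj.delta_effect, ci_qaly=cc_unadj.ci_effect,
        icer_or_label=cc_unadj.icer_or_label,
        n_used=out.complete_case_n, seed=cc_seed))
    out.replicates["complete_case_unadjusted"] = cc_unadj.replicates
    out.ceacs["complete_case_unadjusted"] = ceac_from_replicates(
        cc_unadj.replicates, cfg.wtp_grid)

    rc = fit_adjusted(cc, AdjustmentSpec.cost_default(),
                      intervention_label=cfg.intervention_label)
    rq = fit_adjusted(cc, AdjustmentSpec.qaly_default(),
                      intervention_label=cfg.intervention_label)
    out.results.append(ScenarioResult(
        label="complete_case_adjusted",
        delta_cost=rc.adjusted_increment, ci_cost=(rc.ci_low, rc.ci_high),
        delta_qaly=rq.adjusted_increment, ci_qaly=(rq.ci_low, rq.ci_high),
        icer_or_label=classify(rc.adjusted_increment, rq.adjusted_increment),
        n_used=out.complete_case_n, seed=cfg.seed))
    return out
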