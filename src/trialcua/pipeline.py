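"""End-to-end analysis: dataset -> ledger + utilities -> imputation ->
adjusted GLM increments -> bootstrap cost-effectiveness results."""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from decimal import Decimal
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import cea as cea_mod
from .costing import (
    CostLedger,
    UnitCostTable,
    apply_no_surgery_cost_rule,
    cost_followup,
    cost_intervention,
)
from .errors import ConfigError, InsufficientDataError, TrajectoryError
from .glm_engine import (
    ModelSpec,
    adjusted_mean_difference,
    fit_glm,
    recycled_difference,
    select_family_link,
)
from .missing_data import impute_pmm, missingness_model, rubins_pool
from .qol_valuation import (
    AdditiveMapping,
    QalyOptions,
    UtilityTariff,
    UtilityTrajectory,
    qaly_auc,
    value_eq5d,
    value_iciq,
)
from .schedule import (
    EQ5D_TIMEPOINTS,
    ICIQ_TIMEPOINTS,
    PERIOD_DISCOUNT_YEAR,
    PERIODS,
    anchor_day,
    discount_factor,
)
from .synthetic_trial import ICIQ_ITEMS, TrialDataset
from .qol_valuation import EQ5D_DIMENSIONS

#: analysis-frame utility columns per instrument
U_COLS = {tp: f"u_{tp}" for tp in EQ5D_TIMEPOINTS}
IU_COLS = {tp: f"iu_{tp}" for tp in ICIQ_TIMEPOINTS}
COST_COLS = [
    f"cost_{sector}_{period}"
    for period in PERIODS
    for sector in ("primary", "secondary")
]
IMPUTE_PREDICTORS = ("arm", "age", "pfmt", "u_baseline", "baseline_ui_type")


@dataclass(frozen=True)
class AnalysisOptions:
    """Switches covering the base case and the five sensitivity variants."""

    discount_rate: float = 0.035
    adjust_for_surgery_wait: bool = True
    utility_source: str = "eq5d"  # "eq5d" | "iciq"
    relax_zero_cost: bool = False
    complete_case: bool = False
    m: int = 20
    knn: int = 5
    n_bootstrap: int = 1000
    wtp_grid: tuple = field(default_factory=cea_mod.default_wtp_grid)
    seed: int = 0
    cost_family: str = "auto"
    cost_link: str = "log"
    qaly_family: str = "gaussian"
    qaly_link: str = "identity"

    def __post_init__(self):
        if self.utility_source not in ("eq5d", "iciq"):
            raise ConfigError("utility_source must be 'eq5d' or 'iciq'")
        if self.discount_rate < 0:
            raise ConfigError("discount_rate must be >= 0")
        if self.n_bootstrap < 1:
            raise ConfigError("n_bootstrap must be >= 1")


def _dec_to_float(value) -> float:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return float("nan")
    return float(value)


def build_analysis_table(
    dataset: TrialDataset,
    unit_costs: UnitCostTable,
    tariff: UtilityTariff,
    iciq_mapping: AdditiveMapping,
    relax_zero_cost: bool = False,
):
    """One row per patient: covariates, valued utilities per time point and
    cost components per period (floats; NaN = missing).

    Returns ``(frame, ledger)``; the zero-cost rule for unoperated patients
    without any follow-up CRF is already applied to both.
    """
    pats = dataset.patients
    frame = pd.DataFrame(index=pats.index)
    frame["arm"] = (pats["arm"] == "intervention").astype(int)
    frame["centre"] = pats["centre"]
    frame["age"] = pats["age"]
    frame["pfmt"] = pats["pfmt"]
    frame["baseline_ui_type"] = pats["baseline_ui_type"]
    frame["surgery_received"] = pats["surgery_received"]
    frame["surgery_day"] = pats["surgery_day"]

    # valued utilities
    eq5d = dataset.eq5d.set_index(["patient_id", "timepoint"])
    for tp in EQ5D_TIMEPOINTS:
        values = []
        for pid in frame.index:
            levels = eq5d.loc[(pid, tp), list(EQ5D_DIMENSIONS)]
            if levels.isna().any():
                values.append(float("nan"))
            else:
                values.append(value_eq5d(levels.astype(int), tariff))
        frame[U_COLS[tp]] = values
    iciq = dataset.iciq.set_index(["patient_id", "timepoint"])
    for tp in ICIQ_TIMEPOINTS:
        values = []
        for pid in frame.index:
            resp = iciq.loc[(pid, tp), list(ICIQ_ITEMS)]
            if resp.isna().any():
                values.append(float("nan"))
            else:
                values.append(value_iciq(dict(resp.astype(int)), iciq_mapping))
        frame[IU_COLS[tp]] = values

    # cost ledger
    iv = dataset.intervention.set_index("patient_id")
    resource = dataset.resource_use.pivot_table(
        index="patient_id", columns=["period", "item"], values="count",
        aggfunc="first", dropna=False,
    )
    ledger_rows = {}
    for pid in frame.index:
        row = {}
        if pid in iv.index:
            row["intervention"] = cost_intervention(iv.loc[pid].to_dict(), unit_costs)
        else:
            row["intervention"] = Decimal("0.00")
        for period in PERIODS:
            counts = resource[period].loc[pid].to_dict() if period in resource else {}
            primary, secondary = cost_followup(counts, unit_costs, period)
            row[f"primary_{period}"] = primary
            row[f"secondary_{period}"] = secondary
        ledger_rows[pid] = row
    ledger_frame = pd.DataFrame.from_dict(ledger_rows, orient="index").astype(object)
    ledger_frame.index.name = "patient_id"
    ledger_frame["surgery_received"] = pats["surgery_received"]
    observed_any = (
        dataset.resource_use.dropna(subset=["count"])
        .groupby("patient_id")["count"]
        .size()
        .reindex(frame.index)
        .fillna(0)
        > 0
    )
    ledger_frame["followup_crf_any"] = observed_any
    ledger = apply_no_surgery_cost_rule(CostLedger(ledger_frame), relax=relax_zero_cost)

    frame["cost_intervention"] = [
        _dec_to_float(v) for v in ledger.frame["intervention"]
    ]
    for period in PERIODS:
        for sector in ("primary", "secondary"):
            frame[f"cost_{sector}_{period}"] = [
                _dec_to_float(v) for v in ledger.frame[f"{sector}_{period}"]
            ]
    return frame, ledger


def compute_qalys(
    frame: pd.DataFrame,
    options: AnalysisOptions,
    source: str | None = None,
) -> pd.Series:
    """Discounted QALY per patient from the (possibly imputed) utility columns.

    Surgery-anchored points are placed at surgery day + 28 / + 91 days;
    patients who never had surgery contribute only the baseline and the
    post-randomisation points.  Incomplete trajectories yield NaN.
    """
    source = source or options.utility_source
    timepoints = EQ5D_TIMEPOINTS if source == "eq5d" else ICIQ_TIMEPOINTS
    cols = U_COLS if source == "eq5d" else IU_COLS
    qopts = QalyOptions(
        discount_rate=options.discount_rate,
        adjust_for_surgery_wait=options.adjust_for_surgery_wait,
    )
    out = []
    for pid, row in frame.iterrows():
        surgery_day = row["surgery_day"] if row["surgery_received"] else None
        if isinstance(surgery_day, float) and math.isnan(surgery_day):
            surgery_day = None
        points = []
        for tp in timepoints:
            day = anchor_day(tp, surgery_day)
            if day is None:
                continue
            points.append((day, row[cols[tp]]))
        # late surgery can push anchored points past fixed anchors: order by
        # actual day and drop exact-day duplicates
        points.sort(key=lambda p: p[0])
        times, utils = [], []
        for day, value in points:
            if times and day <= times[-1]:
                continue
            times.append(day)
            utils.append(value)
        try:
            out.append(
                qaly_auc(
                    UtilityTrajectory(
                        patient_id=pid,
                        times=tuple(times),
                        utilities=tuple(utils),
                        surgery_day=surgery_day,
                    ),
                    qopts,
                )
            )
        except TrajectoryError:
            out.append(float("nan"))
    return pd.Series(out, index=frame.index, name="qaly")


def compute_total_cost(frame: pd.DataFrame, rate: float) -> pd.Series:
    """Discounted total cost per patient from the component columns (floats)."""
    total = frame["cost_intervention"].copy()
    for period in PERIODS:
        factor = discount_factor(PERIOD_DISCOUNT_YEAR[period], rate)
        total = total + factor * (
            frame[f"cost_primary_{period}"] + frame[f"cost_secondary_{period}"]
        )
    return total.rename("total_cost")


def derive_outcomes(frame: pd.DataFrame, options: AnalysisOptions) -> pd.DataFrame:
    out = frame.copy()
    out["total_cost"] = compute_total_cost(out, options.discount_rate)
    out["qaly"] = compute_qalys(out, options)
    return out


def _analysis_columns(options: AnalysisOptions) -> list:
    cols = ["cost_intervention", *COST_COLS]
    ucols = U_COLS if options.utility_source == "eq5d" else IU_COLS
    cols += [ucols[tp] for tp in ucols]
    return cols


#: surgery-anchored utility columns: structurally absent (not missing data)
#: for patients who never had surgery
_SURGERY_ANCHORED = {U_COLS["4w"], U_COLS["3m"], IU_COLS["3m"]}


def complete_case_mask(table: pd.DataFrame, options: AnalysisOptions) -> pd.Series:
    """True for patients complete in every column applicable to them."""
    surgery = table["surgery_received"].astype(bool)
    mask = pd.Series(True, index=table.index)
    for col in _analysis_columns(options):
        observed = table[col].notna()
        if col in _SURGERY_ANCHORED:
            observed = observed | ~surgery
        mask &= observed
    return mask


def imputation_columns() -> list:
    """Columns entering multiple imputation: post-baseline utilities for both
    instruments plus the follow-up cost components."""
    cols = [U_COLS[tp] for tp in EQ5D_TIMEPOINTS if tp != "baseline"]
    cols += [IU_COLS[tp] for tp in ICIQ_TIMEPOINTS if tp != "baseline"]
    cols += COST_COLS
    return cols


def make_estimator(cost_spec: ModelSpec, qaly_spec: ModelSpec, arm: str = "arm"):
    """Adjusted incremental (cost, QALY) estimator for bootstrap replicates."""
    cost_spec = replace(cost_spec, cluster=None)
    qaly_spec = replace(qaly_spec, cluster=None)

    def estimator(frame: pd.DataFrame):
        cost_fit = fit_glm(frame, cost_spec)
        qaly_fit = fit_glm(frame, qaly_spec)
        return (
            recycled_difference(cost_fit.result, frame, arm),
            recycled_difference(qaly_fit.result, frame, arm),
        )

    return estimator


def _arm_means(result, frame: pd.DataFrame, arm: str = "arm"):
    d1, d0 = frame.copy(), frame.copy()
    d1[arm] = 1
    d0[arm] = 0
    return float(np.mean(result.predict(d1))), float(np.mean(result.predict(d0)))


def analyse(
    dataset: TrialDataset,
    options: AnalysisOptions = AnalysisOptions(),
    unit_costs: UnitCostTable | None = None,
    tariff: UtilityTariff | None = None,
    iciq_mapping: AdditiveMapping | None = None,
) -> cea_mod.CeaResult:
    """Run the full analysis for one configuration and return a CeaResult.

    Stages: costing + valuation -> (unless complete-case) predictive mean
    matching imputation -> per-imputation adjusted GLM increments pooled by
    Rubin's rules -> cluster bootstrap of the joint increments -> ICER,
    quadrant proportions and CEAC.
    """
    unit_costs = unit_costs or UnitCostTable.toy_default()
    tariff = tariff or UtilityTariff.default_uk()
    iciq_mapping = iciq_mapping or AdditiveMapping.default_iciq()

    imp_seed, boot_seed = np.random.SeedSequence(options.seed).spawn(2)
    table, _ledger = build_analysis_table(
        dataset, unit_costs, tariff, iciq_mapping,
        relax_zero_cost=options.relax_zero_cost,
    )

    base_u = "u_baseline" if options.utility_source == "eq5d" else "iu_baseline"
    if table[base_u].isna().any():
        raise InsufficientDataError(
            f"baseline utility column {base_u!r} must be complete before analysis"
        )

    if options.complete_case:
        completed = [table[complete_case_mask(table, options)].copy()]
    else:
        imputed = impute_pmm(
            table,
            imputation_columns(),
            m=options.m,
            knn=options.knn,
            seed=imp_seed,
            predictors=IMPUTE_PREDICTORS,
        )
        completed = list(imputed.datasets)
    completed = [derive_outcomes(f, options) for f in completed]

    covariates = ("arm", base_u, "pfmt", "age")
    selection_log: list = []
    if options.cost_family == "auto":
        cost_spec, selection_log = select_family_link(
            completed[0], ModelSpec(outcome="total_cost", covariates=covariates)
        )
    else:
        cost_spec = ModelSpec(
            outcome="total_cost", covariates=covariates,
            family=options.cost_family, link=options.cost_link,
        )
    qaly_spec = ModelSpec(
        outcome="qaly", covariates=covariates,
        family=options.qaly_family, link=options.qaly_link,
    )

    cost_est, cost_var, qaly_est, qaly_var = [], [], [], []
    mean_c1, mean_c0, mean_q1, mean_q0 = [], [], [], []
    for frame in completed:
        cost_fit = fit_glm(frame, cost_spec)
        qaly_fit = fit_glm(frame, qaly_spec)
        cdiff = adjusted_mean_difference(cost_fit, method="delta")
        qdiff = adjusted_mean_difference(qaly_fit, method="delta")
        cost_est.append(cdiff.estimate)
        cost_var.append(cdiff.se**2)
        qaly_est.append(qdiff.estimate)
        qaly_var.append(qdiff.se**2)
        c1, c0 = _arm_means(cost_fit.result, frame)
        q1, q0 = _arm_means(qaly_fit.result, frame)
        mean_c1.append(c1)
        mean_c0.append(c0)
        mean_q1.append(q1)
        mean_q0.append(q0)

    delta_cost = rubins_pool(cost_est, cost_var)
    delta_qaly = rubins_pool(qaly_est, qaly_var)

    estimator = make_estimator(cost_spec, qaly_spec)
    draws = cea_mod.bootstrap_cea(
        completed, options.n_bootstrap, boot_seed, estimator
    )
    return cea_mod.CeaResult(
        mean_cost={
            "intervention": float(np.mean(mean_c1)),
            "comparator": float(np.mean(mean_c0)),
        },
        mean_qaly={
            "intervention": float(np.mean(mean_q1)),
            "comparator": float(np.mean(mean_q0)),
        },
        delta_cost=delta_cost,
        delta_qaly=delta_qaly,
        icer=cea_mod.icer(delta_cost.estimate, delta_qaly.estimate),
        draws=draws,
        ceac=cea_mod.ceac(draws, options.wtp_grid),
        quadrants=cea_mod.quadrant_proportions(draws),
        n_patients=int(len(completed[0])),
        selection_log=selection_log,
        options=options,
    )


def missingness_report(
    dataset: TrialDataset,
    unit_costs: UnitCostTable | None = None,
    tariff: UtilityTariff | None = None,
    iciq_mapping: AdditiveMapping | None = None,
):
    """Missingness diagnostics on the assembled analysis table."""
    unit_costs = unit_costs or UnitCostTable.toy_default()
    tariff = tariff or UtilityTariff.default_uk()
    iciq_mapping = iciq_mapping or AdditiveMapping.default_iciq()
    table, _ = build_analysis_table(dataset, unit_costs, tariff, iciq_mapping)
    return missingness_model(table, imputation_columns())
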