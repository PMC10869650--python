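"""Incremental cost-effectiveness: bootstrap joint distribution, ICER and
dominance classification, net monetary benefit, CEACs and the sensitivity
suite."""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, ConvergenceError, EstimationError

#: dominance / ratio labels
COMPARATOR_DOMINATED = "comparator dominated"
INTERVENTION_DOMINATED = "intervention dominated"
ICER_LABEL = "icer"
COST_SAVING_PER_QALY_LOST = "cost saving per QALY lost"
UNDEFINED = "ratio undefined; report delta cost only"


def default_wtp_grid(stop: float = 50_000.0, step: float = 500.0) -> tuple:
    grid = set(np.arange(0.0, stop + step, step))
    grid.update({20_000.0, 30_000.0})
    return tuple(sorted(grid))


@dataclass(frozen=True)
class CeaDraws:
    """Bootstrap sample of joint (delta cost, delta QALY) pairs."""

    delta_cost: np.ndarray
    delta_qaly: np.ndarray
    imputation_index: np.ndarray
    seed: int | None = None
    n_failed: int = 0

    def __post_init__(self):
        if len(self.delta_cost) != len(self.delta_qaly):
            raise ConfigError("delta_cost and delta_qaly must have equal length")
        if len(self.delta_cost) < 1:
            raise ConfigError("need at least one draw")
        if not (
            np.isfinite(self.delta_cost).all() and np.isfinite(self.delta_qaly).all()
        ):
            raise ConfigError("draws must be finite")

    def __len__(self):
        return len(self.delta_cost)

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "replicate": np.arange(len(self)),
                "delta_cost": self.delta_cost,
                "delta_qaly": self.delta_qaly,
                "imputation_index": self.imputation_index,
            }
        )


def bootstrap_cea(
    imputations: Sequence[pd.DataFrame],
    B: int,
    seed,
    estimator: Callable[[pd.DataFrame], tuple],
    cluster_col: str = "centre",
    resample: bool = True,
    max_failure_fraction: float = 0.05,
) -> CeaDraws:
    """Non-parametric bootstrap of the incremental cost/QALY pair.

    Each replicate samples one imputed dataset uniformly, resamples
    clusters (centres) with replacement, and records the estimator's
    (delta cost, delta QALY).  Failed replicates are dropped; more than
    ``max_failure_fraction`` failures aborts.  Deterministic given seed.
    """
    if B < 1:
        raise ConfigError("B must be >= 1")
    frames = list(imputations)
    rng = np.random.default_rng(seed)
    dc, de, prov = [], [], []
    failed = 0
    for _ in range(B):
        idx = int(rng.integers(len(frames)))
        frame = frames[idx]
        if resample:
            ids = pd.unique(frame[cluster_col])
            chosen = rng.choice(ids, size=len(ids), replace=True)
            parts = []
            for k, cid in enumerate(chosen):
                part = frame[frame[cluster_col] == cid].copy()
                part[cluster_col] = k
                parts.append(part)
            sample = pd.concat(parts, ignore_index=True)
        else:
            sample = frame
        try:
            cost_diff, qaly_diff = estimator(sample)
        except (EstimationError, ConvergenceError):
            failed += 1
            continue
        dc.append(cost_diff)
        de.append(qaly_diff)
        prov.append(idx)
    if failed > max_failure_fraction * B or not dc:
        raise EstimationError(
            f"{failed}/{B} bootstrap replicates failed (limit "
            f"{max_failure_fraction:.0%})"
        )
    try:
        seed_int = int(seed)
    except (TypeError, ValueError):
        seed_int = None
    return CeaDraws(
        delta_cost=np.asarray(dc, dtype=float),
        delta_qaly=np.asarray(de, dtype=float),
        imputation_index=np.asarray(prov, dtype=int),
        seed=seed_int,
        n_failed=failed,
    )


@dataclass(frozen=True)
class IcerResult:
    value: float | None
    label: str
    quadrant: str


def _quadrant(delta_cost: float, delta_qaly: float) -> str:
    ew = "E" if delta_qaly >= 0 else "W"
    ns = "N" if delta_cost >= 0 else "S"
    return ns + ew


def icer(delta_cost: float, delta_qaly: float) -> IcerResult:
    """Classify the incremental pair and compute the ratio where it exists.

    (dC<0, dE>0): the comparator is dominated, no ratio reported.
    (dC>0, dE<0): the intervention is dominated.  Northeast pairs report
    dC/dE in pounds per QALY gained; southwest pairs report dC/dE as cost
    saving per QALY lost (a saving below the threshold does not justify
    the loss).  dE = 0 leaves the ratio undefined.
    """
    quadrant = _quadrant(delta_cost, delta_qaly)
    if delta_qaly == 0:
        return IcerResult(value=None, label=UNDEFINED, quadrant=quadrant)
    if delta_qaly > 0 and delta_cost < 0:
        return IcerResult(value=None, label=COMPARATOR_DOMINATED, quadrant=quadrant)
    if delta_qaly < 0 and delta_cost > 0:
        return IcerResult(value=None, label=INTERVENTION_DOMINATED, quadrant=quadrant)
    ratio = delta_cost / delta_qaly
    label = ICER_LABEL if delta_qaly > 0 else COST_SAVING_PER_QALY_LOST
    return IcerResult(value=float(ratio), label=label, quadrant=quadrant)


def nmb(delta_cost: float, delta_qaly: float, wtp: float) -> float:
    """Net monetary benefit ``wtp * delta_qaly - delta_cost``."""
    if wtp < 0:
        raise ConfigError("willingness-to-pay must be >= 0")
    return wtp * delta_qaly - delta_cost


def ceac(draws: CeaDraws, wtp_grid: Sequence[float]) -> pd.DataFrame:
    """Probability the intervention has positive net benefit at each threshold.

    The comparator curve is the exact complement (two comparators).
    """
    wtp_grid = list(wtp_grid)
    if not wtp_grid:
        raise ConfigError("willingness-to-pay grid must not be empty")
    rows = []
    for wtp in wtp_grid:
        if wtp < 0:
            raise ConfigError("willingness-to-pay must be >= 0")
        p = float(np.mean(wtp * draws.delta_qaly - draws.delta_cost > 0))
        rows.append({"wtp": float(wtp), "p_intervention": p, "p_comparator": 1.0 - p})
    return pd.DataFrame(rows)


def quadrant_proportions(draws: CeaDraws) -> Mapping[str, float]:
    quads = [_quadrant(c, e) for c, e in zip(draws.delta_cost, draws.delta_qaly)]
    return {q: quads.count(q) / len(quads) for q in ("NE", "SE", "SW", "NW")}


@dataclass
class CeaResult:
    """Point estimates, dominance classification, draws and CEAC for one analysis."""

    mean_cost: Mapping[str, float]
    mean_qaly: Mapping[str, float]
    delta_cost: object  # PooledEstimate
    delta_qaly: object
    icer: IcerResult
    draws: CeaDraws
    ceac: pd.DataFrame
    quadrants: Mapping[str, float]
    n_patients: int
    selection_log: list
    options: object

    def probability_cost_effective(self, wtp: float) -> float:
        row = self.ceac[np.isclose(self.ceac["wtp"], wtp)]
        if len(row):
            return float(row["p_intervention"].iloc[0])
        return float(np.mean(wtp * self.draws.delta_qaly - self.draws.delta_cost > 0))


SENSITIVITY_VARIANTS = (
    "complete_case",
    "no_surgery_wait_adjustment",
    "iciq_utilities",
    "discount_6pct",
    "relax_zero_cost",
)


def _variant_options(options, name: str):
    if name == "complete_case":
        return replace(options, complete_case=True)
    if name == "no_surgery_wait_adjustment":
        return replace(options, adjust_for_surgery_wait=False)
    if name == "iciq_utilities":
        return replace(options, utility_source="iciq")
    if name == "discount_6pct":
        return replace(options, discount_rate=0.06)
    if name == "relax_zero_cost":
        return replace(options, relax_zero_cost=True)
    raise ConfigError(f"unknown sensitivity variant {name!r}")


def run_sensitivity_suite(
    dataset,
    options,
    unit_costs=None,
    tariff=None,
    iciq_mapping=None,
    variants: Sequence[str] = SENSITIVITY_VARIANTS,
):
    """Base case plus the five sensitivity analyses.

    Returns ``(results, errors)``: a name -> :class:`CeaResult` mapping
    (insertion order: base case first) and a name -> message mapping for
    variants that failed; failures do not stop the remaining variants.
    """
    from .pipeline import analyse  # lazy: pipeline imports this module

    results: dict = {}
    errors: dict = {}
    for name in ("base_case", *variants):
        opts = options if name == "base_case" else _variant_options(options, name)
        try:
            results[name] = analyse(
                dataset, opts, unit_costs=unit_costs, tariff=tariff,
                iciq_mapping=iciq_mapping,
            )
        except Exception as exc:  # keep other variants running
            errors[name] = f"{type(exc).__name__}: {exc}"
    return results, errors


def table3_frame(results: Mapping[str, CeaResult]) -> pd.DataFrame:
    """Report table mirroring the incremental cost-effectiveness layout."""
    rows = []
    for name, res in results.items():
        icer_cell = (
            res.icer.label
            if res.icer.value is None
            else f"{res.icer.value:.0f} ({res.icer.label})"
        )
        rows.append(
            {
                "analysis": name,
                "cost_intervention": round(res.mean_cost["intervention"]),
                "cost_comparator": round(res.mean_cost["comparator"]),
                "cost_diff": round(res.delta_cost.estimate),
                "cost_ci_low": round(res.delta_cost.ci[0]),
                "cost_ci_high": round(res.delta_cost.ci[1]),
                "qaly_intervention": round(res.mean_qaly["intervention"], 3),
                "qaly_comparator": round(res.mean_qaly["comparator"], 3),
                "qaly_diff": round(res.delta_qaly.estimate, 3),
                "qaly_ci_low": round(res.delta_qaly.ci[0], 3),
                "qaly_ci_high": round(res.delta_qaly.ci[1], 3),
                "icer": icer_cell,
                "p_ce_at_0": round(res.probability_cost_effective(0.0), 2),
                "p_ce_at_20000": round(res.probability_cost_effective(20_000.0), 2),
                "p_ce_at_30000": round(res.probability_cost_effective(30_000.0), 2),
            }
        )
    return pd.DataFrame(rows)
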