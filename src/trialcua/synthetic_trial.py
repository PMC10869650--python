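"""Synthetic two-arm, multi-centre RCT datasets.

The generator reproduces the statistical structure the downstream analysis
assumes — 1:1 randomisation across centres, a latent per-patient utility
trajectory mapped to questionnaire item levels through a monotone threshold
ladder, right-skewed resource-use counts, baseline utility imbalance between
arms, and missing-at-random follow-up driven by a logistic model on observed
covariates with missingness rising over time.  All randomness flows from one
seed with named substreams (generation, missingness) so the two components
can be varied independently.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, ndtr as norm_cdf

from .costing import ANAESTHETIST_TYPES
from .errors import ConfigError, DatasetValidationError
from .qol_valuation import EQ5D_DIMENSIONS, UtilityTariff, value_eq5d
from .schedule import EQ5D_TIMEPOINTS, ICIQ_TIMEPOINTS, PERIODS

ARMS = ("intervention", "comparator")
ICIQ_ITEMS = tuple(f"item_{i}" for i in range(1, 9))
RESOURCE_ITEMS = ("gp_visit", "physio_visit", "outpatient_visit", "inpatient_day")

# Severity ladder through the EQ-5D-3L lattice: item levels never decrease
# from one rung to the next, so valuation is strictly decreasing and the
# latent-utility -> state map is a monotone threshold map.
_LADDER_STATES = (
    (1, 1, 1, 1, 1),
    (1, 1, 1, 1, 2),
    (1, 1, 2, 1, 2),
    (1, 1, 2, 2, 2),
    (2, 1, 2, 2, 2),
    (2, 2, 2, 2, 2),
    (2, 2, 3, 2, 2),
    (2, 3, 3, 2, 2),
    (3, 3, 3, 2, 2),
    (3, 3, 3, 3, 2),
    (3, 3, 3, 3, 3),
)


def _default_resource_means() -> dict:
    return {
        "gp_visit": 0.8,
        "physio_visit": 0.25,
        "outpatient_visit": 0.45,
        "inpatient_day": 0.12,
    }


def _default_missingness_coefficients() -> dict:
    return {"age": 0.4, "baseline_utility": -1.2, "arm": 0.1}


def _default_missing_ramp() -> dict:
    return {"4w": 0.55, "3m": 0.65, "15m": 1.0, "24m": 1.0, "36m": 1.0}


def _default_anaesthesia_probs() -> dict:
    return {"general": 0.30, "spinal": 0.10, "la_iv": 0.20, "la_oral": 0.15, "la": 0.25}


@dataclass(frozen=True)
class TrialConfig:
    """Parameters of the synthetic trial.

    ``true_cost_effect`` / ``true_utility_effect`` are the intervention
    minus comparator differences in mean total cost (pounds) and mean
    post-baseline utility.  The cost effect is delivered through theatre
    minutes, converted at ``cost_rate_per_theatre_minute``.
    """

    n_per_arm: int = 298
    n_centres: int = 21
    true_cost_effect: float = 0.0
    true_utility_effect: float = 0.0
    baseline_utility_mean: tuple = (0.86, 0.834)  # (intervention, comparator)
    baseline_utility_sd: tuple = (0.20, 0.25)
    utility_noise_sd: float = 0.07
    surgery_delay_mean_days: float = 90.0
    surgery_delay_shape: float = 3.0
    p_no_surgery: float = 0.04
    theatre_minutes_mean: float = 40.0
    theatre_minutes_shape: float = 6.0
    recovery_minutes_mean: float = 70.0
    recovery_minutes_shape: float = 4.0
    cost_rate_per_theatre_minute: float = 25.0
    anaesthesia_probs: Mapping[str, float] = field(
        default_factory=_default_anaesthesia_probs
    )
    resource_means: Mapping[str, float] = field(default_factory=_default_resource_means)
    resource_dispersion: float = 0.5
    missingness_coefficients: Mapping[str, float] = field(
        default_factory=_default_missingness_coefficients
    )
    missing_within_patient_corr: float = 0.8
    target_missing_fraction: float = 0.45
    missing_ramp: Mapping[str, float] = field(default_factory=_default_missing_ramp)
    seed: int = 0

    def __post_init__(self):
        if self.n_per_arm < 2:
            raise ConfigError("n_per_arm must be >= 2")
        if self.n_centres < 1:
            raise ConfigError("n_centres must be >= 1")
        if not 0.0 <= self.p_no_surgery <= 1.0:
            raise ConfigError("p_no_surgery must be in [0, 1]")
        if not 0.0 <= self.target_missing_fraction < 1.0:
            raise ConfigError("target_missing_fraction must be in [0, 1)")
        probs = dict(self.anaesthesia_probs)
        if abs(sum(probs.values()) - 1.0) > 1e-9 or any(p < 0 for p in probs.values()):
            raise ConfigError("anaesthesia_probs must be a probability distribution")
        for name in ("surgery_delay_mean_days", "surgery_delay_shape",
                     "theatre_minutes_mean", "theatre_minutes_shape",
                     "recovery_minutes_mean", "recovery_minutes_shape",
                     "cost_rate_per_theatre_minute", "resource_dispersion",
                     "utility_noise_sd"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0")
        for ramp in dict(self.missing_ramp).values():
            if not 0.0 <= ramp <= 1.0:
                raise ConfigError("missing_ramp values must be in [0, 1]")
        if not 0.0 <= self.missing_within_patient_corr < 1.0:
            raise ConfigError("missing_within_patient_corr must be in [0, 1)")

    def as_dict(self) -> dict:
        # JSON round trip normalises tuples -> lists so datasets written to
        # disk compare equal after reading back
        return json.loads(json.dumps(dataclasses.asdict(self), sort_keys=True))


@dataclass
class TrialDataset:
    """Patient-level records of a two-arm trial.

    Frames: ``patients`` (one row per patient, indexed by id), ``eq5d`` and
    ``iciq`` (one row per patient x time point; NaN item = missing),
    ``resource_use`` (patient x period x item counts) and ``intervention``
    (surgical details for operated patients).  ``latent`` carries the true
    latent utilities when produced by the generator; it is never serialised
    and is excluded from equality.
    """

    patients: pd.DataFrame
    eq5d: pd.DataFrame
    iciq: pd.DataFrame
    resource_use: pd.DataFrame
    intervention: pd.DataFrame
    config: dict | None = None
    latent: pd.DataFrame | None = None

    def __eq__(self, other):
        if not isinstance(other, TrialDataset):
            return NotImplemented
        return (
            self.patients.equals(other.patients)
            and self.eq5d.equals(other.eq5d)
            and self.iciq.equals(other.iciq)
            and self.resource_use.equals(other.resource_use)
            and self.intervention.equals(other.intervention)
            and self.config == other.config
        )

    def validate(self) -> None:
        pats = self.patients
        bad_arm = ~pats["arm"].isin(ARMS)
        if bad_arm.any():
            raise DatasetValidationError(
                f"invalid arm label(s): {sorted(pats.loc[bad_arm, 'arm'].unique())}",
                column="arm",
            )
        sday = pats["surgery_day"].dropna()
        if (sday < 0).any():
            raise DatasetValidationError("surgery_day must be >= 0", column="surgery_day")
        for dim in EQ5D_DIMENSIONS:
            vals = self.eq5d[dim].dropna()
            if not vals.isin([1, 2, 3]).all():
                raise DatasetValidationError(
                    "EQ-5D item level outside {1,2,3}", column=dim
                )
        for item in ICIQ_ITEMS:
            vals = self.iciq[item].dropna()
            if not vals.isin([1, 2, 3, 4]).all():
                raise DatasetValidationError(
                    "ICIQ item level outside {1,...,4}", column=item
                )
        counts = self.resource_use["count"].dropna()
        if (counts < 0).any():
            raise DatasetValidationError(
                "resource counts must be >= 0", column="count"
            )


def _state_ladder(tariff: UtilityTariff):
    utilities = np.array([value_eq5d(s, tariff) for s in _LADDER_STATES])
    order = np.argsort(utilities)
    states = [_LADDER_STATES[i] for i in order]
    sorted_u = utilities[order]
    midpoints = 0.5 * (sorted_u[1:] + sorted_u[:-1])
    return states, sorted_u, midpoints


def _latent_to_state(latent: np.ndarray, midpoints: np.ndarray) -> np.ndarray:
    """Index into the ascending state ladder via monotone thresholds."""
    return np.searchsorted(midpoints, latent)


def _order_timepoint_frame(frame: pd.DataFrame, timepoints) -> pd.DataFrame:
    frame = frame.copy()
    frame["__tp"] = pd.Categorical(frame["timepoint"], categories=timepoints, ordered=True)
    return (
        frame.sort_values(["patient_id", "__tp"], kind="mergesort")
        .drop(columns="__tp")
        .reset_index(drop=True)
    )


def _nb_counts(rng, mean: float, dispersion: float, size: int) -> np.ndarray:
    if mean <= 0:
        return np.zeros(size, dtype=float)
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p, size=size).astype(float)


def _calibrate_intercept(scores: np.ndarray, target: float) -> float:
    if target <= 0:
        return -np.inf
    lo, hi = -40.0, 40.0
    return brentq(lambda a: float(np.mean(expit(a + scores))) - target, lo, hi)


def generate_trial(config: TrialConfig, tariff: UtilityTariff | None = None) -> TrialDataset:
    """Generate a deterministic synthetic trial dataset for ``config``."""
    if not isinstance(config, TrialConfig):
        raise ConfigError("config must be a TrialConfig")
    tariff = tariff or UtilityTariff.default_uk()
    gen_seed, miss_seed = np.random.SeedSequence(config.seed).spawn(2)
    rng = np.random.default_rng(gen_seed)
    miss_rng = np.random.default_rng(miss_seed)

    n = 2 * config.n_per_arm
    ids = [f"p{i:04d}" for i in range(1, n + 1)]

    # pairwise allocation: one patient per arm per pair, pair assigned to a
    # centre with uneven (Dirichlet) centre weights -> exact 1:1 balance
    weights = rng.dirichlet(np.full(config.n_centres, 8.0))
    pair_centres = rng.choice(config.n_centres, size=config.n_per_arm, p=weights)
    arm_idx = np.empty(n, dtype=int)
    centre = np.empty(n, dtype=int)
    for k in range(config.n_per_arm):
        first = int(rng.integers(2))
        arm_idx[2 * k] = first
        arm_idx[2 * k + 1] = 1 - first
        centre[2 * k] = centre[2 * k + 1] = pair_centres[k] + 1
    is_intervention = arm_idx == 0  # index 0 = intervention
    arm = np.where(is_intervention, ARMS[0], ARMS[1])

    age = np.clip(rng.normal(50.0, 10.0, size=n), 18.0, 89.0)
    pfmt = (rng.random(n) < 0.35).astype(int)
    ui_type = rng.choice(["stress", "mixed"], size=n, p=[0.75, 0.25])
    surgery_received = rng.random(n) >= config.p_no_surgery
    delay = rng.gamma(
        config.surgery_delay_shape,
        config.surgery_delay_mean_days / config.surgery_delay_shape,
        size=n,
    )
    surgery_day = np.where(surgery_received, np.floor(delay), np.nan)

    mean_b = np.where(is_intervention, *config.baseline_utility_mean[:2])
    sd_b = np.where(is_intervention, *config.baseline_utility_sd[:2])
    latent_base = np.clip(rng.normal(mean_b, sd_b), -0.4, 1.0)

    states, ladder_u, midpoints = _state_ladder(tariff)

    # latent utilities per EQ-5D time point (baseline first)
    latent = {"baseline": latent_base}
    for tp in EQ5D_TIMEPOINTS[1:]:
        noise = rng.normal(0.0, config.utility_noise_sd, size=n)
        shift = np.where(is_intervention, config.true_utility_effect, 0.0)
        latent[tp] = np.clip(latent_base + shift + noise, -0.5, 1.0)

    eq5d_rows = []
    observed_baseline_u = np.empty(n)
    for tp in EQ5D_TIMEPOINTS:
        idx = _latent_to_state(latent[tp], midpoints)
        for j in range(n):
            state = states[idx[j]]
            structural_missing = tp in ("4w", "3m") and not surgery_received[j]
            row = {"patient_id": ids[j], "timepoint": tp}
            for dim, level in zip(EQ5D_DIMENSIONS, state):
                row[dim] = np.nan if structural_missing else float(level)
            eq5d_rows.append(row)
            if tp == "baseline":
                observed_baseline_u[j] = ladder_u[idx[j]]

    # condition-specific items share the latent trajectory
    iciq_rows = []
    for tp in ICIQ_TIMEPOINTS:
        u = latent[tp]
        severity = np.clip((1.0 - u) / 0.5, 0.0, 1.0)
        jitter = rng.normal(0.0, 0.25, size=(n, len(ICIQ_ITEMS)))
        levels = np.clip(np.round(1 + severity[:, None] * 3 + jitter), 1, 4)
        for j in range(n):
            structural_missing = tp == "3m" and not surgery_received[j]
            row = {"patient_id": ids[j], "timepoint": tp}
            for i, item in enumerate(ICIQ_ITEMS):
                row[item] = np.nan if structural_missing else float(levels[j, i])
            iciq_rows.append(row)

    resource_rows = []
    for period in PERIODS:
        counts = {
            item: _nb_counts(rng, mean, config.resource_dispersion, n)
            for item, mean in dict(config.resource_means).items()
        }
        for j in range(n):
            for item in RESOURCE_ITEMS:
                resource_rows.append(
                    {
                        "patient_id": ids[j],
                        "period": period,
                        "item": item,
                        "count": counts[item][j] if item in counts else 0.0,
                    }
                )

    # index surgery details; the configured cost effect flows through
    # theatre minutes at the configured conversion rate
    delta_min = config.true_cost_effect / config.cost_rate_per_theatre_minute
    iv_rows = []
    anae_types = sorted(dict(config.anaesthesia_probs))
    anae_p = np.array([dict(config.anaesthesia_probs)[t] for t in anae_types])
    anae_p = anae_p / anae_p.sum()
    for j in range(n):
        if not surgery_received[j]:
            continue
        mean_min = config.theatre_minutes_mean + (delta_min if is_intervention[j] else 0.0)
        mean_min = max(mean_min, 5.0)
        theatre = rng.gamma(config.theatre_minutes_shape, mean_min / config.theatre_minutes_shape)
        recovery = rng.gamma(
            config.recovery_minutes_shape,
            config.recovery_minutes_mean / config.recovery_minutes_shape,
        )
        anaesthesia = str(rng.choice(anae_types, p=anae_p))
        iv_rows.append(
            {
                "patient_id": ids[j],
                "theatre_minutes": round(float(theatre), 1),
                "recovery_minutes": round(float(recovery), 1),
                "device_code": ARMS[0] if is_intervention[j] else ARMS[1],
                "device_count": 1,
                "anaesthesia": anaesthesia,
                "anaesthetist_present": anaesthesia in ANAESTHETIST_TYPES,
                "n_nurses_band5": 2,
                "n_nurses_band4": 1,
                "stay_days": float(_nb_counts(rng, 0.6, 1.0, 1)[0]),
                "catheter": int(rng.random() < 0.5),
                "return_to_theatre": int(rng.random() < 0.02),
            }
        )

    patients = pd.DataFrame(
        {
            "arm": arm,
            "centre": centre,
            "age": age,
            "pfmt": pfmt,
            "baseline_ui_type": ui_type,
            "surgery_received": surgery_received,
            "surgery_day": surgery_day,
        },
        index=pd.Index(ids, name="patient_id"),
    )
    # canonical row order (patient, schedule position) shared with read_dataset
    eq5d = _order_timepoint_frame(pd.DataFrame(eq5d_rows), EQ5D_TIMEPOINTS)
    iciq = _order_timepoint_frame(pd.DataFrame(iciq_rows), ICIQ_TIMEPOINTS)
    resource_use = pd.DataFrame(resource_rows)
    resource_use["__period"] = pd.Categorical(
        resource_use["period"], categories=PERIODS, ordered=True
    )
    resource_use["__item"] = pd.Categorical(
        resource_use["item"], categories=RESOURCE_ITEMS, ordered=True
    )
    resource_use = (
        resource_use.sort_values(["patient_id", "__period", "__item"], kind="mergesort")
        .drop(columns=["__period", "__item"])
        .reset_index(drop=True)
    )
    intervention = pd.DataFrame(
        iv_rows,
        columns=[
            "patient_id", "theatre_minutes", "recovery_minutes", "device_code",
            "device_count", "anaesthesia", "anaesthetist_present",
            "n_nurses_band5", "n_nurses_band4", "stay_days", "catheter",
            "return_to_theatre",
        ],
    )

    # MAR missingness: logistic in observed covariates only, with intercepts
    # calibrated so the realised fraction per time point follows the ramp
    target = config.target_missing_fraction
    if target > 0:
        coefs = dict(config.missingness_coefficients)
        z_age = (age - age.mean()) / age.std()
        scores = (
            coefs.get("age", 0.0) * z_age
            + coefs.get("baseline_utility", 0.0) * observed_baseline_u
            + coefs.get("arm", 0.0) * is_intervention.astype(float)
        )
        ramp = dict(config.missing_ramp)
        # Gaussian-copula patient effect: non-response clusters within
        # patients (monotone-ish, not enforced) while each questionnaire's
        # marginal missingness stays exactly the calibrated logistic rate
        # and depends only on observed covariates (MAR).
        rho = config.missing_within_patient_corr
        z_patient = miss_rng.standard_normal(n)

        def missing_mask(tp: str) -> np.ndarray:
            frac = target * ramp.get(tp, 1.0)
            if frac <= 0:
                return np.zeros(n, dtype=bool)
            a = _calibrate_intercept(scores, frac)
            noise = miss_rng.standard_normal(n)
            v = norm_cdf(np.sqrt(rho) * z_patient + np.sqrt(1.0 - rho) * noise)
            return v < expit(a + scores)

        for tp in EQ5D_TIMEPOINTS[1:]:
            mask = missing_mask(tp)
            sel = eq5d["timepoint"] == tp
            miss_ids = [ids[j] for j in range(n) if mask[j]]
            eq5d.loc[sel & eq5d["patient_id"].isin(miss_ids), list(EQ5D_DIMENSIONS)] = np.nan
        for tp in ICIQ_TIMEPOINTS[1:]:
            mask = missing_mask(tp)
            sel = iciq["timepoint"] == tp
            miss_ids = [ids[j] for j in range(n) if mask[j]]
            iciq.loc[sel & iciq["patient_id"].isin(miss_ids), list(ICIQ_ITEMS)] = np.nan
        for period in PERIODS:
            mask = missing_mask(period)
            sel = resource_use["period"] == period
            miss_ids = [ids[j] for j in range(n) if mask[j]]
            resource_use.loc[
                sel & resource_use["patient_id"].isin(miss_ids), "count"
            ] = np.nan

    latent_frame = pd.DataFrame(latent, index=pd.Index(ids, name="patient_id"))
    dataset = TrialDataset(
        patients=patients,
        eq5d=eq5d,
        iciq=iciq,
        resource_use=resource_use,
        intervention=intervention,
        config=config.as_dict(),
        latent=latent_frame,
    )
    dataset.validate()
    return dataset


# ---------------------------------------------------------------------------
# serialisation: one long CSV (patient, time point, field, value) + JSON
# sidecar holding the generating config
# ---------------------------------------------------------------------------

_STATIC_FIELDS = (
    "arm", "centre", "age", "pfmt", "baseline_ui_type", "surgery_received",
    "surgery_day",
)
_IV_FIELDS = (
    "theatre_minutes", "recovery_minutes", "device_code", "device_count",
    "anaesthesia", "anaesthetist_present", "n_nurses_band5", "n_nurses_band4",
    "stay_days", "catheter", "return_to_theatre",
)


def _format_value(value) -> str:
    if isinstance(value, (bool, np.bool_)):
        return "1" if value else "0"
    if isinstance(value, (int, np.integer)):
        return str(int(value))
    if isinstance(value, (float, np.floating)):
        return repr(float(value))
    return str(value)


def sidecar_path(path) -> Path:
    path = Path(path)
    return path.with_suffix(path.suffix + ".json")


def write_dataset(dataset: TrialDataset, path) -> None:
    """Write a dataset as a long CSV plus a JSON config sidecar."""
    dataset.validate()
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rows = []
    for pid, row in dataset.patients.iterrows():
        for fld in _STATIC_FIELDS:
            value = row[fld]
            if isinstance(value, float) and math.isnan(value):
                continue
            rows.append((pid, "", fld, _format_value(value)))
    for _, row in dataset.intervention.iterrows():
        for fld in _IV_FIELDS:
            rows.append((row["patient_id"], "", f"iv_{fld}", _format_value(row[fld])))
    for _, row in dataset.eq5d.iterrows():
        for dim in EQ5D_DIMENSIONS:
            if not math.isnan(row[dim]):
                rows.append(
                    (row["patient_id"], row["timepoint"], f"eq5d_{dim}",
                     str(int(row[dim])))
                )
    for _, row in dataset.iciq.iterrows():
        for item in ICIQ_ITEMS:
            if not math.isnan(row[item]):
                rows.append(
                    (row["patient_id"], row["timepoint"], f"iciq_{item}",
                     str(int(row[item])))
                )
    for _, row in dataset.resource_use.iterrows():
        if not math.isnan(row["count"]):
            rows.append(
                (row["patient_id"], row["period"], f"resource_{row['item']}",
                 _format_value(row["count"]))
            )
    frame = pd.DataFrame(rows, columns=["patient_id", "timepoint", "field", "value"])
    frame = frame.sort_values(
        ["patient_id", "timepoint", "field"], kind="mergesort"
    ).reset_index(drop=True)
    frame.to_csv(path, index=False)
    with open(sidecar_path(path), "w") as fh:
        json.dump(dataset.config, fh, sort_keys=True, indent=1)
        fh.write("\n")


def _parse_static(pid, fld, raw, row_no):
    try:
        if fld == "arm":
            if raw not in ARMS:
                raise ValueError(f"arm must be one of {ARMS}")
            return raw
        if fld == "centre":
            return int(raw)
        if fld in ("age", "surgery_day"):
            value = float(raw)
            if fld == "surgery_day" and value < 0:
                raise ValueError("surgery_day must be >= 0")
            return value
        if fld == "pfmt":
            return int(raw)
        if fld == "surgery_received":
            return bool(int(raw))
        return raw
    except ValueError as exc:
        raise DatasetValidationError(str(exc), row=row_no, column=fld) from None


def read_dataset(path) -> TrialDataset:
    """Read a dataset written by :func:`write_dataset`, validating the schema.

    Violations (unknown fields, out-of-range item levels, negative counts)
    raise :class:`DatasetValidationError` with the offending CSV row and
    column.
    """
    path = Path(path)
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    expected_cols = ["patient_id", "timepoint", "field", "value"]
    if list(frame.columns) != expected_cols:
        raise DatasetValidationError(
            f"expected columns {expected_cols}, got {list(frame.columns)}"
        )
    side = sidecar_path(path)
    config = None
    if side.exists():
        with open(side) as fh:
            config = json.load(fh)

    pids = list(dict.fromkeys(frame["patient_id"]))
    static: dict[str, dict] = {pid: {} for pid in pids}
    iv: dict[str, dict] = {}
    eq5d_grid = {
        (pid, tp): {dim: np.nan for dim in EQ5D_DIMENSIONS}
        for pid in pids
        for tp in EQ5D_TIMEPOINTS
    }
    iciq_grid = {
        (pid, tp): {item: np.nan for item in ICIQ_ITEMS}
        for pid in pids
        for tp in ICIQ_TIMEPOINTS
    }
    resource_grid = {
        (pid, period, item): np.nan
        for pid in pids
        for period in PERIODS
        for item in RESOURCE_ITEMS
    }

    for i, rec in enumerate(frame.itertuples(index=False)):
        row_no = i + 2  # 1-based with header
        pid, tp, fld, raw = rec.patient_id, rec.timepoint, rec.field, rec.value
        if fld in _STATIC_FIELDS:
            static[pid][fld] = _parse_static(pid, fld, raw, row_no)
        elif fld.startswith("iv_"):
            name = fld[3:]
            if name not in _IV_FIELDS:
                raise DatasetValidationError(
                    f"unknown intervention field {name!r}", row=row_no, column=fld
                )
            entry = iv.setdefault(pid, {"patient_id": pid})
            if name in ("device_code", "anaesthesia"):
                entry[name] = raw
            elif name in ("theatre_minutes", "recovery_minutes", "stay_days"):
                value = float(raw)
                if value < 0:
                    raise DatasetValidationError(
                        f"{name} must be >= 0", row=row_no, column=fld
                    )
                entry[name] = value
            elif name == "anaesthetist_present":
                entry[name] = bool(int(raw))
            else:
                entry[name] = int(raw)
        elif fld.startswith("eq5d_"):
            dim = fld[5:]
            if dim not in EQ5D_DIMENSIONS or tp not in EQ5D_TIMEPOINTS:
                raise DatasetValidationError(
                    f"unknown EQ-5D field/time point", row=row_no, column=fld
                )
            level = float(raw)
            if level not in (1.0, 2.0, 3.0):
                raise DatasetValidationError(
                    "EQ-5D item level outside {1,2,3}", row=row_no, column=fld
                )
            eq5d_grid[(pid, tp)][dim] = level
        elif fld.startswith("iciq_"):
            item = fld[5:]
            if item not in ICIQ_ITEMS or tp not in ICIQ_TIMEPOINTS:
                raise DatasetValidationError(
                    "unknown ICIQ field/time point", row=row_no, column=fld
                )
            level = float(raw)
            if level not in (1.0, 2.0, 3.0, 4.0):
                raise DatasetValidationError(
                    "ICIQ item level outside {1,...,4}", row=row_no, column=fld
                )
            iciq_grid[(pid, tp)][item] = level
        elif fld.startswith("resource_"):
            item = fld[9:]
            if item not in RESOURCE_ITEMS or tp not in PERIODS:
                raise DatasetValidationError(
                    "unknown resource field/period", row=row_no, column=fld
                )
            count = float(raw)
            if count < 0:
                raise DatasetValidationError(
                    "resource counts must be >= 0", row=row_no, column=fld
                )
            resource_grid[(pid, tp, item)] = count
        else:
            raise DatasetValidationError(
                f"unknown field {fld!r}", row=row_no, column=fld
            )

    patients = pd.DataFrame(
        [
            {fld: static[pid].get(fld, np.nan) for fld in _STATIC_FIELDS}
            for pid in pids
        ],
        index=pd.Index(pids, name="patient_id"),
    )
    patients["centre"] = patients["centre"].astype(int)
    patients["pfmt"] = patients["pfmt"].astype(int)
    patients["surgery_received"] = patients["surgery_received"].astype(bool)
    patients["age"] = patients["age"].astype(float)
    patients["surgery_day"] = patients["surgery_day"].astype(float)

    eq5d = pd.DataFrame(
        [
            {"patient_id": pid, "timepoint": tp, **eq5d_grid[(pid, tp)]}
            for pid in pids
            for tp in EQ5D_TIMEPOINTS
        ]
    )
    iciq = pd.DataFrame(
        [
            {"patient_id": pid, "timepoint": tp, **iciq_grid[(pid, tp)]}
            for pid in pids
            for tp in ICIQ_TIMEPOINTS
        ]
    )
    resource_use = pd.DataFrame(
        [
            {
                "patient_id": pid,
                "period": period,
                "item": item,
                "count": resource_grid[(pid, period, item)],
            }
            for pid in pids
            for period in PERIODS
            for item in RESOURCE_ITEMS
        ]
    )
    intervention = pd.DataFrame(
        [iv[pid] for pid in pids if pid in iv],
        columns=["patient_id", *_IV_FIELDS],
    )
    if len(intervention):
        intervention["anaesthetist_present"] = intervention[
            "anaesthetist_present"
        ].astype(bool)

    dataset = TrialDataset(
        patients=patients,
        eq5d=eq5d,
        iciq=iciq,
        resource_use=resource_use,
        intervention=intervention,
        config=config,
    )
    dataset.validate()
    return dataset
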