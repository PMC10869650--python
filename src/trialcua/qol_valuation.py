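"""Utility valuation and discounted QALY area-under-the-curve.

Questionnaire responses are valued with an additive tariff (a value set):
the full-health state scores exactly 1.0 and every departure from full
health subtracts non-negative decrements.  Valued utilities at scheduled
time points form a piecewise-linear trajectory over days since
randomisation; QALYs are the area under that curve, with QALYs accrued in
year two and three down-weighted by annual discount factors.  Patients wait
for surgery after randomisation, so by default the utility is held flat at
the baseline value until the day of surgery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, DatasetValidationError, TrajectoryError
from .schedule import (
    DAYS_PER_MONTH,
    DAYS_PER_YEAR,
    YEAR_BOUNDARIES,
)

EQ5D_DIMENSIONS = (
    "mobility",
    "self_care",
    "usual_activities",
    "pain_discomfort",
    "anxiety_depression",
)


def _read_coefficient_csv(path_or_buf) -> pd.DataFrame:
    frame = pd.read_csv(path_or_buf, dtype={"term": str, "decrement": float})
    required = {"term", "level", "decrement"}
    if not required.issubset(frame.columns):
        raise ConfigError(
            f"coefficient table needs columns {sorted(required)}, got {list(frame.columns)}"
        )
    return frame


@dataclass(frozen=True)
class UtilityTariff:
    """Additive EQ-5D-3L value set.

    ``value(levels)`` computes::

        1 - any_dysfunction_constant * [any level > 1]
          - sum of per-dimension, per-level decrements
          - worst_level_constant * [any level == 3]

    Invariants enforced at construction: all decrements are non-negative,
    level-3 decrements dominate level-2 decrements (so valuation is monotone
    non-increasing in every item), and the all-ones state values to exactly
    1.0 by construction.
    """

    any_dysfunction_constant: float
    worst_level_constant: float
    decrements: Mapping[tuple[str, int], float]

    def __post_init__(self):
        if self.any_dysfunction_constant < 0 or self.worst_level_constant < 0:
            raise ConfigError("tariff constants must be non-negative")
        for (dim, level), dec in self.decrements.items():
            if dim not in EQ5D_DIMENSIONS:
                raise ConfigError(f"unknown tariff dimension {dim!r}")
            if level not in (2, 3):
                raise ConfigError(f"tariff level must be 2 or 3, got {level!r}")
            if dec < 0:
                raise ConfigError(f"negative decrement for {dim} level {level}")
        for dim in EQ5D_DIMENSIONS:
            if (dim, 2) not in self.decrements or (dim, 3) not in self.decrements:
                raise ConfigError(f"tariff missing decrements for dimension {dim!r}")
            if self.decrements[(dim, 3)] < self.decrements[(dim, 2)]:
                raise ConfigError(
                    f"tariff not monotone: {dim} level-3 decrement below level-2"
                )

    @classmethod
    def from_csv(cls, path) -> "UtilityTariff":
        frame = _read_coefficient_csv(path)
        constants = {"any_dysfunction": 0.0, "worst_level": 0.0}
        decrements: dict[tuple[str, int], float] = {}
        for _, row in frame.iterrows():
            term = row["term"]
            if term in constants:
                constants[term] = float(row["decrement"])
            else:
                decrements[(term, int(row["level"]))] = float(row["decrement"])
        return cls(
            any_dysfunction_constant=constants["any_dysfunction"],
            worst_level_constant=constants["worst_level"],
            decrements=decrements,
        )

    @classmethod
    def default_uk(cls) -> "UtilityTariff":
        """The UK general-population EQ-5D-3L value set shipped with the package."""
        ref = resources.files("trialcua.data") / "uk_eq5d3l_tariff.csv"
        with resources.as_file(ref) as path:
            return cls.from_csv(path)

    def value(self, levels: Sequence[int]) -> float:
        return value_eq5d(levels, self)


def value_eq5d(levels: Sequence[int], tariff: UtilityTariff) -> float:
    """Value a five-item EQ-5D-3L response under ``tariff``.

    Raises :class:`DatasetValidationError` when a level is outside {1, 2, 3}.
    The all-ones state returns exactly 1.0.
    """
    levels = tuple(int(v) for v in levels)
    if len(levels) != 5:
        raise DatasetValidationError(f"expected 5 item levels, got {len(levels)}")
    for dim, level in zip(EQ5D_DIMENSIONS, levels):
        if level not in (1, 2, 3):
            raise DatasetValidationError(
                f"item level must be in {{1,2,3}}", column=dim
            )
    if all(level == 1 for level in levels):
        return 1.0
    utility = 1.0 - tariff.any_dysfunction_constant
    for dim, level in zip(EQ5D_DIMENSIONS, levels):
        if level > 1:
            utility -= tariff.decrements[(dim, level)]
    if any(level == 3 for level in levels):
        utility -= tariff.worst_level_constant
    return utility


@dataclass(frozen=True)
class AdditiveMapping:
    """Additive utility mapping for a multi-item questionnaire.

    Same shape as :class:`UtilityTariff` but with a configurable item list
    and level range; used for the condition-specific instrument, whose
    published scoring algorithm is supplied as configuration.
    """

    decrements: Mapping[tuple[str, int], float]
    max_value: float = 1.0

    def __post_init__(self):
        for (item, level), dec in self.decrements.items():
            if dec < 0:
                raise ConfigError(f"negative decrement for {item} level {level}")

    @property
    def items(self) -> tuple[str, ...]:
        return tuple(sorted({item for item, _ in self.decrements}))

    def levels_for(self, item: str) -> tuple[int, ...]:
        return tuple(sorted(level for it, level in self.decrements if it == item))

    @classmethod
    def from_csv(cls, path, max_value: float = 1.0) -> "AdditiveMapping":
        frame = _read_coefficient_csv(path)
        decrements = {
            (row["term"], int(row["level"])): float(row["decrement"])
            for _, row in frame.iterrows()
        }
        return cls(decrements=decrements, max_value=max_value)

    @classmethod
    def default_iciq(cls) -> "AdditiveMapping":
        ref = resources.files("trialcua.data") / "iciq_mapping_default.csv"
        with resources.as_file(ref) as path:
            return cls.from_csv(path)

    def value(self, responses) -> float:
        return value_iciq(responses, self)


def value_iciq(responses, mapping: AdditiveMapping) -> float:
    """Value a condition-specific questionnaire response.

    ``responses`` maps item name to level (or is a sequence aligned with
    ``mapping.items``).  A missing required item yields ``nan`` — the value
    is treated as missing and left to multiple imputation, not raised.
    """
    if not isinstance(responses, Mapping):
        responses = dict(zip(mapping.items, responses))
    utility = mapping.max_value
    for item in mapping.items:
        level = responses.get(item)
        if level is None or (isinstance(level, float) and math.isnan(level)):
            return float("nan")
        level = int(level)
        if level < 1 or level > max(mapping.levels_for(item)):
            raise DatasetValidationError("item level out of range", column=item)
        if level > 1:
            utility -= mapping.decrements[(item, level)]
    return utility


@dataclass(frozen=True)
class QalyOptions:
    """Conventions for the QALY area-under-the-curve."""

    discount_rate: float = 0.035
    adjust_for_surgery_wait: bool = True
    horizon_months: int = 36
    interpolation: str = "linear"

    def __post_init__(self):
        if self.discount_rate < 0:
            raise ConfigError("discount_rate must be >= 0")
        if self.horizon_months <= 0:
            raise ConfigError("horizon_months must be > 0")
        if self.interpolation != "linear":
            raise ConfigError("only linear interpolation is supported")

    @property
    def horizon_days(self) -> float:
        return self.horizon_months * DAYS_PER_MONTH


@dataclass(frozen=True)
class UtilityTrajectory:
    """Utility values at days since randomisation for one patient."""

    patient_id: object
    times: tuple[float, ...]
    utilities: tuple[float, ...]
    surgery_day: float | None = None

    def __post_init__(self):
        if len(self.times) != len(self.utilities):
            raise TrajectoryError("times and utilities differ in length")
        for t0, t1 in zip(self.times, self.times[1:]):
            if not t1 > t0:
                raise TrajectoryError("times must be strictly increasing")
        if self.surgery_day is not None and self.surgery_day < 0:
            raise TrajectoryError("surgery_day must be >= 0")


def _year_factor(day: float, rate: float) -> float:
    # 1-based accrual year for a day inside the horizon
    year = 1 + sum(day >= b for b in YEAR_BOUNDARIES)
    return (1.0 + rate) ** -(year - 1)


def qaly_auc(trajectory: UtilityTrajectory, options: QalyOptions = QalyOptions()) -> float:
    """Discounted QALYs (years) for a piecewise-linear utility trajectory.

    Linear interpolation between non-missing points; QALYs accrued in the
    second and third year are multiplied by ``(1+r)^-1`` and ``(1+r)^-2``.
    With ``adjust_for_surgery_wait`` on and a surgery day present, utility
    is held flat at the first observed (baseline) value until surgery.

    Returns ``nan`` when the last non-missing observation precedes the
    horizon (the trajectory is never extrapolated; the QALY stays missing
    and is handled upstream by imputation).  Raises
    :class:`TrajectoryError` when fewer than two points are observed.
    """
    points = [
        (float(t), min(float(u), 1.0))
        for t, u in zip(trajectory.times, trajectory.utilities)
        if u is not None and not (isinstance(u, float) and math.isnan(u))
    ]
    if not points:
        raise TrajectoryError("cannot compute; impute first")
    if len(points) < 2:
        raise TrajectoryError("need at least two non-missing points; impute first")
    if points[0][0] < 0:
        raise TrajectoryError("times must be >= 0")

    horizon = options.horizon_days
    if points[-1][0] < horizon - 1e-9:
        return float("nan")

    if options.adjust_for_surgery_wait and trajectory.surgery_day is not None:
        t0, u0 = points[0]
        sd = float(trajectory.surgery_day)
        if sd > t0:
            tail = [(t, u) for t, u in points[1:] if t > sd]
            points = [(t0, u0), (sd, u0)] + tail

    rate = options.discount_rate
    cuts = sorted(b for b in YEAR_BOUNDARIES if b < horizon)
    area = 0.0
    for (t0, u0), (t1, u1) in zip(points, points[1:]):
        lo, hi = max(t0, 0.0), min(t1, horizon)
        if hi <= lo:
            continue
        breaks = [lo] + [c for c in cuts if lo < c < hi] + [hi]
        slope = (u1 - u0) / (t1 - t0)
        for a, b in zip(breaks, breaks[1:]):
            ua = u0 + slope * (a - t0)
            ub = u0 + slope * (b - t0)
            factor = _year_factor(0.5 * (a + b), rate)
            area += factor * 0.5 * (ua + ub) * (b - a)
    return area / DAYS_PER_YEAR


def full_health_days(qaly: float) -> float:
    """Express a QALY quantity as equivalent days lived in full health."""
    return qaly * DAYS_PER_YEAR
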