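"""Per-patient costing: component micro-costing of the index intervention,
primary/secondary follow-up costs per period, and annual discounting.

Ledger arithmetic is exact decimal at pence precision; model estimation
downstream works in floating point.  The unit-cost table shipped with the
package is a plausible toy table for testing — real analyses must supply
their own prices.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from typing import Mapping

import pandas as pd

from .errors import ConfigError, DatasetValidationError, UnknownResourceError
from .schedule import PERIOD_DISCOUNT_YEAR, PERIODS, discount_factor

PENNY = Decimal("0.01")

#: follow-up resource items grouped by care sector
SECTOR_BY_ITEM = {
    "gp_visit": "primary",
    "nurse_visit": "primary",
    "physio_visit": "primary",
    "district_nurse_visit": "primary",
    "outpatient_visit": "secondary",
    "inpatient_day": "secondary",
    "continence_procedure": "secondary",
    "ae_admission": "secondary",
}

#: anaesthesia types with an anaesthetist in theatre
ANAESTHETIST_TYPES = frozenset({"general", "spinal", "la_iv"})
ANAESTHESIA_TYPES = ("general", "spinal", "la_iv", "la_oral", "la")


def money(value) -> Decimal:
    """Quantize to pence, half-up."""
    if isinstance(value, Decimal):
        return value.quantize(PENNY, rounding=ROUND_HALF_UP)
    return Decimal(repr(float(value))).quantize(PENNY, rounding=ROUND_HALF_UP)


def _is_missing(value) -> bool:
    return value is None or (isinstance(value, float) and math.isnan(value))


class UnitCostTable:
    """Resource item -> unit price (with unit and source labels)."""

    def __init__(self, prices: Mapping[str, object], units=None, sources=None):
        self._prices = {}
        for item, price in prices.items():
            price = Decimal(str(price))
            if price < 0:
                raise ConfigError(f"negative unit price for {item!r}")
            self._prices[str(item)] = price
        self.units = dict(units or {})
        self.sources = dict(sources or {})

    def __contains__(self, item) -> bool:
        return item in self._prices

    def __iter__(self):
        return iter(self._prices)

    def price(self, item: str) -> Decimal:
        try:
            return self._prices[item]
        except KeyError:
            raise UnknownResourceError(item) from None

    @classmethod
    def from_csv(cls, path) -> "UnitCostTable":
        frame = pd.read_csv(path, dtype={"item": str})
        for col in ("item", "price"):
            if col not in frame.columns:
                raise ConfigError(f"unit-cost table missing column {col!r}")
        return cls(
            prices=dict(zip(frame["item"], frame["price"].astype(str))),
            units=dict(zip(frame["item"], frame.get("unit", ""))),
            sources=dict(zip(frame["item"], frame.get("source", ""))),
        )

    @classmethod
    def toy_default(cls) -> "UnitCostTable":
        """Toy table shipped for testing; not the trial's actual prices."""
        ref = resources.files("trialcua.data") / "unit_costs_toy.csv"
        with resources.as_file(ref) as path:
            return cls.from_csv(path)

    def to_csv(self, path) -> None:
        rows = [
            {
                "item": item,
                "unit": self.units.get(item, ""),
                "price": str(price),
                "source": self.sources.get(item, ""),
            }
            for item, price in self._prices.items()
        ]
        pd.DataFrame(rows).to_csv(path, index=False)


def cost_intervention(record: Mapping, unit_costs: UnitCostTable) -> Decimal:
    """Component cost of the index surgery for one patient.

    ``record`` carries theatre/recovery minutes, device code and count,
    anaesthesia type, anaesthetist presence, nurse staffing (default two
    band-five and one band-four), length of stay, catheterisation and a
    return-to-theatre flag.  Each component is quantity x unit price;
    absent components contribute zero.
    """
    total = Decimal("0")
    minutes = float(record.get("theatre_minutes", 0) or 0)
    if minutes < 0:
        raise DatasetValidationError("theatre_minutes must be >= 0")
    if minutes > 0:
        per_min = unit_costs.price("staff_surgeon_per_min")
        per_min += int(record.get("n_nurses_band5", 2)) * unit_costs.price(
            "staff_nurse_band5_per_min"
        )
        per_min += int(record.get("n_nurses_band4", 1)) * unit_costs.price(
            "staff_nurse_band4_per_min"
        )
        if record.get("anaesthetist_present"):
            per_min += unit_costs.price("staff_anaesthetist_per_min")
        per_min += unit_costs.price("theatre_per_min")
        total += Decimal(repr(minutes)) * per_min
    recovery = float(record.get("recovery_minutes", 0) or 0)
    if recovery < 0:
        raise DatasetValidationError("recovery_minutes must be >= 0")
    if recovery > 0:
        total += Decimal(repr(recovery)) * unit_costs.price("recovery_per_min")
    device = record.get("device_code")
    if device and not _is_missing(device):
        count = int(record.get("device_count", 1) or 1)
        total += count * unit_costs.price(f"device_{device}")
    anaesthesia = record.get("anaesthesia")
    if anaesthesia and not _is_missing(anaesthesia):
        total += unit_costs.price(f"anaesthesia_{anaesthesia}")
    stay = float(record.get("stay_days", 0) or 0)
    if stay < 0:
        raise DatasetValidationError("stay_days must be >= 0")
    if stay > 0:
        total += Decimal(repr(stay)) * unit_costs.price("inpatient_day")
    if record.get("catheter"):
        total += unit_costs.price("catheter")
    if record.get("return_to_theatre"):
        total += unit_costs.price("return_to_theatre")
    return money(total)


def cost_followup(
    counts: Mapping[str, float],
    unit_costs: UnitCostTable,
    period: str,
    sector_by_item: Mapping[str, str] = SECTOR_BY_ITEM,
):
    """Primary and secondary care cost for one patient-period.

    ``counts`` maps resource item to a count; a count of zero is the
    stated zero-fill for a 'no' answer, while ``nan`` marks an unanswered
    item and leaves the whole sector missing (``None``) for imputation.
    """
    if period not in PERIODS:
        raise ConfigError(f"period must be one of {PERIODS}, got {period!r}")
    totals = {"primary": Decimal("0"), "secondary": Decimal("0")}
    missing = {"primary": False, "secondary": False}
    for item, count in counts.items():
        try:
            sector = sector_by_item[item]
        except KeyError:
            raise UnknownResourceError(item) from None
        if _is_missing(count):
            missing[sector] = True
            continue
        count = float(count)
        if count < 0:
            raise DatasetValidationError(
                f"negative resource count for {item!r}", column=item
            )
        if count > 0:
            totals[sector] += Decimal(repr(count)) * unit_costs.price(item)
    primary = None if missing["primary"] else money(totals["primary"])
    secondary = None if missing["secondary"] else money(totals["secondary"])
    return primary, secondary


_LEDGER_COST_COLUMNS = ["intervention"] + [
    f"{sector}_{period}" for period in PERIODS for sector in ("primary", "secondary")
]


@dataclass
class CostLedger:
    """Per-patient intervention and per-period follow-up costs.

    Backed by a frame indexed by patient id with Decimal cost columns
    (``None`` marks missing), plus ``surgery_received`` and
    ``followup_crf_any`` flags used by the zero-cost rule.
    """

    frame: pd.DataFrame

    COST_COLUMNS = tuple(_LEDGER_COST_COLUMNS)

    def __post_init__(self):
        needed = set(self.COST_COLUMNS) | {"surgery_received", "followup_crf_any"}
        missing = needed - set(self.frame.columns)
        if missing:
            raise ConfigError(f"ledger frame missing columns {sorted(missing)}")

    def copy(self) -> "CostLedger":
        return CostLedger(self.frame.copy())

    def component_total(self) -> pd.Series:
        """Undiscounted grand total (None propagates from any component)."""
        return self.frame.apply(_row_total, axis=1, rate=0.0)

    def to_csv(self, path) -> None:
        out = self.frame.copy()
        out.to_csv(path, index_label="patient_id")


def _row_total(row, rate: float):
    total = Decimal("0")
    value = row["intervention"]
    if _is_missing(value):
        return None
    total += money(value)
    for period in PERIODS:
        factor = discount_factor(PERIOD_DISCOUNT_YEAR[period], rate)
        for sector in ("primary", "secondary"):
            value = row[f"{sector}_{period}"]
            if _is_missing(value):
                return None
            total += money(Decimal(str(value)) * Decimal(repr(factor)))
    return total


def total_discounted_cost(ledger: CostLedger, rate: float) -> pd.Series:
    """Total cost per patient with 24- and 36-month period costs discounted.

    Intervention, 3- and 15-month costs are undiscounted (year 1); the
    24-month period carries ``(1+r)^-1`` and the 36-month period
    ``(1+r)^-2``.  Each discounted component is quantized to pence before
    summing.  A missing component makes the total missing (``None``).
    """
    if rate < 0:
        raise ConfigError("discount rate must be >= 0")
    return ledger.frame.apply(_row_total, axis=1, rate=rate)


def apply_no_surgery_cost_rule(ledger: CostLedger, relax: bool = False) -> CostLedger:
    """Zero-cost rule for patients who had no surgery and returned no CRF.

    Default: their secondary-care period costs are set to zero.  With
    ``relax`` on (sensitivity analysis), they are set missing instead and
    left to imputation.  Patients who had surgery, or who returned any
    follow-up CRF, are untouched.
    """
    out = ledger.copy()
    mask = (~out.frame["surgery_received"].astype(bool)) & (
        ~out.frame["followup_crf_any"].astype(bool)
    )
    fill = None if relax else Decimal("0.00")
    for period in PERIODS:
        col = f"secondary_{period}"
        out.frame[col] = out.frame[col].astype(object)
        out.frame.loc[mask, col] = fill
    return out
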