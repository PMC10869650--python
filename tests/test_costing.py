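"""Costing unit tests: micro-costing arithmetic, zero-fill rules, discounting."""

from decimal import Decimal

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st_

from trialcua import (
    ConfigError,
    CostLedger,
    DatasetValidationError,
    UnitCostTable,
    UnknownResourceError,
    apply_no_surgery_cost_rule,
    cost_followup,
    cost_intervention,
    total_discounted_cost,
)


@pytest.fixture()
def toy_table():
    return UnitCostTable(
        {
            "staff_surgeon_per_min": 10,
            "staff_nurse_band5_per_min": 0,
            "staff_nurse_band4_per_min": 0,
            "staff_anaesthetist_per_min": 0,
            "theatre_per_min": 0,
            "recovery_per_min": 0,
            "device_x": 100,
            "gp_visit": 30,
            "outpatient_visit": 120,
        }
    )


def make_ledger(**overrides):
    row = {
        "intervention": Decimal("0"),
        "surgery_received": True,
        "followup_crf_any": True,
    }
    for period in ("3m", "15m", "24m", "36m"):
        row[f"primary_{period}"] = Decimal("0")
        row[f"secondary_{period}"] = Decimal("0")
    row.update(overrides)
    frame = pd.DataFrame([row], index=pd.Index(["p1"], name="patient_id"))
    return CostLedger(frame)


class TestInterventionCosting:
    def test_empty_component_sum_is_zero(self, toy_table):
        assert cost_intervention({}, toy_table) == Decimal("0.00")

    def test_toy_hand_arithmetic(self, toy_table):
        record = {"theatre_minutes": 30, "device_code": "x"}
        assert cost_intervention(record, toy_table) == Decimal("400.00")

    def test_deterministic(self, toy_table):
        record = {"theatre_minutes": 17.5, "device_code": "x", "recovery_minutes": 5}
        assert cost_intervention(record, toy_table) == cost_intervention(
            dict(record), toy_table
        )

    def test_unknown_device_names_the_code(self, toy_table):
        with pytest.raises(UnknownResourceError, match="device_zzz"):
            cost_intervention({"device_code": "zzz"}, toy_table)

    def test_anaesthetist_rate_only_when_present(self):
        table = UnitCostTable(
            {
                "staff_surgeon_per_min": 1,
                "staff_nurse_band5_per_min": 0,
                "staff_nurse_band4_per_min": 0,
                "staff_anaesthetist_per_min": 2,
                "theatre_per_min": 0,
            }
        )
        without = cost_intervention({"theatre_minutes": 10}, table)
        with_ = cost_intervention(
            {"theatre_minutes": 10, "anaesthetist_present": True}, table
        )
        assert with_ - without == Decimal("20.00")

    def test_negative_time_rejected(self, toy_table):
        with pytest.raises(DatasetValidationError):
            cost_intervention({"theatre_minutes": -1}, toy_table)


class TestFollowupCosting:
    def test_all_no_answers_zero_fill(self, toy_table):
        primary, secondary = cost_followup(
            {"gp_visit": 0, "outpatient_visit": 0}, toy_table, "15m"
        )
        assert primary == Decimal("0.00") and secondary == Decimal("0.00")

    def test_hand_arithmetic(self, toy_table):
        primary, secondary = cost_followup(
            {"gp_visit": 2, "outpatient_visit": 1}, toy_table, "3m"
        )
        assert primary == Decimal("60.00")
        assert secondary == Decimal("120.00")

    def test_missing_marked_missing_not_zero(self, toy_table):
        primary, secondary = cost_followup(
            {"gp_visit": float("nan"), "outpatient_visit": float("nan")},
            toy_table,
            "24m",
        )
        assert primary is None and secondary is None

    def test_negative_count_rejected(self, toy_table):
        with pytest.raises(DatasetValidationError):
            cost_followup({"gp_visit": -2}, toy_table, "3m")

    def test_bad_period_rejected(self, toy_table):
        with pytest.raises(ConfigError):
            cost_followup({"gp_visit": 1}, toy_table, "12m")


class TestDiscounting:
    def test_zero_rate_plain_sum(self):
        ledger = make_ledger(
            intervention=Decimal("100"),
            secondary_24m=Decimal("50"),
            secondary_36m=Decimal("50"),
        )
        assert total_discounted_cost(ledger, 0.0).iloc[0] == Decimal("200.00")

    def test_closed_form_oracle(self):
        ledger = make_ledger(
            secondary_24m=Decimal("100"), secondary_36m=Decimal("100")
        )
        assert total_discounted_cost(ledger, 0.035).iloc[0] == Decimal("189.97")

    def test_six_percent_passthrough(self):
        ledger = make_ledger(
            secondary_24m=Decimal("100"), secondary_36m=Decimal("100")
        )
        expected = Decimal("94.34") + Decimal("89.00")  # 100/1.06, 100/1.06^2 to pence
        assert total_discounted_cost(ledger, 0.06).iloc[0] == expected

    def test_15_month_period_not_discounted(self):
        ledger = make_ledger(primary_15m=Decimal("100"))
        assert total_discounted_cost(ledger, 0.035).iloc[0] == Decimal("100.00")

    def test_missing_component_propagates(self):
        ledger = make_ledger(secondary_24m=None)
        assert total_discounted_cost(ledger, 0.035).iloc[0] is None

    @given(
        amounts=st_.lists(
            st_.decimals(min_value=0, max_value=10_000, places=2), min_size=9, max_size=9
        ),
        rate=st_.sampled_from([0.0, 0.015, 0.035, 0.06]),
    )
    @settings(max_examples=50, deadline=None)
    def test_additivity_and_rate_monotonicity(self, amounts, rate):
        cols = ["intervention"] + [
            f"{s}_{p}" for p in ("3m", "15m", "24m", "36m") for s in ("primary", "secondary")
        ]
        ledger = make_ledger(**dict(zip(cols, map(Decimal, map(str, amounts)))))
        total = total_discounted_cost(ledger, rate).iloc[0]
        # additivity: equals the independently discounted component sum
        factors = {"3m": 0, "15m": 0, "24m": 1, "36m": 2}
        expected = Decimal(str(amounts[0])).quantize(Decimal("0.01"))
        for i, col in enumerate(cols[1:], start=1):
            period = col.split("_", 1)[1]
            factor = Decimal(repr((1 + rate) ** -factors[period]))
            expected += (Decimal(str(amounts[i])) * factor).quantize(Decimal("0.01"))
        assert total == expected
        # discounted total never exceeds the undiscounted one
        assert total <= total_discounted_cost(ledger, 0.0).iloc[0]


class TestNoSurgeryRule:
    def patient(self, surgery, crf):
        return make_ledger(
            surgery_received=surgery,
            followup_crf_any=crf,
            secondary_15m=None,
            secondary_24m=None,
        )

    def test_default_sets_secondary_to_zero(self):
        out = apply_no_surgery_cost_rule(self.patient(False, False), relax=False)
        assert out.frame["secondary_15m"].iloc[0] == Decimal("0.00")
        assert out.frame["secondary_24m"].iloc[0] == Decimal("0.00")

    def test_relax_sets_secondary_missing(self):
        out = apply_no_surgery_cost_rule(self.patient(False, False), relax=True)
        assert out.frame["secondary_15m"].iloc[0] is None

    def test_operated_patient_unchanged(self):
        before = self.patient(True, False)
        out = apply_no_surgery_cost_rule(before, relax=False)
        assert out.frame["secondary_15m"].iloc[0] is None
        assert out.frame.equals(before.frame)

    def test_crf_returner_unchanged(self):
        out = apply_no_surgery_cost_rule(self.patient(False, True), relax=False)
        assert out.frame["secondary_15m"].iloc[0] is None


class TestUnitCostTable:
    def test_negative_price_rejected(self):
        with pytest.raises(ConfigError):
            UnitCostTable({"gp_visit": -1})

    def test_csv_round_trip(self, tmp_path, unit_costs):
        path = tmp_path / "uc.csv"
        unit_costs.to_csv(path)
        back = UnitCostTable.from_csv(path)
        for item in unit_costs:
            assert back.price(item) == unit_costs.price(item)
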