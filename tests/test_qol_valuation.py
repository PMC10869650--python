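"""Valuation and QALY-AUC unit tests against independent oracles."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st_

from trialcua import (
    AdditiveMapping,
    ConfigError,
    DatasetValidationError,
    QalyOptions,
    TrajectoryError,
    UtilityTrajectory,
    full_health_days,
    qaly_auc,
    value_eq5d,
    value_iciq,
)
from trialcua.qol_valuation import EQ5D_DIMENSIONS, UtilityTariff

ALL_STATES = list(itertools.product([1, 2, 3], repeat=5))


def hand_summed_worst(tariff_csv_frame: pd.DataFrame) -> float:
    """Independent oracle: sum the coefficient CSV by hand rules."""
    table = tariff_csv_frame
    constants = table[table["level"].isna()].set_index("term")["decrement"]
    level3 = table[table["level"] == 3]["decrement"].sum()
    return 1.0 - constants["any_dysfunction"] - level3 - constants["worst_level"]


@pytest.fixture(scope="module")
def tariff_frame():
    from importlib import resources

    ref = resources.files("trialcua.data") / "uk_eq5d3l_tariff.csv"
    with resources.as_file(ref) as path:
        return pd.read_csv(path)


class TestTariff:
    def test_full_health_identity(self, tariff):
        assert value_eq5d((1, 1, 1, 1, 1), tariff) == 1.0

    def test_worst_state_hand_sum(self, tariff, tariff_frame):
        expected = hand_summed_worst(tariff_frame)
        assert value_eq5d((3, 3, 3, 3, 3), tariff) == pytest.approx(expected, abs=1e-12)
        assert value_eq5d((3, 3, 3, 3, 3), tariff) == pytest.approx(-0.594, abs=1e-9)

    def test_single_dysfunction_two_terms(self, tariff, tariff_frame):
        # 1 - any_dysfunction - mobility level-2 decrement
        constants = tariff_frame[tariff_frame["level"].isna()].set_index("term")[
            "decrement"
        ]
        mob2 = tariff_frame.query("term == 'mobility' and level == 2")[
            "decrement"
        ].iloc[0]
        expected = 1.0 - constants["any_dysfunction"] - mob2
        assert value_eq5d((2, 1, 1, 1, 1), tariff) == pytest.approx(expected, abs=1e-12)

    def test_monotone_over_all_243_states(self, tariff):
        values = {s: value_eq5d(s, tariff) for s in ALL_STATES}
        for state in ALL_STATES:
            for i in range(5):
                if state[i] < 3:
                    worse = list(state)
                    worse[i] += 1
                    assert values[tuple(worse)] <= values[state] + 1e-12

    def test_out_of_range_level_rejected(self, tariff):
        with pytest.raises(DatasetValidationError):
            value_eq5d((4, 1, 1, 1, 1), tariff)
        with pytest.raises(DatasetValidationError):
            value_eq5d((0, 1, 1, 1, 1), tariff)

    def test_non_monotone_table_rejected(self):
        decs = {(d, lv): 0.1 for d in EQ5D_DIMENSIONS for lv in (2, 3)}
        decs[("mobility", 3)] = 0.01  # below level 2
        with pytest.raises(ConfigError):
            UtilityTariff(0.08, 0.2, decs)


class TestIciqMapping:
    def test_best_pattern_is_maximum(self, iciq_mapping):
        best = {item: 1 for item in iciq_mapping.items}
        assert value_iciq(best, iciq_mapping) == iciq_mapping.max_value

    def test_toy_mapping_hand_arithmetic(self):
        mapping = AdditiveMapping({("a", 2): 0.01, ("b", 2): 0.02})
        assert value_iciq({"a": 2, "b": 2}, mapping) == pytest.approx(0.97)
        assert value_iciq({"a": 1, "b": 2}, mapping) == pytest.approx(0.98)

    def test_identical_responses_identical_utilities(self, iciq_mapping):
        resp = {item: 2 for item in iciq_mapping.items}
        assert value_iciq(resp, iciq_mapping) == value_iciq(dict(resp), iciq_mapping)

    def test_missing_item_yields_nan_not_exception(self, iciq_mapping):
        resp = {item: 1 for item in iciq_mapping.items}
        resp[iciq_mapping.items[0]] = float("nan")
        assert math.isnan(value_iciq(resp, iciq_mapping))


HORIZON = 36 * 365.25 / 12
YEARS = (365.25, 730.5)


def oracle_qaly(times, utils, surgery_day, rate, adjust):
    """Independent numeric-integration oracle: trapezoid on a grid holding
    every kink, per discount-year bucket (exact for piecewise linear)."""
    pts = [(t, min(u, 1.0)) for t, u in zip(times, utils) if not np.isnan(u)]
    if adjust and surgery_day is not None and surgery_day > pts[0][0]:
        pts = [pts[0], (surgery_day, pts[0][1])] + [p for p in pts[1:] if p[0] > surgery_day]
    xs = np.array([p[0] for p in pts])
    ys = np.array([p[1] for p in pts])
    total = 0.0
    buckets = [(0.0, YEARS[0], 1.0), (YEARS[0], YEARS[1], (1 + rate) ** -1),
               (YEARS[1], HORIZON, (1 + rate) ** -2)]
    for lo, hi, factor in buckets:
        grid = np.unique(np.concatenate([np.clip(xs, lo, hi), [lo, hi]]))
        vals = np.interp(grid, xs, ys)
        total += factor * np.trapezoid(vals, grid)
    return total / 365.25


class TestQalyAuc:
    def test_rectangle(self):
        traj = UtilityTrajectory("p", (0.0, HORIZON), (1.0, 1.0))
        assert qaly_auc(traj, QalyOptions(discount_rate=0.0)) == pytest.approx(3.0, abs=1e-12)

    def test_discounted_closed_form(self):
        traj = UtilityTrajectory("p", (0.0, HORIZON), (1.0, 1.0))
        expected = 1 + 1 / 1.035 + 1 / 1.035**2
        got = qaly_auc(traj, QalyOptions(discount_rate=0.035))
        assert got == pytest.approx(expected, abs=1e-12)
        assert round(got, 4) == 2.8997

    def test_matches_numeric_oracle_on_random_trajectories(self, rng):
        for _ in range(300):
            k = rng.integers(2, 7)
            interior = np.sort(rng.uniform(1, 1090, size=k - 2)) if k > 2 else []
            times = np.concatenate([[0.0], interior, [1096.0]])
            utils = rng.uniform(-0.3, 1.1, size=len(times))
            surgery_day = float(rng.uniform(0, 200)) if rng.random() < 0.7 else None
            adjust = bool(rng.random() < 0.5)
            traj = UtilityTrajectory("p", tuple(times), tuple(utils), surgery_day)
            got = qaly_auc(
                traj, QalyOptions(discount_rate=0.035, adjust_for_surgery_wait=adjust)
            )
            want = oracle_qaly(times, utils, surgery_day, 0.035, adjust)
            assert got == pytest.approx(want, abs=1e-9)

    def test_surgery_wait_holds_baseline_flat(self):
        # utility jumps after surgery; waiting at baseline 0.5 for 100 days
        traj = UtilityTrajectory("p", (0.0, 200.0, HORIZON), (0.5, 1.0, 1.0), 100.0)
        adjusted = qaly_auc(traj, QalyOptions(discount_rate=0.0))
        plain = qaly_auc(
            traj, QalyOptions(discount_rate=0.0, adjust_for_surgery_wait=False)
        )
        # flat-at-baseline spends longer at 0.5 than straight interpolation
        assert adjusted < plain
        assert adjusted == pytest.approx(
            oracle_qaly(traj.times, traj.utilities, 100.0, 0.0, True), abs=1e-9
        )

    def test_no_adjust_equals_plain_trapezoid(self, rng):
        times = (0.0, 456.0, 730.0, 1096.0)
        utils = tuple(rng.uniform(0, 1, size=4))
        traj = UtilityTrajectory("p", times, utils, surgery_day=120.0)
        got = qaly_auc(traj, QalyOptions(discount_rate=0.0, adjust_for_surgery_wait=False))
        want = np.trapezoid(
            np.interp(np.linspace(0, HORIZON, 200001), times, utils),
            np.linspace(0, HORIZON, 200001),
        ) / 365.25
        assert got == pytest.approx(want, abs=1e-6)

    def test_truncated_trajectory_is_missing(self):
        traj = UtilityTrajectory("p", (0.0, 456.0), (0.8, 0.9))
        assert math.isnan(qaly_auc(traj))

    def test_entirely_missing_raises(self):
        traj = UtilityTrajectory("p", (0.0, HORIZON), (float("nan"), float("nan")))
        with pytest.raises(TrajectoryError, match="impute"):
            qaly_auc(traj)

    @given(
        base=st_.floats(min_value=-0.3, max_value=1.0),
        bump=st_.floats(min_value=0.0, max_value=0.5),
        which=st_.integers(min_value=0, max_value=3),
        rate=st_.sampled_from([0.0, 0.035, 0.06]),
    )
    @settings(max_examples=60, deadline=None)
    def test_monotone_in_each_utility(self, base, bump, which, rate):
        times = (0.0, 400.0, 800.0, 1096.0)
        utils = [base, base, base, base]
        low = qaly_auc(UtilityTrajectory("p", times, tuple(utils)), QalyOptions(rate))
        utils[which] = min(base + bump, 1.0)
        high = qaly_auc(UtilityTrajectory("p", times, tuple(utils)), QalyOptions(rate))
        assert high >= low - 1e-12

    def test_discounting_strictly_decreases_late_positive_utility(self):
        traj = UtilityTrajectory("p", (0.0, 1096.0), (0.8, 0.8))
        assert qaly_auc(traj, QalyOptions(0.035)) < qaly_auc(traj, QalyOptions(0.0))

    def test_full_health_days(self):
        assert full_health_days(1.0) == 365.25
        assert full_health_days(0.005) == pytest.approx(1.82625)
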