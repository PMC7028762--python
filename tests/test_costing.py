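import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from psycea.costing import (
    UnknownServiceItemError,
    add_counseling_fee,
    aggregate_costs,
    annualize_pre,
    cost_records,
    impute_cost_locf,
    per_client_window_costs,
)

from conftest import make_clients, make_utilization


class TestCostRecords:
    @pytest.mark.parametrize(
        "rows,expected_total",
        [
            ([("a", "pre6m", "psychiatric_inpatient_day", 5, np.nan)], 5 * 386),
            (
                [
                    ("a", "fu1", "gp_visit", 3, np.nan),
                    ("a", "fu1", "psychiatrist_visit", 2, np.nan),
                ],
                3 * 20 + 2 * 45,
            ),
            ([("a", "fu2", "day_care_day", 0, np.nan)], 0.0),
            ([("a", "pre6m", "medication", np.nan, 123.45)], 123.45),
        ],
    )
    def test_units_times_price(self, unit_costs, rows, expected_total):
        out = cost_records(make_utilization(rows), unit_costs)
        assert len(out) == len(rows)  # one output row per input row
        assert out["eur"].sum() == pytest.approx(expected_total)

    def test_category_assignment(self, unit_costs):
        out = cost_records(
            make_utilization(
                [
                    ("a", "pre6m", "psychiatric_inpatient_day", 1, np.nan),
                    ("a", "pre6m", "home_nursing_visit", 1, np.nan),
                    ("a", "pre6m", "other", np.nan, 10.0),
                ]
            ),
            unit_costs,
        )
        assert list(out["cost_item"]) == ["inpatient", "complementary", "other"]

    def test_unknown_item_names_label_and_client(self, unit_costs):
        util = make_utilization([("c42", "fu1", "acupuncture_visit", 2, np.nan)])
        with pytest.raises(UnknownServiceItemError, match="acupuncture_visit.*c42"):
            cost_records(util, unit_costs)

    def test_negative_units_rejected(self, unit_costs):
        util = make_utilization([("a", "fu1", "gp_visit", -1, np.nan)])
        with pytest.raises(ValueError, match="units"):
            cost_records(util, unit_costs)


class TestLocf:
    def _expend(self, unit_costs, rows):
        return cost_records(make_utilization(rows), unit_costs)

    def test_carry_forward_scales_by_interval_length(self, unit_costs):
        # observed through fu2; fu3 (6 months) gets fu2 (3 months) costs doubled
        exp = self._expend(
            unit_costs,
            [
                ("a", "pre6m", "gp_visit", 4, np.nan),
                ("a", "fu1", "gp_visit", 1, np.nan),
                ("a", "fu2", "gp_visit", 3, np.nan),
            ],
        )
        out = impute_cost_locf(exp, make_clients({"a": 2}))
        fu3 = out[out["period"] == "fu3"]
        assert fu3["eur"].sum() == pytest.approx(2 * 3 * 20)
        assert set(fu3["imputed"]) == {"locf"}

    def test_fully_observed_is_identity(self, unit_costs):
        exp = self._expend(
            unit_costs,
            [("a", p, "gp_visit", 1, np.nan) for p in ("pre6m", "fu1", "fu2", "fu3")],
        )
        out = impute_cost_locf(exp, make_clients({"a": 3}))
        pd.testing.assert_frame_equal(
            out.sort_values(["period"]).reset_index(drop=True),
            exp.sort_values(["period"]).reset_index(drop=True),
        )

    def test_no_followup_falls_back_to_pre_rates(self, unit_costs):
        exp = self._expend(unit_costs, [("a", "pre6m", "gp_visit", 6, np.nan)])
        out = impute_cost_locf(exp, make_clients({"a": 0}))
        # pre rate is 120 EUR / 6 months: fu1/fu2 get 60, fu3 gets 120
        by_period = out.groupby("period")["eur"].sum()
        assert by_period["fu1"] == pytest.approx(60)
        assert by_period["fu2"] == pytest.approx(60)
        assert by_period["fu3"] == pytest.approx(120)
        assert set(out.loc[out["period"] != "pre6m", "imputed"]) == {"pre_rate"}

    def test_idempotent(self, unit_costs):
        exp = self._expend(
            unit_costs,
            [("a", "pre6m", "gp_visit", 2, np.nan), ("a", "fu1", "day_care_day", 3, np.nan),
             ("b", "pre6m", "medication", np.nan, 50.0)],
        )
        clients = make_clients({"a": 1, "b": 0})
        once = impute_cost_locf(exp, clients)
        twice = impute_cost_locf(once, clients)
        key = ["client_id", "period", "cost_item", "imputed"]
        pd.testing.assert_frame_equal(
            once.sort_values(key).reset_index(drop=True),
            twice.sort_values(key).reset_index(drop=True),
        )

    def test_complete_cohort_totals_unchanged(self, unit_costs):
        exp = self._expend(
            unit_costs,
            [("a", p, "psychiatrist_visit", 2, np.nan) for p in ("pre6m", "fu1", "fu2", "fu3")]
            + [("b", p, "medication", np.nan, 10.0) for p in ("pre6m", "fu1", "fu2", "fu3")],
        )
        out = impute_cost_locf(exp, make_clients({"a": 3, "b": 3}))
        assert out["eur"].sum() == exp["eur"].sum()


def test_annualize_pre_doubles():
    assert annualize_pre(2916) == 5832
    assert annualize_pre(0.0) == 0.0
    assert annualize_pre(247_842.0) == 495_684.0
    pd.testing.assert_series_equal(
        annualize_pre(pd.Series([1.5, 2.0])), pd.Series([3.0, 4.0])
    )


class TestCounselingFee:
    def test_flat_fee_per_client(self, unit_costs):
        exp = cost_records(
            make_utilization([("c1", "fu1", "gp_visit", 1, np.nan)]), unit_costs
        )
        ids = [f"c{i}" for i in range(1, 86)]
        out = add_counseling_fee(exp, ids, 100.0)
        fee_rows = out[out["cost_item"] == "counseling"]
        assert len(fee_rows) == 85
        assert fee_rows["eur"].sum() == 8500.0

    def test_single_client_and_zero_fee(self, unit_costs):
        exp = cost_records(
            make_utilization([("c1", "fu1", "gp_visit", 1, np.nan)]), unit_costs
        )
        one = add_counseling_fee(exp, ["c1"], 100.0)
        assert one.loc[one["cost_item"] == "counseling", "eur"].sum() == 100.0
        zero = add_counseling_fee(exp, ["c1"], 0.0)
        assert zero["eur"].sum() == exp["eur"].sum()

    def test_negative_fee_rejected(self, unit_costs):
        with pytest.raises(ValueError, match="fee"):
            add_counseling_fee(pd.DataFrame(), ["c1"], -1.0)


def _brute_force_summary(expend, n_clients):
    """Independent per-client enumeration of the aggregation (dict arithmetic)."""
    per_client: dict[tuple[str, str], dict[str, float]] = {}
    for rec in expend.to_dict("records"):
        window = "pre12m" if rec["period"] == "pre6m" else "post12m"
        eur = rec["eur"] * (2 if window == "pre12m" else 1)
        cell = per_client.setdefault((rec["cost_item"], window), {})
        cell[rec["client_id"]] = cell.get(rec["client_id"], 0.0) + eur
    out = {}
    for (item, window), cell in per_client.items():
        totals = list(cell.values())
        users = [v for v in totals if v > 0]
        out[(item, window)] = {
            "n_users": len(users),
            "total": sum(totals),
            "per_client_mean": sum(totals) / n_clients,
            "per_user_mean": sum(totals) / len(users) if users else float("nan"),
        }
    return out


class TestAggregate:
    def test_matches_brute_force_enumeration(self, unit_costs):
        rng = np.random.default_rng(3)
        rows = []
        items = unit_costs.items + ["medication", "other"]
        for cid in ["a", "b", "c", "d", "e"]:
            for period in ("pre6m", "fu1", "fu2", "fu3"):
                for item in rng.choice(items, size=3, replace=False):
                    if item in ("medication", "other"):
                        rows.append((cid, period, item, np.nan, float(rng.integers(0, 300))))
                    else:
                        rows.append((cid, period, item, float(rng.integers(0, 8)), np.nan))
        expend = cost_records(make_utilization(rows), unit_costs)
        summary = aggregate_costs(expend, 5)
        oracle = _brute_force_summary(expend, 5)
        for (item, window), expected in oracle.items():
            row = summary.row(item, window)
            assert row["n_users"] == expected["n_users"]
            assert row["total"] == pytest.approx(expected["total"])
            assert row["per_client_mean"] == pytest.approx(expected["per_client_mean"])
            if expected["n_users"]:
                assert row["per_user_mean"] == pytest.approx(expected["per_user_mean"])

    def test_overall_total_is_exact_item_sum(self, unit_costs, calibrated_cohort):
        expend = cost_records(calibrated_cohort.utilization, unit_costs)
        summary = aggregate_costs(expend, len(calibrated_cohort.clients))
        t = summary.table
        for window in ("pre12m", "post12m"):
            items = t[(t["window"] == window) & (t["cost_item"] != "overall")]
            overall = summary.row("overall", window)["total"]
            assert overall == sum(items["total"])  # exact, before any rounding

    @settings(max_examples=20, deadline=None)
    @given(k=st.floats(min_value=0.1, max_value=10.0, allow_nan=False))
    def test_unit_cost_scaling_scales_every_summary(self, unit_costs, k):
        rows = [
            ("a", "pre6m", "psychiatrist_visit", 4, np.nan),
            ("a", "fu1", "day_care_day", 2, np.nan),
            ("b", "fu3", "gp_visit", 5, np.nan),
        ]
        base = aggregate_costs(cost_records(make_utilization(rows), unit_costs), 2)
        scaled = aggregate_costs(
            cost_records(make_utilization(rows), unit_costs.scaled(k)), 2
        )
        for col in ("per_user_mean", "per_client_mean", "total"):
            np.testing.assert_allclose(
                scaled.table[col].to_numpy(), base.table[col].to_numpy() * k
            )

    def test_ci_suppressed_for_single_user(self, unit_costs):
        rows = [
            ("a", "fu1", "day_care_day", 2, np.nan),
            ("a", "fu1", "gp_visit", 1, np.nan),
            ("b", "fu1", "gp_visit", 2, np.nan),
        ]
        summary = aggregate_costs(cost_records(make_utilization(rows), unit_costs), 2)
        single = summary.row("day_care", "post12m")
        assert single["n_users"] == 1
        assert np.isnan(single["per_user_ci_low"])  # printed "(-)"
        multi = summary.row("outpatient", "post12m")
        assert multi["per_user_ci_low"] < multi["per_user_mean"] < multi["per_user_ci_high"]

    def test_one_client_one_item(self, unit_costs):
        rows = [("a", "fu1", "gp_visit", 3, np.nan)]
        summary = aggregate_costs(cost_records(make_utilization(rows), unit_costs), 1)
        row = summary.row("outpatient", "post12m")
        assert row["per_user_mean"] == row["per_client_mean"] == row["total"] == 60.0

    def test_zero_clients_rejected(self, unit_costs):
        with pytest.raises(ValueError, match="n_clients"):
            aggregate_costs(pd.DataFrame(columns=["client_id", "period", "cost_item", "eur"]), 0)


def test_per_client_windows(unit_costs):
    rows = [
        ("a", "pre6m", "gp_visit", 5, np.nan),   # 100 EUR * 2 annualized
        ("a", "fu3", "gp_visit", 3, np.nan),     # 60 EUR
        ("b", "fu1", "medication", np.nan, 80.0),
    ]
    wide = per_client_window_costs(cost_records(make_utilization(rows), unit_costs))
    assert wide.loc["a", "pre12m_eur"] == 200.0
    assert wide.loc["a", "post12m_eur"] == 60.0
    assert wide.loc["b", "pre12m_eur"] == 0.0
    assert wide.loc["b", "post12m_eur"] == 80.0
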