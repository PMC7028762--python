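"""Service-utilization costing from a unit-cost table.

Utilization records (client × period × service item, in natural units) are
turned into expenditures by multiplying with per-unit prices; categories
without a per-unit price (medication, complementary extras, other contacts)
carry direct EUR amounts. Expenditures are completed by last-observation-
carried-forward (LOCF) imputation, the 6-month pre period is annualized ×2,
a flat counseling fee is added to the post window, and everything is
aggregated into the per-user / per-client / total reporting layout with
normal-approximation 95% confidence intervals.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .periods import (
    FOLLOWUP_PERIODS,
    PERIOD_MONTHS,
    PERIODS,
    POST_WINDOW,
    PRE_PERIOD,
    PRE_WINDOW,
    followups_after,
)

#: Categories whose utilization records carry a direct EUR amount instead of units.
DIRECT_CATEGORIES = frozenset({"medication", "complementary", "other"})

#: Canonical category display order of the cost-summary report.
CATEGORY_ORDER = (
    "inpatient",
    "day_care",
    "outpatient",
    "medication",
    "complementary",
    "other",
    "counseling",
)

Z_95 = 1.959963984540054  # two-sided 95% normal quantile


class UnknownServiceItemError(ValueError):
    """A utilization record names a service item absent from the unit-cost table."""


@dataclass(frozen=True)
class UnitCostTable:
    """Service item → EUR per natural unit, with a reporting category per item.

    ``entries`` is a DataFrame indexed by item with columns
    ``unit_label``, ``unit_cost_eur``, ``category``, ``source``.
    """

    entries: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"unit_label", "unit_cost_eur", "category", "source"}
        missing = required - set(self.entries.columns)
        if missing:
            raise ValueError(f"unit-cost table missing columns: {sorted(missing)}")
        if self.entries.index.duplicated().any():
            dupes = self.entries.index[self.entries.index.duplicated()].tolist()
            raise ValueError(f"duplicate service items in unit-cost table: {dupes}")
        if (self.entries["unit_cost_eur"] < 0).any():
            raise ValueError("unit costs must be non-negative")

    @property
    def items(self) -> list[str]:
        return list(self.entries.index)

    def unit_cost(self, item: str) -> float:
        return float(self.entries.at[item, "unit_cost_eur"])

    def category(self, item: str) -> str:
        return str(self.entries.at[item, "category"])

    def scaled(self, k: float) -> "UnitCostTable":
        """A copy with every unit cost multiplied by ``k``."""
        entries = self.entries.copy()
        entries["unit_cost_eur"] = entries["unit_cost_eur"] * k
        return UnitCostTable(entries)

    @classmethod
    def from_csv(cls, path: str | Path) -> "UnitCostTable":
        df = pd.read_csv(path, comment="#")
        return cls(df.set_index("item"))

    def to_csv(self, path: str | Path) -> None:
        self.entries.reset_index().rename(columns={"index": "item"}).to_csv(path, index=False)


def load_unit_costs(path: str | Path | None = None) -> UnitCostTable:
    """Load a unit-cost table; default is the shipped German 2015 preset."""
    if path is None:
        ref = importlib.resources.files("psycea.data") / "unit_costs_de2015.csv"
        with importlib.resources.as_file(ref) as p:
            return UnitCostTable.from_csv(p)
    return UnitCostTable.from_csv(path)


def cost_records(utilization: pd.DataFrame, costs: UnitCostTable) -> pd.DataFrame:
    """Multiply utilization by unit costs: one expenditure row per input row.

    ``utilization`` columns: ``client_id``, ``period``, ``service_item``,
    ``units`` (NaN for direct-amount categories), ``amount_eur`` (NaN for
    tabled items). Output columns: ``client_id``, ``period``, ``cost_item``
    (the reporting category), ``service_item``, ``eur``, ``imputed``.
    """
    util = utilization.copy()
    if "amount_eur" not in util.columns:
        util["amount_eur"] = np.nan

    bad_period = ~util["period"].isin(PERIODS)
    if bad_period.any():
        raise ValueError(f"unknown periods: {sorted(util.loc[bad_period, 'period'].unique())}")

    is_direct = util["service_item"].isin(DIRECT_CATEGORIES)
    tabled = util.loc[~is_direct, "service_item"]
    unknown = ~tabled.isin(costs.entries.index)
    if unknown.any():
        row = util.loc[~is_direct].loc[unknown].iloc[0]
        raise UnknownServiceItemError(
            f"service item {row['service_item']!r} (client {row['client_id']!r}) "
            "is not in the unit-cost table and is not a direct-amount category"
        )

    direct_amounts = util.loc[is_direct, "amount_eur"]
    if direct_amounts.isna().any() or (direct_amounts < 0).any():
        raise ValueError("direct-amount records must carry amount_eur >= 0")
    units = util.loc[~is_direct, "units"]
    if units.isna().any() or (units < 0).any():
        raise ValueError("tabled service items must carry units >= 0")

    eur = pd.Series(np.nan, index=util.index)
    eur[is_direct] = util.loc[is_direct, "amount_eur"].astype(float)
    price = tabled.map(costs.entries["unit_cost_eur"])
    eur[~is_direct] = units.astype(float) * price.astype(float)

    category = util["service_item"].copy()
    category[~is_direct] = tabled.map(costs.entries["category"])

    return pd.DataFrame(
        {
            "client_id": util["client_id"],
            "period": util["period"],
            "cost_item": category,
            "service_item": util["service_item"],
            "eur": eur,
            "imputed": "observed",
        }
    ).reset_index(drop=True)


def impute_cost_locf(expenditures: pd.DataFrame, clients: pd.DataFrame) -> pd.DataFrame:
    """Complete missing follow-up intervals by carrying costs forward.

    For every follow-up interval after a client's last observed visit, the
    per-item costs of that client's last complete follow-up interval are
    copied forward, scaled by the ratio of interval lengths (a 3-month
    interval carried into the 6-month final interval is doubled). A client
    with no complete follow-up at all falls back to carrying the pre-period
    cost *rates* forward (flag ``pre_rate`` instead of ``locf``).

    Idempotent: previously imputed rows are dropped and re-derived, so
    applying the operation twice equals applying it once.
    """
    exp = expenditures.copy()
    if "imputed" not in exp.columns:
        exp["imputed"] = "observed"
    exp = exp[exp["imputed"] == "observed"].copy()

    last_visit = clients.set_index("client_id")["last_observed_visit"]
    imputed_blocks: list[pd.DataFrame] = []
    by_client = dict(iter(exp.groupby("client_id", sort=False)))

    for client_id, last in last_visit.items():
        missing = followups_after(int(last))
        if not missing:
            continue
        rows = by_client.get(client_id)
        if int(last) >= 1:
            source_period, flag = FOLLOWUP_PERIODS[int(last) - 1], "locf"
        else:
            source_period, flag = PRE_PERIOD, "pre_rate"
        source = (
            rows[rows["period"] == source_period]
            if rows is not None
            else exp.iloc[0:0]
        )
        for period in missing:
            if source.empty:
                continue  # zero cost in the source interval carries forward as zero
            block = source.copy()
            block["period"] = period
            block["eur"] = block["eur"] * (PERIOD_MONTHS[period] / PERIOD_MONTHS[source_period])
            block["imputed"] = flag
            imputed_blocks.append(block)

    if imputed_blocks:
        exp = pd.concat([exp, *imputed_blocks], ignore_index=True)
    return exp.reset_index(drop=True)


def annualize_pre(pre6m_values):
    """Extrapolate 6-month pre-period quantities to 12 months (×2).

    Accepts a scalar, array, Series or DataFrame of EUR quantities.
    """
    return pre6m_values * 2


def add_counseling_fee(
    expenditures: pd.DataFrame,
    client_ids,
    fee_per_client: float = 100.0,
    period: str = "fu1",
) -> pd.DataFrame:
    """Add the flat outreach-clinic counseling fee once per client (post window)."""
    if fee_per_client < 0:
        raise ValueError(f"counseling fee must be >= 0, got {fee_per_client}")
    if period not in FOLLOWUP_PERIODS:
        raise ValueError(f"counseling fee must fall in a follow-up period, got {period!r}")
    fee_rows = pd.DataFrame(
        {
            "client_id": list(client_ids),
            "period": period,
            "cost_item": "counseling",
            "service_item": "counseling_outreach_clinic",
            "eur": float(fee_per_client),
            "imputed": "observed",
        }
    )
    return pd.concat([expenditures, fee_rows], ignore_index=True)


@dataclass
class CostSummary:
    """Per-category cost report: users, per-user/per-client means with 95% CIs, totals.

    ``table`` is tidy with one row per (cost_item, window); ``differences``
    holds the post-minus-pre total per category including the overall row.
    """

    table: pd.DataFrame
    differences: pd.Series
    n_clients: int = field(default=0)

    def row(self, cost_item: str, window: str) -> pd.Series:
        t = self.table
        sel = t[(t["cost_item"] == cost_item) & (t["window"] == window)]
        if sel.empty:
            raise KeyError((cost_item, window))
        return sel.iloc[0]

    def to_csv(self, path: str | Path) -> None:
        self.table.assign(
            difference=self.table["cost_item"].map(self.differences)
        ).to_csv(path, index=False)


def _window_stats(per_client: pd.Series, n_clients: int) -> dict:
    """Summary statistics for one (category, window) from per-client totals."""
    total = float(per_client.sum())
    users = per_client[per_client > 0]
    n_users = int(len(users))
    per_client_mean = total / n_clients
    se_client = float(per_client.std(ddof=1) / np.sqrt(n_clients)) if n_clients >= 2 else np.nan
    stats = {
        "n_users": n_users,
        "per_user_mean": total / n_users if n_users else np.nan,
        "per_user_ci_low": np.nan,
        "per_user_ci_high": np.nan,
        "per_client_mean": per_client_mean,
        "per_client_ci_low": per_client_mean - Z_95 * se_client,
        "per_client_ci_high": per_client_mean + Z_95 * se_client,
        "total": total,
    }
    if n_users >= 2:  # a single user gets no interval (printed as "(-)")
        se_user = float(users.std(ddof=1) / np.sqrt(n_users))
        stats["per_user_ci_low"] = stats["per_user_mean"] - Z_95 * se_user
        stats["per_user_ci_high"] = stats["per_user_mean"] + Z_95 * se_user
    return stats


def aggregate_costs(expenditures: pd.DataFrame, n_clients: int) -> CostSummary:
    """Aggregate expenditures into the pre/post 12-month reporting layout.

    The 6-month pre period is annualized ×2 into the ``pre12m`` window; all
    follow-up intervals form ``post12m``. Per-client denominators always use
    ``n_clients`` (non-users count as zero); per-user means divide by the
    number of clients with positive cost on the category.
    """
    if n_clients <= 0:
        raise ValueError(f"n_clients must be positive, got {n_clients}")
    exp = expenditures.copy()
    exp["window"] = np.where(exp["period"] == PRE_PERIOD, PRE_WINDOW, POST_WINDOW)
    exp["eur_w"] = np.where(
        exp["window"] == PRE_WINDOW, annualize_pre(exp["eur"]), exp["eur"]
    )

    categories = [c for c in CATEGORY_ORDER if c in set(exp["cost_item"])]
    categories += [c for c in exp["cost_item"].unique() if c not in categories]
    client_ids = pd.Index(sorted(exp["client_id"].unique()))

    rows = []
    item_totals: dict[str, dict[str, float]] = {PRE_WINDOW: {}, POST_WINDOW: {}}
    per_client_overall = {
        PRE_WINDOW: pd.Series(0.0, index=client_ids),
        POST_WINDOW: pd.Series(0.0, index=client_ids),
    }
    for window in (PRE_WINDOW, POST_WINDOW):
        in_window = exp[exp["window"] == window]
        for cat in categories:
            per_client = (
                in_window[in_window["cost_item"] == cat]
                .groupby("client_id")["eur_w"]
                .sum()
                .reindex(client_ids, fill_value=0.0)
            )
            stats = _window_stats(per_client, n_clients)
            rows.append({"cost_item": cat, "window": window, **stats})
            item_totals[window][cat] = stats["total"]
            per_client_overall[window] += per_client

    for window in (PRE_WINDOW, POST_WINDOW):
        stats = _window_stats(per_client_overall[window], n_clients)
        # conservation by construction: the overall total is the item-total sum
        stats["total"] = sum(item_totals[window].values())
        stats["per_client_mean"] = stats["total"] / n_clients
        stats["per_user_mean"] = stats["total"] / stats["n_users"] if stats["n_users"] else np.nan
        rows.append({"cost_item": "overall", "window": window, **stats})

    table = pd.DataFrame(rows)
    diffs = {
        cat: item_totals[POST_WINDOW].get(cat, 0.0) - item_totals[PRE_WINDOW].get(cat, 0.0)
        for cat in categories
    }
    diffs["overall"] = sum(item_totals[POST_WINDOW].values()) - sum(
        item_totals[PRE_WINDOW].values()
    )
    return CostSummary(table=table, differences=pd.Series(diffs), n_clients=n_clients)


def per_client_window_costs(expenditures: pd.DataFrame) -> pd.DataFrame:
    """Per-client annualized pre/post totals (columns ``pre12m_eur``, ``post12m_eur``)."""
    exp = expenditures.copy()
    exp["window"] = np.where(exp["period"] == PRE_PERIOD, PRE_WINDOW, POST_WINDOW)
    exp["eur_w"] = np.where(exp["window"] == PRE_WINDOW, annualize_pre(exp["eur"]), exp["eur"])
    wide = (
        exp.pivot_table(index="client_id", columns="window", values="eur_w", aggfunc="sum")
        .reindex(columns=[PRE_WINDOW, POST_WINDOW])
        .fillna(0.0)
    )
    wide.columns = ["pre12m_eur", "post12m_eur"]
    return wide.sort_index()
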