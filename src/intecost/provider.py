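"""Provider costs per participant-visit.

Combines top-down allocation of facility cost pools (personnel, overheads,
annuitized capital) with bottom-up ingredients costing of medications and
diagnostics, then applies the arm-specific multimorbidity rules:

* integrated care, multimorbid with HIV: facility components are charged at
  the HIV-alone rate once (shared clinic);
* integrated care, HTN+DM (no HIV): the single shared-clinic rate is charged
  once (by default the costlier of the two constituent streams);
* standard vertical care, multimorbid: a "visit" is the composite of one
  visit per condition, so facility components are summed across streams.

Medication and diagnostic costs are always summed over all of a participant's
conditions in both arms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping

import numpy as np
import pandas as pd

from .conditions import ConditionProfile, PROFILE_LABELS, profile_from_label
from .errors import AllocationError, DataError
from .money import REPORT_YEAR, EconomyParameters, MoneyAmount, annuitize, to_int_dollars, inflate_to_2021
from .records import COST_COMPONENTS, FacilityCostLedger, ITEM_CLASSES

logger = logging.getLogger(__name__)

HtnDmRule = Literal["max", "mean", "htn", "dm"]

#: Provider cost component columns on every visit-cost table, in total order.
PROVIDER_COMPONENTS = ("personnel", "overhead", "capital", "medication", "diagnostic")


@dataclass(frozen=True)
class ProviderCostingOptions:
    htn_dm_rule: HtnDmRule = "max"
    capital_rate: float = 0.03
    min_months_enrolled: int = 2


@dataclass
class AllocatedFacilityRates:
    """Per-visit facility cost rates (2021 Int$) by condition stream."""

    facility_id: str
    country: str
    arm: str
    rates: dict[str, dict[str, float]]  # condition -> component -> Int$/visit

    def stream_total(self, condition: str) -> float:
        return sum(self.rates[condition].values())

    def shared_clinic_stream(self, profile: ConditionProfile, rule: HtnDmRule = "max") -> str:
        """Which stream prices an integrated visit for HTN+DM (no HIV)."""
        if rule == "htn":
            return "HTN"
        if rule == "dm":
            return "DM"
        totals = {c: self.stream_total(c) for c in ("HTN", "DM") if c in self.rates}
        if len(totals) < 2:
            missing = {"HTN", "DM"} - set(totals)
            raise AllocationError(
                f"facility {self.facility_id}: no rate for stream(s) {sorted(missing)}"
            )
        return max(totals, key=totals.get)

    def facility_components(
        self, profile: ConditionProfile, rule: HtnDmRule = "max"
    ) -> dict[str, float]:
        """Personnel/overhead/capital per visit for ``profile`` at this facility."""
        needed = [c for c in profile.conditions]
        if self.arm == "standard":
            # vertical care: one visit per condition, facility costs summed
            out = {comp: 0.0 for comp in COST_COMPONENTS}
            for cond in needed:
                if cond not in self.rates:
                    raise AllocationError(
                        f"facility {self.facility_id}: no rate for stream {cond}"
                    )
                for comp in COST_COMPONENTS:
                    out[comp] += self.rates[cond][comp]
            return out
        # integrated care: one shared clinic visit
        if not profile.is_multimorbid:
            cond = needed[0]
        elif "HIV" in profile.conditions:
            cond = "HIV"
        elif rule == "mean":
            for c in ("HTN", "DM"):
                if c not in self.rates:
                    raise AllocationError(
                        f"facility {self.facility_id}: no rate for stream {c}"
                    )
            return {
                comp: 0.5 * (self.rates["HTN"][comp] + self.rates["DM"][comp])
                for comp in COST_COMPONENTS
            }
        else:
            cond = self.shared_clinic_stream(profile, rule)
        if cond not in self.rates:
            raise AllocationError(f"facility {self.facility_id}: no rate for stream {cond}")
        return dict(self.rates[cond])


def allocate_top_down(
    ledger: FacilityCostLedger,
    economy: EconomyParameters,
    capital_rate: float = 0.03,
) -> AllocatedFacilityRates:
    """Divide a facility's monthly cost pools over its monthly patient visits.

    Capital enters the monthly pools as the annuitized annual cost divided by
    12. Pools recorded in local currency are converted to 2021 Int$ before
    division, so the returned rates are directly comparable across countries.
    """
    total_visits = ledger.total_monthly_visits
    pools = _monthly_pools_intd(ledger, economy, capital_rate)
    if total_visits <= 0:
        if any(v > 0 for v in pools.values()):
            raise AllocationError(
                f"facility {ledger.facility_id}: nonzero costs but zero patient visits"
            )
        return AllocatedFacilityRates(ledger.facility_id, ledger.country, ledger.arm, {})

    rates: dict[str, dict[str, float]] = {}
    for cond, visits in ledger.monthly_stream_visits.items():
        if visits <= 0:
            continue
        rates[cond] = {}
        for comp in COST_COMPONENTS:
            share = _stream_weight(ledger, comp, cond)
            rates[cond][comp] = pools[comp] * share / visits
    # a stream carrying pool weight but no visits has no defined rate
    for comp in COST_COMPONENTS:
        if ledger.stream_weights and comp in ledger.stream_weights:
            for cond, w in ledger.stream_weights[comp].items():
                if w > 0 and ledger.monthly_stream_visits.get(cond, 0) <= 0:
                    raise AllocationError(
                        f"facility {ledger.facility_id}: stream {cond} carries "
                        f"{comp} cost share {w} but has no visits"
                    )
    return AllocatedFacilityRates(ledger.facility_id, ledger.country, ledger.arm, rates)


def _monthly_pools_intd(
    ledger: FacilityCostLedger, economy: EconomyParameters, capital_rate: float
) -> dict[str, float]:
    annual_capital = MoneyAmount(0.0, ledger.monthly_personnel_cost.currency, REPORT_YEAR)
    for item in ledger.capital_items:
        annual_capital = annual_capital + annuitize(item.price, capital_rate, item.useful_life_years)
    return {
        "personnel": to_int_dollars(ledger.monthly_personnel_cost, economy).value,
        "overhead": to_int_dollars(ledger.monthly_overhead_cost, economy).value,
        "capital": to_int_dollars(annual_capital, economy).value / 12.0,
    }


def _stream_weight(ledger: FacilityCostLedger, component: str, cond: str) -> float:
    if ledger.stream_weights and component in ledger.stream_weights:
        return ledger.stream_weights[component].get(cond, 0.0)
    total = ledger.total_monthly_visits
    return ledger.monthly_stream_visits.get(cond, 0.0) / total if total > 0 else 0.0


def ingredients_cost(
    records: pd.DataFrame, economy: EconomyParameters
) -> tuple[float, float]:
    """Bottom-up (medication, diagnostic) cost of one visit, in 2021 Int$.

    ``records`` holds the dispensing rows of a single visit with columns
    ``item_class, units, unit_price, currency, price_year``.
    """
    if records.empty:
        return (0.0, 0.0)
    if "visit_id" in records and records["visit_id"].nunique() > 1:
        raise DataError("ingredients_cost expects records of a single visit")
    if (records["units"] < 0).any() or (records["unit_price"] < 0).any():
        bad = records[(records["units"] < 0) | (records["unit_price"] < 0)].iloc[0]
        raise DataError(
            f"dispensing record for item {bad['item_code']!r} has negative units or price"
        )
    totals = {cls: 0.0 for cls in ITEM_CLASSES}
    for row in records.itertuples(index=False):
        amount = MoneyAmount(row.units * row.unit_price, row.currency, int(row.price_year))
        if amount.currency != "INTD":
            if amount.price_year != REPORT_YEAR:
                cpi = economy.for_currency(amount.currency).cpi_index
                amount = inflate_to_2021(amount, cpi)
            amount = to_int_dollars(amount, economy)
        totals[row.item_class] += amount.value
    return (totals["medication"], totals["diagnostic"])


def provider_cost_per_visit(
    profile: ConditionProfile,
    arm: str,
    rates: AllocatedFacilityRates,
    dispensing: pd.DataFrame,
    economy: EconomyParameters,
    options: ProviderCostingOptions = ProviderCostingOptions(),
) -> dict[str, float]:
    """Full provider cost of one participant-visit (components + total, Int$)."""
    facility = rates.facility_components(profile, options.htn_dm_rule)
    medication, diagnostic = ingredients_cost(dispensing, economy)
    out = dict(facility)
    out["medication"] = medication
    out["diagnostic"] = diagnostic
    out["total"] = sum(out[c] for c in PROVIDER_COMPONENTS)
    return out


def compute_provider_costs(
    participants: pd.DataFrame,
    visits: pd.DataFrame,
    dispensing: pd.DataFrame,
    ledgers: Iterable[FacilityCostLedger],
    economy: EconomyParameters,
    options: ProviderCostingOptions = ProviderCostingOptions(),
) -> pd.DataFrame:
    """Provider cost table with one row per participant-visit.

    Participants enrolled for fewer than ``options.min_months_enrolled``
    months are excluded (costing sample definition).
    """
    eligible = participants[participants["months_enrolled"] >= options.min_months_enrolled]
    vis = visits.merge(
        eligible[["participant_id", "country", "facility_id", "arm", "profile", "facility_level"]],
        on="participant_id",
        how="inner",
    )

    rate_rows = []
    for ledger in ledgers:
        allocated = allocate_top_down(ledger, economy, options.capital_rate)
        for label in PROFILE_LABELS:
            profile = profile_from_label(label)
            try:
                comps = allocated.facility_components(profile, options.htn_dm_rule)
            except AllocationError:
                continue  # profile not served at this facility
            rate_rows.append({"facility_id": ledger.facility_id, "profile": label, **comps})
    rates_df = pd.DataFrame(rate_rows)
    vis = vis.merge(rates_df, on=["facility_id", "profile"], how="left")
    missing = vis[vis["personnel"].isna()]
    if not missing.empty:
        raise AllocationError(
            f"no allocated rates for {len(missing)} visits, e.g. facility "
            f"{missing.iloc[0]['facility_id']} profile {missing.iloc[0]['profile']}"
        )

    ing = _ingredients_by_visit(dispensing, economy)
    vis = vis.merge(ing, on="visit_id", how="left")
    vis[["medication", "diagnostic"]] = vis[["medication", "diagnostic"]].fillna(0.0)
    vis["total"] = sum(vis[c] for c in PROVIDER_COMPONENTS)
    cols = ["participant_id", "visit_id", "country", "facility_id", "facility_level",
            "arm", "profile"] + list(PROVIDER_COMPONENTS) + ["total"]
    return vis[cols]


def _ingredients_by_visit(dispensing: pd.DataFrame, economy: EconomyParameters) -> pd.DataFrame:
    """Vectorised class-wise units x price sums per visit, converted to Int$."""
    if dispensing.empty:
        return pd.DataFrame(columns=["visit_id", "medication", "diagnostic"])
    d = dispensing.copy()
    if (d["units"] < 0).any() or (d["unit_price"] < 0).any():
        bad = d[(d["units"] < 0) | (d["unit_price"] < 0)].iloc[0]
        raise DataError(
            f"dispensing record ({bad['participant_id']}, {bad['visit_id']}, "
            f"{bad['item_code']}) has negative units or price"
        )
    factor = np.ones(len(d))
    for (currency, year), idx in d.groupby(["currency", "price_year"]).groups.items():
        if currency == "INTD":
            continue
        econ = economy.for_currency(currency)
        f = 1.0
        if int(year) != REPORT_YEAR:
            f = econ.cpi_index[REPORT_YEAR] / econ.cpi_index[int(year)]
        factor[d.index.get_indexer(idx)] = f / econ.ppp_rate_2021
    d["cost_intd"] = d["units"] * d["unit_price"] * factor
    wide = (
        d.pivot_table(index="visit_id", columns="item_class", values="cost_intd", aggfunc="sum")
        .reindex(columns=list(ITEM_CLASSES), fill_value=0.0)
        .fillna(0.0)
        .reset_index()
    )
    wide.columns.name = None
    return wide


def summarize_costs(
    costs: pd.DataFrame,
    value: str = "total",
    by: tuple[str, ...] = ("country", "arm", "profile"),
) -> pd.DataFrame:
    """n / mean / sd summary per group (sample sd, n-1 denominator).

    Groups with a single observation report sd = 0 and are flagged.
    """
    if costs.empty:
        raise DataError("cannot summarise an empty cost table")
    grouped = costs.groupby(list(by), observed=True)[value]
    out = grouped.agg(n="count", mean="mean", sd=lambda s: s.std(ddof=1)).reset_index()
    out["single_obs"] = out["n"] == 1
    out.loc[out["single_obs"], "sd"] = 0.0
    return out


def summarize_provider_costs(costs: pd.DataFrame) -> pd.DataFrame:
    """Mean provider cost per participant-visit by country, arm and profile."""
    return summarize_costs(costs, value="total")
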