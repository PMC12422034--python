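"""Patient and societal costs per visit.

Questionnaire expenses are self-reported in local currency, inflated to 2021
prices and converted to Int$; travel, facility and childcare time are valued
at the country's hourly consumption (or salary) value. Standard-arm visits
for multimorbid participants are composites of one vertical visit per
condition, so their time quantities are doubled, and their medication and
other-medical expenses are replaced by the integrated-arm group mean for the
same condition profile at an equivalent facility level.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Mapping

import numpy as np
import pandas as pd

from .conditions import profile_from_label
from .errors import DataError, JoinError, ParameterError
from .money import (
    REPORT_YEAR,
    EconomyParameters,
    MoneyAmount,
    TimeValuationPolicy,
    hourly_time_value,
    inflate_to_2021,
    to_int_dollars,
)

logger = logging.getLogger(__name__)

#: Patient cost component columns, in total order.
PATIENT_COMPONENTS = (
    "medication_expense",
    "other_medical",
    "travel_expense",
    "travel_time_cost",
    "facility_time_cost",
    "caregiver_time_cost",
)


@dataclass(frozen=True)
class PatientCostOptions:
    #: also double the monetary travel expense for standard-arm multimorbid
    #: visits (a second trip implies a second fare); switchable because only
    #: time quantities are explicitly doubled in the source method.
    double_travel_expense: bool = True
    #: "two": all multimorbid standard visits double their time quantities;
    #: "n_conditions": scale by the number of conditions instead.
    time_multiplier: Literal["two", "n_conditions"] = "two"
    #: replace standard-arm medication/other-medical expenses with the
    #: integrated-arm group mean (expense-equality assumption).
    equalise_expenses: bool = True


def _visit_multiplier(profile_label: str, arm: str, options: PatientCostOptions) -> int:
    profile = profile_from_label(profile_label)
    if arm != "standard" or not profile.is_multimorbid:
        return 1
    return profile.n_conditions if options.time_multiplier == "n_conditions" else 2


def patient_cost_per_visit(
    q: Mapping,
    hourly_value: MoneyAmount,
    profile_label: str,
    arm: str,
    economy: EconomyParameters,
    options: PatientCostOptions = PatientCostOptions(),
    expense_overrides: Mapping[str, float] | None = None,
) -> dict[str, float]:
    """Cost one questionnaire record (components + total in 2021 Int$).

    ``q`` must provide the questionnaire fields plus ``currency`` and
    ``price_year``. ``hourly_value`` is the local-currency value of one hour.
    ``expense_overrides`` optionally replaces the medication/other-medical
    components with group means already expressed in Int$ (the
    expense-equality step for standard-arm records).
    """
    if hourly_value is None:
        raise ParameterError("hourly time value is required")
    currency, year = q["currency"], int(q["price_year"])
    cpi = economy.for_currency(currency).cpi_index

    def to_intd(value_local: float) -> float:
        amt = MoneyAmount(float(value_local), currency, year)
        return to_int_dollars(inflate_to_2021(amt, cpi), economy).value

    m = _visit_multiplier(profile_label, arm, options)
    hv_intd = to_int_dollars(inflate_to_2021(hourly_value, cpi), economy).value
    out = {
        "medication_expense": to_intd(q["medication_expense"]),
        "other_medical": to_intd(q["other_medical_expense"]),
        "travel_expense": to_intd(q["travel_expense"]) * (m if options.double_travel_expense else 1),
        "travel_time_cost": float(q["travel_time_h"]) * m * hv_intd,
        "facility_time_cost": float(q["facility_time_h"]) * m * hv_intd,
        "caregiver_time_cost": float(q["childcare_time_h"]) * m * hv_intd,
    }
    if expense_overrides:
        for key in ("medication_expense", "other_medical"):
            if key in expense_overrides:
                out[key] = float(expense_overrides[key])
    for key, v in out.items():
        if v < 0:
            raise DataError(f"negative patient cost component {key} for {q['participant_id']}")
    out["total"] = sum(out[k] for k in PATIENT_COMPONENTS)
    return out


def compute_patient_costs(
    questionnaires: pd.DataFrame,
    participants: pd.DataFrame,
    economy: EconomyParameters,
    policy: TimeValuationPolicy = TimeValuationPolicy(),
    options: PatientCostOptions = PatientCostOptions(),
) -> pd.DataFrame:
    """Patient cost table with one row per questionnaire record (2021 Int$)."""
    q = questionnaires.merge(
        participants[["participant_id", "country", "arm", "profile", "facility_id", "facility_level"]],
        on="participant_id",
        how="inner",
        validate="one_to_one",
    )
    if len(q) < len(questionnaires):
        raise JoinError(
            f"{len(questionnaires) - len(q)} questionnaire record(s) reference unknown participants"
        )

    hv_intd = {}
    for country in q["country"].unique():
        econ = economy.for_country(country)
        hv_local = hourly_time_value(econ, policy)
        hv_intd[country] = to_int_dollars(hv_local, economy).value
    hv = q["country"].map(hv_intd).to_numpy()

    # local-currency expenses -> 2021 Int$
    factor = np.zeros(len(q))
    for (currency, year), idx in q.groupby(["currency", "price_year"]).groups.items():
        econ = economy.for_currency(currency)
        f = 1.0
        if int(year) != REPORT_YEAR:
            f = econ.cpi_index[REPORT_YEAR] / econ.cpi_index[int(year)]
        factor[q.index.get_indexer(idx)] = f / econ.ppp_rate_2021
    med = q["medication_expense"].to_numpy() * factor
    other = q["other_medical_expense"].to_numpy() * factor
    travel = q["travel_expense"].to_numpy() * factor

    n_conds = q["profile"].map(lambda l: profile_from_label(l).n_conditions).to_numpy()
    is_multi_std = (q["arm"] == "standard").to_numpy() & (n_conds >= 2)
    m = np.where(is_multi_std, n_conds if options.time_multiplier == "n_conditions" else 2, 1)

    out = q[["participant_id", "country", "facility_id", "facility_level", "arm", "profile"]].copy()
    out["medication_expense"] = med
    out["other_medical"] = other
    out["travel_expense"] = travel * (m if options.double_travel_expense else 1)
    out["travel_time_cost"] = q["travel_time_h"].to_numpy() * m * hv
    out["facility_time_cost"] = q["facility_time_h"].to_numpy() * m * hv
    out["caregiver_time_cost"] = q["childcare_time_h"].to_numpy() * m * hv

    if options.equalise_expenses:
        _equalise_standard_expenses(out)

    out["total"] = sum(out[c] for c in PATIENT_COMPONENTS)
    return out


def _equalise_standard_expenses(costs: pd.DataFrame) -> None:
    """Replace standard-arm medication/other-medical expenses in place with
    the integrated-arm mean for the same (country, profile, facility level),
    falling back to the (country, profile) mean when no level match exists."""
    integrated = costs[costs["arm"] == "integrated"]
    for col in ("medication_expense", "other_medical"):
        by_level = integrated.groupby(["country", "profile", "facility_level"])[col].mean()
        by_profile = integrated.groupby(["country", "profile"])[col].mean()
        std = costs["arm"] == "standard"
        keys_level = pd.MultiIndex.from_frame(costs.loc[std, ["country", "profile", "facility_level"]])
        keys_profile = pd.MultiIndex.from_frame(costs.loc[std, ["country", "profile"]])
        replacement = pd.Series(by_level.reindex(keys_level).to_numpy(), index=costs.index[std])
        fallback = pd.Series(by_profile.reindex(keys_profile).to_numpy(), index=costs.index[std])
        replacement = replacement.fillna(fallback)
        unmatched = replacement.isna()
        if unmatched.any():
            logger.warning(
                "no integrated-arm expense match for %d standard-arm record(s); "
                "keeping self-reported %s", int(unmatched.sum()), col,
            )
            replacement[unmatched] = costs.loc[std, col].to_numpy()[unmatched.to_numpy()]
        costs.loc[std, col] = replacement.to_numpy()


def societal_cost_per_visit(
    provider_total: float, patient_total: float
) -> float:
    """Societal cost = provider + patient (household caregiver time is
    already inside the patient total)."""
    return provider_total + patient_total


def compute_societal_costs(
    provider_costs: pd.DataFrame, patient_costs: pd.DataFrame
) -> pd.DataFrame:
    """Societal cost per visit for the questionnaire sub-sample.

    Each questionnaire participant's provider cost per visit is their mean
    provider visit cost; participants absent from the provider costing sample
    (enrolled under two months) are dropped with a logged count.
    """
    provider_mean = (
        provider_costs.groupby("participant_id")["total"].mean().rename("provider_total")
    )
    out = patient_costs.merge(provider_mean, on="participant_id", how="inner")
    dropped = len(patient_costs) - len(out)
    if dropped:
        logger.info("dropped %d questionnaire participant(s) without provider costs", dropped)
    out = out.rename(columns={"total": "patient_total"})
    out["societal_total"] = out["provider_total"] + out["patient_total"]
    return out[
        ["participant_id", "country", "facility_id", "facility_level", "arm", "profile",
         "provider_total", "patient_total", "societal_total"]
    ]


def provider_share_of_societal(societal: pd.DataFrame) -> pd.DataFrame:
    """Per-country mean (and sd) percentage of societal costs borne by
    providers. Records with zero societal total are excluded and counted."""
    zero = societal["societal_total"] == 0
    if zero.any():
        logger.warning("excluding %d record(s) with zero societal total", int(zero.sum()))
    s = societal[~zero].copy()
    s["provider_share_pct"] = s["provider_total"] / s["societal_total"] * 100.0
    out = (
        s.groupby("country")["provider_share_pct"]
        .agg(n="count", mean="mean", sd=lambda x: x.std(ddof=1))
        .reset_index()
    )
    out.loc[out["n"] == 1, "sd"] = 0.0
    return out
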