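"""Record types exchanged between the generator and the costing stages."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

from .conditions import CONDITIONS
from .errors import DataError
from .money import MoneyAmount

ARMS = ("integrated", "standard")
COUNTRIES = ("Uganda", "Tanzania")
COST_COMPONENTS = ("personnel", "overhead", "capital")
ITEM_CLASSES = ("medication", "diagnostic")


@dataclass(frozen=True)
class CapitalItem:
    """A capital purchase to be annuitized over its useful life."""

    price: MoneyAmount
    useful_life_years: float

    def __post_init__(self) -> None:
        if self.price.value < 0:
            raise DataError(f"capital item price must be >= 0, got {self.price.value}")
        if self.useful_life_years <= 0:
            raise DataError(
                f"useful_life_years must be > 0, got {self.useful_life_years}"
            )


@dataclass
class FacilityCostLedger:
    """One facility's monthly cost pools and service volumes.

    Personnel and overhead pools are monthly recurrent costs; capital items
    are purchase prices annuitized at allocation time. ``monthly_stream_visits``
    counts visits per condition-specific clinic stream (for an integrated
    facility all streams share the same physical clinic, but volumes are still
    tracked per condition). ``stream_weights`` optionally splits each pool
    across streams; when omitted, pools are split proportionally to visits,
    which yields one uniform rate per pool.
    """

    facility_id: str
    country: str
    arm: str
    facility_level: str
    monthly_personnel_cost: MoneyAmount
    monthly_overhead_cost: MoneyAmount
    capital_items: list[CapitalItem] = field(default_factory=list)
    monthly_patient_counts: dict[str, int] = field(default_factory=dict)
    monthly_stream_visits: dict[str, float] = field(default_factory=dict)
    stream_weights: dict[str, dict[str, float]] | None = None

    def __post_init__(self) -> None:
        if self.arm not in ARMS:
            raise DataError(f"facility {self.facility_id}: unknown arm {self.arm!r}")
        for name, amount in (
            ("monthly_personnel_cost", self.monthly_personnel_cost),
            ("monthly_overhead_cost", self.monthly_overhead_cost),
        ):
            if amount.value < 0:
                raise DataError(f"facility {self.facility_id}: {name} must be >= 0")
        for profile, count in self.monthly_patient_counts.items():
            if count < 0:
                raise DataError(
                    f"facility {self.facility_id}: negative patient count for {profile}"
                )
        for stream, visits in self.monthly_stream_visits.items():
            if stream not in CONDITIONS:
                raise DataError(f"facility {self.facility_id}: unknown stream {stream!r}")
            if visits < 0:
                raise DataError(f"facility {self.facility_id}: negative visits for {stream}")

    @property
    def total_monthly_visits(self) -> float:
        return float(sum(self.monthly_stream_visits.values()))


def validate_dispensing_row(
    participant_id: str, visit_id: str, item_code: str, units: float, unit_price: float
) -> None:
    """Reject negative quantities or prices, identifying the record."""
    if units < 0 or unit_price < 0:
        raise DataError(
            f"dispensing record ({participant_id}, {visit_id}, {item_code}): "
            f"units={units}, unit_price={unit_price} must be >= 0"
        )
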