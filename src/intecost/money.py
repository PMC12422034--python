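"""Financial primitives: currency/price-year aware amounts, inflation to 2021
prices, conversion to 2021 international dollars, capital annuitization and
the valuation of participant time.

All downstream costing stages build on these operations; nothing here knows
about trial arms or condition profiles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Mapping

from .errors import CurrencyMismatchError, ParameterError, SequencingError

Currency = Literal["UGX", "TZS", "INTD"]

#: Reference price year for all reporting.
REPORT_YEAR = 2021

#: Local currency units per 2021 international dollar (World Bank PPP rates).
DEFAULT_PPP_RATES: dict[str, float] = {"UGX": 1310.6, "TZS": 890.58}

CURRENCY_OF_COUNTRY: dict[str, str] = {"Uganda": "UGX", "Tanzania": "TZS"}
COUNTRY_OF_CURRENCY: dict[str, str] = {v: k for k, v in CURRENCY_OF_COUNTRY.items()}


@dataclass(frozen=True)
class MoneyAmount:
    """A monetary value tagged with its currency and price year.

    Arithmetic is deliberately strict: amounts may only be added when both
    currency and price year agree, so unit errors fail loudly instead of
    silently mixing shillings with international dollars.
    """

    value: float
    currency: str
    price_year: int

    def __post_init__(self) -> None:
        if not math.isfinite(self.value):
            raise ValueError(f"money value must be finite, got {self.value}")
        if self.currency not in ("UGX", "TZS", "INTD"):
            raise ValueError(f"unknown currency {self.currency!r}")

    def _check_compatible(self, other: "MoneyAmount") -> None:
        if self.currency != other.currency or self.price_year != other.price_year:
            raise CurrencyMismatchError(
                f"cannot combine {self.currency}@{self.price_year} "
                f"with {other.currency}@{other.price_year}"
            )

    def __add__(self, other: "MoneyAmount") -> "MoneyAmount":
        if not isinstance(other, MoneyAmount):
            return NotImplemented
        self._check_compatible(other)
        return replace(self, value=self.value + other.value)

    def __sub__(self, other: "MoneyAmount") -> "MoneyAmount":
        if not isinstance(other, MoneyAmount):
            return NotImplemented
        self._check_compatible(other)
        return replace(self, value=self.value - other.value)

    def __mul__(self, k: float) -> "MoneyAmount":
        if isinstance(k, MoneyAmount):
            raise CurrencyMismatchError("cannot multiply two money amounts")
        return replace(self, value=self.value * float(k))

    __rmul__ = __mul__

    def __truediv__(self, k: float) -> "MoneyAmount":
        if isinstance(k, MoneyAmount):
            raise CurrencyMismatchError("cannot divide two money amounts")
        return replace(self, value=self.value / float(k))


def intd(value: float) -> MoneyAmount:
    """Shorthand for an amount in 2021 international dollars."""
    return MoneyAmount(value, "INTD", REPORT_YEAR)


@dataclass(frozen=True)
class CountryEconomy:
    """Macro-economic parameters for one country."""

    country: str
    ppp_rate_2021: float
    cpi_index: Mapping[int, float]
    monthly_per_capita_consumption: MoneyAmount
    median_monthly_salary: MoneyAmount | None = None
    che_2021: MoneyAmount | None = None
    gdp_2021: MoneyAmount | None = None

    def __post_init__(self) -> None:
        if self.ppp_rate_2021 <= 0:
            raise ParameterError(f"ppp_rate_2021 must be > 0, got {self.ppp_rate_2021}")
        for year, idx in self.cpi_index.items():
            if idx <= 0:
                raise ParameterError(f"CPI index for {year} must be > 0, got {idx}")


@dataclass(frozen=True)
class EconomyParameters:
    """Per-country economy parameters for the two trial countries."""

    countries: Mapping[str, CountryEconomy]

    def for_country(self, country: str) -> CountryEconomy:
        try:
            return self.countries[country]
        except KeyError:
            raise ParameterError(f"no economy parameters for country {country!r}") from None

    def for_currency(self, currency: str) -> CountryEconomy:
        try:
            return self.for_country(COUNTRY_OF_CURRENCY[currency])
        except KeyError:
            raise ParameterError(f"no country uses currency {currency!r}") from None


@dataclass(frozen=True)
class TimeValuationPolicy:
    """How an hour of participant (or caregiver) time is valued.

    The default divides monthly per-capita consumption by 30 days and then by
    8 working hours; variants use 22 days or the median monthly salary.
    """

    days_per_month: int = 30
    hours_per_day: int = 8
    wage_basis: Literal["consumption", "median_salary"] = "consumption"

    def __post_init__(self) -> None:
        if self.days_per_month not in (22, 30):
            raise ParameterError(f"days_per_month must be 22 or 30, got {self.days_per_month}")
        if self.hours_per_day != 8:
            raise ParameterError(f"hours_per_day is fixed at 8, got {self.hours_per_day}")
        if self.wage_basis not in ("consumption", "median_salary"):
            raise ParameterError(f"unknown wage basis {self.wage_basis!r}")


def inflate_to_2021(amount: MoneyAmount, cpi_index: Mapping[int, float]) -> MoneyAmount:
    """Rescale ``amount`` to 2021 prices using a consumer price index series."""
    if amount.price_year == REPORT_YEAR:
        return amount
    for year in (amount.price_year, REPORT_YEAR):
        if year not in cpi_index:
            raise ParameterError(f"CPI index missing year {year}")
    factor = cpi_index[REPORT_YEAR] / cpi_index[amount.price_year]
    return MoneyAmount(amount.value * factor, amount.currency, REPORT_YEAR)


def to_int_dollars(amount: MoneyAmount, params: EconomyParameters) -> MoneyAmount:
    """Convert a local-currency amount at 2021 prices into 2021 Int$ via PPP."""
    if amount.currency == "INTD":
        return amount
    if amount.price_year != REPORT_YEAR:
        raise SequencingError(
            f"amount is at {amount.price_year} prices; inflate to {REPORT_YEAR} before PPP conversion"
        )
    economy = params.for_currency(amount.currency)
    return MoneyAmount(amount.value / economy.ppp_rate_2021, "INTD", REPORT_YEAR)


def annuity_factor(rate: float, life_years: float) -> float:
    """Present value of a 1-per-year annuity over ``life_years`` at ``rate``."""
    if life_years <= 0:
        raise ParameterError(f"life_years must be > 0, got {life_years}")
    if rate < 0:
        raise ParameterError(f"rate must be >= 0, got {rate}")
    if rate == 0:
        return float(life_years)
    # -expm1(-n*log1p(r))/r is stable for rates down to the underflow limit
    return -math.expm1(-life_years * math.log1p(rate)) / rate


def annuitize(price: MoneyAmount, rate: float, life_years: float) -> MoneyAmount:
    """Equivalent annual cost of a capital purchase.

    The annual amount repays ``price`` exactly over the item's useful life at
    the given discount rate (straight-line in the zero-rate limit).
    """
    return price / annuity_factor(rate, life_years)


def hourly_time_value(
    economy: CountryEconomy,
    policy: TimeValuationPolicy = TimeValuationPolicy(),
    cpi_index: Mapping[int, float] | None = None,
) -> MoneyAmount:
    """Local-currency value of one hour of time at 2021 prices.

    Applied to all participants regardless of employment status.
    """
    if policy.wage_basis == "consumption":
        basis = economy.monthly_per_capita_consumption
    else:
        basis = economy.median_monthly_salary
        if basis is None:
            raise ParameterError(
                f"median monthly salary not available for {economy.country}"
            )
    basis_2021 = inflate_to_2021(basis, cpi_index if cpi_index is not None else economy.cpi_index)
    return basis_2021 / policy.days_per_month / policy.hours_per_day


def default_economy(
    consumption_ugx: float = 120_000.0,
    consumption_tzs: float = 60_000.0,
    salary_ugx: float = 200_000.0,
    salary_tzs: float = 120_000.0,
) -> EconomyParameters:
    """Editable default parameters for the two trial countries.

    PPP rates are the published 2021 World Bank rates; consumption and salary
    levels are placeholders for synthetic runs and should be overridden with
    national survey values for any real analysis.
    """
    flat_cpi = {y: 100.0 for y in range(2017, 2023)}
    return EconomyParameters(
        countries={
            "Uganda": CountryEconomy(
                country="Uganda",
                ppp_rate_2021=DEFAULT_PPP_RATES["UGX"],
                cpi_index=flat_cpi,
                monthly_per_capita_consumption=MoneyAmount(consumption_ugx, "UGX", REPORT_YEAR),
                median_monthly_salary=MoneyAmount(salary_ugx, "UGX", REPORT_YEAR),
                che_2021=intd(4.33e9),
                gdp_2021=intd(114.3e9),
            ),
            "Tanzania": CountryEconomy(
                country="Tanzania",
                ppp_rate_2021=DEFAULT_PPP_RATES["TZS"],
                cpi_index=flat_cpi,
                monthly_per_capita_consumption=MoneyAmount(consumption_tzs, "TZS", REPORT_YEAR),
                median_monthly_salary=MoneyAmount(salary_tzs, "TZS", REPORT_YEAR),
                che_2021=intd(6.7e9),
                gdp_2021=intd(174.0e9),
            ),
        }
    )


def economy_from_dict(raw: Mapping) -> EconomyParameters:
    """Build :class:`EconomyParameters` from a parsed ``economy.yaml`` mapping."""
    countries: dict[str, CountryEconomy] = {}
    for country, spec in raw.items():
        currency = CURRENCY_OF_COUNTRY.get(country)
        if currency is None:
            raise ParameterError(f"unknown country {country!r} in economy file")
        cpi = {int(y): float(v) for y, v in spec.get("cpi_index", {REPORT_YEAR: 100.0}).items()}

        def _local(key: str, default: float | None = None) -> MoneyAmount | None:
            if key not in spec and default is None:
                return None
            entry = spec.get(key, default)
            if isinstance(entry, Mapping):
                return MoneyAmount(float(entry["value"]), currency, int(entry.get("price_year", REPORT_YEAR)))
            return MoneyAmount(float(entry), currency, REPORT_YEAR)

        salary = _local("median_monthly_salary")
        countries[country] = CountryEconomy(
            country=country,
            ppp_rate_2021=float(spec.get("ppp_rate_2021", DEFAULT_PPP_RATES[currency])),
            cpi_index=cpi,
            monthly_per_capita_consumption=_local("monthly_per_capita_consumption", 0.0),
            median_monthly_salary=salary,
            che_2021=intd(float(spec["che_2021"])) if "che_2021" in spec else None,
            gdp_2021=intd(float(spec["gdp_2021"])) if "gdp_2021" in spec else None,
        )
    return EconomyParameters(countries=countries)
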