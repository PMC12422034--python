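"""Synthetic two-country cluster trial generator.

Produces facilities, participants, visits, dispensing records and patient
questionnaires with a fully known ground-truth cost structure, so the whole
costing pipeline can be exercised and validated without any external data.

Facilities are cluster-randomised to arms by balanced permutation within
country. Per-visit cost components are drawn from a non-negative,
right-skewed family (gamma by default, lognormal optional) parameterised by
(mean, sd); an sd of 0 collapses to the mean exactly, which the tests use as
a degenerate oracle. Facility ledgers are constructed so that top-down
allocation recovers each facility's realised stream rates exactly.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Literal, Mapping, Sequence

import logging

import numpy as np
import pandas as pd

from .conditions import CONDITIONS, PROFILE_LABELS, profile_from_label
from .errors import ConfigurationError, DataError
from .money import REPORT_YEAR, EconomyParameters, MoneyAmount, annuity_factor, default_economy
from .records import ARMS, COST_COMPONENTS, CapitalItem, FacilityCostLedger

logger = logging.getLogger(__name__)

COUNTRY_CODES = {"Uganda": "UG", "Tanzania": "TZ"}

SINGLE_LABELS = ("HIV", "HTN", "DM")
MULTI_LABELS = ("HIV+HTN", "HIV+DM", "HTN+DM", "HIV+HTN+DM")

#: Questionnaire fields drawn per (country, profile). Expenses are specified
#: on the Int$ scale and recorded in local currency; times are hours.
EXPENSE_FIELDS = ("medication_expense", "other_medical_expense", "travel_expense")
TIME_FIELDS = ("travel_time_h", "facility_time_h", "childcare_time_h")


@dataclass(frozen=True)
class Dist:
    """Mean/sd specification of one non-negative cost component."""

    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.mean < 0:
            raise ConfigurationError(f"mean must be >= 0, got {self.mean}")
        if self.sd < 0:
            raise ConfigurationError(f"sd must be >= 0, got {self.sd}")


def draw(rng: np.random.Generator, dist: Dist, size: int, family: str = "gamma") -> np.ndarray:
    """Draw ``size`` non-negative values with the requested mean and sd."""
    if size == 0:
        return np.empty(0)
    if dist.sd == 0 or dist.mean == 0:
        return np.full(size, dist.mean, dtype=float)
    if family == "gamma":
        shape = (dist.mean / dist.sd) ** 2
        scale = dist.sd**2 / dist.mean
        return rng.gamma(shape, scale, size)
    if family == "lognormal":
        sigma2 = math.log(1.0 + (dist.sd / dist.mean) ** 2)
        mu = math.log(dist.mean) - sigma2 / 2.0
        return rng.lognormal(mu, math.sqrt(sigma2), size)
    raise ConfigurationError(f"unknown distribution family {family!r}")


@dataclass
class ArmCostTargets:
    """Generating parameters for provider costs in one (country, arm) cell.

    ``facility`` holds per-visit stream rates (between-facility distribution)
    for each single condition and cost component; ``medication`` and
    ``diagnostic`` are per-visit, per-condition ingredient costs. All values
    are on the 2021 Int$ scale.
    """

    facility: dict[str, dict[str, Dist]]
    medication: dict[str, Dist]
    diagnostic: dict[str, Dist]

    def validate(self, where: str) -> None:
        for cond in CONDITIONS:
            if cond not in self.facility:
                raise ConfigurationError(f"{where}.facility missing condition {cond}")
            for comp in COST_COMPONENTS:
                if comp not in self.facility[cond]:
                    raise ConfigurationError(
                        f"{where}.facility[{cond}] missing component {comp}"
                    )
            for table, name in ((self.medication, "medication"), (self.diagnostic, "diagnostic")):
                if cond not in table:
                    raise ConfigurationError(f"{where}.{name} missing condition {cond}")


@dataclass
class CountryConfig:
    n_facilities_per_arm: int
    n_participants: int
    cost_targets: dict[str, ArmCostTargets]  # arm -> targets
    patient_targets: dict[str, dict[str, Dist]]  # profile label -> field -> Dist

    def validate(self, country: str) -> None:
        if self.n_facilities_per_arm <= 0:
            raise ConfigurationError(f"{country}.n_facilities_per_arm must be > 0")
        if self.n_participants < 0:
            raise ConfigurationError(f"{country}.n_participants must be >= 0")
        for arm in ARMS:
            if arm not in self.cost_targets:
                raise ConfigurationError(f"{country}.cost_targets missing arm {arm!r}")
            self.cost_targets[arm].validate(f"{country}.cost_targets[{arm}]")
        for label in PROFILE_LABELS:
            if label not in self.patient_targets:
                raise ConfigurationError(f"{country}.patient_targets missing profile {label}")
            for f in EXPENSE_FIELDS + TIME_FIELDS:
                if f not in self.patient_targets[label]:
                    raise ConfigurationError(
                        f"{country}.patient_targets[{label}] missing field {f}"
                    )


@dataclass
class TrialConfig:
    countries: dict[str, CountryConfig]
    multimorbidity_fraction: float = 0.2362
    single_split: dict[str, float] = field(
        default_factory=lambda: {"HIV": 0.62, "HTN": 0.28, "DM": 0.10}
    )
    multimorbid_split: dict[str, float] = field(
        default_factory=lambda: {"HIV+HTN": 0.40, "HIV+DM": 0.08, "HTN+DM": 0.40, "HIV+HTN+DM": 0.12}
    )
    subsample_fraction: float = 2708 / 6714
    annual_visit_rate: float = 12.0
    visit_rate_overrides: dict[str, float] = field(default_factory=dict)
    months_follow_up: int = 12
    short_enrolment_fraction: float = 0.02
    family: Literal["gamma", "lognormal"] = "gamma"
    capital_life_years: float = 5.0
    capital_rate: float = 0.03

    def validate(self) -> None:
        if not self.countries:
            raise ConfigurationError("countries must be nonempty")
        for country, cc in self.countries.items():
            cc.validate(country)
        for name in ("multimorbidity_fraction", "subsample_fraction", "short_enrolment_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        for name, split, labels in (
            ("single_split", self.single_split, SINGLE_LABELS),
            ("multimorbid_split", self.multimorbid_split, MULTI_LABELS),
        ):
            if any(p < 0 for p in split.values()):
                raise ConfigurationError(f"{name} has negative probability")
            if not set(split) <= set(labels):
                raise ConfigurationError(f"{name} has unknown profiles {set(split) - set(labels)}")
            if abs(sum(split.values()) - 1.0) > 1e-9:
                raise ConfigurationError(f"{name} must sum to 1")
        if self.annual_visit_rate < 0:
            raise ConfigurationError("annual_visit_rate must be >= 0")
        if self.months_follow_up <= 0:
            raise ConfigurationError("months_follow_up must be > 0")
        if self.family not in ("gamma", "lognormal"):
            raise ConfigurationError(f"family must be gamma or lognormal, got {self.family!r}")
        if self.capital_life_years <= 0:
            raise ConfigurationError("capital_life_years must be > 0")

    def visit_rate(self, label: str) -> float:
        return self.visit_rate_overrides.get(label, self.annual_visit_rate)

    def profile_probabilities(self) -> dict[str, float]:
        p_multi = self.multimorbidity_fraction
        probs = {lbl: (1 - p_multi) * p for lbl, p in self.single_split.items()}
        probs.update({lbl: p_multi * p for lbl, p in self.multimorbid_split.items()})
        return probs


@dataclass
class GroundTruth:
    """The generating parameters, with closed-form expected pipeline outputs.

    Expectations are exact when facility-rate sds are zero; with
    between-facility noise the shared-clinic "max" rule makes the HTN+DM
    integrated expectation a lower bound (expectation of a max exceeds the
    max of expectations).
    """

    seed: int
    config: TrialConfig

    def _targets(self, country: str, arm: str) -> ArmCostTargets:
        return self.config.countries[country].cost_targets[arm]

    def expected_facility_components(
        self, country: str, arm: str, profile_label: str, htn_dm_rule: str = "max"
    ) -> dict[str, float]:
        t = self._targets(country, arm)
        profile = profile_from_label(profile_label)
        conds = [c for c in CONDITIONS if c in profile.conditions]
        if arm == "standard":
            return {
                comp: sum(t.facility[c][comp].mean for c in conds) for comp in COST_COMPONENTS
            }
        if not profile.is_multimorbid:
            cond = conds[0]
        elif "HIV" in profile.conditions:
            cond = "HIV"
        else:
            if htn_dm_rule == "mean":
                return {
                    comp: 0.5 * (t.facility["HTN"][comp].mean + t.facility["DM"][comp].mean)
                    for comp in COST_COMPONENTS
                }
            if htn_dm_rule in ("htn", "dm"):
                cond = htn_dm_rule.upper()
            else:
                totals = {
                    c: sum(t.facility[c][comp].mean for comp in COST_COMPONENTS)
                    for c in ("HTN", "DM")
                }
                cond = max(totals, key=totals.get)
        return {comp: t.facility[cond][comp].mean for comp in COST_COMPONENTS}

    def expected_provider_visit_cost(
        self, country: str, arm: str, profile_label: str, htn_dm_rule: str = "max"
    ) -> float:
        t = self._targets(country, arm)
        profile = profile_from_label(profile_label)
        facility = sum(
            self.expected_facility_components(country, arm, profile_label, htn_dm_rule).values()
        )
        ingredients = sum(
            t.medication[c].mean + t.diagnostic[c].mean for c in profile.conditions
        )
        return facility + ingredients

    def expected_provider_difference(
        self, country: str, profile_labels: Sequence[str], htn_dm_rule: str = "max"
    ) -> float:
        """True standard-minus-integrated mean difference over a visit mix."""
        probs = self.config.profile_probabilities()
        weights = {
            lbl: probs[lbl] * self.config.visit_rate(lbl) for lbl in profile_labels
        }
        total = sum(weights.values())
        return sum(
            w / total * (
                self.expected_provider_visit_cost(country, "standard", lbl, htn_dm_rule)
                - self.expected_provider_visit_cost(country, "integrated", lbl, htn_dm_rule)
            )
            for lbl, w in weights.items()
        )

    def expected_patient_visit_cost(
        self,
        country: str,
        arm: str,
        profile_label: str,
        hourly_value_intd: float,
        double_travel_expense: bool = True,
        time_multiplier: int = 2,
    ) -> float:
        t = self.config.countries[country].patient_targets[profile_label]
        profile = profile_from_label(profile_label)
        m = time_multiplier if (arm == "standard" and profile.is_multimorbid) else 1
        expenses = t["medication_expense"].mean + t["other_medical_expense"].mean
        travel = t["travel_expense"].mean * (m if double_travel_expense else 1)
        hours = sum(t[f].mean for f in TIME_FIELDS)
        return expenses + travel + hours * m * hourly_value_intd

    def to_dict(self) -> dict:
        return {"seed": self.seed, "config": _config_to_dict(self.config)}


@dataclass
class TrialData:
    """All record sets of one synthetic trial plus its ground truth."""

    participants: pd.DataFrame
    facilities: pd.DataFrame
    visits: pd.DataFrame
    dispensing: pd.DataFrame
    questionnaires: pd.DataFrame
    ledgers: list[FacilityCostLedger]
    ground_truth: GroundTruth

    def write_csv(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.participants.to_csv(outdir / "participants.csv", index=False)
        self.facilities.to_csv(outdir / "facilities.csv", index=False)
        self.visits.to_csv(outdir / "visits.csv", index=False)
        self.dispensing.to_csv(outdir / "dispensing.csv", index=False)
        self.questionnaires.to_csv(outdir / "questionnaires.csv", index=False)
        ledger_rows, capital_rows = [], []
        for led in self.ledgers:
            for cond, v in led.monthly_stream_visits.items():
                ledger_rows.append(
                    {
                        "facility_id": led.facility_id,
                        "country": led.country,
                        "arm": led.arm,
                        "facility_level": led.facility_level,
                        "currency": led.monthly_personnel_cost.currency,
                        "monthly_personnel_cost": led.monthly_personnel_cost.value,
                        "monthly_overhead_cost": led.monthly_overhead_cost.value,
                        "stream": cond,
                        "monthly_stream_visits": v,
                        **{
                            f"weight_{comp}": (led.stream_weights or {}).get(comp, {}).get(cond, np.nan)
                            for comp in COST_COMPONENTS
                        },
                    }
                )
            for i, item in enumerate(led.capital_items):
                capital_rows.append(
                    {
                        "facility_id": led.facility_id,
                        "item_index": i,
                        "price": item.price.value,
                        "currency": item.price.currency,
                        "price_year": item.price.price_year,
                        "useful_life_years": item.useful_life_years,
                    }
                )
        pd.DataFrame(ledger_rows).to_csv(outdir / "ledgers.csv", index=False)
        pd.DataFrame(capital_rows).to_csv(outdir / "capital_items.csv", index=False)
        with open(outdir / "ground_truth.json", "w") as fh:
            json.dump(self.ground_truth.to_dict(), fh, indent=1, sort_keys=True)


def generate_trial(
    config: TrialConfig, seed: int, economy: EconomyParameters | None = None
) -> TrialData:
    """Generate a complete synthetic trial. Identical (config, seed) pairs
    yield identical outputs."""
    config.validate()
    economy = economy if economy is not None else default_economy()
    rng = np.random.default_rng(seed)

    facilities = _make_facilities(config, rng)
    participants = _make_participants(config, facilities, rng)
    visits = _make_visits(config, participants, rng)
    facility_rates = _draw_facility_rates(config, facilities, rng)
    dispensing = _make_dispensing(config, participants, visits, economy, rng)
    ledgers = _build_ledgers(config, facilities, participants, visits, facility_rates, economy)
    questionnaires = _make_questionnaires(config, participants, economy, rng)
    return TrialData(
        participants=participants,
        facilities=facilities,
        visits=visits,
        dispensing=dispensing,
        questionnaires=questionnaires,
        ledgers=ledgers,
        ground_truth=GroundTruth(seed=seed, config=config),
    )


def _make_facilities(config: TrialConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    for country, cc in config.countries.items():
        code = COUNTRY_CODES.get(country, country[:2].upper())
        n = 2 * cc.n_facilities_per_arm
        arms = np.array(["integrated"] * cc.n_facilities_per_arm + ["standard"] * cc.n_facilities_per_arm)
        rng.shuffle(arms)  # balanced permutation within country
        for i in range(n):
            rows.append(
                {
                    "facility_id": f"{code}-F{i:02d}",
                    "country": country,
                    "arm": arms[i],
                    "facility_level": "primary" if i % 2 == 0 else "secondary",
                }
            )
    return pd.DataFrame(rows)


def _make_participants(
    config: TrialConfig, facilities: pd.DataFrame, rng: np.random.Generator
) -> pd.DataFrame:
    probs = config.profile_probabilities()
    labels = list(probs)
    p = np.array([probs[l] for l in labels])
    frames = []
    for country, cc in config.countries.items():
        code = COUNTRY_CODES.get(country, country[:2].upper())
        fac = facilities[facilities["country"] == country].reset_index(drop=True)
        n = cc.n_participants
        fac_idx = rng.integers(0, len(fac), n)
        profile = rng.choice(labels, size=n, p=p)
        months = np.full(n, config.months_follow_up, dtype=int)
        short = rng.random(n) < config.short_enrolment_fraction
        months[short] = rng.integers(0, 2, short.sum())
        df = pd.DataFrame(
            {
                "participant_id": [f"{code}-P{i:05d}" for i in range(n)],
                "country": country,
                "facility_id": fac["facility_id"].to_numpy()[fac_idx],
                "arm": fac["arm"].to_numpy()[fac_idx],
                "facility_level": fac["facility_level"].to_numpy()[fac_idx],
                "profile": profile,
                "months_enrolled": months,
            }
        )
        # questionnaire subsample: first-k by enrolment order within facility
        df["in_questionnaire_subsample"] = False
        for fid, grp in df.groupby("facility_id"):
            k = int(round(config.subsample_fraction * len(grp)))
            df.loc[grp.index[:k], "in_questionnaire_subsample"] = True
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def _make_visits(
    config: TrialConfig, participants: pd.DataFrame, rng: np.random.Generator
) -> pd.DataFrame:
    rates = participants["profile"].map(config.visit_rate).to_numpy()
    months = participants["months_enrolled"].to_numpy()
    lam = months * rates / 12.0
    counts = rng.poisson(lam)
    counts[months >= 2] = np.maximum(counts[months >= 2], 1)  # costed participants see >= 1 visit
    pid = np.repeat(participants["participant_id"].to_numpy(), counts)
    order = np.concatenate([np.arange(c) for c in counts]) if counts.sum() else np.empty(0, dtype=int)
    return pd.DataFrame(
        {
            "participant_id": pid,
            "visit_id": [f"{p}-V{k:03d}" for p, k in zip(pid, order)],
        }
    )


def _draw_facility_rates(
    config: TrialConfig, facilities: pd.DataFrame, rng: np.random.Generator
) -> dict[str, dict[str, dict[str, float]]]:
    """facility_id -> condition -> component -> realised Int$/visit rate."""
    out: dict[str, dict[str, dict[str, float]]] = {}
    for row in facilities.itertuples(index=False):
        targets = config.countries[row.country].cost_targets[row.arm]
        out[row.facility_id] = {
            cond: {
                comp: float(draw(rng, targets.facility[cond][comp], 1, config.family)[0])
                for comp in COST_COMPONENTS
            }
            for cond in CONDITIONS
        }
    return out


def _make_dispensing(
    config: TrialConfig,
    participants: pd.DataFrame,
    visits: pd.DataFrame,
    economy: EconomyParameters,
    rng: np.random.Generator,
) -> pd.DataFrame:
    vis = visits.merge(
        participants[["participant_id", "country", "arm", "profile"]], on="participant_id"
    )
    # expand: one (medication, diagnostic) pair per condition per visit
    conds_per_label = {lbl: profile_from_label(lbl).singles() for lbl in PROFILE_LABELS}
    n_conds = vis["profile"].map(lambda l: len(conds_per_label[l])).to_numpy()
    rep = vis.loc[vis.index.repeat(n_conds)].reset_index(drop=True)
    rep["condition"] = np.concatenate(
        [[p.label for p in conds_per_label[lbl]] for lbl in vis["profile"]]
    ) if len(vis) else np.empty(0, dtype=object)

    frames = []
    for cls, prefix, table in (
        ("medication", "MED", "medication"),
        ("diagnostic", "DX", "diagnostic"),
    ):
        d = rep.copy()
        d["item_class"] = cls
        d["item_code"] = prefix + "-" + d["condition"]
        price = np.zeros(len(d))
        for (country, arm, cond), idx in d.groupby(["country", "arm", "condition"]).groups.items():
            dist = getattr(config.countries[country].cost_targets[arm], table)[cond]
            ppp = economy.for_country(country).ppp_rate_2021
            price[d.index.get_indexer(idx)] = draw(rng, dist, len(idx), config.family) * ppp
        d["units"] = 1.0
        d["unit_price"] = price
        d["currency"] = d["country"].map({"Uganda": "UGX", "Tanzania": "TZS"})
        d["price_year"] = REPORT_YEAR
        frames.append(d)
    out = pd.concat(frames, ignore_index=True)
    out = out.sort_values(["visit_id", "item_class", "item_code"], kind="stable").reset_index(drop=True)
    return out[
        ["participant_id", "visit_id", "item_code", "item_class", "units",
         "unit_price", "currency", "price_year"]
    ]


def _stream_visit_shares(profile_label: str, arm: str) -> dict[str, float]:
    """How one visit of ``profile`` is attributed to condition streams."""
    profile = profile_from_label(profile_label)
    conds = [c for c in CONDITIONS if c in profile.conditions]
    if arm == "standard":
        return {c: 1.0 for c in conds}  # composite visit: one per vertical clinic
    if "HIV" in profile.conditions or not profile.is_multimorbid:
        return {("HIV" if profile.is_multimorbid else conds[0]): 1.0}
    return {"HTN": 0.5, "DM": 0.5}  # shared integrated clinic, split for volume accounting


def _build_ledgers(
    config: TrialConfig,
    facilities: pd.DataFrame,
    participants: pd.DataFrame,
    visits: pd.DataFrame,
    facility_rates: Mapping[str, Mapping[str, Mapping[str, float]]],
    economy: EconomyParameters,
) -> list[FacilityCostLedger]:
    vis = visits.merge(participants[["participant_id", "facility_id", "profile"]], on="participant_id")
    visit_counts = vis.groupby(["facility_id", "profile"]).size()
    patient_counts = participants.groupby(["facility_id", "profile"]).size()

    ledgers = []
    for row in facilities.itertuples(index=False):
        fid = row.facility_id
        currency = "UGX" if row.country == "Uganda" else "TZS"
        ppp = economy.for_country(row.country).ppp_rate_2021
        rates = facility_rates[fid]

        stream_visits = {c: 0.0 for c in CONDITIONS}
        counts_here = visit_counts.loc[fid] if fid in visit_counts.index.get_level_values(0) else pd.Series(dtype=float)
        for label, n_visits in counts_here.items():
            for cond, share in _stream_visit_shares(label, row.arm).items():
                stream_visits[cond] += share * n_visits / config.months_follow_up
        stream_visits = {c: v for c, v in stream_visits.items() if v > 0}

        pools_intd = {
            comp: sum(rates[c][comp] * v for c, v in stream_visits.items())
            for comp in COST_COMPONENTS
        }
        weights = {
            comp: {
                c: rates[c][comp] * v / pools_intd[comp]
                for c, v in stream_visits.items()
            }
            for comp in COST_COMPONENTS
            if pools_intd[comp] > 0
        }
        capital_items = []
        if pools_intd["capital"] > 0:
            af = annuity_factor(config.capital_rate, config.capital_life_years)
            price_local = pools_intd["capital"] * 12.0 * af * ppp
            capital_items.append(
                CapitalItem(
                    price=MoneyAmount(price_local, currency, REPORT_YEAR),
                    useful_life_years=config.capital_life_years,
                )
            )
        profile_counts = (
            patient_counts.loc[fid].to_dict()
            if fid in patient_counts.index.get_level_values(0)
            else {}
        )
        ledgers.append(
            FacilityCostLedger(
                facility_id=fid,
                country=row.country,
                arm=row.arm,
                facility_level=row.facility_level,
                monthly_personnel_cost=MoneyAmount(pools_intd["personnel"] * ppp, currency, REPORT_YEAR),
                monthly_overhead_cost=MoneyAmount(pools_intd["overhead"] * ppp, currency, REPORT_YEAR),
                capital_items=capital_items,
                monthly_patient_counts={k: int(v) for k, v in profile_counts.items()},
                monthly_stream_visits=stream_visits,
                stream_weights=weights,
            )
        )
    return ledgers


def _make_questionnaires(
    config: TrialConfig,
    participants: pd.DataFrame,
    economy: EconomyParameters,
    rng: np.random.Generator,
) -> pd.DataFrame:
    sub = participants[participants["in_questionnaire_subsample"]].reset_index(drop=True)
    out = pd.DataFrame(
        {
            "participant_id": sub["participant_id"],
            "visit_date": "2021-06-15",
            "currency": sub["country"].map({"Uganda": "UGX", "Tanzania": "TZS"}),
            "price_year": REPORT_YEAR,
        }
    )
    for fld in EXPENSE_FIELDS + TIME_FIELDS:
        values = np.zeros(len(sub))
        for (country, label), idx in sub.groupby(["country", "profile"]).groups.items():
            dist = config.countries[country].patient_targets[label][fld]
            v = draw(rng, dist, len(idx), config.family)
            if fld in EXPENSE_FIELDS:  # targets are Int$-scale, recorded in local currency
                v = v * economy.for_country(country).ppp_rate_2021
            values[sub.index.get_indexer(idx)] = v
        out[fld] = values
    return out


def sample_moments(
    records: pd.DataFrame,
    grouping: Sequence[str],
    value: str,
) -> pd.DataFrame:
    """(n, mean, sd) per group, with the n-1 sample sd. Groups whose values
    are all missing are omitted with a logged warning."""
    if records.empty:
        raise DataError("sample_moments requires nonempty records")
    out = (
        records.groupby(list(grouping), observed=True)[value]
        .agg(n="count", mean="mean", sd=lambda s: s.std(ddof=1))
        .reset_index()
    )
    empty = out[out["n"] == 0]
    if not empty.empty:
        logger.warning("omitting %d empty group(s) from sample_moments", len(empty))
        out = out[out["n"] > 0].reset_index(drop=True)
    out.loc[out["n"] == 1, "sd"] = 0.0
    return out


# ---------------------------------------------------------------------------
# default calibration (order-of-magnitude anchors from the trial's published
# per-visit summaries) and YAML round-trip helpers


def _facility_dist(personnel: float, overhead: float, capital: float, cv: float) -> dict[str, Dist]:
    return {
        "personnel": Dist(personnel, cv * personnel),
        "overhead": Dist(overhead, cv * overhead),
        "capital": Dist(capital, cv * capital),
    }


def _default_arm_targets(country: str, facility_cv: float, ingredient_cv: float) -> ArmCostTargets:
    if country == "Uganda":
        facility = {
            "HIV": _facility_dist(95.0, 35.0, 10.0, facility_cv),
            "HTN": _facility_dist(55.0, 20.0, 5.0, facility_cv),
            "DM": _facility_dist(40.0, 15.0, 5.0, facility_cv),
        }
        med = {"HIV": 20.0, "HTN": 20.0, "DM": 17.0}
        diag = {"HIV": 9.0, "HTN": 7.0, "DM": 7.0}
    else:
        facility = {
            "HIV": _facility_dist(90.0, 30.0, 10.0, facility_cv),
            "HTN": _facility_dist(12.0, 5.0, 2.0, facility_cv),
            "DM": _facility_dist(13.0, 5.0, 2.0, facility_cv),
        }
        med = {"HIV": 15.0, "HTN": 5.0, "DM": 6.0}
        diag = {"HIV": 7.0, "HTN": 3.0, "DM": 4.0}
    return ArmCostTargets(
        facility=facility,
        medication={c: Dist(m, ingredient_cv * m) for c, m in med.items()},
        diagnostic={c: Dist(m, ingredient_cv * m) for c, m in diag.items()},
    )


def _default_patient_targets(country: str, cv: float) -> dict[str, dict[str, Dist]]:
    scale = 1.0 if country == "Uganda" else 0.6
    base = {
        "HIV": (4.0, 1.0, 3.0),
        "HTN": (12.0, 2.0, 4.0),
        "DM": (9.0, 2.0, 3.5),
        "HIV+HTN": (9.0, 2.0, 4.0),
        "HIV+DM": (8.0, 2.0, 4.0),
        "HTN+DM": (14.0, 3.0, 4.5),
        "HIV+HTN+DM": (13.0, 3.0, 5.0),
    }
    out = {}
    for label, (med, other, travel) in base.items():
        out[label] = {
            "medication_expense": Dist(scale * med, cv * scale * med),
            "other_medical_expense": Dist(scale * other, cv * scale * other),
            "travel_expense": Dist(scale * travel, cv * scale * travel),
            "travel_time_h": Dist(1.2, 0.5),
            "facility_time_h": Dist(2.0, 0.8),
            "childcare_time_h": Dist(0.2, 0.3),
        }
    return out


def default_trial_config(
    n_participants: int = 6714,
    n_facilities_per_arm: int = 4,
    facility_cv: float = 0.12,
    ingredient_cv: float = 0.5,
    patient_cv: float = 0.6,
    **overrides,
) -> TrialConfig:
    """A two-country configuration calibrated to the published per-visit
    cost summaries (identical generating single-condition rates in both arms,
    so every between-arm contrast is driven by the multimorbidity rules)."""
    per_country = n_participants // 2
    countries = {
        country: CountryConfig(
            n_facilities_per_arm=n_facilities_per_arm,
            n_participants=per_country,
            cost_targets={
                arm: _default_arm_targets(country, facility_cv, ingredient_cv) for arm in ARMS
            },
            patient_targets=_default_patient_targets(country, patient_cv),
        )
        for country in ("Uganda", "Tanzania")
    }
    return TrialConfig(countries=countries, **overrides)


def contrast_calibrated_config(
    target_saving: float,
    n_participants: int = 500,
    n_facilities_per_arm: int = 2,
    ingredient_sd: float = 15.0,
) -> TrialConfig:
    """Single-country configuration with an exactly known multimorbid saving.

    Multimorbidity is restricted to HTN+DM (no mixture variance across
    multimorbid profiles) and facility stream rates are degenerate, so the
    true standard-minus-integrated mean provider cost difference per
    multimorbid visit equals ``target_saving`` exactly; per-visit noise comes
    from the ingredient draws. Used by the parameter-recovery and uplift
    robustness harnesses.
    """
    if target_saving < 0:
        raise ConfigurationError("target_saving must be >= 0")

    def fixed(personnel: float, overhead: float, capital: float) -> dict[str, Dist]:
        return _facility_dist(personnel, overhead, capital, cv=0.0)

    integrated_facility = {
        "HIV": fixed(95.0, 35.0, 10.0),
        "HTN": fixed(55.0, 20.0, 5.0),  # shared-clinic stream: total 80
        "DM": fixed(40.0, 15.0, 5.0),  # total 60 < 80, so HTN prices HTN+DM
    }
    # standard HTN stream matches integrated; the DM vertical visit carries
    # exactly the target saving (0.6/0.3/0.1 component split)
    standard_facility = {
        "HIV": fixed(95.0, 35.0, 10.0),
        "HTN": fixed(55.0, 20.0, 5.0),
        "DM": fixed(0.6 * target_saving, 0.3 * target_saving, 0.1 * target_saving),
    }
    med = {"HIV": Dist(20.0, ingredient_sd), "HTN": Dist(20.0, ingredient_sd), "DM": Dist(17.0, ingredient_sd)}
    diag = {"HIV": Dist(9.0, ingredient_sd / 2), "HTN": Dist(7.0, ingredient_sd / 2), "DM": Dist(7.0, ingredient_sd / 2)}
    country = CountryConfig(
        n_facilities_per_arm=n_facilities_per_arm,
        n_participants=n_participants,
        cost_targets={
            "integrated": ArmCostTargets(integrated_facility, med, diag),
            "standard": ArmCostTargets(standard_facility, med, diag),
        },
        patient_targets=_default_patient_targets("Uganda", cv=0.5),
    )
    return TrialConfig(
        countries={"Uganda": country},
        multimorbidity_fraction=0.5,
        single_split={"HTN": 1.0},
        multimorbid_split={"HTN+DM": 1.0},
        short_enrolment_fraction=0.0,
    )


def _config_to_dict(config: TrialConfig) -> dict:
    return asdict(config)


def _dist_from(obj) -> Dist:
    if isinstance(obj, Mapping):
        return Dist(float(obj["mean"]), float(obj["sd"]))
    if isinstance(obj, Sequence) and not isinstance(obj, str):
        return Dist(float(obj[0]), float(obj[1]))
    raise ConfigurationError(f"cannot parse distribution spec {obj!r}")


def trial_config_from_dict(raw: Mapping) -> TrialConfig:
    """Build a :class:`TrialConfig` from a parsed YAML mapping."""
    countries = {}
    for country, cc in raw["countries"].items():
        cost_targets = {}
        for arm, t in cc["cost_targets"].items():
            cost_targets[arm] = ArmCostTargets(
                facility={
                    cond: {comp: _dist_from(d) for comp, d in comps.items()}
                    for cond, comps in t["facility"].items()
                },
                medication={c: _dist_from(d) for c, d in t["medication"].items()},
                diagnostic={c: _dist_from(d) for c, d in t["diagnostic"].items()},
            )
        patient_targets = {
            label: {fld: _dist_from(d) for fld, d in fields.items()}
            for label, fields in cc["patient_targets"].items()
        }
        countries[country] = CountryConfig(
            n_facilities_per_arm=int(cc["n_facilities_per_arm"]),
            n_participants=int(cc["n_participants"]),
            cost_targets=cost_targets,
            patient_targets=patient_targets,
        )
    scalars = {
        k: raw[k]
        for k in (
            "multimorbidity_fraction", "single_split", "multimorbid_split",
            "subsample_fraction", "annual_visit_rate", "visit_rate_overrides",
            "months_follow_up", "short_enrolment_fraction", "family",
            "capital_life_years", "capital_rate",
        )
        if k in raw
    }
    return TrialConfig(countries=countries, **scalars)
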