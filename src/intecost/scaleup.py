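"""National scale-up costing and budget impact.

Annualised mean monthly provider costs per participant are combined with
prevalence counts, condition-mix proportions and coverage levels to give
annual national totals per arm and condition profile; the integrated-minus-
standard difference is expressed as a share of current health expenditure
(CHE) and GDP. Accumulation is done in full floating precision; rounding
(half-even to whole Int$, two decimals for percentages) happens only when
reporting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping

import pandas as pd
import yaml

from .conditions import PROFILE_LABELS
from .errors import ParameterError, ScenarioError
from .records import ARMS

Coverage = Literal["current", "target"]

#: target coverage levels: 95% for HIV, 80% for diabetes and hypertension
DEFAULT_TARGET_COVERAGE = {"HIV": 0.95, "HTN": 0.80, "DM": 0.80}


@dataclass(frozen=True)
class ProfileScaleInputs:
    """Scale-up inputs for one condition profile."""

    prevalent_count: float
    proportion: float
    coverage_current: float
    coverage_target: float
    mean_monthly_cost: Mapping[str, float]  # arm -> Int$/participant/month
    mean_monthly_cost_ci: Mapping[str, tuple[float, float]] | None = None
    proportion_ci: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.prevalent_count < 0:
            raise ScenarioError(f"prevalent_count must be >= 0, got {self.prevalent_count}")
        if not 0.0 <= self.proportion <= 1.0:
            raise ScenarioError(f"proportion must be in [0, 1], got {self.proportion}")
        for name, cov in (("current", self.coverage_current), ("target", self.coverage_target)):
            if not 0.0 <= cov <= 1.0:
                raise ScenarioError(f"coverage_{name} must be in [0, 1], got {cov}")
        for arm in ARMS:
            if arm not in self.mean_monthly_cost:
                raise ScenarioError(f"mean_monthly_cost missing arm {arm!r}")

    def coverage(self, which: Coverage) -> float:
        return self.coverage_current if which == "current" else self.coverage_target


@dataclass(frozen=True)
class ScaleUpScenario:
    """Complete national scale-up inputs for one country."""

    country: str
    profiles: Mapping[str, ProfileScaleInputs]
    che: float
    gdp: float
    #: optional decompositions: groups of profiles whose proportions must sum
    #: to 1 (e.g. all profiles sharing one condition's prevalence pool)
    decomposition: Mapping[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [l for l in PROFILE_LABELS if l not in self.profiles]
        if missing:
            raise ScenarioError(f"scenario for {self.country} missing profiles {missing}")
        if self.che <= 0 or self.gdp <= 0:
            raise ParameterError("che and gdp must be > 0")
        for name, labels in self.decomposition.items():
            s = sum(self.profiles[l].proportion for l in labels)
            if abs(s - 1.0) > 1e-9:
                raise ScenarioError(
                    f"proportions in decomposition {name!r} sum to {s}, expected 1"
                )


@dataclass(frozen=True)
class ScaleUpResult:
    """Annual national provider cost totals per profile and arm (2021 Int$)."""

    country: str
    profile_totals: Mapping[str, Mapping[str, float]]  # label -> arm -> Int$/yr
    che: float | None = None
    gdp: float | None = None

    def grand_total(self, arm: str) -> float:
        return sum(t[arm] for t in self.profile_totals.values())

    def profile_difference(self, label: str) -> float:
        t = self.profile_totals[label]
        return t["integrated"] - t["standard"]

    @property
    def overall_difference(self) -> float:
        return self.grand_total("integrated") - self.grand_total("standard")

    def pct_of(self, denominator: float, arm: str | None = None) -> float:
        if denominator <= 0:
            raise ParameterError(f"denominator must be > 0, got {denominator}")
        total = self.overall_difference if arm is None else self.grand_total(arm)
        return total / denominator * 100.0

    def to_frame(self) -> pd.DataFrame:
        """Report-shaped table: whole-Int$ rows (half-even) plus % rows."""
        rows = []
        for label in self.profile_totals:
            t = self.profile_totals[label]
            rows.append(
                {
                    "row": label,
                    "integrated": round(t["integrated"]),
                    "standard": round(t["standard"]),
                    "difference": round(self.profile_difference(label)),
                }
            )
        rows.append(
            {
                "row": "Total",
                "integrated": round(self.grand_total("integrated")),
                "standard": round(self.grand_total("standard")),
                "difference": round(self.overall_difference),
            }
        )
        for name, denom in (("% of GDP", self.gdp), ("% of CHE", self.che)):
            if denom is None:
                continue
            rows.append(
                {
                    "row": name,
                    "integrated": round(self.pct_of(denom, "integrated"), 2),
                    "standard": round(self.pct_of(denom, "standard"), 2),
                    "difference": round(self.pct_of(denom), 2),
                }
            )
        return pd.DataFrame(rows)


def annual_cost_at_scale(
    mean_monthly: float, prevalent_count: float, proportion: float, coverage: float
) -> float:
    """Annualised national cost: mean monthly cost x 12 x prevalence x
    profile proportion x coverage."""
    for name, v in (
        ("mean_monthly", mean_monthly),
        ("prevalent_count", prevalent_count),
        ("proportion", proportion),
        ("coverage", coverage),
    ):
        if v < 0:
            raise ParameterError(f"{name} must be >= 0, got {v}")
    return mean_monthly * 12.0 * prevalent_count * proportion * coverage


def national_totals(scenario: ScaleUpScenario, coverage: Coverage = "current") -> ScaleUpResult:
    """Per-profile and grand annual totals for both arms of one country."""
    profile_totals = {
        label: {
            arm: annual_cost_at_scale(
                inputs.mean_monthly_cost[arm],
                inputs.prevalent_count,
                inputs.proportion,
                inputs.coverage(coverage),
            )
            for arm in ARMS
        }
        for label, inputs in scenario.profiles.items()
    }
    return ScaleUpResult(scenario.country, profile_totals, che=scenario.che, gdp=scenario.gdp)


def aggregate_profile_totals(
    country: str,
    per_profile: Mapping[str, Mapping[str, float]],
    che: float | None = None,
    gdp: float | None = None,
) -> ScaleUpResult:
    """Build a result directly from per-profile annual totals (used to
    reconcile externally published tables against the aggregation)."""
    missing = [l for l in PROFILE_LABELS if l not in per_profile]
    if missing:
        raise ScenarioError(f"per-profile totals missing {missing}")
    totals = {l: {arm: float(per_profile[l][arm]) for arm in ARMS} for l in per_profile}
    return ScaleUpResult(country, totals, che=che, gdp=gdp)


def budget_impact(result: ScaleUpResult, che: float | None = None, gdp: float | None = None) -> dict:
    """Arm totals and their difference as % of CHE and % of GDP (2 dp)."""
    che = che if che is not None else result.che
    gdp = gdp if gdp is not None else result.gdp
    if not che or not gdp or che <= 0 or gdp <= 0:
        raise ParameterError("che and gdp must be positive")
    out = {}
    for name, denom in (("gdp", gdp), ("che", che)):
        out[f"pct_of_{name}"] = {
            "integrated": round(result.pct_of(denom, "integrated"), 2),
            "standard": round(result.pct_of(denom, "standard"), 2),
            "difference": round(result.pct_of(denom), 2),
        }
    return out


def budget_impact_difference(pct_integrated: float, pct_standard: float) -> float:
    """Difference of two published arm-level percentage shares (2 dp)."""
    return round(pct_integrated - pct_standard, 2)


def scenario_from_dict(raw: Mapping) -> ScaleUpScenario:
    """Parse a scenario mapping (one country) from ``scenario.yaml``."""
    profiles = {}
    for label, p in raw["profiles"].items():
        ci = p.get("mean_monthly_cost_ci")
        profiles[label] = ProfileScaleInputs(
            prevalent_count=float(p["prevalent_count"]),
            proportion=float(p["proportion"]),
            coverage_current=float(p["coverage_current"]),
            coverage_target=float(
                p.get("coverage_target", DEFAULT_TARGET_COVERAGE.get(label.split("+")[0], 0.8))
            ),
            mean_monthly_cost={a: float(v) for a, v in p["mean_monthly_cost"].items()},
            mean_monthly_cost_ci=(
                {a: (float(v[0]), float(v[1])) for a, v in ci.items()} if ci else None
            ),
            proportion_ci=(
                tuple(float(v) for v in p["proportion_ci"]) if p.get("proportion_ci") else None
            ),
        )
    return ScaleUpScenario(
        country=raw["country"],
        profiles=profiles,
        che=float(raw["che"]),
        gdp=float(raw["gdp"]),
        decomposition={k: tuple(v) for k, v in raw.get("decomposition", {}).items()},
    )


def load_scenario(path) -> ScaleUpScenario:
    with open(path) as fh:
        return scenario_from_dict(yaml.safe_load(fh))
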